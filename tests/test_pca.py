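"""PCA: oracle equivalence, reconstruction identities, projection, biplot."""

import numpy as np
import pytest

from thzchem import biplot_vectors, pca_fit, pca_project, pca_reconstruct
from thzchem.errors import DegenerateFeatureError, GridMismatchError, InvalidArgumentError


def eig_oracle(X):
    """Brute-force covariance eigendecomposition (test-only reference)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


class TestFit:
    def test_rank_one_data(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        model = pca_fit(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.standard_normal((9, 5))
        model = pca_fit(X, 5)
        np.testing.assert_allclose(pca_reconstruct(model, 5), X, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigendecomposition_oracle(self, seed):
        X = np.random.default_rng(seed).standard_normal((10, 6))
        model = pca_fit(X, 6)
        w, v = eig_oracle(X)
        np.testing.assert_allclose(model.eigenvalues, w[:6], atol=1e-8)
        for j in range(6):
            # sign-insensitive loading comparison
            dot = abs(model.loadings[:, j] @ v[:, j])
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)
        # scores match up to the model's sign convention
        Xc = X - X.mean(axis=0)
        for j in range(6):
            ref = Xc @ v[:, j]
            got = model.scores[:, j]
            assert np.allclose(got, ref, atol=1e-8) or np.allclose(got, -ref, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        model = pca_fit(rng.standard_normal((12, 7)), 6)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-10)

    def test_explained_variance_monotone_and_sums_to_one_at_full_rank(self, rng):
        X = rng.standard_normal((10, 4))
        model = pca_fit(X, 4)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        model = pca_fit(rng.standard_normal((15, 6)), 4)
        for j in range(4):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((11, 5))
        perm = np.random.default_rng(1).permutation(11)
        m1 = pca_fit(X, 3)
        m2 = pca_fit(X[perm], 3)
        np.testing.assert_allclose(m1.loadings, m2.loadings, atol=1e-8)
        np.testing.assert_allclose(m1.scores[perm], m2.scores, atol=1e-8)

    def test_scaled_fit_rejects_constant_column(self, rng):
        X = rng.standard_normal((8, 3))
        X[:, 1] = 2.5
        with pytest.raises(DegenerateFeatureError):
            pca_fit(X, 2, scale=True)
        pca_fit(X, 2, scale=False)  # unscaled fit tolerates it

    def test_component_bounds(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(InvalidArgumentError):
            pca_fit(X, 5)


class TestProject:
    def test_self_consistency(self, rng):
        X = rng.standard_normal((10, 6))
        model = pca_fit(X, 4)
        np.testing.assert_allclose(pca_project(model, X), model.scores, atol=1e-10)

    def test_mean_row_maps_to_origin(self, rng):
        X = rng.standard_normal((10, 6))
        model = pca_fit(X, 3)
        np.testing.assert_allclose(pca_project(model, X.mean(axis=0)), 0.0, atol=1e-10)

    def test_scaled_self_consistency(self, rng):
        X = rng.standard_normal((10, 6)) * [1, 5, 10, 0.1, 2, 3]
        model = pca_fit(X, 3, scale=True)
        np.testing.assert_allclose(pca_project(model, X), model.scores, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        model = pca_fit(rng.standard_normal((6, 4)), 2)
        with pytest.raises(GridMismatchError):
            pca_project(model, np.zeros((2, 5)))

    def test_replicate_cloud_centers_on_clean_score(self, small_dataset):
        """Noisy replicates of one sample project near its clean score with
        spread far below the inter-sample spread."""
        from thzchem import SimConfig, add_noise, normalize_matrix, simulate_spectrum, snv

        ds = small_dataset
        norm = normalize_matrix(ds.spectra_matrix(), "snv")
        model = pca_fit(norm.values, 2)
        cfg = ds.config
        row = ds.descriptors.iloc[0]
        clean, _ = simulate_spectrum(row, cfg, seed=123)
        clean_score = pca_project(model, snv(clean.absorbance))
        reps = np.vstack(
            [snv(add_noise(clean, cfg, seed=1000 + r).absorbance) for r in range(5)]
        )
        rep_scores = pca_project(model, reps)
        cloud_spread = np.linalg.norm(rep_scores - clean_score, axis=1).max()
        inter = np.linalg.norm(model.scores - model.scores.mean(0), axis=1).mean()
        assert cloud_spread < 0.5 * inter


class TestReconstruct:
    def test_error_non_increasing_in_k(self, rng):
        X = rng.standard_normal((12, 8))
        model = pca_fit(X, 8)
        errs = [np.linalg.norm(X - pca_reconstruct(model, k)) for k in range(1, 9)]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))

    def test_eckart_young_identity(self, rng):
        """Squared Frobenius error at k equals the discarded eigenvalue mass."""
        X = rng.standard_normal((12, 8))
        model = pca_fit(X, 8)
        n = X.shape[0]
        total = ((X - X.mean(0)) ** 2).sum()
        for k in range(1, 9):
            err = np.linalg.norm(X - pca_reconstruct(model, k)) ** 2
            expected = total - model.eigenvalues[:k].sum() * (n - 1)
            np.testing.assert_allclose(err, expected, atol=1e-8)

    def test_k_out_of_range(self, rng):
        model = pca_fit(rng.standard_normal((6, 4)), 3)
        with pytest.raises(InvalidArgumentError):
            pca_reconstruct(model, 0)
        with pytest.raises(InvalidArgumentError):
            pca_reconstruct(model, 4)

    def test_five_loading_reconstruction_tracks_spectra(self, small_dataset):
        """Five components reproduce SNV spectra closely (polymorph-panel use)."""
        from thzchem import normalize_matrix

        norm = normalize_matrix(small_dataset.spectra_matrix(), "snv")
        model = pca_fit(norm.values, 5)
        recon = pca_reconstruct(model, 5)
        # most variance captured: relative residual well below 50%
        rel = np.linalg.norm(norm.values - recon) / np.linalg.norm(
            norm.values - norm.values.mean(0)
        )
        assert rel < 0.7


class TestBiplot:
    def test_rank_one_arrows_collinear(self):
        t = np.linspace(0, 1, 8)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 0.001 * np.random.default_rng(0).standard_normal((8, 3))
        bi = biplot_vectors(pca_fit(X, 2))
        # all arrows nearly parallel to PC1
        assert np.all(np.abs(bi.arrows[:, 1]) < 0.05 * np.abs(bi.arrows[:, 0]).max())

    def test_dominant_uncorrelated_pair_orthogonal(self, small_dataset):
        """MP and Mr arrows are near-orthogonal, as for two independent
        dominant descriptors."""
        df = small_dataset.descriptors
        model = pca_fit(df.to_numpy(float), 2, scale=False)
        bi = biplot_vectors(model, feature_names=list(df.columns))
        mp = bi.arrows[list(df.columns).index("MP")]
        mr = bi.arrows[list(df.columns).index("Mr")]
        cos = abs(mp @ mr) / (np.linalg.norm(mp) * np.linalg.norm(mr))
        assert cos < 0.3

    def test_covariance_identity(self, rng):
        """Arrow_j equals cov(raw descriptor j, scores)/sqrt(eigenvalue)."""
        X = rng.standard_normal((20, 5)) * [10, 1, 1, 5, 1]
        model = pca_fit(X, 2)
        bi = biplot_vectors(model)
        Xc = X - X.mean(0)
        n = X.shape[0]
        for j in range(5):
            cov = Xc[:, j] @ model.scores[:, :2] / (n - 1)
            expected = cov / np.sqrt(model.eigenvalues[:2])
            np.testing.assert_allclose(bi.arrows[j], expected, atol=1e-8)

    def test_requires_two_components(self, rng):
        model = pca_fit(rng.standard_normal((6, 4)), 1)
        with pytest.raises(InvalidArgumentError):
            biplot_vectors(model)
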