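"""Distance matrices, UPGMA against a brute-force oracle, cuts, Newick."""

import numpy as np
import pytest

from thzchem import (
    DistanceMatrix,
    SpectraMatrix,
    cut_tree,
    cut_tree_k,
    distance_matrix,
    ordered_matrix,
    to_newick,
    upgma,
)
from thzchem.errors import InvalidArgumentError


def upgma_oracle(d):
    """Reference UPGMA that keeps every cross-pair leaf distance explicitly.

    Clusters are frozensets of leaf indices; at every step the pair with the
    smallest mean over all cross leaf pairs is merged (ties by lowest
    creation-index pair, mirroring the implementation's convention).
    """
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                pairs = [d[i, j] for i in clusters[a] for j in clusters[b]]
                cand = (float(np.mean(pairs)), a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((a, b, h, len(merged)))
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return merges


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [chr(65 + i) for i in range(values.shape[0])]
    return DistanceMatrix(ids, values)


class TestDistanceMatrix:
    def test_duplicate_rows_zero_distance(self):
        m = SpectraMatrix(["a", "b"], [1.0, 2.0], [[1.0, 2.0], [1.0, 2.0]])
        assert distance_matrix(m).values[0, 1] == 0.0

    def test_three_four_five(self):
        m = SpectraMatrix(["a", "b"], [1.0, 2.0], [[0.0, 0.0], [3.0, 4.0]])
        assert distance_matrix(m).values[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.standard_normal((8, 20))
        m = SpectraMatrix([f"s{i}" for i in range(8)], np.arange(20.0), X)
        got = distance_matrix(m).values
        for i in range(8):
            for j in range(8):
                expected = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert got[i, j] == pytest.approx(expected, abs=1e-10)


class TestUpgma:
    def test_hand_executed_three_leaves(self):
        d = _dm([[0, 1, 4], [1, 0, 5], [4, 5, 0]])
        tree = upgma(d)
        (a1, b1, h1, s1), (a2, b2, h2, s2) = tree.merges
        assert (a1, b1, h1, s1) == (0, 1, 1.0, 2)
        assert (a2, b2, s2) == (2, 3, 3)
        assert h2 == pytest.approx(4.5)

    def test_two_leaves(self):
        tree = upgma(_dm([[0, 3.2], [3.2, 0]]))
        assert tree.merges == [(0, 1, 3.2, 2)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Random 7-leaf metric matrices: identical topology and heights."""
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = upgma(_dm(d))
        expected = upgma_oracle(d)
        assert len(tree.merges) == len(expected)
        for got, exp in zip(tree.merges, expected):
            assert got[0] == exp[0] and got[1] == exp[1] and got[3] == exp[3]
            assert got[2] == pytest.approx(exp[2], abs=1e-10)

    def test_heights_non_decreasing(self, rng):
        pts = rng.standard_normal((10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = upgma(_dm(d, [f"s{i}" for i in range(10)]))
        heights = [m[2] for m in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_leaf_order_is_permutation(self, rng):
        pts = rng.standard_normal((9, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = upgma(_dm(d, [f"s{i}" for i in range(9)]))
        assert sorted(tree.leaf_order) == list(range(9))

    def test_matches_scipy_average_linkage(self, rng):
        """Cross-check against scipy's average-linkage merge heights."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        pts = rng.standard_normal((12, 5))
        Z = linkage(pdist(pts), method="average")
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = upgma(_dm(d, [f"s{i}" for i in range(12)]))
        np.testing.assert_allclose([m[2] for m in tree.merges], Z[:, 2], atol=1e-8)


class TestCutTree:
    def _tree(self):
        return upgma(_dm([[0, 1, 4], [1, 0, 5], [4, 5, 0]]))

    def test_cut_at_root_single_cluster(self):
        labels = cut_tree(self._tree(), 10.0)
        assert set(labels.values()) == {1}

    def test_cut_below_first_merge_singletons(self):
        labels = cut_tree(self._tree(), 0.5)
        assert sorted(labels.values()) == [1, 2, 3]

    def test_three_separated_peak_groups_recovered(self):
        """Spectra with band centers near 35, 55 and 72 cm^-1 split into the
        three generating groups at an intermediate cut height."""
        import pandas as pd

        from thzchem import SimConfig, normalize_matrix, simulate_spectrum, add_noise
        from thzchem.preprocessing import SpectraMatrix

        cfg = SimConfig(
            peaks_per_sample=(1, 1),
            peak_width_range=(3.0, 3.0),
            mp_link_strength=1.0,
            n_points=401,
        )
        # melting points mapped by the affine link onto the three band centers
        groups = {35.0: 87.5, 55.0: 158.9, 72.0: 219.6}
        spectra, truth_labels = [], {}
        i = 0
        for g, (center, mp) in enumerate(groups.items()):
            for rep in range(4):
                sid = f"g{g}r{rep}"
                row = pd.Series({"MP": mp + 2.0 * rep}, name=sid)
                clean, _ = simulate_spectrum(row, cfg, seed=i)
                spectra.append(add_noise(clean, cfg, seed=1000 + i))
                truth_labels[sid] = g
                i += 1
        m = normalize_matrix(SpectraMatrix.from_spectra(spectra), "snv")
        tree = upgma(distance_matrix(m))
        heights = [mg[2] for mg in tree.merges]
        cut = 0.5 * (heights[-3] + heights[-2])  # between 4-cluster and 3-cluster merges
        labels = cut_tree(tree, cut)
        assert len(set(labels.values())) == 3
        # cluster labels refine the generating groups exactly
        for sid_a, la in labels.items():
            for sid_b, lb in labels.items():
                assert (la == lb) == (truth_labels[sid_a] == truth_labels[sid_b])

    def test_row_permutation_invariance_up_to_relabeling(self, rng):
        pts = rng.standard_normal((8, 3)) * 3
        ids = [f"s{i}" for i in range(8)]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels1 = cut_tree_k(upgma(_dm(d, ids)), 3)
        perm = np.random.default_rng(2).permutation(8)
        d2 = d[np.ix_(perm, perm)]
        labels2 = cut_tree_k(upgma(_dm(d2, [ids[i] for i in perm])), 3)
        # same partition of sample ids
        def partition(lbl):
            groups = {}
            for s, g in lbl.items():
                groups.setdefault(g, set()).add(s)
            return {frozenset(v) for v in groups.values()}

        assert partition(labels1) == partition(labels2)


class TestNewick:
    def test_two_leaf_ultrametric(self):
        tree = upgma(_dm([[0, 1.0], [1.0, 0]]))
        assert to_newick(tree) == "(A:0.5,B:0.5);"

    def test_three_leaf_example(self):
        tree = upgma(_dm([[0, 1, 4], [1, 0, 5], [4, 5, 0]]))
        assert to_newick(tree) == "((A:0.5,B:0.5):1.75,C:2.25);"

    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_topology_and_ultrametricity(self, seed):
        import dendropy

        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(7)]
        tree = upgma(_dm(d, ids))
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(ids)
        # ultrametric: every leaf sits at root_height/2 from the root
        root_h = tree.merges[-1][2] / 2
        for leaf in parsed.leaf_node_iter():
            depth = leaf.distance_from_root()
            assert depth == pytest.approx(root_h, abs=1e-8)


class TestOrderedMatrix:
    def test_adjacent_rows_are_similar(self, small_dataset):
        """Dendrogram leaf ordering places similar spectra adjacently:
        median adjacent-pair distance below the dataset median distance."""
        from thzchem import normalize_matrix

        norm = normalize_matrix(small_dataset.spectra_matrix(), "snv")
        dm = distance_matrix(norm)
        tree = upgma(dm)
        om = ordered_matrix(norm, tree)
        adjacent = [
            np.linalg.norm(om.values[i] - om.values[i + 1])
            for i in range(len(om.sample_ids) - 1)
        ]
        iu = np.triu_indices(len(norm.sample_ids), k=1)
        assert np.median(adjacent) < np.median(dm.values[iu])
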