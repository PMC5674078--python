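"""Principal component analysis by SVD.

Covers the two PCA variants the pipeline needs: unscaled (covariance) PCA for
molecular descriptor tables, where the raw variance ordering of the
descriptors is the signal, and mean-centered PCA for SNV-normalized spectra.
Scores, orthonormal loadings, explained-variance ratios, out-of-sample
projection, k-component reconstruction and correlation-style biplot
coordinates are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFeatureError, GridMismatchError, InvalidArgumentError


@dataclass
class PcaModel:
    """A fitted PCA projection.

    ``loadings`` has one orthonormal column per component (eigenvectors of the
    covariance of the processed data); ``scores`` are the centered (and, if
    ``scaled``, autoscaled) data projected on them; ``eigenvalues`` are the
    per-component variances (n-1 denominator); ``explained_variance_ratio``
    is each eigenvalue over the total variance of the processed data.
    """

    mean: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    scaled: bool
    scale_factors: np.ndarray | None = None
    data: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class BiplotVectors:
    """Descriptor arrows and sample points in the first two components."""

    arrows: np.ndarray          # (n_features, 2): loading * sqrt(eigenvalue)
    points: np.ndarray          # (n_samples, 2): first two score columns
    feature_names: list[str] | None = None


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-|loading| entry is positive (in place)."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]


def pca_fit(data: np.ndarray, n_components: int, scale: bool = False) -> PcaModel:
    """Fit PCA on a samples x features matrix.

    Always mean-centers; autoscales columns (unit sample sd) iff ``scale``.
    Components are ordered by decreasing variance, with the sign of each
    loading column fixed so its largest-magnitude entry is positive.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("data must be a 2-D matrix")
    n, p = X.shape
    if n < 2 or p < 1:
        raise InvalidArgumentError("need >= 2 samples and >= 1 feature")
    if not 1 <= n_components <= min(n - 1, p):
        raise InvalidArgumentError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )

    mean = X.mean(axis=0)
    Xc = X - mean
    scale_factors = None
    if scale:
        scale_factors = Xc.std(axis=0, ddof=1)
        if np.any(scale_factors == 0.0):
            raise DegenerateFeatureError("constant column cannot be autoscaled")
        Xc = Xc / scale_factors

    # SVD of the centered data is numerically preferable to forming X'X.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals_all = s**2 / (n - 1)
    total_var = eigvals_all.sum()

    loadings = vt[:n_components].T.copy()
    scores = Xc @ loadings
    _fix_signs(loadings, scores)
    eigvals = eigvals_all[:n_components]
    ratio = eigvals / total_var if total_var > 0 else np.zeros_like(eigvals)
    return PcaModel(
        mean=mean,
        loadings=loadings,
        scores=scores,
        eigenvalues=eigvals,
        explained_variance_ratio=ratio,
        scaled=scale,
        scale_factors=scale_factors,
        data=X,
    )


def pca_project(model: PcaModel, new_data: np.ndarray) -> np.ndarray:
    """Project new rows into an existing model's score space."""
    Xn = np.atleast_2d(np.asarray(new_data, dtype=float))
    if Xn.shape[1] != model.mean.size:
        raise GridMismatchError(
            f"feature count {Xn.shape[1]} does not match model ({model.mean.size})"
        )
    Xc = Xn - model.mean
    if model.scaled:
        Xc = Xc / model.scale_factors
    return Xc @ model.loadings


def pca_reconstruct(model: PcaModel, k: int) -> np.ndarray:
    """Reconstruct the fitted data from the first ``k`` components."""
    if not 1 <= k <= model.n_components:
        raise InvalidArgumentError(f"k must be in [1, {model.n_components}]")
    Xc_hat = model.scores[:, :k] @ model.loadings[:, :k].T
    if model.scaled:
        Xc_hat = Xc_hat * model.scale_factors
    return model.mean + Xc_hat


def biplot_vectors(model: PcaModel, feature_names: list[str] | None = None) -> BiplotVectors:
    """Correlation-style biplot: arrow_j = loadings[j, :2] * sqrt(eigenvalues[:2])."""
    if model.n_components < 2:
        raise InvalidArgumentError("biplot requires a model with >= 2 components")
    arrows = model.loadings[:, :2] * np.sqrt(model.eigenvalues[:2])
    points = model.scores[:, :2].copy()
    return BiplotVectors(arrows=arrows, points=points, feature_names=feature_names)
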