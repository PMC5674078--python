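"""A priori / a posteriori similarity maps and their concordance.

The descriptor ("a priori") map is the first two unscaled-PCA scores of the
physicochemical descriptor table; the spectral ("a posteriori") map is the
first two scores of mean-centered PCA on SNV-normalized spectra. Concordance
between the two maps — samples that are neighbors in one map being neighbors
in the other — is quantified with a k-nearest-neighbor overlap against a
permutation null, and with the pairwise agreement of UPGMA groupings of each
map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clustering import DistanceMatrix, cut_tree_k, upgma
from .errors import InvalidArgumentError
from .pca import pca_fit
from .preprocessing import SpectraMatrix, normalize_matrix


@dataclass
class SimilarityMap:
    """Per-sample 2D coordinates (first two PC scores) with provenance."""

    sample_ids: list[str]
    coords: np.ndarray                   # (n, 2)
    source: Literal["descriptors", "spectra"]
    explained_variance_pair: tuple[float, float]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), 2):
            raise InvalidArgumentError("coords must be (n_samples, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coords must be finite")


@dataclass
class ConcordanceResult:
    """k-NN overlap between two maps with a label-permutation null."""

    knn_k: int
    per_sample_overlap: pd.Series
    mean_overlap: float
    null_mean: float
    null_q95: float
    p_value: float


def build_map(
    data: pd.DataFrame | SpectraMatrix,
    scale: bool = False,
    normalize: str = "snv",
) -> SimilarityMap:
    """First-two-component PCA map of a descriptor table or spectra matrix.

    Descriptor tables use covariance (unscaled) PCA by default so the wide
    descriptors (MP, Mr) dominate; spectra are row-normalized (SNV by
    default) and then mean-centered only.
    """
    if isinstance(data, SpectraMatrix):
        m = normalize_matrix(data, normalize)  # type: ignore[arg-type]
        ids = m.sample_ids
        X = m.values
        source: Literal["descriptors", "spectra"] = "spectra"
    else:
        ids = [str(i) for i in data.index]
        X = data.to_numpy(dtype=float)
        source = "descriptors"
    if X.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 samples to build a map")
    model = pca_fit(X, n_components=2, scale=scale)
    evr = model.explained_variance_ratio
    return SimilarityMap(
        sample_ids=list(ids),
        coords=model.scores[:, :2],
        source=source,
        explained_variance_pair=(float(evr[0]), float(evr[1])),
    )


def _knn_sets(coords: np.ndarray, k: int) -> list[frozenset[int]]:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return [frozenset(order[i, :k].tolist()) for i in range(coords.shape[0])]


def _mean_overlap(coords_a: np.ndarray, coords_b: np.ndarray, k: int) -> np.ndarray:
    nn_a = _knn_sets(coords_a, k)
    nn_b = _knn_sets(coords_b, k)
    return np.array([len(a & b) / k for a, b in zip(nn_a, nn_b)])


def knn_concordance(
    map_a: SimilarityMap,
    map_b: SimilarityMap,
    k: int = 3,
    permutations: int = 2000,
    seed: int = 0,
) -> ConcordanceResult:
    """Mean k-NN overlap between two maps with a permutation p-value.

    Neighborhoods use Euclidean distance in each map's raw score coordinates,
    so the statistic is invariant under independent isometries of either map.
    The null permutes the sample labels of ``map_b``; the p-value is
    ``(1 + #null >= observed) / (1 + permutations)``.
    """
    if map_a.sample_ids != map_b.sample_ids:
        if sorted(map_a.sample_ids) != sorted(map_b.sample_ids):
            raise InvalidArgumentError("maps must share the same sample-id set")
        # align map_b rows to map_a's order
        pos = {s: i for i, s in enumerate(map_b.sample_ids)}
        coords_b = map_b.coords[[pos[s] for s in map_a.sample_ids]]
    else:
        coords_b = map_b.coords
    n = len(map_a.sample_ids)
    if not 1 <= k < n:
        raise InvalidArgumentError("k must satisfy 1 <= k < n_samples")
    if permutations < 1:
        raise InvalidArgumentError("permutations must be >= 1")

    overlaps = _mean_overlap(map_a.coords, coords_b, k)
    observed = float(overlaps.mean())

    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for i in range(permutations):
        perm = rng.permutation(n)
        null[i] = float(_mean_overlap(map_a.coords, coords_b[perm], k).mean())
    p = (1 + int(np.sum(null >= observed))) / (1 + permutations)
    return ConcordanceResult(
        knn_k=k,
        per_sample_overlap=pd.Series(overlaps, index=map_a.sample_ids),
        mean_overlap=observed,
        null_mean=float(null.mean()),
        null_q95=float(np.quantile(null, 0.95)),
        p_value=float(p),
    )


@dataclass
class GroupConcordance:
    """Agreement of UPGMA groupings of the two maps."""

    n_groups: int
    groups_a: dict[str, int]
    groups_b: dict[str, int]
    pair_agreement: float
    majority_mapping_fraction: float


def _coords_distance(ids: list[str], coords: np.ndarray) -> DistanceMatrix:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, 0.5 * (d + d.T))


def group_concordance(
    map_a: SimilarityMap, map_b: SimilarityMap, n_groups: int = 8
) -> GroupConcordance:
    """UPGMA-group each map and measure cross-map grouping agreement.

    ``pair_agreement`` is the fraction of sample pairs classified
    concordantly (grouped together in both maps, or apart in both — the Rand
    index). ``majority_mapping_fraction`` is the fraction of samples whose
    map-a group's majority lands in a single map-b group and who follow that
    majority.
    """
    n = len(map_a.sample_ids)
    if not 2 <= n_groups < n:
        raise InvalidArgumentError("n_groups must satisfy 2 <= n_groups < n")
    if map_a.sample_ids != map_b.sample_ids:
        raise InvalidArgumentError("maps must list samples in the same order")

    ga = cut_tree_k(upgma(_coords_distance(map_a.sample_ids, map_a.coords)), n_groups)
    gb = cut_tree_k(upgma(_coords_distance(map_b.sample_ids, map_b.coords)), n_groups)

    ids = map_a.sample_ids
    la = np.array([ga[s] for s in ids])
    lb = np.array([gb[s] for s in ids])
    same_a = la[:, None] == la[None, :]
    same_b = lb[:, None] == lb[None, :]
    iu = np.triu_indices(n, k=1)
    agreement = float(np.mean(same_a[iu] == same_b[iu]))

    # majority mapping: within each map-a group, the modal map-b group
    follow = 0
    for g in np.unique(la):
        members = np.nonzero(la == g)[0]
        target_groups, counts = np.unique(lb[members], return_counts=True)
        modal = target_groups[np.argmax(counts)]
        follow += int(np.sum(lb[members] == modal))
    return GroupConcordance(
        n_groups=n_groups,
        groups_a=ga,
        groups_b=gb,
        pair_agreement=agreement,
        majority_mapping_fraction=follow / n,
    )


def descriptor_overlay(
    map_: SimilarityMap, descriptors: pd.DataFrame, descriptor: str
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Join map coordinates with one descriptor's values for overlay plots.

    Returns the joined table (sample_id, PC1, PC2, value) in map order, and
    the Spearman correlation of the descriptor with each map axis (``None``
    where the correlation is undefined, e.g. a constant descriptor).
    """
    if descriptor not in descriptors.columns:
        raise InvalidArgumentError(f"unknown descriptor {descriptor!r}")
    values = descriptors.loc[[s for s in map_.sample_ids], descriptor].to_numpy(float)
    table = pd.DataFrame(
        {
            "sample_id": map_.sample_ids,
            "PC1": map_.coords[:, 0],
            "PC2": map_.coords[:, 1],
            descriptor: values,
        }
    )
    corr: dict[str, float | None] = {}
    for axis, col in (("PC1", map_.coords[:, 0]), ("PC2", map_.coords[:, 1])):
        if np.std(values) == 0.0 or np.std(col) == 0.0:
            corr[axis] = None
        else:
            rho = spearmanr(values, col).statistic
            corr[axis] = None if np.isnan(rho) else float(rho)
    return table, corr
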