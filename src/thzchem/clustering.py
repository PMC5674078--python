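"""Euclidean spectral distances and UPGMA hierarchical clustering.

The dendrogram axis is kept in spectral-distance units: the height of each
merge is the unweighted average of all cross-pair leaf distances between the
two clusters being joined (not halved), so a horizontal cut reads directly as
a Euclidean spectral distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .preprocessing import SpectraMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise InvalidArgumentError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise InvalidArgumentError("distance matrix diagonal must be zero")


@dataclass
class LinkageTree:
    """UPGMA merge history.

    ``merges`` lists ``(cluster_a, cluster_b, height, new_size)`` in merge
    order. Leaves are clusters ``0..n-1`` in input row order; merge ``i``
    creates cluster ``n + i``. ``leaf_order`` is the display permutation of
    ``sample_ids``.
    """

    sample_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)


def distance_matrix(m: SpectraMatrix) -> DistanceMatrix:
    """Point-wise Euclidean distance between all spectrum pairs."""
    if m.values.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 spectra")
    diff = m.values[:, None, :] - m.values[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry
    return DistanceMatrix(m.sample_ids, d)


def upgma(d: DistanceMatrix) -> LinkageTree:
    """Unweighted pair-group agglomeration with arithmetic-mean linkage.

    At every step the closest pair of clusters is merged at a height equal to
    the average of all cross-pair leaf distances between them; ties are broken
    by the lexicographically lowest (cluster_a, cluster_b) index pair.
    """
    n = len(d.sample_ids)
    # active clusters: id -> (size, row of average distances to other actives)
    dist: dict[int, dict[int, float]] = {
        i: {j: float(d.values[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    while len(dist) > 1:
        best: tuple[float, int, int] | None = None
        for a in sorted(dist):
            for b in sorted(dist[a]):
                if b <= a:
                    continue
                cand = (dist[a][b], a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best  # type: ignore[misc]
        new_size = sizes[a] + sizes[b]
        merges.append((a, b, h, new_size))
        children[next_id] = (a, b)

        new_row: dict[int, float] = {}
        for k in dist:
            if k in (a, b):
                continue
            # unweighted average over all cross leaf pairs
            new_row[k] = (sizes[a] * dist[a][k] + sizes[b] * dist[b][k]) / new_size
        del dist[a], dist[b]
        for k in dist:
            dist[k].pop(a, None)
            dist[k].pop(b, None)
            dist[k][next_id] = new_row[k]
        dist[next_id] = new_row
        sizes[next_id] = new_size
        next_id += 1

    leaf_order = _leaf_order(children, next_id - 1, n)
    return LinkageTree(sample_ids=d.sample_ids, merges=merges, leaf_order=leaf_order)


def _min_leaf(children: dict[int, tuple[int, int]], node: int, n: int) -> int:
    while node >= n:
        a, b = children[node]
        node = min(_min_leaf(children, a, n), _min_leaf(children, b, n))
    return node


def _leaf_order(children: dict[int, tuple[int, int]], root: int, n: int) -> list[int]:
    """Depth-first order placing the subtree with the lowest leaf index first."""
    if root < n:
        return [root]
    a, b = children[root]
    if _min_leaf(children, a, n) > _min_leaf(children, b, n):
        a, b = b, a
    return _leaf_order(children, a, n) + _leaf_order(children, b, n)


def cut_tree(t: LinkageTree, height: float) -> dict[str, int]:
    """Cluster assignment after removing all merges higher than ``height``.

    Labels are 1..k in order of first appearance along the display leaf order.
    """
    if height < 0:
        raise InvalidArgumentError("cut height must be >= 0")
    n = t.n_leaves
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, h, _) in enumerate(t.merges):
        if h <= height:
            new = n + i
            parent[find(a)] = new
            parent[find(b)] = new

    labels: dict[str, int] = {}
    root_to_label: dict[int, int] = {}
    for leaf in t.leaf_order:
        r = find(leaf)
        if r not in root_to_label:
            root_to_label[r] = len(root_to_label) + 1
        labels[t.sample_ids[leaf]] = root_to_label[r]
    return labels


def cut_tree_k(t: LinkageTree, n_clusters: int) -> dict[str, int]:
    """Cluster assignment with exactly ``n_clusters`` groups (undo the last merges)."""
    n = t.n_leaves
    if not 1 <= n_clusters <= n:
        raise InvalidArgumentError(f"n_clusters must be in [1, {n}]")
    if n_clusters == n:
        height = -1.0  # below every merge
    else:
        height = t.merges[n - n_clusters - 1][2]
        # guard against ties at the boundary height
        if n - n_clusters < len(t.merges) and t.merges[n - n_clusters][2] <= height:
            return _cut_by_merge_count(t, n - n_clusters)
    if height < 0:
        return {t.sample_ids[i]: rank + 1 for rank, i in enumerate(t.leaf_order)}
    return cut_tree(t, height)


def _cut_by_merge_count(t: LinkageTree, n_merges: int) -> dict[str, int]:
    n = t.n_leaves
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, _) in enumerate(t.merges[:n_merges]):
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new
    labels: dict[str, int] = {}
    root_to_label: dict[int, int] = {}
    for leaf in t.leaf_order:
        r = find(leaf)
        if r not in root_to_label:
            root_to_label[r] = len(root_to_label) + 1
        labels[t.sample_ids[leaf]] = root_to_label[r]
    return labels


def to_newick(t: LinkageTree) -> str:
    """Rooted ultrametric Newick string.

    Each merge at height h places its node at depth h/2 above the leaves, so
    leaf-to-ancestor path lengths reproduce half the merge heights and the
    tree round-trips through any standard Newick parser.
    """
    n = t.n_leaves
    node_height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h, _) in enumerate(t.merges):
        node = n + i
        children[node] = (a, b)
        node_height[node] = h / 2.0

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - node_height[node]
        if node < n:
            return f"{t.sample_ids[node]}:{bl:.10g}"
        a, b = children[node]
        if _min_leaf(children, a, n) > _min_leaf(children, b, n):
            a, b = b, a
        inner = f"({render(a, node_height[node])},{render(b, node_height[node])})"
        return f"{inner}:{bl:.10g}"

    root = n + len(t.merges) - 1 if t.merges else 0
    if not t.merges:
        return f"{t.sample_ids[0]};"
    a, b = children[root]
    if _min_leaf(children, a, n) > _min_leaf(children, b, n):
        a, b = b, a
    rh = node_height[root]
    return f"({render(a, rh)},{render(b, rh)});"


def ordered_matrix(m: SpectraMatrix, t: LinkageTree) -> SpectraMatrix:
    """Reorder spectra rows by dendrogram leaf order (intensity-image export)."""
    idx = t.leaf_order
    return SpectraMatrix(
        [m.sample_ids[i] for i in idx], m.grid.copy(), m.values[idx, :]
    )
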