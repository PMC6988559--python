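"""Spatially constrained hierarchy of site pairs (Ward on fluvial distance).

The hierarchy is agglomerative under the Ward minimum-variance criterion,
computed with the Lance–Williams recurrence on squared input dissimilarities

    d²(k, i∪j) = [(n_i+n_k) d²(k,i) + (n_j+n_k) d²(k,j) − n_k d²(i,j)]
                 / (n_i + n_j + n_k).

The spatially constrained method with its spatial mixing weight fixed at 1
degenerates to plain Ward on the spatial (fluvial) matrix, which is what is
implemented: the compositional matrix plays no role in the tree.  Only
cluster memberships — not merge heights — feed the downstream scan, so the
contract is topology equivalence with any Ward-on-d² variant.  Ties are
broken by the lexicographically smallest pair of node indices, which makes
the tree deterministic; fluvial distances that violate the triangle
inequality (possible after pairing approximations) are accepted with a
logged warning, as the Ward recurrence does not require metricity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("scalescan")

__all__ = ["MergeTree", "ward_dendrogram", "cut_clusters"]


@dataclass
class MergeTree:
    """Agglomeration history: leaves 0..n−1, merge i creates node n+i."""

    labels: list[str]
    merges: list[tuple[int, int, float]]  # (left node, right node, height)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves has exactly n-1 merges")

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage array (for plotting/cross-checks)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            z[k] = [a, b, h, sizes[n + k]]
        return z

    def cut(self, K: int) -> dict[str, int]:
        """Partition the leaves into exactly K clusters.

        Cluster ids are 1..K, ordered by each cluster's smallest member
        label; the K-cut always refines the (K−1)-cut because both are
        prefixes of the same merge sequence.
        """
        n = self.n_leaves
        if not 1 <= K <= n:
            raise ValueError(f"K={K} outside 1..{n}")
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for k, (a, b, _) in enumerate(self.merges[: n - K]):
            parent[find(a)] = parent[find(b)] = n + k
        groups: dict[int, list[str]] = {}
        for i, label in enumerate(self.labels):
            groups.setdefault(find(i), []).append(label)
        ordered = sorted(groups.values(), key=lambda mem: min(mem))
        return {label: cid for cid, members in enumerate(ordered, start=1)
                for label in members}

    def to_newick(self) -> str:
        """Newick string; branch length = parent height − child height."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for k, (a, b, h) in enumerate(self.merges):
            heights[n + k] = h
            children[n + k] = (a, b)

        def esc(label: str) -> str:
            return label.replace(" ", "_").replace("(", "").replace(")", "")

        def render(node: int, parent_h: float) -> str:
            bl = max(parent_h - heights[node], 0.0)
            if node < n:
                return f"{esc(self.labels[node])}:{bl:.6f}"
            a, b = children[node]
            inner = ",".join(render(c, heights[node]) for c in (a, b))
            return f"({inner}):{bl:.6f}"

        root = 2 * n - 2
        a, b = children[root]
        inner = ",".join(render(c, heights[root]) for c in (a, b))
        return f"({inner});"


def _validate_square(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(d < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")


def _warn_triangle_violations(d: np.ndarray) -> None:
    n = len(d)
    if n > 60:  # O(n^3) check only for the small matrices this tool targets
        return
    viol = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(d[i, j] > d[i] + d[j] + 1e-9):
                viol += 1
    if viol:
        logger.warning("fluvial distance matrix violates the triangle "
                       "inequality for %d pairs; Ward applied regardless", viol)


def ward_dendrogram(D, labels: list[str] | None = None) -> MergeTree:
    """Ward hierarchy over a symmetric zero-diagonal distance matrix.

    ``D`` may be a numpy array, a pandas DataFrame (labels from its index),
    or an skbio DistanceMatrix (labels from its ids).
    """
    if isinstance(D, pd.DataFrame):
        if labels is None:
            labels = [str(x) for x in D.index]
        d = D.to_numpy(dtype=float)
    elif hasattr(D, "ids") and hasattr(D, "data"):  # skbio DistanceMatrix
        if labels is None:
            labels = [str(x) for x in D.ids]
        d = np.asarray(D.data, dtype=float)
    else:
        d = np.asarray(D, dtype=float)
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    _validate_square(d)
    _warn_triangle_violations(d)

    # Lance-Williams on squared dissimilarities; heights on the d scale.
    d2 = d.astype(float) ** 2
    active: dict[int, int] = {i: 1 for i in range(n)}     # node id -> size
    pos: dict[int, int] = {i: i for i in range(n)}        # node id -> matrix row
    work = d2.copy()
    np.fill_diagonal(work, np.inf)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        nodes = sorted(active)
        best = None
        for ai in range(len(nodes)):
            for bi in range(ai + 1, len(nodes)):
                a, b = nodes[ai], nodes[bi]
                v = work[pos[a], pos[b]]
                if best is None or v < best[0] - 1e-15:
                    best = (v, a, b)
        v, a, b = best
        new = n + step
        height = float(np.sqrt(max(v, 0.0)))
        merges.append((a, b, height))
        na, nb = active[a], active[b]
        ra, rb = pos[a], pos[b]
        for k in active:
            if k in (a, b):
                continue
            nk = active[k]
            rk = pos[k]
            upd = ((na + nk) * work[rk, ra] + (nb + nk) * work[rk, rb]
                   - nk * v) / (na + nb + nk)
            work[rk, ra] = work[ra, rk] = upd
        del active[a], active[b]
        active[new] = na + nb
        pos[new] = ra
        work[rb, :] = np.inf
        work[:, rb] = np.inf
        work[ra, ra] = np.inf
    return MergeTree(labels=list(map(str, labels)), merges=merges)


def cut_clusters(tree: MergeTree, K: int) -> dict[str, int]:
    """Cut the hierarchy into exactly K clusters (see :meth:`MergeTree.cut`)."""
    return tree.cut(K)
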