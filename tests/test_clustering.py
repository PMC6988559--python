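"""Ward hierarchy on arbitrary distance matrices, and its cuts."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from scalescan import cut_clusters, ward_dendrogram


def naive_ward_merge_order(d: np.ndarray) -> list[frozenset]:
    """Independent O(N³) Ward agglomeration, no Lance–Williams recurrence.

    At each step merge the two clusters with the smallest increase of
    pooled within-cluster inertia, recomputed from scratch via Huygens'
    identity E(C) = Σ_{i<j∈C} d²(i,j) / |C| (the within-cluster sum of
    squares for Euclidean d): cost(A,B) = E(A∪B) − E(A) − E(B).
    """
    n = len(d)
    d2 = d ** 2

    def intra(c: frozenset) -> float:
        return sum(d2[i, j] for i, j in itertools.combinations(sorted(c), 2)
                   ) / len(c)

    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            cost = intra(ca | cb) - intra(ca) - intra(cb)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def merge_sets(tree) -> list[frozenset]:
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _) in enumerate(tree.merges):
        members[n + k] = members[a] | members[b]
        out.append(members[n + k])
    return out


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    return squareform(pdist(pts)), pts


def test_two_leaves_single_merge():
    tree = ward_dendrogram(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
    assert len(tree.merges) == 1
    assert tree.merges[0][2] == pytest.approx(3.0)


def test_first_merge_minimizes_ward_cost():
    d = np.array([[0, 1, 10], [1, 0, 9], [10, 9, 0]], dtype=float)
    tree = ward_dendrogram(d, ["s1", "s2", "s3"])
    assert merge_sets(tree)[0] == frozenset([0, 1])
    assert cut_clusters(tree, 2) == {"s1": 1, "s2": 1, "s3": 2}


def test_duplicate_points_merge_first_at_height_zero():
    d = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float)
    tree = ward_dendrogram(d)
    a, b, h = tree.merges[0]
    assert {a, b} == {0, 1} and h == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("n", [5, 8, 10])
def test_topology_matches_naive_oracle(seed, n):
    d, _ = random_distance_matrix(np.random.default_rng(seed), n)
    assert merge_sets(ward_dendrogram(d)) == naive_ward_merge_order(d)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_topology_matches_scipy_ward(seed):
    d, pts = random_distance_matrix(np.random.default_rng(seed), 12)
    tree = ward_dendrogram(d)
    z = linkage(squareform(d), method="ward")
    for K in range(1, 13):
        ours = cut_clusters(tree, K)
        theirs = fcluster(z, K, criterion="maxclust")
        # same partition up to label permutation
        by_ours = {}
        for i, lab in enumerate(tree.labels):
            by_ours.setdefault(ours[lab], set()).add(i)
        by_scipy = {}
        for i, c in enumerate(theirs):
            by_scipy.setdefault(c, set()).add(i)
        assert set(map(frozenset, by_ours.values())) == \
            set(map(frozenset, by_scipy.values()))


def test_heights_are_monotone(dataset):
    tree = ward_dendrogram(dataset.network.fluvial_distance_matrix())
    heights = [h for _, _, h in tree.merges]
    assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))


def test_cuts_are_nested(dataset):
    tree = ward_dendrogram(dataset.network.fluvial_distance_matrix())
    n = tree.n_leaves
    prev = tree.cut(1)
    for K in range(2, n + 1):
        cur = tree.cut(K)
        assert len(set(cur.values())) == K
        # refinement: members sharing a cluster at K share one at K-1
        for a in tree.labels:
            for b in tree.labels:
                if cur[a] == cur[b]:
                    assert prev[a] == prev[b]
        prev = cur


def test_permutation_equivariance():
    d, _ = random_distance_matrix(np.random.default_rng(5), 9)
    labels = [f"p{i}" for i in range(9)]
    perm = np.random.default_rng(6).permutation(9)
    tree = ward_dendrogram(d, labels)
    tree_p = ward_dendrogram(d[np.ix_(perm, perm)],
                             [labels[i] for i in perm])
    for K in (2, 4, 7):
        a, b = tree.cut(K), tree_p.cut(K)
        groups_a = {}
        groups_b = {}
        for lab in labels:
            groups_a.setdefault(a[lab], set()).add(lab)
            groups_b.setdefault(b[lab], set()).add(lab)
        assert set(map(frozenset, groups_a.values())) == \
            set(map(frozenset, groups_b.values()))


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError):
        ward_dendrogram(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        ward_dendrogram(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    tree = ward_dendrogram(np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        tree.cut(3)


def test_newick_export_parses_and_preserves_leaves(dataset):
    import io
    from skbio import TreeNode
    tree = ward_dendrogram(dataset.network.fluvial_distance_matrix())
    parsed = TreeNode.read(io.StringIO(tree.to_newick()))
    tips = {t.name for t in parsed.tips()}
    assert tips == set(tree.labels)
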