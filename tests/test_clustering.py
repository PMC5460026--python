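"""Clustering tests, including independent brute-force oracles for the
divisive (splinter) procedure and the Ward criterion."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from sigrobust.cluster import (
    DissimilarityMatrix,
    cut_labels,
    cut_tree,
    diana,
    euclidean_dissimilarity,
    from_newick,
    to_newick,
    ward_hclust,
)

from conftest import points_to_dm


# ---------------------------------------------------------------------------
# independent oracles (deliberately written differently from the package)
# ---------------------------------------------------------------------------

def oracle_splinter(d, members):
    """Reference splinter split: seed by max average dissimilarity, then move
    the best-improving object until the fixpoint."""
    members = sorted(members)
    avg = {i: np.mean([d[i, j] for j in members if j != i]) for i in members}
    seed = min(members, key=lambda i: (-avg[i], i))
    splinter, rest = [seed], [i for i in members if i != seed]
    while len(rest) > 1:
        gains = {}
        for i in rest:
            to_rest = np.mean([d[i, j] for j in rest if j != i])
            to_spl = np.mean([d[i, j] for j in splinter])
            gains[i] = to_rest - to_spl
        cand = min(rest, key=lambda i: (-gains[i], i))
        if gains[cand] <= 0:
            break
        splinter.append(cand)
        rest.remove(cand)
    return sorted(splinter), sorted(rest)


def diana_splits(tree):
    """Recover the split sequence (cluster, childA, childB, height) from a
    divisive dendrogram, in execution order."""
    n = tree.n_leaves
    sets = tree.node_leafsets()
    out = []
    for row in range(len(tree.merges) - 1, -1, -1):
        a, b, h = tree.merges[row]
        out.append((sets[n + row], sets[a], sets[b], h))
    return out


def verify_diana_tree(tree, d):
    """Check every recorded split: the divided cluster had maximal diameter
    among the active clusters, and the two-way partition equals the
    independently recomputed splinter fixpoint."""
    def diam(s):
        s = sorted(s)
        return max((d[i, j] for i in s for j in s), default=0.0)

    active = [frozenset(range(tree.n_leaves))]
    for cluster, part_a, part_b, h in diana_splits(tree):
        assert cluster in active
        assert np.isclose(h, diam(cluster))
        assert all(diam(c) <= diam(cluster) + 1e-12
                   for c in active if len(c) > 1)
        spl, rest = oracle_splinter(d, cluster)
        assert {frozenset(spl), frozenset(rest)} == {part_a, part_b}
        active.remove(cluster)
        active.extend([part_a, part_b])


def oracle_ward(points):
    """Naive O(n^3) Ward from coordinates: at each step merge the pair with
    the smallest increase-in-ESS criterion, recording the merged leaf sets
    and the ward.D2 height sqrt(2 * |A||B|/(|A|+|B|) * ||mu_A - mu_B||^2)."""
    pts = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(pts))]
    steps = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bj in range(ai + 1, len(clusters)):
                a, b = clusters[ai], clusters[bj]
                mu_a, mu_b = pts[a].mean(0), pts[b].mean(0)
                cost = (len(a) * len(b) / (len(a) + len(b))
                        * ((mu_a - mu_b) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, ai, bj)
        cost, ai, bj = best
        merged = clusters[ai] + clusters[bj]
        steps.append((frozenset(clusters[ai]), frozenset(clusters[bj]),
                      np.sqrt(2 * cost)))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bj)]
        clusters.append(merged)
    return steps


# ---------------------------------------------------------------------------
# euclidean distances
# ---------------------------------------------------------------------------

class TestEuclidean:
    def test_3_4_5_triangle(self):
        m = pd.DataFrame([[0.0, 3.0], [0.0, 4.0]], columns=["a", "b"])
        dm = euclidean_dissimilarity(m)
        assert np.isclose(dm.values[0, 1], 5.0)

    def test_identical_columns(self):
        m = pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], columns=["a", "b"])
        assert euclidean_dissimilarity(m).values[0, 1] == 0.0

    def test_one_dimensional_positions(self):
        m = pd.DataFrame([[0.0, 1.0, 3.0]], columns=list("abc"))
        d = euclidean_dissimilarity(m).values
        assert np.allclose([d[0, 1], d[0, 2], d[1, 2]], [1.0, 3.0, 2.0])

    def test_nan_rejected(self):
        m = pd.DataFrame([[np.nan, 1.0], [2.0, 2.0]], columns=["a", "b"])
        with pytest.raises(ValueError):
            euclidean_dissimilarity(m)


# ---------------------------------------------------------------------------
# DIANA
# ---------------------------------------------------------------------------

class TestDiana:
    def test_first_split_separates_far_pairs(self):
        tree = diana(points_to_dm([0.0, 1.0, 9.0, 10.0]))
        # root merge joins {0,1} and {9,10}
        sets = tree.node_leafsets()
        a, b, h = tree.merges[-1]
        assert {sets[a], sets[b]} == {frozenset({0, 1}), frozenset({2, 3})}
        assert np.isclose(h, 10.0)  # diameter of the whole set

    def test_two_identical_points(self):
        tree = diana(points_to_dm([5.0, 5.0]))
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == 0.0

    def test_divisive_coefficient_range(self, dataset):
        from sigrobust import median_standardize, subset_to_signature
        sub, _ = subset_to_signature(dataset.matrix, dataset.signature("epithelial"))
        tree = diana(euclidean_dissimilarity(median_standardize(sub)))
        assert 0.0 < tree.divisive_coefficient < 1.0

    @pytest.mark.parametrize("trial", range(20))
    def test_random_instances_verify(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 9))
        pts = rng.normal(size=(n, 3))
        dm = points_to_dm(pts)
        tree = diana(dm)
        verify_diana_tree(tree, dm.values)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        dm = points_to_dm(rng.normal(size=(12, 4)))
        tree = diana(dm)
        heights = [h for _, _, h in tree.merges]
        assert heights == sorted(heights)


# ---------------------------------------------------------------------------
# Ward
# ---------------------------------------------------------------------------

class TestWard:
    def test_well_separated_pairs_merge_first(self):
        tree = ward_hclust(points_to_dm([0.0, 1.0, 9.0, 10.0]))
        sets = tree.node_leafsets()
        first_two = {sets[4], sets[5]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_identical_points_zero_heights(self):
        tree = ward_hclust(points_to_dm([2.0, 2.0, 2.0]))
        assert all(h == 0.0 for _, _, h in tree.merges)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        tree = ward_hclust(points_to_dm(rng.normal(size=(15, 3))))
        heights = [h for _, _, h in tree.merges]
        assert heights == sorted(heights)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_naive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 8))
        pts = rng.normal(size=(n, 2))
        tree = ward_hclust(points_to_dm(pts))
        sets = tree.node_leafsets()
        expected = oracle_ward(pts)
        for row, (ea, eb, eh) in enumerate(expected):
            a, b, h = tree.merges[row]
            assert {sets[a], sets[b]} == {ea, eb}
            assert np.isclose(h, eh)

    def test_matches_scipy_linkage(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 5))
        tree = ward_hclust(points_to_dm(pts))
        Z = sch.linkage(pts, method="ward")
        assert np.allclose(sorted(h for _, _, h in tree.merges),
                           sorted(Z[:, 2]))
        # identical flat clusterings at several k
        for k in (2, 3, 5, 8):
            ours = cut_labels(tree, k)
            theirs = sch.fcluster(Z, t=k, criterion="maxclust")
            pairs_ours = (ours[:, None] == ours[None, :])
            pairs_theirs = (theirs[:, None] == theirs[None, :])
            assert (pairs_ours == pairs_theirs).all()


# ---------------------------------------------------------------------------
# cutting and serialization
# ---------------------------------------------------------------------------

class TestCutTree:
    @pytest.fixture()
    def tree(self):
        return ward_hclust(points_to_dm([0.0, 1.0, 9.0, 10.0],
                                        ids=list("abcd")))

    def test_k1_all_together(self, tree):
        assert set(cut_tree(tree, 1).values()) == {1}

    def test_kn_singletons(self, tree):
        labels = cut_tree(tree, 4)
        assert sorted(labels.values()) == [1, 2, 3, 4]

    def test_k2_splits_far_pairs(self, tree):
        labels = cut_tree(tree, 2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 5)

    @pytest.mark.parametrize("maker", [diana, ward_hclust])
    def test_cuts_are_nested(self, maker):
        rng = np.random.default_rng(2)
        tree = maker(points_to_dm(rng.normal(size=(14, 3))))
        for k in range(1, 14):
            a = cut_labels(tree, k)
            b = cut_labels(tree, k + 1)
            # every k+1 cluster sits inside exactly one k cluster
            for lab in np.unique(b):
                assert len(np.unique(a[b == lab])) == 1

    @pytest.mark.parametrize("maker", [diana, ward_hclust])
    def test_permutation_equivariance(self, maker):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        ids = [f"s{i}" for i in range(10)]
        perm = rng.permutation(10)
        t1 = maker(points_to_dm(pts, ids))
        t2 = maker(points_to_dm(pts[perm], [ids[i] for i in perm]))
        for k in range(1, 11):
            l1, l2 = cut_tree(t1, k), cut_tree(t2, k)
            for x in ids:
                for y in ids:
                    assert (l1[x] == l1[y]) == (l2[x] == l2[y])


class TestNewick:
    @pytest.mark.parametrize("maker,kind", [(ward_hclust, "agglomerative"),
                                            (diana, "divisive")])
    def test_round_trip(self, maker, kind):
        rng = np.random.default_rng(8)
        tree = maker(points_to_dm(rng.normal(size=(9, 2))))
        back = from_newick(to_newick(tree), kind=kind)
        assert sorted(back.leaf_ids) == sorted(tree.leaf_ids)
        assert np.allclose(sorted(h for _, _, h in back.merges),
                           sorted(h for _, _, h in tree.merges), atol=1e-8)
        for k in (2, 4, 7):
            a, b = cut_tree(tree, k), cut_tree(back, k)
            for x in tree.leaf_ids:
                for y in tree.leaf_ids:
                    assert (a[x] == a[y]) == (b[x] == b[y])

    def test_quoted_labels(self):
        tree = ward_hclust(points_to_dm([0.0, 5.0], ids=["sample 1", "s(2)"]))
        back = from_newick(to_newick(tree))
        assert sorted(back.leaf_ids) == ["s(2)", "sample 1"]


def test_dissimilarity_validation():
    with pytest.raises(ValueError):
        DissimilarityMatrix(ids=["a", "b"], values=np.array([[0, 1], [2, 0]]))
    with pytest.raises(ValueError):
        DissimilarityMatrix(ids=["a"], values=np.zeros((2, 2)))
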