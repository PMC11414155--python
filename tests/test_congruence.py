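import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from clonescan.congruence import (
    Dendrogram,
    bakers_gamma,
    mantel,
    pearson_distance_correlation,
    permanova,
    ward_dendrogram,
)
from clonescan.io import DistanceMatrix


def _random_dm(rng, n, labels=None):
    pts = rng.normal(size=(n, 3))
    d = squareform(np.round(np.linalg.norm(pts[:, None] - pts[None], axis=-1), 12)[
        np.triu_indices(n, 1)
    ])
    return DistanceMatrix(labels or [f"s{i}" for i in range(n)], d)


class TestMantel:
    def test_perfect_linear_association(self):
        # enough labels that a random permutation essentially never
        # reproduces the identity relabelling
        d1 = _random_dm(np.random.default_rng(12), 12)
        d2 = DistanceMatrix(d1.labels, 2 * d1.values)
        res = mantel(d1, d2, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_exact_enumeration_on_four_labels(self, toy_distance_matrix):
        """Permutation p converges to the exact all-relabelings p."""
        rng = np.random.default_rng(1)
        d1 = toy_distance_matrix
        d2 = _random_dm(rng, 4, labels=d1.labels)
        iu = np.triu_indices(4, 1)
        v1 = d1.values[iu]

        def corr(mat):
            return stats.pearsonr(v1, mat[iu]).statistic

        r_obs = corr(d2.values)
        exceed = sum(
            corr(d2.values[np.ix_(p, p)]) >= r_obs - 1e-12
            for p in map(list, itertools.permutations(range(4)))
        )
        exact_p = exceed / 24  # includes identity, which always ties
        res = mantel(d1, d2, n_perm=9999, seed=2)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_label_intersection(self, toy_distance_matrix):
        d1 = toy_distance_matrix
        extra = DistanceMatrix(
            ["B", "C", "D", "E"],
            np.array(
                [
                    [0, 0.2, 0.3, 0.4],
                    [0.2, 0, 0.25, 0.5],
                    [0.3, 0.25, 0, 0.6],
                    [0.4, 0.5, 0.6, 0],
                ]
            ),
        )
        res = mantel(d1, extra, n_perm=99, seed=0)
        assert res.n == 3

    def test_too_few_shared_labels(self, toy_distance_matrix):
        other = DistanceMatrix(["A", "B"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="shared labels"):
            mantel(toy_distance_matrix, other, n_perm=9, seed=0)

    def test_zero_variance_rejected(self):
        d1 = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        )
        d2 = _random_dm(np.random.default_rng(0), 3, labels=d1.labels)
        with pytest.raises(ValueError, match="zero-variance"):
            mantel(d1, d2, n_perm=9, seed=0)

    def test_argument_order_symmetric_r(self, toy_distance_matrix):
        rng = np.random.default_rng(3)
        d2 = _random_dm(rng, 4, labels=toy_distance_matrix.labels)
        r1 = mantel(toy_distance_matrix, d2, n_perm=99, seed=1).r
        r2 = mantel(d2, toy_distance_matrix, n_perm=99, seed=1).r
        assert r1 == pytest.approx(r2)

    def test_p_never_zero(self, toy_distance_matrix):
        d2 = DistanceMatrix(toy_distance_matrix.labels, 2 * toy_distance_matrix.values)
        res = mantel(toy_distance_matrix, d2, n_perm=99, seed=0)
        assert res.p > 0

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        d1 = _random_dm(rng, 8)
        d2 = _random_dm(rng, 8, labels=d1.labels)
        res = mantel(d1, d2, n_perm=99, seed=0)
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, d1.labels),
            skbio_distance.DistanceMatrix(d2.values, d2.labels),
            permutations=0,
            alternative="greater",
        )
        assert res.r == pytest.approx(float(r_skbio))


class TestPearsonDistances:
    def test_identical_matrices(self, toy_distance_matrix):
        rho, p = pearson_distance_correlation(
            toy_distance_matrix, toy_distance_matrix
        )
        assert rho == pytest.approx(1.0)

    def test_matches_direct_formula(self, toy_distance_matrix):
        rng = np.random.default_rng(5)
        d2 = _random_dm(rng, 4, labels=toy_distance_matrix.labels)
        rho, p = pearson_distance_correlation(toy_distance_matrix, d2)
        iu = np.triu_indices(4, 1)
        expect = stats.pearsonr(toy_distance_matrix.values[iu], d2.values[iu])
        assert rho == pytest.approx(expect.statistic)
        assert p == pytest.approx(expect.pvalue)

    def test_constant_matrix_rejected(self):
        d1 = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        )
        with pytest.raises(ValueError):
            pearson_distance_correlation(d1, d1)


def brute_force_ward(d: DistanceMatrix):
    """Ward clustering recomputing the SS-increase criterion from scratch
    each step (heights = sqrt(2 * increase), the Ward.D2 convention)."""
    n = d.n
    D2 = d.values**2

    def ss(cluster):
        idx = list(cluster)
        if len(idx) < 2:
            return 0.0
        sub = D2[np.ix_(idx, idx)]
        return float(np.triu(sub, 1).sum()) / len(idx)

    clusters = {i: frozenset([i]) for i in range(n)}
    heights = []
    merge_sets = []
    for _ in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            delta = ss(clusters[a] | clusters[b]) - ss(clusters[a]) - ss(clusters[b])
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        heights.append(math.sqrt(2 * delta))
        merge_sets.append(clusters[a] | clusters[b])
        new = max(clusters) + 1
        clusters[new] = clusters.pop(a) | clusters.pop(b)
    return heights, merge_sets


class TestWard:
    def test_two_labels(self):
        d = DistanceMatrix(["A", "B"], [[0, 0.4], [0.4, 0]])
        t = ward_dendrogram(d)
        assert t.heights[0] == pytest.approx(0.4)

    def test_nearest_pair_merges_first(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]]),
        )
        t = ward_dendrogram(d)
        assert sorted(t.merges[0]) == [0, 1]

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_recomputation(self, n):
        rng = np.random.default_rng(n)
        d = _random_dm(rng, n)
        t = ward_dendrogram(d)
        bf_heights, bf_sets = brute_force_ward(d)
        assert np.allclose(t.heights, bf_heights)
        # same clusters formed, in the same order
        members = {i: {i} for i in range(n)}
        for k, (a, b) in enumerate(t.merges):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            assert merged == set(bf_sets[k])

    def test_matches_scipy_heights(self):
        rng = np.random.default_rng(9)
        d = _random_dm(rng, 7)
        t = ward_dendrogram(d)
        Z = linkage(squareform(d.values), method="ward")
        assert np.allclose(np.sort(t.heights), np.sort(Z[:, 2]))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            d = _random_dm(np.random.default_rng(seed), 8)
            t = ward_dendrogram(d)
            assert np.all(np.diff(t.heights) >= -1e-12)

    def test_deterministic_tie_break(self):
        # four equidistant points: first merge must involve the two
        # lexicographically smallest labels
        vals = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(["d", "c", "b", "a"], vals)
        t = ward_dendrogram(d)
        first = {d.labels[i] for i in t.merges[0]}
        assert first == {"a", "b"}


def _tree(labels, merges, heights):
    return Dendrogram(labels, np.array(merges), np.array(heights, dtype=float))


class TestBakersGamma:
    def test_identical_trees(self):
        t = _tree(["A", "B", "C", "D"], [[0, 1], [2, 3], [4, 5]], [0.1, 0.2, 0.5])
        res = bakers_gamma(t, t, n_perm=99, seed=0)
        assert res.gamma == pytest.approx(1.0)

    def test_four_leaf_hand_enumeration(self):
        # t1 = ((A,B),(C,D)); t2 = ((A,C),(B,D)).
        # Merge depths (clusters at first co-clustering), pairs in order
        # AB, AC, AD, BC, BD, CD:
        #   t1: AB->3, CD->2, rest->1 ; t2: AC->3, BD->2, rest->1
        t1 = _tree(["A", "B", "C", "D"], [[0, 1], [2, 3], [4, 5]], [0.1, 0.2, 0.5])
        t2 = _tree(["A", "C", "B", "D"], [[0, 1], [2, 3], [4, 5]], [0.1, 0.2, 0.5])
        v1 = [3, 1, 1, 1, 1, 2]
        v2 = [1, 3, 1, 1, 2, 1]
        expect = stats.spearmanr(v1, v2).statistic
        res = bakers_gamma(t1, t2, n_perm=99, seed=0)
        assert res.gamma == pytest.approx(expect)

    def test_leaf_set_mismatch(self):
        t1 = _tree(["A", "B"], [[0, 1]], [0.1])
        t2 = _tree(["A", "C"], [[0, 1]], [0.1])
        with pytest.raises(ValueError, match="C"):
            bakers_gamma(t1, t2, n_perm=9, seed=0)

    def test_invariant_to_leaf_order_rotation(self):
        rng = np.random.default_rng(6)
        d = _random_dm(rng, 6)
        t1 = ward_dendrogram(d)
        # same topology, leaves listed in a different order
        perm = [3, 1, 0, 5, 4, 2]
        d2 = DistanceMatrix(
            [d.labels[i] for i in perm], d.values[np.ix_(perm, perm)]
        )
        t2 = ward_dendrogram(d2)
        res = bakers_gamma(t1, t2, n_perm=49, seed=0)
        assert res.gamma == pytest.approx(1.0)

    def test_null_centred_near_zero(self):
        rng = np.random.default_rng(7)
        d = _random_dm(rng, 10)
        t1 = ward_dendrogram(d)
        gammas = []
        for s in range(40):
            perm = np.random.default_rng(s).permutation(10)
            d2 = DistanceMatrix(
                [d.labels[i] for i in perm], d.values
            )
            t2 = ward_dendrogram(d2)
            gammas.append(bakers_gamma(t1, t2, n_perm=9, seed=s).gamma)
        assert abs(np.mean(gammas)) < 0.2


class TestPermanova:
    def test_perfect_separation(self):
        # two tight clusters far apart
        pts = np.vstack([np.zeros((3, 2)), 10 + np.zeros((3, 2))])
        pts += np.random.default_rng(0).normal(scale=0.01, size=pts.shape)
        from scipy.spatial.distance import pdist

        d = DistanceMatrix([f"s{i}" for i in range(6)], squareform(pdist(pts)))
        res = permanova(d, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert res.pseudo_f > 100
        # only 10 distinct splits of 3+3, so the smallest attainable p is
        # bounded by the rate at which permutations rebuild the true split
        assert res.p <= 0.2

    def test_six_point_toy_matches_direct_sums(self):
        rng = np.random.default_rng(8)
        d = _random_dm(rng, 6)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, groups, n_perm=49, seed=0)
        D2 = d.values**2
        sst = D2[np.triu_indices(6, 1)].sum() / 6
        ssw = (
            D2[np.ix_([0, 1, 2], [0, 1, 2])][np.triu_indices(3, 1)].sum() / 3
            + D2[np.ix_([3, 4, 5], [3, 4, 5])][np.triu_indices(3, 1)].sum() / 3
        )
        f = ((sst - ssw) / 1) / (ssw / 4)
        assert res.pseudo_f == pytest.approx(f)
        assert res.r2 == pytest.approx((sst - ssw) / sst)

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        d = _random_dm(rng, 9)
        groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        res = permanova(d, groups, n_perm=49, seed=0)
        sk = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d.values, d.labels),
            grouping=groups,
            permutations=0,
        )
        assert res.pseudo_f == pytest.approx(float(sk["test statistic"]))

    def test_single_group_rejected(self, toy_distance_matrix):
        with pytest.raises(ValueError, match="2 groups"):
            permanova(toy_distance_matrix, ["g"] * 4, n_perm=9, seed=0)
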