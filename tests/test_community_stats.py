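import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from aldernet.community_stats import (
    anosim,
    bray_curtis,
    heatmap_matrix,
    linear_fit_r2,
    linkage_to_newick,
    simper,
    spearman_matrix,
)
from conftest import make_profile


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_anosim_r(dist: np.ndarray, labels) -> float:
    """ANOSIM R straight from its definition, loops and all."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [dist[i, j] for i, j in pairs]
    ranks = ss.rankdata(values)
    within = [r for (i, j), r in zip(pairs, ranks) if labels[i] == labels[j]]
    between = [r for (i, j), r in zip(pairs, ranks) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


def brute_anosim_exact_p(dist: np.ndarray, labels) -> float:
    observed = brute_anosim_r(dist, labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if brute_anosim_r(dist, perm) >= observed:
            count += 1
    return count / total


def random_distance_matrix(rng, n):
    condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
    return squareform(condensed)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        dm = bray_curtis(make_profile([[0.3, 0.3], [0.7, 0.7]]))
        assert dm[("S1", "S2")] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        dm = bray_curtis(make_profile([[1.0, 0.0], [0.0, 1.0]]))
        assert dm[("S1", "S2")] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        dm = bray_curtis(make_profile([[0.25, 0.5], [0.25, 0.0]]))
        # raw columns (1,1) vs (2,0) scaled: BC is scale-free per column pair
        assert dm[("S1", "S2")] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


class TestAnosim:
    def test_equal_dissimilarities_give_zero(self):
        dist = squareform([1.0] * 15)
        dm = DistanceMatrix(dist, ids=[f"s{i}" for i in range(6)])
        res = anosim(dm, ["a", "a", "a", "b", "b", "b"])
        assert res.r == pytest.approx(0.0)

    def test_complete_separation_gives_one(self):
        n = 6
        dist = np.zeros((n, n))
        labels = ["a", "a", "a", "b", "b", "b"]
        rng = np.random.default_rng(0)
        for i in range(n):
            for j in range(i + 1, n):
                low = labels[i] == labels[j]
                dist[i, j] = dist[j, i] = rng.uniform(0.1, 0.2) if low else rng.uniform(0.8, 0.9)
        dm = DistanceMatrix(dist, ids=[f"s{i}" for i in range(n)])
        assert anosim(dm, labels).r == pytest.approx(1.0)

    def test_exact_p_matches_brute_enumeration(self):
        rng = np.random.default_rng(42)
        labels = ["a", "a", "a", "b", "b", "b"]
        for _ in range(5):
            dist = random_distance_matrix(rng, 6)
            dm = DistanceMatrix(dist, ids=[f"s{i}" for i in range(6)])
            res = anosim(dm, labels)
            assert res.method == "exact"
            assert res.n_permutations == 20
            assert res.p == brute_anosim_exact_p(dist, labels)
            assert res.r == pytest.approx(
                brute_anosim_r(dist, labels), abs=1e-12
            )

    def test_r_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        dist = random_distance_matrix(rng, 8)
        labels = ["a"] * 4 + ["b"] * 4
        ids = [f"s{i}" for i in range(8)]
        r1 = anosim(DistanceMatrix(dist, ids=ids), labels).r
        r2 = anosim(DistanceMatrix(np.sqrt(dist), ids=ids), labels).r
        r3 = anosim(DistanceMatrix(dist**3, ids=ids), labels).r
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(9)
        dist = random_distance_matrix(rng, 9)
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        ids = [f"s{i}" for i in range(9)]
        dm = DistanceMatrix(dist, ids=ids)
        ours = anosim(dm, labels)
        from skbio.stats.distance import anosim as skbio_anosim

        theirs = skbio_anosim(dm, grouping=labels, permutations=999)
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)
        assert ours.p == pytest.approx(theirs["p-value"], abs=0.05)

    def test_small_group_rejected(self):
        dm = DistanceMatrix(random_distance_matrix(np.random.default_rng(0), 4),
                            ids=list("abcd"))
        with pytest.raises(ValueError, match="fewer than two"):
            anosim(dm, ["x", "y", "y", "y"])

    def test_permutation_mode_reproducible(self):
        rng = np.random.default_rng(3)
        dist = random_distance_matrix(rng, 12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ids = [f"s{i}" for i in range(12)]
        dm = DistanceMatrix(dist, ids=ids)
        r1 = anosim(dm, labels, n_permutations=500, seed=5)
        r2 = anosim(dm, labels, n_permutations=500, seed=5)
        assert r1.method == "permutation"
        assert (r1.r, r1.p) == (r2.r, r2.p)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


class TestSimper:
    def test_swapped_taxa_contribute_equally(self):
        prof = make_profile([[0.8, 0.8, 0.2, 0.2], [0.2, 0.2, 0.8, 0.8]])
        res = simper(prof, ["g1", "g1", "g2", "g2"])
        np.testing.assert_allclose(res.contributions["percent"], [50.0, 50.0])

    def test_identical_groups_zero(self):
        prof = make_profile([[0.5, 0.5], [0.5, 0.5]])
        res = simper(prof, ["g1", "g2"])
        assert res.overall_dissimilarity == pytest.approx(0.0)
        assert (res.contributions["mean_contribution"] == 0).all()

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(7)
        values = rng.dirichlet(np.ones(3), size=4).T  # 3 taxa x 4 samples
        prof = make_profile(values)
        labels = ["g1", "g1", "g2", "g2"]
        res = simper(prof, labels)
        # oracle: direct loops over the 4 between pairs
        expected = np.zeros(3)
        for j in [0, 1]:
            for k in [2, 3]:
                denom = (values[:, j] + values[:, k]).sum()
                expected += np.abs(values[:, j] - values[:, k]) / denom
        expected /= 4
        by_taxon = res.contributions.set_index("taxon")["mean_contribution"]
        for i, otu in enumerate(prof.values.index):
            assert by_taxon[otu] == pytest.approx(expected[i], abs=1e-12)

    def test_contributions_sum_to_mean_between_bray_curtis(self):
        rng = np.random.default_rng(11)
        values = rng.dirichlet(np.ones(8), size=6).T
        prof = make_profile(values)
        labels = ["g1"] * 3 + ["g2"] * 3
        res = simper(prof, labels)
        bc = pdist(values.T, metric="braycurtis")
        sq = squareform(bc)
        between = [sq[j, k] for j in range(3) for k in range(3, 6)]
        assert res.overall_dissimilarity == pytest.approx(
            np.mean(between), abs=1e-10
        )
        assert res.contributions["cumulative_percent"].iloc[-1] == pytest.approx(
            100.0
        )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_monotone_relationships(self):
        x = pd.DataFrame([[1, 2, 3, 4, 5]], index=["x"])
        y = pd.DataFrame(
            [[2, 4, 8, 16, 32], [-1, -2, -3, -4, -5]], index=["up", "down"]
        )
        rho, _ = spearman_matrix(x, y)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_exact_small_n_p_value(self):
        x = pd.DataFrame([[1, 2, 3, 4]], index=["x"])
        y = pd.DataFrame([[2, 1, 4, 3]], index=["y"])
        rho, p = spearman_matrix(x, y)
        assert rho.loc["x", "y"] == pytest.approx(0.6)
        # oracle: enumerate all 24 orderings of y
        count = 0
        for perm in itertools.permutations([2, 1, 4, 3]):
            r = ss.spearmanr([1, 2, 3, 4], perm).statistic
            if abs(r) >= 0.6 - 1e-12:
                count += 1
        assert p.loc["x", "y"] == pytest.approx(count / 24)

    def test_constant_variable_missing_with_warning(self):
        x = pd.DataFrame([[1, 1, 1, 1, 1]], index=["flat"])
        y = pd.DataFrame([[1, 2, 3, 4, 5]], index=["y"])
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_matrix(x, y)
        assert np.isnan(rho.loc["flat", "y"])


# ---------------------------------------------------------------------------
# linear fit
# ---------------------------------------------------------------------------


class TestLinearFit:
    def test_exact_line(self):
        fit = linear_fit_r2([0, 1, 2, 3], [1, 3, 5, 7])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_covariance(self):
        fit = linear_fit_r2([-1, 0, 1], [1, 0, 1])
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols(self):
        fit = linear_fit_r2([0, 1, 2], [0, 1, 1])
        assert fit.slope == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(0.75)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_r2([2, 2, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# heat-map clustering
# ---------------------------------------------------------------------------


def brute_complete_linkage_heights(points: np.ndarray) -> list[float]:
    """Hand agglomeration: merge the closest pair of clusters under the
    complete-linkage (maximum) distance, recording each merge height."""
    clusters = [[i] for i in range(len(points))]
    dist = squareform(pdist(points))
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    dist[i, j] for i in clusters[a] for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestHeatmap:
    def test_constant_row_normalizes_to_zero(self):
        prof = make_profile([[0.2, 0.2, 0.2], [0.1, 0.5, 0.2]])
        res = heatmap_matrix(prof, cluster_columns=False)
        np.testing.assert_allclose(res.matrix.loc["OTU_01"], 0.0)

    def test_identical_rows_adjacent(self):
        prof = make_profile(
            [
                [0.1, 0.2, 0.7],
                [0.7, 0.2, 0.1],
                [0.1, 0.2, 0.7],
            ],
            otu_ids=["a", "z", "b"],
        )
        res = heatmap_matrix(prof, cluster_columns=False)
        ia, ib = res.row_order.index("a"), res.row_order.index("b")
        assert abs(ia - ib) == 1

    def test_merge_heights_match_hand_agglomeration(self):
        rng = np.random.default_rng(4)
        values = rng.dirichlet(np.ones(5), size=4).T  # 5 rows (wide spread)
        prof = make_profile(values)
        res = heatmap_matrix(prof, cluster_columns=False)
        normed = res.matrix.loc[list(prof.values.index)].to_numpy()
        expected = sorted(brute_complete_linkage_heights(normed))
        got = sorted(res.row_linkage[:, 2])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_two_separated_pairs_cut_cleanly(self):
        prof = make_profile(
            [
                [0.9, 0.8, 0.1, 0.1],
                [0.8, 0.9, 0.1, 0.2],
                [0.1, 0.1, 0.9, 0.8],
                [0.2, 0.1, 0.8, 0.9],
            ],
            otu_ids=["a1", "a2", "b1", "b2"],
        )
        res = heatmap_matrix(prof, cluster_columns=False)
        order = res.row_order
        assert {order[0], order[1]} in ({"a1", "a2"}, {"b1", "b2"})

    def test_newick_parses_and_keeps_leaves(self):
        import dendropy

        prof = make_profile(np.random.default_rng(2).dirichlet(np.ones(6), 4).T)
        res = heatmap_matrix(prof, cluster_columns=False)
        newick = linkage_to_newick(res.row_linkage, list(prof.values.index))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        taxa = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
        assert taxa == set(prof.values.index)
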