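import numpy as np
import pytest

from geosurr.geometry_stats import (
    BinnedWeightProfile,
    DegenerateInputError,
    binned_weight_profile,
    com_distances,
    compare_profiles,
    division_spearman,
    hub_strength_by_division,
    identify_hubs,
    mean_neighbor_fiber_distance,
    normalized_metric_ratio,
    pearson_r,
    permutation_test,
    spearman_rho,
    tukey_range_test,
    zscore_log_weights,
)
from geosurr.graph_model import InvalidInputError

from . import oracles

rng = np.random.default_rng(17)


class TestZscoreLogWeights:
    def test_two_point_case(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = np.e
        Z = zscore_log_weights(W)
        assert np.isclose(Z[0, 1], -1.0)  # population convention
        assert np.isclose(Z[0, 2], 1.0)

    def test_mean_zero_sd_one(self, benchmark):
        g, _ = benchmark
        Z = zscore_log_weights(g.weights)
        iu, ju = np.triu_indices(g.n_nodes, 1)
        z = Z[iu, ju]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_invariant_to_rescaling(self, small_benchmark):
        g, _ = small_benchmark
        Z1 = zscore_log_weights(g.weights)
        Z2 = zscore_log_weights(42.0 * g.weights)
        assert np.allclose(Z1, Z2, atol=1e-9, equal_nan=True)

    def test_degenerate_rejected(self):
        W = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(DegenerateInputError):
            zscore_log_weights(W)


class TestBinnedProfile:
    def test_single_bin_reproduces_global_stats(self):
        Z = np.full((4, 4), np.nan)
        F = np.zeros((4, 4))
        iu, ju = np.triu_indices(4, 1)
        z = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 0.0])
        z = (z - z.mean()) / z.std()
        Z[iu, ju] = Z[ju, iu] = z
        F[iu, ju] = F[ju, iu] = 0.5
        prof = binned_weight_profile(Z, F, width=1.0)
        assert prof.n_bins == 1
        assert np.isclose(prof.bin_means[0], 0.0, atol=1e-12)
        assert np.isclose(prof.bin_sds[0], 1.0)

    def test_two_forced_bins(self):
        Z = np.full((4, 4), np.nan)
        F = np.zeros((4, 4))
        pairs = [(0, 1, -1.0, 0.5), (2, 3, -1.0, 0.7),
                 (0, 2, 1.0, 1.5), (1, 3, 1.0, 1.6)]
        for i, j, z, f in pairs:
            Z[i, j] = Z[j, i] = z
            F[i, j] = F[j, i] = f
        prof = binned_weight_profile(Z, F, width=1.0)
        assert np.allclose(prof.bin_means, [-1.0, 1.0])
        assert np.allclose(prof.bin_sds, [0.0, 0.0])
        assert np.array_equal(prof.bin_counts, [2, 2])

    def test_matches_loop_oracle(self, benchmark):
        g, _ = benchmark
        Z = zscore_log_weights(g.weights)
        prof = binned_weight_profile(Z, g.fiber_distances)
        iu, ju = np.triu_indices(g.n_nodes, 1)
        means, sds, counts = oracles.binned_profile_loops(
            Z[iu, ju].tolist(), g.fiber_distances[iu, ju].tolist(), 1.0)
        assert np.array_equal(prof.bin_counts, counts)
        assert np.allclose(prof.bin_means, means, equal_nan=True)
        assert np.allclose(prof.bin_sds, sds, equal_nan=True)

    def test_count_weighted_means_average_to_zero(self, benchmark):
        g, _ = benchmark
        Z = zscore_log_weights(g.weights)
        prof = binned_weight_profile(Z, g.fiber_distances)
        ok = prof.bin_counts > 0
        total = np.sum(prof.bin_means[ok] * prof.bin_counts[ok])
        assert abs(total / prof.bin_counts.sum()) < 1e-9


def _profile(means, counts=None):
    means = np.asarray(means, dtype=float)
    nb = len(means)
    counts = np.full(nb, 10) if counts is None else np.asarray(counts)
    edges = np.arange(nb + 1, dtype=float)
    return BinnedWeightProfile(edges, means, np.ones(nb), counts)


class TestCompareProfiles:
    def test_identical_replicates_not_flagged(self):
        ref = _profile([0.0, 0.5, 1.0])
        reps = [_profile([0.0, 0.5, 1.0]) for _ in range(5)]
        assert not compare_profiles(reps, ref).any()

    def test_large_shift_flagged_in_one_bin(self):
        ref = _profile([0.0, 0.0, 0.0])
        r = np.random.default_rng(0)
        reps = [_profile([0.0 + 0.01 * r.standard_normal(),
                          10.0 + 0.01 * r.standard_normal(),
                          0.0 + 0.01 * r.standard_normal()])
                for _ in range(5)]
        flags = compare_profiles(reps, ref)
        assert flags.tolist() == [False, True, False]
        # hand-computed t statistic for the shifted bin is enormous
        vals = np.array([p.bin_means[1] for p in reps])
        t = (vals.mean() - 0.0) / (vals.std(ddof=1) / np.sqrt(5))
        assert abs(t) > 100

    def test_alpha_zero_flags_nothing(self):
        ref = _profile([0.0, 0.0])
        reps = [_profile([5.0, 5.0]) for _ in range(4)]
        assert not compare_profiles(reps, ref, alpha=0.0).any()

    def test_rejects_single_replicate(self):
        ref = _profile([0.0])
        with pytest.raises(InvalidInputError):
            compare_profiles([ref], ref)


class TestIdentifyHubs:
    def test_top_fraction_count(self):
        v = rng.random(20)
        hubs = identify_hubs(v, 0.15)
        assert hubs.n == 3

    def test_all_equal_takes_first_indices_with_warning(self):
        with pytest.warns(UserWarning):
            hubs = identify_hubs(np.ones(10), 0.2)
        assert np.array_equal(hubs.indices, [0, 1])

    def test_matches_sort_oracle(self):
        v = rng.random(100)
        hubs = identify_hubs(v, 0.15)
        expect = np.sort(np.argsort(-v)[:15])
        assert np.array_equal(hubs.indices, expect)
        assert np.all(v[hubs.indices] >= hubs.threshold_value)


class TestComDistances:
    def test_node_at_center_of_mass(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
        d = com_distances(coords, np.ones(3), np.array([0]))
        assert np.isclose(d[0], 0.0)

    def test_symmetric_pair(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        d = com_distances(coords, np.ones(2), np.array([0, 1]))
        assert np.allclose(d, [1.0, 1.0])

    def test_matches_weighted_mean_oracle(self):
        coords = rng.normal(size=(30, 3))
        vols = rng.random(30) + 0.1
        subset = np.arange(0, 30, 3)
        d = com_distances(coords, vols, subset)
        com = np.zeros(3)
        for i in range(30):
            com += vols[i] * coords[i]
        com /= vols.sum()
        expect = [np.sqrt(((coords[i] - com) ** 2).sum()) for i in subset]
        assert np.allclose(d, expect, atol=1e-12)

    def test_rejects_empty_subset(self):
        with pytest.raises(InvalidInputError):
            com_distances(np.zeros((3, 3)), None, np.array([], dtype=int))


class TestMeanNeighborDistance:
    def test_equal_weights(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = 1.0
        F = np.zeros((3, 3))
        F[0, 1] = F[1, 0] = 2.0
        F[0, 2] = F[2, 0] = 4.0
        assert np.isclose(mean_neighbor_fiber_distance(W, F)[0], 3.0)

    def test_weighted_mean(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 3.0
        W[0, 2] = W[2, 0] = 1.0
        F = np.zeros((3, 3))
        F[0, 1] = F[1, 0] = 2.0
        F[0, 2] = F[2, 0] = 4.0
        assert np.isclose(mean_neighbor_fiber_distance(W, F)[0], 2.5)

    def test_matches_loop_oracle(self, benchmark):
        g, _ = benchmark
        got = mean_neighbor_fiber_distance(g.weights, g.fiber_distances)
        i = 17
        num = sum(g.weights[i, j] * g.fiber_distances[i, j]
                  for j in range(g.n_nodes))
        den = sum(g.weights[i, j] for j in range(g.n_nodes))
        assert np.isclose(got[i], num / den, atol=1e-9)

    def test_unweighted_mode(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 3.0
        W[0, 2] = W[2, 0] = 1.0
        F = np.zeros((3, 3))
        F[0, 1] = F[1, 0] = 2.0
        F[0, 2] = F[2, 0] = 4.0
        d = mean_neighbor_fiber_distance(W, F, weighted=False)
        assert np.isclose(d[0], 3.0)


class TestNormalizedRatio:
    def test_equal_gives_one(self):
        assert normalized_metric_ratio(2.0, [2.0, 2.0, 2.0]) == 1.0

    def test_simple_ratio(self):
        assert normalized_metric_ratio(3.0, [2.0, 2.0, 2.0]) == 1.5

    def test_matches_direct_computation(self):
        ens = rng.random(100) + 0.5
        assert np.isclose(normalized_metric_ratio(1.3, ens),
                          1.3 / ens.mean(), atol=1e-15)

    def test_zero_mean_rejected(self):
        with pytest.raises(InvalidInputError):
            normalized_metric_ratio(1.0, [1.0, -1.0])


class TestHubStrengthByDivision:
    def test_single_division_gets_all(self):
        from geosurr.geometry_stats import HubSet
        hubs = HubSet(np.array([0, 1]), 0.5, "strength", 1.0)
        s = np.array([2.0, 3.0, 1.0, 1.0])
        div = np.array(["A", "A", "B", "B"], dtype=object)
        out = hub_strength_by_division(s, hubs, div)
        assert out == {"A": 100.0, "B": 0.0}

    def test_split_75_25(self):
        from geosurr.geometry_stats import HubSet
        hubs = HubSet(np.array([0, 1]), 0.5, "strength", 1.0)
        s = np.array([3.0, 1.0, 5.0, 5.0])
        div = np.array(["A", "B", "C", "C"], dtype=object)
        out = hub_strength_by_division(s, hubs, div)
        assert out["A"] == 75.0 and out["B"] == 25.0 and out["C"] == 0.0

    def test_sums_to_100(self, benchmark):
        g, _ = benchmark
        s = g.weights.sum(1)
        hubs = identify_hubs(s, 0.15)
        out = hub_strength_by_division(s, hubs, g.division)
        assert abs(sum(out.values()) - 100.0) < 1e-9
        # loop oracle for one division
        div0 = g.division[0]
        mask = hubs.mask(g.n_nodes)
        expect = 100.0 * s[mask & (g.division == div0)].sum() / s[mask].sum()
        assert np.isclose(out[str(div0)], expect, atol=1e-12)


class TestCorrelations:
    def test_monotone_gives_one(self):
        x = np.arange(10.0)
        assert np.isclose(spearman_rho(x, np.exp(x)), 1.0)
        assert np.isclose(spearman_rho(x, -x), -1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = rng.random(20)
        y = rng.random(20)
        assert np.isclose(spearman_rho(x, y),
                          oracles.spearman_via_ranks(x, y), atol=1e-12)
        assert np.isclose(pearson_r(x, y),
                          oracles.pearson_direct(x, y), atol=1e-12)

    def test_division_restriction(self, small_benchmark):
        g, _ = small_benchmark
        Wb = g.weights * np.exp(rng.normal(0, 0.1, g.weights.shape))
        Wb = (Wb + Wb.T) / 2
        np.fill_diagonal(Wb, 0.0)
        out = division_spearman(g.weights, Wb, g.division, g.hemisphere)
        da, db, lat = next(iter(out))
        iu, ju = np.triu_indices(g.n_nodes, 1)
        in_pair = (((g.division[iu] == da) & (g.division[ju] == db))
                   | ((g.division[iu] == db) & (g.division[ju] == da)))
        same = g.hemisphere[iu] == g.hemisphere[ju]
        sel = in_pair & (same if lat == "ipsi" else ~same)
        expect = oracles.spearman_via_ranks(g.weights[iu[sel], ju[sel]],
                                            Wb[iu[sel], ju[sel]])
        assert np.isclose(out[(da, db, lat)], expect, atol=1e-9)


class TestStatisticalTests:
    def test_identical_groups_not_significant(self):
        g1 = np.arange(10.0)
        p_tukey = tukey_range_test([g1, g1 + 1e-12])[0, 1]
        assert p_tukey > 0.99
        p_perm = permutation_test(g1, g1.copy(), n_perm=99, seed=0)
        assert p_perm > 0.5

    def test_separated_groups_hit_minimal_p(self):
        r = np.random.default_rng(1)
        a = r.normal(0.0, 1.0, 10)
        b = r.normal(20.0, 1.0, 10)
        p = permutation_test(a, b, n_perm=999, seed=1)
        assert np.isclose(p, 1.0 / 1000.0)
        assert tukey_range_test([a, b])[0, 1] < 1e-6

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        r = np.random.default_rng(2)
        groups = [r.normal(0, 1, 12), r.normal(0.8, 1, 12), r.normal(2, 1, 12)]
        got = tukey_range_test(groups)
        data = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 12)
        sm = pairwise_tukeyhsd(data, labels)
        assert np.allclose([got[0, 1], got[0, 2], got[1, 2]],
                           sm.pvalues, atol=1e-6)

    def test_permutation_deterministic(self):
        a, b = rng.random(8), rng.random(8)
        p1 = permutation_test(a, b, n_perm=199, seed=42)
        p2 = permutation_test(a, b, n_perm=199, seed=42)
        assert p1 == p2

    def test_rejects_bad_nperm(self):
        with pytest.raises(InvalidInputError):
            permutation_test([1.0], [2.0], n_perm=0)
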