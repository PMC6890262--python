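"""Mutual-information machinery: closed forms, exact enumeration, optimization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from onoffcoding import infomax as im
from onoffcoding.distributions import Laplace

LOG2 = math.log(2.0)


class TestNoiseEntropy:
    def test_noiseless_limit_is_zero(self):
        assert im.noise_entropy(0.0) == 0.0

    def test_matches_high_precision_evaluation(self):
        # independent arbitrary-precision evaluation of the defining formula
        import sympy

        q = sympy.exp(-1)
        ref = float(-((1 - q) * sympy.log(1 - q) + q * sympy.log(q)) / (1 - q))
        assert im.noise_entropy(math.exp(-1)) == pytest.approx(ref, rel=1e-14)
        assert ref == pytest.approx(1.041, abs=1e-3)

    def test_small_q_series(self):
        q = math.exp(-10)
        # leading behaviour H_q ~ -q log q for q -> 0
        assert im.noise_entropy(q) == pytest.approx(-q * math.log(q), rel=0.15)
        assert 0 < im.noise_entropy(q) < 1e-3

    def test_domain_errors(self):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                im.noise_entropy(bad)


class TestMaxInformation:
    @pytest.mark.parametrize("N,R,bits", [
        (2, 0.1, 0.102), (2, 1, 0.771), (3, 1, 1.04),
        (5, 1, 1.47), (6, 10, 2.81),
    ])
    def test_closed_form_values(self, N, R, bits):
        got = im.max_information(N, R=R).bits
        assert float(f"{got:.3g}") == bits

    def test_noiseless_upper_bound(self):
        for N in (1, 4, 17):
            assert im.max_information(N, 0.0).nats == pytest.approx(math.log(N + 1))

    def test_high_noise_limit(self):
        # RN -> 0: I -> log(RN/e + 1)
        N, R = 100, 1e-5
        got = im.max_information(N, R=R).nats
        assert got == pytest.approx(math.log(R * N / math.e + 1.0), rel=1e-3)

    def test_monotone_in_N_and_R(self):
        vals_N = [im.max_information(N, R=1.0).nats for N in range(1, 12)]
        assert np.all(np.diff(vals_N) > 0)
        vals_R = [im.max_information(4, R=R).nats for R in (0.01, 0.1, 1, 10, 100)]
        assert np.all(np.diff(vals_R) > 0)


class TestOptimalPartition:
    def test_large_population_regime_equal_intervals(self):
        # N >> 1 with 1 - q = O(1): p_edge = p = p_0 = 1/(N+1)
        N, R = 400, 6.0
        part = im.optimal_partition(N, N // 2, math.exp(-R))
        for val in (part.p, part.p_edge, part.p_silent):
            assert val == pytest.approx(1.0 / (N + 1), rel=0.02)

    def test_high_noise_regime_edges_1_over_e(self):
        # RN -> 0: p_edge -> 1/e and silent interval -> 1 - 2/e
        q = math.exp(-1e-6)
        part = im.optimal_partition(10, 5, q)
        assert part.p_edge == pytest.approx(1.0 / math.e, rel=1e-3)
        assert part.p_silent == pytest.approx(1.0 - 2.0 / math.e, rel=1e-3)

    def test_noiseless_edges_equal_interior(self):
        part = im.optimal_partition(5, 3, 0.0)
        assert part.p_edge == pytest.approx(part.p)

    def test_masses_sum_to_one(self):
        for (N, m, R) in [(1, 1, 0.5), (2, 0, 3.0), (7, 3, 0.2)]:
            part = im.optimal_partition(N, m, math.exp(-R))
            assert part.masses.sum() == pytest.approx(1.0, abs=1e-12)


class TestOptimalThresholds:
    def test_single_noiseless_on_cell_splits_at_median(self):
        prof = im.optimal_thresholds(im.PopulationSpec(1, "N", 1e9), Laplace())
        assert prof.positions[0] == pytest.approx(0.5, abs=1e-8)
        assert prof.thresholds[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("R", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("N", [2, 3, 4])
    def test_equal_coding_theorem(self, N, R):
        # every non-overlapping mixture transmits exactly the closed-form optimum
        q = math.exp(-R)
        ref = im.max_information(N, q).nats
        for m in range(N + 1):
            prof = im.optimal_thresholds(im.PopulationSpec.mixture(N, m, R))
            assert im.exact_information(prof, q).nats == pytest.approx(
                ref, abs=1e-12)

    def test_interval_widths_match_grid_search_oracle(self):
        # brute-force simplex grid maximization, homogeneous ON, N=4, R=1
        N, R = 4, 1.0
        q = math.exp(-R)
        grid = np.arange(0.05, 1.0, 0.05)
        best, best_x = -1.0, None
        from itertools import combinations

        for xs in combinations(grid, N):
            x = np.asarray(xs)
            nats = im.pattern_information(np.diff(np.r_[0.0, x, 1.0]), "N" * N, q).nats
            if nats > best:
                best, best_x = nats, x
        prof = im.optimal_thresholds(im.PopulationSpec.mixture(N, N, R))
        assert im.exact_information(prof, q).nats >= best - 1e-12
        assert np.allclose(prof.positions, best_x, atol=0.05)
        widths = np.diff(prof.positions)
        assert np.allclose(widths, im.optimal_partition(N, N, q).p, atol=1e-12)

    def test_overlapping_labels_rejected(self):
        with pytest.raises(im.OverlappingLabelsError):
            im.optimal_thresholds(im.PopulationSpec(2, "NF", 1.0))


class TestExactInformation:
    def test_single_cell_at_median_noiseless_is_one_bit(self):
        prof = im.ThresholdProfile.from_positions([0.5], "N")
        assert im.exact_information(prof, 0.0).bits == pytest.approx(1.0)

    def test_table2_value_n2(self):
        prof = im.optimal_thresholds(im.PopulationSpec.mixture(2, 2, 0.1))
        assert f"{im.exact_information(prof, math.exp(-0.1)).bits:.3g}" == "0.102"

    def test_large_N_refused(self):
        prof = im.ThresholdProfile.from_positions(
            np.linspace(0.01, 0.99, 21), "N" * 21)
        with pytest.raises(ValueError, match="[Mm]onte|enumeration"):
            im.exact_information(prof, 0.3)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.floats(0.0, 0.95), st.integers(0, 2 ** 31 - 1))
    def test_matches_recursive_form_on_homogeneous_populations(self, N, q, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0.01, 0.99, size=N))
        if len(np.unique(x)) < N:
            return
        prof = im.ThresholdProfile.from_positions(x, "N" * N)
        exact = im.exact_information(prof, q).nats
        rec = im.information_recursive(np.sort(1.0 - x), q).nats
        assert exact == pytest.approx(rec, abs=1e-10)

    def test_recursive_table2_value(self):
        part = im.optimal_partition(2, 2, math.exp(-1.0))
        u = np.cumsum(part.masses[::-1])[:2]  # response masses from the top
        got = im.information_recursive(np.sort(u), math.exp(-1.0)).bits
        assert f"{got:.3g}" == "0.771"

    def test_posterior_readjustment_reproduces_subpopulation_optimum(self):
        # observing silence of the first cell and revising the remaining
        # intervals lands exactly on the (N-1)-cell optimal profile
        N, R = 5, 1.0
        q = math.exp(-R)
        part = im.optimal_partition(N, N, q)
        u = np.sort(np.cumsum(part.masses[::-1])[:N])
        u1 = u[0]
        revised = (u[1:] - u1 * (1 - q)) / (1 - u1 * (1 - q))
        part_sub = im.optimal_partition(N - 1, N - 1, q)
        u_sub = np.sort(np.cumsum(part_sub.masses[::-1])[: N - 1])
        assert np.allclose(revised, u_sub, atol=1e-12)


class TestOptimizeThresholds:
    def test_fixed_overlapping_labels_table2(self):
        _, res = im.optimize_thresholds(im.PopulationSpec(2, "NF", 0.1),
                                        "fixed_labels", seed=1)
        assert f"{res.bits:.3g}" == "0.0952"

    def test_enforced_overlap_n3(self):
        _, res = im.optimize_thresholds(im.PopulationSpec.mixture(3, 1, 1.0),
                                        "enforce_overlap", seed=1)
        assert f"{res.bits:.3g}" == "1"
        assert res.diagnostics["configurations"] == ["FNF", "NFN"]

    def test_allowed_overlap_n3_recovers_closed_form_and_configs(self):
        _, res = im.optimize_thresholds(im.PopulationSpec.mixture(3, 1, 1.0),
                                        "allow_overlap", seed=1)
        ref = im.max_information(3, R=1.0).bits
        assert res.bits == pytest.approx(ref, abs=1e-5)
        assert res.diagnostics["configurations"] == ["FFF", "FFN", "FNN", "NNN"]

    def test_enumeration_refused_for_large_N(self):
        with pytest.raises(ValueError):
            im.optimize_thresholds(im.PopulationSpec.mixture(11, 5, 1.0),
                                   "allow_overlap")


class TestMeanSpikeCount:
    def test_large_population_homogeneous_is_half_R(self):
        N, R = 200, 2.0
        spec = im.PopulationSpec.mixture(N, N, R)
        prof = im.optimal_thresholds(spec)
        assert im.mean_spike_count(spec, prof) == pytest.approx(R / 2, rel=0.02)

    def test_equal_mixture_halves_the_homogeneous_cost(self):
        N, R = 200, 2.0
        hom = im.PopulationSpec.mixture(N, N, R)
        mix = im.PopulationSpec.mixture(N, N // 2, R)
        r_hom = im.mean_spike_count(hom, im.optimal_thresholds(hom))
        r_mix = im.mean_spike_count(mix, im.optimal_thresholds(mix))
        assert r_mix == pytest.approx(r_hom / 2, rel=0.03)

    @pytest.mark.parametrize("m_frac", [0.0, 0.5, 1.0])
    def test_high_noise_regime_R_over_e(self, m_frac):
        N, R = 50, 1e-5  # RN -> 0
        spec = im.PopulationSpec.mixture(N, int(m_frac * N), R)
        prof = im.optimal_thresholds(spec)
        assert im.mean_spike_count(spec, prof) == pytest.approx(
            R / math.e, rel=1e-3)
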