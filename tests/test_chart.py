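"""Truncated-life-test np chart: probability chain, limits, ARL and application."""

import numpy as np
import pytest
from scipy.special import comb

from ntsg import (
    ChartConfig,
    NtsWeibullParams,
    SubgroupCounts,
    apply_chart,
    arl,
    arl_profile,
    control_limits,
    counts_from_times,
    design_chart,
    empirical_limits,
    eta_q,
    in_control_prob,
    load_survival_times,
    p_fail,
    percentile_life,
)
from ntsg.chart import make_design

# the two published worked designs used throughout
CFG_N30 = ChartConfig(n=30, delta=2.5, lambda_=1.5, r0=370.0)
DESIGN_N30 = make_design(CFG_N30, k=2.981, tau=0.948)
CFG_FIT = ChartConfig(n=20, delta=0.42771, lambda_=1.02405, r0=500.0)
DESIGN_FIT = make_design(CFG_FIT, k=3.158, tau=0.773)


class TestEtaQ:
    def test_hand_values(self):
        assert eta_q(1.5, 0.5) == pytest.approx(0.7762963984055685, abs=1e-12)
        assert eta_q(1.02405, 0.5) == pytest.approx(1.9903884710122077, abs=1e-12)

    def test_vanishes_at_low_percentiles(self):
        assert eta_q(1.5, 1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            eta_q(1.0, 0.5)
        with pytest.raises(ValueError):
            eta_q(1.5, 1.0)


class TestFailureProbability:
    def test_published_in_control_values(self):
        assert p_fail(0.948, 2.5, 1.5) == pytest.approx(0.4367, abs=0.001)
        assert p_fail(0.773, 0.42771, 1.02405) == pytest.approx(0.39527, abs=0.002)

    def test_in_control_matches_literal_formula(self):
        for tau, d, lam in [(0.948, 2.5, 1.5), (0.773, 0.42771, 1.02405), (1.1, 4.1, 1.3)]:
            expo = tau**d * eta_q(lam, 0.5)
            s = np.sin(0.5 * np.pi * (1.0 - np.exp(-expo)))
            literal = 1.0 - lam * (1.0 - s) / (lam - s)
            assert p_fail(tau, d, lam) == pytest.approx(literal, abs=1e-12)

    def test_shifted_value_frozen_oracle(self):
        # life-scale shift c=2 on the n=30 design chain
        assert p_fail(0.948, 2.5, 1.5, c=2.0) == pytest.approx(0.205602, abs=1e-4)

    def test_strictly_decreasing_in_shift(self):
        c = np.linspace(0.2, 4.0, 60)
        p = np.array([p_fail(0.948, 2.5, 1.5, c=ci) for ci in c])
        assert np.all(np.diff(p) < 0)

    def test_truncation_variant_agrees_only_in_control(self):
        assert p_fail(0.948, 2.5, 1.5, c=1.0, variant="tau") == pytest.approx(
            p_fail(0.948, 2.5, 1.5, c=1.0), abs=1e-15
        )
        assert p_fail(0.948, 2.5, 1.5, c=2.0, variant="tau") != pytest.approx(
            p_fail(0.948, 2.5, 1.5, c=2.0), abs=1e-3
        )

    def test_invalid_inputs_rejected(self):
        for bad in [dict(tau=0.0), dict(c=0.0), dict(delta=-1.0)]:
            kw = dict(tau=0.9, delta=2.5, lambda_=1.5)
            kw.update(bad)
            with pytest.raises(ValueError):
                p_fail(kw["tau"], kw["delta"], kw["lambda_"], c=kw.get("c", 1.0))


class TestControlLimits:
    def test_published_integer_limits(self):
        p0 = p_fail(0.948, 2.5, 1.5)
        lcl, ucl, lcl_i, ucl_i = control_limits(30, p0, 2.981)
        assert (lcl_i, ucl_i) == (5, 21)

    def test_published_raw_upper_limit(self):
        p0 = p_fail(0.773, 0.42771, 1.02405)
        lcl, ucl, lcl_i, ucl_i = control_limits(20, p0, 3.158)
        assert ucl == pytest.approx(14.8103, abs=0.001)
        assert lcl_i == 1

    def test_zero_coefficient_collapses_to_center(self):
        lcl, ucl, *_ = control_limits(30, 0.4, 0.0)
        assert lcl == ucl == pytest.approx(12.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            control_limits(30, 0.0, 2.0)


class TestInControlProbability:
    def test_whole_support_gives_one(self):
        assert in_control_prob(30, 0.4, 0.0, 30.0) == pytest.approx(1.0, abs=1e-15)

    def test_empty_decision_set_gives_zero(self):
        assert in_control_prob(30, 0.4, 28.2, 28.9) == 0.0

    def test_matches_brute_force_pmf_enumeration(self):
        # independent oracle: binomial pmf built from the multiplicative recurrence
        rng = np.random.default_rng(14)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            p = float(rng.uniform(0.05, 0.95))
            lcl = float(rng.uniform(0.0, n / 3))
            ucl = float(rng.uniform(lcl + 0.5, n))
            d = np.arange(0, n + 1)
            pmf = comb(n, d) * p**d * (1 - p) ** (n - d)
            d_lo = int(np.floor(lcl)) + 1 if lcl > 0 else 0
            expected = pmf[(d >= d_lo) & (d <= int(np.floor(ucl)))].sum()
            assert in_control_prob(n, p, lcl, ucl) == pytest.approx(expected, abs=1e-12)

    def test_matches_monte_carlo_binomial_sampling(self):
        n, p = 30, p_fail(0.948, 2.5, 1.5)
        lcl, ucl = DESIGN_N30.lcl_raw, DESIGN_N30.ucl_raw
        rng = np.random.default_rng(77)
        draws = rng.binomial(n, p, size=1_000_000)
        d_lo = int(np.floor(lcl)) + 1
        inside = np.mean((draws >= d_lo) & (draws <= int(np.floor(ucl))))
        pic = in_control_prob(n, p, lcl, ucl)
        se = np.sqrt(pic * (1 - pic) / draws.size)
        assert abs(inside - pic) < 4 * se


class TestArl:
    def test_published_run_lengths_for_the_n30_design(self):
        d = DESIGN_N30
        assert d.arl0 == pytest.approx(370.67, rel=0.02)
        p_2 = p_fail(d.tau, 2.5, 1.5, c=2.0)
        p_half = p_fail(d.tau, 2.5, 1.5, c=0.5)
        assert arl(30, p_2, d.lcl_raw, d.ucl_raw) == pytest.approx(2.51, rel=0.02)
        assert arl(30, p_half, d.lcl_raw, d.ucl_raw) == pytest.approx(1.18, rel=0.02)

    def test_infinite_when_chart_cannot_signal(self):
        assert np.isinf(arl(2, 0.5, 0.0, 2.0))


class TestArlProfile:
    def test_entry_at_unit_shift_equals_in_control_arl(self):
        curve = arl_profile(DESIGN_N30, CFG_N30, c_grid=[0.5, 1.0, 2.0])
        entries = {c: a for c, _, a in curve.entries}
        assert entries[1.0] == DESIGN_N30.arl0

    def test_decreasing_beyond_unit_shift(self):
        c_grid = np.linspace(1.0, 4.0, 16)
        curve = arl_profile(DESIGN_N30, CFG_N30, c_grid=c_grid)
        arls = np.array([a for _, _, a in curve.entries])
        assert np.all(np.diff(arls) < 0)

    def test_small_shift_detected_immediately(self):
        curve = arl_profile(DESIGN_N30, CFG_N30, c_grid=[0.01])
        assert curve.entries[0][2] == pytest.approx(1.0, abs=1e-6)

    def test_below_unit_shift_never_exceeds_in_control_arl(self):
        curve = arl_profile(DESIGN_N30, CFG_N30, c_grid=np.linspace(0.1, 0.95, 18))
        assert all(a <= DESIGN_N30.arl0 for _, _, a in curve.entries)

    def test_larger_subgroups_detect_shifts_faster(self):
        # published n=20 vs n=30 designs at the same target in-control ARL
        cfg20 = ChartConfig(n=20, delta=2.5, lambda_=1.5, r0=370.0)
        d20 = make_design(cfg20, k=3.031, tau=0.991)
        for c in (1.2, 1.3, 1.5, 2.0, 3.0, 4.0):
            a30 = arl_profile(DESIGN_N30, CFG_N30, c_grid=[c]).entries[0][2]
            a20 = arl_profile(d20, cfg20, c_grid=[c]).entries[0][2]
            assert a30 <= a20


class TestDesignSearch:
    def test_finds_design_hitting_target(self):
        design = design_chart(CFG_N30)
        assert CFG_N30.r0 <= design.arl0 <= CFG_N30.r0 * 1.02

    def test_published_constants_are_feasible(self):
        assert DESIGN_N30.arl0 >= 370.0
        assert DESIGN_FIT.arl0 >= 500.0

    def test_trivial_target_feasible(self):
        cfg = ChartConfig(n=10, delta=2.5, lambda_=1.5, r0=1.0)
        design = design_chart(cfg, k_grid=[2.0, 3.0], tau_grid=[0.5, 0.9])
        assert design.arl0 >= 1.0

    def test_deterministic(self):
        a = design_chart(CFG_N30, seed=1)
        b = design_chart(CFG_N30, seed=2)
        assert (a.k, a.tau) == (b.k, b.tau)

    def test_infeasible_reports_nearest_candidates(self):
        cfg = ChartConfig(n=3, delta=2.5, lambda_=1.5, r0=1e5)
        with pytest.raises(ValueError, match="nearest"):
            design_chart(cfg, k_grid=[2.0, 2.5], tau_grid=[0.5, 0.9])


class TestApplyChart:
    def test_decisions_match_the_probability_summation_set(self):
        d = DESIGN_N30
        counts = SubgroupCounts(counts=np.arange(0, 31), n=30)
        decisions = apply_chart(counts, d)
        for dd, signal in zip(decisions["failures"], decisions["signal"]):
            inside = d.d_lo <= dd <= d.ucl_int
            assert signal == (not inside)

    def test_central_counts_never_signal(self):
        mid = int((DESIGN_N30.lcl_raw + DESIGN_N30.ucl_raw) / 2)
        counts = SubgroupCounts(counts=np.full(12, mid), n=30)
        assert not apply_chart(counts, DESIGN_N30)["signal"].any()

    def test_survival_time_application_signals(self):
        # reconstructed failure counts from the published lifetimes, monitored
        # with the chart designed at the fitted parameters
        pars = NtsWeibullParams(0.42771, 0.88512, 1.02405)
        t0 = 0.773 * percentile_life(0.5, pars)
        counts = counts_from_times(load_survival_times().values, 20, t0)
        decisions = apply_chart(counts, DESIGN_FIT)
        assert decisions["signal"].any()

    def test_count_exceeding_subgroup_size_rejected(self):
        with pytest.raises(ValueError):
            SubgroupCounts(counts=np.array([31]), n=30)

    def test_mismatched_subgroup_size_rejected(self):
        counts = SubgroupCounts(counts=np.array([3]), n=20)
        with pytest.raises(ValueError):
            apply_chart(counts, DESIGN_N30)


class TestEmpiricalLimits:
    def test_degenerate_mean_count(self):
        assert empirical_limits(0.0, 30, 3.0) == (0.0, 0.0)

    def test_reproduces_model_based_limits_at_np0(self):
        p0 = p_fail(0.948, 2.5, 1.5)
        lcl, ucl, *_ = control_limits(30, p0, 2.981)
        e_lcl, e_ucl = empirical_limits(30 * p0, 30, 2.981)
        assert e_lcl == pytest.approx(lcl, abs=1e-12)
        assert e_ucl == pytest.approx(ucl, abs=1e-12)

    def test_direct_arithmetic(self):
        lcl, ucl = empirical_limits(13.1, 30, 3.0)
        half = 3.0 * np.sqrt(13.1 * (1 - 13.1 / 30))
        assert ucl == pytest.approx(13.1 + half)
        assert lcl == pytest.approx(13.1 - half)


class TestPercentileLife:
    def test_published_median_life_and_test_duration(self):
        pars = NtsWeibullParams(0.42771, 0.88512, 1.02405)
        xi = percentile_life(0.5, pars)
        assert xi == pytest.approx(6.64895, rel=0.01)
        assert 0.773 * xi == pytest.approx(5.1369, rel=0.01)

    def test_large_amplification_reduces_to_sine_weibull_median(self):
        d, a = 1.2, 0.3
        lam = 1e8
        xi = percentile_life(0.5, NtsWeibullParams(d, a, lam))
        sine_median = (-np.log(1 - (2 / np.pi) * np.arcsin(0.5)) / a) ** (1 / d)
        assert xi == pytest.approx(sine_median, rel=1e-6)


class TestCountsFromTimes:
    def test_partial_block_dropped(self):
        counts = counts_from_times(np.arange(1.0, 48.0), 20, 10.0)
        assert counts.counts.size == 2

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            counts_from_times([1.0, 2.0], 20, 1.0)
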