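"""The seven estimators of the selected-subpopulation effect."""

import numpy as np
import pytest

from enrichest import (
    ShrinkageConfig,
    build_design,
    estimate_all,
    multiple_iteration_adjusted,
    naive,
    partition_umvcue,
    select,
    shrinkage_factor,
    shrinkage_l1,
    shrinkage_l2,
    single_iteration_adjusted,
    subpop_from_partitions,
    theta_from_delta,
    umvcue,
    unbiased_weighted,
)
from enrichest.estimators import EstimationError
from enrichest.simulate import simulate_stage1_means, vector_estimates, vector_select


def _no_truncation_trial(xbar1=(1.2, 0.7, 0.4, 0.1), xbar2=(1.0, 0.9, 0.5, 0.2)):
    d = build_design((0.25, 0.5, 0.75, 1.0), 1.0, -np.inf, (50,) * 4, (50,) * 4)
    s1 = subpop_from_partitions(xbar1, d, 1)
    out = select(s1, d)
    s2 = subpop_from_partitions(xbar2, d, 2, s=out.s)
    return d, s1, out, s2


class TestNaive:
    def test_worked_example(self, worked_stage1, worked_stage2):
        assert naive(worked_stage1, worked_stage2, 2) == pytest.approx(2.614, abs=5e-4)

    def test_equal_stage_means_are_convex_fixed_point(self, worked_design):
        s1 = subpop_from_partitions((2.0,) * 4, worked_design, 1)
        s2 = subpop_from_partitions((2.0, 2.0), worked_design, 2)
        assert naive(s1, s2, 2) == pytest.approx(2.0)

    def test_stop_decision_has_no_estimand(self, worked_design):
        s1 = subpop_from_partitions((0.0,) * 4, worked_design, 1)
        out = select(s1, worked_design)
        with pytest.raises(EstimationError):
            estimate_all(s1, s1, out, worked_design)


class TestUmvcue:
    def test_worked_example(self, worked_stage1, worked_stage2, worked_outcome, worked_design):
        est = umvcue(worked_stage1, worked_stage2, worked_outcome, worked_design)
        assert est == pytest.approx(2.839, abs=1e-3)

    def test_no_truncation_equals_naive(self):
        d, s1, out, s2 = _no_truncation_trial()
        assert umvcue(s1, s2, out, d) == pytest.approx(naive(s1, s2, out.s), abs=1e-12)

    def test_rejection_sampling_rao_blackwell_oracle(self, rng):
        # UMVCUE = E[stage-2 mean | sufficient statistic, selection event]:
        # approximate the conditional expectation by retaining simulated
        # trials whose sufficient statistic falls in a narrow bin around an
        # observed value, and compare with the formula at the bin centre.
        d = build_design((0.5, 1.0), 1.0, 0.0, (40, 40), (40, 40))
        n = 1_500_000
        delta = np.array([0.25, -0.25])
        x1 = rng.normal(delta, np.sqrt(d.tau2_1), size=(n, 2))
        dec = vector_select(x1, d)
        keep = dec == 1
        y21 = rng.normal(delta[0], np.sqrt(d.tau2_2(1)[0]), size=n)
        t = d.t_fraction(1)
        theta_hat = t * x1[:, 0] + (1 - t) * y21
        # observed trial: sufficient statistic (theta_hat, x_12)
        obs_stat, obs_x12 = 0.35, -0.30
        bin1, bin2 = 0.02, 0.06
        sel = (
            keep
            & (np.abs(theta_hat - obs_stat) < bin1)
            & (np.abs(x1[:, 1] - obs_x12) < bin2)
        )
        assert sel.sum() > 400
        mc = y21[sel].mean()
        mc_se = y21[sel].std(ddof=1) / np.sqrt(sel.sum())
        # reconstruct a consistent observed trial: choose x_11 inside the
        # selection box [b, u) = [0, 0.3), then pick the stage-2 mean so
        # that theta_hat matches obs_stat (the UMVCUE depends on the data
        # only through the sufficient statistic, not on x_11 itself)
        x11 = 0.15
        y21_obs = (obs_stat - t * x11) / (1 - t)
        s1 = subpop_from_partitions((x11, obs_x12), d, 1)
        out = select(s1, d)
        assert out.decision == 1
        s2 = subpop_from_partitions((y21_obs,), d, 2, s=1)
        est = umvcue(s1, s2, out, d)
        assert abs(est - mc) < 3 * mc_se + 0.01

    def test_extreme_truncation_is_finite(self, worked_design):
        # naive estimate far below the truncation interval [b, u): both
        # phi/Phi arguments land deep in the same tail, so the ratio must be
        # evaluated in its stable scaled form, never 0/0
        s1 = subpop_from_partitions((3.0, 2.0, 0.8, 0.0), worked_design, 1)
        out = select(s1, worked_design)
        assert out.decision == 2
        s2 = subpop_from_partitions((-30.0, -30.0), worked_design, 2)
        est = umvcue(s1, s2, out, worked_design)
        assert np.isfinite(est)
        # the correction removes truncation bias toward the interval
        assert est < naive(s1, s2, 2)


class TestPartitionUmvcue:
    def test_worked_example(self, worked_stage1, worked_stage2, worked_outcome, worked_design):
        est1 = partition_umvcue(1, worked_stage1, worked_stage2, worked_outcome, worked_design)
        est2 = partition_umvcue(2, worked_stage1, worked_stage2, worked_outcome, worked_design)
        assert est1 == pytest.approx(3.272, abs=1e-3)
        assert est2 == pytest.approx(2.657, abs=1e-3)

    def test_no_truncation_equals_partition_naive(self):
        d, s1, out, s2 = _no_truncation_trial()
        expected = (50 * s1.xbar[0] + 50 * s2.xbar[0]) / 100
        assert partition_umvcue(1, s1, s2, out, d) == pytest.approx(expected, abs=1e-12)

    def test_unselected_partition_rejected(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        with pytest.raises(EstimationError):
            partition_umvcue(3, worked_stage1, worked_stage2, worked_outcome, worked_design)


class TestUnbiasedWeighted:
    def test_worked_example(self, worked_stage1, worked_stage2, worked_outcome, worked_design):
        est = unbiased_weighted(worked_stage1, worked_stage2, worked_outcome, worked_design)
        assert est == pytest.approx(2.965, abs=2e-3)

    def test_equals_umvcue_when_first_subpopulation_selected(self, rng):
        d = build_design((0.25, 0.5, 0.75, 1.0), 1.0, 0.3, (50,) * 4, (50,) * 4)
        found = 0
        for _ in range(300):
            x1 = rng.normal((0.4, -0.5, -0.5, -0.5), np.sqrt(d.tau2_1))
            s1 = subpop_from_partitions(x1, d, 1)
            out = select(s1, d)
            if out.decision != 1:
                continue
            found += 1
            x2 = rng.normal(0.4, np.sqrt(d.tau2_2(1)[0]), size=1)
            s2 = subpop_from_partitions(x2, d, 2, s=1)
            assert unbiased_weighted(s1, s2, out, d) == pytest.approx(
                umvcue(s1, s2, out, d), abs=1e-12
            )
        assert found > 20

    def test_conditional_mean_recovers_true_effect(self, rng):
        # simulation check of conditional unbiasedness at modest scale
        d = build_design((0.25, 0.5, 0.75, 1.0), 1.0, 0.0, (50,) * 4, 600)
        delta = (0.1, 0.0, -0.2, -0.1)
        theta = theta_from_delta(delta, d).theta_arr
        n = 150_000
        x1 = simulate_stage1_means(delta, d, rng, n)
        dec = vector_select(x1, d)
        s = 2
        rows = np.nonzero(dec == s)[0]
        x2 = rng.normal(np.asarray(delta)[:s], np.sqrt(d.tau2_2(s)), size=(rows.size, s))
        est = vector_estimates(x1[rows], x2, s, d, which=("umvcue", "unbiased"))
        for name in ("umvcue", "unbiased"):
            err = est[name] - theta[s - 1]
            assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(rows.size)


class TestBiasAdjusted:
    def test_single_iteration_worked_example(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        est, bias = single_iteration_adjusted(
            worked_stage1, worked_stage2, worked_outcome, worked_design
        )
        assert est == pytest.approx(2.633, abs=2e-3)
        assert bias < 0

    def test_single_iteration_no_truncation_equals_naive(self):
        d, s1, out, s2 = _no_truncation_trial()
        est, bias = single_iteration_adjusted(s1, s2, out, d)
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert est == pytest.approx(naive(s1, s2, out.s))

    def test_multiple_iteration_no_truncation_fixed_point_immediate(self):
        d, s1, out, s2 = _no_truncation_trial()
        res = multiple_iteration_adjusted(s1, s2, out, d)
        assert res.converged and res.iterations == 1
        assert res.estimate == pytest.approx(naive(s1, s2, out.s), abs=1e-12)

    def test_multiple_iteration_residual_bound_when_converged(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        res = multiple_iteration_adjusted(
            worked_stage1, worked_stage2, worked_outcome, worked_design, tol=0.001
        )
        assert res.converged
        assert res.residual <= 0.001

    def test_multiple_iteration_sits_above_single_iteration(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        si, _ = single_iteration_adjusted(
            worked_stage1, worked_stage2, worked_outcome, worked_design
        )
        mi = multiple_iteration_adjusted(
            worked_stage1, worked_stage2, worked_outcome, worked_design
        )
        assert mi.estimate > si

    def test_joint_scheme_exceeds_plugin_scheme(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        plugin = multiple_iteration_adjusted(
            worked_stage1, worked_stage2, worked_outcome, worked_design
        )
        joint = multiple_iteration_adjusted(
            worked_stage1, worked_stage2, worked_outcome, worked_design, dropped="iterate"
        )
        assert joint.estimate > plugin.estimate


class TestShrinkage:
    def test_factor_hand_arithmetic(self, worked_stage1, worked_design):
        # 1 - 2(K-3) sigma^2 / [n sum (xbar - mean)^2] with sigma=7, n=45
        spread = float(((worked_stage1.xbar - 1.45) ** 2).sum())
        expected = 1 - 2 * 49 / (45 * spread)
        c, c_plus = shrinkage_factor(worked_stage1, worked_design)
        assert c == pytest.approx(expected)
        assert c_plus == pytest.approx(expected)

    def test_k_minus_1_variant_fully_shrinks_worked_example(
        self, worked_stage1, worked_design
    ):
        cfg = ShrinkageConfig(c_variant="k_minus_1")
        c, c_plus = shrinkage_factor(worked_stage1, worked_design, cfg)
        assert c < 0 and c_plus == 0.0

    def test_zero_spread_gives_complete_shrinkage(self, worked_design):
        s1 = subpop_from_partitions((2.0,) * 4, worked_design, 1)
        c, c_plus = shrinkage_factor(s1, worked_design)
        assert c == -np.inf and c_plus == 0.0

    def test_large_spread_gives_no_shrinkage(self, worked_design):
        s1 = subpop_from_partitions((300.0, 100.0, -100.0, -300.0), worked_design, 1)
        _, c_plus = shrinkage_factor(s1, worked_design)
        assert c_plus == pytest.approx(1.0, abs=1e-3)

    def test_l1_equals_naive_without_shrinkage(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design, monkeypatch
    ):
        # C+ = 1 leaves the stage-1 means untouched
        import enrichest.estimators as mod

        monkeypatch.setattr(mod, "shrinkage_factor", lambda *a, **k: (1.0, 1.0))
        est, _, _ = shrinkage_l1(worked_stage1, worked_stage2, worked_outcome, worked_design)
        assert est == pytest.approx(naive(worked_stage1, worked_stage2, 2))

    def test_l1_complete_shrinkage_reproduces_printed_value(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        cfg = ShrinkageConfig(c_variant="k_minus_1")  # C+ = 0 on these data
        est, _, c_plus = shrinkage_l1(
            worked_stage1, worked_stage2, worked_outcome, worked_design, cfg
        )
        assert c_plus == 0.0
        assert est == pytest.approx(2.164, abs=1e-3)

    def test_l1_equals_naive_when_full_population_selected(self, rng):
        # equal prevalences + common t: shrinking toward the grand mean
        # cancels in the full-population weighted sum
        d = build_design((0.25, 0.5, 0.75, 1.0), 1.0, -np.inf, (50,) * 4, (50,) * 4)
        x1 = rng.normal(0.3, 0.5, size=4)
        x2 = rng.normal(0.3, 0.5, size=4)
        s1 = subpop_from_partitions(x1, d, 1)
        out = select(s1, d)
        s2 = subpop_from_partitions(x2, d, 2, s=4)
        est, _, _ = shrinkage_l1(s1, s2, out, d)
        assert est == pytest.approx(naive(s1, s2, 4), abs=1e-12)

    def test_l2_limits(self, worked_design, rng):
        # huge between-partition spread -> prior variance dominates -> naive;
        # zero spread -> complete shrinkage to the grand mean
        d = build_design((0.25, 0.5, 0.75, 1.0), 1.0, -np.inf, (50,) * 4, (50,) * 4)
        x1 = np.array([400.0, 200.0, -200.0, -400.0])
        x2 = rng.normal(0, 1, size=4)
        s1 = subpop_from_partitions(x1, d, 1)
        out = select(s1, d)
        s2 = subpop_from_partitions(x2, d, 2, s=4)
        est, _, status = shrinkage_l2(s1, s2, out, d)
        assert status == "ok"
        assert est == pytest.approx(naive(s1, s2, 4), rel=1e-3)

        s1c = subpop_from_partitions((2.0,) * 4, d, 1)
        outc = select(s1c, d)
        est_c, _, _ = shrinkage_l2(s1c, s2, outc, d)
        t = d.t_fraction(4)
        expected = t * 2.0 + (1 - t) * float(np.cumsum(0.25 * x2)[-1])
        assert est_c == pytest.approx(expected, abs=1e-9)

    def test_l2_worked_example_soft_range(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        est, trace, status = shrinkage_l2(
            worked_stage1, worked_stage2, worked_outcome, worked_design
        )
        assert status == "ok"
        assert 2.164 - 1e-6 <= est <= 2.614


class TestEstimateAll:
    def test_worked_example_report(
        self, worked_stage1, worked_stage2, worked_outcome, worked_design
    ):
        rep = estimate_all(worked_stage1, worked_stage2, worked_outcome, worked_design)
        assert rep.s == 2
        assert rep.naive == pytest.approx(2.614, abs=5e-4)
        assert rep.umvcue == pytest.approx(2.839, abs=1e-3)
        assert rep.unbiased == pytest.approx(2.965, abs=2e-3)
        assert rep.si == pytest.approx(2.633, abs=2e-3)
        assert rep.u == pytest.approx(2.6)
        # truncation-correction arguments on both scales
        assert rep.f_b == pytest.approx(0.779, abs=2e-3)
        assert rep.f_u == pytest.approx(0.018, abs=2e-3)
        assert rep.f_v == pytest.approx((0.896, 1.101), abs=2e-3)
        assert rep.f_w == pytest.approx((-0.179, 0.026), abs=2e-3)

    def test_no_truncation_collapse(self):
        d, s1, out, s2 = _no_truncation_trial()
        rep = estimate_all(s1, s2, out, d)
        base = rep.naive
        for val in (rep.umvcue, rep.unbiased, rep.si, rep.mi):
            assert val == pytest.approx(base, abs=1e-9)

    def test_random_trial_report_is_finite(self, rng):
        d = build_design((0.25, 0.5, 0.75, 1.0), 1.0, 0.0, (50,) * 4, 600)
        for _ in range(5):
            x1 = rng.normal(0.2, np.sqrt(d.tau2_1))
            s1 = subpop_from_partitions(x1, d, 1)
            out = select(s1, d)
            if out.stopped:
                continue
            x2 = rng.normal(0.2, np.sqrt(d.tau2_2(out.s)), size=out.s)
            s2 = subpop_from_partitions(x2, d, 2, s=out.s)
            rep = estimate_all(s1, s2, out, d)
            assert 0 < rep.t_s < 1
            vals = rep.as_dict()["estimates"].values()
            assert all(np.isfinite(v) for v in vals)
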