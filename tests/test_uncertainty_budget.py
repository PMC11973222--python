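"""Intermediate precision, trueness, total uncertainty and N_opt."""

import math

import numpy as np
import pytest

import psdcount as pc
from psdcount.particle_data import ParticleDataError

FMIN = pc.Measurand.FMIN


def _realized_day_sd(design):
    f = np.array(design.ground_truth["day_factors"])
    return float(f.std(ddof=1) / f.mean())


class TestIntermediatePrecision:
    def test_zero_for_constant_data_without_day_effect(self):
        design = pc.generate(pc.SyntheticSpec(
            "lognormal", median=20, iqr_pct=0, n=200, seed=0,
            design=pc.DesignSpec(days=3, reps_per_day=2, between_day_cv=0.0)))
        u_ip, dbar = pc.intermediate_precision(design, FMIN, "D50", n=100,
                                               reps=20, seed=0)
        assert u_ip == 0.0
        assert dbar == pytest.approx(20.0)

    def test_subset_larger_than_dataset_rejected(self, small_design):
        with pytest.raises(ParticleDataError):
            pc.intermediate_precision(small_design, FMIN, "D50", n=10**6, reps=5, seed=0)

    def test_day_effect_recovery_averaged_over_realizations(self):
        """At full n the estimator recovers a 3% day-effect CV within +-1%
        absolute, averaging over independent day realizations (with 3 days
        a single realization is chi-square(2)-spread around the nominal CV)."""
        vals = []
        for seed in range(16):
            design = pc.generate(pc.SyntheticSpec(
                "lognormal", median=20, iqr_pct=30, n=4000, seed=100 + seed,
                design=pc.DesignSpec(days=3, reps_per_day=2, between_day_cv=0.03)))
            u_ip, _ = pc.intermediate_precision(design, FMIN, "D50", n=4000,
                                                reps=50, seed=seed)
            vals.append(u_ip)
        assert np.mean(vals) == pytest.approx(0.03, abs=0.01)

    def test_small_n_count_noise_dominates(self, small_design):
        """At n=20 the count contribution u_n/2 and the day-effect floor add
        in quadrature."""
        u_ip, _ = pc.intermediate_precision(small_design, FMIN, "D50", n=20,
                                            reps=300, seed=2)
        s = pc.iqr_to_logsd(30.0)
        count = s * math.sqrt(math.pi / 2) / math.sqrt(20)  # u_n / 2
        floor = _realized_day_sd(small_design)
        assert u_ip == pytest.approx(math.hypot(count, floor), rel=0.25)


class TestTrueness:
    def test_exact_agreement_is_zero(self):
        assert pc.trueness_uncertainty(20.0, 20.0, 0.0, 0.0) == 0.0

    def test_arithmetic(self):
        # sqrt(0.4^2 + 0.3^2) / 20 = 0.025
        assert pc.trueness_uncertainty(20.4, 20.0, 0.3, 0.0) == pytest.approx(0.025)

    def test_certified_must_be_positive(self):
        with pytest.raises(ParticleDataError):
            pc.trueness_uncertainty(20.0, 0.0, 0.1, 0.0)

    def test_known_bias_recovery_at_large_n(self):
        """A generated +2% bias is recovered as delta/certified = 0.02 +- 0.005
        (averaged over day-effect realizations, whose mean-of-3 spread is the
        dominant noise term)."""
        deltas = []
        for seed in range(96):
            design = pc.generate(pc.SyntheticSpec(
                "lognormal", median=20, iqr_pct=30, n=2000, seed=1000 + seed,
                design=pc.DesignSpec(days=3, reps_per_day=2,
                                     between_day_cv=0.03, bias_fraction=0.02)))
            meds = [np.median(pc.derive_measurand(ds, FMIN))
                    for _, _, ds in design.datasets]
            deltas.append(np.mean(meds) / design.certified_value - 1.0)
        assert np.mean(deltas) == pytest.approx(0.02, abs=0.005)


@pytest.fixture(scope="module")
def curve(small_design):
    return pc.budget_curve(small_design, FMIN, "D50", reps=100, seed=5)


class TestBudgetCurve:
    def test_quadrature_identity_exact(self, curve):
        recomputed = 2.0 * np.sqrt(curve.u_ip**2 + curve.u_tr**2 + curve.u_cal**2)
        assert np.array_equal(recomputed, curve.u_cx)

    def test_u_cx_at_least_twice_u_cal(self):
        design = pc.generate(pc.SyntheticSpec(
            "lognormal", median=20, iqr_pct=0, n=200, seed=0,
            design=pc.DesignSpec(days=3, reps_per_day=2, between_day_cv=0.0)))
        design = pc.ValidationDesign(design.datasets, certified_value=20.0,
                                     u_certified=0.0, u_cal_rel=0.01)
        c = pc.budget_curve(design, FMIN, "D50", n_grid=[10, 50, 100], reps=20, seed=0)
        assert np.allclose(c.u_cx, 0.02)  # all components zero except u_cal

    def test_three_four_five_combination(self):
        assert pc.combine_expanded(0.03, 0.04, 0.0) == pytest.approx(0.10)

    def test_missing_u_tr_requires_fixed_value(self, small_design):
        bare = pc.ValidationDesign(small_design.datasets, certified_value=None,
                                   u_cal_rel=0.0)
        with pytest.raises(ParticleDataError, match="fixed relative u_tr"):
            pc.budget_curve(bare, FMIN, "D50", n_grid=[10, 100, 1000],
                            reps=10, seed=0)
        c = pc.budget_curve(bare, FMIN, "D50", n_grid=[10, 100, 1000],
                            reps=10, seed=0, u_tr_fixed=0.04)
        assert np.allclose(c.u_tr, 0.04)

    def test_saturates_at_generator_floor(self, curve, small_design):
        """u_cx at n_tot sits within 10% of the floor implied by the realized
        day effects and the applied bias."""
        gt = small_design.ground_truth
        f = np.array(gt["day_factors"])
        bias = 1.0 + gt["bias_fraction"]
        ip_floor = _realized_day_sd(small_design)
        # trueness floor: true bias of the grand mean plus the SE-of-mean term
        # produced by the day-factor spread over the 6 datasets
        delta = abs(bias * f.mean() - 1.0)
        fvec = np.repeat(f, 2)
        se_mean = bias * fvec.std(ddof=1) / math.sqrt(fvec.size)
        tr_floor = math.hypot(delta, se_mean)
        floor = 2.0 * math.hypot(ip_floor, tr_floor)
        assert curve.u_cx[-1] == pytest.approx(floor, rel=0.10)

    def test_roughly_non_increasing(self, curve):
        assert np.all(np.diff(curve.u_cx) <= 0.05 * curve.u_cx[:-1])

    def test_u_cx_dominates_count_component(self, curve):
        assert np.all(curve.u_cx >= curve.u_n_component - 0.10 * curve.u_cx)

    def test_json_roundtrip(self, curve):
        back = pc.BudgetCurve.from_dict(curve.to_dict())
        assert np.array_equal(back.u_cx, curve.u_cx)


class TestPiecewiseFit:
    @staticmethod
    def _two_line(xs, bp, sl, sr, a):
        return a + sl * np.minimum(xs, bp) + sr * np.maximum(0.0, xs - bp) \
            + sl * 0  # noqa: E501 - continuity built in

    def test_exact_two_line_recovery(self):
        x = np.linspace(1.0, 4.0, 16)
        y = -0.5 - 0.5 * np.minimum(x, 2.3) - 0.05 * np.maximum(0.0, x - 2.3)
        fit = pc.fit_piecewise(10**x, 10**y)
        assert fit.breakpoint_log10n == pytest.approx(2.3, abs=0.05)
        assert fit.slope_left == pytest.approx(-0.5, abs=0.02)
        assert fit.slope_right == pytest.approx(-0.05, abs=0.02)
        assert fit.identifiable

    def test_single_slope_unidentifiable(self):
        n = np.logspace(1, 4, 12)
        u = 0.8 / np.sqrt(n)
        fit = pc.fit_piecewise(n, u)
        assert not fit.identifiable

    def test_planted_crossover_recovered_within_factor_two(self):
        # u(N) = 2 sqrt(a/N + c) with components crossing at N = 200
        c = 0.02**2
        a = 200 * c
        n = np.logspace(1, 4, 25)
        fit = pc.fit_piecewise(n, 2 * np.sqrt(a / n + c))
        assert 100 <= fit.n_opt <= 400
        assert fit.slope_right > fit.slope_left

    def test_needs_six_points_and_a_decade(self):
        with pytest.raises(ParticleDataError):
            pc.fit_piecewise([10, 20, 40, 80, 160], np.ones(5))
        with pytest.raises(ParticleDataError):
            pc.fit_piecewise([10, 12, 14, 16, 18, 20],
                             [0.5, 0.4, 0.35, 0.3, 0.28, 0.27])

    def test_n_opt_scales_with_polydispersity(self):
        """Broader populations keep the count contribution dominant to larger
        N: N_opt increases over IQR% 30 -> 45 -> 68 (shared day factors)."""
        n_opts = []
        for iqr in (30.0, 45.0, 68.0):
            design = pc.generate(pc.SyntheticSpec(
                "lognormal", median=20, iqr_pct=iqr, n=4000, seed=31,
                design=pc.DesignSpec(days=3, reps_per_day=2, between_day_cv=0.03)))
            c = pc.budget_curve(design, FMIN, "D50", reps=60, seed=3)
            n_opts.append(pc.fit_piecewise(c.n_grid, c.u_cx).n_opt)
        assert n_opts[0] < n_opts[1] < n_opts[2]
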