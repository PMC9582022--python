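"""Interaction probing: simple slopes, crossover, Johnson-Neyman, PoI, PA, verdicts."""

import numpy as np
import pytest
from scipy import stats

import peersusc as ps
from peersusc import susceptibility as susc


def _fit(b_x=0.31, b_z=0.09, b_xz=0.21, se=0.07, rho=0.1, df=80):
    """InteractionFit with a simple exchangeable covariance."""
    cov = np.full((3, 3), rho * se**2)
    np.fill_diagonal(cov, se**2)
    return susc.InteractionFit(b_x=b_x, b_z=b_z, b_xz=b_xz, cov=cov, df_resid=df)


def _random_fit(rng):
    b = rng.normal(0, 0.3, 3)
    a = rng.normal(0, 0.08, (3, 3))
    cov = a @ a.T + 1e-4 * np.eye(3)
    return susc.InteractionFit(b[0], b[1], b[2], cov, int(rng.integers(30, 200)))


class TestSimpleSlope:
    def test_reduces_to_main_effect_at_mean_moderator(self):
        fit = _fit()
        s = susc.simple_slope(fit, 0.0)
        assert s.slope == pytest.approx(fit.b_x)
        assert s.se == pytest.approx(np.sqrt(fit.cov[0, 0]))

    def test_linear_combination_at_plus_minus_one_sd(self):
        fit = _fit(b_x=0.31, b_xz=0.21)
        assert susc.simple_slope(fit, +1.0).slope == pytest.approx(0.52)
        assert susc.simple_slope(fit, -1.0).slope == pytest.approx(0.10)

    def test_se_matches_parametric_bootstrap_oracle(self, rng):
        fit = _random_fit(rng)
        level = 0.7
        draws = rng.multivariate_normal([fit.b_x, fit.b_z, fit.b_xz], fit.cov, 100_000)
        oracle_se = (draws[:, 0] + level * draws[:, 2]).std(ddof=1)
        s = susc.simple_slope(fit, level)
        assert s.se == pytest.approx(oracle_se, rel=0.02)

    def test_missing_covariance_rejected(self):
        with pytest.raises(ValueError):
            susc.InteractionFit(0.3, 0.1, 0.2, np.full((3, 3), np.nan), 80)
        with pytest.raises(ValueError):
            susc.InteractionFit(0.3, 0.1, 0.2, np.eye(2), 80)


class TestSmallMultiples:
    def test_default_levels(self):
        slopes = susc.small_multiples(_fit())
        assert [s.moderator_level for s in slopes] == [-1.0, -0.5, 0.0, 0.5, 1.0]

    def test_zero_interaction_gives_identical_slopes(self):
        slopes = susc.small_multiples(_fit(b_xz=0.0))
        assert len({round(s.slope, 12) for s in slopes}) == 1

    def test_levels_permuted_gives_permuted_results(self):
        fit = _fit()
        a = susc.small_multiples(fit, levels=[-1, 0, 1])
        b = susc.small_multiples(fit, levels=[1, -1, 0])
        assert [s.slope for s in b] == [a[2].slope, a[0].slope, a[1].slope]

    def test_significance_monotone_for_strong_positive_interaction(self, study_fit):
        slopes = susc.small_multiples(study_fit)
        sig = [s.significant for s in slopes]
        assert sig == sorted(sig)  # once significant, stays significant upward


class TestCrossover:
    def test_symmetric_when_moderator_main_effect_zero(self):
        assert susc.crossover(_fit(b_z=0.0)) == 0.0

    def test_typical_coefficient_magnitudes(self):
        assert susc.crossover(_fit(b_z=0.09, b_xz=0.29)) == pytest.approx(-0.3103, abs=1e-4)

    def test_predicted_outcomes_equal_at_crossover(self):
        fit = _fit(b_x=0.4, b_z=0.13, b_xz=0.27)
        xc = susc.crossover(fit)
        y_hi = fit.b_x * xc + fit.b_z * (+1) + fit.b_xz * xc * (+1)
        y_lo = fit.b_x * xc + fit.b_z * (-1) + fit.b_xz * xc * (-1)
        assert y_hi == pytest.approx(y_lo, abs=1e-12)

    def test_undefined_without_interaction(self):
        assert np.isnan(susc.crossover(_fit(b_xz=0.0)))


def _grid_significance_bounds(fit, alpha=0.05, lo=-4, hi=4, n=10_001):
    """Brute-force scan: t-test of the moderator's conditional effect at each x."""
    xs = np.linspace(lo, hi, n)
    theta = fit.b_z + fit.b_xz * xs
    var = fit.cov[1, 1] + xs**2 * fit.cov[2, 2] + 2 * xs * fit.cov[1, 2]
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return xs, np.abs(theta) > tcrit * np.sqrt(var)


class TestJohnsonNeyman:
    def test_boundaries_match_grid_oracle(self, rng):
        checked = 0
        for _ in range(50):
            fit = _random_fit(rng)
            ros = susc.johnson_neyman(fit)
            xs, sig = _grid_significance_bounds(fit)
            if ros.degenerate_case != "none":
                # oracle agreement on the degenerate verdicts
                if ros.degenerate_case == "entire_range_significant":
                    assert sig.all()
                continue
            flips = xs[np.flatnonzero(np.diff(sig.astype(int)))]
            bounds = [b for b in (ros.lower_bound, ros.upper_bound) if -4 < b < 4]
            assert len(flips) == len(bounds)
            for b, f in zip(sorted(bounds), flips):
                assert b == pytest.approx(f, abs=1e-3 + (xs[1] - xs[0]))
            checked += 1
        assert checked >= 30  # most random fixtures are non-degenerate

    def test_conditional_effect_at_boundary_sits_at_critical_t(self, study_fit):
        ros = susc.johnson_neyman(study_fit)
        fit = susc.InteractionFit.from_results(study_fit)
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        for bound in (ros.lower_bound, ros.upper_bound):
            eff = susc._conditional_effect(fit, "z", bound, 0.05)
            assert abs(eff.t) == pytest.approx(tcrit, abs=1e-6)

    def test_strong_interaction_has_finite_real_bounds(self, study_fit):
        ros = susc.johnson_neyman(study_fit)
        assert ros.degenerate_case == "none"
        assert np.isfinite(ros.lower_bound) and np.isfinite(ros.upper_bound)
        assert ros.lower_bound <= ros.upper_bound
        assert ros.significant_outside

    def test_null_fit_is_degenerate(self):
        fit = _fit(b_z=0.0, b_xz=0.0)
        ros = susc.johnson_neyman(fit)
        assert ros.degenerate_case == "no_real_roots"

    def test_moderator_axis_probes_predictor_slope(self):
        fit = _fit(b_x=0.5, b_z=0.0, b_xz=0.25)
        ros = susc.johnson_neyman(fit, axis="moderator")
        # boundary solves |bX + bXZ z| = tcrit * se: check via the slope test
        s = susc.simple_slope(fit, ros.lower_bound)
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        assert abs(s.t) == pytest.approx(tcrit, abs=1e-6)


class TestProportionOfInteraction:
    def test_symmetric_crossover_gives_half(self):
        assert susc.proportion_of_interaction(0.0) == 0.5

    def test_typical_crossover_location(self):
        poi = susc.proportion_of_interaction(-0.310)
        assert poi == pytest.approx(2.31**2 / (2.31**2 + 1.69**2), abs=1e-6)
        assert poi == pytest.approx(0.6514, abs=1e-3)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(8)
        xs = np.linspace(-2, 2, 100_001)
        for _ in range(20):
            xc = rng.uniform(-1.8, 1.8)
            b_xz = rng.uniform(0.05, 0.5)
            gap = 2 * b_xz * np.abs(xs - xc)  # |line(+1SD) - line(-1SD)|
            right = np.trapezoid(np.where(xs > xc, gap, 0.0), xs)
            total = np.trapezoid(gap, xs)
            assert susc.proportion_of_interaction(xc) == pytest.approx(
                right / total, abs=1e-6
            )

    def test_saturates_outside_plot_range(self):
        assert susc.proportion_of_interaction(-2.5) == 1.0
        assert susc.proportion_of_interaction(2.5) == 0.0

    def test_reflection_symmetry(self):
        fit = _fit(b_z=0.12, b_xz=0.3)
        xc = susc.crossover(fit)
        poi = susc.proportion_of_interaction(xc)
        # negate the predictor: (bX, bZ, bXZ) -> (-bX, bZ, -bXZ)
        reflected = _fit(b_x=-fit.b_x, b_z=fit.b_z, b_xz=-fit.b_xz)
        assert susc.crossover(reflected) == pytest.approx(-xc)
        assert susc.proportion_of_interaction(susc.crossover(reflected)) == pytest.approx(
            1 - poi
        )
        # negate the moderator: (bX, -bZ, -bXZ) leaves crossover and PoI alone
        neg_mod = _fit(b_x=fit.b_x, b_z=-fit.b_z, b_xz=-fit.b_xz)
        assert susc.crossover(neg_mod) == pytest.approx(xc)

    def test_undefined_crossover_rejected(self):
        with pytest.raises(ValueError):
            susc.proportion_of_interaction(float("nan"))


class TestProportionAffected:
    def test_crossover_below_sample_minimum(self, rng):
        x = rng.normal(size=100)
        assert susc.proportion_affected(x, x.min() - 1) == 1.0

    def test_crossover_at_median(self, rng):
        x = rng.normal(size=101)
        assert susc.proportion_affected(x, np.median(x)) == pytest.approx(0.5, abs=0.005)

    def test_converges_to_normal_cdf(self):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(100_000)
        assert susc.proportion_affected(x, -0.310) == pytest.approx(
            stats.norm.cdf(0.310), abs=0.005
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            susc.proportion_affected([], 0.0)


class TestEvaluateCriteria:
    def test_study_conditions_yield_differential_susceptibility(self, study_fit):
        report = study_fit.probe()
        assert report.verdict == "differential_susceptibility"
        assert all(c.met for c in report.criteria[:1])
        assert 0.2 < report.poi < 0.8
        assert report.pa > 0.16

    def test_null_interaction_yields_no_moderation(self):
        cfg = ps.SynthConfig(n_subjects=200, beta_xz=0.0, cov_betas={}, seed=31)
        cohort = ps.generate_cohort(cfg, with_timeseries=False)
        res = ps.ModerationModel(cohort.records, outcome="behavior_composite").fit()
        report = res.probe()
        assert report.verdict == "no_moderation"
        # criteria 3-4 are only evaluated once the interaction is significant
        assert report.criteria[2].met is None and report.criteria[3].met is None

    def test_ordinal_interaction_flagged_not_differential(self, rng):
        # crossover far outside the plotting window -> PoI saturates
        fit = _fit(b_x=0.4, b_z=0.45, b_xz=0.15, se=0.03)
        x = rng.standard_normal(500)
        report = susc.evaluate_criteria(fit, x_values=x, interaction_p=1e-5)
        assert report.poi in (0.0, 1.0)
        assert report.verdict == "diathesis_stress_like"
        assert "strict" in report.criteria[2].evidence

    def test_report_serialization_roundtrip(self, study_fit):
        report = study_fit.probe()
        d = report.to_dict()
        assert d["verdict"] == report.verdict
        assert len(d["slopes"]) == 5
        text = report.summary()
        assert "crossover" in text and "PoI" in text and "PA" in text
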