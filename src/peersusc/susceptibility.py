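"""Differential-susceptibility probing of a fitted interaction.

Given a moderated-regression fit y = b0 + bX*X + bZ*Z + bXZ*X*Z + ...,
the battery asks whether the interaction reflects a "for better AND for
worse" (disordinal, crossover-type) pattern rather than a one-sided
diathesis-stress pattern:

* simple slopes of X at fixed moderator levels ("small multiples",
  -1 SD to +1 SD in 0.5 SD steps), with SEs from the coefficient
  covariance and t-tests on the step-3 residual df;
* the crossover point ``x_c = -bZ / bXZ``, the predictor value where all
  moderator levels predict the same outcome;
* Johnson-Neyman regions of significance — by default on the PREDICTOR
  axis (the values of peer norms at which the moderator's conditional
  effect ``bZ + bXZ*x`` is significant; evidence of differential
  susceptibility requires significance at both ends of the +-2 SD
  normative range), with the conventional moderator-axis probe also
  available;
* the Proportion of Interaction (PoI): the share of the area between the
  +-1 SD moderator regression lines, over a +-2 SD predictor window, that
  lies on the favorable side of the crossover (≈0.5 for a symmetric
  crossover; 0.40-0.60 strict band, 0.20-0.80 lenient band);
* the Proportion Affected (PA): the fraction of sampled predictor values
  above the crossover (> 16% expected under differential susceptibility);
* a four-criterion verdict combining the Bonferroni-gated interaction
  test, the simple-slope pattern, and the index battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .moderation import X_NAME, XZ_NAME, Z_NAME

NORMATIVE_RANGE_SD = 2.0
POI_STRICT = (0.40, 0.60)
POI_LENIENT = (0.20, 0.80)
PA_MINIMUM = 0.16
SMALL_MULTIPLE_LEVELS = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class InteractionFit:
    """Minimal interaction fit for probing: coefficients, covariance, df.

    ``cov`` is the 3x3 covariance of (bX, bZ, bXZ) in that order. Built
    directly (e.g. from a published coefficient table) or via
    :meth:`from_results` from a :class:`~peersusc.moderation.ModerationResults`.
    """

    b_x: float
    b_z: float
    b_xz: float
    cov: np.ndarray
    df_resid: int

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (3, 3):
            raise ValueError("cov must be the 3x3 covariance of (bX, bZ, bXZ)")
        if not np.all(np.isfinite(self.cov)):
            raise ValueError("non-finite coefficient covariance")
        if self.df_resid < 1:
            raise ValueError("df_resid must be positive")

    @classmethod
    def from_results(cls, results) -> "InteractionFit":
        names = [X_NAME, Z_NAME, XZ_NAME]
        missing = [n for n in names if n not in results.params.index]
        if missing:
            raise KeyError(f"fit lacks interaction terms: {missing}")
        cov = results.cov_params.loc[names, names].to_numpy()
        if not np.all(np.isfinite(cov)):
            raise ValueError("non-finite coefficient covariance")
        return cls(
            b_x=float(results.params[X_NAME]),
            b_z=float(results.params[Z_NAME]),
            b_xz=float(results.params[XZ_NAME]),
            cov=cov,
            df_resid=int(results.df_resid),
        )


def _as_fit(fit) -> InteractionFit:
    if isinstance(fit, InteractionFit):
        return fit
    return InteractionFit.from_results(fit)


@dataclass
class SimpleSlope:
    """Conditional slope at a fixed level of the other variable."""

    moderator_level: float
    slope: float
    se: float
    t: float
    p: float
    ci: tuple
    significant: bool


def _conditional_effect(fit: InteractionFit, which: str, at: float, alpha: float) -> SimpleSlope:
    """t-test of a conditional effect: X's slope at moderator level
    (``which='x'``) or Z's effect at a predictor value (``which='z'``)."""
    # covariance index order: (bX, bZ, bXZ)
    if which == "x":
        b1, i1 = fit.b_x, 0
    elif which == "z":
        b1, i1 = fit.b_z, 1
    else:
        raise ValueError(which)
    slope = b1 + fit.b_xz * at
    var = fit.cov[i1, i1] + at**2 * fit.cov[2, 2] + 2 * at * fit.cov[i1, 2]
    se = float(np.sqrt(var))
    t = slope / se
    p = 2 * stats.t.sf(abs(t), fit.df_resid)
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return SimpleSlope(
        moderator_level=float(at),
        slope=float(slope),
        se=se,
        t=float(t),
        p=float(p),
        ci=(float(slope - tcrit * se), float(slope + tcrit * se)),
        significant=bool(p < alpha),
    )


def simple_slope(fit, moderator_level: float, alpha: float = 0.05) -> SimpleSlope:
    """Slope of the predictor at a fixed moderator level (SD units).

    ``slope = bX + bXZ * z0`` with
    ``se = sqrt(var(bX) + z0^2 var(bXZ) + 2 z0 cov(bX, bXZ))`` and a
    t-test on the step-3 residual df.
    """
    return _conditional_effect(_as_fit(fit), "x", moderator_level, alpha)


def small_multiples(fit, levels=SMALL_MULTIPLE_LEVELS, alpha: float = 0.05) -> list:
    """Simple slopes across moderator levels (-1 SD..+1 SD in 0.5 SD steps)."""
    fit = _as_fit(fit)
    return [_conditional_effect(fit, "x", lv, alpha) for lv in levels]


def crossover(fit) -> float:
    """Crossover point ``x_c = -bZ / bXZ``; NaN when the interaction is zero."""
    fit = _as_fit(fit)
    if fit.b_xz == 0:
        return float("nan")
    return -fit.b_z / fit.b_xz


@dataclass
class RosResult:
    """Johnson-Neyman region-of-significance bounds.

    ``axis='predictor'`` (default) gives the predictor values at which the
    moderator's conditional effect is significant — the pivoted usage for
    differential-susceptibility probing; ``axis='moderator'`` is the
    conventional probe of the predictor's slope across moderator values.
    ``significant_outside`` is True when the significant region is
    outside [lower, upper] (the typical strong-interaction geometry).
    """

    axis: str
    lower_bound: float
    upper_bound: float
    bounds_within_normative_range: bool
    normative_range: float
    degenerate_case: str  # none | no_real_roots | entire_range_significant
    significant_outside: bool = True
    alpha: float = 0.05


def johnson_neyman(
    fit,
    axis: str = "predictor",
    alpha: float = 0.05,
    normative_range: float = NORMATIVE_RANGE_SD,
) -> RosResult:
    """Regions of significance of a conditional effect.

    Solves ``theta(v)^2 = t_crit^2 * var(theta(v))`` where, on the
    predictor axis, ``theta(x) = bZ + bXZ*x`` (and symmetrically for the
    moderator axis), i.e. the quadratic with
    ``a = bXZ^2 - t^2 var(bXZ)``, ``b = 2(b1*bXZ - t^2 cov(b1,bXZ))``,
    ``c = b1^2 - t^2 var(b1)``. Real roots are returned sorted; with no
    real roots the effect is either significant over the whole axis or
    nowhere, and the result is tagged accordingly.
    """
    f = _as_fit(fit)
    if axis == "predictor":
        b1, i1 = f.b_z, 1
    elif axis == "moderator":
        b1, i1 = f.b_x, 0
    else:
        raise ValueError("axis must be 'predictor' or 'moderator'")
    t2 = stats.t.ppf(1 - alpha / 2, f.df_resid) ** 2
    a = f.b_xz**2 - t2 * f.cov[2, 2]
    b = 2 * (b1 * f.b_xz - t2 * f.cov[i1, 2])
    c = b1**2 - t2 * f.cov[i1, i1]

    def _result(lo, hi, tag, outside):
        within = (
            tag == "none"
            and abs(lo) <= normative_range
            and abs(hi) <= normative_range
        )
        return RosResult(axis, lo, hi, within, normative_range, tag, outside, alpha)

    if a == 0 and b == 0:
        if c > 0:
            return _result(np.nan, np.nan, "entire_range_significant", False)
        return _result(np.nan, np.nan, "no_real_roots", False)
    if a == 0:
        root = -c / b
        # significance region is one-sided; report the single boundary twice
        return _result(float(root), float(root), "none", b > 0)
    disc = b**2 - 4 * a * c
    if disc < 0:
        # quadratic never crosses zero: sign of a decides everything
        if a > 0:
            return _result(np.nan, np.nan, "entire_range_significant", False)
        return _result(np.nan, np.nan, "no_real_roots", False)
    r1 = (-b - np.sqrt(disc)) / (2 * a)
    r2 = (-b + np.sqrt(disc)) / (2 * a)
    lo, hi = sorted((float(r1), float(r2)))
    return _result(lo, hi, "none", a > 0)


def proportion_of_interaction(
    fit_or_crossover, x_range=(-NORMATIVE_RANGE_SD, NORMATIVE_RANGE_SD)
) -> float:
    """PoI: share of the between-lines area right of the crossover.

    For moderator lines at +-1 SD the area between them grows as
    ``(x - x_c)^2`` on each side, giving the closed form
    ``(hi - x_c)^2 / ((hi - x_c)^2 + (x_c - lo)^2)`` over the plotting
    window ``[lo, hi]``; a crossover outside the window saturates the
    index at 0 or 1 (an ordinal interaction).
    """
    if isinstance(fit_or_crossover, (int, float, np.floating)):
        x_c = float(fit_or_crossover)
    else:
        x_c = crossover(fit_or_crossover)
    if not np.isfinite(x_c):
        raise ValueError("crossover undefined (zero interaction)")
    lo, hi = x_range
    if lo >= hi:
        raise ValueError("empty x_range")
    if x_c <= lo:
        return 1.0
    if x_c >= hi:
        return 0.0
    right = (hi - x_c) ** 2
    left = (x_c - lo) ** 2
    return float(right / (right + left))


def proportion_affected(x_values, crossover_x: float) -> float:
    """PA: fraction of subjects whose predictor value exceeds the crossover."""
    x = np.asarray(x_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty predictor sample")
    if not np.isfinite(crossover_x):
        raise ValueError("crossover undefined")
    return float(np.mean(x > crossover_x))


@dataclass
class Criterion:
    name: str
    met: "bool | None"
    evidence: str


@dataclass
class DiffSusceptibilityReport:
    """Crossover, RoS, PoI, PA, simple slopes, and the four-criterion verdict."""

    network: str | None
    crossover_x: float
    ros: RosResult
    poi: float
    pa: float
    slopes: list
    criteria: list
    verdict: str  # differential_susceptibility | diathesis_stress_like | no_moderation
    alpha: float
    alpha_corrected: float
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Differential-susceptibility report — network: {self.network}",
            f"crossover x_c = {self.crossover_x: .3f} SD",
        ]
        if self.ros.degenerate_case == "none":
            lines.append(
                f"RoS bounds: [{self.ros.lower_bound: .3f}, {self.ros.upper_bound: .3f}] SD "
                f"(within +-{self.ros.normative_range:g} SD: {self.ros.bounds_within_normative_range})"
            )
        else:
            lines.append(f"RoS: {self.ros.degenerate_case}")
        lines.append(f"PoI = {100 * self.poi:.1f}% right / {100 * (1 - self.poi):.1f}% left of crossover")
        lines.append(f"PA  = {100 * self.pa:.1f}% of subjects above crossover")
        lines.append("simple slopes (moderator level: b, p):")
        for s in self.slopes:
            flag = "sig." if s.significant else "n.s."
            lines.append(
                f"  {s.moderator_level:+.1f} SD: b = {s.slope: .3f} (SE {s.se:.3f}), "
                f"p = {s.p:.4f} [{flag}]"
            )
        lines.append("criteria:")
        for c in self.criteria:
            state = {True: "met", False: "NOT met", None: "not evaluated"}[c.met]
            lines.append(f"  {c.name}: {state} — {c.evidence}")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "crossover_x": self.crossover_x,
            "ros": {
                "axis": self.ros.axis,
                "lower_bound": self.ros.lower_bound,
                "upper_bound": self.ros.upper_bound,
                "bounds_within_normative_range": self.ros.bounds_within_normative_range,
                "degenerate_case": self.ros.degenerate_case,
            },
            "poi": self.poi,
            "pa": self.pa,
            "slopes": [
                {
                    "level": s.moderator_level,
                    "slope": s.slope,
                    "se": s.se,
                    "p": s.p,
                    "significant": s.significant,
                }
                for s in self.slopes
            ],
            "criteria": [{"name": c.name, "met": c.met, "evidence": c.evidence} for c in self.criteria],
            "verdict": self.verdict,
        }


def evaluate_criteria(
    results,
    x_values=None,
    *,
    interaction_p: float | None = None,
    bootstrap_ci=None,
    alpha: float = 0.05,
    alpha_corrected: float = 0.0125,
    normative_range: float = NORMATIVE_RANGE_SD,
    x_range=(-NORMATIVE_RANGE_SD, NORMATIVE_RANGE_SD),
    poi_strict=POI_STRICT,
    poi_lenient=POI_LENIENT,
    pa_minimum: float = PA_MINIMUM,
    network: str | None = None,
) -> DiffSusceptibilityReport:
    """Assemble the four-criterion differential-susceptibility verdict.

    Criterion 1: the interaction survives the multiplicity-corrected
    threshold (and, when a bootstrap CI table is supplied or already
    attached to the results, the BC interval excludes zero). Criterion 2:
    the predictor's simple slope is significant at +1 SD but not -1 SD of
    the moderator. Criteria 3-4 (evaluated only when criterion 1 holds):
    the effect crosses over inside the normative range — both RoS bounds
    within +-2 SD, PoI in the lenient 0.20-0.80 band (the strict 0.40-0.60
    band is reported as evidence), and PA > 0.16.

    Verdict: ``no_moderation`` without criterion 1;
    ``differential_susceptibility`` when criterion 1 and the full index
    battery hold; ``diathesis_stress_like`` for a significant but ordinal
    or one-sided interaction. Criterion 2 is reported as evidence but
    does not gate the verdict — near-threshold simple slopes at the low
    moderator level are a significance-threshold artifact, and the index
    battery is the formal test.
    """
    fit = _as_fit(results)
    if network is None:
        network = getattr(results, "network", None)
    if interaction_p is None and hasattr(results, "pvalues"):
        interaction_p = float(results.pvalues[XZ_NAME])
    if bootstrap_ci is None:
        bootstrap_ci = getattr(results, "bootstrap", None)
    if x_values is None and hasattr(results, "model"):
        x_values = results.model.x

    # criterion 1 — gated interaction
    if interaction_p is None:
        raise ValueError("need an interaction p-value (fit results or interaction_p=)")
    c1 = interaction_p < alpha_corrected
    evid1 = f"interaction p = {interaction_p:.4g} vs corrected alpha {alpha_corrected:g}"
    if bootstrap_ci is not None and XZ_NAME in getattr(bootstrap_ci, "index", []):
        excl = bool(bootstrap_ci.loc[XZ_NAME, "significant"])
        c1 = c1 and excl
        evid1 += (
            f"; BC bootstrap CI [{bootstrap_ci.loc[XZ_NAME, 'ci_lower']:.3f}, "
            f"{bootstrap_ci.loc[XZ_NAME, 'ci_upper']:.3f}] "
            + ("excludes 0" if excl else "covers 0")
        )

    slopes = small_multiples(fit, alpha=alpha)
    hi = _conditional_effect(fit, "x", +1.0, alpha)
    lo = _conditional_effect(fit, "x", -1.0, alpha)
    c2 = hi.significant and not lo.significant
    evid2 = (
        f"slope at +1 SD b = {hi.slope:.3f} (p = {hi.p:.4f}), "
        f"at -1 SD b = {lo.slope:.3f} (p = {lo.p:.4f})"
    )

    x_c = crossover(fit)
    ros = johnson_neyman(fit, axis="predictor", alpha=alpha, normative_range=normative_range)
    if np.isfinite(x_c):
        poi = proportion_of_interaction(x_c, x_range)
    else:
        poi = float("nan")
    pa = proportion_affected(x_values, x_c) if (x_values is not None and np.isfinite(x_c)) else float("nan")

    if c1:
        ros_ok = ros.bounds_within_normative_range and ros.significant_outside
        strict_ok = np.isfinite(poi) and poi_strict[0] <= poi <= poi_strict[1]
        lenient_ok = np.isfinite(poi) and poi_lenient[0] <= poi <= poi_lenient[1]
        pa_ok = np.isfinite(pa) and pa > pa_minimum
        c3 = bool(ros_ok and lenient_ok)
        c4 = bool(pa_ok)
        evid3 = (
            f"RoS within +-{normative_range:g} SD: {ros_ok}; "
            f"PoI = {poi:.3f} (strict {poi_strict[0]:.2f}-{poi_strict[1]:.2f}: {strict_ok}, "
            f"lenient {poi_lenient[0]:.2f}-{poi_lenient[1]:.2f}: {lenient_ok})"
        )
        evid4 = f"PA = {pa:.3f} vs minimum {pa_minimum:.2f}"
        if c3 and c4:
            verdict = "differential_susceptibility"
        else:
            verdict = "diathesis_stress_like"
    else:
        c3 = c4 = None
        evid3 = evid4 = "not evaluated (criterion 1 not met)"
        verdict = "no_moderation"

    criteria = [
        Criterion("1: significant gated interaction", bool(c1), evid1),
        Criterion("2: slope significant at high, not low, moderator", bool(c2), evid2),
        Criterion("3: crossover within normative range (RoS + PoI)", c3, evid3),
        Criterion("4: sufficient proportion affected", c4, evid4),
    ]
    return DiffSusceptibilityReport(
        network=network,
        crossover_x=float(x_c),
        ros=ros,
        poi=float(poi),
        pa=float(pa),
        slopes=slopes,
        criteria=criteria,
        verdict=verdict,
        alpha=alpha,
        alpha_corrected=alpha_corrected,
    )
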