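"""Hierarchical moderated regression of behavior on peer norms x connectivity.

The model follows the three-step hierarchical OLS design used in
moderation analyses of differential susceptibility:

* step 1 — covariates only (sex, age, usable resting-state volumes);
* step 2 — adds the main effects of peer norms (X) and within-network
  connectivity (Z);
* step 3 — adds their product X*Z, formed AFTER standardizing X and Z and
  entered as the raw product (probing algebra — crossover, simple slopes,
  Johnson-Neyman — requires the unrescaled product).

:class:`ModerationModel` is constructed from a subject-records DataFrame
and ``fit()`` returns a :class:`ModerationResults` carrying the three
nested fits, R^2 / delta-R^2 / adjusted R^2 / AIC, the step-3 coefficient
covariance needed by the probing battery, conventional OLS SEs and
t-based p-values, and bias-corrected (BC) case-resampling bootstrap CIs
on demand. Families of interaction tests across networks are gated with
a Bonferroni-corrected threshold, and cross-model coefficient equality is
assessed with a Wald z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .connectivity import DEFAULT_NETWORKS

X_NAME = "peer_norms"
Z_NAME = "connectivity"
XZ_NAME = "peer_norms_x_connectivity"
DEFAULT_COVARIATES = ("sex", "age", "usable_volumes")

BONFERRONI_FAMILY = 4  # one interaction test per candidate network


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance column — cannot standardize")
    return (v - v.mean()) / sd


def bonferroni_gate(p_values, n_tests: int | None = None, family_alpha: float = 0.05):
    """Family-wise gate: threshold ``alpha / n_tests``, strict comparison.

    Returns ``(threshold, decisions)`` where ``decisions[i]`` is True iff
    ``p_values[i] < threshold``. With the four-network family at
    alpha = 0.05 the threshold is 0.0125.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if n_tests is None:
        n_tests = p.size
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = family_alpha / n_tests
    return threshold, (p < threshold)


class ModerationModel:
    """Hierarchical moderated regression for one candidate network.

    Parameters
    ----------
    records : DataFrame
        One row per subject. Needs the predictor column (default
        ``peer_norms_z``), a ``conn_<network>`` moderator column, the
        covariates, and the outcome column.
    network : str
        Candidate network name; selects ``conn_<network>`` as moderator.
    outcome : str
        Outcome column (the behavior composite by default).
    covariates : sequence of str
        Step-1 covariate columns.
    standardize : bool
        z-score predictor, moderator and covariates (sample SD) before
        fitting. The interaction is always the product of the
        standardized parts.
    standardize_outcome : bool
        Additionally z-score the outcome (off by default so that analyses
        on an already-scaled outcome, or simulation-recovery work on the
        generated scale, keep their coefficients).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        network: str = "affective_salience",
        outcome: str = "behavior_composite_z",
        predictor: str = "peer_norms_z",
        covariates=DEFAULT_COVARIATES,
        standardize: bool = True,
        standardize_outcome: bool = False,
    ):
        self.network = network
        self.outcome_name = outcome
        zcol = f"conn_{network}"
        needed = [predictor, zcol, outcome, *covariates]
        missing = [c for c in needed if c not in records.columns]
        if missing:
            raise KeyError(f"records missing columns: {missing}")
        data = records[needed].dropna()
        n = len(data)
        n_predictors = len(covariates) + 3
        if n <= n_predictors + 2:
            raise ValueError(f"insufficient sample size n={n} for {n_predictors} predictors")
        x = data[predictor].to_numpy(dtype=float)
        z = data[zcol].to_numpy(dtype=float)
        covs = data[list(covariates)].to_numpy(dtype=float)
        if standardize:
            x, z = _zscore(x), _zscore(z)
            covs = np.column_stack([_zscore(covs[:, j]) for j in range(covs.shape[1])])
        y = data[outcome].to_numpy(dtype=float)
        if standardize_outcome:
            y = _zscore(y)
        self.covariate_names = list(covariates)
        self.x, self.z, self.covariates, self.y = x, z, covs, y
        self.n = n
        self.subject_index = data.index.to_numpy()

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs) -> "ModerationModel":
        return cls(records, **kwargs)

    # -- design matrices ------------------------------------------------
    def _designs(self):
        const = np.ones(self.n)
        d1 = np.column_stack([const, self.covariates])
        d2 = np.column_stack([d1, self.x, self.z])
        d3 = np.column_stack([d2, self.x * self.z])
        names1 = ["const", *self.covariate_names]
        names2 = names1 + [X_NAME, Z_NAME]
        names3 = names2 + [XZ_NAME]
        return (d1, names1), (d2, names2), (d3, names3)

    def fit(self) -> "ModerationResults":
        (d1, n1), (d2, n2), (d3, n3) = self._designs()
        fits = {}
        for step, (d, names) in enumerate([(d1, n1), (d2, n2), (d3, n3)], start=1):
            exog = pd.DataFrame(d, columns=names)
            if np.linalg.matrix_rank(d) < d.shape[1]:
                raise np.linalg.LinAlgError(f"rank-deficient design at step {step}")
            fits[step] = sm.OLS(self.y, exog).fit()
        return ModerationResults(self, fits)


def _aic_gaussian(rss: float, n: int, n_coef: int) -> float:
    """AIC with the ``n ln(RSS/n) + 2k`` convention, k counting the error variance."""
    return n * np.log(rss / n) + 2 * (n_coef + 1)


class ModerationResults:
    """Results of the three-step hierarchical fit.

    Exposes ``params``, ``bse``, ``pvalues``, ``cov_params`` (all step 3),
    per-step ``r2``, ``delta_r2`` (step 3 - step 2), ``adj_r2``, ``aic``
    and ``df_resid``; ``bootstrap_ci`` adds the bias-corrected bootstrap
    intervals reported alongside the OLS SEs.
    """

    def __init__(self, model: ModerationModel, fits: dict):
        self.model = model
        self.network = model.network
        self.outcome_name = model.outcome_name
        self.steps = fits
        final = fits[3]
        self.params = final.params
        self.bse = final.bse
        self.pvalues = final.pvalues
        self.tvalues = final.tvalues
        self.cov_params = final.cov_params()
        self.df_resid = int(final.df_resid)
        self.n = model.n
        self.r2 = {s: float(f.rsquared) for s, f in fits.items()}
        self.delta_r2 = self.r2[3] - self.r2[2]
        self.adj_r2 = float(final.rsquared_adj)
        self.aic = _aic_gaussian(float(final.ssr), self.n, len(final.params))
        self.bootstrap = None  # populated by bootstrap_ci

    # -- bootstrap ------------------------------------------------------
    def _design3(self):
        (d3, names3) = self.model._designs()[2]
        return d3, names3

    def bootstrap_ci(
        self, B: int = 5000, seed: int | None = None, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Bias-corrected (BC) percentile bootstrap CIs for the step-3 model.

        Case resampling of subjects with replacement, ``B`` resamples
        (>= 1000), solved in vectorized batches via the normal equations.
        The BC interval shifts the percentile endpoints by twice the
        median-bias z0 of the bootstrap distribution; a coefficient is
        flagged significant when its interval excludes zero. Rare
        rank-deficient resamples are redrawn (count in the ``n_redrawn``
        attribute of the returned frame).
        """
        if B < 1000:
            raise ValueError("use at least 1000 bootstrap resamples")
        rng = np.random.default_rng(seed)
        X, names = self._design3()
        y = self.model.y
        boot = _case_bootstrap(X, y, B, rng)
        est = self.params.to_numpy()
        z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
        rows = []
        for j, name in enumerate(names):
            bj = boot.coefs[:, j]
            prop = np.clip(np.mean(bj < est[j]), 1.0 / (B + 1), 1.0 - 1.0 / (B + 1))
            z0 = stats.norm.ppf(prop)
            lo_q = stats.norm.cdf(2 * z0 + z_lo)
            hi_q = stats.norm.cdf(2 * z0 + z_hi)
            lo, hi = np.quantile(bj, [lo_q, hi_q])
            rows.append(
                {
                    "coefficient": name,
                    "estimate": est[j],
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "z0": z0,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        table = pd.DataFrame(rows).set_index("coefficient")
        table.attrs["n_redrawn"] = boot.n_redrawn
        table.attrs["B"] = B
        self.bootstrap = table
        return table

    # -- reporting ------------------------------------------------------
    def coefficient_table(self) -> pd.DataFrame:
        """Step-wise coefficient table: B, SE, p, and bootstrap CI if computed."""
        rows = []
        for step, fit in self.steps.items():
            for name in fit.params.index:
                if name == "const" or _step_of(name, self.model) != step:
                    continue
                row = {
                    "step": step,
                    "coefficient": name,
                    "b": fit.params[name],
                    "se": fit.bse[name],
                    "p": fit.pvalues[name],
                }
                if self.bootstrap is not None and name in self.bootstrap.index:
                    row["ci_lower"] = self.bootstrap.loc[name, "ci_lower"]
                    row["ci_upper"] = self.bootstrap.loc[name, "ci_upper"]
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable hierarchical-regression table."""
        lines = [
            f"Hierarchical moderated regression — network: {self.network}",
            f"outcome: {self.outcome_name}   n = {self.n}",
            "-" * 64,
        ]
        table = self.coefficient_table()
        for step in (1, 2, 3):
            lines.append(f"Step {step}  (R2 = {self.r2[step]:.3f})")
            sub = table[table["step"] == step]
            for _, row in sub.iterrows():
                ci = ""
                if "ci_lower" in row and np.isfinite(row.get("ci_lower", np.nan)):
                    ci = f"  95% CI [{row['ci_lower']: .3f}, {row['ci_upper']: .3f}]"
                stars = "*" if row["p"] < 0.0125 else ""
                lines.append(
                    f"  {row['coefficient']:<28s} {row['b']: .3f} ({row['se']:.3f}){stars}{ci}"
                )
        lines += [
            "-" * 64,
            f"delta R2 (step 3 - step 2) = {self.delta_r2:.4f}",
            f"adjusted R2 (step 3)       = {self.adj_r2:.4f}",
            f"AIC (step 3)               = {self.aic:.2f}",
        ]
        return "\n".join(lines)

    # -- probing entry point --------------------------------------------
    def probe(self, x_values=None, **kwargs):
        """Differential-susceptibility report for this fit (see susceptibility module)."""
        from . import susceptibility

        if x_values is None:
            x_values = self.model.x
        return susceptibility.evaluate_criteria(self, x_values=x_values, **kwargs)


def _step_of(name: str, model: ModerationModel) -> int:
    if name in model.covariate_names:
        return 1
    if name in (X_NAME, Z_NAME):
        return 2
    if name == XZ_NAME:
        return 3
    return 1


@dataclass
class _BootstrapDraws:
    coefs: np.ndarray
    n_redrawn: int


def _case_bootstrap(X, y, B, rng, chunk: int = 2000) -> _BootstrapDraws:
    """Vectorized case-resampling OLS: coefficients for B resamples."""
    n, p = X.shape
    out = np.empty((B, p))
    n_redrawn = 0
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        Xb = X[idx]
        yb = y[idx]
        XtX = np.einsum("bni,bnj->bij", Xb, Xb)
        Xty = np.einsum("bni,bn->bi", Xb, yb)
        try:
            out[done : done + b] = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for k in range(b):
                while True:
                    try:
                        out[done + k] = np.linalg.solve(XtX[k], Xty[k])
                        break
                    except np.linalg.LinAlgError:
                        n_redrawn += 1
                        i = rng.integers(0, n, size=n)
                        Xk, yk = X[i], y[i]
                        XtX[k] = Xk.T @ Xk
                        Xty[k] = Xk.T @ yk
        done += b
    return _BootstrapDraws(out, n_redrawn)


@dataclass
class WaldComparison:
    """Cross-model equality-of-coefficient test."""

    coefficient: str
    model_a: str
    model_b: str
    z: float
    p: float
    method: str


def wald_compare(
    fit_a: ModerationResults,
    fit_b: ModerationResults,
    coefficient: str = XZ_NAME,
    method: str = "independence",
    B: int = 2000,
    seed: int | None = None,
) -> WaldComparison:
    """Wald z for equality of one coefficient across two fitted models.

    ``independence``: z = (bA - bB) / sqrt(seA^2 + seB^2), ignoring the
    cross-model covariance. ``bootstrap``: both models are refit on the
    same case resamples (they must share subjects) and z is the observed
    difference over the bootstrap SD of the difference. Two-sided normal
    p either way. Swapping the models negates z.
    """
    for fit in (fit_a, fit_b):
        if coefficient not in fit.params.index:
            raise KeyError(f"coefficient {coefficient!r} absent from model {fit.network}")
    ba, bb = fit_a.params[coefficient], fit_b.params[coefficient]
    if method == "independence":
        se = np.sqrt(fit_a.bse[coefficient] ** 2 + fit_b.bse[coefficient] ** 2)
        z = (ba - bb) / se
    elif method == "bootstrap":
        if not np.array_equal(fit_a.model.subject_index, fit_b.model.subject_index):
            raise ValueError("bootstrap comparison requires fits on the same subjects")
        rng = np.random.default_rng(seed)
        Xa, names_a = fit_a._design3()
        Xb, names_b = fit_b._design3()
        ja, jb = names_a.index(coefficient), names_b.index(coefficient)
        n = Xa.shape[0]
        idx = rng.integers(0, n, size=(B, n))
        diffs = np.empty(B)
        for k in range(B):
            i = idx[k]
            ca = np.linalg.lstsq(Xa[i], fit_a.model.y[i], rcond=None)[0][ja]
            cb = np.linalg.lstsq(Xb[i], fit_b.model.y[i], rcond=None)[0][jb]
            diffs[k] = ca - cb
        z = (ba - bb) / diffs.std(ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2 * stats.norm.sf(abs(z))
    return WaldComparison(coefficient, fit_a.network, fit_b.network, float(z), float(p), method)


@dataclass
class AllNetworksFit:
    """Per-network fits plus the simultaneous all-networks model."""

    fits: dict
    simultaneous: "sm.regression.linear_model.RegressionResultsWrapper"
    simultaneous_names: list
    condition_number: float
    bonferroni_threshold: float
    interaction_p: dict
    significant: dict


def fit_all_networks(
    records: pd.DataFrame,
    outcome: str = "behavior_composite_z",
    networks=None,
    predictor: str = "peer_norms_z",
    covariates=DEFAULT_COVARIATES,
    family_alpha: float = 0.05,
    **model_kwargs,
) -> AllNetworksFit:
    """Fit the four separate hierarchical models and the simultaneous model.

    The interaction p-values of the separate fits are gated at the
    Bonferroni-corrected threshold (family alpha over the number of
    networks). The simultaneous model enters all network moderators and
    all products at once; its design condition number is recorded as a
    collinearity diagnostic.
    """
    if networks is None:
        networks = list(DEFAULT_NETWORKS)
    if not networks:
        raise ValueError("empty network list")
    # listwise deletion over every column any of the fits will use, so the
    # separate and simultaneous models share the same subjects
    needed = [predictor, outcome, *covariates] + [f"conn_{net}" for net in networks]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise KeyError(f"records missing columns: {missing}")
    records = records.dropna(subset=needed)
    fits = {
        net: ModerationModel(
            records, network=net, outcome=outcome, predictor=predictor,
            covariates=covariates, **model_kwargs,
        ).fit()
        for net in networks
    }
    p_int = {net: float(fit.pvalues[XZ_NAME]) for net, fit in fits.items()}
    threshold, decisions = bonferroni_gate(
        [p_int[n] for n in networks], n_tests=len(networks), family_alpha=family_alpha
    )
    significant = dict(zip(networks, (bool(d) for d in decisions)))

    # simultaneous model on the listwise-complete rows shared by all fits
    first = fits[networks[0]].model
    x = first.x
    cols = [np.ones(first.n), *first.covariates.T, x]
    names = ["const", *first.covariate_names, X_NAME]
    for net in networks:
        z = fits[net].model.z
        cols += [z]
        names += [f"conn_{net}"]
    for net in networks:
        cols += [x * fits[net].model.z]
        names += [f"{X_NAME}_x_{net}"]
    design = np.column_stack(cols)
    simultaneous = sm.OLS(first.y, pd.DataFrame(design, columns=names)).fit()
    cond = float(np.linalg.cond(design))
    return AllNetworksFit(
        fits=fits,
        simultaneous=simultaneous,
        simultaneous_names=names,
        condition_number=cond,
        bonferroni_threshold=threshold,
        interaction_p=p_int,
        significant=significant,
    )
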