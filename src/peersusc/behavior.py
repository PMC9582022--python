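"""Questionnaire scoring and the adolescent behavior composite.

Three self-report scales drive the analysis: perceived peer-group norms
(16 items, 1-6; the eight positive-behavior items are reverse coded so
that higher scores mean relatively more negative than positive norms),
prosocial tendencies (21 items, 1-5), and risk-taking frequency (14
items, 0-3). Every scale is scored as the mean item rating after reverse
coding. The behavior composite reverses the prosocial mean on its 1-5
range, z-scores it together with the risk mean across the cohort, and
averages the two: higher values mean relatively more risky than
prosocial behavior.

Internal consistency is summarized by Cronbach's alpha. All z-scoring
uses the sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScaleDefinition:
    """Multi-item Likert scale: item count, response range, reverse-keyed items.

    ``reverse_items`` holds 1-based item indices.
    """

    name: str
    k_items: int
    response_min: float
    response_max: float
    reverse_items: frozenset = field(default_factory=frozenset)
    item_prefix: str = ""

    def __post_init__(self):
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be below response_max")
        if self.k_items < 2:
            raise ValueError("a scale needs at least two items")
        bad = [i for i in self.reverse_items if not 1 <= i <= self.k_items]
        if bad:
            raise ValueError(f"reverse item indices out of range: {bad}")

    @property
    def item_columns(self) -> list[str]:
        prefix = self.item_prefix or self.name
        return [f"{prefix}_{i:02d}" for i in range(1, self.k_items + 1)]


# The 8/8 negative/positive split of the peer-norms items is a convention
# of this package (the instrument mixes both valences); positions 9-16
# carry the positive behaviors and are reverse coded.
PEER_NORMS = ScaleDefinition(
    "peer_norms", 16, 1, 6, frozenset(range(9, 17)), item_prefix="pn"
)
PROSOCIAL = ScaleDefinition("prosocial", 21, 1, 5, item_prefix="ptm")
RISK = ScaleDefinition("risk", 14, 0, 3, item_prefix="art")

DEFAULT_SCALES = {s.name: s for s in (PEER_NORMS, PROSOCIAL, RISK)}

#: Minimum fraction of answered items for a row mean to be computed.
MIN_COMPLETE_FRACTION = 0.80


def _item_array(responses, scale: ScaleDefinition) -> np.ndarray:
    if isinstance(responses, pd.DataFrame):
        cols = [c for c in scale.item_columns if c in responses.columns]
        if len(cols) == scale.k_items:
            responses = responses[cols]
        arr = responses.to_numpy(dtype=float)
    else:
        arr = np.asarray(responses, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != scale.k_items:
        raise ValueError(
            f"{scale.name}: expected {scale.k_items} item columns, got {arr.shape[1]}"
        )
    observed = arr[np.isfinite(arr)]
    if observed.size and (
        observed.min() < scale.response_min or observed.max() > scale.response_max
    ):
        raise ValueError(f"{scale.name}: responses outside the scale range")
    return arr


def reverse_code(responses, scale: ScaleDefinition):
    """Map ``x -> min + max - x`` on the scale's reverse-keyed items.

    Applying it twice is the identity.
    """
    arr = _item_array(responses, scale).copy()
    idx = [i - 1 for i in sorted(scale.reverse_items)]
    if idx:
        arr[:, idx] = scale.response_min + scale.response_max - arr[:, idx]
    return arr


def score_scale(
    responses, scale: ScaleDefinition, min_complete: float = MIN_COMPLETE_FRACTION
) -> np.ndarray:
    """Per-subject mean rating after reverse coding.

    Rows with fewer than ``min_complete`` of the items answered get NaN
    (flagged, excluded downstream) rather than an imputed score; rows with
    partial but sufficient data use the mean of observed items.
    """
    arr = reverse_code(responses, scale)
    answered = np.isfinite(arr).mean(axis=1)
    with np.errstate(invalid="ignore"):
        scores = np.nanmean(arr, axis=1)
    scores[answered < min_complete] = np.nan
    return scores


def standardize(values) -> np.ndarray:
    """z-scores with sample SD (ddof=1): mean 0, SD 1 across the cohort.

    NaNs pass through and are excluded from the mean/SD.
    """
    arr = np.asarray(values, dtype=float)
    ok = np.isfinite(arr)
    if ok.sum() < 2:
        raise ValueError("need at least two observed values to standardize")
    sd = arr[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance — cannot standardize")
    out = np.full(arr.shape, np.nan)
    out[ok] = (arr[ok] - arr[ok].mean()) / sd
    return out


def behavior_composite(prosocial_mean, risk_mean) -> np.ndarray:
    """Cohort behavior composite: z(reverse-coded prosocial) and z(risk) averaged.

    The prosocial mean is reversed on its 1-5 range (``6 - mean``) so that
    on both ingredients larger values point toward risk; the composite is
    the average of the two cohort z-scores (higher = more risky than
    prosocial).
    """
    prosocial_mean = np.asarray(prosocial_mean, dtype=float)
    risk_mean = np.asarray(risk_mean, dtype=float)
    reversed_prosocial = (PROSOCIAL.response_min + PROSOCIAL.response_max) - prosocial_mean
    return (standardize(reversed_prosocial) + standardize(risk_mean)) / 2.0


def cronbach_alpha(item_matrix, scale: ScaleDefinition | None = None) -> float:
    """Cronbach's alpha, ``(k/(k-1)) * (1 - sum(item var) / var(total))``.

    When a scale is given, reverse coding is applied first. Variances use
    ddof=1; rows with any missing item are dropped.
    """
    if scale is not None:
        arr = reverse_code(item_matrix, scale)
    else:
        arr = np.asarray(item_matrix, dtype=float)
    arr = arr[np.isfinite(arr).all(axis=1)]
    n, k = arr.shape
    if k < 2:
        raise ValueError("alpha needs at least two items")
    if n < 3:
        raise ValueError("alpha needs at least three complete rows")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def score_items(items: pd.DataFrame, scales=None) -> pd.DataFrame:
    """Score an item-level table into per-subject scale scores.

    Expects columns ``pn_01..pn_16``, ``ptm_01..ptm_21``, ``art_01..art_14``
    plus any passthrough covariates (``subject_id``, ``age``, ``sex``,
    ...). Returns a DataFrame with ``peer_norms_raw``, ``peer_norms_z``,
    ``prosocial_mean``, ``risk_mean``, ``behavior_composite_z`` and the
    passthrough columns.
    """
    if scales is None:
        scales = DEFAULT_SCALES
    out = {}
    passthrough = [
        c
        for c in items.columns
        if not any(c.startswith(s.item_prefix + "_") for s in scales.values())
    ]
    for c in passthrough:
        out[c] = items[c].to_numpy()
    pn = score_scale(items, scales["peer_norms"])
    out["peer_norms_raw"] = pn
    out["peer_norms_z"] = standardize(pn)
    out["prosocial_mean"] = score_scale(items, scales["prosocial"])
    out["risk_mean"] = score_scale(items, scales["risk"])
    out["behavior_composite_z"] = behavior_composite(out["prosocial_mean"], out["risk_mean"])
    return pd.DataFrame(out)


def build_records(
    items: pd.DataFrame, connectivity: pd.DataFrame | None = None, scales=None
) -> pd.DataFrame:
    """Scored subject records, optionally joined with cohort connectivity.

    ``connectivity`` is the subject x network table from
    :func:`peersusc.connectivity.cohort_connectivity`; the join is on
    ``subject_id`` and missing matches raise rather than drop.
    """
    scored = score_items(items, scales=scales)
    if connectivity is None:
        return scored
    merged = scored.merge(connectivity, on="subject_id", how="left", suffixes=("", "_conn"))
    conn_cols = [c for c in connectivity.columns if c.startswith("conn_")]
    unmatched = merged[conn_cols].isna().all(axis=1)
    if unmatched.any():
        raise KeyError(
            "no connectivity for subjects: "
            f"{merged.loc[unmatched, 'subject_id'].tolist()}"
        )
    return merged
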