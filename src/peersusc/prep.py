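"""ROI-level resting-state timeseries preparation.

Motion quality control and nuisance removal for ROI-averaged BOLD
timeseries: framewise displacement (FD, Power convention: summed absolute
backward differences of the six rigid-body parameters, rotations converted
to millimetres on a 50 mm sphere), a simple ROI-level DVARS (QC metric
only, never used for censoring), strict-threshold scrubbing, the
subject-level usability rule (exclude when more than 10% of volumes exceed
the FD threshold before scrubbing, or when the scan is shorter than four
minutes), a discrete-cosine high-pass drift basis (128 s cut-off), and OLS
confound regression.

The fixed pipeline order is FD -> QC -> confound regression (including the
cosine drift columns) -> scrubbing; :func:`prep_subject` runs the chain and
logs what it did. A censored-aware variant (scrub before regressing) is
available via a flag; the two orderings are *not* equivalent and the
difference is demonstrated in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fMRIPrep-dialect motion parameter columns (translations mm, rotations rad).
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

#: Default nuisance columns regressed alongside the cosine basis.
DEFAULT_CONFOUNDS = MOTION_COLUMNS + ["csf", "white_matter"]

FD_THRESHOLD_MM = 0.30
HEAD_RADIUS_MM = 50.0
DCT_CUTOFF_S = 128.0
MIN_DURATION_S = 240.0
MAX_HIGH_FD_FRACTION = 0.10


@dataclass
class QcResult:
    """Subject-level motion quality-control summary.

    ``usable`` is True iff at most 10% of volumes exceed the FD threshold
    (computed before any scrubbing) and the acquisition lasts at least
    four minutes. ``reasons`` lists which rule(s) failed.
    """

    subject_id: str | None
    n_volumes: int
    pct_high_fd_prescrub: float
    mean_fd: float
    max_fd: float
    duration_seconds: float
    usable: bool
    reasons: list[str] = field(default_factory=list)


def _as_matrix(x, name="input"):
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (volumes x columns)")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")
    return arr


def compute_fd(motion, head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement from six rigid-body parameters.

    Parameters
    ----------
    motion : array-like or DataFrame, shape (T, 6)
        Three translations (mm) followed by three rotations (radians).
        A DataFrame with the fMRIPrep column names is reordered
        automatically.
    head_radius_mm : float
        Sphere radius used to convert rotation angles to arc length.

    Returns
    -------
    fd : ndarray, shape (T,)
        ``fd[i] = sum |d trans_i| + r * sum |d rot_i|`` for ``i >= 1``;
        the first volume has no predecessor and is defined as 0.
    """
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    if isinstance(motion, pd.DataFrame):
        motion = motion[MOTION_COLUMNS]
    arr = _as_matrix(motion, "motion")
    if arr.shape[1] != 6:
        raise ValueError("motion must have six columns (3 trans, 3 rot)")
    if arr.shape[0] < 2:
        raise ValueError("need at least two volumes to compute FD")
    d = np.abs(np.diff(arr, axis=0))
    fd = np.zeros(arr.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def compute_dvars(ts) -> np.ndarray:
    """ROI-level DVARS: RMS across ROIs of the backward temporal difference.

    First volume is 0 by convention. This is a QC descriptive only — the
    pipeline never censors on DVARS.
    """
    arr = _as_matrix(ts, "timeseries")
    if arr.shape[0] < 2:
        raise ValueError("need at least two volumes to compute DVARS")
    diff = np.diff(arr, axis=0)
    dvars = np.zeros(arr.shape[0])
    dvars[1:] = np.sqrt(np.mean(diff**2, axis=1))
    return dvars


def flag_scrub(fd, threshold_mm: float = FD_THRESHOLD_MM) -> np.ndarray:
    """Boolean censor mask: True where ``fd`` strictly exceeds the threshold.

    No neighbour augmentation — exactly the flagged volumes are censored.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    fd = np.asarray(fd, dtype=float)
    return fd > threshold_mm


def qc_subject(
    fd,
    tr_seconds: float,
    threshold_mm: float = FD_THRESHOLD_MM,
    max_high_fd_fraction: float = MAX_HIGH_FD_FRACTION,
    min_duration_seconds: float = MIN_DURATION_S,
    subject_id: str | None = None,
) -> QcResult:
    """Apply the subject-exclusion rule to a pre-scrubbing FD trace.

    The high-FD fraction uses all volumes as denominator and is computed
    before scrubbing; both exclusion comparisons are strict
    (``fraction > 0.10``, ``duration < 240 s``). Mean and max FD summarize
    volumes 1..T-1 (the first FD value is a convention, not a measurement).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD trace")
    n = fd.size
    frac_high = float(np.mean(fd > threshold_mm))
    duration = n * tr_seconds
    reasons = []
    if frac_high > max_high_fd_fraction:
        reasons.append("high motion")
    if duration < min_duration_seconds:
        reasons.append("short scan")
    body = fd[1:] if n > 1 else fd
    return QcResult(
        subject_id=subject_id,
        n_volumes=n,
        pct_high_fd_prescrub=frac_high,
        mean_fd=float(body.mean()),
        max_fd=float(body.max()),
        duration_seconds=float(duration),
        usable=not reasons,
        reasons=reasons,
    )


def dct_basis(n_volumes: int, tr_seconds: float, cutoff_seconds: float = DCT_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift basis for high-pass filtering by regression.

    Columns are the orthonormal DCT-II components with period longer than
    ``cutoff_seconds``; their count is ``floor(2 * T * tr / cutoff)`` (the
    constant term is excluded — an intercept is always added by the
    regression step). For an 8-minute scan at TR = 2 s and the 128 s
    cut-off this yields 7 columns.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if cutoff_seconds <= 2 * tr_seconds:
        raise ValueError("cutoff_seconds must exceed twice the TR")
    # component k has period 2*T*tr/k; keep those strictly longer than the
    # cutoff (so a cutoff at or beyond the run length leaves no columns)
    ratio = 2.0 * n_volumes * tr_seconds / cutoff_seconds
    n_cols = max(int(np.ceil(ratio)) - 1, 0)
    t = np.arange(n_volumes)
    k = np.arange(1, n_cols + 1)
    # DCT-II: orthonormal over t = 0..N-1, mutually orthogonal and
    # orthogonal to the constant vector.
    basis = np.sqrt(2.0 / n_volumes) * np.cos(
        np.pi * np.outer(2 * t + 1, k) / (2.0 * n_volumes)
    )
    return basis


def regress_confounds(ts, confounds, columns=None):
    """OLS-residualize each ROI timeseries against a confound design.

    An intercept is always included, so residuals are mean-centred and
    orthogonal to every selected confound column. ``confounds`` may be a
    DataFrame (then ``columns`` selects by name) or a plain matrix.
    Returns the same container type as ``ts``.
    """
    is_df = isinstance(ts, pd.DataFrame)
    y = _as_matrix(ts, "timeseries")
    if isinstance(confounds, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in confounds.columns]
            if missing:
                raise KeyError(f"confound columns not found: {missing}")
            confounds = confounds[list(columns)]
        conf = confounds.to_numpy(dtype=float)
    else:
        conf = _as_matrix(confounds, "confounds")
        if columns is not None:
            conf = conf[:, list(columns)]
    if conf.shape[0] != y.shape[0]:
        raise ValueError(
            f"confounds have {conf.shape[0]} rows but timeseries has {y.shape[0]} volumes"
        )
    design = np.column_stack([np.ones(y.shape[0]), conf])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("confound design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if is_df:
        return pd.DataFrame(resid, index=ts.index, columns=ts.columns)
    return resid


def scrub(ts, censor_mask):
    """Drop censored volumes (no interpolation).

    ``censor_mask`` is True for volumes to remove and must cover every
    volume; removing all of them is an error.
    """
    mask = np.asarray(censor_mask, dtype=bool)
    n = ts.shape[0]
    if mask.size != n:
        raise ValueError(f"censor mask length {mask.size} != volume count {n}")
    if mask.all():
        raise ValueError("all volumes censored — no data left")
    keep = ~mask
    if isinstance(ts, pd.DataFrame):
        return ts.loc[keep].reset_index(drop=True)
    return np.asarray(ts)[keep]


def n_volumes_for(duration_seconds: float, tr_seconds: float) -> int:
    """Number of volumes an acquisition of the given duration yields."""
    if tr_seconds <= 0 or duration_seconds <= 0:
        raise ValueError("duration and TR must be positive")
    return int(duration_seconds / tr_seconds)


def usable_sample(
    n_scanned: int,
    n_missing_imaging: int = 0,
    n_missing_questionnaire: int = 0,
    n_failed_qc: int = 0,
) -> int:
    """Sample accounting: scanned cohort minus the exclusion categories.

    Exclusions are disjoint categories (missing resting-state data,
    missing questionnaires, motion/duration QC failures); the result must
    stay positive.
    """
    n = n_scanned - n_missing_imaging - n_missing_questionnaire - n_failed_qc
    if n <= 0:
        raise ValueError("exclusions remove the entire sample")
    return n


def read_confounds(path) -> pd.DataFrame:
    """Read an fMRIPrep-dialect confounds TSV.

    Expects the motion columns ``trans_x .. rot_z``; if the
    ``framewise_displacement`` column is absent it is recomputed from the
    motion parameters.
    """
    conf = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in conf.columns]
    if missing:
        raise KeyError(f"confounds file {path} missing motion columns: {missing}")
    if "framewise_displacement" not in conf.columns:
        conf["framewise_displacement"] = compute_fd(conf[MOTION_COLUMNS])
    else:
        # fMRIPrep writes n/a for the first frame; coerce to the 0 convention
        conf["framewise_displacement"] = (
            pd.to_numeric(conf["framewise_displacement"], errors="coerce").fillna(0.0)
        )
    return conf


def prep_subject(
    ts: pd.DataFrame,
    confounds: pd.DataFrame,
    tr_seconds: float,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    cutoff_seconds: float = DCT_CUTOFF_S,
    confound_columns=None,
    include_global_signal: bool = False,
    censor_aware_regression: bool = False,
):
    """Run the full per-subject preparation chain.

    FD -> QC -> confound regression (nuisance columns + cosine drift
    basis) -> scrubbing. With ``censor_aware_regression`` the projection is
    estimated on the kept volumes only (scrub first). The global signal is
    extracted into the confounds table by convention but is not regressed
    unless requested.

    Returns
    -------
    (clean, qc, log) : (DataFrame, QcResult, dict)
        ``clean`` is the residualized, scrubbed timeseries; ``log`` records
        the order of operations, columns used, and censored volume count.
    """
    if confound_columns is None:
        confound_columns = list(DEFAULT_CONFOUNDS)
        if include_global_signal and "global_signal" in confounds.columns:
            confound_columns.append("global_signal")
    if "framewise_displacement" in confounds.columns:
        fd = confounds["framewise_displacement"].to_numpy(dtype=float)
    else:
        fd = compute_fd(confounds[MOTION_COLUMNS])
    qc = qc_subject(fd, tr_seconds, threshold_mm=fd_threshold_mm)
    n = ts.shape[0]
    basis = dct_basis(n, tr_seconds, cutoff_seconds)
    design = pd.concat(
        [
            confounds[confound_columns].reset_index(drop=True),
            pd.DataFrame(basis, columns=[f"cosine{k:02d}" for k in range(basis.shape[1])]),
        ],
        axis=1,
    )
    mask = flag_scrub(fd, fd_threshold_mm)
    if censor_aware_regression:
        clean = regress_confounds(scrub(ts, mask), scrub(design, mask))
        order = ["fd", "qc", "scrub", "regress"]
    else:
        clean = scrub(regress_confounds(ts, design), mask)
        order = ["fd", "qc", "regress", "scrub"]
    log = {
        "order": order,
        "confound_columns": list(design.columns),
        "fd_threshold_mm": fd_threshold_mm,
        "cutoff_seconds": cutoff_seconds,
        "n_volumes_in": int(n),
        "n_censored": int(mask.sum()),
        "n_volumes_out": int(clean.shape[0]),
    }
    return clean, qc, log
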