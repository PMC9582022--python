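"""Synthetic resting-state cohorts with known ground truth.

Every downstream stage (prep -> connectivity -> scoring -> moderation ->
probing) is testable without any scanner data: the generator draws, per
subject,

* six rigid-body motion parameters as a smooth random walk plus sparse
  spikes large enough to push framewise displacement past the 0.30 mm
  scrubbing threshold (a small "high-motion" subpopulation emulates
  QC-failing scans);
* ROI-averaged timeseries as multivariate normal draws with block
  covariance — within-network off-diagonals at the subject's target
  correlation, a weak positive background between networks — plus an
  optional motion-locked artifact;
* Likert item responses under a parallel-items model calibrated to a
  target Cronbach alpha, discretized by rounding to the response range;
* a behavior outcome from the moderated-regression generative model
  ``y = bX*X + bZ*Z + bXZ*X*Z + covariate effects + N(0, noise_sd)``
  where Z is the subject's (standardized) true moderator-network
  connectivity.

All randomness flows from a single seed; the same config is
bit-reproducible. True connectivity targets, generative coefficients and
the implied crossover point are recorded in a :class:`GroundTruth` before
any noise is added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import behavior as bhv
from .connectivity import DEFAULT_NETWORKS
from .prep import MOTION_COLUMNS, compute_fd, flag_scrub, qc_subject

# Network-level means and SDs of within-network connectivity used as
# sampling distributions for per-subject targets (moderate positive
# coupling, distinct per network).
DEFAULT_NETWORK_R = {
    "affective_salience": 0.49,
    "motivational_relevance": 0.30,
    "mentalizing": 0.51,
    "cognitive_control": 0.53,
}
DEFAULT_NETWORK_R_SD = {
    "affective_salience": 0.18,
    "motivational_relevance": 0.15,
    "mentalizing": 0.13,
    "cognitive_control": 0.15,
}
DEFAULT_ITEM_ALPHA = {"peer_norms": 0.83, "prosocial": 0.75, "risk": 0.78}


@dataclass
class SynthConfig:
    """All knobs of the synthetic cohort in one place.

    The defaults are the package's canonical study conditions: an
    8-minute scan (240 volumes at TR 2 s), early-adolescent covariate
    distributions (age uniform on 11.94-14.49 years, sex Bernoulli(0.5)
    coded girl = 1), standardized effect sizes (0.4, 0.1, 0.3) for peer
    norms, connectivity and their product, residual SD 0.5, and scale
    reliabilities of 0.83/0.75/0.78.
    """

    n_subjects: int = 87
    n_volumes: int = 240
    tr_seconds: float = 2.0
    network_r: dict = field(default_factory=lambda: dict(DEFAULT_NETWORK_R))
    network_r_sd: dict = field(default_factory=lambda: dict(DEFAULT_NETWORK_R_SD))
    between_network_r: float = 0.1
    motion_spike_rate: float = 0.03
    motion_spike_scale: float = 0.6
    motion_artifact_scale: float = 1.0
    p_high_motion: float = 0.05
    high_motion_spike_rate: float = 0.12
    p_partial_scan: float = 0.14
    min_partial_volumes: int = 129
    beta_x: float = 0.4
    beta_z: float = 0.1
    beta_xz: float = 0.3
    cov_betas: dict = field(
        default_factory=lambda: {"age": 0.17, "sex": -0.15, "usable_volumes": 0.20}
    )
    noise_sd: float = 0.5
    item_alpha: dict = field(default_factory=lambda: dict(DEFAULT_ITEM_ALPHA))
    behavior_item_loading: float = 0.7
    moderator_network: str = "affective_salience"
    age_range: tuple = (11.94, 14.49)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        for net, r in self.network_r.items():
            if not 0 <= r < 1:
                raise ValueError(f"network_r[{net!r}] = {r} outside [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("motion_spike_rate", "p_high_motion", "p_partial_scan"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")


@dataclass
class GroundTruth:
    """Generative truth recorded before noise: targets, betas, crossover."""

    connectivity: pd.DataFrame  # subject x network target correlations
    betas: dict  # beta_x, beta_z, beta_xz
    cov_betas: dict
    noise_sd: float
    crossover_x: float  # -beta_z / beta_xz (NaN when beta_xz == 0)
    seed: int


@dataclass
class Cohort:
    """Everything one synthetic study produces."""

    config: SynthConfig
    records: pd.DataFrame
    items: pd.DataFrame
    timeseries: dict
    confounds: dict
    ground_truth: GroundTruth


def _safe_z(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def generate_motion(
    n_volumes: int,
    spike_rate: float = 0.03,
    spike_scale: float = 0.6,
    seed=None,
    walk_sd_trans: float = 0.005,
    walk_sd_rot: float = 1e-4,
) -> pd.DataFrame:
    """Six rigid-body parameter traces: random-walk drift plus sparse spikes.

    Spikes are persistent position shifts of ``spike_scale`` mm applied to
    one random translation axis with probability ``spike_rate`` per
    volume (volumes 1..T-1, so each spike produces exactly one
    high-displacement frame). With the default scale a spike's framewise
    displacement is far above the 0.30 mm threshold, so the expected
    fraction of scrub-flagged volumes is ~``spike_rate``.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_volumes, 6))
    steps[1:, :3] = rng.normal(0, walk_sd_trans, (n_volumes - 1, 3))
    steps[1:, 3:] = rng.normal(0, walk_sd_rot, (n_volumes - 1, 3))
    spikes = rng.random(n_volumes - 1) < spike_rate
    for t in np.flatnonzero(spikes) + 1:
        axis = rng.integers(0, 3)
        steps[t, axis] += spike_scale * rng.choice([-1.0, 1.0])
    return pd.DataFrame(np.cumsum(steps, axis=0), columns=MOTION_COLUMNS)


def generate_confounds(motion: pd.DataFrame, ts: pd.DataFrame | None = None, seed=None) -> pd.DataFrame:
    """fMRIPrep-style confounds table for a motion trace.

    Columns: the six motion parameters, framewise displacement, and
    csf / white-matter / global-signal nuisance series (AR(1) noise; the
    global signal is the ROI-mean of the timeseries when one is given).
    """
    rng = np.random.default_rng(seed)
    n = len(motion)
    fd = compute_fd(motion)

    def ar1(rho=0.3):
        innov = np.concatenate(
            [rng.normal(size=1), rng.normal(0, np.sqrt(1 - rho**2), n - 1)]
        )
        return lfilter([1.0], [1.0, -rho], innov)

    conf = motion.copy()
    conf["framewise_displacement"] = fd
    conf["csf"] = ar1()
    conf["white_matter"] = ar1()
    if ts is not None:
        conf["global_signal"] = np.asarray(ts).mean(axis=1)
    else:
        conf["global_signal"] = ar1()
    return conf


def _block_covariance(targets: dict, between_r: float) -> tuple[np.ndarray, list]:
    labels, blocks = [], []
    for net in DEFAULT_NETWORKS.values():
        if net.name not in targets:
            raise KeyError(f"no target correlation for network {net.name!r}")
        labels += list(net.roi_labels)
        blocks += [targets[net.name]] * len(net.roi_labels)
    p = len(labels)
    cov = np.full((p, p), between_r, dtype=float)
    blocks = np.asarray(blocks)
    for net in DEFAULT_NETWORKS.values():
        idx = [labels.index(r) for r in net.roi_labels]
        r = targets[net.name]
        if not 0 <= r < 1:
            raise ValueError(f"target r for {net.name!r} outside [0, 1)")
        cov[np.ix_(idx, idx)] = r
    np.fill_diagonal(cov, 1.0)
    return cov, labels


def generate_roi_timeseries(
    targets: dict,
    n_volumes: int,
    seed=None,
    between_network_r: float = 0.1,
    fd: np.ndarray | None = None,
    motion_artifact_scale: float = 0.0,
) -> pd.DataFrame:
    """Block-correlated ROI timeseries for one subject.

    ``targets`` maps network name -> within-network correlation in
    [0, 1); between-network off-diagonals sit at ``between_network_r``.
    When an FD trace and a nonzero artifact scale are given, a
    motion-locked component (FD times per-ROI loadings around the scale)
    is added — it is what confound regression and scrubbing later remove.
    """
    rng = np.random.default_rng(seed)
    cov, labels = _block_covariance(targets, between_network_r)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("requested block covariance is not positive definite") from err
    ts = rng.standard_normal((n_volumes, len(labels))) @ chol.T
    if fd is not None and motion_artifact_scale > 0:
        fd = np.asarray(fd, dtype=float)
        if fd.size != n_volumes:
            raise ValueError("fd length must match n_volumes")
        loadings = motion_artifact_scale * rng.normal(1.0, 0.3, len(labels))
        ts = ts + np.outer(fd, loadings)
    return pd.DataFrame(ts, columns=labels)


def generate_items(
    scale: bhv.ScaleDefinition,
    true_scores,
    target_alpha: float,
    seed=None,
    discretize: bool = True,
) -> pd.DataFrame:
    """Item responses under a parallel-items model with a target alpha.

    Each item is ``sign * T + e`` (sign -1 on reverse-keyed items) with
    item-noise variance set by the Spearman-Brown relation
    ``r = alpha / (k - alpha (k - 1))``, then linearly mapped onto the
    response range (item SD = span/4 around the midpoint) and, by
    default, rounded and clamped to legal responses. Continuous items hit
    the target alpha in expectation; discretization costs a little.
    """
    if not 0 < target_alpha < 1:
        raise ValueError("target_alpha must be in (0, 1)")
    t = np.asarray(true_scores, dtype=float)
    k = scale.k_items
    r = target_alpha / (k - target_alpha * (k - 1))
    if not 0 < r < 1:
        raise ValueError(f"impossible alpha/k combination: alpha={target_alpha}, k={k}")
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt((1 - r) / r)
    signs = np.ones(k)
    for i in scale.reverse_items:
        signs[i - 1] = -1.0
    latent = t[:, None] * signs[None, :] + rng.normal(0, noise_sd, (t.size, k))
    mid = (scale.response_min + scale.response_max) / 2.0
    span = scale.response_max - scale.response_min
    items = mid + latent / np.sqrt(1 + noise_sd**2) * (span / 4.0)
    if discretize:
        items = np.clip(np.round(items), scale.response_min, scale.response_max)
    else:
        items = np.clip(items, scale.response_min, scale.response_max)
    return pd.DataFrame(items, columns=scale.item_columns)


def generate_cohort(config: SynthConfig, with_timeseries: bool = True) -> Cohort:
    """Draw a complete synthetic study under one seed.

    Returns records (one row per subject: covariates, latent standardized
    peer norms, true per-network connectivity, the generated behavior
    composite on its raw scale plus item-scored summaries, and the QC
    verdict), the item-response table, per-subject timeseries and
    confounds (timeseries optional — simulation studies that only need
    the regression records can skip the expensive draw), and the recorded
    :class:`GroundTruth`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    sids = [f"sub-{i + 1:03d}" for i in range(n)]

    # --- true connectivity targets (ground truth, before any noise) ----
    targets = {}
    for net, mu in cfg.network_r.items():
        sd = cfg.network_r_sd.get(net, 0.15)
        targets[net] = np.clip(rng.normal(mu, sd, n), 0.02, 0.85)
    truth_conn = pd.DataFrame(targets, index=sids)
    truth_conn.index.name = "subject_id"

    # --- covariates ----------------------------------------------------
    age = rng.uniform(*cfg.age_range, n)
    sex = rng.integers(0, 2, n).astype(float)  # girl = 1, boy = 0

    # --- scan, motion, confounds, (optionally) timeseries --------------
    high_motion = rng.random(n) < cfg.p_high_motion
    partial = rng.random(n) < cfg.p_partial_scan
    timeseries, confounds = {}, {}
    usable_volumes = np.empty(n)
    qc_usable = np.empty(n, dtype=bool)
    qc_reasons = []
    for i, sid in enumerate(sids):
        n_vol = int(
            rng.integers(cfg.min_partial_volumes, cfg.n_volumes)
            if partial[i]
            else cfg.n_volumes
        )
        rate = cfg.high_motion_spike_rate if high_motion[i] else cfg.motion_spike_rate
        motion = generate_motion(n_vol, rate, cfg.motion_spike_scale, seed=rng)
        fd = compute_fd(motion)
        if with_timeseries:
            ts = generate_roi_timeseries(
                {net: targets[net][i] for net in targets},
                n_vol,
                seed=rng,
                between_network_r=cfg.between_network_r,
                fd=fd,
                motion_artifact_scale=cfg.motion_artifact_scale,
            )
            timeseries[sid] = ts
            confounds[sid] = generate_confounds(motion, ts, seed=rng)
        else:
            confounds[sid] = generate_confounds(motion, None, seed=rng)
        usable_volumes[i] = n_vol - int(flag_scrub(fd).sum())
        qc = qc_subject(fd, cfg.tr_seconds, subject_id=sid)
        qc_usable[i] = qc.usable
        qc_reasons.append(";".join(qc.reasons))

    # --- generative outcome model --------------------------------------
    x_latent = rng.standard_normal(n)
    x = _safe_z(x_latent)
    z = _safe_z(truth_conn[cfg.moderator_network].to_numpy())
    y = cfg.beta_x * x + cfg.beta_z * z + cfg.beta_xz * x * z
    cov_values = {"age": age, "sex": sex, "usable_volumes": usable_volumes}
    for name, beta in cfg.cov_betas.items():
        y = y + beta * _safe_z(cov_values[name])
    if cfg.noise_sd > 0:
        y = y + rng.normal(0, cfg.noise_sd, n)

    # --- item responses -------------------------------------------------
    y_z = _safe_z(y)
    w = cfg.behavior_item_loading
    risk_latent = w * y_z + np.sqrt(1 - w**2) * rng.standard_normal(n)
    prosocial_latent = -w * y_z + np.sqrt(1 - w**2) * rng.standard_normal(n)
    items = pd.concat(
        [
            pd.DataFrame({"subject_id": sids, "age": age, "sex": sex,
                          "usable_volumes": usable_volumes}),
            generate_items(bhv.PEER_NORMS, x, cfg.item_alpha["peer_norms"], seed=rng),
            generate_items(bhv.PROSOCIAL, prosocial_latent, cfg.item_alpha["prosocial"], seed=rng),
            generate_items(bhv.RISK, risk_latent, cfg.item_alpha["risk"], seed=rng),
        ],
        axis=1,
    )

    scored_prosocial = bhv.score_scale(items, bhv.PROSOCIAL)
    scored_risk = bhv.score_scale(items, bhv.RISK)
    records = pd.DataFrame(
        {
            "subject_id": sids,
            "age": age,
            "sex": sex,
            "usable_volumes": usable_volumes,
            "qc_usable": qc_usable,
            "qc_reasons": qc_reasons,
            "peer_norms_z": x,
            "prosocial_mean": scored_prosocial,
            "risk_mean": scored_risk,
            "behavior_composite": y,
            "behavior_composite_z": bhv.behavior_composite(scored_prosocial, scored_risk),
        }
    )
    for net in truth_conn.columns:
        records[f"conn_{net}"] = truth_conn[net].to_numpy()

    truth = GroundTruth(
        connectivity=truth_conn,
        betas={"beta_x": cfg.beta_x, "beta_z": cfg.beta_z, "beta_xz": cfg.beta_xz},
        cov_betas=dict(cfg.cov_betas),
        noise_sd=cfg.noise_sd,
        crossover_x=(-cfg.beta_z / cfg.beta_xz) if cfg.beta_xz != 0 else float("nan"),
        seed=cfg.seed,
    )
    return Cohort(cfg, records, items, timeseries, confounds, truth)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort to disk in the plain-text study layout.

    ``timeseries/<sub>_timeseries.tsv`` (header = ROI labels),
    ``confounds/<sub>_confounds.tsv`` (fMRIPrep columns),
    ``behavior_items.csv``, ``records.csv``, ``ground_truth.json`` and a
    ``manifest.json`` naming subjects, TR and the ground-truth path.
    """
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "confounds").mkdir(exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        ts.to_csv(out / "timeseries" / f"{sid}_timeseries.tsv", sep="\t",
                  index=False, float_format="%.6f")
    for sid, conf in cohort.confounds.items():
        conf.to_csv(out / "confounds" / f"{sid}_confounds.tsv", sep="\t",
                    index=False, float_format="%.6f")
    cohort.items.to_csv(out / "behavior_items.csv", index=False)
    cohort.records.to_csv(out / "records.csv", index=False)
    truth = cohort.ground_truth
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "betas": truth.betas,
                "cov_betas": truth.cov_betas,
                "noise_sd": truth.noise_sd,
                "crossover_x": truth.crossover_x,
                "seed": truth.seed,
                "connectivity": truth.connectivity.reset_index().to_dict(orient="list"),
            },
            fh,
            indent=2,
        )
    manifest = {
        "subjects": list(cohort.records["subject_id"]),
        "tr_seconds": cohort.config.tr_seconds,
        "n_volumes": {sid: int(len(c)) for sid, c in cohort.confounds.items()},
        "ground_truth": "ground_truth.json",
        "items": "behavior_items.csv",
        "records": "records.csv",
        "config": {k: v for k, v in asdict(cohort.config).items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
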