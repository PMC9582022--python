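"""Within-network intrinsic connectivity.

A network is an ordered roster of ROI labels; a subject's within-network
connectivity is the arithmetic mean of the Pearson correlations over all
unordered ROI pairs of that roster, computed on the prepared (confound
regressed, scrubbed) ROI-averaged timeseries. Averaging raw r is the
default; an optional Fisher-z average (transform, mean, back-transform) is
provided.

Four default rosters encode the a priori social-cognitive/affective
networks (mentalizing, cognitive control, motivational relevance,
affective salience). The laterality of the VTA and OFC labels is treated
as single midline/combined regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NetworkDefinition:
    """Named network with an ordered, unique ROI-label roster (>= 2)."""

    name: str
    roi_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.roi_labels) < 2:
            raise ValueError(f"network {self.name!r} needs at least two ROIs")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError(f"duplicate ROI labels in network {self.name!r}")

    @property
    def n_edges(self) -> int:
        k = len(self.roi_labels)
        return k * (k - 1) // 2


DEFAULT_NETWORKS: dict[str, NetworkDefinition] = {
    "mentalizing": NetworkDefinition(
        "mentalizing",
        ("tpj_l", "tpj_r", "psts_l", "psts_r", "pcc",
         "temporal_pole_l", "temporal_pole_r", "dmpfc"),
    ),
    "cognitive_control": NetworkDefinition(
        "cognitive_control",
        ("dlpfc_l", "dlpfc_r", "ipl_l", "ipl_r"),
    ),
    "motivational_relevance": NetworkDefinition(
        "motivational_relevance",
        ("vs_l", "vs_r", "caudate_l", "caudate_r", "vta", "ofc"),
    ),
    "affective_salience": NetworkDefinition(
        "affective_salience",
        ("amygdala_l", "amygdala_r", "dacc", "insula_l", "insula_r",
         "putamen_l", "putamen_r"),
    ),
}

#: All ROI labels in canonical order (25 across the four networks).
ALL_ROI_LABELS: tuple[str, ...] = tuple(
    label for net in DEFAULT_NETWORKS.values() for label in net.roi_labels
)


@dataclass
class ConnectivityResult:
    """Per-subject, per-network mean edge correlation."""

    subject_id: str | None
    network: str
    mean_within_r: float
    n_edges: int
    usable_volumes: int


def _roi_matrix(ts, roi_labels):
    if isinstance(ts, pd.DataFrame):
        missing = [r for r in roi_labels if r not in ts.columns]
        if missing:
            raise KeyError(f"ROI labels not in timeseries: {missing}")
        arr = ts[list(roi_labels)].to_numpy(dtype=float)
    else:
        arr = np.asarray(ts, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least three volumes after scrubbing")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = [roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI(s): {bad}")
    return arr


def pairwise_correlations(ts, roi_labels) -> pd.DataFrame:
    """Pearson r for every unordered ROI pair.

    Returns a DataFrame with columns ``roi_a``, ``roi_b``, ``r`` covering
    all k(k-1)/2 pairs in roster order.
    """
    roi_labels = list(roi_labels)
    arr = _roi_matrix(ts, roi_labels)
    corr = np.corrcoef(arr, rowvar=False)
    iu, ju = np.triu_indices(len(roi_labels), k=1)
    return pd.DataFrame(
        {
            "roi_a": [roi_labels[i] for i in iu],
            "roi_b": [roi_labels[j] for j in ju],
            "r": corr[iu, ju],
        }
    )


def within_network_connectivity(
    ts, network: NetworkDefinition, fisher_z: bool = False, subject_id: str | None = None
) -> ConnectivityResult:
    """Mean correlation over all within-network edges.

    With ``fisher_z`` the edge correlations are arctanh-transformed,
    averaged, and the mean mapped back with tanh; the default is the plain
    mean of raw r values.
    """
    edges = pairwise_correlations(ts, network.roi_labels)
    r = edges["r"].to_numpy()
    if fisher_z:
        mean_r = float(np.tanh(np.mean(np.arctanh(r))))
    else:
        mean_r = float(np.mean(r))
    return ConnectivityResult(
        subject_id=subject_id,
        network=network.name,
        mean_within_r=mean_r,
        n_edges=network.n_edges,
        usable_volumes=int(ts.shape[0]),
    )


def cohort_connectivity(
    timeseries: "dict[str, pd.DataFrame] | str | Path",
    networks: "dict[str, NetworkDefinition] | None" = None,
    fisher_z: bool = False,
    subjects: "list[str] | None" = None,
) -> pd.DataFrame:
    """Subject x network connectivity table.

    ``timeseries`` is either a mapping ``subject_id -> prepared timeseries
    DataFrame`` or a directory of ``<subject>_timeseries.tsv`` files.
    Returns one row per subject with a ``conn_<network>`` column per
    network plus ``usable_volumes``. Subjects requested via ``subjects``
    but absent from the input raise a ``KeyError`` (never silently
    dropped).
    """
    if networks is None:
        networks = DEFAULT_NETWORKS
    if not networks:
        raise ValueError("empty network list")
    if not isinstance(timeseries, dict):
        directory = Path(timeseries)
        timeseries = {
            p.name.replace("_timeseries.tsv", ""): pd.read_csv(p, sep="\t")
            for p in sorted(directory.glob("*_timeseries.tsv"))
        }
        if not timeseries:
            raise FileNotFoundError(f"no *_timeseries.tsv files under {directory}")
    if subjects is not None:
        missing = [s for s in subjects if s not in timeseries]
        if missing:
            raise KeyError(f"missing subjects: {missing}")
        timeseries = {s: timeseries[s] for s in subjects}
    rows = []
    for sid, ts in timeseries.items():
        row = {"subject_id": sid, "usable_volumes": int(ts.shape[0])}
        for net in networks.values():
            res = within_network_connectivity(ts, net, fisher_z=fisher_z, subject_id=sid)
            row[f"conn_{net.name}"] = res.mean_within_r
        rows.append(row)
    return pd.DataFrame(rows)
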