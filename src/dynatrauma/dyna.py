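"""Dynamic network analysis (DyNA) of serial inflammatory mediator data.

Within consecutive time windows, pool all (patient, timepoint) observations
of a patient group, correlate every mediator pair, and connect pairs whose
correlation magnitude reaches a threshold.  Per-window networks are
summarized by a network complexity score (NCS, degree sum normalized by the
number of other mediators) and by per-mediator connectivity totals across
windows; "most connected" mediators are those at or above the third quartile
of the totals within their group.

Correlations are Pearson on log10 concentrations by default: plasma
mediator levels are approximately log-normal, and correlating on the log
scale keeps edge detection invariant to each analyte's dynamic range.  Set
``scale="linear"`` to correlate raw concentrations instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stratify import CohortSplit

__all__ = [
    "TimeWindow",
    "DynaNetwork",
    "NCSTrajectory",
    "make_windows",
    "window_of",
    "window_correlations",
    "build_network",
    "network_complexity",
    "ncs_trajectory",
    "connectivity_summary",
]

DEFAULT_THRESHOLD = 0.95
MIN_PAIRED_OBS = 3  # a pair needs at least this many paired observations


@dataclass(frozen=True)
class TimeWindow:
    """Half-open window [start_h, end_h); the last window of a schedule is
    closed on the right so the final sample is not dropped."""

    label: str
    start_h: float
    end_h: float
    closed_right: bool = False

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError(f"window {self.label}: end must exceed start")

    def contains(self, hour: float) -> bool:
        if self.closed_right:
            return self.start_h <= hour <= self.end_h
        return self.start_h <= hour < self.end_h


@dataclass
class DynaNetwork:
    """Thresholded correlation network for one (window, group)."""

    window: TimeWindow
    group_label: str
    nodes: List[str]
    edges: Dict[FrozenSet[str], float]  # pair -> signed correlation
    n_obs: int

    @property
    def degrees(self) -> Dict[str, int]:
        deg = {m: 0 for m in self.nodes}
        for pair in self.edges:
            for m in pair:
                deg[m] += 1
        return deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, r in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, r=r, sign=int(np.sign(r)))
        return g


@dataclass
class NCSTrajectory:
    """Network complexity score per window for one patient group."""

    group_label: str
    values: Dict[str, float]  # window label -> NCS

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.group_label)


def make_windows(schedule: Sequence[float]) -> List[TimeWindow]:
    """Daily windows covering a sampling schedule.

    The first window [0, 24) aggregates the sub-daily samples of the first
    day; subsequent windows are [24, 48), [48, 72), ...; the final window is
    closed at its right edge.  Labels are ``d1, d2, ...``.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")
    last = float(schedule[-1])
    n_days = max(1, int(np.ceil(last / 24.0)))
    windows = []
    for d in range(n_days):
        windows.append(
            TimeWindow(
                label=f"d{d + 1}",
                start_h=24.0 * d,
                end_h=24.0 * (d + 1),
                closed_right=(d == n_days - 1),
            )
        )
    return windows


def window_of(windows: Sequence[TimeWindow], hour: float) -> TimeWindow:
    for w in windows:
        if w.contains(hour):
            return w
    raise ValueError(f"hour {hour} falls in no window")


def _observation_matrix(
    panel, window: TimeWindow, patients: Sequence[str], scale: str
) -> pd.DataFrame:
    med = panel.mediators
    sel = med[med["patient_id"].isin(set(patients))]
    hrs = sel["time_h"].to_numpy(dtype=float)
    if window.closed_right:
        inwin = (hrs >= window.start_h) & (hrs <= window.end_h)
    else:
        inwin = (hrs >= window.start_h) & (hrs < window.end_h)
    sel = sel[inwin]
    if sel.empty:
        return pd.DataFrame()
    mat = sel.pivot_table(
        index=["patient_id", "time_h"], columns="mediator",
        values="concentration", aggfunc="mean",
    )
    if scale == "log":
        mat = np.log10(mat)
    elif scale != "linear":
        raise ValueError("scale must be 'log' or 'linear'")
    return mat


def window_correlations(
    panel,
    window: TimeWindow,
    patients: Sequence[str],
    scale: str = "log",
) -> Optional[pd.DataFrame]:
    """Mediator x mediator Pearson correlation over all in-window
    (patient, timepoint) observations of the given patients.

    Cells with fewer than three paired observations or zero variance are
    NaN (undefined, distinct from 0).  Returns None when the window holds no
    usable observations at all (the empty-network signal).
    """
    mat = _observation_matrix(panel, window, patients, scale)
    if mat.empty:
        return None
    corr = mat.corr(min_periods=MIN_PAIRED_OBS)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def build_network(
    corr: Optional[pd.DataFrame],
    threshold: float = DEFAULT_THRESHOLD,
    window: Optional[TimeWindow] = None,
    group_label: str = "",
    nodes: Optional[Sequence[str]] = None,
    n_obs: int = 0,
) -> DynaNetwork:
    """Edges are mediator pairs with defined |r| >= threshold; sign retained."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    window = window or TimeWindow("w", 0.0, 1.0)
    if corr is None:
        return DynaNetwork(window, group_label, list(nodes or []), {}, 0)
    names = list(corr.columns)
    edges: Dict[FrozenSet[str], float] = {}
    vals = corr.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = vals[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                edges[frozenset((names[i], names[j]))] = float(r)
    return DynaNetwork(window, group_label, names, edges, n_obs)


def network_complexity(
    network: DynaNetwork,
    n_mediators: int,
    normalization: str = "degree_sum_norm",
) -> float:
    """Network complexity score.

    Default ``degree_sum_norm``: sum of node degrees divided by
    (n_mediators - 1), so an edgeless network scores 0 and a complete graph
    on n mediators scores n.  Alternatives: ``degree_sum`` (raw degree sum)
    and ``edges`` (edge count), for matching other normalization
    conventions.
    """
    if n_mediators < 2:
        raise ValueError("need at least two mediators")
    degree_sum = 2 * network.n_edges
    if normalization == "degree_sum_norm":
        return degree_sum / (n_mediators - 1)
    if normalization == "degree_sum":
        return float(degree_sum)
    if normalization == "edges":
        return float(network.n_edges)
    raise ValueError(f"unknown normalization {normalization!r}")


def group_networks(
    panel,
    patients: Sequence[str],
    windows: Sequence[TimeWindow],
    threshold: float = DEFAULT_THRESHOLD,
    group_label: str = "",
    scale: str = "log",
) -> List[DynaNetwork]:
    """One thresholded network per window for a fixed patient group."""
    nets = []
    mediators = sorted(panel.mediators["mediator"].unique())
    for w in windows:
        mat = _observation_matrix(panel, w, patients, scale)
        if mat.empty:
            nets.append(DynaNetwork(w, group_label, mediators, {}, 0))
            continue
        corr = mat.corr(min_periods=MIN_PAIRED_OBS)
        np.fill_diagonal(corr.values, 1.0)
        net = build_network(corr, threshold, window=w, group_label=group_label,
                            n_obs=len(mat))
        nets.append(net)
    return nets


def ncs_trajectory(
    panel,
    split: CohortSplit,
    windows: Sequence[TimeWindow],
    threshold: float = DEFAULT_THRESHOLD,
    scale: str = "log",
    normalization: str = "degree_sum_norm",
) -> Tuple[NCSTrajectory, NCSTrajectory]:
    """NCS per window for the risk and control groups of a cohort split."""
    n_med = len(sorted(panel.mediators["mediator"].unique()))
    out = []
    for label, pats in (("risk", split.risk_patients), ("control", split.control_patients)):
        nets = group_networks(panel, pats, windows, threshold, label, scale)
        values = {n.window.label: network_complexity(n, n_med, normalization) for n in nets}
        out.append(NCSTrajectory(label, values))
    return out[0], out[1]


def connectivity_summary(
    networks: Sequence[DynaNetwork],
) -> Tuple[pd.Series, int, List[str]]:
    """Per-mediator connection totals across windows for one group.

    Returns (totals, group_total, most_connected) where ``most_connected``
    holds the mediators whose total reaches the third quartile of the
    per-mediator totals (75th percentile, linear interpolation).
    """
    if not networks:
        return pd.Series(dtype=float), 0, []
    nodes = networks[0].nodes
    for n in networks[1:]:
        if n.nodes != nodes:
            raise ValueError("networks must share the mediator list")
    totals = pd.Series(0, index=nodes, dtype=int)
    for n in networks:
        for m, d in n.degrees.items():
            totals[m] += d
    group_total = int(totals.sum())
    if len(totals) == 0:
        return totals, 0, []
    q3 = float(np.percentile(totals.to_numpy(), 75))
    top = [m for m in nodes if totals[m] >= q3]
    return totals, group_total, top
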