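"""Group-comparison statistics with normality-gated test selection.

The battery mirrors common clinical-outcomes practice: D'Agostino-Pearson
normality screens decide between parametric and rank-based tests
(two groups: Student's t vs Mann-Whitney U; three or more: one-way ANOVA
with Tukey HSD vs Kruskal-Wallis with Dunn's post hoc); contingency
outcomes use Fisher's exact test; longitudinal variables use a two-way
fixed-effects ANOVA with group and time factors, the group main effect
being the headline p value.  Two significance levels are carried
throughout: 0.05 for clinical outcomes and a stricter 0.01 for the serial
inflammatory-mediator screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .stratify import CohortSplit
from .synthetic import LongitudinalPanel

__all__ = [
    "CLINICAL_ALPHA",
    "MEDIATOR_ALPHA",
    "GroupComparison",
    "MediatorScreenResult",
    "InsufficientDataError",
    "select_and_compare",
    "contingency_compare",
    "multi_group_compare",
    "timecourse_compare",
    "mediator_screen",
]

log = logging.getLogger(__name__)

CLINICAL_ALPHA = 0.05
MEDIATOR_ALPHA = 0.01
NORMALITY_ALPHA = 0.05  # per-group D'Agostino-Pearson gate
_MIN_NORMALITY_N = 8  # below this the normality test is unusable
_EXACT_MAX_N = 8  # exact Mann-Whitney enumeration up to this group size


class InsufficientDataError(ValueError):
    pass


@dataclass
class GroupComparison:
    outcome_name: str
    group_labels: List[str]
    group_ns: List[int]
    group_means: List[float]
    group_sems: List[float]
    test_used: str  # t | mann_whitney | fisher | anova_tukey | kruskal_dunn | two_way_anova
    statistic: float
    p_value: float
    alpha_applied: float
    posthoc: Optional[pd.DataFrame] = None
    interaction_p: Optional[float] = None
    time_p: Optional[float] = None
    notes: List[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha_applied)


@dataclass
class MediatorScreenResult:
    comparisons: Dict[str, GroupComparison]
    directions: Dict[str, str]  # elevated_in_risk | lowered_in_risk | ns
    alpha: float

    @property
    def significant_mediators(self) -> List[str]:
        return [m for m, c in self.comparisons.items() if c.significant]


def _summ(x: np.ndarray) -> Tuple[int, float, float]:
    n = len(x)
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return n, float(np.mean(x)), sem


def _is_normal(x: np.ndarray) -> bool:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.normaltest(x).pvalue > NORMALITY_ALPHA


def _mw_exact(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney by exhaustive permutation of group
    labels (mid-rank U; handles ties correctly at small n)."""

    def u_stat(a, b):
        ranks = stats.rankdata(np.concatenate([a, b]))
        r1 = ranks[: len(a)].sum()
        return r1 - len(a) * (len(a) + 1) / 2.0

    u_obs = u_stat(x, y)
    res = stats.permutation_test(
        (x, y), u_stat, permutation_type="independent",
        alternative="two-sided", n_resamples=np.inf,
    )
    return float(u_obs), float(res.pvalue)


def select_and_compare(
    x: Sequence[float], y: Sequence[float], alpha: float = CLINICAL_ALPHA,
    outcome_name: str = "", labels: Tuple[str, str] = ("risk", "control"),
) -> GroupComparison:
    """Two-group comparison with normality-gated test selection.

    Both samples normal by D'Agostino-Pearson (p > 0.05) -> two-sided
    Student's t; otherwise two-sided Mann-Whitney U (exact enumeration for
    group sizes <= 8, normal approximation with tie correction above).
    Groups smaller than 8 cannot be normality-tested and fall through to
    Mann-Whitney (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    notes: List[str] = []
    if len(x) < 3 or len(y) < 3:
        raise InsufficientDataError("each group needs at least 3 observations")
    if min(len(x), len(y)) < _MIN_NORMALITY_N:
        normal = False
        notes.append("group too small for normality test; Mann-Whitney used")
        log.debug("normality test skipped (n < %d) for %s", _MIN_NORMALITY_N, outcome_name)
    else:
        normal = _is_normal(x) and _is_normal(y)
    if normal:
        stat, p = stats.ttest_ind(x, y)
        test = "t"
    else:
        if max(len(x), len(y)) <= _EXACT_MAX_N:
            stat, p = _mw_exact(x, y)
            notes.append("exact Mann-Whitney enumeration")
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "mann_whitney"
    nx, mx, sx = _summ(x)
    ny, my, sy = _summ(y)
    return GroupComparison(outcome_name, list(labels), [nx, ny], [mx, my],
                           [sx, sy], test, float(stat), float(p), alpha, notes=notes)


def contingency_compare(
    table: Sequence[Sequence[int]], alpha: float = CLINICAL_ALPHA,
    outcome_name: str = "", labels: Tuple[str, str] = ("risk", "control"),
) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 table (rows = groups)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integers")
    if t.sum() < 1:
        raise InsufficientDataError("empty table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    ns = t.sum(axis=1)
    props = t[:, 0] / np.maximum(ns, 1)
    return GroupComparison(outcome_name, list(labels), [int(n) for n in ns],
                           [float(v) for v in props], [float("nan")] * 2,
                           "fisher", float(odds), float(p), alpha)


def _dunn_posthoc(samples: Sequence[np.ndarray], labels: Sequence[str]) -> pd.DataFrame:
    """Dunn's z tests from pooled mid-ranks with tie correction; p values
    Bonferroni-adjusted by the number of pairwise comparisons."""
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start: start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)
    k = len(samples)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = min(1.0, 2 * stats.norm.sf(abs(z)) * m)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": z, "p_adj": p})
    return pd.DataFrame(rows)


def multi_group_compare(
    samples: Sequence[Sequence[float]], alpha: float = CLINICAL_ALPHA,
    outcome_name: str = "", labels: Optional[Sequence[str]] = None,
) -> GroupComparison:
    """Three-plus-group comparison.

    All groups normal -> one-way ANOVA with Tukey HSD post hoc; otherwise
    Kruskal-Wallis with Dunn's post hoc.  For two groups use
    :func:`select_and_compare`.
    """
    if len(samples) < 3:
        raise ValueError("fewer than 3 groups: use select_and_compare")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) < 3 for a in arrays):
        raise InsufficientDataError("each group needs at least 3 observations")
    labels = list(labels) if labels else [f"g{i + 1}" for i in range(len(arrays))]
    normal = all(len(a) >= _MIN_NORMALITY_N and _is_normal(a) for a in arrays)
    if normal:
        stat, p = stats.f_oneway(*arrays)
        tk = stats.tukey_hsd(*arrays)
        rows = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                rows.append({"group_a": labels[i], "group_b": labels[j],
                             "statistic": float(tk.statistic[i, j]),
                             "p_adj": float(tk.pvalue[i, j])})
        posthoc = pd.DataFrame(rows)
        test = "anova_tukey"
    else:
        stat, p = stats.kruskal(*arrays)
        posthoc = _dunn_posthoc(arrays, labels)
        test = "kruskal_dunn"
    ns, means, sems = zip(*(_summ(a) for a in arrays))
    return GroupComparison(outcome_name, labels, list(ns), list(means),
                           list(sems), test, float(stat), float(p), alpha,
                           posthoc=posthoc)


def _two_way_anova(
    df: pd.DataFrame, value: str, include_interaction: bool = True
) -> Tuple[float, float, float, float]:
    """Additive two-way fixed-effects ANOVA on (group, time) observations.

    Fit by OLS with type-II sums of squares (statsmodels), so unbalanced
    cells are handled.  Returns (F_group, p_group, p_time, p_interaction);
    the interaction p comes from a separate augmented fit and is NaN when
    ``include_interaction`` is off.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = df.assign(time=df["time"].astype(str))
    add = anova_lm(smf.ols(f"{value} ~ C(group) + C(time)", data=data).fit(), typ=2)
    f_group = float(add.loc["C(group)", "F"])
    p_group = float(add.loc["C(group)", "PR(>F)"])
    p_time = float(add.loc["C(time)", "PR(>F)"])
    p_inter = float("nan")
    if include_interaction:
        full = anova_lm(smf.ols(f"{value} ~ C(group) * C(time)", data=data).fit(), typ=2)
        p_inter = float(full.loc["C(group):C(time)", "PR(>F)"])
    return f_group, p_group, p_time, p_inter


def _panel_long(panel: LongitudinalPanel, split: CohortSplit, variable: str) -> pd.DataFrame:
    if variable in ("modscore", "creatinine"):
        df = panel.daily[["patient_id", "day", variable]].rename(
            columns={"day": "time", variable: "value"}
        )
    else:
        med = panel.mediators
        df = med[med["mediator"] == variable][["patient_id", "time_h", "concentration"]]
        if df.empty:
            raise InsufficientDataError(f"no observations for {variable!r}")
        df = df.rename(columns={"time_h": "time", "concentration": "value"})
    group = df["patient_id"].map(
        {**{p: "risk" for p in split.risk_patients},
         **{p: "control" for p in split.control_patients}}
    )
    df = df.assign(group=group).dropna(subset=["group"])
    return df


def timecourse_compare(
    panel: LongitudinalPanel, split: CohortSplit, variable: str,
    alpha: float = CLINICAL_ALPHA, include_interaction: bool = True,
) -> GroupComparison:
    """Two-way (group x time) fixed-effects ANOVA for one serial variable.

    ``variable`` is a mediator name, ``"modscore"`` or ``"creatinine"``.
    The headline p value is the group main effect from the additive model;
    the time main effect and the interaction (from an augmented fit) are
    reported secondarily.
    """
    df = _panel_long(panel, split, variable)
    counts = df.groupby(["group", "time"], observed=True)["value"].size().unstack(fill_value=0)
    if counts.shape[0] < 2:
        raise InsufficientDataError(f"{variable}: a group is absent from the panel")
    shared = (counts >= 2).all(axis=0)
    if int(shared.sum()) < 2:
        raise InsufficientDataError(
            f"{variable}: need >=2 shared timepoints with >=2 patients per group"
        )
    f_group, p_group, p_time, p_inter = _two_way_anova(
        df, "value", include_interaction=include_interaction
    )
    by = df.groupby("group", observed=True)["value"]
    stats_rows = {g: _summ(v.to_numpy()) for g, v in by}
    labels = [g for g in ("risk", "control") if g in stats_rows]
    ns = [stats_rows[g][0] for g in labels]
    means = [stats_rows[g][1] for g in labels]
    sems = [stats_rows[g][2] for g in labels]
    return GroupComparison(variable, labels, ns, means, sems, "two_way_anova",
                           float(f_group), float(p_group), alpha,
                           interaction_p=p_inter, time_p=p_time)


def mediator_screen(
    panel: LongitudinalPanel, split: CohortSplit, alpha: float = MEDIATOR_ALPHA,
) -> MediatorScreenResult:
    """Per-mediator group effect over the full time course at the mediator
    alpha; direction from the overall risk-vs-control mean."""
    comparisons: Dict[str, GroupComparison] = {}
    directions: Dict[str, str] = {}
    for m in sorted(panel.mediators["mediator"].unique()):
        comp = timecourse_compare(panel, split, m, alpha=alpha,
                                  include_interaction=False)
        comparisons[m] = comp
        if comp.significant and len(comp.group_means) == 2:
            risk_mean, control_mean = comp.group_means
            directions[m] = ("elevated_in_risk" if risk_mean > control_mean
                             else "lowered_in_risk")
        else:
            directions[m] = "ns"
    return MediatorScreenResult(comparisons, directions, alpha)
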