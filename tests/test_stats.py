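"""Outcome statistics: test selection, exactness at small n, post hocs, and
the two-way ANOVA against a hand sums-of-squares decomposition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_severe_cohort, panel_from_matrix
from dynatrauma.stats import (
    InsufficientDataError,
    contingency_compare,
    mediator_screen,
    multi_group_compare,
    select_and_compare,
    timecourse_compare,
    _mw_exact,
    _two_way_anova,
)
from dynatrauma.stratify import CohortSplit
from dynatrauma.synthetic import LongitudinalPanel, null_effect_model


def mw_enumeration_pvalue(x, y):
    """Oracle: exact two-sided Mann-Whitney p by full enumeration of all
    C(n1+n2, n1) group assignments (mid-rank U; two-sided p is twice the
    smaller one-sided tail, capped at 1, the exact-test convention)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    ge = le = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        u = u_of(idx)
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    return min(1.0, 2 * min(ge, le) / total)


def fisher_enumeration_pvalue(table):
    """Oracle: two-sided Fisher p by enumerating all tables with the
    observed margins; sum hypergeometric probabilities <= observed."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


def hand_two_way_anova(df):
    """Oracle: additive two-way ANOVA from explicit sums of squares via
    projection matrices built from raw indicator columns."""
    y = df["value"].to_numpy(dtype=float)
    n = len(y)

    def design(cols):
        mats = [np.ones((n, 1))]
        for col in cols:
            vals = sorted(df[col].unique())
            mats.append(np.column_stack([
                (df[col] == v).to_numpy(dtype=float) for v in vals[1:]
            ]))
        return np.hstack(mats)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), int(np.linalg.matrix_rank(X))

    rss_t, rk_t = rss(design(["time"]))
    rss_full, rk_full = rss(design(["group", "time"]))
    df_num = rk_full - rk_t
    df_den = n - rk_full
    f = ((rss_t - rss_full) / df_num) / (rss_full / df_den)
    return f, float(sps.f.sf(f, df_num, df_den))


# ------------------------------------------------------- two-group compare

def test_identical_samples_give_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    comp = select_and_compare(x, x)
    assert comp.test_used == "mann_whitney"
    assert comp.p_value == pytest.approx(1.0)


def test_separated_triples_exact_p():
    comp = select_and_compare([1, 2, 3], [4, 5, 6])
    assert comp.test_used == "mann_whitney"
    assert comp.p_value == pytest.approx(0.1, abs=1e-12)  # 2 of C(6,3)=20


def test_exact_mw_agrees_with_enumeration_including_ties():
    rng = np.random.default_rng(12)
    for _ in range(25):
        n1, n2 = rng.integers(3, 9, 2)
        x = rng.integers(0, 5, n1).astype(float)  # heavy ties
        y = rng.integers(0, 5, n2).astype(float)
        if len(set(x)) + len(set(y)) < 2:
            continue
        _, p = _mw_exact(x, y)
        assert p == pytest.approx(mw_enumeration_pvalue(x, y), abs=1e-9)


def test_normal_samples_take_t_path():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.1, 1, 40)
    comp = select_and_compare(x, y)
    assert comp.test_used == "t"
    t_ref, p_ref = sps.ttest_ind(x, y)
    assert comp.p_value == pytest.approx(p_ref)


def test_small_samples_raise():
    with pytest.raises(InsufficientDataError):
        select_and_compare([1, 2], [3, 4, 5])


# ------------------------------------------------------------- contingency

def test_fisher_balanced_table_p_one():
    comp = contingency_compare([[5, 5], [5, 5]])
    assert comp.p_value == pytest.approx(1.0)


def test_fisher_agrees_with_hypergeometric_enumeration():
    rng = np.random.default_rng(8)
    tables = [[[10, 0], [0, 10]], [[3, 7], [6, 2]], [[1, 9], [5, 5]]]
    tables += [rng.integers(0, 12, (2, 2)).tolist() for _ in range(20)]
    for t in tables:
        if sum(map(sum, t)) == 0:
            continue
        comp = contingency_compare(t)
        assert comp.p_value == pytest.approx(fisher_enumeration_pvalue(t), abs=1e-9)


# -------------------------------------------------------------- multigroup

def test_three_identical_groups_not_significant():
    g = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    comp = multi_group_compare([g, g, g])
    assert comp.p_value > 0.99
    assert not comp.posthoc["p_adj"].lt(0.05).any()


def test_planted_outlier_group_flagged_by_tukey_and_f_oracle():
    rng = np.random.default_rng(5)
    g1 = 1 + 0.05 * rng.standard_normal(10)
    g2 = 2 + 0.05 * rng.standard_normal(10)
    g3 = 9 + 0.05 * rng.standard_normal(10)
    comp = multi_group_compare([g1, g2, g3], labels=["a", "b", "c"])
    assert comp.test_used == "anova_tukey"
    # oracle: F from explicit between/within sums of squares
    allv = np.concatenate([g1, g2, g3])
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in (g1, g2, g3))
    ssw = sum(((g - g.mean()) ** 2).sum() for g in (g1, g2, g3))
    f_oracle = (ssb / 2) / (ssw / (len(allv) - 3))
    assert comp.statistic == pytest.approx(f_oracle, rel=1e-9)
    sig_pairs = {frozenset((r.group_a, r.group_b))
                 for r in comp.posthoc.itertuples() if r.p_adj < 0.05}
    assert frozenset(("a", "c")) in sig_pairs and frozenset(("b", "c")) in sig_pairs


def test_skewed_groups_take_kruskal_dunn_path():
    rng = np.random.default_rng(6)
    gs = [rng.exponential(1, 30), rng.exponential(1, 30), rng.exponential(3, 30)]
    comp = multi_group_compare(gs, labels=["a", "b", "c"])
    assert comp.test_used == "kruskal_dunn"
    assert comp.p_value < 0.01
    dunn = comp.posthoc.set_index(["group_a", "group_b"])
    assert dunn.loc[("a", "c"), "p_adj"] < 0.05
    assert dunn.loc[("a", "b"), "p_adj"] > 0.05


def test_two_groups_redirected():
    with pytest.raises(ValueError, match="select_and_compare"):
        multi_group_compare([[1, 2, 3], [4, 5, 6]])


# ---------------------------------------------------------- two-way ANOVA

def test_two_way_anova_matches_hand_sums_of_squares():
    """Balanced 2 groups x 2 times, 3 replicates per cell, fixed values."""
    df = pd.DataFrame({
        "group": ["r"] * 6 + ["c"] * 6,
        "time": ([0] * 3 + [24] * 3) * 2,
        "value": [5.1, 4.9, 5.3, 7.2, 7.0, 6.9,
                  4.0, 4.2, 3.8, 6.1, 5.9, 6.0],
    })
    f_group, p_group, p_time, p_inter = _two_way_anova(df, "value")
    f_oracle, p_oracle = hand_two_way_anova(df)
    assert f_group == pytest.approx(f_oracle, rel=1e-9)
    assert p_group == pytest.approx(p_oracle, rel=1e-9)
    assert p_time < 1e-6  # strong planted time effect


def test_two_way_anova_unbalanced_matches_hand_type_ii():
    rng = np.random.default_rng(11)
    rows = []
    for g, n_per in (("r", 4), ("c", 7)):
        for t in (0, 24, 48):
            for _ in range(n_per):
                rows.append({"group": g, "time": t,
                             "value": rng.normal(1.0 + (g == "r"), 1.0)})
    df = pd.DataFrame(rows)
    f_group, p_group, *_ = _two_way_anova(df, "value")
    f_oracle, p_oracle = hand_two_way_anova(df)
    assert f_group == pytest.approx(f_oracle, rel=1e-9)
    assert p_group == pytest.approx(p_oracle, rel=1e-9)


def test_timecourse_detects_constant_shift():
    rng = np.random.default_rng(2)
    hours = np.repeat([0.0, 24.0, 48.0], 20)
    base = rng.lognormal(3, 0.05, (60, 1))
    panel_a = base
    panel_b = base * 1.5  # constant multiplicative shift
    values = np.vstack([panel_a, panel_b])
    panel = panel_from_matrix(values, np.concatenate([hours, hours]), ["X"])
    ids = [f"P{i:04d}" for i in range(120)]
    split = CohortSplit(risk_patients=ids[60:], control_patients=ids[:60])
    comp = timecourse_compare(panel, split, "X")
    assert comp.p_value < 1e-10
    assert comp.group_means[0] > comp.group_means[1]


def test_timecourse_requires_both_groups():
    values = np.ones((10, 1)) * 5
    panel = panel_from_matrix(values, np.zeros(10), ["X"])
    split = CohortSplit(risk_patients=[f"P{i:04d}" for i in range(10)],
                        control_patients=["absent"])
    with pytest.raises(InsufficientDataError):
        timecourse_compare(panel, split, "X")


def test_permuted_group_labels_are_null():
    """Shuffling group labels leaves the group main effect non-significant
    in most replicates (p roughly uniform)."""
    rng = np.random.default_rng(23)
    pvals = []
    for _ in range(30):
        values = rng.lognormal(2, 0.5, (40, 1))
        hours = np.tile([0.0, 24.0], 20)
        panel = panel_from_matrix(values, hours, ["X"])
        ids = [f"P{i:04d}" for i in range(40)]
        perm = rng.permutation(ids)
        split = CohortSplit(risk_patients=list(perm[:20]),
                            control_patients=list(perm[20:]))
        pvals.append(timecourse_compare(panel, split, "X").p_value)
    assert np.mean(np.array(pvals) < 0.05) <= 0.2
    assert np.median(pvals) > 0.2


# --------------------------------------------------------- mediator screen

def test_mediator_screen_alpha_zero_flags_nothing(severe_cohort):
    _, _, _, panel, split = severe_cohort
    screen = mediator_screen(panel, split, alpha=0.0)
    assert screen.significant_mediators == []
    assert set(screen.directions.values()) == {"ns"}


def test_mediator_screen_flags_table_mediators_with_directions(severe_cohort):
    _, _, _, panel, split = severe_cohort
    screen = mediator_screen(panel, split, alpha=0.01)
    expected_up = {"Eotaxin", "MCP-1"}
    expected_down = {"IFN-a", "IL-2", "IL-4", "IL-9", "IL-15", "IL-17A", "IL-23"}
    for m in expected_up:
        assert screen.directions[m] == "elevated_in_risk"
    for m in expected_down:
        assert screen.directions[m] == "lowered_in_risk"


def test_dual_alpha_logged_on_results(severe_cohort):
    _, _, outcomes, panel, split = severe_cohort
    risk = set(split.risk_patients)
    x = [o.los_days for o in outcomes if o.patient_id in risk]
    y = [o.los_days for o in outcomes if o.patient_id not in risk]
    clin = select_and_compare(x, y, alpha=0.05)
    assert clin.alpha_applied == 0.05
    screen = mediator_screen(panel, split)
    assert all(c.alpha_applied == 0.01 for c in screen.comparisons.values())
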