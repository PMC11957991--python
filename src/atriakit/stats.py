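"""Normality-gated statistical battery for repeated-measures EP cohorts.

The study design measures every animal under three conditions
(unanesthetized / isoflurane / pentobarbital).  Test selection is gated by
Shapiro–Wilk normality in *all* groups (two-sided alpha 0.05 throughout):

* three within-animal conditions — repeated-measures one-way ANOVA with a
  Tukey post-hoc (studentized range on the RM error mean square) when
  normal, otherwise Friedman's test with Dunn's multiple-comparison
  correction;
* two independent groups (male vs female) — Student's pooled t-test when
  normal, otherwise Mann–Whitney;
* dominant-frequency groups — Kruskal–Wallis with Dunn's multiple
  comparisons;
* delta-from-baseline contrasts — per-animal differences relative to the
  unanesthetized state, compared between sexes with the two-group path.

Dunn's post-hoc (both the Friedman within-block flavor and the
independent-sample flavor) uses rank-sum z statistics with a
Bonferroni-type family correction.  A summary-statistics t-test
(``summary_stat_ttest``) verifies printed mean ± SEM comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.anova import AnovaRM

__all__ = ["ConditionTriplet", "TestReport", "normality_gate",
           "compare_three_conditions", "compare_two_groups",
           "summary_stat_ttest", "delta_from_uas", "compare_df_groups",
           "ALPHA", "CONDITIONS"]

ALPHA = 0.05
CONDITIONS = ("UAS", "ISO", "PEN")


@dataclass
class ConditionTriplet:
    """One animal's values under the three recording conditions."""

    animal_id: str
    sex: str
    values: dict     # condition -> float

    def complete(self, conditions=CONDITIONS) -> bool:
        return all(c in self.values and np.isfinite(self.values[c])
                   for c in conditions)


@dataclass
class TestReport:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    normality_passed: bool | None = None
    pairwise: list = field(default_factory=list)  # (contrast, adjusted p)
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def normality_gate(groups: dict | list, alpha: float = ALPHA) -> dict:
    """Shapiro–Wilk normality per group; gate passes iff every group does.

    Returns ``{"per_group": {name: bool}, "passed": bool}``.  Degenerate
    (constant) samples fail with an explicit flag; groups need n >= 3.
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    per_group: dict = {}
    degenerate = []
    for name, g in groups.items():
        x = np.asarray(g, float)
        if len(x) < 3:
            raise ValueError(f"group {name!r} has n < 3")
        if np.ptp(x) == 0:
            per_group[name] = False
            degenerate.append(name)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_group[name] = bool(st.shapiro(x).pvalue > alpha)
    return {"per_group": per_group, "passed": all(per_group.values()),
            "degenerate": degenerate}


# ---------------------------------------------------------------------------
# three within-animal conditions
# ---------------------------------------------------------------------------

def _rm_anova(data: np.ndarray, conditions) -> tuple[float, float, float, int]:
    """RM-ANOVA via statsmodels; returns (F, p, ms_error, df_error)."""
    n, k = data.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "condition": list(conditions) * n,
        "value": data.ravel(),
    })
    res = AnovaRM(long, "value", "subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    F, p = float(row["F Value"]), float(row["Pr > F"])
    # error mean square recovered from the within-subject decomposition
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    df_err = (n - 1) * (k - 1)
    ms_err = (ss_tot - ss_cond - ss_subj) / df_err
    return F, p, ms_err, df_err


def _tukey_rm(data: np.ndarray, conditions, ms_err: float,
              df_err: int) -> list:
    """Tukey pairwise p-values using the RM-ANOVA error mean square."""
    n, k = data.shape
    means = data.mean(axis=0)
    se = np.sqrt(ms_err / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / se if se > 0 else 0.0
            p = float(st.studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
            out.append((f"{conditions[i]} vs {conditions[j]}", min(1.0, p)))
    return out


def _dunn_friedman(data: np.ndarray, conditions) -> list:
    """Dunn's post-hoc after Friedman: within-block rank sums, Bonferroni."""
    n, k = data.shape
    ranks = st.rankdata(data, axis=1)
    rank_sums = ranks.sum(axis=0)
    se = np.sqrt(n * k * (k + 1) / 6.0)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(rank_sums[i] - rank_sums[j]) / se
            p = min(1.0, 2.0 * st.norm.sf(z) * m)
            out.append((f"{conditions[i]} vs {conditions[j]}", float(p)))
    return out


def compare_three_conditions(triplets: list[ConditionTriplet],
                             force_nonparametric: bool = False,
                             force_parametric: bool = False,
                             conditions=CONDITIONS) -> TestReport:
    """Within-animal three-condition comparison with gated test selection.

    Normal in all conditions — repeated-measures one-way ANOVA plus Tukey
    post-hoc; otherwise Friedman plus Dunn.  Incomplete triplets are
    dropped with a warning; fewer than three complete triplets is an error.
    ``force_nonparametric`` (study convention for AF-substrate parameters)
    and ``force_parametric`` (calibration use) bypass the gate.
    """
    complete = [t for t in triplets if t.complete(conditions)]
    if len(complete) < len(triplets):
        warnings.warn(f"dropped {len(triplets) - len(complete)} incomplete "
                      "triplet(s)", stacklevel=2)
    if len(complete) < 3:
        raise ValueError("need at least 3 complete triplets")
    data = np.array([[t.values[c] for c in conditions] for t in complete])
    gate = normality_gate({c: data[:, i] for i, c in enumerate(conditions)})
    if force_parametric:
        normal = True
    elif force_nonparametric:
        normal = False
    else:
        normal = gate["passed"]
    if normal:
        if np.allclose(data, data[:, :1]):
            return TestReport("rm_anova + tukey", 0.0, 1.0, gate["passed"],
                              notes=["degenerate: no variation"])
        F, p, ms_err, df_err = _rm_anova(data, conditions)
        pairwise = _tukey_rm(data, conditions, ms_err, df_err)
        return TestReport("rm_anova + tukey", F, p, gate["passed"], pairwise)
    if np.allclose(data, data[:, :1]):
        return TestReport("friedman + dunn", 0.0, 1.0, gate["passed"],
                          notes=["degenerate: no variation"])
    stat, p = st.friedmanchisquare(*[data[:, i] for i in range(data.shape[1])])
    pairwise = _dunn_friedman(data, conditions)
    return TestReport("friedman + dunn", float(stat), float(p),
                      gate["passed"], pairwise)


# ---------------------------------------------------------------------------
# two groups
# ---------------------------------------------------------------------------

def compare_two_groups(x, y, paired: bool = False,
                       force: str | None = None) -> TestReport:
    """Two-sided two-group comparison with the normality gate.

    Student's pooled t-test (paired t-test when ``paired``) when both
    groups pass Shapiro–Wilk, otherwise Mann–Whitney (Wilcoxon signed-rank
    when paired).  ``force`` in {"t", "mannwhitney"} bypasses the gate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 per group")
    gate = normality_gate({"x": x, "y": y})
    use_t = gate["passed"] if force is None else (force == "t")
    notes = list(gate["degenerate"] and ["degenerate group(s)"] or [])
    if use_t:
        if paired:
            res = st.ttest_rel(x, y)
            name = "paired t"
        else:
            res = st.ttest_ind(x, y, equal_var=True)
            name = "student t"
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # identical constant samples
            stat, p = 0.0, 1.0
    else:
        if paired:
            d = x - y
            if np.all(d == 0):
                return TestReport("wilcoxon", 0.0, 1.0, gate["passed"],
                                  notes=["degenerate: all differences zero"])
            res = st.wilcoxon(x, y)
            name = "wilcoxon"
        else:
            if np.ptp(np.concatenate([x, y])) == 0:
                return TestReport("mann-whitney", 0.0, 1.0, gate["passed"],
                                  notes=["degenerate: all values tied"])
            res = st.mannwhitneyu(x, y, alternative="two-sided")
            name = "mann-whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    return TestReport(name, stat, p, gate["passed"], notes=notes)


def summary_stat_ttest(m1: float, sem1: float, n1: int,
                       m2: float, sem2: float, n2: int,
                       welch: bool = False) -> dict:
    """Two-sample t-test from printed summary statistics (mean ± SEM, n).

    Pooled-variance Student by default (``welch=True`` for Welch), with
    sd = sem * sqrt(n).  Returns ``{"t", "df", "p"}`` (two-sided).
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    res = st.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                  equal_var=not welch)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return {"t": float(res.statistic), "df": float(df),
            "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# delta contrasts and dominant-frequency groups
# ---------------------------------------------------------------------------

def delta_from_uas(triplets: list[ConditionTriplet],
                   baseline: str = "UAS") -> pd.DataFrame:
    """Per-animal condition deltas relative to the unanesthetized state.

    Animals missing the baseline are dropped with a warning.  Returns a
    tidy frame ``animal_id, sex, condition, delta`` (one row per
    non-baseline condition present).
    """
    rows = []
    dropped = 0
    for t in triplets:
        if baseline not in t.values or not np.isfinite(t.values[baseline]):
            dropped += 1
            continue
        base = t.values[baseline]
        for cond, v in t.values.items():
            if cond == baseline or not np.isfinite(v):
                continue
            rows.append((t.animal_id, t.sex, cond, v - base))
    if dropped:
        warnings.warn(f"dropped {dropped} animal(s) without {baseline}",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["animal_id", "sex", "condition",
                                       "delta"])


def _dunn_independent(groups: dict) -> list:
    """Dunn's test for independent samples with tie correction, Bonferroni."""
    names = list(groups)
    allv = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = [len(groups[g]) for g in names]
    ranks = st.rankdata(allv)
    n_tot = len(allv)
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {g: ranks[bounds[i]:bounds[i + 1]].mean()
                  for i, g in enumerate(names)}
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                         * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
            z = abs(mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * st.norm.sf(z) * m)
            out.append((f"{gi} vs {gj}", float(p)))
    return out


def compare_df_groups(groups: dict) -> TestReport:
    """Kruskal–Wallis over dominant-frequency groups with Dunn post-hoc.

    ``groups`` maps condition name to the per-window DF values.  Needs at
    least two groups with n >= 3 each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in groups.items():
        if len(g) < 3:
            raise ValueError(f"group {name!r} has n < 3")
    vals = [np.asarray(g, float) for g in groups.values()]
    if np.ptp(np.concatenate(vals)) == 0:
        return TestReport("kruskal-wallis + dunn", 0.0, 1.0,
                          notes=["degenerate: all values tied"])
    stat, p = st.kruskal(*vals)
    return TestReport("kruskal-wallis + dunn", float(stat), float(p),
                      pairwise=_dunn_independent(groups))
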