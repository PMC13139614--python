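"""Time-course assembly and group statistics.

Concentration-dependent differences in each spheroid metric are tested per
drug and per timepoint with a classical one-way ANOVA; when the ANOVA is
significant, Tukey's honestly-significant-difference (HSD) post-hoc test
identifies the concentration pairs that differ (Tukey–Kramer form for
unequal group sizes).  The many ANOVAs across metrics / timepoints / drugs
are treated as independent questions: no global multiplicity correction is
applied across them.  Pearson correlation summarizes monotone
concentration–response relationships.

ANOVA, Tukey HSD and Pearson r are implemented from the standard formulas
(they are part of this pipeline's reproduction surface) and cross-checked
against independent library implementations in the test suite.

Significance symbols follow the convention: '-' for p > 0.05, '*' for
p < 0.05, '**' for p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "build_timecourse",
    "one_way_anova",
    "tukey_hsd",
    "pearson_corr",
    "significance_symbol",
    "significance_report",
    "summarize_timecourse",
    "piecewise_slopes",
]

KEY_COLUMNS = ["condition", "concentration_um", "sample_id", "time_hr"]


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA outcome."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int

    def __post_init__(self) -> None:
        if self.f_statistic < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid ANOVA result")


def build_timecourse(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort the long-format metrics table.

    Rows are keyed by (condition, concentration, sample, time); duplicate
    keys are an error.  Missing timepoints are allowed and simply reduce the
    per-group n at that time.
    """
    df = pd.DataFrame(records).copy()
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing key columns: {missing}")
    if df.duplicated(subset=KEY_COLUMNS).any():
        dup = df[df.duplicated(subset=KEY_COLUMNS, keep=False)][KEY_COLUMNS]
        raise ValueError(f"duplicate (condition, concentration, sample, time) keys:\n{dup}")
    return df.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)


def summarize_timecourse(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean ± SD (and n) per condition/concentration per timepoint."""
    g = table.groupby(["condition", "concentration_um", "time_hr"])[metric]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        raise ValueError("degenerate input: all values identical")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """F = MS_between / MS_within with p from the F distribution."""
    gs = _check_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0:
        raise ValueError("not enough observations for residual degrees of freedom")
    if ss_within == 0:
        # group means differ (non-degenerate overall) but zero residual:
        # infinite F, p -> 0
        return AnovaResult(f_statistic=np.inf, p_value=0.0, df_between=df_b, df_within=df_w)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f_statistic=float(f), p_value=p, df_between=df_b, df_within=df_w)


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (Tukey–Kramer for unequal n).

    Returns one row per unordered group pair with the mean difference
    (B − A) and the studentized-range adjusted p-value.
    """
    gs = _check_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    df_w = sum(g.size for g in gs) - k
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            diff = b.mean() - a.mean()
            if ms_within == 0:
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(diff),
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


def pearson_corr(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must be non-constant")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    return min(max(r, -1.0), 1.0)


def significance_symbol(p: float) -> str:
    """'-' for p > 0.05, '*' for p < 0.05, '**' for p < 0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


def significance_report(
    table: pd.DataFrame,
    metric: str,
    times_hr=(0.0, 12.0, 100.0),
    group_col: str = "concentration_um",
    condition: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint ANOVA across groups, with gated Tukey post-hoc.

    For every requested time, groups the metric by ``group_col`` (within one
    condition if given), runs the one-way ANOVA, maps p to its symbol, and —
    only when the ANOVA is significant at ``alpha`` — attaches the Tukey
    pairwise table.
    """
    df = table if condition is None else table[table["condition"] == condition]
    rows = []
    for t in times_hr:
        sub = df[np.isclose(df["time_hr"], t)]
        if sub.empty:
            raise ValueError(f"no rows at time {t} hr")
        grouped = [
            (lvl, g[metric].to_numpy()) for lvl, g in sub.groupby(group_col, sort=True)
        ]
        labels = [str(lvl) for lvl, _ in grouped]
        res = one_way_anova([v for _, v in grouped])
        tukey = (
            tukey_hsd([v for _, v in grouped], labels=labels)
            if res.p_value < alpha
            else None
        )
        rows.append(
            {
                "metric": metric,
                "time_hr": float(t),
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "symbol": significance_symbol(res.p_value),
                "tukey": tukey,
            }
        )
    return pd.DataFrame(rows)


def piecewise_slopes(times_hr, values, breakpoint_hr: float) -> dict:
    """Exploratory two-segment slope summary around a chosen breakpoint.

    Plain least-squares slopes before and after ``breakpoint_hr``.  This is a
    descriptive convenience for eyeballing trend changes in a time course; it
    is not part of the standard statistical readout and implements no
    changepoint detection.
    """
    t = np.asarray(times_hr, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 4:
        raise ValueError("need equal-length inputs with at least 4 points")
    first = t <= breakpoint_hr
    if first.sum() < 2 or (~first).sum() < 2:
        raise ValueError("each segment needs at least 2 points")
    s1 = np.polyfit(t[first], v[first], 1)[0]
    s2 = np.polyfit(t[~first], v[~first], 1)[0]
    return {
        "breakpoint_hr": float(breakpoint_hr),
        "slope_before": float(s1),
        "slope_after": float(s2),
        "slope_change": float(s2 - s1),
    }
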