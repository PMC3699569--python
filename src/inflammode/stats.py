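"""Group-comparison statistics on replicate data or (mean, SEM, n) summaries.

The study design reports everything as mean +/- SEM with known group sizes,
so every test here can be computed from summary statistics alone and agrees
exactly with the raw-replicate computation. Provided: two-sample t tests
(Welch or pooled "Student's"), a two-way factorial ANOVA operating on cell
summaries, the Holm-Sidak step-down multiplicity adjustment, and the
LPS-induction fold-change contrast between age groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError
from .synthetic import GroupSummary, TimeCourseDataset


@dataclass(frozen=True)
class TTestResult:
    """Two-sided t test outcome."""

    t: float
    df: float
    p: float
    method: str  # "welch" | "pooled" | "one-sample-degenerate" | "degenerate"


@dataclass(frozen=True)
class AnovaResult:
    """Two-way factorial ANOVA decomposition."""

    table: pd.DataFrame  # rows: factor A, factor B, interaction, residual

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def t_from_summary(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
    method: str = "welch",
) -> TTestResult:
    """Two-sample t test from printed (mean, SEM, n) columns.

    Welch (default): ``t = (m1 - m2)/sqrt(sem1^2 + sem2^2)`` with
    Satterthwaite degrees of freedom. Pooled: the classical equal-variance
    form with ``sd = sem * sqrt(n)``. If exactly one group has zero SEM
    (e.g. every value at the detection floor), the test degrades to a
    one-sample test of the other group against that constant with
    ``df = n - 1`` and method ``one-sample-degenerate``. Two zero-SEM
    groups give the fully degenerate p of 0 (means differ) or 1 (equal).
    """
    if n1 < 1 or n2 < 1:
        raise InvalidInputError("need n >= 1 in both groups")
    if sem1 < 0 or sem2 < 0 or not (math.isfinite(sem1) and math.isfinite(sem2)):
        raise InvalidInputError("SEMs must be finite and >= 0")
    if method not in ("welch", "pooled"):
        raise InvalidInputError("method must be 'welch' or 'pooled'")

    if sem1 == 0.0 and sem2 == 0.0:
        import warnings

        warnings.warn("both groups have zero SEM; test is degenerate", stacklevel=2)
        if mean1 == mean2:
            return TTestResult(t=0.0, df=float(n1 + n2 - 2), p=1.0,
                               method="degenerate")
        return TTestResult(t=math.inf if mean1 > mean2 else -math.inf,
                           df=float(n1 + n2 - 2), p=0.0, method="degenerate")

    if sem1 == 0.0 or sem2 == 0.0:
        # one group is a constant: one-sample test of the other against it
        if sem1 == 0.0:
            m, s, n, const = mean2, sem2, n2, mean1
            sign = -1.0
        else:
            m, s, n, const = mean1, sem1, n1, mean2
            sign = 1.0
        t = sign * (m - const) / s
        df = float(n - 1)
        p = 2.0 * sps.t.sf(abs(t), df)
        return TTestResult(t=t, df=df, p=min(p, 1.0),
                           method="one-sample-degenerate")

    if method == "welch":
        v1, v2 = sem1 ** 2, sem2 ** 2
        t = (mean1 - mean2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        sd1, sd2 = sem1 * math.sqrt(n1), sem2 * math.sqrt(n2)
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=min(p, 1.0), method=method)


def t_from_replicates(x1, x2, method: str = "welch") -> TTestResult:
    """Two-sample t test from raw replicates via their summaries."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return t_from_summary(
        float(x1.mean()), float(x1.std(ddof=1) / math.sqrt(len(x1))), len(x1),
        float(x2.mean()), float(x2.std(ddof=1) / math.sqrt(len(x2))), len(x2),
        method=method,
    )


def _design_matrices(levels_a, levels_b, cells):
    """Weighted design matrices (effects coding) for the cell-mean models."""
    a_idx = {lv: i for i, lv in enumerate(levels_a)}
    b_idx = {lv: i for i, lv in enumerate(levels_b)}

    def effect_code(idx, n_levels):
        row = np.zeros(n_levels - 1)
        if idx < n_levels - 1:
            row[idx] = 1.0
        else:
            row[:] = -1.0
        return row

    cols_a, cols_b, cols_ab = [], [], []
    for (a, b, *_rest) in cells:
        ca = effect_code(a_idx[a], len(levels_a))
        cb = effect_code(b_idx[b], len(levels_b))
        cols_a.append(ca)
        cols_b.append(cb)
        cols_ab.append(np.outer(ca, cb).ravel())
    ones = np.ones((len(cells), 1))
    return ones, np.array(cols_a), np.array(cols_b), np.array(cols_ab)


def anova_two_way_from_cells(summary: GroupSummary | pd.DataFrame,
                             factor_a: str, factor_b: str) -> AnovaResult:
    """Two-way factorial ANOVA from per-cell (mean, sem, n) summaries.

    Between-cell sums of squares come from weighted model comparisons on
    the cell means (weights = cell n, effects coding; Type II); the within
    (residual) sum of squares is ``sum (n-1) sd^2`` with ``sd = sem *
    sqrt(n)``. For balanced grids this equals the classical raw-data
    two-way ANOVA exactly.
    """
    df = summary.records if isinstance(summary, GroupSummary) else summary
    for col in (factor_a, factor_b, "mean", "sem", "n"):
        if col not in df.columns:
            raise InvalidInputError(f"summary table lacks column {col!r}")
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    grid = {(a, b) for a in levels_a for b in levels_b}
    have = set(zip(df[factor_a], df[factor_b]))
    missing = sorted(grid - have)
    if missing:
        raise InvalidInputError(f"incomplete factorial grid; missing cells: {missing}")
    if len(df) != len(grid):
        raise InvalidInputError("summary table must have exactly one row per cell")
    if (df["n"] < 2).any():
        raise InvalidInputError("every cell needs n >= 2")

    cells = list(zip(df[factor_a], df[factor_b]))
    y = df["mean"].to_numpy(dtype=float)
    n = df["n"].to_numpy(dtype=float)
    sd = df["sem"].to_numpy(dtype=float) * np.sqrt(n)
    w = np.sqrt(n)

    ones, xa, xb, xab = _design_matrices(levels_a, levels_b, cells)

    def wrss(*blocks):
        X = np.hstack(blocks)
        beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        r = y - X @ beta
        return float(np.sum(n * r * r))

    rss_full = wrss(ones, xa, xb, xab)
    rss_ab = wrss(ones, xa, xb)
    rss_a = wrss(ones, xa)
    rss_b = wrss(ones, xb)

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    ss_a = rss_b - rss_ab   # Type II: A adjusted for B
    ss_b = rss_a - rss_ab
    ss_ab = rss_ab - rss_full
    ss_within = float(np.sum((n - 1.0) * sd * sd))
    df_within = float(np.sum(n - 1.0))
    ms_within = ss_within / df_within

    rows = {}
    for name, ss, d in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
                        (f"{factor_a}:{factor_b}", ss_ab, df_ab)):
        ss = max(ss, 0.0)
        F = (ss / d) / ms_within if ms_within > 0 else math.inf if ss > 0 else 0.0
        if ms_within > 0:
            p = float(sps.f.sf(F, d, df_within))
        else:
            p = 0.0 if ss > 0 else 1.0
        rows[name] = {"sum_sq": ss, "df": float(d), "F": F, "p": p}
    rows["residual"] = {"sum_sq": ss_within, "df": df_within,
                        "F": math.nan, "p": math.nan}
    table = pd.DataFrame(rows).T[["sum_sq", "df", "F", "p"]]
    return AnovaResult(table=table)


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorted ascending, ``adj_i = 1 - (1 - p_i)^(m - i)`` for rank i
    (0-based), then enforced monotone non-decreasing and mapped back.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def fold_change_contrast(
    dataset: TimeCourseDataset,
    at_time: float = 90.0,
    ages: Sequence[str] = ("young", "middle-aged"),
    method: str = "welch",
) -> pd.DataFrame:
    """Compare LPS-induced fold induction between age groups.

    Per animal in the LPS arm, fold = value / (same-age saline group mean
    at the same time). The per-age fold distributions are then compared
    with a two-sample t test from their summaries. Analytes whose saline
    mean is zero (floored) are reported as missing with a reason code.

    Returns a table with per-age mean folds, the t statistic, df and p (or
    a ``reason`` for missing rows).
    """
    df = dataset.records
    df = df[df["time_min"] == at_time]
    rows = []
    for analyte, grp in df.groupby("analyte"):
        folds = {}
        reason = None
        for age in ages:
            saline = grp[(grp["age"] == age) & (grp["treatment"] == "saline")]
            lps = grp[(grp["age"] == age) & (grp["treatment"] == "LPS")]
            if saline.empty or lps.empty:
                raise InvalidInputError(
                    f"both treatments required for age {age!r}, analyte {analyte!r}"
                )
            base = float(saline["value"].mean())
            if base == 0.0:
                reason = f"zero saline mean for {age}"
                break
            folds[age] = lps["value"].to_numpy(dtype=float) / base
        if reason is not None:
            rows.append({"analyte": analyte, "fold_mean_" + ages[0]: math.nan,
                         "fold_mean_" + ages[1]: math.nan, "t": math.nan,
                         "df": math.nan, "p": math.nan, "reason": reason})
            continue
        res = t_from_replicates(folds[ages[0]], folds[ages[1]], method=method)
        rows.append({
            "analyte": analyte,
            "fold_mean_" + ages[0]: float(folds[ages[0]].mean()),
            "fold_mean_" + ages[1]: float(folds[ages[1]].mean()),
            "t": res.t, "df": res.df, "p": res.p, "reason": "",
        })
    return pd.DataFrame(rows)
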