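"""Descriptive cohort statistics computed from published-style group summaries.

These operate on printed summary statistics (mean +/- SD with group sizes)
and 2x2 count tables rather than raw per-patient data: the pooled-variance
two-sample t for continuous characteristics and the uncorrected Pearson
chi-squared for categorical ones (no Yates continuity correction — the
conventional choice for baseline-characteristics tables of this size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def pooled_t(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic and its degrees of freedom."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return t, df


def pooled_t_pvalue(a: GroupSummary, b: GroupSummary) -> float:
    t, df = pooled_t(a, b)
    return float(2.0 * stats.t.sf(abs(t), df))


def chi2_2x2(table) -> tuple[float, int]:
    """Uncorrected Pearson chi-squared for a 2x2 count table (df = 1)."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    expected = np.outer(row, col) / tab.sum()
    chi2 = float(((tab - expected) ** 2 / expected).sum())
    return chi2, 1


def chi2_2x2_pvalue(table) -> float:
    chi2, df = chi2_2x2(table)
    return float(stats.chi2.sf(chi2, df))


def table_one(summaries: "pd.DataFrame") -> "pd.DataFrame":
    """Statistic + p columns for a baseline-characteristics table.

    Input rows describe one characteristic each. Continuous rows
    (type="continuous") carry mean1, sd1, n1, mean2, sd2, n2 and get the
    pooled two-sample t; categorical rows (type="categorical") carry the
    2x2 counts a, b, c, d (group1/group2 x with/without) and get the
    uncorrected Pearson chi-squared.
    """
    import pandas as pd

    rows = []
    for _, r in summaries.iterrows():
        if r["type"] == "continuous":
            a = GroupSummary(float(r["mean1"]), float(r["sd1"]), int(r["n1"]))
            b = GroupSummary(float(r["mean2"]), float(r["sd2"]), int(r["n2"]))
            stat, _ = pooled_t(a, b)
            p = pooled_t_pvalue(a, b)
        elif r["type"] == "categorical":
            tab = [[int(r["a"]), int(r["b"])], [int(r["c"]), int(r["d"])]]
            stat, _ = chi2_2x2(tab)
            p = chi2_2x2_pvalue(tab)
        else:
            raise ValueError(f"unknown row type {r['type']!r}")
        rows.append({"characteristic": r["characteristic"],
                     "statistic": stat, "p": p})
    return pd.DataFrame(rows)
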