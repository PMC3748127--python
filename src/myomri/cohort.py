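"""Cohort assembly and group statistics (mean ± SEM, %, t-tests, Pearson).

A cohort table is tidy: one row per animal × variable with the group label
(WT or Tg) and units.  Summaries mirror how small-animal phenotyping studies
report: group mean ± SEM, integer-rounded percent differences relative to
the control group, equal-variance unpaired t-tests and Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COLUMNS = ("animal", "group", "variable", "value", "units")


@dataclass
class CohortTable:
    """Tidy per-animal results container."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["animal", "variable"])
        if dup.any():
            raise ValueError("one value per animal and variable is required")

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "CohortTable":
        return cls(pd.DataFrame.from_records(records, columns=list(COLUMNS)))

    def values(self, variable: str, group: str) -> np.ndarray:
        sel = (self.data.variable == variable) & (self.data.group == group)
        return self.data.loc[sel, "value"].to_numpy(dtype=float)


def group_summary(table: CohortTable, variable: str) -> pd.DataFrame:
    """Per-group n, mean and SEM (= sd/sqrt(n), ddof=1) for one variable."""
    sub = table.data[table.data.variable == variable]
    if sub.empty:
        raise ValueError(f"variable {variable!r} not present in cohort table")
    rows = []
    for group, g in sub.groupby("group"):
        v = g.value.to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"group {group!r} needs >= 2 animals for a SEM")
        rows.append(
            {
                "group": group,
                "n": v.size,
                "mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
            }
        )
    return pd.DataFrame(rows)


def percent_difference(mean_ref: float, mean_other: float) -> Tuple[float, int]:
    """Percent change of ``mean_other`` relative to the reference (WT) mean.

    Returns the exact value and the integer-rounded form used for reporting.
    """
    if mean_ref == 0:
        raise ValueError("reference mean must be nonzero")
    exact = 100.0 * (mean_other - mean_ref) / mean_ref
    return exact, int(round(exact))


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Sample Pearson correlation: (r, r^2, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided equal-variance Student t-test: (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: CohortTable, variable: str, reference: str = "WT"
) -> Dict[str, float]:
    """Mean ± SEM per group, percent difference vs reference, and t-test."""
    summary = group_summary(table, variable)
    groups = list(summary.group)
    if reference not in groups or len(groups) != 2:
        raise ValueError("expected exactly two groups including the reference")
    other = next(g for g in groups if g != reference)
    m_ref = float(summary.loc[summary.group == reference, "mean"].iloc[0])
    m_oth = float(summary.loc[summary.group == other, "mean"].iloc[0])
    pct, pct_int = percent_difference(m_ref, m_oth)
    t, p = unpaired_t(table.values(variable, reference), table.values(variable, other))
    return {
        "mean_ref": m_ref,
        "mean_other": m_oth,
        "percent_difference": pct,
        "percent_difference_rounded": pct_int,
        "t": t,
        "p": p,
    }
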