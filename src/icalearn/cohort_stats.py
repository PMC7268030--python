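"""Demographic and clinical comparison statistics from printed summaries.

Published cohort tables usually report group means with standard
deviations and gender percentages rather than raw data.  These helpers
recompute the corresponding pooled-variance two-sample t tests and
Pearson chi-square tests (no continuity correction) directly from those
summary statistics, so printed table values can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: n, mean, SD (in the variable's units)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class CountTable2x2:
    """2x2 group-by-category counts (e.g. group x gender)."""

    cells: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        arr = np.asarray(self.cells)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("cells must be a 2x2 table of non-negative counts")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("every marginal must be > 0 for the test to be defined")


def t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance Student t from two group summaries.

    Sign follows ``a.mean - b.mean``; df = n_a + n_b - 2; two-sided p.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group SDs are zero (degenerate input)")
    n1, n2 = a.n, b.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.sd**2 + (n2 - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def chi2_2x2(table: CountTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction; df = 1."""
    obs = np.asarray(table.cells, dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, 1, p


def percent_to_count(percent: float, n: int, tol: float = 0.5) -> int:
    """Back out the integer count behind a printed percentage of n.

    Raises if no integer count reproduces the printed percent within
    ``tol`` percentage points (a data-entry inconsistency).
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    count = round(percent * n / 100.0)
    if abs(100.0 * count / n - percent) > tol:
        raise ValueError(
            f"{percent}% of n={n} is not within {tol} points of any integer count"
        )
    return int(count)


def gender_chi2(
    percent_a: float, n_a: int, percent_b: float, n_b: int
) -> tuple[float, int, float]:
    """Chi-square on a gender table reconstructed from printed male percents."""
    males_a = percent_to_count(percent_a, n_a)
    males_b = percent_to_count(percent_b, n_b)
    table = CountTable2x2(((males_a, n_a - males_a), (males_b, n_b - males_b)))
    return chi2_2x2(table)
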