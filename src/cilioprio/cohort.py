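"""Cohort-level comparison statistics.

Prevalence proportions, 2x2 chi-square contingency tests, Welch t-tests from
summary statistics (mean +/- SD per group, as clinical tables report them),
and the Mann-Whitney U test for non-normal continuous variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "proportion_pct",
    "chisq_2x2",
    "welch_from_summary",
    "mannwhitney",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Event / non-event counts for two groups: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*k/n rounded half-away-from-zero to `decimals` places.

    Half-away-from-zero (not banker's rounding) matches the convention of
    clinical prevalence tables.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def chisq_2x2(t: ContingencyTable2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on a 2x2 table.

    Yates continuity correction is off by default; both modes are exposed.
    """
    table = t.array
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def welch_from_summary(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Welch unequal-variance t-test from per-group (mean, sd, n).

    Returns (t statistic, Welch-Satterthwaite df, two-sided p).
    """
    se1, se2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    df = (se1 + se2) ** 2 / (se1**2 / (g1.n - 1) + se2**2 / (g2.n - 1))
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    return float(res.statistic), float(df), float(res.pvalue)


def mannwhitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with tie correction.

    Exact null distribution for small samples without ties, normal
    approximation otherwise (scipy's automatic method selection).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
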