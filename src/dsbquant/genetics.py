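"""Recombination-genetics arithmetic and summary-statistic tests.

Map distances use Haldane's function, which assumes crossovers occur as a
Poisson process with no interference: a recombinant fraction ``R`` maps to
``d = -50 ln(1 - 2R)`` centimorgans, and conversely
``R = (1 - exp(-d/50)) / 2``.  Intragenic (gene-conversion) frequencies are
expressed per 10^6 viable spores, as is conventional for fission-yeast
*ade6* crosses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CrossCounts",
    "SummaryStat",
    "FoldChange",
    "TTestResult",
    "ChiSquareResult",
    "haldane",
    "haldane_R",
    "fold_change",
    "ttest_from_summary",
    "chisq_2x2",
]


@dataclass(frozen=True)
class CrossCounts:
    """Outcome of one cross: recombinant count among total viable spores."""

    recombinants: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.recombinants <= self.total):
            raise ValueError(
                f"recombinants must lie in [0, total]; got "
                f"{self.recombinants}/{self.total}"
            )
        if self.total <= 0:
            raise ValueError("total viable spores must be positive")

    @property
    def frequency(self) -> float:
        """Recombinants per 10^6 viable spores."""
        return 1e6 * self.recombinants / self.total

    @property
    def fraction(self) -> float:
        return self.recombinants / self.total


@dataclass(frozen=True)
class SummaryStat:
    """Mean ± SEM over n replicate crosses."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    percent_change: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def haldane(R: float) -> float:
    """Convert a recombinant fraction to map distance in cM (Haldane).

    ``d = -50 ln(1 - 2R)``; defined for ``0 <= R < 0.5``.
    """
    if not 0.0 <= R < 0.5:
        raise ValueError(f"recombinant fraction must be in [0, 0.5); got {R}")
    return -50.0 * math.log1p(-2.0 * R)


def haldane_R(d: float) -> float:
    """Inverse Haldane: map distance in cM to recombinant fraction."""
    if d < 0:
        raise ValueError(f"map distance must be >= 0; got {d}")
    return -0.5 * math.expm1(-d / 50.0)


def fold_change(a: float, b: float) -> FoldChange:
    """Ratio b/a and percent change 100*(b-a)/a for two summary values.

    ``a`` is the reference (e.g. the cross without the extra cassette).
    """
    if a <= 0:
        raise ValueError("reference value must be positive")
    return FoldChange(ratio=b / a, percent_change=100.0 * (b - a) / a)


def ttest_from_summary(
    a: SummaryStat, b: SummaryStat, df_rule: str = "pooled-count"
) -> TTestResult:
    """Unpaired two-sided t-test from per-group mean ± SEM summaries.

    The statistic is ``t = |mean_b - mean_a| / sqrt(sem_a^2 + sem_b^2)``.
    Degrees of freedom follow ``df_rule``:

    - ``"pooled-count"`` (default): ``n_a + n_b - 2``.
    - ``"welch"``: Welch-Satterthwaite from the SEMs,
      ``(sa^2+sb^2)^2 / (sa^4/(n_a-1) + sb^4/(n_b-1))``.

    With raw replicate values unavailable, only the SEM-combined statistic
    can be formed; both df conventions are offered because published P
    values rarely state which was used.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    se2 = a.sem**2 + b.sem**2
    if se2 == 0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
        raise ValueError("both SEMs are zero but means differ: t undefined")
    t = abs(b.mean - a.mean) / math.sqrt(se2)
    if df_rule == "pooled-count":
        df = float(a.n + b.n - 2)
    elif df_rule == "welch":
        df = se2**2 / (a.sem**4 / (a.n - 1) + b.sem**4 / (b.n - 1))
    else:
        raise ValueError(f"unknown df_rule {df_rule!r}")
    p = 2.0 * stats.t.sf(t, df)
    return TTestResult(t=t, df=df, p=float(p))


def chisq_2x2(
    table: "np.ndarray | list", correction: bool = False
) -> ChiSquareResult:
    """Pearson contingency chi-square on a 2x2 table of counts, df=1.

    Yates continuity correction is off by default; enable with
    ``correction=True``.
    """
    arr = np.asarray(table, dtype=float).reshape(2, 2)
    if (arr < 0).any():
        raise ValueError("counts must be >= 0")
    if arr.sum(axis=0).min() <= 0 or arr.sum(axis=1).min() <= 0:
        raise ValueError("both margins must be positive")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p))
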