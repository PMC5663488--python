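"""Exact 2x2 case-control inference.

The statistics stack used throughout the package:

* odds ratio by the cross-product, with the Haldane-Anscombe correction
  (add 0.5 to every cell) applied *only* when the table contains a zero cell;
* Woolf (log-normal) confidence interval, on the corrected cells whenever the
  correction was applied, with the conventional two-decimal normal critical
  value (1.96 at 95%);
* two-sided Fisher exact P by the point-probability rule: the sum of
  hypergeometric probabilities of all tables with the same margins whose
  point probability does not exceed that of the observed table (relative tie
  tolerance 1e-7);
* Bonferroni correction ``pc = min(1, m * p)`` with an NS flag when the
  corrected value hits the cap;
* two-sided Mann-Whitney rank-sum comparison for continuous phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CarrierTable",
    "Direction",
    "AssociationResult",
    "CorrectedP",
    "odds_ratio",
    "woolf_ci",
    "fisher_exact_two_sided",
    "bonferroni",
    "rank_sum_compare",
    "associate",
]

#: relative tolerance for point-probability ties in the two-sided Fisher rule
_FISHER_TIE_RTOL = 1e-7

#: significance level for the NS flag and the direction call
_ALPHA = 0.05


@dataclass(frozen=True)
class CarrierTable:
    """A 2x2 case/control x carrier/non-carrier table.

    ``a``/``b`` are case carriers/non-carriers; ``c``/``d`` the control
    counterparts.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each arm must contain at least one individual")

    @property
    def case_total(self) -> int:
        return self.a + self.b

    @property
    def control_total(self) -> int:
        return self.c + self.d

    @property
    def case_frequency(self) -> float:
        """Carrier frequency among cases, in percent."""
        return 100.0 * self.a / self.case_total

    @property
    def control_frequency(self) -> float:
        return 100.0 * self.c / self.control_total

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def swapped_arms(self) -> "CarrierTable":
        """The same table with case and control rows exchanged."""
        return CarrierTable(self.c, self.d, self.a, self.b)

    def _effective_cells(self) -> tuple[float, float, float, float]:
        # Haldane-Anscombe: +0.5 to all four cells, but only when needed.
        if self.has_zero_cell:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


def odds_ratio(table: CarrierTable) -> float:
    """Cross-product odds ratio with the conditional Haldane-Anscombe correction."""
    a, b, c, d = table._effective_cells()
    return (a * d) / (b * c)


def _z_critical(level: float) -> float:
    # Two-decimal critical value (1.96 at 95%), the convention of the
    # published tables this package is validated against.
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return round(float(stats.norm.ppf((1.0 + level) / 2.0)), 2)


def woolf_ci(table: CarrierTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio.

    Uses the corrected cells whenever :func:`odds_ratio` applies the
    zero-cell correction, so the interval always brackets the reported OR.
    """
    z = _z_critical(level)
    a, b, c, d = table._effective_cells()
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def fisher_exact_two_sided(table: CarrierTable) -> float:
    """Two-sided Fisher exact P by the point-probability rule.

    Sums hypergeometric probabilities of every table with the observed
    margins whose point probability is <= that of the observed table, with a
    relative tolerance of 1e-7 for ties.
    """
    n = table.a + table.b + table.c + table.d
    carriers = table.a + table.c
    cases = table.case_total
    rv = stats.hypergeom(n, carriers, cases)
    lo = max(0, cases + carriers - n)
    hi = min(cases, carriers)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = pmf[table.a - lo]
    mask = pmf <= p_obs * (1.0 + _FISHER_TIE_RTOL)
    if mask.all():
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


class CorrectedP(NamedTuple):
    """Bonferroni-corrected P plus the not-significant flag."""

    value: float
    ns: bool


def bonferroni(p: float, m: int) -> CorrectedP:
    """``pc = min(1, m * p)``, flagged NS when the correction hits the cap.

    The NS flag mirrors the reporting convention of the tables this package
    is validated against: a numeric corrected P is shown only when
    ``m * p < 1``, otherwise the unit is marked not significant.
    """
    if m < 1:
        raise ValueError(f"number of units tested must be >= 1, got {m}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return CorrectedP(min(1.0, p * m), p * m >= 1.0)


def rank_sum_compare(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = 25,
) -> float:
    """Two-sided Mann-Whitney U P value.

    Computed exactly (full permutation distribution) when both samples have
    at most ``exact_threshold`` observations and carry no ties, otherwise by
    the tie-corrected normal approximation with continuity correction.
    Missing values (NaN) are dropped; an all-missing sample is an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    xa = xa[~np.isnan(xa)]
    ya = ya[~np.isnan(ya)]
    if xa.size == 0 or ya.size == 0:
        raise ValueError("rank_sum_compare requires non-empty samples")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(xa.size, ya.size) <= exact_threshold:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


class Direction(str, Enum):
    PREDISPOSING = "predisposing"
    PROTECTIVE = "protective"
    NONE = "none"


@dataclass
class AssociationResult:
    """Full association statistics for one tested unit.

    ``pc`` is ``None`` when no multiple-testing correction was requested for
    the unit (e.g. serogroup rows); ``ns`` flags units whose corrected P hit
    the 1.0 cap (or, absent a correction, whose uncorrected P is >= 0.05).
    """

    unit: str
    table: CarrierTable
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p: float = field(init=False)
    pc: float | None = None
    ns: bool = False
    level: float = 0.95
    m: int | None = None

    def __post_init__(self) -> None:
        self.or_ = odds_ratio(self.table)
        self.ci_low, self.ci_high = woolf_ci(self.table, self.level)
        self.p = fisher_exact_two_sided(self.table)
        if self.m is not None:
            self.pc, self.ns = bonferroni(self.p, self.m)
        else:
            self.ns = self.p >= _ALPHA

    @property
    def case_frequency(self) -> float:
        return self.table.case_frequency

    @property
    def control_frequency(self) -> float:
        return self.table.control_frequency

    @property
    def direction(self) -> Direction:
        if self.p >= _ALPHA or self.or_ == 1.0:
            return Direction.NONE
        return Direction.PREDISPOSING if self.or_ > 1.0 else Direction.PROTECTIVE


def associate(
    unit: str,
    a: int,
    case_total: int,
    c: int,
    control_total: int,
    m: int | None = None,
    level: float = 0.95,
) -> AssociationResult:
    """Convenience constructor from carrier counts and arm totals."""
    table = CarrierTable(a, case_total - a, c, control_total - c)
    return AssociationResult(unit=unit, table=table, m=m, level=level)
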