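"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from hla_assoc import GenotypeRecord, Locus, parse_allele


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Brute-force two-sided Fisher P by full hypergeometric enumeration.

    Exact rational arithmetic, independent of the package's implementation:
    enumerates every table with the observed margins and sums the point
    probabilities not exceeding that of the observed table.
    """
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = comb(n, row)
    lo = max(0, row + col - n)
    hi = min(row, col)
    probs = {
        x: Fraction(comb(col, x) * comb(n - col, row - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def printed_equal(value: float, printed: str) -> bool:
    """Does ``value`` round to ``printed`` at the printed precision?

    Handles both fixed notation (``0.0634`` -> 4 decimals) and scientific
    notation (``1.89e-21`` -> 3 significant digits).
    """
    printed = printed.strip()
    if "e" in printed.lower():
        mantissa = printed.lower().split("e")[0]
        sig = len(mantissa.replace(".", "").replace("-", "").lstrip("0"))
        fmt = f"%.{sig - 1}e"
        return (fmt % value) == (fmt % float(printed))
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return (f"%.{decimals}f" % value) == printed


def make_record(
    sample_id: str,
    status: str,
    drb1: tuple[str, str],
    dqb1: tuple[str, str] | None = None,
    **phenotypes,
) -> GenotypeRecord:
    """Terse GenotypeRecord builder from bare allele names."""
    return GenotypeRecord(
        sample_id=sample_id,
        status=status,
        drb1=(parse_allele(drb1[0], Locus.DRB1), parse_allele(drb1[1], Locus.DRB1)),
        dqb1=(
            (parse_allele(dqb1[0], Locus.DQB1), parse_allele(dqb1[1], Locus.DQB1))
            if dqb1
            else None
        ),
        phenotypes=phenotypes,
    )


@pytest.fixture
def toy_cohort() -> list[GenotypeRecord]:
    """Six samples, two-locus, hand-checkable carrier counts.

    DRB1 carriers: 04:05 in case1 (het), case2 (hom), ctrl1 -> a=2, c=1.
    """
    return [
        make_record("case1", "case", ("04:05", "08:03"), ("04:01", "06:01")),
        make_record("case2", "case", ("04:05", "04:05"), ("04:01", "04:01")),
        make_record("case3", "case", ("13:02", "09:01"), ("06:04", "03:03")),
        make_record("ctrl1", "control", ("04:05", "13:02"), ("04:01", "06:04")),
        make_record("ctrl2", "control", ("09:01", "09:01"), ("03:03", "03:03")),
        make_record("ctrl3", "control", ("15:02", "08:03"), ("06:01", "06:01")),
    ]
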