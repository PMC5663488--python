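"""Amino-acid residue translation and per-residue carrier scans.

Alleles are translated to residues at polymorphic positions of the mature
beta chain (position 1 = first residue after the signal peptide) through a
user-supplied lookup table; no sequence inference is performed.  A sample
carries residue r at position p iff at least one of its alleles encodes r at
p, so residue scans inherit the dominant-model counting of allele scans.
When a residue is encoded by exactly one allele in a cohort, its scan result
is identical to that allele's — this equivalence is what lets a residue scan
localise an allele association to specific positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort_io import CountFixture, GenotypeRecord
from .contingency import AssociationResult, associate
from .nomenclature import AlleleCall, Locus, parse_allele

__all__ = ["ResidueTable", "ResidueUnit", "residues_of", "residue_carrier_scan"]


@dataclass(frozen=True, order=True)
class ResidueUnit:
    """One (position, residue) pair tested in a scan."""

    position: int
    residue: str

    @property
    def label(self) -> str:
        return f"{self.position}{self.residue}"

    def __str__(self) -> str:
        return self.label


class ResidueTable:
    """Lookup of (allele, position) -> one-letter residue."""

    def __init__(self, entries: dict[tuple[AlleleCall, int], str]):
        for (allele, pos), res in entries.items():
            if pos < 1:
                raise ValueError(f"{allele} position {pos}: positions are >= 1")
            if len(res) != 1 or not res.isalpha():
                raise ValueError(
                    f"{allele} position {pos}: residue {res!r} is not a "
                    "one-letter amino acid code"
                )
        self._entries = dict(entries)
        self._alleles = frozenset(a for a, _ in entries)
        self._positions = tuple(sorted({p for _, p in entries}))

    @classmethod
    def from_tsv(cls, path: str | Path, locus_hint: Locus | str = Locus.DRB1) -> "ResidueTable":
        """Load from a TSV with columns ``allele``, ``position``, ``residue``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        entries: dict[tuple[AlleleCall, int], str] = {}
        for _, row in df.iterrows():
            key = (parse_allele(row["allele"], locus_hint), int(row["position"]))
            if key in entries and entries[key] != row["residue"].upper():
                raise ValueError(
                    f"conflicting residues for {key[0]} position {key[1]}"
                )
            entries[key] = row["residue"].upper()
        return cls(entries)

    @classmethod
    def bundled_drb1(cls) -> "ResidueTable":
        """The partial curated DRbeta table shipped with the package."""
        from importlib import resources

        return cls.from_tsv(
            str(resources.files("hla_assoc").joinpath("data", "residues_drb1_curated.tsv"))
        )

    @property
    def alleles(self) -> frozenset[AlleleCall]:
        return self._alleles

    @property
    def positions(self) -> tuple[int, ...]:
        return self._positions

    def get(self, allele: AlleleCall, position: int) -> str | None:
        return self._entries.get((allele, position))

    def polymorphic_positions(self, alleles: Sequence[AlleleCall] | None = None) -> list[int]:
        """Positions with more than one residue among the given alleles."""
        alleles = list(alleles) if alleles is not None else sorted(self._alleles)
        out = []
        for p in self._positions:
            residues = {self.get(a, p) for a in alleles} - {None}
            if len(residues) > 1:
                out.append(p)
        return out


def residues_of(
    allele: AlleleCall,
    table: ResidueTable,
    positions: Sequence[int],
) -> dict[int, str | None]:
    """Residues of ``allele`` at the requested positions.

    Uncovered positions map to ``None`` (an explicit gap); an allele absent
    from the table entirely raises ``KeyError`` naming it.
    """
    if allele not in table.alleles:
        raise KeyError(f"allele {allele} is absent from the residue table")
    return {p: table.get(allele, p) for p in positions}


def _coverage_check(table: ResidueTable, alleles: Sequence[AlleleCall], positions: Sequence[int]) -> None:
    gaps = [
        (str(a), p)
        for a in alleles
        for p in positions
        if table.get(a, p) is None
    ]
    if gaps:
        raise ValueError(
            f"residue table does not cover all observed alleles: missing {gaps[:5]}"
            + ("..." if len(gaps) > 5 else "")
        )


def residue_carrier_scan(
    records: Sequence[GenotypeRecord] | None = None,
    fixtures: Sequence[CountFixture] | None = None,
    table: ResidueTable | None = None,
    locus: Locus = Locus.DRB1,
    positions: Sequence[int] | None = None,
    m: int | None = None,
    level: float = 0.95,
) -> list[AssociationResult]:
    """Per-residue carrier association over :class:`ResidueUnit`s.

    With per-sample ``records``, carriage is counted exactly.  With
    pre-aggregated allele-carrier ``fixtures``, the residue carrier count is
    approximated by the sum of the encoding alleles' carrier counts, capped
    at the arm total — an upper bound, since co-carriage of two alleles
    encoding the same residue is not recoverable from margins.

    The Bonferroni multiplier defaults to the number of residue units
    tested.  Positions default to all polymorphic positions covered for the
    observed alleles.
    """
    if table is None:
        raise ValueError("a ResidueTable is required")
    if (records is None) == (fixtures is None):
        raise ValueError("provide exactly one of records= or fixtures=")

    if records is not None:
        cases = [r for r in records if r.is_case]
        controls = [r for r in records if not r.is_case]
        observed = sorted({a for r in records for a in r.alleles(locus)})
    else:
        assert fixtures is not None
        observed = sorted({parse_allele(f.unit, locus) for f in fixtures})
    if positions is None:
        positions = table.polymorphic_positions(observed)
    _coverage_check(table, observed, positions)

    units = sorted(
        {
            ResidueUnit(p, table.get(a, p))  # type: ignore[arg-type]
            for a in observed
            for p in positions
        }
    )
    if m is None:
        m = max(1, len(units))

    results = []
    if records is not None:
        for unit in units:
            def carries(r: GenotypeRecord) -> bool:
                return any(
                    table.get(a, unit.position) == unit.residue
                    for a in r.alleles(locus)
                )

            a_ct = sum(carries(r) for r in cases)
            c_ct = sum(carries(r) for r in controls)
            results.append(
                associate(unit.label, a_ct, len(cases), c_ct, len(controls), m=m, level=level)
            )
    else:
        assert fixtures is not None
        case_total = fixtures[0].case_total
        control_total = fixtures[0].control_total
        by_allele = {parse_allele(f.unit, locus): f for f in fixtures}
        for unit in units:
            encoders = [a for a in observed if table.get(a, unit.position) == unit.residue]
            a_ct = min(case_total, sum(by_allele[a].case_carriers for a in encoders))
            c_ct = min(control_total, sum(by_allele[a].control_carriers for a in encoders))
            results.append(
                associate(unit.label, a_ct, case_total, c_ct, control_total, m=m, level=level)
            )
    return results
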