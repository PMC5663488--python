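"""Cis/trans DQ alpha-beta heterodimer enumeration.

A DRB1-DQB1 diplotype implies, through the conserved haplotype structure, a
DQA1 allele on each chromosome.  The two chromosomes then encode four DQ
alpha-beta molecules: two *cis* (alpha and beta from the same chromosome)
and two *trans* (alpha from one chromosome, beta from the other).  The
trans-complementing molecules are of particular interest because their
(in)stability has been proposed to modulate disease risk in DR4/DR8
heterozygotes.

DQA1 assignments are population-level presumptions supplied as data
(``data/dqa1_linkage.tsv``), never typed results; stability labels come from
an optional user lookup and are free text — this module never computes
stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .nomenclature import AlleleCall, Locus, parse_allele
from .phasing import Diplotype, Haplotype

__all__ = ["DQLinkageMap", "HeterodimerPair", "HeterodimerSet", "enumerate_heterodimers"]


class DQLinkageMap:
    """Haplotype -> presumed DQA1 allele lookup."""

    def __init__(self, mapping: Mapping[Haplotype, AlleleCall]):
        for hap, dqa1 in mapping.items():
            if dqa1.locus is not Locus.DQA1:
                raise ValueError(f"{hap}: linked allele {dqa1} is not at DQA1")
        self._map = dict(mapping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DQLinkageMap":
        """Load from a TSV with columns ``drb1``, ``dqb1``, ``dqa1``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        mapping = {}
        for _, row in df.iterrows():
            hap = Haplotype(
                parse_allele(row["drb1"], Locus.DRB1),
                parse_allele(row["dqb1"], Locus.DQB1),
            )
            if hap in mapping:
                raise ValueError(f"duplicate linkage entry for {hap}")
            mapping[hap] = parse_allele(row["dqa1"], Locus.DQA1)
        return cls(mapping)

    @classmethod
    def default(cls) -> "DQLinkageMap":
        """The bundled three-haplotype map (nothing inferred beyond it)."""
        from importlib import resources

        return cls.from_tsv(
            str(resources.files("hla_assoc").joinpath("data", "dqa1_linkage.tsv"))
        )

    def dqa1_of(self, hap: Haplotype) -> AlleleCall:
        try:
            return self._map[hap]
        except KeyError:
            raise KeyError(
                f"haplotype {hap} is not covered by the DQA1 linkage map"
            ) from None

    def __contains__(self, hap: Haplotype) -> bool:
        return hap in self._map


@dataclass(frozen=True)
class HeterodimerPair:
    """One DQ alpha-beta molecule with its phase tag and stability label."""

    dqa1: AlleleCall
    dqb1: AlleleCall
    phase: str  # "cis" | "trans"
    stability: str = "unknown"

    @property
    def label(self) -> str:
        return f"{self.dqa1}-{self.dqb1}"


@dataclass(frozen=True)
class HeterodimerSet:
    """The four molecules implied by one diplotype: 2 cis + 2 trans."""

    cis: tuple[HeterodimerPair, HeterodimerPair]
    trans: tuple[HeterodimerPair, HeterodimerPair]

    def all_pairs(self) -> tuple[HeterodimerPair, ...]:
        return self.cis + self.trans


def enumerate_heterodimers(
    diplotype: Diplotype,
    linkage: DQLinkageMap | None = None,
    stability: Mapping[tuple[AlleleCall, AlleleCall], str] | None = None,
) -> HeterodimerSet:
    """Enumerate the cis and trans DQ molecules implied by a diplotype.

    ``cis = {(a1, b1), (a2, b2)}`` and ``trans = {(a1, b2), (a2, b1)}``
    where ``ai`` is the mapped DQA1 and ``bi`` the DQB1 of haplotype i.
    Stability labels are attached where the lookup covers a pair, else
    ``"unknown"``.  A haplotype missing from the map raises ``KeyError``
    naming it.
    """
    linkage = linkage or DQLinkageMap.default()
    h1, h2 = diplotype.haplotypes()
    a1, a2 = linkage.dqa1_of(h1), linkage.dqa1_of(h2)
    b1, b2 = h1.dqb1, h2.dqb1

    def make(dqa1: AlleleCall, dqb1: AlleleCall, phase: str) -> HeterodimerPair:
        label = "unknown"
        if stability is not None:
            label = stability.get((dqa1, dqb1), "unknown")
        return HeterodimerPair(dqa1, dqb1, phase, label)

    return HeterodimerSet(
        cis=(make(a1, b1, "cis"), make(a2, b2, "cis")),
        trans=(make(a1, b2, "trans"), make(a2, b1, "trans")),
    )
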