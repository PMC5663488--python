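"""HLA allele nomenclature: parsing, serological groups, shared-epitope alleles.

Works at two-field resolution throughout (e.g. ``DRB1*04:05``).  Higher-field
typing results are truncated to two fields (with a logged note), because
carrier counting, serogroup membership, and haplotype phasing in this package
are all defined on two-field names.

Serogroup and shared-epitope catalogs ship as editable TSV data files
(``data/serogroups.tsv``, ``data/shared_epitope.tsv``) so catalogs for other
populations can be substituted without touching code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "AlleleCall",
    "AlleleParseError",
    "SerogroupMap",
    "SharedEpitopeSet",
    "parse_allele",
    "serogroup_of",
    "is_shared_epitope",
]

# Recognised motifs at DRbeta 70-74 defining the shared epitope.
SHARED_EPITOPE_MOTIFS = frozenset({"QKRAA", "RRRAA", "QRRAA"})

_NAME_RE = re.compile(r"^(\d{2}):(\d{2})$")
_FIELD_RE = re.compile(r"^\d{2}$")


class Locus(str, Enum):
    """HLA class II loci handled by this package."""

    DRB1 = "DRB1"
    DQB1 = "DQB1"
    DQA1 = "DQA1"


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class AlleleCall:
    """A locus plus a two-field allele name — the atomic unit of all counting.

    Attributes
    ----------
    locus : Locus
    name : str
        Two colon-separated two-digit fields, e.g. ``"04:05"``.
    """

    locus: Locus
    name: str

    def __post_init__(self) -> None:
        if not isinstance(self.locus, Locus):
            object.__setattr__(self, "locus", Locus(self.locus))
        if not _NAME_RE.match(self.name):
            raise AlleleParseError(
                f"allele name {self.name!r} does not match the two-field "
                "form 'NN:NN'"
            )

    def __str__(self) -> str:
        return f"{self.locus.value}*{self.name}"

    @property
    def label(self) -> str:
        """Canonical rendering, ``<locus>*<name>``."""
        return str(self)


def parse_allele(text: str, locus_hint: Locus | str | None = None) -> AlleleCall:
    """Parse an HLA allele string into an :class:`AlleleCall`.

    Accepts ``"DRB1*04:05"``, higher-resolution names such as
    ``"DRB1*04:05:01"`` (truncated to two fields, logged), optional ``HLA-``
    prefix, and bare names like ``"04:05"`` when ``locus_hint`` is given.

    Raises
    ------
    AlleleParseError
        If the string is empty, the locus is missing and no hint is given,
        or a field is not a two-digit number.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele string")
    token = text.strip()
    if token.upper().startswith("HLA-"):
        token = token[4:]

    if "*" in token:
        locus_part, _, name_part = token.partition("*")
        try:
            locus = Locus(locus_part.upper())
        except ValueError:
            raise AlleleParseError(
                f"unknown locus {locus_part!r} in allele {text!r}"
            ) from None
    else:
        if locus_hint is None:
            raise AlleleParseError(
                f"allele {text!r} carries no locus and no locus hint was given"
            )
        locus = Locus(locus_hint)
        name_part = token

    fields = name_part.split(":")
    if len(fields) < 2:
        raise AlleleParseError(
            f"allele {text!r}: expected at least two ':'-separated fields"
        )
    if len(fields) > 2:
        logger.info(
            "allele %s truncated to two-field resolution (%s:%s)",
            text,
            fields[0],
            fields[1],
        )
        fields = fields[:2]
    for f in fields:
        if not _FIELD_RE.match(f):
            raise AlleleParseError(
                f"allele {text!r}: field {f!r} is not a two-digit number"
            )
    return AlleleCall(locus, f"{fields[0]}:{fields[1]}")


def _read_tsv(source: str | Path) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", comment="#", dtype=str)


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("hla_assoc").joinpath("data", filename)))


class SerogroupMap:
    """Disjoint serological groups of alleles at one or more loci.

    The bundled default carries the DR4/DR6/DR8 DRB1 groups used throughout
    this package's analyses.
    """

    def __init__(self, groups: dict[str, frozenset[AlleleCall]]):
        self.groups = {g: frozenset(members) for g, members in groups.items()}
        seen: dict[AlleleCall, str] = {}
        for group, members in self.groups.items():
            for allele in members:
                if allele in seen:
                    raise ValueError(
                        f"allele {allele} belongs to both {seen[allele]!r} "
                        f"and {group!r}; groups must be disjoint"
                    )
                seen[allele] = group
        self._by_allele = seen
        self._loci = frozenset(a.locus for a in seen)

    @classmethod
    def from_tsv(cls, path: str | Path, locus_hint: Locus | str = Locus.DRB1) -> "SerogroupMap":
        """Load from a TSV with columns ``group`` and ``allele``."""
        df = _read_tsv(path)
        groups: dict[str, set[AlleleCall]] = {}
        for _, row in df.iterrows():
            groups.setdefault(row["group"], set()).add(
                parse_allele(row["allele"], locus_hint)
            )
        return cls({g: frozenset(m) for g, m in groups.items()})

    @classmethod
    def default(cls) -> "SerogroupMap":
        """The bundled DR4/DR6/DR8 catalog."""
        return cls.from_tsv(_data_path("serogroups.tsv"))

    def serogroup_of(self, allele: AlleleCall) -> str | None:
        """Return the unique group containing ``allele``, else ``None``.

        Raises ``KeyError`` if the allele's locus is absent from the map
        entirely (a likely sign of using the wrong catalog).
        """
        if allele.locus not in self._loci:
            raise KeyError(
                f"locus {allele.locus.value} is not covered by this serogroup map"
            )
        return self._by_allele.get(allele)

    def members(self, group: str) -> frozenset[AlleleCall]:
        return self.groups[group]

    def __contains__(self, group: str) -> bool:
        return group in self.groups


class SharedEpitopeSet:
    """The set of DRB1 alleles whose DRbeta 70-74 motif is a shared epitope.

    Shared-epitope alleles carry QKRAA, RRRAA, or QRRAA at positions 70-74 of
    the mature DRbeta chain, the classical rheumatoid-arthritis risk motif.
    """

    def __init__(self, motifs_by_allele: dict[AlleleCall, str]):
        for allele, motif in motifs_by_allele.items():
            if allele.locus is not Locus.DRB1:
                raise ValueError(f"shared-epitope allele {allele} is not at DRB1")
            if motif not in SHARED_EPITOPE_MOTIFS:
                raise ValueError(
                    f"{allele}: motif {motif!r} is not a shared-epitope motif "
                    f"(expected one of {sorted(SHARED_EPITOPE_MOTIFS)})"
                )
        self.motifs_by_allele = dict(motifs_by_allele)
        self.alleles = frozenset(motifs_by_allele)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SharedEpitopeSet":
        """Load from a TSV with columns ``allele`` and ``motif_70_74``."""
        df = _read_tsv(path)
        return cls(
            {
                parse_allele(row["allele"], Locus.DRB1): row["motif_70_74"]
                for _, row in df.iterrows()
            }
        )

    @classmethod
    def default(cls) -> "SharedEpitopeSet":
        return cls.from_tsv(_data_path("shared_epitope.tsv"))

    def is_shared_epitope(self, allele: AlleleCall) -> bool:
        if allele.locus is not Locus.DRB1:
            raise ValueError(
                f"shared-epitope status is defined for DRB1 alleles only, got {allele}"
            )
        return allele in self.alleles


def serogroup_of(allele: AlleleCall, smap: SerogroupMap | None = None) -> str | None:
    """Group label containing ``allele``, or ``None`` (default catalog if unset)."""
    return (smap or SerogroupMap.default()).serogroup_of(allele)


def is_shared_epitope(allele: AlleleCall, se: SharedEpitopeSet | None = None) -> bool:
    """True iff ``allele`` is a shared-epitope DRB1 allele."""
    return (se or SharedEpitopeSet.default()).is_shared_epitope(allele)
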