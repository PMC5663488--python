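"""Association scans: allele/serogroup carriers, genotype classes, subgroups.

Carrier scans follow the dominant model — an individual counts once whether
heterozygous or homozygous.  Dosage becomes visible only in the genotype
scan, where classes such as ``DRB1*04:05/DRB1*04:05`` (homozygote),
``DRB1*04:05/not`` (single-copy carrier), or serogroup pairs like ``DR4/DR8``
are tested as member-vs-rest 2x2 tables.

The Bonferroni multiplier ``m`` for allele scans defaults to the number of
distinct alleles observed at the locus in the combined cohort; serogroup and
genotype results carry no corrected P by default, mirroring how such tables
are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort_io import CountFixture, GenotypeRecord
from .contingency import AssociationResult, CarrierTable, associate, fisher_exact_two_sided, rank_sum_compare
from .nomenclature import AlleleCall, AlleleParseError, Locus, SerogroupMap, parse_allele

__all__ = [
    "GenotypeClass",
    "SubgroupComparison",
    "carrier_scan",
    "genotype_scan",
    "subgroup_compare",
]


@dataclass(frozen=True)
class GenotypeClass:
    """An unordered pair of slots, each an allele, a serogroup label, or
    the token ``"not"`` (meaning: any allele other than the first slot's).

    A sample matches an allele pair iff its two alleles are exactly that
    multiset; a serogroup pair iff its alleles fall one in each group; and
    ``X/not`` iff it carries exactly one copy of X.
    """

    first: AlleleCall | str
    second: AlleleCall | str

    @property
    def label(self) -> str:
        def render(slot: AlleleCall | str) -> str:
            return str(slot)

        return f"{render(self.first)}/{render(self.second)}"

    @classmethod
    def parse(cls, label: str, serogroups: SerogroupMap | None = None) -> "GenotypeClass":
        parts = label.split("/")
        if len(parts) != 2:
            raise ValueError(f"genotype class {label!r}: expected 'X/Y' or 'X/not'")
        smap = serogroups

        def parse_slot(token: str) -> AlleleCall | str:
            token = token.strip()
            if token == "not":
                return "not"
            try:
                return parse_allele(token)
            except AlleleParseError:
                if smap is not None and token in smap:
                    return token
                if smap is None and token.startswith("DR"):
                    return token
                raise ValueError(
                    f"genotype class {label!r}: slot {token!r} is neither an "
                    "allele nor a known serogroup"
                ) from None

        first, second = parse_slot(parts[0]), parse_slot(parts[1])
        if first == "not":
            raise ValueError(f"genotype class {label!r}: 'not' must be the second slot")
        return cls(first, second)

    def matches(
        self,
        alleles: tuple[AlleleCall, AlleleCall],
        serogroups: SerogroupMap | None = None,
    ) -> bool:
        x, y = alleles
        if self.second == "not":
            target = self.first
            if not isinstance(target, AlleleCall):
                raise ValueError(f"{self.label}: 'X/not' requires an allele slot")
            return (x == target) != (y == target)

        def slot_matches(slot: AlleleCall | str, allele: AlleleCall) -> bool:
            if isinstance(slot, AlleleCall):
                return allele == slot
            if serogroups is None:
                raise ValueError(
                    f"{self.label}: serogroup slot {slot!r} needs a serogroup map"
                )
            return serogroups.serogroup_of(allele) == slot

        return (slot_matches(self.first, x) and slot_matches(self.second, y)) or (
            slot_matches(self.first, y) and slot_matches(self.second, x)
        )


def _split_records(records: Sequence[GenotypeRecord]):
    cases = [r for r in records if r.is_case]
    controls = [r for r in records if not r.is_case]
    if not cases or not controls:
        raise ValueError("cohort must contain both cases and controls")
    return cases, controls


def _observed_alleles(records: Sequence[GenotypeRecord], locus: Locus) -> list[AlleleCall]:
    seen = {a for r in records for a in r.alleles(locus)}
    return sorted(seen)


def carrier_scan(
    records: Sequence[GenotypeRecord] | None = None,
    fixtures: Sequence[CountFixture] | None = None,
    locus: Locus = Locus.DRB1,
    units: Sequence[AlleleCall | str] | None = None,
    serogroups: SerogroupMap | None = None,
    m: int | None = None,
    level: float = 0.95,
) -> list[AssociationResult]:
    """Per-unit carrier association under the dominant model.

    Units may be alleles or serogroup labels.  With per-sample ``records``,
    carrier counts are tallied directly (homozygotes once); with pre-
    aggregated ``fixtures``, the given counts are used as-is.  ``m`` defaults
    to the number of distinct alleles at the locus (allele rows for fixture
    input); serogroup units carry no corrected P.
    """
    if (records is None) == (fixtures is None):
        raise ValueError("provide exactly one of records= or fixtures=")

    results: list[AssociationResult] = []
    if records is not None:
        cases, controls = _split_records(records)
        observed = _observed_alleles(records, locus)
        if units is None:
            units = list(observed)
        if m is None:
            m = max(1, len(observed))
        for unit in units:
            if isinstance(unit, AlleleCall):
                if unit.locus is not locus:
                    raise ValueError(f"unit {unit} is not at locus {locus.value}")
                a = sum(r.carries(unit) for r in cases)
                c = sum(r.carries(unit) for r in controls)
                unit_m: int | None = m
                label = str(unit)
            else:
                if serogroups is None:
                    raise ValueError(f"serogroup unit {unit!r} needs a serogroup map")
                members = serogroups.members(unit)
                a = sum(any(al in members for al in r.alleles(locus)) for r in cases)
                c = sum(any(al in members for al in r.alleles(locus)) for r in controls)
                unit_m = None
                label = unit
            results.append(
                associate(label, a, len(cases), c, len(controls), m=unit_m, level=level)
            )
        return results

    # fixture mode
    assert fixtures is not None
    def unit_kind(label: str) -> str:
        try:
            allele = parse_allele(label)
            return "allele" if allele.locus is locus else "other"
        except AlleleParseError:
            return "serogroup"

    allele_rows = [f for f in fixtures if unit_kind(f.unit) == "allele"]
    if m is None:
        m = max(1, len(allele_rows))
    wanted = {str(u) for u in units} if units is not None else None
    for f in fixtures:
        if wanted is not None and f.unit not in wanted:
            continue
        kind = unit_kind(f.unit)
        results.append(
            associate(
                f.unit,
                f.case_carriers,
                f.case_total,
                f.control_carriers,
                f.control_total,
                m=m if kind == "allele" else None,
                level=level,
            )
        )
    return results


def genotype_scan(
    records: Sequence[GenotypeRecord] | None = None,
    fixtures: Sequence[CountFixture] | None = None,
    classes: Sequence[GenotypeClass | str] | None = None,
    locus: Locus = Locus.DRB1,
    serogroups: SerogroupMap | None = None,
    level: float = 0.95,
) -> list[AssociationResult]:
    """Genotype-class association: class members vs all others, per arm.

    No multiple-testing correction is applied (genotype tables are reported
    with uncorrected P only).
    """
    if (records is None) == (fixtures is None):
        raise ValueError("provide exactly one of records= or fixtures=")

    if fixtures is not None:
        return [
            associate(
                f.unit,
                f.case_carriers,
                f.case_total,
                f.control_carriers,
                f.control_total,
                level=level,
            )
            for f in fixtures
        ]

    assert records is not None
    if not classes:
        raise ValueError("genotype_scan over records requires classes")
    cases, controls = _split_records(records)
    parsed = [
        c if isinstance(c, GenotypeClass) else GenotypeClass.parse(c, serogroups)
        for c in classes
    ]
    results = []
    for cls in parsed:
        a = sum(cls.matches(r.alleles(locus), serogroups) for r in cases)
        c = sum(cls.matches(r.alleles(locus), serogroups) for r in controls)
        results.append(associate(cls.label, a, len(cases), c, len(controls), level=level))
    return results


@dataclass
class ArmSummary:
    """Phenotype summary for one stratum of cases."""

    n: int
    positive: int | None = None
    mean: float | None = None
    sd: float | None = None

    @property
    def percent(self) -> float | None:
        return 100.0 * self.positive / self.n if self.positive is not None and self.n else None


@dataclass
class SubgroupComparison:
    """Carriers vs non-carriers of an allele, among cases only."""

    stratifier: str
    phenotype: str
    test: str
    carriers: ArmSummary
    non_carriers: ArmSummary
    p: float


def subgroup_compare(
    records: Sequence[GenotypeRecord],
    stratifier: AlleleCall,
    phenotype: str,
) -> SubgroupComparison:
    """Compare a phenotype between case carriers and non-carriers.

    Boolean phenotypes are tested with the two-sided Fisher exact test on
    the non-missing 2x2; numeric phenotypes with the Mann-Whitney rank-sum
    test.  Percentages, means and SDs use non-missing denominators.
    """
    cases = [r for r in records if r.is_case]
    if not cases:
        raise ValueError("no cases in cohort")
    strata: dict[bool, list[object]] = {True: [], False: []}
    for r in cases:
        v = r.phenotypes.get(phenotype)
        if v is not None:
            strata[r.carries(stratifier)].append(v)
    if not strata[True] and not strata[False]:
        raise ValueError(f"phenotype {phenotype!r} is missing for every case")

    values = strata[True] + strata[False]
    is_boolean = all(isinstance(v, bool) for v in values)
    if is_boolean:
        a = sum(strata[True])
        b = len(strata[True]) - a
        c = sum(strata[False])
        d = len(strata[False]) - c
        if (a + b) == 0 or (c + d) == 0:
            raise ValueError(
                f"phenotype {phenotype!r}: one stratum has no non-missing values"
            )
        p = fisher_exact_two_sided(CarrierTable(a, b, c, d))
        carriers = ArmSummary(n=a + b, positive=a)
        non_carriers = ArmSummary(n=c + d, positive=c)
        test = "fisher_exact"
    else:
        x = np.asarray([float(v) for v in strata[True]], dtype=float)
        y = np.asarray([float(v) for v in strata[False]], dtype=float)
        p = rank_sum_compare(x, y)
        carriers = ArmSummary(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)) if x.size > 1 else 0.0)
        non_carriers = ArmSummary(n=y.size, mean=float(y.mean()), sd=float(y.std(ddof=1)) if y.size > 1 else 0.0)
        test = "rank_sum"
    return SubgroupComparison(
        stratifier=str(stratifier),
        phenotype=phenotype,
        test=test,
        carriers=carriers,
        non_carriers=non_carriers,
        p=p,
    )
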