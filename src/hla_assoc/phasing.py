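"""DRB1-DQB1 haplotype phasing by direct counting, plus haplotype/diplotype scans.

Because DRB1 and DQB1 sit close together and are in strong linkage
disequilibrium, two-locus phase can be resolved by direct counting rather
than probabilistic phasing: any sample homozygous at one or both loci has a
unique phasing.  Only doubly-heterozygous samples are ambiguous between two
candidate phasings; those are resolved by

1. catalog membership, when a catalog of permitted haplotypes is supplied
   and exactly one phasing consists of permitted haplotypes; else
2. iterative frequency assignment: haplotype counts are initialised from the
   unambiguous samples, each ambiguous sample is assigned to the phasing
   with the larger product of current haplotype frequencies, and the
   procedure is iterated to a fixed point (capped at 100 rounds).  Exact
   ties are flagged ambiguous and excluded from haplotype counts.

Ambiguity counts are always reported so the user can see how much the rule
mattered.  Excluded-ambiguous samples reduce the denominators of haplotype
and diplotype scans (but not of single-locus scans).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cohort_io import CountFixture, GenotypeRecord
from .contingency import AssociationResult, associate
from .nomenclature import AlleleCall, Locus, parse_allele

__all__ = [
    "Haplotype",
    "Diplotype",
    "PhasingResult",
    "phase_cohort",
    "haplotype_carrier_scan",
    "diplotype_scan",
]

_MAX_ROUNDS = 100


@dataclass(frozen=True, order=True)
class Haplotype:
    """An ordered DRB1-DQB1 allele pair on one chromosome."""

    drb1: AlleleCall
    dqb1: AlleleCall

    def __post_init__(self) -> None:
        if self.drb1.locus is not Locus.DRB1 or self.dqb1.locus is not Locus.DQB1:
            raise ValueError(
                f"haplotype must be DRB1 then DQB1, got {self.drb1}/{self.dqb1}"
            )

    @property
    def label(self) -> str:
        return f"{self.drb1}-{self.dqb1}"

    def __str__(self) -> str:
        return self.label

    @classmethod
    def parse(cls, text: str) -> "Haplotype":
        first, sep, second = text.partition("-D")
        if not sep:
            raise ValueError(f"haplotype {text!r}: expected '<drb1>-<dqb1>'")
        return cls(parse_allele(first, Locus.DRB1), parse_allele("D" + second, Locus.DQB1))


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of haplotypes (stored sorted)."""

    h1: Haplotype
    h2: Haplotype

    def __post_init__(self) -> None:
        a, b = sorted((self.h1, self.h2))
        object.__setattr__(self, "h1", a)
        object.__setattr__(self, "h2", b)

    @property
    def label(self) -> str:
        return f"{self.h1}/{self.h2}"

    def __str__(self) -> str:
        return self.label

    @property
    def is_homozygous(self) -> bool:
        return self.h1 == self.h2

    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return self.h1, self.h2

    def carries(self, hap: Haplotype) -> bool:
        return hap == self.h1 or hap == self.h2

    @classmethod
    def parse(cls, text: str) -> "Diplotype":
        first, sep, second = text.partition("/")
        if not sep:
            raise ValueError(f"diplotype {text!r}: expected '<hap>/<hap>'")
        return cls(Haplotype.parse(first), Haplotype.parse(second))


def _candidate_phasings(record: GenotypeRecord) -> list[Diplotype]:
    d1, d2 = record.drb1
    if record.dqb1 is None:
        raise ValueError(f"sample {record.sample_id!r} is not DQB1-typed")
    q1, q2 = record.dqb1
    direct = Diplotype(Haplotype(d1, q1), Haplotype(d2, q2))
    crossed = Diplotype(Haplotype(d1, q2), Haplotype(d2, q1))
    if direct == crossed or d1 == d2 or q1 == q2:
        return [direct]
    return [direct, crossed]


@dataclass
class PhasingResult:
    """Phase assignments for a cohort.

    ``assignments`` maps sample id to a :class:`Diplotype`, or ``None`` for
    samples left ambiguous (tied candidate phasings).  Frequencies are over
    assigned haplotypes only.
    """

    assignments: dict[str, Diplotype | None]
    statuses: dict[str, str]
    n_ambiguous: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_ambiguous = sum(d is None for d in self.assignments.values())

    @property
    def n_samples(self) -> int:
        return len(self.assignments)

    @property
    def n_phased(self) -> int:
        return self.n_samples - self.n_ambiguous

    def haplotype_counts(self) -> Counter[Haplotype]:
        counts: Counter[Haplotype] = Counter()
        for d in self.assignments.values():
            if d is not None:
                counts.update(d.haplotypes())
        return counts

    def haplotype_frequencies(self) -> dict[Haplotype, float]:
        counts = self.haplotype_counts()
        total = sum(counts.values())
        return {h: c / total for h, c in counts.items()} if total else {}

    def subset(self, status: str) -> "PhasingResult":
        keep = {s for s, st in self.statuses.items() if st == status}
        return PhasingResult(
            assignments={s: d for s, d in self.assignments.items() if s in keep},
            statuses={s: status for s in keep},
        )


def phase_cohort(
    records: Sequence[GenotypeRecord],
    catalog: Iterable[Haplotype] | None = None,
) -> PhasingResult:
    """Phase a two-locus cohort by direct counting.

    Raises ``ValueError`` listing the offending sample ids if any record
    lacks DQB1 typing.
    """
    untyped = [r.sample_id for r in records if r.dqb1 is None]
    if untyped:
        raise ValueError(f"samples not DQB1-typed: {untyped}")
    catalog_set = frozenset(catalog) if catalog is not None else None

    assignments: dict[str, Diplotype | None] = {}
    pending: list[tuple[GenotypeRecord, Diplotype, Diplotype]] = []
    counts: Counter[Haplotype] = Counter()

    for r in records:
        candidates = _candidate_phasings(r)
        if len(candidates) == 1:
            assignments[r.sample_id] = candidates[0]
            counts.update(candidates[0].haplotypes())
            continue
        direct, crossed = candidates
        if catalog_set is not None:
            in_cat = [
                all(h in catalog_set for h in d.haplotypes())
                for d in (direct, crossed)
            ]
            if in_cat[0] != in_cat[1]:
                chosen = direct if in_cat[0] else crossed
                assignments[r.sample_id] = chosen
                counts.update(chosen.haplotypes())
                continue
        pending.append((r, direct, crossed))

    # iterative frequency assignment for doubly-heterozygous leftovers
    current: dict[str, Diplotype | None] = {r.sample_id: None for r, _, _ in pending}
    for _ in range(_MAX_ROUNDS):
        pool = counts.copy()
        for d in current.values():
            if d is not None:
                pool.update(d.haplotypes())
        new: dict[str, Diplotype | None] = {}
        for r, direct, crossed in pending:
            # +0.5 smoothing: a phasing made of observed haplotypes beats one
            # requiring unseen recombinants; an exact tie stays ambiguous
            w_direct = (pool[direct.h1] + 0.5) * (pool[direct.h2] + 0.5)
            w_crossed = (pool[crossed.h1] + 0.5) * (pool[crossed.h2] + 0.5)
            if w_direct > w_crossed:
                new[r.sample_id] = direct
            elif w_crossed > w_direct:
                new[r.sample_id] = crossed
            else:
                new[r.sample_id] = None
        if new == current:
            break
        current = new

    assignments.update(current)
    # preserve input order
    ordered = {r.sample_id: assignments[r.sample_id] for r in records}
    return PhasingResult(
        assignments=ordered,
        statuses={r.sample_id: r.status for r in records},
    )


def _arm_counts(
    phasing: PhasingResult, predicate
) -> tuple[int, int]:
    carriers = 0
    total = 0
    for d in phasing.assignments.values():
        if d is None:
            continue
        total += 1
        if predicate(d):
            carriers += 1
    return carriers, total


def _resolve_arms(
    phasing: PhasingResult,
    controls: PhasingResult | None,
) -> tuple[PhasingResult, PhasingResult]:
    if controls is not None:
        return phasing, controls
    return phasing.subset("case"), phasing.subset("control")


def haplotype_carrier_scan(
    phasing: PhasingResult | None = None,
    controls: PhasingResult | None = None,
    fixtures: Sequence[CountFixture] | None = None,
    units: Sequence[Haplotype | str] | None = None,
    m: int | None = None,
    level: float = 0.95,
) -> list[AssociationResult]:
    """Per-haplotype carrier association (dominant model, phased samples only).

    ``phasing`` may hold both arms (statuses are used to split) or cases
    only with ``controls`` given separately; alternatively pre-aggregated
    ``fixtures`` provide the counts.  No corrected P is attached unless
    ``m`` is passed explicitly.
    """
    if (phasing is None) == (fixtures is None):
        raise ValueError("provide exactly one of phasing= or fixtures=")
    if fixtures is not None:
        wanted = {str(u) for u in units} if units is not None else None
        return [
            associate(
                f.unit, f.case_carriers, f.case_total,
                f.control_carriers, f.control_total, m=m, level=level,
            )
            for f in fixtures
            if wanted is None or f.unit in wanted
        ]

    assert phasing is not None
    case_ph, control_ph = _resolve_arms(phasing, controls)
    if units is None:
        seen = set(case_ph.haplotype_counts()) | set(control_ph.haplotype_counts())
        unit_haps = sorted(seen)
    else:
        unit_haps = [u if isinstance(u, Haplotype) else Haplotype.parse(u) for u in units]
    results = []
    for hap in unit_haps:
        a, n_case = _arm_counts(case_ph, lambda d: d.carries(hap))
        c, n_ctrl = _arm_counts(control_ph, lambda d: d.carries(hap))
        results.append(associate(hap.label, a, n_case, c, n_ctrl, m=m, level=level))
    return results


def diplotype_scan(
    phasing: PhasingResult | None = None,
    controls: PhasingResult | None = None,
    fixtures: Sequence[CountFixture] | None = None,
    classes: Sequence[Diplotype | str] | None = None,
    level: float = 0.95,
) -> list[AssociationResult]:
    """Diplotype-class association: class members vs all phased others.

    Classes are :class:`Diplotype` objects, ``"<hap>/<hap>"`` labels, or
    ``"<hap>/not"`` for single-copy carriers of a haplotype.  Zero-cell
    tables are handled by the usual conditional correction (structural zeros
    are common here).
    """
    if (phasing is None) == (fixtures is None):
        raise ValueError("provide exactly one of phasing= or fixtures=")
    if fixtures is not None:
        return [
            associate(
                f.unit, f.case_carriers, f.case_total,
                f.control_carriers, f.control_total, level=level,
            )
            for f in fixtures
        ]

    assert phasing is not None
    if not classes:
        raise ValueError("diplotype_scan over phasings requires classes")
    case_ph, control_ph = _resolve_arms(phasing, controls)
    results = []
    for cls in classes:
        if isinstance(cls, Diplotype):
            label = cls.label
            predicate = lambda d, target=cls: d == target
        else:
            first, _, second = str(cls).partition("/")
            if second == "not":
                hap = Haplotype.parse(first)
                label = f"{hap}/not"
                # single-copy carriers: exactly one chromosome bears hap
                predicate = lambda d, h=hap: (d.h1 == h) != (d.h2 == h)
            else:
                target = Diplotype.parse(str(cls))
                label = target.label
                predicate = lambda d, t=target: d == t
        a, n_case = _arm_counts(case_ph, predicate)
        c, n_ctrl = _arm_counts(control_ph, predicate)
        results.append(associate(label, a, n_case, c, n_ctrl, level=level))
    return results
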