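"""Cohort data model and TSV input/output.

Two kinds of inputs are supported:

* per-sample genotype tables (``genotypes.tsv``): one row per individual with
  case/control status, two DRB1 alleles, optionally two DQB1 alleles, and
  free phenotype columns;
* pre-aggregated count tables (``counts.tsv``): one row per tested unit with
  carrier counts and arm totals, e.g. transcriptions of published tables.

All files are UTF-8 TSV with a header row; lines starting with ``#`` are
comments (outputs carry a ``#`` provenance line).  Phenotype missingness is
explicit: empty fields become ``None``/NaN and every downstream percentage is
computed over non-missing denominators (pairwise deletion).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .nomenclature import AlleleCall, AlleleParseError, Locus, parse_allele

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeRecord",
    "CountFixture",
    "CohortIOError",
    "read_genotypes",
    "write_genotypes",
    "read_count_fixture",
    "write_count_fixture",
    "bundled_fixture_path",
    "provenance_line",
]

GENOTYPE_COLUMNS = ["sample_id", "status", "DRB1_1", "DRB1_2", "DQB1_1", "DQB1_2"]
STATUS_TOKENS = {"case", "control"}

#: phenotype columns recognised as boolean (others are parsed as numeric
#: when possible and kept as strings otherwise)
BOOLEAN_PHENOTYPES = {"ana", "asma", "cirrhosis", "definite_aih", "male"}


class CohortIOError(ValueError):
    """Raised on malformed cohort or count files."""


@dataclass
class GenotypeRecord:
    """One genotyped individual.

    ``drb1``/``dqb1`` are unordered allele pairs (stored sorted);
    ``phenotypes`` maps free column names to values, with ``None`` for
    missing entries.
    """

    sample_id: str
    status: str
    drb1: tuple[AlleleCall, AlleleCall]
    dqb1: tuple[AlleleCall, AlleleCall] | None = None
    phenotypes: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in STATUS_TOKENS:
            raise CohortIOError(
                f"sample {self.sample_id!r}: unknown status {self.status!r} "
                f"(expected one of {sorted(STATUS_TOKENS)})"
            )
        self.drb1 = _validated_pair(self.sample_id, self.drb1, Locus.DRB1)
        if self.dqb1 is not None:
            self.dqb1 = _validated_pair(self.sample_id, self.dqb1, Locus.DQB1)

    @property
    def is_case(self) -> bool:
        return self.status == "case"

    def alleles(self, locus: Locus) -> tuple[AlleleCall, AlleleCall]:
        if locus is Locus.DRB1:
            return self.drb1
        if locus is Locus.DQB1:
            if self.dqb1 is None:
                raise CohortIOError(f"sample {self.sample_id!r} is not DQB1-typed")
            return self.dqb1
        raise CohortIOError(f"no genotype stored at locus {locus.value}")

    def carries(self, allele: AlleleCall) -> bool:
        """Dominant-model carriage: at least one copy at the allele's locus."""
        return allele in self.alleles(allele.locus)


def _validated_pair(
    sample_id: str,
    pair: Sequence[AlleleCall],
    locus: Locus,
) -> tuple[AlleleCall, AlleleCall]:
    if len(pair) != 2:
        raise CohortIOError(f"sample {sample_id!r}: expected two {locus.value} alleles")
    a, b = pair
    if a.locus is not locus or b.locus is not locus:
        raise CohortIOError(
            f"sample {sample_id!r}: alleles {a}, {b} are not both at {locus.value}"
        )
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class CountFixture:
    """Carrier/member counts for one unit, pre-aggregated per arm."""

    unit: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        for carriers, total, arm in (
            (self.case_carriers, self.case_total, "case"),
            (self.control_carriers, self.control_total, "control"),
        ):
            if not 0 <= carriers <= total:
                raise CohortIOError(
                    f"unit {self.unit!r}: {arm} carriers {carriers} exceed "
                    f"total {total}"
                )

    @property
    def case_frequency(self) -> float:
        return 100.0 * self.case_carriers / self.case_total

    @property
    def control_frequency(self) -> float:
        return 100.0 * self.control_carriers / self.control_total


def _parse_phenotype(column: str, raw: object) -> object:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    text = str(raw).strip()
    if column in BOOLEAN_PHENOTYPES:
        low = text.lower()
        if low in {"1", "true", "yes", "pos"}:
            return True
        if low in {"0", "false", "no", "neg"}:
            return False
        raise CohortIOError(f"column {column!r}: cannot read {text!r} as boolean")
    try:
        return float(text)
    except ValueError:
        return text


def read_genotypes(path: str | Path) -> list[GenotypeRecord]:
    """Read a per-sample genotype TSV into :class:`GenotypeRecord` objects.

    DQB1 columns are optional; any column beyond the fixed six is treated as
    a phenotype.  Malformed rows raise :class:`CohortIOError` naming the row;
    duplicated sample ids are an error.  A per-file summary (arm sizes and
    per-column missingness) is logged at INFO.
    """
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "status", "DRB1_1", "DRB1_2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing required columns {missing}")
    has_dqb1 = "DQB1_1" in df.columns and "DQB1_2" in df.columns
    phenotype_cols = [c for c in df.columns if c not in GENOTYPE_COLUMNS]

    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        sid = row["sample_id"]
        if pd.isna(sid) or not str(sid).strip():
            raise CohortIOError(f"{path} row {rowno}: empty sample_id")
        sid = str(sid).strip()
        if sid in seen:
            raise CohortIOError(f"{path} row {rowno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            drb1 = (
                parse_allele(row["DRB1_1"], Locus.DRB1),
                parse_allele(row["DRB1_2"], Locus.DRB1),
            )
            dqb1 = None
            if has_dqb1 and not (pd.isna(row["DQB1_1"]) or pd.isna(row["DQB1_2"])):
                dqb1 = (
                    parse_allele(row["DQB1_1"], Locus.DQB1),
                    parse_allele(row["DQB1_2"], Locus.DQB1),
                )
            phenotypes = {
                c: _parse_phenotype(c, row[c]) for c in phenotype_cols
            }
            records.append(
                GenotypeRecord(
                    sample_id=sid,
                    status=str(row["status"]).strip() if pd.notna(row["status"]) else "",
                    drb1=drb1,
                    dqb1=dqb1,
                    phenotypes=phenotypes,
                )
            )
        except (AlleleParseError, CohortIOError, TypeError) as exc:
            raise CohortIOError(f"{path} row {rowno}: {exc}") from exc

    n_cases = sum(r.is_case for r in records)
    logger.info(
        "%s: %d records (%d cases, %d controls)",
        path.name, len(records), n_cases, len(records) - n_cases,
    )
    for col in phenotype_cols:
        n_missing = sum(r.phenotypes.get(col) is None for r in records)
        if n_missing:
            logger.info("%s: column %s missing in %d rows", path.name, col, n_missing)
    return records


def write_genotypes(
    records: Iterable[GenotypeRecord],
    path: str | Path,
    provenance: str | None = None,
) -> None:
    """Write records back to the canonical TSV dialect (round-trip stable)."""
    records = list(records)
    phenotype_cols: list[str] = []
    for r in records:
        for c in r.phenotypes:
            if c not in phenotype_cols:
                phenotype_cols.append(c)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "status": r.status,
            "DRB1_1": str(r.drb1[0]),
            "DRB1_2": str(r.drb1[1]),
            "DQB1_1": str(r.dqb1[0]) if r.dqb1 else "",
            "DQB1_2": str(r.dqb1[1]) if r.dqb1 else "",
        }
        for c in phenotype_cols:
            v = r.phenotypes.get(c)
            if v is None:
                row[c] = ""
            elif isinstance(v, bool):
                row[c] = int(v)
            elif isinstance(v, float) and v == int(v):
                row[c] = int(v)
            else:
                row[c] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS + phenotype_cols)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_count_fixture(path: str | Path) -> list[CountFixture]:
    """Read a pre-aggregated count TSV into :class:`CountFixture` rows.

    Required columns: ``unit``, ``case_carriers``, ``case_total``,
    ``control_carriers``, ``control_total``.  Extra columns (for instance
    published reference statistics) are ignored here and may be read
    separately with pandas.
    """
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"count fixture not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["unit", "case_carriers", "case_total", "control_carriers", "control_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing required columns {missing}")
    fixtures = []
    for i, row in df.iterrows():
        try:
            fixtures.append(
                CountFixture(
                    unit=str(row["unit"]),
                    case_carriers=int(row["case_carriers"]),
                    case_total=int(row["case_total"]),
                    control_carriers=int(row["control_carriers"]),
                    control_total=int(row["control_total"]),
                )
            )
        except (CohortIOError, ValueError) as exc:
            raise CohortIOError(f"{path} row {i + 2}: {exc}") from exc
    return fixtures


def write_count_fixture(
    fixtures: Iterable[CountFixture],
    path: str | Path,
    provenance: str | None = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "unit": f.unit,
                "case_carriers": f.case_carriers,
                "case_total": f.case_total,
                "control_carriers": f.control_carriers,
                "control_total": f.control_total,
            }
            for f in fixtures
        ]
    )
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def bundled_fixture_path(name: str) -> Path:
    """Path to one of the packaged data files (e.g. ``table2_drb1_carriers.tsv``)."""
    from importlib import resources

    return Path(str(resources.files("hla_assoc").joinpath("data", name)))


def provenance_line(tool_version: str, inputs: Sequence[Path | str], seed: int | None = None) -> str:
    """``tool=... input=<name>:<sha256-12> seed=...`` header for outputs."""
    parts = [f"hla-assoc {tool_version}"]
    for p in inputs:
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:12] if p.exists() else "absent"
        parts.append(f"input={p.name}:{digest}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)
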