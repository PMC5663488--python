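"""Synthetic two-locus case-control cohorts.

The generator emulates exactly the statistical structure the analysis
assumes: diplotypes are two independent draws from a haplotype frequency
vector (Hardy-Weinberg equilibrium), linkage disequilibrium between DRB1 and
DQB1 arises structurally because haplotypes are the sampling unit, and
disease status follows a Bernoulli draw whose odds are a baseline times the
product of multipliers for every carried unit (allele, serogroup pair,
genotype class, haplotype, or diplotype).  Case/control labels are drawn per
individual and rejection sampling continues until both arm sizes are met, so
the case arm is distributed as genotypes-given-disease.

Phenotype fields are generated with carrier-dependent shifts (immunoglobulin
G mean shift, anti-smooth-muscle antibody probability uplift, and friends)
as smoke-test settings; no distributional fidelity beyond mean/SD and rates
is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import GenotypeClass
from .cohort_io import CountFixture, GenotypeRecord
from .contingency import CarrierTable, odds_ratio
from .nomenclature import AlleleCall, AlleleParseError, Locus, SerogroupMap, parse_allele
from .phasing import Diplotype, Haplotype

__all__ = [
    "PhenotypeEffects",
    "SyntheticCohortConfig",
    "sample_cohort",
    "default_config",
    "default_config_from_fixture",
]

_FREQ_TOL = 1e-9
_BATCH = 4096
#: give up if this many times the requested cohort has been drawn without
#: filling both arms (signals an unreachable arm, e.g. probability ~0)
_MAX_DRAW_FACTOR = 2000


@dataclass(frozen=True)
class PhenotypeEffects:
    """Carrier-dependent phenotype generator settings.

    Defaults mimic the contrasts seen between DRB1*04:05 carriers and
    non-carriers in the reference cohort (IgG shift about +470 mg/dl, ASMA
    positivity 55% vs 19%), applied to carriers of ``flag_allele``.
    """

    flag_allele: str = "DRB1*04:05"
    male_rate: float = 0.119
    onset_mean: float = 59.1
    onset_sd: float = 13.5
    ana_rate: float = 0.872
    igg_mean: float = 2119.8
    igg_sd: float = 840.8
    igg_shift: float = 467.3
    asma_rate: float = 0.191
    asma_rate_carrier: float = 0.552
    iaihg_mean: float = 15.6
    iaihg_sd: float = 2.9
    iaihg_shift: float = 1.3
    definite_rate: float = 0.537
    definite_rate_carrier: float = 0.719


@dataclass
class SyntheticCohortConfig:
    """Everything needed to draw a reproducible synthetic cohort.

    ``odds`` maps unit labels to odds multipliers; labels may be alleles
    (``DRB1*04:05``), genotype classes (``DR4/DR8``), haplotypes
    (``DRB1*04:05-DQB1*04:01``), or diplotypes (``.../...``).
    """

    haplotypes: tuple[Haplotype, ...]
    frequencies: tuple[float, ...]
    odds: dict[str, float] = field(default_factory=dict)
    baseline_odds: float = 0.05
    n_cases: int = 360
    n_controls: int = 413
    phenotypes: PhenotypeEffects | None = field(default_factory=PhenotypeEffects)
    serogroups: SerogroupMap | None = None

    def __post_init__(self) -> None:
        self.haplotypes = tuple(self.haplotypes)
        self.frequencies = tuple(float(f) for f in self.frequencies)
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if any(not 0.0 < f <= 1.0 for f in self.frequencies):
            raise ValueError("haplotype frequencies must lie in (0, 1]")
        if abs(sum(self.frequencies) - 1.0) > _FREQ_TOL:
            raise ValueError(
                f"haplotype frequencies sum to {sum(self.frequencies)!r}, not 1"
            )
        if any(v <= 0 for v in self.odds.values()):
            raise ValueError("odds multipliers must be positive")
        if self.baseline_odds <= 0:
            raise ValueError("baseline odds must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("arm sizes must be >= 1")


def _match_matrix(config: SyntheticCohortConfig, key: str) -> np.ndarray:
    """Boolean K x K matrix: does diplotype (h_i, h_j) carry/match ``key``."""
    haps = config.haplotypes
    K = len(haps)
    M = np.zeros((K, K), dtype=bool)

    if "/" in key:  # diplotype or genotype class
        if "-" in key:
            first, _, second = key.partition("/")
            hap = Haplotype.parse(first)
            if second == "not":
                for i in range(K):
                    for j in range(K):
                        M[i, j] = (haps[i] == hap) != (haps[j] == hap)
            else:
                target = Diplotype.parse(key)
                for i in range(K):
                    for j in range(K):
                        M[i, j] = Diplotype(haps[i], haps[j]) == target
        else:
            cls = GenotypeClass.parse(key, config.serogroups)
            for i in range(K):
                for j in range(K):
                    M[i, j] = cls.matches((haps[i].drb1, haps[j].drb1), config.serogroups)
        return M

    if "-" in key:  # haplotype carrier
        hap = Haplotype.parse(key)
        carrier = np.array([h == hap for h in haps])
        return carrier[:, None] | carrier[None, :]

    try:  # allele carrier
        allele = parse_allele(key)
        if allele.locus is Locus.DRB1:
            carrier = np.array([h.drb1 == allele for h in haps])
        elif allele.locus is Locus.DQB1:
            carrier = np.array([h.dqb1 == allele for h in haps])
        else:
            raise ValueError(f"odds key {key!r}: DQA1 units are not simulated")
        return carrier[:, None] | carrier[None, :]
    except AlleleParseError:
        raise ValueError(f"odds key {key!r} is not a recognisable unit") from None


def _phenotypes_for(
    rng: np.random.Generator,
    eff: PhenotypeEffects,
    carrier: bool,
) -> dict[str, object]:
    asma_p = eff.asma_rate_carrier if carrier else eff.asma_rate
    definite_p = eff.definite_rate_carrier if carrier else eff.definite_rate
    igg_mu = eff.igg_mean + (eff.igg_shift if carrier else 0.0)
    iaihg_mu = eff.iaihg_mean + (eff.iaihg_shift if carrier else 0.0)
    return {
        "male": bool(rng.random() < eff.male_rate),
        "age_onset": round(float(np.clip(rng.normal(eff.onset_mean, eff.onset_sd), 1, 95)), 1),
        "ana": bool(rng.random() < eff.ana_rate),
        "asma": bool(rng.random() < asma_p),
        "igg": round(float(max(rng.normal(igg_mu, eff.igg_sd), 100.0)), 1),
        "iaihg_score": round(float(np.clip(rng.normal(iaihg_mu, eff.iaihg_sd), 0, 25)), 1),
        "definite_aih": bool(rng.random() < definite_p),
    }


def sample_cohort(
    config: SyntheticCohortConfig,
    seed: int,
    return_truth: bool = False,
) -> list[GenotypeRecord] | tuple[list[GenotypeRecord], list[Diplotype]]:
    """Draw a cohort under HWE with genotype-dependent disease odds.

    Fully reproducible given ``(config, seed)``.  Raises ``ValueError`` when
    an arm is unreachable (its label probability is ~0 under the disease
    model).  With ``return_truth=True``, the simulated diplotypes are
    returned alongside the (unphased) records, in record order.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(config.frequencies)
    K = len(config.haplotypes)

    unit_matrices = [
        (_match_matrix(config, key), mult) for key, mult in config.odds.items()
    ]
    flag_matrix = None
    if config.phenotypes is not None:
        flag_matrix = _match_matrix(config, config.phenotypes.flag_allele)

    cases: list[tuple[int, int, bool]] = []
    controls: list[tuple[int, int, bool]] = []
    drawn = 0
    budget = _MAX_DRAW_FACTOR * (config.n_cases + config.n_controls)
    while len(cases) < config.n_cases or len(controls) < config.n_controls:
        if drawn > budget:
            raise ValueError(
                "could not fill both arms: an arm has near-zero probability "
                "under the configured disease model"
            )
        idx = rng.choice(K, size=(_BATCH, 2), p=freqs)
        odds = np.full(_BATCH, config.baseline_odds)
        for M, mult in unit_matrices:
            odds = np.where(M[idx[:, 0], idx[:, 1]], odds * mult, odds)
        p_case = odds / (1.0 + odds)
        is_case = rng.random(_BATCH) < p_case
        flagged = (
            flag_matrix[idx[:, 0], idx[:, 1]]
            if flag_matrix is not None
            else np.zeros(_BATCH, dtype=bool)
        )
        drawn += _BATCH
        for k in range(_BATCH):
            bucket = cases if is_case[k] else controls
            want = config.n_cases if is_case[k] else config.n_controls
            if len(bucket) < want:
                bucket.append((int(idx[k, 0]), int(idx[k, 1]), bool(flagged[k])))

    records: list[GenotypeRecord] = []
    truth: list[Diplotype] = []
    for arm, status in ((cases, "case"), (controls, "control")):
        for n, (i, j, flag) in enumerate(arm, start=1):
            h1, h2 = config.haplotypes[i], config.haplotypes[j]
            phen = (
                _phenotypes_for(rng, config.phenotypes, flag)
                if config.phenotypes is not None
                else {}
            )
            records.append(
                GenotypeRecord(
                    sample_id=f"{status}_{n:05d}",
                    status=status,
                    drb1=(h1.drb1, h2.drb1),
                    dqb1=(h1.dqb1, h2.dqb1),
                    phenotypes=phen,
                )
            )
            truth.append(Diplotype(h1, h2))
    return (records, truth) if return_truth else records


def default_config_from_fixture(
    fixtures: Sequence[CountFixture],
    n_cases: int = 360,
    n_controls: int = 413,
    baseline_odds: float = 0.05,
    residual: Haplotype | None = None,
) -> SyntheticCohortConfig:
    """Back-solve a config from haplotype carrier-count rows.

    Control haplotype frequencies come from the HWE inversion of the control
    carrier frequency, ``f = 1 - sqrt(1 - carrier)``; the remainder of the
    probability mass goes to a pooled residual pseudo-haplotype.  Odds
    multipliers are the carrier odds ratios recomputed from the counts.
    """
    haps: list[Haplotype] = []
    freqs: list[float] = []
    odds: dict[str, float] = {}
    for f in fixtures:
        try:
            hap = Haplotype.parse(f.unit)
        except (ValueError, AlleleParseError):
            continue  # skip diplotype/other rows
        carrier = f.control_carriers / f.control_total
        if carrier >= 1.0:
            raise ValueError(f"{f.unit}: control carrier frequency must be < 1")
        freq = 1.0 - math.sqrt(1.0 - carrier)
        if freq == 0.0:
            continue
        haps.append(hap)
        freqs.append(freq)
        table = CarrierTable(
            f.case_carriers,
            f.case_total - f.case_carriers,
            f.control_carriers,
            f.control_total - f.control_carriers,
        )
        odds[hap.label] = odds_ratio(table)
    mass = sum(freqs)
    if mass >= 1.0:
        raise ValueError(f"back-solved frequencies sum to {mass:.4f} >= 1")
    residual = residual or Haplotype(
        parse_allele("DRB1*99:99"), parse_allele("DQB1*99:99")
    )
    haps.append(residual)
    freqs.append(1.0 - mass)
    return SyntheticCohortConfig(
        haplotypes=tuple(haps),
        frequencies=tuple(freqs),
        odds=odds,
        baseline_odds=baseline_odds,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def default_config(n_cases: int = 360, n_controls: int = 413) -> SyntheticCohortConfig:
    """Config back-solved from the bundled haplotype count table."""
    from .cohort_io import bundled_fixture_path, read_count_fixture

    fixtures = read_count_fixture(bundled_fixture_path("table5_haplotypes.tsv"))
    return default_config_from_fixture(fixtures, n_cases=n_cases, n_controls=n_controls)
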