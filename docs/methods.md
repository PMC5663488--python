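# Methods

## Scope and model

`hla-assoc` implements a case–control association analysis for HLA class II
genotyping data at two-field resolution. The disease model throughout is the
dominant (carrier) model: an individual is a carrier of an allele,
serogroup, haplotype, or amino-acid residue if at least one of their two
chromosomes bears it, and homozygotes count once. Every association is a
2×2 table of carriers/non-carriers × cases/controls; dosage is visible only
in the genotype and diplotype scans, where classes such as homozygote
(`X/X`), single-copy carrier (`X/not`), or serogroup crossings (`DR4/DR8`)
are tested as class-members versus everyone else.

## The statistics stack

All scans share one inference stack, chosen so that the package exactly
reproduces the published tables it ships as regression fixtures:

* **Odds ratio.** The cross-product `ad/bc`. If any cell is zero, the
  Haldane–Anscombe correction adds 0.5 to *all four* cells first. The
  correction is conditional — applied only in the presence of a zero —
  because the reference tables are only consistent with that policy: the
  DRB1\*04:05 carrier table (185, 175, 243, 783) prints OR 3.41
  (uncorrected; correcting would give 3.40), while the zero-cell
  DRB1\*14:02 table (1, 359, 0, 1026) prints 8.57 (corrected).
* **Confidence interval.** Woolf's log-normal interval,
  `exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d))`, on the corrected cells
  whenever the correction fired, so the interval always brackets the
  reported OR. The critical value is the conventional two-decimal normal
  quantile (1.96 at 95%), not `norm.ppf(0.975) = 1.959964`: the two differ
  in the last printed digit of very wide intervals (e.g. upper bounds
  210.76 vs 210.75), and only the two-decimal value reproduces all 62
  reference intervals.
* **P value.** Two-sided Fisher exact P under the point-probability rule:
  the sum of hypergeometric probabilities, over all tables with the
  observed margins, that do not exceed the observed table's point
  probability (relative tie tolerance 1e-7). Computed on
  `scipy.stats.hypergeom` over the full support; the test suite checks it
  exhaustively against an independent exact-rational enumeration for every
  margin configuration with total ≤ 30.
* **Multiple testing.** Bonferroni: `Pc = min(1, m·P)` where `m` is the
  number of alleles (or residue units) tested — by default the count of
  distinct alleles observed at the locus in the combined cohort. A unit is
  flagged NS when `m·P ≥ 1`, i.e. when the correction hits the cap; that is
  the convention the reference tables follow (a unit with uncorrected
  P = 0.035 and m = 30 prints NS, while P = 0.0298 prints Pc = 0.8949).
  Serogroup, genotype, and haplotype rows carry no corrected P by default,
  mirroring how such tables are reported.
* **Continuous phenotypes.** Two-sided Mann–Whitney U via
  `scipy.stats.mannwhitneyu`: exact when both samples have ≤ 25
  observations and no ties, otherwise the tie-corrected normal
  approximation with continuity correction. Phenotype missingness is
  handled by pairwise deletion — every percentage, mean, and test uses
  non-missing denominators only.

## Haplotype phasing by direct counting

DRB1 and DQB1 are in strong linkage disequilibrium, so two-locus phase is
resolved by direct counting rather than full EM. Samples homozygous at one
or both loci phase uniquely. A doubly-heterozygous sample has exactly two
candidate phasings and is resolved by:

1. **Catalog membership**, when a catalog of permitted haplotypes is given
   and exactly one phasing consists entirely of permitted haplotypes;
2. **Iterative frequency assignment** otherwise: haplotype counts are
   initialised from the unambiguous samples, each ambiguous sample is
   assigned to the phasing with the larger product of pooled counts, and
   the procedure iterates to a fixed point (capped at 100 rounds, reached
   within 2–3 in practice). Counts enter the product with +0.5 smoothing,
   so a phasing composed of observed haplotypes beats one requiring unseen
   recombinants; an exact tie leaves the sample flagged ambiguous.

Ambiguous samples are excluded from haplotype counts and from the
denominators of haplotype and diplotype scans (but not from single-locus
scans); the ambiguity count is always reported. Under strong LD (each DRB1
allele tied to one dominant DQB1 partner at ≥ 95%) the simulation tests
recover the true phase for > 99% of samples at n = 1000.

## Residue scans

Alleles translate to residues at polymorphic positions of the mature
β-chain (position 1 = first residue after the signal peptide) through an
explicit lookup table — no sequence inference. A sample carries residue r
at position p iff one of its alleles encodes it, so when a residue is
unique to one allele the residue-level result is identical,
field-for-field, to that allele's result; this equivalence is asserted as a
property test and is the mechanism by which a residue scan localises an
allele association. Scanning from pre-aggregated allele counts (rather than
per-sample records) approximates a residue's carrier count by the capped
sum of its encoding alleles' carrier counts — an upper bound, since
co-carriage is not recoverable from margins; exact counting requires
per-sample input.

The bundled DRβ residue table is deliberately partial: the 70–74
shared-epitope motifs for the eight classical shared-epitope alleles
(QKRAA/QRRAA/RRRAA), DERAA for DRB1\*13:01/\*13:02, and positions
11/13/33/57/96 for DRB1\*04:05. It is a convenience default for
demonstrations; scans for publication should use a table derived from a
current IMGT/HLA protein alignment. No test depends on the biological
correctness of the bundled curation — synthetic tables drive all
assertions.

## DQ heterodimer enumeration

Each DRB1-DQB1 haplotype implies, through the conserved haplotype structure
of the study population, a DQA1 allele (supplied as data; the bundled map
contains exactly three entries: 04:05-04:01 → DQA1\*03:03, 08:02-03:02 →
DQA1\*03:01, 08:03-06:01 → DQA1\*01:03, and nothing inferred beyond them).
A diplotype then encodes four DQ α-β molecules: cis pairs (α₁β₁, α₂β₂) and
trans pairs (α₁β₂, α₂β₁). The cis and trans sets always conserve the DQA1
and DQB1 allele multisets, and a homozygous diplotype gives identical cis
and trans sets — both are property-tested over random inputs. Stability of
a molecule is a free-text annotation from an optional user lookup; the
package never computes it.

## Synthetic cohorts

The generator emulates exactly what the analysis assumes, nothing more:

* **HWE with structural LD**: a diplotype is two independent draws from a
  haplotype frequency vector, so within-locus Hardy–Weinberg proportions
  hold and DRB1–DQB1 LD arises because haplotypes are the sampling unit.
* **Multiplicative disease odds**: an individual's disease odds are a
  baseline times the product of multipliers for each carried unit (allele,
  serogroup class, haplotype, or diplotype — a multiplier applies once,
  dominant-style). This is the simplest model consistent with OR-only
  reporting, and it makes a single unit's configured multiplier equal its
  population carrier OR, which the recovery tests exploit. It is a
  simulation assumption, not a claim about disease biology.
* **Rejection sampling**: individuals are drawn and labelled by a Bernoulli
  draw on `odds/(1+odds)` until both arm sizes are met, so the case arm is
  distributed as genotype-given-disease. An arm whose probability is ~0
  raises an error after a bounded number of draws.
* **Phenotypes**: carrier-dependent shifts mimicking the reference cohort's
  contrasts (IgG +467 mg/dl and ASMA 55% vs 19% in carriers of the flagged
  allele, defaults editable via `PhenotypeEffects`); only means/SDs and
  rates are emulated, not distribution shapes.

`default_config()` back-solves a realistic catalog from the bundled
haplotype table: control haplotype frequencies by HWE inversion of control
carrier frequencies (`f = 1 − sqrt(1 − carrier)`, e.g. 19.1% carriers →
f ≈ 0.101), odds multipliers from the recomputed carrier ORs, and a pooled
residual pseudo-haplotype (`DRB1*99:99-DQB1*99:99`) absorbing the remaining
mass. Cohorts are byte-reproducible given (config, seed).

What the generator does **not** emulate — genotyping error, population
substructure, allele frequencies outside the bundled catalog, realistic
phenotype distributions — bounds what the passing tests show: they validate
the inference machinery under its own assumptions, not robustness to
real-data artefacts.

## Numerical and design choices

* Fisher P values snap to exactly 1.0 when the tie rule includes the whole
  support, avoiding floating-point sums of 0.9999999999.
* Allele names with more than two fields are truncated to two (with a
  logged note); the analysis is defined at two-field resolution.
* The sampling unit for the problem sizes used in tests and the acceptance
  script (cohorts of 360/413 to 500/500, 5–200 replicates per property)
  was chosen to give each Monte-Carlo check ≥ 3-standard-error headroom at
  its threshold while keeping the default suite fast.
* Serogroup maps, shared-epitope sets, residue tables, and the DQA1 linkage
  map are all editable TSV data, so catalogs for other populations can be
  substituted without code changes.

## Known limitations

* Phase ambiguity is resolved deterministically, with no uncertainty
  propagation into downstream P values (out of scope by design; the
  ambiguity count is reported so users can judge exposure).
* No covariate adjustment, trend tests, or permutation-based family-wise
  correction — the inference surface is deliberately the exact 2×2 stack.
* The `m·P ≥ 1 → NS` reporting rule and the two-decimal z convention are
  choices made to match the published tables this package regresses
  against; both are documented above so divergent conventions elsewhere are
  diagnosable.
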