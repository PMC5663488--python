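"""Allele/serogroup carrier scans, genotype classes, subgroup comparisons."""

import numpy as np
import pytest

from hla_assoc import (
    CountFixture,
    GenotypeClass,
    Locus,
    SerogroupMap,
    carrier_scan,
    genotype_scan,
    parse_allele,
    subgroup_compare,
)
from hla_assoc.cohort_io import bundled_fixture_path, read_count_fixture
from hla_assoc.simulate import PhenotypeEffects, SyntheticCohortConfig, sample_cohort
from hla_assoc.phasing import Haplotype
from conftest import make_record, printed_equal


@pytest.fixture(scope="module")
def table2_results():
    fixtures = read_count_fixture(bundled_fixture_path("table2_drb1_carriers.tsv"))
    return {r.unit: r for r in carrier_scan(fixtures=fixtures, locus=Locus.DRB1)}


class TestCarrierScan:
    def test_hand_counted_cohort(self, toy_cohort):
        results = {r.unit: r for r in carrier_scan(records=toy_cohort)}
        r = results["DRB1*04:05"]
        # homozygote counted once under the dominant model
        assert (r.table.a, r.table.c) == (2, 1)
        assert (r.table.case_total, r.table.control_total) == (3, 3)
        assert results["DRB1*08:03"].table.a == 1

    def test_default_m_is_observed_allele_count(self, toy_cohort):
        results = carrier_scan(records=toy_cohort)
        # 5 distinct DRB1 alleles in the toy cohort
        assert all(r.m == 5 for r in results)

    def test_serogroup_units_have_no_pc(self, toy_cohort):
        results = carrier_scan(
            records=toy_cohort,
            units=[parse_allele("DRB1*04:05"), "DR8"],
            serogroups=SerogroupMap.default(),
        )
        by_unit = {r.unit: r for r in results}
        assert by_unit["DRB1*04:05"].pc is not None
        assert by_unit["DR8"].pc is None
        # DR8 carriers: case1 (08:03), ctrl3 (08:03)
        assert (by_unit["DR8"].table.a, by_unit["DR8"].table.c) == (1, 1)

    def test_aggregation_consistency(self):
        # carrier counts from per-sample records equal counts from the
        # fixture built by aggregating those records
        config = SyntheticCohortConfig(
            haplotypes=(
                Haplotype.parse("DRB1*04:05-DQB1*04:01"),
                Haplotype.parse("DRB1*08:03-DQB1*06:01"),
                Haplotype.parse("DRB1*13:02-DQB1*06:04"),
            ),
            frequencies=(0.3, 0.4, 0.3),
            odds={"DRB1*04:05": 3.0},
            n_cases=80,
            n_controls=80,
            phenotypes=None,
        )
        records = sample_cohort(config, seed=11)
        direct = carrier_scan(records=records)
        fixtures = [
            CountFixture(r.unit, r.table.a, r.table.case_total, r.table.c, r.table.control_total)
            for r in direct
        ]
        from_fixture = carrier_scan(fixtures=fixtures)
        for d, f in zip(direct, from_fixture):
            assert (d.unit, d.table, d.or_, d.p) == (f.unit, f.table, f.or_, f.p)

    def test_serogroup_count_bounds(self):
        config = SyntheticCohortConfig(
            haplotypes=(
                Haplotype.parse("DRB1*04:05-DQB1*04:01"),
                Haplotype.parse("DRB1*04:01-DQB1*03:01"),
                Haplotype.parse("DRB1*09:01-DQB1*03:03"),
            ),
            frequencies=(0.3, 0.3, 0.4),
            n_cases=100,
            n_controls=100,
            phenotypes=None,
        )
        records = sample_cohort(config, seed=5)
        smap = SerogroupMap.default()
        results = {
            r.unit: r
            for r in carrier_scan(
                records=records,
                units=[parse_allele("DRB1*04:05"), parse_allele("DRB1*04:01"), "DR4"],
                serogroups=smap,
            )
        }
        members = [results["DRB1*04:05"].table.a, results["DRB1*04:01"].table.a]
        dr4 = results["DR4"].table.a
        assert max(members) <= dr4 <= sum(members)

    def test_empty_unit_on_balanced_cohort(self, toy_cohort):
        (r,) = carrier_scan(records=toy_cohort, units=[parse_allele("DRB1*16:02")])
        assert (r.table.a, r.table.c) == (0, 0)
        assert r.or_ == 1.0  # corrected, balanced arms
        assert r.p == 1.0

    def test_wrong_locus_unit_is_error(self, toy_cohort):
        with pytest.raises(ValueError, match="locus"):
            carrier_scan(records=toy_cohort, units=[parse_allele("DQB1*04:01")])


class TestTable2Regression:
    def test_three_significant_units(self, table2_results):
        sig = {
            r.unit: r for r in table2_results.values()
            if r.pc is not None and r.pc < 0.05
        }
        assert set(sig) == {"DRB1*04:01", "DRB1*04:05", "DRB1*13:02"}
        assert sig["DRB1*04:01"].direction.value == "predisposing"
        assert sig["DRB1*04:05"].direction.value == "predisposing"
        assert sig["DRB1*13:02"].direction.value == "protective"

    def test_protective_serogroup(self, table2_results):
        dr6 = table2_results["DR6"]
        assert round(dr6.or_, 2) == 0.54
        assert printed_equal(dr6.p, "2.10e-5")

    def test_case_frequencies_match_counts(self, table2_results):
        for r in table2_results.values():
            assert r.table.a <= r.table.case_total
            assert r.case_frequency == pytest.approx(
                100 * r.table.a / r.table.case_total
            )


class TestGenotypeScan:
    def test_class_matching_semantics(self):
        smap = SerogroupMap.default()
        a0405 = parse_allele("DRB1*04:05")
        a0803 = parse_allele("DRB1*08:03")
        hom = GenotypeClass.parse("DRB1*04:05/DRB1*04:05")
        het_only = GenotypeClass.parse("DRB1*04:05/not")
        cross = GenotypeClass.parse("DR4/DR8", smap)
        dr4dr4 = GenotypeClass.parse("DR4/DR4", smap)

        assert hom.matches((a0405, a0405))
        assert not hom.matches((a0405, a0803))
        assert het_only.matches((a0405, a0803))
        assert not het_only.matches((a0405, a0405))
        assert cross.matches((a0405, a0803), smap)
        assert cross.matches((a0803, a0405), smap)  # order-free
        assert not cross.matches((a0405, a0405), smap)
        assert dr4dr4.matches((a0405, parse_allele("DRB1*04:01")), smap)
        assert not dr4dr4.matches((a0405, a0803), smap)

    def test_records_scan(self, toy_cohort):
        smap = SerogroupMap.default()
        results = {
            r.unit: r
            for r in genotype_scan(
                records=toy_cohort,
                classes=["DRB1*04:05/DRB1*04:05", "DRB1*04:05/not", "DR4/DR8"],
                serogroups=smap,
            )
        }
        assert results["DRB1*04:05/DRB1*04:05"].table.a == 1  # case2
        assert results["DRB1*04:05/not"].table.a == 1  # case1
        assert results["DRB1*04:05/not"].table.c == 1  # ctrl1
        assert results["DR4/DR8"].table.a == 1  # case1 04:05+08:03

    def test_empty_class_balanced(self, toy_cohort):
        (r,) = genotype_scan(
            records=toy_cohort, classes=["DRB1*16:02/DRB1*16:02"]
        )
        assert r.or_ == 1.0 and r.p == 1.0

    def test_table4_reference_rows(self):
        fixtures = read_count_fixture(bundled_fixture_path("table4_drb1_genotypes.tsv"))
        results = {r.unit: r for r in genotype_scan(fixtures=fixtures)}
        assert round(results["DR4/DR8"].or_, 2) == 3.52
        assert printed_equal(results["DR4/DR8"].p, "3.12e-9")
        assert round(results["DRB1*04:05/DRB1*04:05"].or_, 2) == 2.79
        assert all(r.pc is None for r in results.values())


class TestSubgroupCompare:
    def test_definite_disease_contrast(self):
        # 133/185 carriers vs 94/175 non-carriers classified definite
        records = []
        for i in range(185):
            records.append(
                make_record(f"c{i}", "case", ("04:05", "09:01"), definite_aih=i < 133)
            )
        for i in range(175):
            records.append(
                make_record(f"n{i}", "case", ("13:02", "09:01"), definite_aih=i < 94)
            )
        cmp = subgroup_compare(records, parse_allele("DRB1*04:05"), "definite_aih")
        assert printed_equal(cmp.p, "0.0005")
        assert cmp.carriers.n == 185 and round(cmp.carriers.percent, 1) == 71.9
        assert cmp.test == "fisher_exact"

    def test_constant_phenotype(self):
        records = [
            make_record("a", "case", ("04:05", "09:01"), asma=True),
            make_record("b", "case", ("13:02", "09:01"), asma=True),
        ]
        cmp = subgroup_compare(records, parse_allele("DRB1*04:05"), "asma")
        assert cmp.p == 1.0

    def test_missing_values_excluded_pairwise(self):
        records = [
            make_record("a", "case", ("04:05", "09:01"), igg=2600.0),
            make_record("b", "case", ("04:05", "09:01"), igg=None),
            make_record("c", "case", ("13:02", "09:01"), igg=2000.0),
        ]
        cmp = subgroup_compare(records, parse_allele("DRB1*04:05"), "igg")
        assert cmp.carriers.n == 1 and cmp.non_carriers.n == 1

    def test_all_missing_is_error(self):
        records = [make_record("a", "case", ("04:05", "09:01"), igg=None)]
        with pytest.raises(ValueError, match="missing"):
            subgroup_compare(records, parse_allele("DRB1*04:05"), "igg")

    def test_igg_shift_detected_in_replicates(self):
        # +400 mg/dl IgG shift in carriers, 200 carriers vs 200 non-carriers:
        # the rank-sum comparison should call it at P < 0.01 nearly always
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 100
        sd = PhenotypeEffects().igg_sd
        for _ in range(n_rep):
            records = []
            for i in range(200):
                records.append(
                    make_record(
                        f"c{i}", "case", ("04:05", "09:01"),
                        igg=float(rng.normal(2500, sd)),
                    )
                )
            for i in range(200):
                records.append(
                    make_record(
                        f"n{i}", "case", ("13:02", "09:01"),
                        igg=float(rng.normal(2100, sd)),
                    )
                )
            cmp = subgroup_compare(records, parse_allele("DRB1*04:05"), "igg")
            hits += cmp.p < 0.01
        assert hits >= 0.95 * n_rep
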