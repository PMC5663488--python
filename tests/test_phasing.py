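"""Haplotype phasing by direct counting; haplotype/diplotype scans."""

from collections import Counter

import pytest

from hla_assoc import (
    Diplotype,
    Haplotype,
    diplotype_scan,
    haplotype_carrier_scan,
    phase_cohort,
)
from hla_assoc.cohort_io import bundled_fixture_path, read_count_fixture
from conftest import make_record, printed_equal

H = Haplotype.parse


class TestLabels:
    def test_haplotype_parse_and_render(self):
        hap = H("DRB1*04:05-DQB1*04:01")
        assert hap.label == "DRB1*04:05-DQB1*04:01"
        assert Haplotype.parse(hap.label) == hap

    def test_diplotype_is_unordered(self):
        d1 = Diplotype(H("DRB1*04:05-DQB1*04:01"), H("DRB1*08:03-DQB1*06:01"))
        d2 = Diplotype(H("DRB1*08:03-DQB1*06:01"), H("DRB1*04:05-DQB1*04:01"))
        assert d1 == d2 and d1.label == d2.label

    def test_wrong_locus_order_rejected(self):
        with pytest.raises(ValueError):
            Haplotype(
                H("DRB1*04:05-DQB1*04:01").dqb1,
                H("DRB1*04:05-DQB1*04:01").drb1,
            )


class TestPhaseCohort:
    def test_double_homozygote(self):
        rec = make_record("s", "case", ("04:05", "04:05"), ("04:01", "04:01"))
        result = phase_cohort([rec])
        d = result.assignments["s"]
        assert d == Diplotype(H("DRB1*04:05-DQB1*04:01"), H("DRB1*04:05-DQB1*04:01"))
        assert result.haplotype_counts()[H("DRB1*04:05-DQB1*04:01")] == 2

    def test_single_locus_homozygote(self):
        rec = make_record("s", "case", ("04:05", "08:03"), ("04:01", "04:01"))
        result = phase_cohort([rec])
        d = result.assignments["s"]
        assert set(d.haplotypes()) == {
            H("DRB1*04:05-DQB1*04:01"),
            H("DRB1*08:03-DQB1*04:01"),
        }

    def test_frequency_rule_resolves_double_heterozygote(self):
        # unambiguous pool: 30x H1, 15x H2, 5x H3 (as homozygotes)
        pool = []
        for i in range(30):
            pool.append(make_record(f"a{i}", "control", ("04:05", "04:05"), ("04:01", "04:01")))
        for i in range(15):
            pool.append(make_record(f"b{i}", "control", ("08:03", "08:03"), ("06:01", "06:01")))
        for i in range(5):
            pool.append(make_record(f"c{i}", "control", ("13:02", "13:02"), ("06:04", "06:04")))
        amb = make_record("amb", "control", ("04:05", "08:03"), ("04:01", "06:01"))
        result = phase_cohort(pool + [amb])
        # freq(H1)*freq(H2) > 0 = freq of either crossed haplotype
        assert result.assignments["amb"] == Diplotype(
            H("DRB1*04:05-DQB1*04:01"), H("DRB1*08:03-DQB1*06:01")
        )
        assert result.n_ambiguous == 0

    def test_unresolvable_tie_flagged_ambiguous(self):
        # no unambiguous pool at all: both phasings weigh zero
        amb = make_record("amb", "case", ("04:05", "08:03"), ("04:01", "06:01"))
        result = phase_cohort([amb])
        assert result.assignments["amb"] is None
        assert result.n_ambiguous == 1
        assert result.haplotype_counts() == Counter()

    def test_catalog_resolves_ambiguity(self):
        amb = make_record("amb", "case", ("04:05", "08:03"), ("04:01", "06:01"))
        catalog = [H("DRB1*04:05-DQB1*04:01"), H("DRB1*08:03-DQB1*06:01")]
        result = phase_cohort([amb], catalog=catalog)
        assert result.assignments["amb"] == Diplotype(*catalog)

    def test_allele_conservation(self, toy_cohort):
        result = phase_cohort(toy_cohort)
        for rec in toy_cohort:
            d = result.assignments[rec.sample_id]
            if d is None:
                continue
            assert tuple(sorted((d.h1.drb1, d.h2.drb1))) == rec.drb1
            assert tuple(sorted((d.h1.dqb1, d.h2.dqb1))) == rec.dqb1

    def test_count_bookkeeping(self, toy_cohort):
        result = phase_cohort(toy_cohort)
        assert sum(result.haplotype_counts().values()) == 2 * result.n_phased
        freqs = result.haplotype_frequencies()
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_missing_locus_error_lists_samples(self):
        rec = make_record("nodq", "case", ("04:05", "08:03"))
        with pytest.raises(ValueError, match="nodq"):
            phase_cohort([rec])


class TestHaplotypeScan:
    def test_table5_reference_rows(self):
        fixtures = read_count_fixture(bundled_fixture_path("table5_haplotypes.tsv"))
        results = {r.unit: r for r in haplotype_carrier_scan(fixtures=fixtures)}
        r = results["DRB1*04:05-DQB1*04:01"]
        assert round(r.or_, 2) == 4.32
        assert printed_equal(r.p, "1.99e-20")
        assert round(results["DRB1*04:01-DQB1*03:01"].or_, 2) == 4.42
        assert all(r.pc is None for r in results.values())

    def test_records_scan_uses_phased_denominators(self, toy_cohort):
        phasing = phase_cohort(toy_cohort)
        results = {r.unit: r for r in haplotype_carrier_scan(phasing=phasing)}
        r = results["DRB1*04:05-DQB1*04:01"]
        assert r.table.case_total == 3 and r.table.control_total == 3
        assert (r.table.a, r.table.c) == (2, 1)


class TestDiplotypeScan:
    def test_table5_reference_rows(self):
        fixtures = read_count_fixture(bundled_fixture_path("table5_haplotypes.tsv"))
        results = {r.unit: r for r in diplotype_scan(fixtures=fixtures)}
        r = results["DRB1*04:05-DQB1*04:01/DRB1*08:02-DQB1*03:02"]
        assert round(r.or_, 2) == 24.77
        assert printed_equal(r.p, "0.0004")
        r2 = results["DRB1*04:05-DQB1*04:01/DRB1*08:03-DQB1*06:01"]
        assert round(r2.or_, 2) == 10.64
        assert printed_equal(r2.p, "1.18e-6")

    def test_records_scan_classes(self, toy_cohort):
        phasing = phase_cohort(toy_cohort)
        results = {
            r.unit: r
            for r in diplotype_scan(
                phasing=phasing,
                classes=[
                    "DRB1*04:05-DQB1*04:01/DRB1*04:05-DQB1*04:01",
                    "DRB1*04:05-DQB1*04:01/not",
                ],
            )
        }
        assert results["DRB1*04:05-DQB1*04:01/DRB1*04:05-DQB1*04:01"].table.a == 1
        het = results["DRB1*04:05-DQB1*04:01/not"]
        assert het.table.a == 1  # case1: one 04:05-04:01 chromosome
        assert het.table.c == 1  # ctrl1

    def test_absent_homozygous_class_balanced(self, toy_cohort):
        phasing = phase_cohort(toy_cohort)
        (r,) = diplotype_scan(
            phasing=phasing,
            classes=["DRB1*16:02-DQB1*05:02/DRB1*16:02-DQB1*05:02"],
        )
        assert r.table.a == 0 and r.table.c == 0
        assert r.p == 1.0
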