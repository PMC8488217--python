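"""Domain-type invariants and file round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from ctcconcord import (
    FormatError,
    IntervalSet,
    ObservedCall,
    SampleProfile,
    SiteList,
    VariantKey,
)
from ctcconcord.io import (
    load_effect_map,
    read_bed,
    read_readcounts,
    read_site_list,
    read_variant_table,
    write_readcounts,
    write_variant_table,
)

from conftest import make_call, make_variant


class TestVariantKey:
    def test_identity_ignores_annotation(self):
        a = VariantKey("chr7", 55259515, "T", "G", gene="EGFR",
                       effect="nonsynonymous_snv", is_hotspot=True)
        b = VariantKey("chr7", 55259515, "T", "G")
        assert a == b and hash(a) == hash(b)
        assert len({a, b}) == 1

    @pytest.mark.parametrize("kwargs", [
        dict(chrom="chr1", pos=0, ref="A", alt="T"),
        dict(chrom="chr1", pos=5, ref="A", alt="A"),
        dict(chrom="chr1", pos=5, ref="A", alt="T", effect="weird"),
    ])
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(FormatError):
            VariantKey(**kwargs)

    def test_vaf_definition_and_undefined_flag(self):
        call = make_call(make_variant(10), "S", alt=40, depth=102)
        # informative reads are ref+alt, not total depth
        call = ObservedCall(call.variant, "S", ref_reads=60, alt_reads=40,
                            depth=102)
        assert call.vaf == pytest.approx(0.40)
        empty = ObservedCall(call.variant, "S", 0, 0, 0)
        assert empty.vaf is None


class TestVariantTable:
    def test_tsv_round_trip_preserves_every_field(self, tmp_path):
        calls = [
            ObservedCall(VariantKey("chr7", 55259515, "T", "G", gene="EGFR",
                                    effect="nonsynonymous_snv"),
                         "P3_PG", 60, 40, 102),
            ObservedCall(VariantKey("chr2", 17, "AT", "A", gene="G1",
                                    effect="frameshift_indel"),
                         "P3_CTC1", 10, 5, 16),
        ]
        path = tmp_path / "v.tsv"
        write_variant_table(calls, path)
        back = read_variant_table(path, dialect="tsv")
        assert sorted(back, key=lambda c: c.variant.site) == sorted(
            calls, key=lambda c: c.variant.site)
        assert {c.variant.gene for c in back} == {"EGFR", "G1"}
        assert back[0].vaf is not None

    def test_empty_table_and_missing_column(self, tmp_path):
        path = tmp_path / "v.tsv"
        write_variant_table([], path)
        assert read_variant_table(path) == []
        bad = tmp_path / "bad.tsv"
        bad.write_text("chrom\tpos\tref\n")
        with pytest.raises(FormatError, match="missing required columns"):
            read_variant_table(bad)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect\tsample_id\tref_reads"
            "\talt_reads\tdepth\n"
            "chr1\tnotanint\tA\tT\tG\tnonsynonymous_snv\tS\t1\t1\t2\n")
        with pytest.raises(FormatError, match="line 2"):
            read_variant_table(path)

    def test_vcf_dialect_cross_checked_against_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = tmp_path / "v.vcf"
        path.write_text("""\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=chr7>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr7\t55259515\t.\tT\tG\t.\tPASS\tGENE=EGFR;EFFECT=nonsynonymous_snv\tAD:DP\t90,10:100\t50,25:80
""")
        calls = read_variant_table(path, dialect="vcf")
        assert len(calls) == 2
        by_sample = {c.sample_id: c for c in calls}
        assert by_sample["S1"].ref_reads == 90
        assert by_sample["S1"].alt_reads == 10
        assert by_sample["S1"].vaf == pytest.approx(0.10)
        assert by_sample["S1"].variant.gene == "EGFR"
        # independent parser agreement on the same records
        with pysam.VariantFile(str(path)) as vf:
            rec = next(iter(vf))
            assert rec.pos == calls[0].variant.pos
            assert tuple(rec.samples["S1"]["AD"]) == (90, 10)
            assert tuple(rec.samples["S2"]["AD"]) == (50, 25)


class TestIntervals:
    def test_bed_convention_and_merge(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        ivs = read_bed(bed)
        assert list(ivs) == [("chr1", 100, 300)]
        assert not ivs.contains("chr1", 100)   # BED start is 0-based
        assert ivs.contains("chr1", 101)
        assert ivs.contains("chr1", 300)
        assert not ivs.contains("chr1", 301)
        assert not ivs.contains("chr2", 150)

    def test_empty_bed_contains_nothing(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("")
        ivs = read_bed(bed)
        assert len(ivs) == 0 and not ivs.contains("chr1", 1)

    def test_invalid_interval_rejected(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("chr1\t200\t100\n")
        with pytest.raises(FormatError):
            read_bed(bed)
        with pytest.raises(FormatError):
            IntervalSet([("chr1", 5, 5)])

    def test_contains_agrees_with_linear_scan(self):
        rng = np.random.default_rng(42)
        raw = [(f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 50)))
               for s in rng.integers(0, 2000, size=200)]
        ivs = IntervalSet(raw)
        for _ in range(10_000):
            chrom = f"chr{rng.integers(1, 5)}"
            pos = int(rng.integers(1, 2100))
            brute = any(c == chrom and s <= pos - 1 < e for c, s, e in raw)
            assert ivs.contains(chrom, pos) == brute

    def test_interval_covers_exactly_end_minus_start_positions(self):
        ivs = IntervalSet([("chrX", 37, 61)])
        hits = sum(ivs.contains("chrX", p) for p in range(1, 200))
        assert hits == 61 - 37


class TestSiteAndReadcountTables:
    def test_site_list_exact_membership(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\nchr1\t10\tA\tT\t0.01\n")
        sites = read_site_list(path, label="population_db")
        assert make_variant(10) in sites
        assert VariantKey("chr1", 10, "A", "C") not in sites
        assert sites.label == "population_db"

    def test_readcounts_round_trip_distinguishes_zero_from_absent(self, tmp_path):
        v = make_variant(500)
        rc = {("S1", v): (30, 0, 31)}
        path = tmp_path / "rc.tsv"
        write_readcounts(rc, path)
        back = read_readcounts(path)
        assert back[("S1", v)] == (30, 0, 31)   # assayed, zero alt
        assert ("S2", v) not in back            # never assayed


def test_effect_map_targets_closed_vocabulary():
    mapping = load_effect_map()
    assert mapping["nonsynonymous SNV"] == "nonsynonymous_snv"
    assert mapping["frameshift deletion"] == "frameshift_indel"
    assert mapping["synonymous SNV"] == "synonymous"


def test_sample_profile_validates_role_and_ownership():
    v = make_variant(7)
    with pytest.raises(Exception):
        SampleProfile("S", "P", "weird_role", [])
    with pytest.raises(Exception):
        SampleProfile("S", "P", "PM", [make_call(v, "OTHER", 3, 10)])
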