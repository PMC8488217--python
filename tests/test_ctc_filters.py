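"""The five-step CTC cascade: set filters, rescue verdicts, audit."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ctcconcord import (
    ConfigurationError,
    FilterConfig,
    IntervalSet,
    SampleProfile,
    SiteList,
    call_ctc_somatic,
    filter_blacklist,
    filter_population_db,
    filter_wbc_controls,
    merge_ctc_replicates,
    require_tumor_concordance,
    rescue_missing_variants,
)

from conftest import make_call, make_variant
from test_stats import enumeration_oracle

CFG = FilterConfig()


def calls_at(positions, sample="C1", alt=20, depth=60):
    return {make_call(make_variant(p), sample, alt, depth) for p in positions}


class TestSetFilters:
    def test_population_db_removes_exact_matches_only(self):
        calls = calls_at([10, 20, 30])
        popdb = SiteList([("chr1", 20, "A", "T"), ("chr1", 30, "A", "G")])
        out = filter_population_db(calls, popdb)
        assert {c.variant.pos for c in out} == {10, 30}  # 30 differs in alt
        assert filter_population_db(calls, SiteList()) == calls
        allhit = SiteList([("chr1", p, "A", "T") for p in (10, 20, 30)])
        assert filter_population_db(calls, allhit) == set()

    def test_blacklist_respects_half_open_boundary(self):
        calls = calls_at([150, 200, 201])
        bl = IntervalSet([("chr1", 100, 200)])
        out = filter_blacklist(calls, bl)
        assert {c.variant.pos for c in out} == {201}
        assert filter_blacklist(calls, IntervalSet()) == calls

    def test_any_wbc_control_excludes(self):
        calls = calls_at([10, 20])
        wbc = [SampleProfile("W1", "P", "WBC_oligo",
                             [make_call(make_variant(10), "W1", 5, 50)]),
               SampleProfile("W2", "P", "WBC_oligo", []),
               SampleProfile("W3", "P", "WBC_bulk", [])]
        out = filter_wbc_controls(calls, wbc)
        assert {c.variant.pos for c in out} == {20}
        assert filter_wbc_controls(calls, []) == calls

    def test_non_wbc_role_in_control_list_rejected(self):
        tumor = SampleProfile("T", "P", "PM", [])
        with pytest.raises(ConfigurationError):
            filter_wbc_controls(calls_at([10]), [tumor])

    def test_concordance_keeps_either_tumor_set(self):
        calls = calls_at([10, 20, 30])
        pm = {make_variant(10)}
        pg = {make_variant(20), make_variant(10)}
        out = require_tumor_concordance(calls, [pm, pg])
        assert {c.variant.pos for c in out} == {10, 20}
        with pytest.raises(ConfigurationError):
            require_tumor_concordance(calls, [])

    def test_first_three_filters_commute(self):
        rng = np.random.default_rng(11)
        positions = rng.choice(5000, size=60, replace=False)
        calls = calls_at(positions.tolist())
        popdb = SiteList([("chr1", int(p), "A", "T")
                          for p in positions[:15]])
        bl = IntervalSet([("chr1", int(p) - 1, int(p) + 5)
                          for p in positions[15:30]])
        wbc = [SampleProfile("W", "P", "WBC_oligo",
                             [make_call(make_variant(int(p)), "W", 4, 40)
                              for p in positions[25:40]])]
        steps = {
            "pop": lambda cs: filter_population_db(cs, popdb),
            "bl": lambda cs: filter_blacklist(cs, bl),
            "wbc": lambda cs: filter_wbc_controls(cs, wbc),
        }
        results = set()
        for order in itertools.permutations(steps):
            cur = calls
            for name in order:
                cur = steps[name](cur)
            results.add(frozenset(c.variant for c in cur))
        assert len(results) == 1


class TestReplicateMerge:
    def setup_method(self):
        v1, v2, v3 = (make_variant(p) for p in (10, 20, 30))
        self.tubes = [
            SampleProfile("C1", "P", "CTC", [make_call(v1, "C1", 10, 50),
                                             make_call(v2, "C1", 8, 50)]),
            SampleProfile("C2", "P", "CTC", [make_call(v1, "C2", 12, 50)]),
            SampleProfile("C3", "P", "CTC", [make_call(v1, "C3", 9, 50),
                                             make_call(v3, "C3", 7, 50)]),
        ]

    def test_union_intersection_majority(self):
        assert {c.variant.pos for c in merge_ctc_replicates(self.tubes, "union")} \
            == {10, 20, 30}
        assert {c.variant.pos
                for c in merge_ctc_replicates(self.tubes, "intersection")} == {10}
        assert {c.variant.pos
                for c in merge_ctc_replicates(self.tubes, "majority")} == {10}

    def test_representative_call_has_max_alt_reads(self):
        merged = merge_ctc_replicates(self.tubes, "union")
        rep = {c.variant.pos: c for c in merged}[10]
        assert rep.sample_id == "C2" and rep.alt_reads == 12

    def test_empty_or_unknown_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            merge_ctc_replicates([], "union")
        with pytest.raises(ConfigurationError):
            merge_ctc_replicates(self.tubes, "best-of")


class TestRescue:
    def test_strong_support_is_rescued(self):
        v = make_variant(10)
        verdicts = rescue_missing_variants(
            [v], {v: (35, 5)}, {v: (80, 0)}, CFG)
        (w,) = verdicts
        p = enumeration_oracle(5, 35, 0, 80)
        assert p < 0.01
        assert w.decision == "rescued" and w.p == pytest.approx(p, abs=1e-12)

    def test_read_floor_blocks_rescue_even_with_small_p(self):
        v = make_variant(10)
        # 3 alt reads out of 40 against a deep clean background: p < 0.01
        # but the >= 4 read floor fails -> indeterminate, never rescued
        (w,) = rescue_missing_variants([v], {v: (37, 3)}, {v: (500, 0)}, CFG)
        assert w.p < CFG.rescue_keep_p_max
        assert w.decision == "indeterminate"

    def test_background_level_support_dropped_as_coverage(self):
        v = make_variant(10)
        (w,) = rescue_missing_variants([v], {v: (79, 1)}, {v: (158, 2)}, CFG)
        assert w.p > 0.05 and w.decision == "dropped_low_coverage"

    def test_unassayed_site_flagged_not_assayed(self):
        v = make_variant(10)
        (w,) = rescue_missing_variants([v], {}, {}, CFG)
        assert w.decision == "not_assayed" and w.p is None

    def test_absent_contrast_uses_matched_depth_null(self):
        v = make_variant(10)
        (w,) = rescue_missing_variants([v], {v: (35, 5)}, {}, CFG)
        assert w.p == pytest.approx(enumeration_oracle(5, 35, 0, 40), abs=1e-12)

    def test_verdicts_partition_all_missing_variants(self):
        rng = np.random.default_rng(5)
        variants = [make_variant(int(p))
                    for p in rng.choice(10_000, 80, replace=False)]
        ctc_rc = {}
        contrast = {}
        for i, v in enumerate(variants):
            if i % 5 == 0:
                continue  # unassayed
            depth = int(rng.integers(5, 120))
            alt = int(rng.integers(0, depth // 2 + 1))
            ctc_rc[v] = (depth - alt, alt)
            contrast[v] = (int(rng.integers(50, 300)), int(rng.integers(0, 3)))
        verdicts = rescue_missing_variants(variants, ctc_rc, contrast, CFG)
        assert len(verdicts) == len(variants)
        assert {w.variant for w in verdicts} == set(variants)
        for w in verdicts:
            assert w.decision in {"rescued", "dropped_low_coverage",
                                  "indeterminate", "not_assayed"}
            if w.decision == "rescued":
                assert (w.alt_reads_in_ctc >= CFG.rescue_min_alt_reads
                        and w.p < CFG.rescue_keep_p_max)
            elif w.decision == "dropped_low_coverage":
                assert w.p > CFG.rescue_drop_p_min


class TestCascade:
    def test_handmade_patient_audit_counts(self, handmade_patient):
        bundle, popdb, blacklist, v = handmade_patient
        tumor_set = set(v.values())  # v1..v8 all somatic in PM
        final, verdicts, audit = call_ctc_somatic(
            bundle, popdb, blacklist, [tumor_set], CFG)
        by_step = {a.step: a for a in audit}
        assert by_step["population_db"].n_removed == 1
        assert by_step["blacklist"].n_removed == 1
        assert by_step["wbc_controls"].n_removed == 1
        assert by_step["tumor_concordance"].n_removed == 0
        assert by_step["rescue"].n_out == 1          # v6 rescued
        decisions = {w.variant: w.decision for w in verdicts}
        assert decisions[v[6]] == "rescued"
        assert decisions[v[7]] == "dropped_low_coverage"
        assert decisions[v[8]] == "not_assayed"
        assert final == {v[i] for i in range(1, 7)}

    def test_called_and_rescued_parts_are_disjoint(self, handmade_patient):
        bundle, popdb, blacklist, v = handmade_patient
        final, verdicts, _ = call_ctc_somatic(
            bundle, popdb, blacklist, [set(v.values())], CFG)
        merged = {c.variant for s in bundle.ctc_samples for c in s.calls}
        rescued = {w.variant for w in verdicts if w.decision == "rescued"}
        assert rescued.isdisjoint(merged)
        assert rescued <= set(v.values())
        assert final - rescued <= merged

    def test_requires_ctc_sample_and_tumor_sets(self, handmade_patient):
        bundle, popdb, blacklist, v = handmade_patient
        no_ctc = type(bundle)(bundle.patient_id,
                              samples=[s for s in bundle.samples
                                       if s.role != "CTC"],
                              readcounts=bundle.readcounts)
        with pytest.raises(ConfigurationError):
            call_ctc_somatic(no_ctc, popdb, blacklist, [set(v.values())], CFG)
        with pytest.raises(ConfigurationError):
            call_ctc_somatic(bundle, popdb, blacklist, [], CFG)

    def test_all_discordant_ctc_gives_empty_set(self, handmade_patient):
        bundle, popdb, blacklist, v = handmade_patient
        foreign = {make_variant(999_999)}
        final, verdicts, audit = call_ctc_somatic(
            bundle, popdb, blacklist, [foreign], CFG)
        assert final == set()
        assert {a.step for a in audit} >= {"tumor_concordance", "rescue"}
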