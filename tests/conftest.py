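"""Shared fixtures: a tiny hand-built patient and a small simulated cohort."""

from __future__ import annotations

import pytest

from ctcconcord import (
    IntervalSet,
    ObservedCall,
    PatientBundle,
    Resources,
    SampleProfile,
    SiteList,
    VariantKey,
    resources_from_cohort,
)
from ctcconcord.io import read_gene_lists, read_stem_annotations
from ctcconcord.simulate import SimConfig, simulate_cohort


def make_variant(pos: int, gene: str = "", effect: str = "nonsynonymous_snv",
                 chrom: str = "chr1", hotspot: bool = False) -> VariantKey:
    return VariantKey(chrom, pos, "A", "T", gene=gene, effect=effect,
                      is_hotspot=hotspot)


def make_call(variant: VariantKey, sample_id: str, alt: int, depth: int
              ) -> ObservedCall:
    return ObservedCall(variant=variant, sample_id=sample_id,
                        ref_reads=depth - alt, alt_reads=alt, depth=depth)


@pytest.fixture(scope="session")
def genedb():
    return read_gene_lists()


@pytest.fixture(scope="session")
def stem_annotations():
    return read_stem_annotations()


@pytest.fixture(scope="session")
def default_cohort():
    """9-patient cohort under the default study conditions."""
    return simulate_cohort(SimConfig(n_patients=9, seed=20210722))


@pytest.fixture(scope="session")
def default_resources(default_cohort):
    return resources_from_cohort(default_cohort)


@pytest.fixture()
def empty_resources(genedb, stem_annotations):
    return Resources(popdb=SiteList(label="population_db"),
                     hotspots=SiteList(label="hotspot"),
                     blacklist=IntervalSet(),
                     genedb=genedb,
                     stem_annotations=stem_annotations)


@pytest.fixture()
def handmade_patient():
    """A 10-variant patient with one planted removal per cascade step.

    PM somatic truth v1..v8; CTC calls v1..v5 plus artifacts a1 (popdb),
    a2 (blacklist), a3 (WBC-shared); v6 is missing from CTC calls but has
    strong read support (rescuable); v7 missing with background-level
    support; v8 missing and unassayed.
    """
    v = {i: make_variant(1000 * i, gene=f"GENE{i}") for i in range(1, 9)}
    a1 = make_variant(100_001, gene="POPG")
    a2 = make_variant(200_001, gene="BLKG")
    a3 = make_variant(300_001, gene="WBCG")

    pm_calls = [make_call(v[i], "PX_PM", 80, 200) for i in range(1, 9)]
    ctc_calls = ([make_call(v[i], "PX_CTC1", 20, 60) for i in range(1, 6)]
                 + [make_call(a1, "PX_CTC1", 15, 60),
                    make_call(a2, "PX_CTC1", 15, 60),
                    make_call(a3, "PX_CTC1", 15, 60)])
    wbc_calls = [make_call(a3, "PX_WBCo", 10, 100)]

    bundle = PatientBundle("PX", samples=[
        SampleProfile("PX_PM", "PX", "PM", pm_calls),
        SampleProfile("PX_CTC1", "PX", "CTC", ctc_calls),
        SampleProfile("PX_WBCo", "PX", "WBC_oligo", wbc_calls),
        SampleProfile("PX_WBCb", "PX", "WBC_bulk", []),
    ])
    for i in range(1, 9):
        bundle.readcounts[("PX_WBCb", v[i])] = (200, 0, 200)
        bundle.readcounts[("PX_WBCo", v[i])] = (100, 0, 100)
    # v6: missed by the caller, 12/60 alt reads in the CTC tube -> rescuable
    bundle.readcounts[("PX_CTC1", v[6])] = (48, 12, 60)
    # v7: one background-level alt read -> dropped as a coverage artifact
    bundle.readcounts[("PX_CTC1", v[7])] = (79, 1, 80)
    # v8: never assayed in CTC data (no entry)

    popdb = SiteList([a1.site], label="population_db")
    blacklist = IntervalSet([(a2.chrom, a2.pos - 1, a2.pos)])
    return bundle, popdb, blacklist, v


@pytest.fixture()
def handmade_resources(handmade_patient, genedb, stem_annotations):
    _, popdb, blacklist, _ = handmade_patient
    return Resources(popdb=popdb, hotspots=SiteList(label="hotspot"),
                     blacklist=blacklist, genedb=genedb,
                     stem_annotations=stem_annotations)
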