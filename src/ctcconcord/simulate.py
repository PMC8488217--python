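"""Synthetic patient cohorts with the error structure of WGA 10-cell WES.

The generator emulates the regime the pipeline is built for: per patient a
primary-tumor (PM) truth set, a progressive (PG) truth set sharing a
configurable fraction with PM, and a CTC truth set drawn variant-by-variant
from PG (rate ``ctc_from_pg``), from the PM-private remainder
(``ctc_from_pm``) and from fresh private variants.  Observed read counts
follow a negative-binomial depth model with binomial allele sampling;
pooled-10-cell amplification artifacts are planted explicitly: allelic
dropout (total alt-allele loss per site per CTC tube), Poisson false
positives (a fixed share of which leak into the oligo-WBC control, since
control tubes go through the same amplification), germline leakage listed
in the population database, and alignment artifacts inside emitted
blacklist regions.  Every observed call carries a truth label so filter
performance is measurable exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .model import (
    ConfigurationError,
    IntervalSet,
    ObservedCall,
    PatientBundle,
    SampleProfile,
    SiteList,
    VariantKey,
)
from . import io as cio

#: Recurrently mutated cancer genes given extra weight in the gene pool so
#: the screening stage has realistic material to match.
CANCER_GENES = [
    "EGFR", "TP53", "MUC16", "NUMA1", "ZNF143", "SHKBP1", "RRAD", "PPIL2",
    "LZTR1", "PELP1", "BPTF", "ELP3", "CSMD3", "PON1", "ORC1", "ST6GAL2",
    "KEAP1", "NOTCH1", "LEF1", "TAOK1", "IRS1", "RASAL2", "ABCC11", "MDM2",
    "SMAD4", "RB1", "MSH6", "ATR", "FAT1", "NOTCH2",
]

GENE_POOL = CANCER_GENES * 5 + [f"G{i:04d}" for i in range(370)]

_SNV_EFFECTS = ["nonsynonymous_snv", "stopgain", "stoploss", "splicing"]
_SNV_WEIGHTS = [0.86, 0.06, 0.03, 0.05]
_BASES = "ACGT"

#: Share of WGA false positives that also appear in the oligo-WBC control
#: (both tube types are amplified with the same chemistry).
WBC_SHARED_FP = 0.2


def _role_key(role: str) -> str:
    if role.startswith("PG_"):
        return "PG"
    return role


@dataclass
class SimConfig:
    """Cohort-generation parameters; identical config => identical cohort."""

    n_patients: int = 9
    n_truth_variants: int = 200
    pm_pg_overlap: float = 0.4
    ctc_from_pm: float = 0.05
    ctc_from_pg: float = 0.15
    ctc_private: float = 0.05
    depth_mean: dict[str, float] = field(default_factory=lambda: {
        "PM": 250.0, "PG": 250.0, "CTC": 100.0,
        "WBC_oligo": 150.0, "WBC_bulk": 200.0})
    depth_dispersion: float = 5.0
    wga_dropout: float = 0.1
    wga_fp_rate: float = 10.0
    germline_rate: float = 0.05
    blacklist_rate: float = 0.02
    tumor_vaf_range: tuple[float, float] = (0.05, 0.6)
    seq_error_rate: float = 1e-3
    caller_sensitivity: float = 0.9
    call_min_alt: int = 2
    call_min_vaf: float = 0.02
    indel_fraction: float = 0.1
    hotspot_fraction: float = 0.02
    n_ctc_replicates: int = 3
    n_popdb_decoys: int = 100
    pg_role: str = "PG_lymph"
    pm_missing_patients: tuple[int, ...] = ()
    patient_prefix: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {"pm_pg_overlap": self.pm_pg_overlap,
                 "ctc_from_pm": self.ctc_from_pm,
                 "ctc_from_pg": self.ctc_from_pg,
                 "ctc_private": self.ctc_private,
                 "wga_dropout": self.wga_dropout,
                 "germline_rate": self.germline_rate,
                 "blacklist_rate": self.blacklist_rate,
                 "caller_sensitivity": self.caller_sensitivity,
                 "hotspot_fraction": self.hotspot_fraction}
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {value}")
        if self.ctc_from_pm + self.ctc_from_pg + self.ctc_private == 0:
            raise ConfigurationError(
                "CTC truth has no source: ctc_from_pm, ctc_from_pg and "
                "ctc_private are all zero")
        if any(m <= 0 for m in self.depth_mean.values()):
            raise ConfigurationError("depth means must be positive")
        if self.pg_role not in ("PG_lung", "PG_lymph", "PG_hydrothorax"):
            raise ConfigurationError(f"unknown pg_role {self.pg_role!r}")
        lo, hi = self.tumor_vaf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(
                f"tumor_vaf_range must satisfy 0 < low <= high <= 1, "
                f"got {self.tumor_vaf_range}")


def noise_free(config: SimConfig, depth: float = 500.0) -> SimConfig:
    """Copy of ``config`` with every noise mechanism switched off."""
    return replace(
        config,
        wga_dropout=0.0, wga_fp_rate=0.0, germline_rate=0.0,
        blacklist_rate=0.0, seq_error_rate=0.0, caller_sensitivity=1.0,
        hotspot_fraction=0.0,
        depth_mean={k: depth for k in config.depth_mean})


@dataclass
class PatientTruth:
    pm: set[VariantKey] | None
    pg: set[VariantKey]
    ctc: set[VariantKey]
    #: (sample_id, variant) -> one of true_somatic / germline_leak /
    #: blacklist_artifact / wga_false_positive / wbc_artifact
    labels: dict[tuple[str, VariantKey], str]
    vaf: dict[VariantKey, float]


@dataclass
class SyntheticCohort:
    config: SimConfig
    bundles: list[PatientBundle]
    truth: dict[str, PatientTruth]
    popdb: SiteList
    hotspots: SiteList
    blacklist: IntervalSet


class _VariantFactory:
    """Draws unique variant identities for one patient."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, effect: str | None = None,
             indel_fraction: float = 0.1) -> VariantKey:
        while True:
            chrom = f"chr{int(self.rng.integers(1, 23))}"
            pos = int(self.rng.integers(1, 50_000_001))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                break
        if effect is None:
            if self.rng.random() < indel_fraction:
                effect = ("frameshift_indel"
                          if self.rng.random() < 0.7 else "nonframeshift_indel")
            else:
                effect = str(self.rng.choice(_SNV_EFFECTS, p=_SNV_WEIGHTS))
        gene = str(self.rng.choice(GENE_POOL))
        base = _BASES[int(self.rng.integers(4))]
        if effect in ("frameshift_indel", "nonframeshift_indel"):
            ins = _BASES[int(self.rng.integers(4))]
            if self.rng.random() < 0.5:
                ref, alt = base, base + ins          # insertion
            else:
                ref, alt = base + ins, base          # deletion
        else:
            alt = _BASES[(int(self.rng.integers(3)) + _BASES.index(base) + 1) % 4]
            ref = base
        return VariantKey(chrom, pos, ref, alt, gene=gene, effect=effect)


def _observe(rng: np.random.Generator, depth_mean: float, dispersion: float,
             vaf: float, error: float) -> tuple[int, int, int] | None:
    """One (ref, alt, depth) draw; None when the site drew zero coverage."""
    p = dispersion / (dispersion + depth_mean)
    depth = int(rng.negative_binomial(dispersion, p))
    if depth == 0:
        return None
    rate = vaf if vaf > 0 else error
    alt = int(rng.binomial(depth, rate)) if rate > 0 else 0
    return depth - alt, alt, depth


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with per-call truth labels."""
    bundles: list[PatientBundle] = []
    truth: dict[str, PatientTruth] = {}
    popdb_sites: list[tuple[str, int, str, str]] = []
    hotspot_sites: list[tuple[str, int, str, str]] = []
    blacklist_iv: list[tuple[str, int, int]] = []

    for idx in range(config.n_patients):
        pid = f"{config.patient_prefix}{idx + 1}"
        rng = np.random.default_rng([config.seed, idx])
        factory = _VariantFactory(rng)
        n = config.n_truth_variants
        has_pm = idx not in config.pm_missing_patients

        # --- truth sets -------------------------------------------------
        vaf_lo, vaf_hi = config.tumor_vaf_range
        vafs: dict[VariantKey, float] = {}
        hot: set[VariantKey] = set()

        def new_truth_variant() -> VariantKey:
            v = factory.draw(indel_fraction=config.indel_fraction)
            if rng.random() < config.hotspot_fraction:
                # hotspot variants get a deliberately sub-threshold VAF so
                # the relaxed hotspot rule is what keeps them
                v = v.with_hotspot(True)
                hot.add(v)
                vafs[v] = float(rng.uniform(0.015, 0.03))
            else:
                vafs[v] = float(rng.uniform(vaf_lo, vaf_hi))
            return v

        if has_pm:
            pm_list = [new_truth_variant() for _ in range(n)]
            shared = [v for v in pm_list if rng.random() < config.pm_pg_overlap]
            pg_list = shared + [new_truth_variant()
                                for _ in range(n - len(shared))]
            pm: set[VariantKey] | None = set(pm_list)
        else:
            pm_list, pm = [], None
            pg_list = [new_truth_variant() for _ in range(n)]
        pg = set(pg_list)

        ctc_list = [v for v in pg_list if rng.random() < config.ctc_from_pg]
        if pm is not None:
            ctc_list += [v for v in pm_list
                         if v not in pg and rng.random() < config.ctc_from_pm]
        n_private = int(rng.poisson(config.ctc_private * n))
        ctc_list += [new_truth_variant() for _ in range(n_private)]
        ctc = set(ctc_list)

        # --- planted artifacts ------------------------------------------
        n_germ = int(rng.binomial(n, config.germline_rate))
        germline = [factory.draw(indel_fraction=config.indel_fraction)
                    for _ in range(n_germ)]
        for g in germline:
            vafs[g] = 0.5
            popdb_sites.append(g.site)

        n_bl = int(rng.binomial(n, config.blacklist_rate))
        bl_artifacts = [factory.draw(indel_fraction=0.0) for _ in range(n_bl)]
        for v in bl_artifacts:
            vafs[v] = float(rng.uniform(0.1, 0.4))
            start = max(0, v.pos - 1 - int(rng.integers(0, 50)))
            blacklist_iv.append((v.chrom, start, v.pos + int(rng.integers(1, 50))))

        # --- samples ----------------------------------------------------
        sample_defs: list[tuple[str, str]] = []
        if has_pm:
            sample_defs.append((f"{pid}_PM", "PM"))
        sample_defs.append((f"{pid}_PG", config.pg_role))
        for r in range(config.n_ctc_replicates):
            sample_defs.append((f"{pid}_CTC{r + 1}", "CTC"))
        sample_defs.append((f"{pid}_WBCo", "WBC_oligo"))
        sample_defs.append((f"{pid}_WBCb", "WBC_bulk"))

        # WGA false positives per CTC tube; a fixed share leaks into the
        # oligo-WBC control
        fp_by_ctc: dict[str, list[VariantKey]] = {}
        wbc_shared_fp: list[VariantKey] = []
        for sid, role in sample_defs:
            if role != "CTC":
                continue
            n_fp = int(rng.poisson(config.wga_fp_rate))
            fps = [factory.draw(indel_fraction=0.0) for _ in range(n_fp)]
            for v in fps:
                vafs[v] = float(rng.uniform(0.05, 0.3))
                if rng.random() < WBC_SHARED_FP:
                    wbc_shared_fp.append(v)
            fp_by_ctc[sid] = fps

        universe: list[VariantKey] = list(dict.fromkeys(
            (pm_list if has_pm else []) + pg_list + ctc_list + germline
            + bl_artifacts + [v for fps in fp_by_ctc.values() for v in fps]))
        for v in hot:
            hotspot_sites.append(v.site)

        # --- observation ------------------------------------------------
        bundle = PatientBundle(pid)
        labels: dict[tuple[str, VariantKey], str] = {}
        for sid, role in sample_defs:
            mean = config.depth_mean[_role_key(role)]
            present: dict[VariantKey, str] = {}
            if role == "PM" and pm is not None:
                present.update({v: "true_somatic" for v in pm_list})
            elif role.startswith("PG"):
                present.update({v: "true_somatic" for v in pg_list})
            elif role == "CTC":
                present.update({v: "true_somatic" for v in ctc_list})
                present.update({v: "blacklist_artifact" for v in bl_artifacts})
                present.update({v: "wga_false_positive" for v in fp_by_ctc[sid]})
            elif role == "WBC_oligo":
                present.update({v: "wbc_artifact" for v in wbc_shared_fp})
            for g in germline:
                present[g] = "germline_leak"

            calls: list[ObservedCall] = []
            for v in universe:
                obs_vaf = vafs[v] if v in present else 0.0
                dropped = (role == "CTC" and obs_vaf > 0
                           and rng.random() < config.wga_dropout)
                if dropped:
                    obs_vaf = 0.0
                drawn = _observe(rng, mean, config.depth_dispersion,
                                 obs_vaf, config.seq_error_rate)
                if drawn is None:
                    continue  # site not assayed in this sample
                ref, alt, depth = drawn
                bundle.readcounts[(sid, v)] = (ref, alt, depth)
                if alt < config.call_min_alt or alt / depth < config.call_min_vaf:
                    continue
                if v in present and not dropped:
                    if (role == "CTC"
                            and rng.random() >= config.caller_sensitivity):
                        continue  # caller miss: reads exist, call does not
                    label = present[v]
                elif role in ("WBC_oligo", "WBC_bulk"):
                    label = "wbc_artifact"  # amplification/sequencing error
                else:
                    continue  # bulk callers suppress error-level support
                calls.append(ObservedCall(variant=v, sample_id=sid,
                                          ref_reads=ref, alt_reads=alt,
                                          depth=depth))
                labels[(sid, v)] = label
            bundle.samples.append(SampleProfile(
                sample_id=sid, patient_id=pid, role=role, calls=calls))
        bundles.append(bundle)
        truth[pid] = PatientTruth(pm=pm, pg=pg, ctc=ctc, labels=labels,
                                  vaf=vafs)

    # cohort-level decoy polymorphism sites keep the popdb from being
    # trivially identical to the planted germline set
    rng0 = np.random.default_rng([config.seed, 10_000_019])
    decoy_factory = _VariantFactory(rng0)
    for _ in range(config.n_popdb_decoys):
        popdb_sites.append(decoy_factory.draw(indel_fraction=0.0).site)

    return SyntheticCohort(
        config=config,
        bundles=bundles,
        truth=truth,
        popdb=SiteList(popdb_sites, label="population_db"),
        hotspots=SiteList(hotspot_sites, label="hotspot"),
        blacklist=IntervalSet(blacklist_iv),
    )


def merge_cohorts(*cohorts: SyntheticCohort) -> SyntheticCohort:
    """Concatenate sub-cohorts simulated under different conditions.

    Patient ids must be distinct across inputs (use ``patient_prefix``).
    The merged object carries the first sub-cohort's config.
    """
    if not cohorts:
        raise ConfigurationError("merge_cohorts needs at least one cohort")
    bundles: list[PatientBundle] = []
    truth: dict[str, PatientTruth] = {}
    pop: list = []
    hot: list = []
    bl: list = []
    for c in cohorts:
        overlap = set(truth) & set(c.truth)
        if overlap:
            raise ConfigurationError(
                f"duplicate patient ids across sub-cohorts: {sorted(overlap)}")
        bundles.extend(c.bundles)
        truth.update(c.truth)
        pop.extend(c.popdb)
        hot.extend(c.hotspots)
        bl.extend(c.blacklist)
    return SyntheticCohort(
        config=cohorts[0].config, bundles=bundles, truth=truth,
        popdb=SiteList(pop, label="population_db"),
        hotspots=SiteList(hot, label="hotspot"),
        blacklist=IntervalSet(bl))


def study_cohort(seed: int, n_lymph: int = 6, n_tumorlike: int = 3,
                 n_truth_variants: int = 200) -> SyntheticCohort:
    """Default nine-patient cohort mirroring the study layout.

    Most progressive lesions are lymph-node biopsies whose CTC sharing is
    low (5%); a minority are lung/hydrothorax lesions with high sharing
    (30%); one patient in each group lacks a primary sample.
    """
    lymph = simulate_cohort(SimConfig(
        n_patients=n_lymph, n_truth_variants=n_truth_variants,
        ctc_from_pg=0.05, pg_role="PG_lymph",
        pm_missing_patients=(3,) if n_lymph > 3 else (),
        patient_prefix="L", seed=seed))
    tumorlike = simulate_cohort(SimConfig(
        n_patients=n_tumorlike, n_truth_variants=n_truth_variants,
        ctc_from_pg=0.30, pg_role="PG_hydrothorax",
        pm_missing_patients=(0,) if n_tumorlike > 0 else (),
        patient_prefix="T", seed=seed + 1))
    return merge_cohorts(lymph, tumorlike)


def write_fixture(cohort: SyntheticCohort, out_dir: str | Path) -> list[Path]:
    """Emit the cohort in the exact input formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    all_calls = [c for b in cohort.bundles for s in b.samples for c in s.calls]
    cio.write_variant_table(all_calls, out / "variants.tsv")
    written.append(out / "variants.tsv")

    sample_rows = sorted(
        (s.sample_id, s.patient_id, s.role)
        for b in cohort.bundles for s in b.samples)
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample_id\tpatient_id\trole\n")
        for sid, pid, role in sample_rows:
            fh.write(f"{sid}\t{pid}\t{role}\n")
    written.append(out / "samples.tsv")

    readcounts = {k: v for b in cohort.bundles for k, v in b.readcounts.items()}
    cio.write_readcounts(readcounts, out / "readcounts.tsv")
    written.append(out / "readcounts.tsv")

    cio.write_site_list(cohort.popdb, out / "popdb.tsv")
    cio.write_site_list(cohort.hotspots, out / "hotspots.tsv")
    cio.write_bed(cohort.blacklist, out / "blacklist.bed")
    written += [out / "popdb.tsv", out / "hotspots.tsv", out / "blacklist.bed"]

    label_rows = sorted(
        (pid, sid, v.chrom, v.pos, v.ref, v.alt, label)
        for pid, t in cohort.truth.items()
        for (sid, v), label in t.labels.items())
    with open(out / "truth_labels.tsv", "w") as fh:
        fh.write("patient_id\tsample_id\tchrom\tpos\tref\talt\tlabel\n")
        for row in label_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    written.append(out / "truth_labels.tsv")

    set_rows = []
    for pid, t in sorted(cohort.truth.items()):
        for name, s in (("PM", t.pm), ("PG", t.pg), ("CTC", t.ctc)):
            if s is None:
                continue
            for v in sorted(s, key=lambda x: x.site):
                set_rows.append((pid, name, v.chrom, v.pos, v.ref, v.alt,
                                 v.gene, v.effect))
    with open(out / "truth_sets.tsv", "w") as fh:
        fh.write("patient_id\ttruth_set\tchrom\tpos\tref\talt\tgene\teffect\n")
        for row in set_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    written.append(out / "truth_sets.tsv")

    manifest = {
        "config": _config_json(cohort.config),
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in written},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def _config_json(config: SimConfig) -> dict:
    d = asdict(config)
    d["tumor_vaf_range"] = list(d["tumor_vaf_range"])
    d["pm_missing_patients"] = list(d["pm_missing_patients"])
    return d
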