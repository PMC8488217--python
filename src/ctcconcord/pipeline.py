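"""End-to-end per-patient execution and cohort report assembly.

For each patient: tumor-vs-WBC somatic calling for the primary (PM) and
progressive (PG) samples, the five-step CTC cascade with rescue, TMB,
7-region Venn partitions at variant and gene level, shared proportions
under both denominators, and annotation screening.  Patients are processed
independently; one patient's failure is recorded and the cohort continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import io as cio
from .concordance import (
    ConcordanceReport,
    PatientReport,
    UndefinedProportionError,
    cohort_shared_summary,
    recurrence_matrix,
    shared_proportion,
    tmb_change,
    venn_partition,
)
from .ctc import call_ctc_somatic
from .model import (
    ConfigurationError,
    GeneListDB,
    IntervalSet,
    PatientBundle,
    SampleProfile,
    SiteList,
    VariantKey,
)
from .screen import screen_all
from .somatic import FilterConfig, call_tumor_somatic, compute_tmb

log = logging.getLogger(__name__)


@dataclass
class Resources:
    """Shared reference inputs of a run."""

    popdb: SiteList
    hotspots: SiteList
    blacklist: IntervalSet
    genedb: GeneListDB
    stem_annotations: Mapping[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    """File-based run description (paths resolved relative to nothing)."""

    variants: str
    samples: str
    readcounts: str
    popdb: str
    blacklist: str
    hotspots: str | None = None
    drug_genes: str | None = None
    pathways: str | None = None
    stem_annotations: str | None = None
    out_dir: str = "results/run"
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fc = FilterConfig(**raw.pop("filter_config", {}))
        return cls(filter_config=fc, **raw)

    def validate(self) -> None:
        required = {"variants": self.variants, "samples": self.samples,
                    "readcounts": self.readcounts, "popdb": self.popdb,
                    "blacklist": self.blacklist}
        for name, p in required.items():
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")


def _annotate_hotspots(bundle: PatientBundle, hotspots: SiteList) -> PatientBundle:
    if len(hotspots) == 0:
        return bundle
    out = PatientBundle(bundle.patient_id, samples=[],
                        readcounts=dict(bundle.readcounts))
    for s in bundle.samples:
        calls = []
        for c in s.calls:
            if c.variant in hotspots and not c.variant.is_hotspot:
                c = type(c)(variant=c.variant.with_hotspot(True),
                            sample_id=c.sample_id, ref_reads=c.ref_reads,
                            alt_reads=c.alt_reads, depth=c.depth)
            calls.append(c)
        out.samples.append(SampleProfile(
            sample_id=s.sample_id, patient_id=s.patient_id,
            role=s.role, calls=calls))
    return out


def _gene_set(variants: set[VariantKey] | None) -> set[str]:
    if variants is None:
        return set()
    return {v.gene.upper() for v in variants if v.gene}


def _safe_shared(a: set | None, b: set | None, denominator: str) -> float | None:
    if a is None or b is None:
        return None
    try:
        return shared_proportion(a, b, denominator)
    except UndefinedProportionError:
        return None


def run_patient(bundle: PatientBundle, resources: Resources,
                config: FilterConfig | None = None) -> PatientReport:
    """Full analysis of one patient bundle."""
    config = config or FilterConfig()
    if not bundle.ctc_samples:
        raise ConfigurationError(
            f"patient {bundle.patient_id}: missing CTC sample")
    if not bundle.wbc_samples:
        raise ConfigurationError(
            f"patient {bundle.patient_id}: missing WBC control")
    if bundle.pm_sample is None and not bundle.pg_samples:
        raise ConfigurationError(
            f"patient {bundle.patient_id}: needs a PM or PG sample")

    bundle = _annotate_hotspots(bundle, resources.hotspots)

    bulk = bundle.by_role("WBC_bulk")
    normal = bulk[0] if bulk else bundle.by_role("WBC_oligo")[0]

    pm = bundle.pm_sample
    pm_set = (call_tumor_somatic(pm, normal, config, bundle.readcounts)
              if pm is not None else None)
    pg_set: set[VariantKey] | None = None
    for pg in bundle.pg_samples:
        called = call_tumor_somatic(pg, normal, config, bundle.readcounts)
        pg_set = called if pg_set is None else pg_set | called

    tumor_sets = [s for s in (pm_set, pg_set) if s is not None]
    ctc_set, verdicts, audit = call_ctc_somatic(
        bundle, resources.popdb, resources.blacklist, tumor_sets, config)

    tmb_pm = compute_tmb(pm_set, config) if pm_set is not None else None
    tmb_pg = compute_tmb(pg_set, config) if pg_set is not None else None
    direction = (tmb_change(tmb_pm, tmb_pg)
                 if tmb_pm is not None and tmb_pg is not None else None)

    pm_v = pm_set or set()
    pg_v = pg_set or set()
    venn_v = venn_partition(pm_v, pg_v, ctc_set)
    venn_g = venn_partition(_gene_set(pm_set), _gene_set(pg_set),
                            _gene_set(ctc_set))

    shared = {
        "pm_pg_of_pm": _safe_shared(pm_set, pg_set, "a"),
        "pm_pg_of_pg": _safe_shared(pm_set, pg_set, "b"),
        "ctc_pm_of_pm": _safe_shared(ctc_set, pm_set, "b"),
        "ctc_pm_of_ctc": _safe_shared(ctc_set, pm_set, "a"),
        "ctc_pg_of_pg": _safe_shared(ctc_set, pg_set, "b"),
        "ctc_pg_of_ctc": _safe_shared(ctc_set, pg_set, "a"),
    }

    union = pm_v | pg_v | ctc_set
    roles_by_variant: dict[VariantKey, list[str]] = {}
    for role, s in (("PM", pm_v), ("PG", pg_v), ("CTC", ctc_set)):
        for v in s:
            roles_by_variant.setdefault(v, []).append(role)
    hits = screen_all(union, resources.genedb, resources.stem_annotations,
                      roles_by_variant)

    return PatientReport(
        patient_id=bundle.patient_id, pm_set=pm_set, pg_set=pg_set,
        ctc_set=ctc_set, venn_variant=venn_v, venn_gene=venn_g,
        tmb_pm=tmb_pm, tmb_pg=tmb_pg, tmb_direction=direction,
        shared=shared, screen_hits=hits, audit=audit,
        rescue_verdicts=verdicts)


def run_bundles(bundles: Sequence[PatientBundle], resources: Resources,
                config: FilterConfig | None = None) -> ConcordanceReport:
    """Run every patient; failures are recorded, not fatal."""
    config = config or FilterConfig()
    report = ConcordanceReport(config={"filter_config": config.to_dict()})
    for bundle in sorted(bundles, key=lambda b: b.patient_id):
        try:
            report.patients.append(run_patient(bundle, resources, config))
        except Exception as exc:  # noqa: BLE001 — cohort continues
            log.warning("patient %s failed: %s", bundle.patient_id, exc)
            report.failures[bundle.patient_id] = str(exc)
    if report.patients:
        try:
            frac_pm, frac_pg = cohort_shared_summary(
                [(p.pm_set, p.pg_set, p.ctc_set) for p in report.patients])
            report.cohort_frac_of_pm = frac_pm
            report.cohort_frac_of_pg = frac_pg
        except UndefinedProportionError:
            pass
        cells = []
        for p in report.patients:
            if p.pm_set is not None:
                cells.append((p.patient_id, "PM", p.pm_set))
            if p.pg_set is not None:
                cells.append((p.patient_id, "PG", p.pg_set))
            cells.append((p.patient_id, "CTC", p.ctc_set))
        report.recurrence = recurrence_matrix(cells, top_n=40)
    return report


def run_cohort(run_config: RunConfig) -> tuple[ConcordanceReport, list[Path]]:
    """Load inputs from files, run the cohort, write the report."""
    run_config.validate()
    bundles = cio.load_bundles(run_config.variants, run_config.samples,
                               run_config.readcounts)
    if not bundles:
        raise ConfigurationError("cohort is empty: no patients found")
    resources = Resources(
        popdb=cio.read_site_list(run_config.popdb, label="population_db"),
        hotspots=(cio.read_site_list(run_config.hotspots, label="hotspot")
                  if run_config.hotspots else SiteList(label="hotspot")),
        blacklist=cio.read_bed(run_config.blacklist),
        genedb=cio.read_gene_lists(run_config.drug_genes, run_config.pathways),
        stem_annotations=cio.read_stem_annotations(run_config.stem_annotations),
    )
    report = run_bundles(bundles, resources, run_config.filter_config)
    files = cio.write_report(report, run_config.out_dir)
    return report, files


def resources_from_cohort(cohort, drug_genes=None, pathways=None,
                          stem_annotations=None) -> Resources:
    """Resources for an in-memory SyntheticCohort (bundled gene lists)."""
    return Resources(
        popdb=cohort.popdb, hotspots=cohort.hotspots,
        blacklist=cohort.blacklist,
        genedb=cio.read_gene_lists(drug_genes, pathways),
        stem_annotations=cio.read_stem_annotations(stem_annotations),
    )
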