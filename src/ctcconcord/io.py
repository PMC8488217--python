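"""Readers and writers for variant tables, readcounts, BED, site and gene lists.

All tabular formats are UTF-8 TSV with a header row; variant tables may
alternatively be VCF v4.2 with per-sample AD/DP FORMAT fields (read through
cyvcf2).  Every writer orders rows deterministically so that identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    EFFECTS,
    FormatError,
    GeneListDB,
    IntervalSet,
    ObservedCall,
    PatientBundle,
    ReadCounts,
    SampleProfile,
    SiteList,
    VariantKey,
)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "effect",
                   "sample_id", "ref_reads", "alt_reads", "depth"]


def _data_path(name: str):
    return resources.files("ctcconcord").joinpath("data", name)


def load_effect_map(path: str | Path | None = None) -> dict[str, str]:
    """Upstream annotator effect strings -> the closed 8-class vocabulary."""
    src = Path(path) if path else _data_path("effect_map.tsv")
    df = pd.read_csv(src, sep="\t", dtype=str)
    mapping = dict(zip(df["annotator_effect"], df["effect_class"]))
    bad = set(mapping.values()) - EFFECTS
    if bad:
        raise FormatError(f"effect map targets unknown classes: {sorted(bad)}")
    return mapping


def read_variant_table(path: str | Path, dialect: str = "tsv",
                       effect_map: Mapping[str, str] | None = None
                       ) -> list[ObservedCall]:
    """Read per-sample variant observations from TSV or VCF."""
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, effect_map or {})
    raise FormatError(f"unknown variant-table dialect {dialect!r}")


def _read_variant_tsv(path: str | Path) -> list[ObservedCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    calls: list[ObservedCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
            variant = VariantKey(row.chrom, pos, row.ref, row.alt,
                                 gene=row.gene, effect=row.effect or "other")
            calls.append(ObservedCall(
                variant=variant, sample_id=row.sample_id,
                ref_reads=int(row.ref_reads), alt_reads=int(row.alt_reads),
                depth=int(row.depth)))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    return calls


def _read_variant_vcf(path: str | Path,
                      effect_map: Mapping[str, str]) -> list[ObservedCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[ObservedCall] = []
    for rec in vcf:
        gene = rec.INFO.get("GENE") or ""
        raw_effect = rec.INFO.get("EFFECT") or ""
        effect = effect_map.get(raw_effect,
                                raw_effect if raw_effect in EFFECTS else "other")
        for alt in rec.ALT:
            variant = VariantKey(rec.CHROM, rec.POS, rec.REF, alt,
                                 gene=gene, effect=effect)
            ad = rec.format("AD")
            dp = rec.format("DP")
            if ad is None:
                raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AD")
            for i, sid in enumerate(samples):
                ref_reads = int(ad[i][0])
                alt_reads = int(ad[i][1])
                if ref_reads < 0 or alt_reads < 0:  # missing in this sample
                    continue
                depth = int(dp[i][0]) if dp is not None else ref_reads + alt_reads
                calls.append(ObservedCall(variant=variant, sample_id=sid,
                                          ref_reads=ref_reads,
                                          alt_reads=alt_reads, depth=depth))
    return calls


def write_variant_table(calls: Iterable[ObservedCall], path: str | Path) -> None:
    rows = sorted(
        ({"chrom": c.variant.chrom, "pos": c.variant.pos,
          "ref": c.variant.ref, "alt": c.variant.alt,
          "gene": c.variant.gene, "effect": c.variant.effect,
          "sample_id": c.sample_id, "ref_reads": c.ref_reads,
          "alt_reads": c.alt_reads, "depth": c.depth}
         for c in calls),
        key=lambda r: (r["sample_id"], r["chrom"], r["pos"], r["ref"], r["alt"]))
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> IntervalSet:
    """BED3+ -> normalized, merged IntervalSet (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path} line {i}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path} line {i}: start >= end ({start} >= {end})")
            intervals.append((parts[0], start, end))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_site_list(path: str | Path, label: str = "") -> SiteList:
    """TSV chrom,pos,ref,alt(,af) -> SiteList keyed on exact identity."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sites = [(r.chrom, int(r.pos), r.ref, r.alt)
             for r in df.itertuples(index=False)]
    return SiteList(sites, label=label or Path(path).stem)


def write_site_list(sites: SiteList, path: str | Path) -> None:
    rows = [{"chrom": c, "pos": p, "ref": r, "alt": a} for c, p, r, a in sites]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False)


def read_gene_lists(drug_path: str | Path | None = None,
                    pathway_path: str | Path | None = None,
                    stem_keywords: list[str] | None = None) -> GeneListDB:
    """Load the screening database; bundled illustrative defaults otherwise."""
    drug_src = Path(drug_path) if drug_path else _data_path("drug_genes.tsv")
    pw_src = Path(pathway_path) if pathway_path else _data_path("pathways.tsv")
    drug_df = pd.read_csv(drug_src, sep="\t", dtype=str, keep_default_na=False)
    pw_df = pd.read_csv(pw_src, sep="\t", dtype=str, keep_default_na=False)
    drug_map: dict[str, list[tuple[str, str]]] = {}
    for r in drug_df.itertuples(index=False):
        drug_map.setdefault(r.gene.upper(), []).append((r.drug, r.association))
    pathway_map: dict[str, list[tuple[str, str]]] = {}
    for r in pw_df.itertuples(index=False):
        pathway_map.setdefault(r.gene.upper(), []).append(
            (r.pathway, r.pathway_class))
    return GeneListDB(drug_map=drug_map, pathway_map=pathway_map,
                      stem_keywords=stem_keywords or ["stem cell"])


def read_stem_annotations(path: str | Path | None = None) -> dict[str, str]:
    src = Path(path) if path else _data_path("stem_annotations.tsv")
    df = pd.read_csv(src, sep="\t", dtype=str, keep_default_na=False)
    return dict(zip(df["gene"].str.upper(), df["annotation"]))


def read_samples_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "patient_id", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def read_readcounts(path: str | Path) -> dict[tuple[str, VariantKey], ReadCounts]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["sample_id", "chrom", "pos", "ref", "alt",
              "ref_reads", "alt_reads", "depth"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out: dict[tuple[str, VariantKey], ReadCounts] = {}
    for r in df.itertuples(index=False):
        v = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        out[(r.sample_id, v)] = (int(r.ref_reads), int(r.alt_reads), int(r.depth))
    return out


def write_readcounts(readcounts: Mapping[tuple[str, VariantKey], ReadCounts],
                     path: str | Path) -> None:
    rows = sorted(
        ({"sample_id": sid, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
          "alt": v.alt, "ref_reads": rc[0], "alt_reads": rc[1], "depth": rc[2]}
         for (sid, v), rc in readcounts.items()),
        key=lambda r: (r["sample_id"], r["chrom"], r["pos"], r["ref"], r["alt"]))
    pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                                "ref_reads", "alt_reads", "depth"]
                 ).to_csv(path, sep="\t", index=False)


def load_bundles(variants_path: str | Path, samples_path: str | Path,
                 readcounts_path: str | Path | None = None
                 ) -> list[PatientBundle]:
    """Assemble PatientBundles from the three cohort-level tables."""
    calls = read_variant_table(variants_path, dialect="tsv")
    samples_df = read_samples_table(samples_path)
    readcounts = read_readcounts(readcounts_path) if readcounts_path else {}
    by_sample: dict[str, list[ObservedCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    bundles: dict[str, PatientBundle] = {}
    sample_patient: dict[str, str] = {}
    for r in samples_df.itertuples(index=False):
        bundle = bundles.setdefault(r.patient_id, PatientBundle(r.patient_id))
        bundle.samples.append(SampleProfile(
            sample_id=r.sample_id, patient_id=r.patient_id, role=r.role,
            calls=by_sample.get(r.sample_id, [])))
        sample_patient[r.sample_id] = r.patient_id
    unknown = set(by_sample) - set(sample_patient)
    if unknown:
        raise FormatError(
            f"variant table references samples absent from the samples table: "
            f"{sorted(unknown)}")
    for (sid, v), rc in readcounts.items():
        pid = sample_patient.get(sid)
        if pid is not None:
            bundles[pid].readcounts[(sid, v)] = rc
    out = list(bundles.values())
    for b in out:  # re-validate the at-most-one-PM invariant after assembly
        b.__post_init__()
    return sorted(out, key=lambda b: b.patient_id)


# --------------------------------------------------------------------------
# Report output


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_report(report, out_dir: str | Path) -> list[Path]:
    """Write the ConcordanceReport as deterministic TSV files + a JSON mirror."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    venn_rows, shared_rows, tmb_rows, screen_rows = [], [], [], []
    audit_rows, rescue_rows = [], []
    for p in sorted(report.patients, key=lambda x: x.patient_id):
        for unit, venn in (("variant", p.venn_variant), ("gene", p.venn_gene)):
            venn_rows.append({"patient": p.patient_id, "unit": unit,
                              **venn.as_dict(),
                              "n_pm": venn.n_pm, "n_pg": venn.n_pg,
                              "n_ctc": venn.n_ctc})
        for key in sorted(p.shared):
            val = p.shared[key]
            shared_rows.append({"patient": p.patient_id, "comparison": key,
                                "value": "" if val is None else f"{val:.6f}"})
        tmb_rows.append({"patient": p.patient_id,
                         "tmb_pm": "" if p.tmb_pm is None else f"{p.tmb_pm:.6f}",
                         "tmb_pg": "" if p.tmb_pg is None else f"{p.tmb_pg:.6f}",
                         "direction": p.tmb_direction or ""})
        for h in sorted(p.screen_hits,
                        key=lambda h: (h.category, h.variant.site, h.detail)):
            screen_rows.append({
                "patient": p.patient_id, "gene": h.variant.gene,
                "chrom": h.variant.chrom, "pos": h.variant.pos,
                "category": h.category, "detail": h.detail,
                "sample_roles": ",".join(h.sample_roles)})
        for a in p.audit:
            audit_rows.append({"patient": p.patient_id, "step": a.step,
                               "n_in": a.n_in, "n_removed": a.n_removed,
                               "n_out": a.n_out})
        for w in sorted(p.rescue_verdicts, key=lambda w: w.variant.site):
            rescue_rows.append({
                "patient": p.patient_id, "chrom": w.variant.chrom,
                "pos": w.variant.pos, "ref": w.variant.ref,
                "alt": w.variant.alt, "alt_reads_in_ctc": w.alt_reads_in_ctc,
                "p": "" if w.p is None else f"{w.p:.6g}",
                "decision": w.decision})

    files = {
        "venn_counts.tsv": pd.DataFrame(
            venn_rows, columns=["patient", "unit", "pm_only", "pg_only",
                                "ctc_only", "pm_pg_only", "pm_ctc_only",
                                "pg_ctc_only", "pm_pg_ctc", "n_pm", "n_pg",
                                "n_ctc"]),
        "shared_proportions.tsv": pd.DataFrame(
            shared_rows, columns=["patient", "comparison", "value"]),
        "tmb.tsv": pd.DataFrame(
            tmb_rows, columns=["patient", "tmb_pm", "tmb_pg", "direction"]),
        "screening.tsv": pd.DataFrame(
            screen_rows, columns=["patient", "gene", "chrom", "pos",
                                  "category", "detail", "sample_roles"]),
        "filter_audit.tsv": pd.DataFrame(
            audit_rows, columns=["patient", "step", "n_in", "n_removed",
                                 "n_out"]),
        "rescue_verdicts.tsv": pd.DataFrame(
            rescue_rows, columns=["patient", "chrom", "pos", "ref", "alt",
                                  "alt_reads_in_ctc", "p", "decision"]),
    }
    for name, df in files.items():
        path = out / name
        _tsv(df, path)
        written.append(path)

    if report.recurrence is not None:
        rec = report.recurrence.copy()
        rec.columns = [f"{p}:{r}" for p, r in rec.columns]
        path = out / "recurrence_matrix.tsv"
        rec.to_csv(path, sep="\t")
        written.append(path)

    mirror = {
        "config": report.config,
        "cohort": {"frac_of_pm": report.cohort_frac_of_pm,
                   "frac_of_pg": report.cohort_frac_of_pg},
        "patients": {
            p.patient_id: {
                "venn_variant": p.venn_variant.as_dict(),
                "venn_gene": p.venn_gene.as_dict(),
                "tmb_pm": p.tmb_pm, "tmb_pg": p.tmb_pg,
                "tmb_direction": p.tmb_direction,
                "shared": p.shared,
                "n_ctc_final": len(p.ctc_set),
            } for p in sorted(report.patients, key=lambda x: x.patient_id)},
        "failures": dict(sorted(report.failures.items())),
    }
    path = out / "report.json"
    path.write_text(json.dumps(mirror, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
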