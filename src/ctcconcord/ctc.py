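"""The five-step CTC variant-filtering cascade with read-backed rescue.

Pooled 10-cell CTC tubes are whole-genome amplified before exome capture,
so their raw call sets carry germline leakage, alignment artifacts in
blacklisted regions, amplification false positives shared with the WBC
controls, and allelic-dropout false negatives.  The cascade removes the
first three classes by set subtraction, requires concordance with the
patient's tumor somatic sets, and finally re-examines the read support of
tumor variants that the CTC caller missed:

1. remove variants present in the population polymorphism database;
2. remove variants inside blacklisted genomic regions;
3. remove variants called in any WBC control;
4. keep only variants also present in the PM/PG somatic sets;
5. rescue: a tumor variant absent from the CTC call set is accepted as a
   true CTC mutation when its CTC read support shows >= 4 alt reads and a
   Fisher p < 0.01 against the configured contrast; p > 0.05 indicates the
   miss is explained by coverage and the variant is removed.  Evidence in
   between (or strong p with < 4 reads) is classed indeterminate and
   excluded from the final set but reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import (
    NONSYNONYMOUS_EFFECTS,
    WBC_ROLES,
    ConfigurationError,
    IntervalSet,
    ObservedCall,
    PatientBundle,
    SampleProfile,
    SiteList,
    VariantKey,
    union_variant_sets,
)
from .somatic import FilterConfig, passes_vaf_rule
from .stats import fisher_exact


@dataclass(frozen=True)
class RescueVerdict:
    """Outcome of the rescue re-examination for one missing tumor variant."""

    variant: VariantKey
    alt_reads_in_ctc: int
    p: float | None
    decision: str  # rescued | dropped_low_coverage | indeterminate | not_assayed


@dataclass(frozen=True)
class AuditRow:
    step: str
    n_in: int
    n_removed: int
    n_out: int


def filter_population_db(calls: set[ObservedCall],
                         popdb: SiteList) -> set[ObservedCall]:
    """Filter (1): drop calls whose site is a known population polymorphism."""
    return {c for c in calls if c.variant not in popdb}


def filter_blacklist(calls: set[ObservedCall],
                     blacklist: IntervalSet) -> set[ObservedCall]:
    """Filter (2): drop calls falling inside blacklisted genomic regions."""
    return {c for c in calls
            if not blacklist.contains(c.variant.chrom, c.variant.pos)}


def filter_wbc_controls(calls: set[ObservedCall],
                        wbc_samples: Sequence[SampleProfile]) -> set[ObservedCall]:
    """Filter (3): drop calls seen in any WBC control of any type."""
    for s in wbc_samples:
        if s.role not in WBC_ROLES:
            raise ConfigurationError(
                f"sample {s.sample_id} has role {s.role}, expected a WBC role")
    seen = union_variant_sets([s.variant_set() for s in wbc_samples])
    return {c for c in calls if c.variant not in seen}


def require_tumor_concordance(
        ctc_calls: set[ObservedCall],
        tumor_sets: Sequence[set[VariantKey]]) -> set[ObservedCall]:
    """Filter (4): keep CTC calls present in at least one tumor somatic set."""
    if not tumor_sets:
        raise ConfigurationError(
            "require_tumor_concordance needs at least one tumor somatic set")
    tumor_union = union_variant_sets(tumor_sets)
    return {c for c in ctc_calls if c.variant in tumor_union}


def _classify(alt: int, p: float, config: FilterConfig) -> str:
    if alt >= config.rescue_min_alt_reads and p < config.rescue_keep_p_max:
        return "rescued"
    if p > config.rescue_drop_p_min:
        return "dropped_low_coverage"
    return "indeterminate"


def rescue_missing_variants(
    tumor_variants: Iterable[VariantKey],
    ctc_readcounts: Mapping[VariantKey, tuple[int, int]],
    contrast_readcounts: Mapping[VariantKey, tuple[int, int]],
    config: FilterConfig | None = None,
) -> list[RescueVerdict]:
    """Filter (5): one verdict per tumor variant missing from the CTC calls.

    Both readcount mappings are ``variant -> (ref_reads, alt_reads)``.  A
    variant absent from ``ctc_readcounts`` was never assayed in the CTC data
    and gets a ``not_assayed`` verdict.  A variant whose contrast site is
    absent is tested against a matched-depth zero-alt background.
    """
    config = config or FilterConfig()
    verdicts: list[RescueVerdict] = []
    for v in sorted(set(tumor_variants), key=lambda x: x.site):
        rc = ctc_readcounts.get(v)
        if rc is None:
            verdicts.append(RescueVerdict(v, 0, None, "not_assayed"))
            continue
        ref, alt = rc
        contrast = contrast_readcounts.get(v)
        if contrast is None:
            contrast = (ref + alt, 0)  # matched-depth zero-alt background
        c_ref, c_alt = contrast
        if ref + alt + c_ref + c_alt == 0:
            verdicts.append(RescueVerdict(v, alt, None, "not_assayed"))
            continue
        p = fisher_exact((alt, ref, c_alt, c_ref),
                         alternative=config.fisher_alternative)
        verdicts.append(RescueVerdict(v, alt, p, _classify(alt, p, config)))
    return verdicts


def merge_ctc_replicates(ctc_samples: Sequence[SampleProfile],
                         how: str = "union") -> set[ObservedCall]:
    """Combine replicate 10-CTC tubes into one call set.

    union (default): a variant called in any tube is kept; intersection:
    all tubes; majority: more than half.  The representative call for a
    variant is the one with the most alt reads (ties: lowest sample_id),
    so the merged set is deterministic.
    """
    if not ctc_samples:
        raise ConfigurationError("no CTC samples to merge")
    counts: Counter[VariantKey] = Counter()
    best: dict[VariantKey, ObservedCall] = {}
    for s in ctc_samples:
        for call in s.calls:
            v = call.variant
            counts[v] += 1
            cur = best.get(v)
            if cur is None or (call.alt_reads, cur.sample_id) > (cur.alt_reads, call.sample_id):
                best[v] = call
    n = len(ctc_samples)
    if how == "union":
        need = 1
    elif how == "intersection":
        need = n
    elif how == "majority":
        need = n // 2 + 1
    else:
        raise ConfigurationError(f"unknown replicate merge rule {how!r}")
    return {best[v] for v, k in counts.items() if k >= need}


def call_ctc_somatic(
    bundle: PatientBundle,
    popdb: SiteList,
    blacklist: IntervalSet,
    tumor_sets: Sequence[set[VariantKey]],
    config: FilterConfig | None = None,
) -> tuple[set[VariantKey], list[RescueVerdict], list[AuditRow]]:
    """Run the full cascade for one patient.

    Returns the final high-confidence CTC variant set, the rescue verdicts,
    and a per-step audit of input/removed/output counts.
    """
    config = config or FilterConfig()
    ctc_samples = bundle.ctc_samples
    if not ctc_samples:
        raise ConfigurationError(
            f"patient {bundle.patient_id} has no CTC sample")
    if not tumor_sets:
        raise ConfigurationError(
            f"patient {bundle.patient_id}: no tumor somatic sets for concordance")

    audit: list[AuditRow] = []

    def step(name: str, before: set, after: set) -> None:
        audit.append(AuditRow(name, len(before),
                              len(before) - len(after), len(after)))

    merged = merge_ctc_replicates(ctc_samples, config.ctc_replicate_merge)
    merged_variants = {c.variant for c in merged}
    audit.append(AuditRow("merge_replicates",
                          sum(len(s.calls) for s in ctc_samples),
                          sum(len(s.calls) for s in ctc_samples) - len(merged),
                          len(merged)))

    # The standard-WES effect/VAF rules are applied to CTC calls too; the
    # VAF rule can be switched off for WGA-distorted allele fractions.
    cur = {c for c in merged if c.variant.effect in NONSYNONYMOUS_EFFECTS}
    step("effect_filter", merged, cur)
    if config.apply_vaf_rule_to_ctc:
        nxt = {c for c in cur if c.vaf is not None and passes_vaf_rule(c, config)}
        step("vaf_filter", cur, nxt)
        cur = nxt

    nxt = filter_population_db(cur, popdb)
    step("population_db", cur, nxt)
    cur = nxt

    nxt = filter_blacklist(cur, blacklist)
    step("blacklist", cur, nxt)
    cur = nxt

    nxt = filter_wbc_controls(cur, bundle.wbc_samples)
    step("wbc_controls", cur, nxt)
    cur = nxt

    nxt = require_tumor_concordance(cur, tumor_sets)
    step("tumor_concordance", cur, nxt)
    cur = nxt

    surviving = {c.variant for c in cur}

    tumor_union = union_variant_sets(tumor_sets)
    missing = tumor_union - merged_variants
    ctc_ids = [s.sample_id for s in ctc_samples]
    if config.rescue_contrast == "wbc_background":
        oligo = [s.sample_id for s in bundle.by_role("WBC_oligo")]
        contrast_ids = oligo or [s.sample_id for s in bundle.wbc_samples]
    else:
        contrast_ids = [s.sample_id for s in bundle.by_role(
            {"PM", "PG_lung", "PG_lymph", "PG_hydrothorax"})]

    ctc_rc: dict[VariantKey, tuple[int, int]] = {}
    contrast_rc: dict[VariantKey, tuple[int, int]] = {}
    for v in missing:
        pooled = bundle.pooled_counts(ctc_ids, v)
        if pooled is not None:
            ctc_rc[v] = (pooled[0], pooled[1])
        pooled_c = bundle.pooled_counts(contrast_ids, v)
        if pooled_c is not None:
            contrast_rc[v] = (pooled_c[0], pooled_c[1])

    verdicts = rescue_missing_variants(missing, ctc_rc, contrast_rc, config)
    rescued = {w.variant for w in verdicts if w.decision == "rescued"}
    audit.append(AuditRow("rescue", len(missing),
                          len(missing) - len(rescued), len(rescued)))

    final = surviving | rescued
    audit.append(AuditRow("final", len(surviving) + len(rescued), 0, len(final)))
    return final, verdicts, audit
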