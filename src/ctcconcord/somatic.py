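"""Bulk-tumor somatic variant filtering against matched WBC, and TMB.

A tumor variant is kept as somatic when all three rules hold:

1. it is protein-altering and its VAF exceeds ``vaf_min`` (default 3%),
   or exceeds ``hotspot_vaf_min`` (default 1%) at a cancer hotspot site;
2. the tumor/normal VAF ratio exceeds ``vaf_ratio_min`` (default 5),
   with a normal VAF of zero (or an uncalled normal) treated as an
   infinite ratio;
3. the Fisher exact test of (alt, ref) reads tumor-vs-WBC gives
   p < ``fisher_p_max`` (default 0.01).

All thresholds are strict inequalities exactly as configured.  TMB is the
count of protein-altering somatic variants per megabase of coding region.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

from .model import (
    NONSYNONYMOUS_EFFECTS,
    ConfigurationError,
    ObservedCall,
    ReadCounts,
    SampleProfile,
    VariantKey,
)
from .stats import fisher_exact


@dataclass
class FilterConfig:
    """Every threshold of the filtering cascade as a named parameter."""

    vaf_min: float = 0.03
    hotspot_vaf_min: float = 0.01
    vaf_ratio_min: float = 5.0
    fisher_p_max: float = 0.01
    rescue_min_alt_reads: int = 4
    rescue_keep_p_max: float = 0.01
    rescue_drop_p_min: float = 0.05
    coding_region_mb: float = 35.0
    fisher_sidedness: str = "two_sided"          # or "one_sided"
    ratio_definition: str = "tumor_vs_normal_vaf"  # or "alt_over_ref_in_tumor"
    rescue_contrast: str = "wbc_background"        # or "tumor_literal"
    ctc_replicate_merge: str = "union"             # or "intersection", "majority"
    apply_vaf_rule_to_ctc: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.hotspot_vaf_min <= self.vaf_min < 1.0):
            raise ConfigurationError(
                "need 0 < hotspot_vaf_min <= vaf_min < 1, got "
                f"{self.hotspot_vaf_min} / {self.vaf_min}")
        if self.vaf_ratio_min <= 0:
            raise ConfigurationError("vaf_ratio_min must be positive")
        if not (0.0 < self.fisher_p_max <= 1.0):
            raise ConfigurationError("fisher_p_max must be in (0,1]")
        if self.rescue_keep_p_max > self.rescue_drop_p_min:
            raise ConfigurationError(
                "rescue_keep_p_max must not exceed rescue_drop_p_min")
        if self.coding_region_mb <= 0:
            raise ConfigurationError("coding_region_mb must be positive")
        if self.fisher_sidedness not in ("two_sided", "one_sided"):
            raise ConfigurationError(
                f"unknown fisher_sidedness {self.fisher_sidedness!r}")
        if self.ratio_definition not in ("tumor_vs_normal_vaf",
                                         "alt_over_ref_in_tumor"):
            raise ConfigurationError(
                f"unknown ratio_definition {self.ratio_definition!r}")
        if self.rescue_contrast not in ("wbc_background", "tumor_literal"):
            raise ConfigurationError(
                f"unknown rescue_contrast {self.rescue_contrast!r}")
        if self.ctc_replicate_merge not in ("union", "intersection", "majority"):
            raise ConfigurationError(
                f"unknown ctc_replicate_merge {self.ctc_replicate_merge!r}")

    @property
    def fisher_alternative(self) -> str:
        return "two-sided" if self.fisher_sidedness == "two_sided" else "greater"

    def to_dict(self) -> dict:
        return asdict(self)


def passes_vaf_rule(call: ObservedCall, config: FilterConfig) -> bool:
    """VAF > 3% rule, relaxed to > 1% at cancer hotspots; protein-altering only."""
    if call.variant.effect not in NONSYNONYMOUS_EFFECTS:
        return False
    vaf = call.vaf
    if vaf is None:
        raise ValueError(
            f"VAF undefined (no informative reads) at {call.variant.site}")
    if vaf > config.vaf_min:
        return True
    return call.variant.is_hotspot and vaf > config.hotspot_vaf_min


def passes_ratio_rule(tumor_call: ObservedCall,
                      normal_call: ObservedCall | None,
                      config: FilterConfig) -> bool:
    """Tumor/normal VAF ratio rule (default reading of "variant/reference > 5").

    With ``ratio_definition = alt_over_ref_in_tumor`` the alternative literal
    reading — alt reads over ref reads within the tumor — is used instead.
    """
    if config.ratio_definition == "alt_over_ref_in_tumor":
        if tumor_call.ref_reads == 0:
            return tumor_call.alt_reads > 0
        return tumor_call.alt_reads / tumor_call.ref_reads > config.vaf_ratio_min
    tumor_vaf = tumor_call.vaf
    if tumor_vaf is None:
        raise ValueError(
            f"VAF undefined (no informative reads) at {tumor_call.variant.site}")
    if normal_call is None:
        return True
    normal_vaf = normal_call.vaf
    if normal_vaf is None or normal_vaf == 0.0:
        return True
    return tumor_vaf / normal_vaf > config.vaf_ratio_min


def tumor_vs_normal_test(tumor_call: ObservedCall,
                         normal_counts: tuple[int, int],
                         config: FilterConfig | None = None) -> float:
    """Fisher p for (tumor alt, tumor ref) vs (normal alt, normal ref).

    ``normal_counts`` is (ref_reads, alt_reads) of the matched control.
    """
    config = config or FilterConfig()
    n_ref, n_alt = normal_counts
    return fisher_exact(
        (tumor_call.alt_reads, tumor_call.ref_reads, n_alt, n_ref),
        alternative=config.fisher_alternative,
    )


def call_tumor_somatic(
    tumor: SampleProfile,
    normal: SampleProfile,
    config: FilterConfig | None = None,
    readcounts: Mapping[tuple[str, VariantKey], ReadCounts] | None = None,
) -> set[VariantKey]:
    """Somatic variant set of one tumor sample against its WBC control.

    For tumor variants not called in the normal, the normal read support is
    looked up in ``readcounts`` (``(sample_id, variant) -> (ref, alt, depth)``).
    A site the normal never assayed passes the ratio and Fisher rules by the
    infinite-ratio convention.
    """
    if normal is None:
        raise ConfigurationError("call_tumor_somatic requires a normal sample")
    if tumor.patient_id != normal.patient_id:
        raise ConfigurationError(
            f"tumor {tumor.sample_id} and normal {normal.sample_id} "
            "belong to different patients")
    normal_calls = {c.variant: c for c in normal.calls}
    kept: set[VariantKey] = set()
    for call in tumor.calls:
        if not passes_vaf_rule(call, config or FilterConfig()):
            continue
        config = config or FilterConfig()
        normal_call = normal_calls.get(call.variant)
        if normal_call is None and readcounts is not None:
            rc = readcounts.get((normal.sample_id, call.variant))
            if rc is not None:
                normal_call = ObservedCall(
                    variant=call.variant, sample_id=normal.sample_id,
                    ref_reads=rc[0], alt_reads=rc[1], depth=rc[2])
        if not passes_ratio_rule(call, normal_call, config):
            continue
        if normal_call is None:
            # Site never assayed in the normal: no test possible; the
            # infinite-ratio convention keeps the variant.
            kept.add(call.variant)
            continue
        p = tumor_vs_normal_test(
            call, (normal_call.ref_reads, normal_call.alt_reads), config)
        if p < config.fisher_p_max:
            kept.add(call.variant)
    return kept


def compute_tmb(variants: Iterable[VariantKey] | set[VariantKey],
                config: FilterConfig | None = None) -> float:
    """Mutations per megabase of coding region (variants already filtered)."""
    config = config or FilterConfig()
    if config.coding_region_mb <= 0:
        raise ConfigurationError("coding_region_mb must be positive")
    return len(set(variants)) / config.coding_region_mb
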