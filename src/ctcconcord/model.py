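"""Domain types for tumor/CTC whole-exome variant analysis.

The unit of all set algebra is :class:`VariantKey` — the literal genomic
identity (chrom, pos, ref, alt) of a small variant.  Gene symbol, effect
class and hotspot status ride along as annotation but never enter equality
or hashing, so two samples calling the same allele always agree on identity
regardless of annotation provenance.

Coordinates are 1-based (VCF convention) everywhere except
:class:`IntervalSet`, which stores BED-style 0-based half-open intervals;
the conversion happens in exactly one place, :meth:`IntervalSet.contains`.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

#: Closed effect vocabulary.  Upstream annotator strings are mapped onto
#: these eight classes by :func:`ctcconcord.io.load_effect_map`.
EFFECTS = frozenset({
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "splicing",
    "synonymous",
    "other",
})

#: Protein-altering classes that count as "non-synonymous SNVs/Indels" for
#: filtering and TMB purposes (splicing included: it disrupts the product).
NONSYNONYMOUS_EFFECTS = frozenset({
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "splicing",
})

#: Closed sample-role vocabulary.  PM = primary specimen; PG_* = progressive
#: specimen by tissue of origin; CTC = pooled 10-cell circulating tumor cell
#: tube; WBC_oligo = pooled 10-cell white blood cell control; WBC_bulk =
#: bulk-blood white blood cell control.
ROLES = frozenset({
    "PM",
    "PG_lung",
    "PG_lymph",
    "PG_hydrothorax",
    "CTC",
    "WBC_oligo",
    "WBC_bulk",
})

PG_ROLES = frozenset({"PG_lung", "PG_lymph", "PG_hydrothorax"})
WBC_ROLES = frozenset({"WBC_oligo", "WBC_bulk"})
TUMOR_ROLES = frozenset({"PM"}) | PG_ROLES


class FormatError(ValueError):
    """Malformed input file content."""


class ConfigurationError(ValueError):
    """Invalid configuration or sample layout."""


@dataclass(frozen=True)
class VariantKey:
    """Genomic identity of a small variant plus carried annotation.

    Equality and hashing depend only on ``(chrom, pos, ref, alt)``.
    Indels are VCF-style left-anchored; no normalization is applied —
    identity is literal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = field(default="", compare=False)
    effect: str = field(default="other", compare=False)
    is_hotspot: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref and alt alleles are identical: {self.ref!r}")
        if self.effect not in EFFECTS:
            raise FormatError(f"unknown effect class {self.effect!r}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_hotspot(self, flag: bool) -> "VariantKey":
        return VariantKey(self.chrom, self.pos, self.ref, self.alt,
                          gene=self.gene, effect=self.effect, is_hotspot=flag)


@dataclass(frozen=True)
class ObservedCall:
    """A variant observed in one sample with its read support."""

    variant: VariantKey
    sample_id: str
    ref_reads: int
    alt_reads: int
    depth: int

    def __post_init__(self) -> None:
        if min(self.ref_reads, self.alt_reads, self.depth) < 0:
            raise FormatError("read counts must be non-negative")

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction, or None when no informative reads."""
        n = self.ref_reads + self.alt_reads
        if n == 0:
            return None
        return self.alt_reads / n


@dataclass
class SampleProfile:
    """All calls of one sample of one patient."""

    sample_id: str
    patient_id: str
    role: str
    calls: list[ObservedCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown sample role {self.role!r}")
        for c in self.calls:
            if c.sample_id != self.sample_id:
                raise ConfigurationError(
                    f"call {c.variant.site} carries sample_id {c.sample_id!r}, "
                    f"expected {self.sample_id!r}")

    def variant_set(self) -> set[VariantKey]:
        return {c.variant for c in self.calls}


#: readcounts value: (ref_reads, alt_reads, depth) at an assayed site.
ReadCounts = tuple[int, int, int]


@dataclass
class PatientBundle:
    """All samples of one patient plus the site-level readcount matrix.

    ``readcounts`` distinguishes "site not assayed" (absent key) from
    "assayed with zero alt reads" (present, alt == 0) — the rescue step
    depends on this distinction.
    """

    patient_id: str
    samples: list[SampleProfile] = field(default_factory=list)
    readcounts: dict[tuple[str, VariantKey], ReadCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(1 for s in self.samples if s.role == "PM") > 1:
            raise ConfigurationError(
                f"patient {self.patient_id}: more than one PM sample")

    def by_role(self, roles: Iterable[str] | str) -> list[SampleProfile]:
        if isinstance(roles, str):
            roles = {roles}
        roles = set(roles)
        return [s for s in self.samples if s.role in roles]

    @property
    def pm_sample(self) -> SampleProfile | None:
        pm = self.by_role("PM")
        return pm[0] if pm else None

    @property
    def pg_samples(self) -> list[SampleProfile]:
        return self.by_role(PG_ROLES)

    @property
    def ctc_samples(self) -> list[SampleProfile]:
        return self.by_role("CTC")

    @property
    def wbc_samples(self) -> list[SampleProfile]:
        return self.by_role(WBC_ROLES)

    def counts_at(self, sample_id: str, variant: VariantKey) -> ReadCounts | None:
        return self.readcounts.get((sample_id, variant))

    def pooled_counts(self, sample_ids: Iterable[str],
                      variant: VariantKey) -> ReadCounts | None:
        """Sum readcounts over samples that assayed the site; None if none did."""
        ref = alt = depth = 0
        seen = False
        for sid in sample_ids:
            rc = self.readcounts.get((sid, variant))
            if rc is not None:
                ref += rc[0]
                alt += rc[1]
                depth += rc[2]
                seen = True
        return (ref, alt, depth) if seen else None


class IntervalSet:
    """Per-chromosome merged, sorted 0-based half-open intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise FormatError(
                    f"interval start >= end: {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 1-based ``pos`` falls in an interval on ``chrom``."""
        if pos < 1:
            raise FormatError(f"position must be >= 1, got {pos}")
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p0 = pos - 1  # the single BED <-> 1-based conversion point
        i = bisect_right(starts, p0) - 1
        return i >= 0 and p0 < self._ends[chrom][i]

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield (chrom, s, e)


class SiteList:
    """A labelled set of exact (chrom, pos, ref, alt) identities."""

    def __init__(self, sites: Iterable[tuple[str, int, str, str]] = (),
                 label: str = "") -> None:
        self.label = label
        self._sites: frozenset[tuple[str, int, str, str]] = frozenset(sites)

    def __contains__(self, variant: VariantKey) -> bool:
        return variant.site in self._sites

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[tuple[str, int, str, str]]:
        return iter(sorted(self._sites))


@dataclass
class GeneListDB:
    """Gene-level screening resources.

    drug_map: GENE -> [(drug, association note), ...]
    pathway_map: GENE -> [(pathway name, pathway class), ...] where the class
    is "oncogenic" or "ddr".
    stem_keywords: substrings searched (after normalization) in free-text
    gene annotations.
    """

    drug_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    pathway_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    stem_keywords: list[str] = field(default_factory=lambda: ["stem cell"])

    def __post_init__(self) -> None:
        self.drug_map = {g.upper(): v for g, v in self.drug_map.items()}
        self.pathway_map = {g.upper(): v for g, v in self.pathway_map.items()}
        for entries in self.pathway_map.values():
            for _, cls in entries:
                if cls not in ("oncogenic", "ddr"):
                    raise ConfigurationError(
                        f"unknown pathway class {cls!r} (expected oncogenic/ddr)")


def union_variant_sets(sets: Iterable[set[VariantKey]]) -> set[VariantKey]:
    out: set[VariantKey] = set()
    for s in sets:
        out |= s
    return out
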