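"""Screening of variant sets against drug-gene, pathway and stem-cell lists.

Matching is gene-symbol level (case-insensitive) because the reference
lists — PharmGKB-style drug-gene relationships, the 10 canonical oncogenic
signaling pathways and 10 DNA damage repair pathway gene lists, and
free-text "stem cell" keyword annotations — are gene-keyed.  Hits are
candidates for manual curation, not curated conclusions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import ConfigurationError, GeneListDB, VariantKey

CATEGORIES = ("chemo", "stem", "oncogenic_pathway", "ddr_pathway")


@dataclass(frozen=True)
class ScreenHit:
    variant: VariantKey
    category: str
    detail: str
    sample_roles: tuple[str, ...] = ()


def _sorted_variants(variants: Iterable[VariantKey]) -> list[VariantKey]:
    return sorted(set(variants), key=lambda v: v.site)


def _roles_for(variant: VariantKey,
               roles_by_variant: Mapping[VariantKey, Iterable[str]] | None
               ) -> tuple[str, ...]:
    if roles_by_variant is None:
        return ()
    return tuple(sorted(set(roles_by_variant.get(variant, ()))))


def screen_drug_genes(
    variants: Iterable[VariantKey],
    db: GeneListDB,
    roles_by_variant: Mapping[VariantKey, Iterable[str]] | None = None,
) -> list[ScreenHit]:
    """One chemo hit per (variant, drug association) on a gene-symbol match."""
    if not db.drug_map:
        warnings.warn("drug-gene database is empty; no chemo hits possible")
    hits: list[ScreenHit] = []
    for v in _sorted_variants(variants):
        if not v.gene:
            continue
        for drug, note in db.drug_map.get(v.gene.upper(), []):
            detail = f"{drug} ({note})" if note else drug
            hits.append(ScreenHit(v, "chemo", detail, _roles_for(v, roles_by_variant)))
    return hits


def screen_pathways(
    variants: Iterable[VariantKey],
    db: GeneListDB,
    roles_by_variant: Mapping[VariantKey, Iterable[str]] | None = None,
) -> list[ScreenHit]:
    """One hit per (variant, pathway) membership, classed oncogenic or DDR."""
    hits: list[ScreenHit] = []
    for v in _sorted_variants(variants):
        if not v.gene:
            continue
        for pathway, cls in db.pathway_map.get(v.gene.upper(), []):
            if cls == "oncogenic":
                category = "oncogenic_pathway"
            elif cls == "ddr":
                category = "ddr_pathway"
            else:  # GeneListDB validates on load; guard against raw dicts
                raise ConfigurationError(f"unknown pathway class {cls!r}")
            hits.append(ScreenHit(v, category, pathway,
                                  _roles_for(v, roles_by_variant)))
    return hits


def _normalize_text(text: str) -> str:
    # "stem cell", "Stem-cell" and "stem  cell" must all match.
    return re.sub(r"\s+", " ", text.lower().replace("-", " ")).strip()


def screen_stem_keywords(
    variants: Iterable[VariantKey],
    annotations: Mapping[str, str],
    db: GeneListDB,
    roles_by_variant: Mapping[VariantKey, Iterable[str]] | None = None,
) -> list[ScreenHit]:
    """Keyword search (default "stem cell") over free-text gene annotations.

    Hits are flagged "candidate": the downstream literature check is a
    manual step outside this package.
    """
    if not db.stem_keywords:
        raise ConfigurationError("stem keyword list is empty")
    norm_annotations = {g.upper(): _normalize_text(a)
                        for g, a in annotations.items()}
    keywords = [_normalize_text(k) for k in db.stem_keywords]
    hits: list[ScreenHit] = []
    for v in _sorted_variants(variants):
        if not v.gene:
            continue
        text = norm_annotations.get(v.gene.upper())
        if text is None:
            continue
        for kw in keywords:
            if kw in text:
                hits.append(ScreenHit(v, "stem", f"candidate: {kw}",
                                      _roles_for(v, roles_by_variant)))
                break
    return hits


def screen_all(
    variants: Iterable[VariantKey],
    db: GeneListDB,
    annotations: Mapping[str, str] | None = None,
    roles_by_variant: Mapping[VariantKey, Iterable[str]] | None = None,
) -> list[ScreenHit]:
    hits = screen_drug_genes(variants, db, roles_by_variant)
    hits += screen_pathways(variants, db, roles_by_variant)
    hits += screen_stem_keywords(variants, annotations or {}, db, roles_by_variant)
    return hits
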