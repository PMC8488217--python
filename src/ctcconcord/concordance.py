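"""Per-patient and cohort set analytics over PM / PG / CTC variant sets.

The three somatic sets of a patient are compared as a 7-region Venn
partition, as pairwise shared proportions (reported under both candidate
denominators, because a "shared proportion" is ambiguous until its
denominator is fixed), as a TMB trajectory from primary to progressive
disease, and — across the cohort — as a gene recurrence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import pandas as pd

from .model import ConfigurationError, VariantKey

VENN_REGIONS = ("pm_only", "pg_only", "ctc_only", "pm_pg_only",
                "pm_ctc_only", "pg_ctc_only", "pm_pg_ctc")


class UndefinedProportionError(ZeroDivisionError):
    """A shared proportion over an empty denominator set."""


@dataclass(frozen=True)
class VennPartition:
    """Counts of the 7 disjoint regions of a 3-set Venn diagram."""

    pm_only: int
    pg_only: int
    ctc_only: int
    pm_pg_only: int
    pm_ctc_only: int
    pg_ctc_only: int
    pm_pg_ctc: int
    n_pm: int
    n_pg: int
    n_ctc: int

    @property
    def union_size(self) -> int:
        return (self.pm_only + self.pg_only + self.ctc_only
                + self.pm_pg_only + self.pm_ctc_only + self.pg_ctc_only
                + self.pm_pg_ctc)

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in VENN_REGIONS}


def venn_partition(pm: set, pg: set, ctc: set) -> VennPartition:
    """Exact 7-region partition of three sets (variants or gene symbols)."""
    return VennPartition(
        pm_only=len(pm - pg - ctc),
        pg_only=len(pg - pm - ctc),
        ctc_only=len(ctc - pm - pg),
        pm_pg_only=len((pm & pg) - ctc),
        pm_ctc_only=len((pm & ctc) - pg),
        pg_ctc_only=len((pg & ctc) - pm),
        pm_pg_ctc=len(pm & pg & ctc),
        n_pm=len(pm),
        n_pg=len(pg),
        n_ctc=len(ctc),
    )


def shared_proportion(a: set, b: set, denominator: str = "a") -> float:
    """|a ∩ b| divided by |a| or |b|.

    The asymmetry is deliberate: "fraction of CTC mutations shared with PG"
    and "fraction of PG mutations found in CTCs" are different quantities.
    """
    if denominator == "a":
        denom = a
    elif denominator == "b":
        denom = b
    else:
        raise ConfigurationError(f"denominator must be 'a' or 'b', got {denominator!r}")
    if not denom:
        raise UndefinedProportionError("shared proportion over an empty set")
    return len(a & b) / len(denom)


def cohort_shared_summary(
    patients: Sequence[tuple[set | None, set | None, set | None]],
) -> tuple[float, float]:
    """Pooled triple-overlap fractions of PM and of PG mutations.

    Each patient contributes (pm, pg, ctc); a patient missing a set (None)
    is excluded from the pools that need it.  Returns
    (sum |PM∩PG∩CTC| / sum |PM|, sum |PM∩PG∩CTC| / sum |PG|) — pooled
    counts, not a mean of per-patient ratios.
    """
    tri_pm = tri_pg = pool_pm = pool_pg = 0
    for pm, pg, ctc in patients:
        if pm is not None and pg is not None and ctc is not None:
            tri = len(pm & pg & ctc)
        else:
            tri = None
        if pm is not None:
            pool_pm += len(pm)
            if tri is not None:
                tri_pm += tri
        if pg is not None:
            pool_pg += len(pg)
            if tri is not None:
                tri_pg += tri
    if pool_pm == 0 and pool_pg == 0:
        raise UndefinedProportionError(
            "no patient contributed a PM or PG set to the cohort pools")
    frac_pm = tri_pm / pool_pm if pool_pm else float("nan")
    frac_pg = tri_pg / pool_pg if pool_pg else float("nan")
    return frac_pm, frac_pg


def tmb_change(pm_tmb: float, pg_tmb: float) -> str:
    """Direction of the TMB trajectory from primary to progressive disease."""
    if pg_tmb > pm_tmb:
        return "increased"
    if pg_tmb < pm_tmb:
        return "decreased"
    return "unchanged"


def recurrence_matrix(
    patient_role_sets: Iterable[tuple[str, str, set[VariantKey]]],
    top_n: int = 40,
) -> pd.DataFrame:
    """Binary gene x (patient, role) presence matrix for the top genes.

    ``patient_role_sets`` yields (patient_id, role, variant set) cells.
    Genes are ranked by the number of cells in which they are mutated,
    ties broken lexicographically by symbol; the top ``top_n`` rows are
    returned.  Variants with an empty gene symbol are ignored.
    """
    if top_n < 1:
        raise ConfigurationError(f"top_n must be >= 1, got {top_n}")
    cells: list[tuple[str, str]] = []
    presence: dict[str, set[tuple[str, str]]] = {}
    for patient_id, role, variants in patient_role_sets:
        cell = (patient_id, role)
        cells.append(cell)
        for v in variants:
            if v.gene:
                presence.setdefault(v.gene.upper(), set()).add(cell)
    ranked = sorted(presence, key=lambda g: (-len(presence[g]), g))[:top_n]
    columns = pd.MultiIndex.from_tuples(
        sorted(set(cells)), names=["patient", "role"])
    data = [[int(cell in presence[g]) for cell in columns] for g in ranked]
    return pd.DataFrame(data, index=pd.Index(ranked, name="gene"),
                        columns=columns, dtype=int)


@dataclass
class PatientReport:
    """Everything the pipeline computed for one patient."""

    patient_id: str
    pm_set: set[VariantKey] | None
    pg_set: set[VariantKey] | None
    ctc_set: set[VariantKey]
    venn_variant: VennPartition
    venn_gene: VennPartition
    tmb_pm: float | None
    tmb_pg: float | None
    tmb_direction: str | None
    shared: dict[str, float | None] = field(default_factory=dict)
    screen_hits: list = field(default_factory=list)
    audit: list = field(default_factory=list)
    rescue_verdicts: list = field(default_factory=list)


@dataclass
class ConcordanceReport:
    """Cohort-level pipeline output."""

    patients: list[PatientReport] = field(default_factory=list)
    cohort_frac_of_pm: float | None = None
    cohort_frac_of_pg: float | None = None
    recurrence: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
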