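"""The multi-stage variant filter cascade and its funnel report.

The cascade prioritizes candidate germline variants in multiplex families:
(a) drop common variants (population MAF above a rarity threshold),
(b) keep protein-altering exonic variants plus near-exon splice-region
variants, (c) require read-level support (allelic fraction of the
alternate allele in at least one affected carrier), (d) keep variants that
are computationally deleterious (CADD phred) and/or clinically suspicious
(ACMG ordinal class), and optionally restrict to genes previously
associated with the phenotype. Each stage is a pure predicate, so the
final survivor set is invariant to stage order; counts are reported per
stage in the funnel layout familiar from cohort-study summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .models import (
    NONSYNONYMOUS_EXONIC,
    AnnotationRecord,
    Consequence,
    GenotypeMatrix,
    GT_ALT_ALT,
    GT_REF_ALT,
    Pedigree,
    Variant,
)


class ConfigError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds of the cascade.

    maf_max:
        rarity cutoff; records with population MAF above it are removed.
        A missing MAF means the variant is novel and always passes.
    novel_only:
        when True keep only novel (MAF missing or exactly 0) variants —
        the stricter first-pass rarity rule, relaxable to ``maf_max``.
    splice_window:
        bases around exons within which non-protein-altering variants are
        retained (valid 20-30).
    af_min:
        minimum alternate-allele read fraction required in at least one
        affected carrier.
    cadd_min, acmg_min, rescue_mode:
        deleteriousness stage; ``either`` keeps a variant passing the CADD
        or the ACMG clause, ``both`` requires both.
    """

    maf_max: float = 0.001
    novel_only: bool = False
    splice_window: int = 30
    af_min: float = 0.30
    cadd_min: float = 20.0
    acmg_min: int = 3
    rescue_mode: str = "either"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_max <= 1.0:
            raise ConfigError(f"maf_max {self.maf_max} outside [0, 1]")
        if not (20 <= self.splice_window <= 30 or math.isinf(self.splice_window)):
            raise ConfigError(f"splice_window {self.splice_window} outside 20-30")
        if not 0.0 <= self.af_min <= 1.0:
            raise ConfigError(f"af_min {self.af_min} outside [0, 1]")
        if self.acmg_min not in range(1, 6):
            raise ConfigError(f"acmg_min {self.acmg_min} not in 1..5")
        if self.rescue_mode not in {"either", "both"}:
            raise ConfigError(f"rescue_mode must be 'either' or 'both'")


#: Stage keys in execution order (rarity, consequence, read support,
#: deleteriousness); segregation stages are appended by the pipeline.
STAGE_ORDER = [
    "total",
    "maf_le_threshold",
    "maf_eq_0",
    "nonsynonymous_exonic_splicing",
    "allelic_fraction",
    "cadd_acmg",
    "pedigree_filtered",
    "segregating",
]

#: Column labels used when the funnel is written in the familiar
#: summary-table layout (rarity before consequence is presentational).
FUNNEL_TABLE_COLUMNS = {
    "total": "Total Variants",
    "nonsynonymous_exonic_splicing": "Total Nonsynonymous Exonic and Splicing Variants",
    "maf_le_threshold": "Total of Rare Variants MAF <= 0.001",
    "maf_eq_0": "Total of Rare Variants MAF = 0",
    "pedigree_filtered": "Pedigree Filtering",
    "cadd_acmg": "Total Variants with CADD >= 20 and/or ACMG Class >= 3",
    "segregating": "Segregating Variants",
}


@dataclass
class FunnelReport:
    """Per-family survivor counts and ids after each cascade stage."""

    family_id: str
    counts: dict[str, int] = field(default_factory=dict)
    survivors: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, variant_ids: list[str]) -> None:
        self.counts[stage] = len(variant_ids)
        self.survivors[stage] = list(variant_ids)

    @property
    def executed_stages(self) -> list[str]:
        return [s for s in STAGE_ORDER if s in self.counts]


# ---------------------------------------------------------------------------
# individual stage predicates
# ---------------------------------------------------------------------------

def passes_maf(record: AnnotationRecord, cfg: FilterConfig) -> bool:
    if record.maf is None:
        return True
    if not 0.0 <= record.maf <= 1.0:
        raise ValueError(f"{record.variant_id}: maf {record.maf} outside [0, 1]")
    if cfg.novel_only:
        return record.maf == 0.0
    return record.maf <= cfg.maf_max


def filter_by_maf(records: list[AnnotationRecord], cfg: FilterConfig) -> list[AnnotationRecord]:
    """Rarity filter: drop records whose population MAF exceeds the cutoff."""
    return [r for r in records if passes_maf(r, cfg)]


def passes_consequence(variant: Variant, cfg: FilterConfig) -> bool:
    if variant.consequence in NONSYNONYMOUS_EXONIC:
        return True
    # exonic synonymous changes are removed outright; the splice-window
    # exception rescues only variants flanking an exon
    if variant.consequence is Consequence.SYNONYMOUS:
        return False
    return variant.distance_to_exon <= cfg.splice_window


def filter_by_consequence(variants: list[Variant], cfg: FilterConfig) -> list[Variant]:
    """Keep protein-altering exonic variants and near-exon splice variants."""
    return [v for v in variants if passes_consequence(v, cfg)]


def passes_allelic_fraction(
    variant_id: str,
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: FilterConfig,
) -> tuple[bool, bool]:
    """Return (keep, af_unassessed) for one variant.

    Kept iff at least one sequenced affected carrier shows an alternate
    allelic fraction >= af_min. Variants with no usable depth in any
    affected carrier are kept but flagged unassessed rather than dropped.
    """
    if not genotypes.has_variant(variant_id):
        return True, True
    any_assessed = False
    for m in pedigree.members:
        if m.affected is not True or not m.sequenced:
            continue
        if m.individual_id not in genotypes.sample_ids:
            continue
        gt = genotypes.genotype(variant_id, m.individual_id)
        if gt not in (GT_REF_ALT, GT_ALT_ALT):
            continue
        af = genotypes.allelic_fraction(variant_id, m.individual_id)
        if af is None:
            continue
        any_assessed = True
        if af >= cfg.af_min:
            return True, False
    if not any_assessed:
        return True, True
    return False, False


def filter_by_allelic_fraction(
    variants: list[Variant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: FilterConfig,
) -> list[Variant]:
    kept = []
    for v in variants:
        keep, _ = passes_allelic_fraction(v.variant_id, genotypes, pedigree, cfg)
        if keep:
            kept.append(v)
    return kept


def passes_cadd_acmg(record: AnnotationRecord, cfg: FilterConfig) -> bool:
    cadd_ok = record.cadd_phred is not None and record.cadd_phred >= cfg.cadd_min
    acmg_ok = record.acmg_class is not None and record.acmg_class >= cfg.acmg_min
    if cfg.rescue_mode == "either":
        return cadd_ok or acmg_ok
    return cadd_ok and acmg_ok


def filter_by_cadd_acmg(records: list[AnnotationRecord], cfg: FilterConfig) -> list[AnnotationRecord]:
    """Deleteriousness filter on CADD phred and the ACMG ordinal class."""
    return [r for r in records if passes_cadd_acmg(r, cfg)]


def restrict_to_known_genes(
    records: list[AnnotationRecord], gene_set: set[str]
) -> list[AnnotationRecord]:
    """Keep records in previously phenotype-associated genes.

    Also stamps ``known_tc_gene`` on every input record (case-insensitive
    symbol match), so callers can stratify afterwards.
    """
    if not gene_set:
        raise ConfigError("known-gene restriction requires a non-empty gene set")
    upper = {g.upper() for g in gene_set}
    for r in records:
        r.known_tc_gene = r.gene.upper() in upper
    return [r for r in records if r.known_tc_gene]


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_cascade(
    variants: list[Variant],
    records: list[AnnotationRecord],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: FilterConfig | None = None,
) -> FunnelReport:
    """Run stages (rarity, consequence, read support, CADD/ACMG) in order.

    Returns a funnel report whose ``survivors['cadd_acmg']`` list is the
    input handed to segregation. Both the MAF <= threshold count and the
    MAF = 0 count are recorded (summary tables conventionally report
    both), but only the configured rarity rule removes variants.
    """
    cfg = cfg or FilterConfig()
    by_id_v = {v.variant_id: v for v in variants}
    by_id_r = {r.variant_id: r for r in records}
    orphans = set(by_id_v) ^ set(by_id_r)
    if orphans:
        raise ValueError(
            "variant/annotation tables are inconsistent; orphan ids: "
            + ", ".join(sorted(orphans)[:10])
        )
    report = FunnelReport(pedigree.family_id)
    ids = [v.variant_id for v in variants]
    report.record("total", ids)

    # (a) rarity
    ids = [i for i in ids if passes_maf(by_id_r[i], cfg)]
    report.record("maf_le_threshold", ids)
    report.record(
        "maf_eq_0",
        [i for i in ids if by_id_r[i].maf is None or by_id_r[i].maf == 0.0],
    )
    # (b) consequence
    ids = [i for i in ids if passes_consequence(by_id_v[i], cfg)]
    report.record("nonsynonymous_exonic_splicing", ids)
    # (c) read support
    kept = []
    for i in ids:
        keep, unassessed = passes_allelic_fraction(i, genotypes, pedigree, cfg)
        if keep:
            if unassessed:
                by_id_r[i].flags.add("af_unassessed")
            kept.append(i)
    ids = kept
    report.record("allelic_fraction", ids)
    # (d) deleteriousness
    ids = [i for i in ids if passes_cadd_acmg(by_id_r[i], cfg)]
    report.record("cadd_acmg", ids)
    return report


def funnel_table(reports: list[FunnelReport]) -> "pd.DataFrame":
    """Funnel counts as one row per family in the summary-table layout."""
    import pandas as pd

    rows = []
    for rep in reports:
        row = {"Family ID": rep.family_id}
        for stage, label in FUNNEL_TABLE_COLUMNS.items():
            if stage in rep.counts:
                row[label] = rep.counts[stage]
        rows.append(row)
    return pd.DataFrame(rows)
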