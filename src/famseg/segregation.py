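"""Pedigree-based segregation filtering under a dominant model.

A variant segregates with the disease when every genotyped affected
individual carries it (heterozygous or homozygous) and at most a tolerated
number of genotyped unaffected individuals carry it. The one-unaffected-
carrier tolerance reflects incomplete penetrance: a single healthy carrier
is compatible with a dominant susceptibility allele, several are not.
Homozygous-reference unaffected relatives never count against a variant.

Two entry points mirror the two stages of a family study: a prefilter on
the exome-sequenced subset of each family (typically two or more cases and
one unaffected relative), and a full-family re-assessment once every
member with available DNA has been genotyped at the candidate sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .models import (
    GT_ALT_ALT,
    GT_MISSING,
    GT_REF_ALT,
    GT_REF_REF,
    GenotypeMatrix,
    Pedigree,
)

logger = logging.getLogger(__name__)

CARRIER_CODES = (GT_REF_ALT, GT_ALT_ALT)


@dataclass
class SegregationConfig:
    model: str = "dominant"
    max_unaffected_carriers: int = 1
    min_genotyped_affected: int = 2
    treat_missing_affected: str = "ignore"  # or "fail"

    def __post_init__(self) -> None:
        if self.model != "dominant":
            raise ValueError("only the dominant model is implemented")
        if self.max_unaffected_carriers < 0:
            raise ValueError("max_unaffected_carriers must be >= 0")
        if self.min_genotyped_affected < 1:
            raise ValueError("min_genotyped_affected must be >= 1")
        if self.treat_missing_affected not in {"fail", "ignore"}:
            raise ValueError("treat_missing_affected must be 'fail' or 'ignore'")


@dataclass
class SegregationVerdict:
    variant_id: str
    family_id: str
    segregates: bool
    n_affected_carriers: int
    n_affected_genotyped: int
    n_unaffected_carriers: int
    reason: str  # ok | missing_in_affected | too_many_unaffected_carriers | insufficient_data

    def __post_init__(self) -> None:
        assert not (self.segregates and self.reason != "ok")


def assess_segregation(
    variant_id: str,
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: SegregationConfig | None = None,
) -> SegregationVerdict:
    """Judge one variant against the dominant segregation rule.

    Individuals with unknown phenotype are excluded from both criteria.
    Affected individuals without a genotype are, by default, dropped from
    the "carried by all affecteds" universe rather than counted as
    counter-evidence (absence of data is not a reference call).
    """
    cfg = cfg or SegregationConfig()
    n_aff_genotyped = 0
    n_aff_carriers = 0
    missing_in_affected = False
    n_unaff_carriers = 0
    present = genotypes.has_variant(variant_id)
    for m in pedigree.members:
        if m.affected is None or m.individual_id not in genotypes.sample_ids:
            continue
        gt = genotypes.genotype(variant_id, m.individual_id) if present else GT_MISSING
        if m.affected:
            if gt == GT_MISSING:
                if cfg.treat_missing_affected == "fail":
                    missing_in_affected = True
                continue
            n_aff_genotyped += 1
            if gt in CARRIER_CODES:
                n_aff_carriers += 1
            else:
                missing_in_affected = True
        else:
            if gt in CARRIER_CODES:
                n_unaff_carriers += 1

    def verdict(segregates: bool, reason: str) -> SegregationVerdict:
        return SegregationVerdict(
            variant_id=variant_id,
            family_id=pedigree.family_id,
            segregates=segregates,
            n_affected_carriers=n_aff_carriers,
            n_affected_genotyped=n_aff_genotyped,
            n_unaffected_carriers=n_unaff_carriers,
            reason=reason,
        )

    if n_aff_genotyped < cfg.min_genotyped_affected:
        return verdict(False, "insufficient_data")
    if missing_in_affected or n_aff_carriers < n_aff_genotyped:
        return verdict(False, "missing_in_affected")
    if n_unaff_carriers > cfg.max_unaffected_carriers:
        return verdict(False, "too_many_unaffected_carriers")
    return verdict(True, "ok")


def pedigree_prefilter(
    survivor_ids: list[str],
    genotypes_wes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: SegregationConfig | None = None,
) -> list[str]:
    """Segregation on the sequenced family subset; returns surviving ids.

    Families with fewer genotyped affecteds than required pass all their
    variants through (verdict ``insufficient_data``) with a warning —
    an under-sequenced family cannot refute segregation.
    """
    cfg = cfg or SegregationConfig()
    sequenced = [m.individual_id for m in pedigree.members if m.sequenced]
    matrix = genotypes_wes.subset_samples(sequenced)
    kept: list[str] = []
    warned = False
    for vid in survivor_ids:
        v = assess_segregation(vid, matrix, pedigree, cfg)
        if v.segregates:
            kept.append(vid)
        elif v.reason == "insufficient_data":
            if not warned:
                logger.warning(
                    "%s: fewer than %d genotyped affected individuals; "
                    "pedigree prefilter passes all variants unassessed",
                    pedigree.family_id,
                    cfg.min_genotyped_affected,
                )
                warned = True
            kept.append(vid)
    return kept


def full_family_segregation(
    survivor_ids: list[str],
    genotypes_all: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: SegregationConfig | None = None,
) -> list[SegregationVerdict]:
    """Re-assess survivors on the complete family genotype matrix.

    This models the confirmation stage in which candidate sites are typed
    in every family member with available DNA; extending the genotyped set
    can only eliminate candidates, never rescue them.
    """
    cfg = cfg or SegregationConfig()
    return [
        assess_segregation(vid, genotypes_all, pedigree, cfg)
        for vid in survivor_ids
    ]
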