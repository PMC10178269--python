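"""Synthetic multi-family exome datasets with known ground truth.

Emulates the statistical structure a pedigree-based rare-variant study
assumes: an autosomal-dominant susceptibility allele with incomplete
penetrance spiked into one founder per family, Mendelian gene dropping of
that allele and of rare/common background variation, read-depth and
allelic-fraction models for heterozygous calls, and annotation-score
distributions with the tool-specific missingness pattern typical of
truncating variants (substitution-scoring predictors return nothing).

Every draw flows from one :class:`numpy.random.Generator`, so a fixed
seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_annotation_table, write_ped, write_vcf
from .models import (
    GT_ALT_ALT,
    GT_MISSING,
    GT_REF_ALT,
    GT_REF_REF,
    AnnotationRecord,
    Consequence,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PredictorCell,
    TRUNCATING,
    Variant,
)

# tools that score amino-acid substitutions and hence usually return no
# prediction for truncating (nonsense/frameshift) variants
SUBSTITUTION_TOOLS = ("SIFT", "PolyPhen2", "MutationAssessor", "FATHMM")


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study-design and generative parameters of the simulator.

    Defaults describe a multiplex autosomal-dominant family study: ~18
    families of 2+ affected members, penetrance 0.9, rare phenocopies,
    exome-scale background variation dominated by common polymorphism,
    150x mean coverage, and symmetric Beta(20, 20) allelic fractions for
    heterozygous calls (mean 0.5, sd ~ 0.078).
    """

    n_families: int = 18
    pedigree_template: str = "three_generation"  # or nuclear_extended
    n_affected_target: int = 3
    penetrance: float = 0.9
    phenocopy_rate: float = 0.01
    n_background_variants: int = 5000
    # population-frequency mixture of background variants
    maf_weights: tuple[float, float, float] = (0.70, 0.20, 0.10)  # common, rare, novel
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    rare_maf_range: tuple[float, float] = (0.0001, 0.001)
    # causal-variant annotation profile
    causal_truncating_prob: float = 0.2
    causal_cadd_mean: float = 30.0
    causal_cadd_sd: float = 3.0
    causal_cadd_floor: float = 20.0
    causal_damaging_prob: float = 0.9
    causal_acmg_probs: tuple[float, ...] = (0.0, 0.0, 0.4, 0.4, 0.2)  # classes 1..5
    # background annotation profile: CADD mixture favoring sub-threshold
    background_damaging_prob: float = 0.15
    background_cadd_high_weight: float = 0.15
    background_acmg_probs: tuple[float, ...] = (0.30, 0.35, 0.30, 0.04, 0.01)
    # sequencing model
    het_af_beta: tuple[float, float] = (20.0, 20.0)
    depth_mean: float = 150.0
    missing_tool_prob: float = 0.9  # substitution tools on truncating variants
    n_unaffected_sequenced: int = 1
    max_pedigree_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.penetrance, self.phenocopy_rate, self.causal_damaging_prob,
                  self.background_damaging_prob, self.missing_tool_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.maf_weights) - 1.0) > 1e-9:
            raise ValueError("maf_weights must sum to 1")
        if self.pedigree_template not in {"three_generation", "nuclear_extended"}:
            raise ValueError(f"unknown template {self.pedigree_template!r}")


@dataclass
class SimulatedTruth:
    """Ground truth for one simulated family."""

    family_id: str
    causal_variant_id: str
    founder_carrier: str
    carriers: set[str]
    mechanism: dict[str, str]  # affected individual -> genetic | phenocopy

    def to_json(self) -> dict:
        return {
            "family_id": self.family_id,
            "causal_variant_id": self.causal_variant_id,
            "founder_carrier": self.founder_carrier,
            "carriers": sorted(self.carriers),
            "mechanism": dict(sorted(self.mechanism.items())),
        }


@dataclass
class FamilyDataset:
    pedigree: Pedigree
    variants: list[Variant]
    genotypes: GenotypeMatrix  # all family members
    annotations: list[AnnotationRecord]
    truth: SimulatedTruth


# ---------------------------------------------------------------------------
# pedigree structure
# ---------------------------------------------------------------------------

def _template_members(template: str, fam: str) -> list[tuple[str, str | None, str | None, int]]:
    """(id, father, mother, sex) rows; parents precede children."""
    if template == "nuclear_extended":
        rows = [
            (f"{fam}_I1", None, None, 1),
            (f"{fam}_I2", None, None, 2),
            (f"{fam}_II1", f"{fam}_I1", f"{fam}_I2", 1),
            (f"{fam}_II2", f"{fam}_I1", f"{fam}_I2", 2),
            (f"{fam}_II3", f"{fam}_I1", f"{fam}_I2", 1),
            (f"{fam}_II4", f"{fam}_I1", f"{fam}_I2", 2),
            (f"{fam}_II1s", None, None, 2),
            (f"{fam}_III1", f"{fam}_II1", f"{fam}_II1s", 1),
            (f"{fam}_III2", f"{fam}_II1", f"{fam}_II1s", 2),
        ]
    else:  # three_generation
        rows = [
            (f"{fam}_I1", None, None, 1),
            (f"{fam}_I2", None, None, 2),
        ]
        for c in range(1, 4):
            child_sex = 1 if c % 2 else 2
            spouse_sex = 2 if child_sex == 1 else 1
            rows.append((f"{fam}_II{c}", f"{fam}_I1", f"{fam}_I2", child_sex))
            rows.append((f"{fam}_II{c}s", None, None, spouse_sex))
        for c in range(1, 4):
            father = f"{fam}_II{c}" if c % 2 else f"{fam}_II{c}s"
            mother = f"{fam}_II{c}s" if c % 2 else f"{fam}_II{c}"
            for g in range(1, 3):
                rows.append((f"{fam}_III{c}{g}", father, mother, 1 if g % 2 else 2))
    return rows


def _drop_column(
    rows: list[tuple[str, str | None, str | None, int]],
    founder_genotypes: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Mendelian transmission of one variant through a member list."""
    gts: dict[str, int] = {}
    for iid, father, mother, _sex in rows:
        if father is None and mother is None:
            gts[iid] = founder_genotypes.get(iid, GT_REF_REF)
        else:
            alleles = 0
            for parent in (father, mother):
                pg = gts[parent]
                if pg == GT_ALT_ALT:
                    alleles += 1
                elif pg == GT_REF_ALT:
                    alleles += int(rng.integers(0, 2))
            gts[iid] = alleles
    return gts


def simulate_pedigree(
    cfg: SimulationConfig, rng: np.random.Generator, family_id: str = "FAM1"
) -> tuple[Pedigree, SimulatedTruth]:
    """Build one family carrying a dominant susceptibility allele.

    One member of the founder couple is a heterozygous carrier; the allele
    is gene-dropped; carriers become affected with probability
    ``penetrance`` and non-carriers with ``phenocopy_rate``. The draw is
    repeated (bounded) until the family reaches ``n_affected_target``
    affected members — the ascertainment condition of a multiplex study.
    """
    rows = _template_members(cfg.pedigree_template, family_id)
    founder_couple = [rows[0][0], rows[1][0]]
    for _ in range(cfg.max_pedigree_retries):
        carrier_founder = founder_couple[int(rng.integers(0, 2))]
        gts = _drop_column(rows, {carrier_founder: GT_REF_ALT}, rng)
        carriers = {iid for iid, g in gts.items() if g in (GT_REF_ALT, GT_ALT_ALT)}
        affected: dict[str, bool] = {}
        mechanism: dict[str, str] = {}
        for iid, *_ in rows:
            if iid in carriers:
                if rng.random() < cfg.penetrance:
                    affected[iid] = True
                    mechanism[iid] = "genetic"
                else:
                    affected[iid] = False
            else:
                if rng.random() < cfg.phenocopy_rate:
                    affected[iid] = True
                    mechanism[iid] = "phenocopy"
                else:
                    affected[iid] = False
        if sum(affected.values()) < cfg.n_affected_target:
            continue
        # sequencing design: every case plus a limited number of relatives
        unaffected_ids = [iid for iid, *_ in rows if not affected[iid]]
        perm = rng.permutation(len(unaffected_ids))
        seq_unaffected = {unaffected_ids[i] for i in perm[: cfg.n_unaffected_sequenced]}
        members = [
            Individual(
                individual_id=iid,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affected=affected[iid],
                sequenced=affected[iid] or iid in seq_unaffected,
            )
            for iid, father, mother, sex in rows
        ]
        truth = SimulatedTruth(
            family_id=family_id,
            causal_variant_id=f"{family_id}_causal",
            founder_carrier=carrier_founder,
            carriers=carriers,
            mechanism=mechanism,
        )
        return Pedigree(family_id, members), truth
    raise SimulationError(
        f"{family_id}: could not reach {cfg.n_affected_target} affected members "
        f"in {cfg.max_pedigree_retries} draws; consider higher penetrance"
    )


def gene_drop(
    pedigree: Pedigree,
    maf_or_founders: float | dict[str, int],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Drop one variant through a pedigree; returns id -> genotype code.

    ``maf_or_founders`` is either a population allele frequency (founder
    genotypes drawn from Hardy-Weinberg) or an explicit founder genotype
    assignment (unlisted founders are homozygous reference). No de novo
    events are generated.
    """
    rows = [(m.individual_id, m.father_id, m.mother_id, m.sex)
            for m in pedigree.topological_order()]
    if isinstance(maf_or_founders, dict):
        founders = maf_or_founders
    else:
        maf = float(maf_or_founders)
        founders = {}
        for m in pedigree.founders():
            founders[m.individual_id] = int(rng.binomial(1, maf) + rng.binomial(1, maf))
    return _drop_column(rows, founders, rng)


# ---------------------------------------------------------------------------
# genotype matrix with depths
# ---------------------------------------------------------------------------

def _genotype_matrix(
    pedigree: Pedigree,
    variant_ids: list[str],
    mafs: list[float],
    causal_column: dict[str, int] | None,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    members = pedigree.topological_order()
    sample_ids = [m.individual_id for m in members]
    n_v, n_s = len(variant_ids), len(sample_ids)
    gt = np.zeros((n_v, n_s), dtype=np.int8)
    # founders from Hardy-Weinberg, children by transmission (vectorized
    # over variants, member by member in pedigree order)
    col = {s: j for j, s in enumerate(sample_ids)}
    maf_arr = np.asarray(mafs)
    for m in members:
        j = col[m.individual_id]
        if m.father_id is None and m.mother_id is None:
            gt[:, j] = rng.binomial(1, maf_arr) + rng.binomial(1, maf_arr)
        else:
            alleles = np.zeros(n_v, dtype=np.int8)
            for parent in (m.father_id, m.mother_id):
                pg = gt[:, col[parent]]
                transmitted = np.where(
                    pg == 2, 1, np.where(pg == 1, rng.integers(0, 2, size=n_v), 0)
                )
                alleles += transmitted.astype(np.int8)
            gt[:, j] = alleles
    if causal_column is not None:
        gt[0, :] = [causal_column[s] for s in sample_ids]
    # read depths
    dp = rng.poisson(cfg.depth_mean, size=(n_v, n_s)).astype(np.int64)
    dp = np.maximum(dp, 1)
    alpha, beta = cfg.het_af_beta
    het_p = rng.beta(alpha, beta, size=(n_v, n_s))
    p = np.where(gt == GT_REF_ALT, het_p, np.where(gt == GT_ALT_ALT, 0.999, 0.001))
    ad_alt = rng.binomial(dp, p)
    ad_ref = dp - ad_alt
    return GenotypeMatrix(variant_ids, sample_ids, gt,
                          ad_ref.astype(np.int32), ad_alt.astype(np.int32))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_TOOL_LABELS = {
    # tool -> (damaging label/score sampler, tolerated label/score sampler)
    "SIFT": (("D", 0.0, 0.05), ("T", 0.06, 1.0)),
    "PolyPhen2": (("PD", 0.85, 1.0), ("B", 0.0, 0.84)),
    "LoFtool": (("PD", 0.001, 0.5), ("B", 0.501, 0.999)),
    "MutationAssessor": (("M", 1.9, 4.5), ("L", 0.0, 1.89)),
    "MutationTaster": (("DC", 0.9, 1.0), ("P", 0.0, 0.49)),
    "FATHMM": (("D", -5.0, -1.5), ("T", -1.49, 5.0)),
}


def _sample_cell(tool: str, damaging: bool, rng: np.random.Generator) -> PredictorCell:
    label, lo, hi = _TOOL_LABELS[tool][0 if damaging else 1]
    score = round(float(rng.uniform(lo, hi)), 3)
    if tool == "MutationAssessor" and damaging and score > 3.5:
        label = "H"
    return PredictorCell(label=label, score=score)


def simulate_annotations(
    variants: list[Variant],
    causal_ids: set[str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mafs: dict[str, float | None],
    family_id: str = "",
) -> list[AnnotationRecord]:
    """Draw per-variant annotation records from the causal or background
    profile; truncating variants lose substitution-tool predictions with
    the configured probability."""
    records = []
    for v in variants:
        causal = v.variant_id in causal_ids
        if causal:
            cadd = -1.0
            while cadd < cfg.causal_cadd_floor:
                cadd = float(rng.normal(cfg.causal_cadd_mean, cfg.causal_cadd_sd))
            acmg = 1 + int(rng.choice(5, p=cfg.causal_acmg_probs))
            p_damaging = cfg.causal_damaging_prob
        else:
            if rng.random() < cfg.background_cadd_high_weight:
                cadd = float(np.clip(rng.normal(23.0, 3.0), 0.0, None))
            else:
                cadd = float(np.clip(rng.normal(10.0, 5.0), 0.0, None))
            acmg = 1 + int(rng.choice(5, p=cfg.background_acmg_probs))
            p_damaging = cfg.background_damaging_prob
        cadd = round(cadd, 1)
        tool_scores: dict[str, PredictorCell] = {"CADD": PredictorCell(score=cadd)}
        truncating = v.consequence in TRUNCATING
        for tool in _TOOL_LABELS:
            if (
                truncating
                and tool in SUBSTITUTION_TOOLS
                and rng.random() < cfg.missing_tool_prob
            ):
                continue
            tool_scores[tool] = _sample_cell(tool, rng.random() < p_damaging, rng)
        records.append(
            AnnotationRecord(
                variant_id=v.variant_id,
                gene=v.gene,
                family_id=family_id,
                maf=mafs[v.variant_id],
                cadd_phred=cadd,
                acmg_class=acmg,
                tool_scores=tool_scores,
                consequence=v.consequence,
            )
        )
    return records


# ---------------------------------------------------------------------------
# whole families and datasets
# ---------------------------------------------------------------------------

_CSQ_MIX = [
    (Consequence.MISSENSE, 0.45),
    (Consequence.SYNONYMOUS, 0.25),
    (Consequence.NONCODING, 0.15),
    (Consequence.SPLICE_REGION, 0.07),
    (Consequence.NONSENSE, 0.03),
    (Consequence.FRAMESHIFT, 0.03),
    (Consequence.INFRAME_INDEL, 0.02),
]

_BASES = np.array(list("ACGT"))


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def simulate_family(
    cfg: SimulationConfig, rng: np.random.Generator, family_id: str
) -> FamilyDataset:
    """One family: pedigree, spiked causal variant, background variation,
    genotypes with depths, and annotation records."""
    pedigree, truth = simulate_pedigree(cfg, rng, family_id)
    causal_gts = {
        m.individual_id: (GT_REF_ALT if m.individual_id in truth.carriers else GT_REF_REF)
        for m in pedigree.members
    }

    variants: list[Variant] = []
    mafs_list: list[float] = []
    maf_map: dict[str, float | None] = {}
    causal_truncating = rng.random() < cfg.causal_truncating_prob
    ref, alt = _random_snv(rng)
    causal = Variant(
        variant_id=truth.causal_variant_id,
        chrom=f"chr{int(rng.integers(1, 23))}",
        pos=int(rng.integers(10_000, 50_000_000)),
        ref=ref,
        alt=alt if not causal_truncating else ref + "A" if ref != "A" else ref + "C",
        gene=f"GENE_{family_id}_C",
        consequence=Consequence.NONSENSE if causal_truncating else Consequence.MISSENSE,
    )
    variants.append(causal)
    mafs_list.append(0.0)
    maf_map[causal.variant_id] = None  # novel

    csq_values = [c for c, _ in _CSQ_MIX]
    csq_probs = [p for _, p in _CSQ_MIX]
    categories = rng.choice(3, size=cfg.n_background_variants, p=list(cfg.maf_weights))
    csq_idx = rng.choice(len(csq_values), size=cfg.n_background_variants, p=csq_probs)
    for i in range(cfg.n_background_variants):
        cat = categories[i]
        if cat == 0:
            maf = float(rng.uniform(*cfg.common_maf_range))
        elif cat == 1:
            maf = float(rng.uniform(*cfg.rare_maf_range))
        else:
            maf = 0.0
        csq = csq_values[int(csq_idx[i])]
        if csq is Consequence.SPLICE_REGION:
            dist = int(rng.integers(1, 51))
        elif csq is Consequence.NONCODING:
            dist = int(rng.integers(1, 201))
        else:
            dist = 0
        ref, alt = _random_snv(rng)
        v = Variant(
            variant_id=f"{family_id}_bg{i:05d}",
            chrom=f"chr{int(rng.integers(1, 23))}",
            pos=int(rng.integers(10_000, 50_000_000)),
            ref=ref,
            alt=alt,
            gene=f"GENE_{family_id}_{i:05d}",
            consequence=csq,
            distance_to_exon=dist,
        )
        variants.append(v)
        mafs_list.append(maf)
        maf_map[v.variant_id] = None if maf == 0.0 else maf

    genotypes = _genotype_matrix(
        pedigree, [v.variant_id for v in variants], mafs_list, causal_gts, cfg, rng
    )
    annotations = simulate_annotations(
        variants, {causal.variant_id}, cfg, rng, maf_map, family_id
    )
    return FamilyDataset(pedigree, variants, genotypes, annotations, truth)


def simulate_dataset(cfg: SimulationConfig) -> list[FamilyDataset]:
    """All families of a study, one independent causal variant each."""
    rng = np.random.default_rng(cfg.seed)
    return [
        simulate_family(cfg, rng, f"FAM{i + 1}")
        for i in range(cfg.n_families)
    ]


def write_dataset(out_dir: str | Path, families: list[FamilyDataset]) -> dict[str, Path]:
    """Write VCF + PED + annotation table + truth JSON for a dataset.

    Samples from all families share one VCF; a variant is genotyped only
    in its own family (other samples are emitted as missing calls).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_samples: list[str] = []
    for fd in families:
        all_samples.extend(fd.genotypes.sample_ids)
    all_variants: list[Variant] = []
    gt_blocks, adr_blocks, ada_blocks = [], [], []
    offset = 0
    n_total = sum(len(fd.variants) for fd in families)
    gt = np.full((n_total, len(all_samples)), GT_MISSING, dtype=np.int8)
    adr = np.full((n_total, len(all_samples)), -1, dtype=np.int32)
    ada = np.full((n_total, len(all_samples)), -1, dtype=np.int32)
    col_offset = 0
    row_offset = 0
    for fd in families:
        n_v = len(fd.variants)
        n_s = len(fd.genotypes.sample_ids)
        gt[row_offset:row_offset + n_v, col_offset:col_offset + n_s] = fd.genotypes.gt
        adr[row_offset:row_offset + n_v, col_offset:col_offset + n_s] = fd.genotypes.ad_ref
        ada[row_offset:row_offset + n_v, col_offset:col_offset + n_s] = fd.genotypes.ad_alt
        all_variants.extend(fd.variants)
        row_offset += n_v
        col_offset += n_s
    matrix = GenotypeMatrix([v.variant_id for v in all_variants], all_samples, gt, adr, ada)
    paths = {
        "vcf": out_dir / "variants.vcf",
        "ped": out_dir / "families.ped",
        "annotations": out_dir / "annotations.tsv",
        "truth": out_dir / "truth.json",
    }
    write_vcf(paths["vcf"], all_variants, matrix)
    write_ped(paths["ped"], [fd.pedigree for fd in families])
    write_annotation_table(
        paths["annotations"], [r for fd in families for r in fd.annotations]
    )
    truth_payload = [fd.truth.to_json() for fd in families]
    paths["truth"].write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# consistency checks
# ---------------------------------------------------------------------------

#: child genotypes possible given (father, mother) genotype codes
_MENDEL_OK = {
    (0, 0): {0},
    (0, 1): {0, 1}, (1, 0): {0, 1},
    (0, 2): {1}, (2, 0): {1},
    (1, 1): {0, 1, 2},
    (1, 2): {1, 2}, (2, 1): {1, 2},
    (2, 2): {2},
}


def count_mendelian_violations(genotypes: GenotypeMatrix, pedigree: Pedigree) -> int:
    """Exhaustive parent-child consistency check; missing calls are skipped."""
    sidx = {s: j for j, s in enumerate(genotypes.sample_ids)}
    violations = 0
    for m in pedigree.members:
        if m.father_id is None or m.mother_id is None:
            continue
        if not all(x in sidx for x in (m.individual_id, m.father_id, m.mother_id)):
            continue
        child = genotypes.gt[:, sidx[m.individual_id]]
        father = genotypes.gt[:, sidx[m.father_id]]
        mother = genotypes.gt[:, sidx[m.mother_id]]
        for c, f, mo in zip(child, father, mother):
            if GT_MISSING in (c, f, mo):
                continue
            if int(c) not in _MENDEL_OK[(int(f), int(mo))]:
                violations += 1
    return violations
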