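"""Pipeline orchestration: cascade -> segregation -> consensus -> reports.

Ties the stage modules together behind one reproducible entry point that
reads a multi-sample VCF, a PED file and an annotation table, analyses
each family independently, and writes tab-separated reports plus a run
manifest (config hash, input checksums, timings) so that identical inputs
and configuration yield identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import ConsensusConfig, classify_all
from .enrichment import EnrichmentConfig, run_ora
from .filters import FilterConfig, FunnelReport, funnel_table, run_cascade
from .io import (
    StructuralError,
    load_joined_fixture,
    packaged_tc_genes,
    read_annotation_table,
    read_gmt,
    read_ped,
    read_vcf,
)
from .models import ACMG_LABEL, AnnotationRecord, GenotypeMatrix, Pedigree, Variant
from .segregation import (
    SegregationConfig,
    full_family_segregation,
    pedigree_prefilter,
)
from .simulate import FamilyDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    ped: str = ""
    annotations: str = ""
    gmt: str = ""
    out_dir: str = "famseg_out"
    seed: int = 0
    log_level: str = "INFO"
    filters: FilterConfig = field(default_factory=FilterConfig)
    segregation: SegregationConfig = field(default_factory=SegregationConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def config_hash(self) -> str:
        payload = asdict(self)
        # identify the analysis, not where it writes or how it logs
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        for cfg in ("filters", "segregation", "consensus", "enrichment"):
            for key, value in list(payload[cfg].items()):
                if isinstance(value, (set, frozenset)):
                    payload[cfg][key] = sorted(value)
                if isinstance(value, dict):
                    payload[cfg][key] = {
                        k: sorted(v) if isinstance(v, (set, frozenset)) else v
                        for k, v in value.items()
                    }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-family analysis
# ---------------------------------------------------------------------------

def analyze_family(
    variants: list[Variant],
    records: list[AnnotationRecord],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    filter_cfg: FilterConfig | None = None,
    seg_cfg: SegregationConfig | None = None,
) -> tuple[FunnelReport, list]:
    """Cascade, sequenced-subset prefilter, and full-family segregation.

    Returns the funnel report (with the two segregation stages appended)
    and the full-family verdict list for the prefilter survivors.
    """
    filter_cfg = filter_cfg or FilterConfig()
    seg_cfg = seg_cfg or SegregationConfig()
    report = run_cascade(variants, records, genotypes, pedigree, filter_cfg)
    survivors = report.survivors["cadd_acmg"]
    prefiltered = pedigree_prefilter(survivors, genotypes, pedigree, seg_cfg)
    report.record("pedigree_filtered", prefiltered)
    verdicts = full_family_segregation(prefiltered, genotypes, pedigree, seg_cfg)
    segregating = [v.variant_id for v in verdicts if v.segregates]
    report.record("segregating", segregating)
    return report, verdicts


def analyze_simulated_family(
    fd: FamilyDataset,
    filter_cfg: FilterConfig | None = None,
    seg_cfg: SegregationConfig | None = None,
) -> tuple[FunnelReport, list]:
    return analyze_family(
        fd.variants, fd.annotations, fd.genotypes, fd.pedigree, filter_cfg, seg_cfg
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage on files; returns the output directory.

    Pre-flight cross-validation (VCF samples must appear in the PED)
    happens before any computation; every output table carries a header
    comment with the config hash and seed.
    """
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    variants, matrix = read_vcf(cfg.vcf)
    pedigrees = read_ped(cfg.ped)
    records = read_annotation_table(cfg.annotations)
    ped_ids = {m.individual_id for ped in pedigrees for m in ped.members}
    orphan_samples = [s for s in matrix.sample_ids if s not in ped_ids]
    if orphan_samples:
        raise StructuralError(
            f"VCF samples absent from PED: {', '.join(orphan_samples[:10])}"
        )
    timings["load"] = time.perf_counter() - t0

    by_family: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        by_family.setdefault(r.family_id, []).append(r)
    by_id_v = {v.variant_id: v for v in variants}

    header = f"# famseg {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n"
    reports: list[FunnelReport] = []
    verdict_rows = []
    segregating_records: list[AnnotationRecord] = []
    t1 = time.perf_counter()
    for ped in pedigrees:
        fam_records = by_family.get(ped.family_id, [])
        fam_variants = [by_id_v[r.variant_id] for r in fam_records]
        fam_matrix = matrix.subset_samples([m.individual_id for m in ped.members])
        report, verdicts = analyze_family(
            fam_variants, fam_records, fam_matrix, ped, cfg.filters, cfg.segregation
        )
        reports.append(report)
        for v in verdicts:
            verdict_rows.append(
                {
                    "variant_id": v.variant_id,
                    "family_id": v.family_id,
                    "segregates": v.segregates,
                    "reason": v.reason,
                    "n_affected_carriers": v.n_affected_carriers,
                    "n_affected_genotyped": v.n_affected_genotyped,
                    "n_unaffected_carriers": v.n_unaffected_carriers,
                }
            )
        seg_ids = set(report.survivors["segregating"])
        segregating_records.extend(r for r in fam_records if r.variant_id in seg_ids)
    timings["cascade_segregation"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    calls, consensus_summary = classify_all(segregating_records, cfg.consensus)
    timings["consensus"] = time.perf_counter() - t2

    def write_table(path: Path, df: pd.DataFrame) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    write_table(out_dir / "funnel.tsv", funnel_table(reports))
    (out_dir / "funnel.json").write_text(
        json.dumps(
            {r.family_id: r.counts for r in reports}, indent=2, sort_keys=True
        ) + "\n"
    )
    write_table(out_dir / "segregation.tsv", pd.DataFrame(verdict_rows))
    call_rows = [
        {
            "variant_id": c.variant_id,
            "family_id": c.family_id,
            "gene": c.gene,
            **{f"verdict_{t.lower()}": v for t, v in c.verdicts.items()},
            "n_damaging": c.n_damaging,
            "n_available": c.n_available,
            "fraction": round(c.fraction, 4),
            "is_candidate": c.is_candidate,
            "low_support": c.low_support,
        }
        for c in calls
    ]
    write_table(out_dir / "consensus.tsv", pd.DataFrame(call_rows))

    enrichment_rows = []
    if cfg.gmt:
        t3 = time.perf_counter()
        gene_sets = read_gmt(cfg.gmt)
        candidate_genes = {c.gene for c in calls if c.is_candidate}
        if candidate_genes:
            for r in run_ora(candidate_genes, gene_sets, cfg.enrichment):
                enrichment_rows.append(
                    {
                        "term_id": r.term_id,
                        "term_name": r.term_name,
                        "k": r.k,
                        "K": r.K,
                        "n": r.n,
                        "N": r.N,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "enrichment_factor": round(r.enrichment_factor, 4),
                        "retained": r.retained,
                        "cluster_id": r.cluster_id,
                        "member_genes": ",".join(r.member_genes),
                    }
                )
        timings["enrichment"] = time.perf_counter() - t3
    write_table(out_dir / "enrichment.tsv", pd.DataFrame(enrichment_rows))

    manifest = {
        "tool": f"famseg {__version__}",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {
            name: _sha256_file(path)
            for name, path in (
                ("vcf", cfg.vcf), ("ped", cfg.ped), ("annotations", cfg.annotations)
            )
            if path
        },
        "outputs": {
            p.name: _sha256_file(p)
            for p in sorted(out_dir.glob("*.tsv"))
        },
        "consensus_summary": consensus_summary,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out_dir


def result_checksums(out_dir: str | Path) -> dict[str, str]:
    """Checksums of the result tables (manifest and timings excluded)."""
    out_dir = Path(out_dir)
    sums = {}
    for p in sorted(out_dir.glob("*.tsv")):
        sums[p.name] = _sha256_file(p)
    for p in sorted(out_dir.glob("*.json")):
        if p.name != "manifest.json":
            sums[p.name] = _sha256_file(p)
    return sums


# ---------------------------------------------------------------------------
# packaged-study summary
# ---------------------------------------------------------------------------

def paper_summary() -> dict:
    """Headline tallies recomputed from the packaged reference tables.

    Covers the segregating-variant totals and phenotype split, the number
    of families with at least one segregating variant, the known-TC-gene
    stratum with its ACMG class tally, and consensus-candidate counts
    under both denominator modes.
    """
    records = load_joined_fixture()
    tc_genes = packaged_tc_genes()
    known = [r for r in records if r.gene.upper() in tc_genes]
    for r in records:
        r.known_tc_gene = r.gene.upper() in tc_genes
    acmg_tally: dict[str, int] = {}
    for r in known:
        label = ACMG_LABEL[r.acmg_class]
        acmg_tally[label] = acmg_tally.get(label, 0) + 1
    families = {r.family_id for r in records}
    summary = {
        "n_segregating_variants": len(records),
        "n_families_with_segregating_variant": len(families),
        "n_mtc_variants": sum(r.family_id.startswith("MTC") for r in records),
        "n_nmtc_variants": sum(r.family_id.startswith("NMTC") for r in records),
        "n_known_tc_gene_variants": len(known),
        "n_novel_gene_variants": len(records) - len(known),
        "known_tc_gene_acmg_tally": dict(sorted(acmg_tally.items())),
        "known_tc_genes": sorted({r.gene for r in known}),
    }
    for mode in ("available", "all_seven"):
        _, agg = classify_all(records, ConsensusConfig(denominator=mode))
        summary[f"consensus_{mode}"] = {
            "n_candidates": agg["n_candidates"],
            "n_candidates_novel_gene": agg["n_candidates_novel_gene"],
            "n_candidates_known_tc_gene": agg["n_candidates_known_tc_gene"],
            "n_families_with_candidate": agg["n_families_with_candidate"],
        }
    return summary
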