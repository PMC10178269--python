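"""Multi-tool in-silico pathogenicity consensus.

Seven predictors are consulted per variant (SIFT, PolyPhen-2, LoFtool,
MutationAssessor, MutationTaster, FATHMM, CADD). Each emits a
damaging/tolerated/missing verdict from its published label vocabulary or,
when only a number is available, from its documented score threshold. A
variant is a consensus candidate when it is called damaging by at least
60% of tools — by default 60% of the tools for which a prediction was
obtained; a stricter mode divides by all seven regardless of missingness.

Printed categorical labels take precedence over numeric re-thresholding:
published annotation tables occasionally describe a tool's scale
inaccurately in prose while the labels themselves are consistent, so the
label is treated as the tool's authoritative call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import PREDICTOR_TOOLS, AnnotationRecord, PredictorCell


class ToolError(ValueError):
    pass


@dataclass
class ConsensusConfig:
    """Per-tool damaging rules and the consensus threshold.

    Score thresholds follow each tool's documentation: SIFT <= 0.05
    deleterious; PolyPhen-2 >= 0.85 confidently damaging; FATHMM <= -1.5
    pathogenic; CADD phred >= 20 (top percentiles of deleteriousness);
    LoFtool percentile <= 0.5 intolerant; MutationAssessor >= 1.9 (the
    medium-impact band); MutationTaster probability >= 0.5 disease-causing.
    """

    fraction_min: float = 0.60
    denominator: str = "available"  # or "all_seven"
    min_available: int = 1
    low_support_below: int = 3

    sift_max: float = 0.05
    polyphen_min: float = 0.85
    fathmm_max: float = -1.5
    cadd_min: float = 20.0
    loftool_max: float = 0.5
    ma_min: float = 1.9
    mt_min: float = 0.5

    damaging_labels: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "SIFT": frozenset({"D"}),
            "PolyPhen2": frozenset({"PD", "P"}),
            "LoFtool": frozenset({"PD", "D"}),
            "MutationAssessor": frozenset({"M", "H"}),
            "MutationTaster": frozenset({"DC", "DC_automatic"}),
            "FATHMM": frozenset({"D"}),
            "CADD": frozenset(),
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_min <= 1.0:
            raise ValueError("fraction_min must be in (0, 1]")
        if self.denominator not in {"available", "all_seven"}:
            raise ValueError("denominator must be 'available' or 'all_seven'")
        if self.min_available < 1:
            raise ValueError("min_available must be >= 1")


@dataclass
class ConsensusCall:
    variant_id: str
    verdicts: dict[str, str]  # tool -> damaging | tolerated | missing
    n_damaging: int
    n_available: int
    fraction: float
    is_candidate: bool
    low_support: bool
    family_id: str = ""
    gene: str = ""
    known_tc_gene: bool = False


def _score_verdict(tool: str, score: float, cfg: ConsensusConfig) -> str:
    if tool == "SIFT":
        return "damaging" if score <= cfg.sift_max else "tolerated"
    if tool == "PolyPhen2":
        return "damaging" if score >= cfg.polyphen_min else "tolerated"
    if tool == "LoFtool":
        return "damaging" if 0.0 <= score <= cfg.loftool_max else "tolerated"
    if tool == "MutationAssessor":
        return "damaging" if score >= cfg.ma_min else "tolerated"
    if tool == "MutationTaster":
        return "damaging" if score >= cfg.mt_min else "tolerated"
    if tool == "FATHMM":
        return "damaging" if score <= cfg.fathmm_max else "tolerated"
    if tool == "CADD":
        return "damaging" if score >= cfg.cadd_min else "tolerated"
    raise ToolError(f"unknown predictor tool {tool!r}")


def tool_verdict(tool: str, cell: PredictorCell, cfg: ConsensusConfig | None = None) -> str:
    """One tool's damaging/tolerated/missing verdict for one cell.

    The printed label decides when present; the numeric threshold is a
    fallback for score-only cells. CADD carries no label vocabulary.
    """
    cfg = cfg or ConsensusConfig()
    if tool not in PREDICTOR_TOOLS:
        raise ToolError(f"unknown predictor tool {tool!r}")
    if cell.missing:
        return "missing"
    if cell.label is not None and tool != "CADD":
        return "damaging" if cell.label in cfg.damaging_labels[tool] else "tolerated"
    if cell.score is None:
        return "missing"
    return _score_verdict(tool, cell.score, cfg)


def consensus_call(record: AnnotationRecord, cfg: ConsensusConfig | None = None) -> ConsensusCall:
    """Aggregate the seven tool verdicts into a candidacy decision."""
    cfg = cfg or ConsensusConfig()
    verdicts = {}
    for tool in PREDICTOR_TOOLS:
        cell = record.tool_scores.get(tool, PredictorCell())
        verdicts[tool] = tool_verdict(tool, cell, cfg)
    n_damaging = sum(v == "damaging" for v in verdicts.values())
    n_available = sum(v != "missing" for v in verdicts.values())
    denom = len(PREDICTOR_TOOLS) if cfg.denominator == "all_seven" else n_available
    fraction = n_damaging / denom if denom else 0.0
    is_candidate = n_available >= cfg.min_available and fraction >= cfg.fraction_min
    return ConsensusCall(
        variant_id=record.variant_id,
        verdicts=verdicts,
        n_damaging=n_damaging,
        n_available=n_available,
        fraction=fraction,
        is_candidate=is_candidate,
        low_support=0 < n_available < cfg.low_support_below,
        family_id=record.family_id,
        gene=record.gene,
        known_tc_gene=record.known_tc_gene,
    )


def classify_all(
    records: list[AnnotationRecord], cfg: ConsensusConfig | None = None
) -> tuple[list[ConsensusCall], dict]:
    """Per-variant calls plus aggregate candidate counts.

    The summary reports totals overall, per family, and stratified by the
    known-phenotype-gene flag, and names the denominator mode used.
    """
    cfg = cfg or ConsensusConfig()
    calls = [consensus_call(r, cfg) for r in records]
    per_family: dict[str, int] = {}
    for c in calls:
        if c.is_candidate:
            per_family[c.family_id] = per_family.get(c.family_id, 0) + 1
    summary = {
        "denominator": cfg.denominator,
        "n_records": len(calls),
        "n_candidates": sum(c.is_candidate for c in calls),
        "n_candidates_known_tc_gene": sum(
            c.is_candidate and c.known_tc_gene for c in calls
        ),
        "n_candidates_novel_gene": sum(
            c.is_candidate and not c.known_tc_gene for c in calls
        ),
        "candidates_per_family": per_family,
        "n_families_with_candidate": len(per_family),
        "n_low_support": sum(c.low_support for c in calls),
    }
    return calls, summary
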