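"""Core domain types for pedigree-aware variant prioritization.

The in-memory model mirrors what a multiplex-family exome study works with:
variants with functional annotations, per-sample genotypes with allele
depths, pedigrees with affection status, and per-tool pathogenicity
predictions of the kind clinical annotation platforms print
(``"D (0.019)"``-style cells).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# The seven in-silico predictors the consensus classifier knows about.
PREDICTOR_TOOLS = (
    "SIFT",
    "PolyPhen2",
    "LoFtool",
    "MutationAssessor",
    "MutationTaster",
    "FATHMM",
    "CADD",
)

# Five-tier clinical classification mapped onto an ordinal scale so that
# threshold rules like "class >= 3" are well defined.
ACMG_ORDINAL = {"B": 1, "LB": 2, "VUS": 3, "LP": 4, "P": 5}
ACMG_LABEL = {v: k for k, v in ACMG_ORDINAL.items()}


class Consequence(str, enum.Enum):
    """Coding-impact class of a variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


#: Consequence classes treated as protein-altering exonic changes: these pass
#: the consequence filter unconditionally.
NONSYNONYMOUS_EXONIC = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
    }
)

#: Classes that truncate the protein; annotation tools that score amino-acid
#: substitutions typically return no prediction for these.
TRUNCATING = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})


@dataclass(frozen=True)
class Variant:
    """One genomic alteration, 1-based VCF-style coordinates."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    distance_to_exon: int = 0
    cdna_hgvs: str = ""
    protein_hgvs: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical for {self.variant_id}")
        if self.distance_to_exon < 0:
            raise ValueError("distance_to_exon must be non-negative")
        exonic = self.consequence in NONSYNONYMOUS_EXONIC or (
            self.consequence is Consequence.SYNONYMOUS
        )
        if exonic and self.distance_to_exon != 0:
            raise ValueError(
                f"{self.variant_id}: exonic consequence "
                f"{self.consequence.value} requires distance_to_exon == 0"
            )


@dataclass(frozen=True)
class PredictorCell:
    """One predictor's output for one variant: a label, a score, or both.

    Annotation tables print these as ``"D (0.019)"``, a bare label, a bare
    number, or a missing marker. A fully missing cell has both fields None.
    """

    label: str | None = None
    score: float | None = None

    @property
    def missing(self) -> bool:
        return self.label is None and self.score is None


MISSING_CELL = PredictorCell()


@dataclass
class AnnotationRecord:
    """Per-variant annotations consumed by the filter cascade and classifier.

    ``maf`` of None means the variant is unobserved in population databases
    ("novel"), which every rarity filter treats as passing.
    """

    variant_id: str
    gene: str
    family_id: str = ""
    maf: float | None = None
    cadd_phred: float | None = None
    acmg_class: int | None = None
    tool_scores: dict[str, PredictorCell] = field(default_factory=dict)
    known_tc_gene: bool = False
    consequence: Consequence | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 1]")
        if self.acmg_class is not None and self.acmg_class not in range(1, 6):
            raise ValueError(
                f"{self.variant_id}: acmg_class {self.acmg_class} not in 1..5"
            )
        unknown = set(self.tool_scores) - set(PREDICTOR_TOOLS)
        if unknown:
            raise ValueError(f"{self.variant_id}: unknown predictor tools {unknown}")


@dataclass(frozen=True)
class Individual:
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown (PED convention)
    affected: bool | None = None  # None = unknown phenotype
    sequenced: bool = True


@dataclass
class Pedigree:
    """Family structure; the substrate of segregation filtering."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = {m.individual_id for m in self.members}
        if len(ids) != len(self.members):
            raise ValueError(f"{self.family_id}: duplicate individual ids")
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"{self.family_id}: dangling parent id {parent!r} "
                        f"referenced by {m.individual_id}"
                    )
        self._check_acyclic()
        if not any(m.affected for m in self.members):
            raise ValueError(f"{self.family_id}: pedigree has no affected member")

    def _check_acyclic(self) -> None:
        by_id = {m.individual_id: m for m in self.members}
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(
                    f"{self.family_id}: {iid} is its own ancestor "
                    f"(cycle {' -> '.join(stack + [iid])})"
                )
            state[iid] = 0
            m = by_id[iid]
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for m in self.members:
            visit(m.individual_id, [])

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def affected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affected is True]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affected is False]

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def topological_order(self) -> list[Individual]:
        """Members ordered so every parent precedes its children."""
        done: dict[str, Individual] = {}
        remaining = list(self.members)
        while remaining:
            progressed = False
            for m in list(remaining):
                ok = all(
                    p is None or p in done for p in (m.father_id, m.mother_id)
                )
                if ok:
                    done[m.individual_id] = m
                    remaining.remove(m)
                    progressed = True
            if not progressed:  # pragma: no cover - guarded by __post_init__
                raise ValueError(f"{self.family_id}: pedigree is cyclic")
        return list(done.values())


# Genotype codes used in GenotypeMatrix arrays.
GT_MISSING = -1
GT_REF_REF = 0
GT_REF_ALT = 1
GT_ALT_ALT = 2

GT_NAMES = {GT_MISSING: "missing", GT_REF_REF: "ref_ref",
            GT_REF_ALT: "ref_alt", GT_ALT_ALT: "alt_alt"}


class GenotypeMatrix:
    """Diploid calls plus allele depths for (variant x sample).

    Backed by int arrays: ``gt`` holds codes -1/0/1/2 (missing, hom-ref,
    het, hom-alt); ``ad_ref``/``ad_alt`` hold read depths with -1 meaning
    depth unavailable for that cell.
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        sample_ids: Sequence[str],
        gt: np.ndarray,
        ad_ref: np.ndarray | None = None,
        ad_alt: np.ndarray | None = None,
    ) -> None:
        self.variant_ids = list(variant_ids)
        self.sample_ids = list(sample_ids)
        shape = (len(self.variant_ids), len(self.sample_ids))
        self.gt = np.asarray(gt, dtype=np.int8)
        if self.gt.shape != shape:
            raise ValueError(f"gt shape {self.gt.shape} != {shape}")
        if ad_ref is None:
            ad_ref = np.full(shape, -1, dtype=np.int32)
        if ad_alt is None:
            ad_alt = np.full(shape, -1, dtype=np.int32)
        self.ad_ref = np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(ad_alt, dtype=np.int32)
        if self.ad_ref.shape != shape or self.ad_alt.shape != shape:
            raise ValueError("allele-depth array shape mismatch")
        self._vidx = {v: i for i, v in enumerate(self.variant_ids)}
        self._sidx = {s: j for j, s in enumerate(self.sample_ids)}

    # -- lookups ---------------------------------------------------------
    def genotype(self, variant_id: str, sample_id: str) -> int:
        return int(self.gt[self._vidx[variant_id], self._sidx[sample_id]])

    def depths(self, variant_id: str, sample_id: str) -> tuple[int, int]:
        i, j = self._vidx[variant_id], self._sidx[sample_id]
        return int(self.ad_ref[i, j]), int(self.ad_alt[i, j])

    def allelic_fraction(self, variant_id: str, sample_id: str) -> float | None:
        """alt-supporting read fraction, or None when depth is unavailable."""
        ar, aa = self.depths(variant_id, sample_id)
        if ar < 0 or aa < 0 or ar + aa == 0:
            return None
        return aa / (ar + aa)

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._vidx

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        keep = [s for s in sample_ids if s in self._sidx]
        cols = [self._sidx[s] for s in keep]
        return GenotypeMatrix(
            self.variant_ids,
            keep,
            self.gt[:, cols],
            self.ad_ref[:, cols],
            self.ad_alt[:, cols],
        )

    def row(self, variant_id: str) -> Mapping[str, int]:
        i = self._vidx[variant_id]
        return {s: int(self.gt[i, j]) for j, s in enumerate(self.sample_ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variant_ids == other.variant_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
        )
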