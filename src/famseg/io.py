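"""Readers and writers for the formats the pipeline touches.

Covers multi-sample VCF 4.2 (via pysam for parsing; writing emits plain
text), 6-column PED, tab-separated annotation tables whose predictor cells
look like ``"D (0.019)"``, gene lists, GMT gene sets, and the packaged
reference tables of segregating variants and per-tool predictions. All
text readers transparently accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
import pysam

from .models import (
    ACMG_ORDINAL,
    GT_ALT_ALT,
    GT_MISSING,
    GT_REF_ALT,
    GT_REF_REF,
    PREDICTOR_TOOLS,
    AnnotationRecord,
    Consequence,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PredictorCell,
    Variant,
)

MISSING_MARKERS = {"---", "--", "", "NA", "."}

# lenient on purpose: published tables contain cells like "T(0.04)" and
# "T 1.22)" with inconsistent spacing/parentheses, and U+2212 minus signs.
_CELL_RE = re.compile(
    r"^\s*(?P<label>[A-Za-z][A-Za-z_]*)?\s*\(?\s*(?P<score>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)?\s*\)?\s*$"
)


class ParseError(ValueError):
    """Malformed content in an input file."""


class StructuralError(ValueError):
    """Inputs are individually well formed but mutually inconsistent."""


class IntegrityError(ValueError):
    """A packaged fixture does not match its recorded checksum."""


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# ---------------------------------------------------------------------------
# predictor cells
# ---------------------------------------------------------------------------

def parse_predictor_cell(text: str, tool: str = "") -> PredictorCell:
    """Parse one annotation-table cell into a :class:`PredictorCell`.

    Accepted forms: ``"D (0.019)"``, ``"D"``, ``"0.019"``, and the missing
    markers ``---``/``--``/``NA``/empty. Unicode minus is normalized.
    """
    raw = text
    text = text.strip().replace("−", "-")
    if text in MISSING_MARKERS:
        return PredictorCell()
    m = _CELL_RE.match(text)
    if m is None or (m.group("label") is None and m.group("score") is None):
        raise ParseError(f"unparseable predictor cell {raw!r} (tool {tool or '?'})")
    score = m.group("score")
    return PredictorCell(
        label=m.group("label"),
        score=float(score) if score is not None else None,
    )


def format_predictor_cell(cell: PredictorCell) -> str:
    """Inverse of :func:`parse_predictor_cell` for representable cells."""
    if cell.missing:
        return "---"
    if cell.label is not None and cell.score is not None:
        return f"{cell.label} ({cell.score!r})"
    if cell.label is not None:
        return cell.label
    return repr(cell.score)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column PED file into one :class:`Pedigree` per family.

    Phenotype column follows the PED convention: 2 affected, 1 unaffected,
    0/-9 unknown. A 7th column, when present, is read as a 0/1 "sequenced"
    flag (all individuals default to sequenced).
    """
    families: dict[str, list[Individual]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 PED columns")
            fam, iid, father, mother, sex, pheno = fields[:6]
            affected = {"2": True, "1": False}.get(pheno)
            if pheno not in {"2", "1", "0", "-9"}:
                raise ParseError(f"{path}:{lineno}: bad phenotype {pheno!r}")
            sequenced = True
            if len(fields) >= 7:
                sequenced = fields[6] not in {"0"}
            families.setdefault(fam, []).append(
                Individual(
                    individual_id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=int(sex) if sex in {"0", "1", "2"} else 0,
                    affected=affected,
                    sequenced=sequenced,
                )
            )
    return [Pedigree(fam, members) for fam, members in families.items()]


def write_ped(path: str | Path, pedigrees: Iterable[Pedigree]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ped in pedigrees:
            for m in ped.members:
                pheno = {True: "2", False: "1", None: "0"}[m.affected]
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            str(m.sex),
                            pheno,
                            "1" if m.sequenced else "0",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_CODE = {
    (0, 0): GT_REF_REF,
    (0, 1): GT_REF_ALT,
    (1, 0): GT_REF_ALT,
    (1, 1): GT_ALT_ALT,
}


def read_vcf(path: str | Path) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a VCF 4.x into variants plus a genotype/allele-depth matrix.

    Multiallelic records are decomposed into one variant per ALT allele;
    the AD of the kept ALT is preserved and the remaining depth is folded
    into the reference depth. Missing AD yields depth -1 (unavailable),
    never zero.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.header.samples)
    variants: list[Variant] = []
    gt_rows: list[np.ndarray] = []
    adr_rows: list[np.ndarray] = []
    ada_rows: list[np.ndarray] = []
    def info_get(info, key, default):
        try:
            value = info.get(key, default)
        except (KeyError, ValueError):  # key absent from the header
            return default
        return default if value is None else value

    for rec in vcf:
        alts = rec.alts or ()
        for alt_index, alt in enumerate(alts, start=1):
            info = rec.info
            gene = str(info_get(info, "GENE", ""))
            csq = str(info_get(info, "CSQ", Consequence.NONCODING.value))
            try:
                consequence = Consequence(csq)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} has unknown "
                    f"consequence {csq!r}"
                ) from exc
            dist = int(info_get(info, "EXDIST", 0))
            vid = rec.id if rec.id and len(alts) == 1 else (
                f"{rec.id or f'{rec.chrom}_{rec.pos}'}_alt{alt_index}"
                if len(alts) > 1
                else f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}"
            )
            variants.append(
                Variant(
                    variant_id=vid,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=gene,
                    consequence=consequence,
                    distance_to_exon=dist,
                )
            )
            gt_row = np.full(len(samples), GT_MISSING, dtype=np.int8)
            adr = np.full(len(samples), -1, dtype=np.int32)
            ada = np.full(len(samples), -1, dtype=np.int32)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call.get("GT")
                if alleles is None or any(a is None for a in alleles):
                    continue
                # per-allele view: count copies of this ALT
                nalt = sum(1 for a in alleles if a == alt_index)
                if nalt == 0 and any(a not in (0, alt_index) for a in alleles):
                    gt_row[j] = GT_REF_REF  # carries only other alleles
                else:
                    gt_row[j] = {0: GT_REF_REF, 1: GT_REF_ALT, 2: GT_ALT_ALT}[nalt]
                ad = call.get("AD")
                if ad is not None and ad[0] is not None:
                    total = sum(a for a in ad if a is not None)
                    a_alt = ad[alt_index] if len(ad) > alt_index and ad[alt_index] is not None else 0
                    ada[j] = a_alt
                    adr[j] = total - a_alt
            gt_rows.append(gt_row)
            adr_rows.append(adr)
            ada_rows.append(ada)
    vids = [v.variant_id for v in variants]
    n = len(vids)
    matrix = GenotypeMatrix(
        vids,
        samples,
        np.vstack(gt_rows) if n else np.empty((0, len(samples)), dtype=np.int8),
        np.vstack(adr_rows) if n else None,
        np.vstack(ada_rows) if n else None,
    )
    return variants, matrix


def write_vcf(path: str | Path, variants: list[Variant], matrix: GenotypeMatrix,
              extra_header_lines: Iterable[str] = ()) -> None:
    """Write an uncompressed VCF 4.2 with GT/AD/DP and annotation INFO keys."""
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos, variants[i].alt))
    contigs = []
    for i in order:
        if variants[i].chrom not in contigs:
            contigs.append(variants[i].chrom)
    code_to_gt = {GT_MISSING: "./.", GT_REF_REF: "0/0", GT_REF_ALT: "0/1", GT_ALT_ALT: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##INFO=<ID=EXDIST,Number=1,Type=Integer,Description="Distance to nearest exon (0=exonic)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for i in order:
            v = variants[i]
            info = f"GENE={v.gene};CSQ={v.consequence.value};EXDIST={v.distance_to_exon}"
            cells = []
            for s in matrix.sample_ids:
                gt = code_to_gt[matrix.genotype(v.variant_id, s)]
                ar, aa = matrix.depths(v.variant_id, s)
                if ar < 0 or aa < 0:
                    cells.append(f"{gt}:.:.")
                else:
                    cells.append(f"{gt}:{ar},{aa}:{ar + aa}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT:AD:DP\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

#: column order of the tab-separated annotation-table interchange format
ANNOTATION_COLUMNS = [
    "variant_id", "family_id", "gene", "consequence", "maf", "cadd_phred",
    "acmg_class", "known_tc_gene", "sift", "polyphen2", "loftool",
    "mutation_assessor", "mutation_taster", "fathmm",
]

_TOOL_COLUMNS = {
    "SIFT": "sift",
    "PolyPhen2": "polyphen2",
    "LoFtool": "loftool",
    "MutationAssessor": "mutation_assessor",
    "MutationTaster": "mutation_taster",
    "FATHMM": "fathmm",
}


def _acmg_to_ordinal(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    s = str(value).strip()
    if s in ACMG_ORDINAL:
        return ACMG_ORDINAL[s]
    return int(float(s))


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read the tab-separated annotation table into records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = {"variant_id", "gene"} - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    records = []
    for _, row in df.iterrows():
        tool_scores: dict[str, PredictorCell] = {}
        for tool, col in _TOOL_COLUMNS.items():
            if col in df.columns:
                cell = parse_predictor_cell(row[col], tool)
                if not cell.missing:
                    tool_scores[tool] = cell
        cadd = float(row["cadd_phred"]) if row.get("cadd_phred", "") != "" else None
        if cadd is not None:
            tool_scores["CADD"] = PredictorCell(score=cadd)
        csq = row.get("consequence", "")
        records.append(
            AnnotationRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                family_id=row.get("family_id", ""),
                maf=float(row["maf"]) if row.get("maf", "") != "" else None,
                cadd_phred=cadd,
                acmg_class=_acmg_to_ordinal(row.get("acmg_class", "")),
                tool_scores=tool_scores,
                known_tc_gene=str(row.get("known_tc_gene", "")).strip().lower()
                in {"1", "true", "yes"},
                consequence=Consequence(csq) if csq else None,
            )
        )
    return records


def write_annotation_table(path: str | Path, records: list[AnnotationRecord]) -> None:
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id,
            "family_id": r.family_id,
            "gene": r.gene,
            "consequence": r.consequence.value if r.consequence else "",
            "maf": "" if r.maf is None else repr(r.maf),
            "cadd_phred": "" if r.cadd_phred is None else repr(r.cadd_phred),
            "acmg_class": "" if r.acmg_class is None else str(r.acmg_class),
            "known_tc_gene": "yes" if r.known_tc_gene else "no",
        }
        for tool, col in _TOOL_COLUMNS.items():
            row[col] = format_predictor_cell(r.tool_scores.get(tool, PredictorCell()))
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lists / gene sets
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' comments allowed. Upper-cased."""
    genes = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.upper())
    return genes


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read GMT gene sets: term_id -> (description, gene symbols)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            sets[term] = (desc, {g.strip().upper() for g in genes if g.strip()})
    return sets


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("famseg").joinpath("data", name))


def packaged_tc_genes() -> set[str]:
    """The packaged starter list of thyroid-cancer-associated genes."""
    return read_gene_list(_data_path("tc_genes.txt"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_fixture(name: str) -> list[AnnotationRecord]:
    """Load a packaged reference table ("table2" or "table4").

    ``table2`` carries the 53 family-segregating variants with their ACMG
    class and known-TC-gene flag; ``table4`` carries the per-tool
    pathogenicity predictions (seven predictors incl. CADD) for the same
    53 variants. Both are verified against a checksum manifest and basic
    row-count invariants at load.
    """
    if name not in {"table2", "table4"}:
        raise ValueError(f"unknown fixture {name!r}")
    path = _data_path(f"{name}.tsv")
    manifest = json.loads(_data_path("manifest.json").read_text())
    digest = _sha256(path)
    if digest != manifest[f"{name}.tsv"]:
        raise IntegrityError(
            f"{path.name}: sha256 {digest} does not match packaged manifest"
        )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[AnnotationRecord] = []
    for _, row in df.iterrows():
        vid = f"{row['family_id']}:{row['gene']}"
        if name == "table2":
            rec = AnnotationRecord(
                variant_id=vid,
                gene=row["gene"],
                family_id=row["family_id"],
                maf=float(row["maf"]) if row["maf"] != "" else None,
                acmg_class=ACMG_ORDINAL[row["acmg_class"]],
                known_tc_gene=row["known_tc_gene"] == "Yes",
                consequence=Consequence(row["consequence"]),
            )
            rec.flags.add(f"position={row['position']}")
        else:
            tool_scores = {}
            for tool, col in _TOOL_COLUMNS.items():
                cell = parse_predictor_cell(row[col], tool)
                if not cell.missing:
                    tool_scores[tool] = cell
            cadd = float(row["cadd_phred"])
            tool_scores["CADD"] = PredictorCell(score=cadd)
            rec = AnnotationRecord(
                variant_id=vid,
                gene=row["gene"],
                family_id=row["family_id"],
                cadd_phred=cadd,
                tool_scores=tool_scores,
            )
            if row.get("loftool_suspect", "0") == "1":
                rec.flags.add("loftool_suspect")
        records.append(rec)
    # integrity invariants of the published variant list
    if len(records) != 53:
        raise IntegrityError(f"{name}: expected 53 rows, found {len(records)}")
    n_mtc = sum(r.family_id.startswith("MTC") for r in records)
    n_nmtc = sum(r.family_id.startswith("NMTC") for r in records)
    if (n_mtc, n_nmtc) != (16, 37):
        raise IntegrityError(
            f"{name}: expected 16 MTC / 37 NMTC rows, found {n_mtc}/{n_nmtc}"
        )
    return records


def load_joined_fixture() -> list[AnnotationRecord]:
    """Join table2 and table4 on variant id into fully annotated records."""
    t2 = {r.variant_id: r for r in load_fixture("table2")}
    t4 = {r.variant_id: r for r in load_fixture("table4")}
    if set(t2) != set(t4):
        raise IntegrityError("table2/table4 variant ids do not match")
    joined = []
    for vid, r2 in t2.items():
        r4 = t4[vid]
        joined.append(
            AnnotationRecord(
                variant_id=vid,
                gene=r2.gene,
                family_id=r2.family_id,
                maf=r2.maf,
                cadd_phred=r4.cadd_phred,
                acmg_class=r2.acmg_class,
                tool_scores=dict(r4.tool_scores),
                known_tc_gene=r2.known_tc_gene,
                consequence=r2.consequence,
                flags=set(r2.flags) | set(r4.flags),
            )
        )
    return joined
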