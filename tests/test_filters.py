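"""Filter-cascade stages: unit rules, properties, and the funnel."""

import itertools

import numpy as np
import pytest

from famseg import (
    AnnotationRecord,
    FilterConfig,
    GenotypeMatrix,
    Pedigree,
    Individual,
    Variant,
    filter_by_cadd_acmg,
    filter_by_consequence,
    filter_by_maf,
    restrict_to_known_genes,
    run_cascade,
)
from famseg.filters import (
    ConfigError,
    passes_allelic_fraction,
    passes_cadd_acmg,
    passes_consequence,
    passes_maf,
)
from famseg.models import Consequence, GT_REF_ALT, GT_REF_REF


def rec(vid="v", maf=None, cadd=None, acmg=None, gene="G"):
    return AnnotationRecord(
        variant_id=vid, gene=gene, maf=maf, cadd_phred=cadd, acmg_class=acmg
    )


# ---------------------------------------------------------------------------
# rarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "maf,novel_only,kept",
    [
        (0.0002, False, True),   # rare enough at the default 0.001 cutoff
        (None, False, True),     # novel passes any rarity filter
        (None, True, True),
        (0.005, False, False),
        (0.0002, True, False),   # observed at all -> fails the novel-only rule
        (0.0, True, True),
        (0.001, False, True),    # boundary is inclusive
    ],
)
def test_maf_filter(maf, novel_only, kept):
    cfg = FilterConfig(novel_only=novel_only)
    assert passes_maf(rec(maf=maf), cfg) is kept


def test_maf_filter_preserves_order():
    records = [rec(vid=f"v{i}", maf=0.0001 * i) for i in range(10)]
    kept = filter_by_maf(records, FilterConfig())
    assert [r.variant_id for r in kept] == [f"v{i}" for i in range(10)]


def test_maf_out_of_range_rejected():
    r = rec()
    r.maf = 1.5  # bypass constructor validation
    with pytest.raises(ValueError):
        passes_maf(r, FilterConfig())


# ---------------------------------------------------------------------------
# consequence / splice window
# ---------------------------------------------------------------------------

def var(csq, dist=0, vid="v"):
    return Variant(vid, "chr1", 100, "A", "G", "G1", csq, distance_to_exon=dist)


def test_consequence_rules():
    cfg = FilterConfig()
    assert passes_consequence(var(Consequence.MISSENSE), cfg)
    assert not passes_consequence(var(Consequence.SYNONYMOUS), cfg)
    assert passes_consequence(var(Consequence.NONCODING, dist=15), cfg)


def test_splice_window_brute_force_scan():
    """Kept set over distances 0..40 is exactly {d <= window}."""
    for window in (20, 25, 30):
        cfg = FilterConfig(splice_window=window)
        kept = {
            d
            for d in range(41)
            if passes_consequence(var(Consequence.SPLICE_REGION, dist=d), cfg)
        }
        assert kept == {d for d in range(41) if d <= window}


def test_splice_window_range_enforced():
    with pytest.raises(ConfigError):
        FilterConfig(splice_window=10)


# ---------------------------------------------------------------------------
# allelic fraction
# ---------------------------------------------------------------------------

def _ped_two_affected():
    return Pedigree(
        "F",
        [
            Individual("A1", affected=True),
            Individual("A2", affected=True),
            Individual("U1", affected=False),
        ],
    )


def _matrix(gt_row, adr_row, ada_row):
    return GenotypeMatrix(
        ["v"],
        ["A1", "A2", "U1"],
        np.array([gt_row], dtype=np.int8),
        np.array([adr_row], dtype=np.int32),
        np.array([ada_row], dtype=np.int32),
    )


def test_allelic_fraction_kept_at_third():
    m = _matrix([1, 0, 0], [20, 30, 30], [10, 0, 0])  # fraction 10/30 = 0.333
    keep, unassessed = passes_allelic_fraction("v", m, _ped_two_affected(), FilterConfig())
    assert keep and not unassessed


def test_allelic_fraction_sole_low_carrier_removed():
    m = _matrix([1, 0, 0], [27, 30, 30], [3, 0, 0])  # fraction 0.1
    keep, _ = passes_allelic_fraction("v", m, _ped_two_affected(), FilterConfig())
    assert not keep


def test_allelic_fraction_at_least_one_rule():
    """Enumerate carrier-fraction pairs: kept iff max fraction >= 0.30."""
    fractions = [0.05, 0.25, 0.29, 0.30, 0.45, 0.60]
    for fa, fb in itertools.product(fractions, repeat=2):
        ada = [round(fa * 100), round(fb * 100), 0]
        adr = [100 - ada[0], 100 - ada[1], 100]
        m = _matrix([1, 1, 0], adr, ada)
        keep, _ = passes_allelic_fraction("v", m, _ped_two_affected(), FilterConfig())
        assert keep == (max(fa, fb) >= 0.30)


def test_allelic_fraction_no_depth_flagged_unassessed():
    m = _matrix([1, 1, 0], [-1, -1, -1], [-1, -1, -1])
    keep, unassessed = passes_allelic_fraction("v", m, _ped_two_affected(), FilterConfig())
    assert keep and unassessed


# ---------------------------------------------------------------------------
# CADD / ACMG rescue
# ---------------------------------------------------------------------------

def test_cadd_acmg_examples():
    cfg = FilterConfig()
    assert passes_cadd_acmg(rec(cadd=33, acmg=4), cfg)       # both pass
    assert not passes_cadd_acmg(rec(cadd=10, acmg=1), cfg)   # both fail
    # rescued by CADD alone despite a likely-benign class
    assert passes_cadd_acmg(rec(cadd=21.4, acmg=2), cfg)


def test_cadd_acmg_truth_table_both_modes():
    """Exhaustive (pass/fail)^2 cells under either- and both-rescue."""
    cells = {
        (True, True): rec(cadd=25, acmg=4),
        (True, False): rec(cadd=25, acmg=1),
        (False, True): rec(cadd=15, acmg=3),
        (False, False): rec(cadd=15, acmg=1),
    }
    either = FilterConfig(rescue_mode="either")
    both = FilterConfig(rescue_mode="both")
    for (cadd_ok, acmg_ok), r in cells.items():
        assert passes_cadd_acmg(r, either) == (cadd_ok or acmg_ok)
        assert passes_cadd_acmg(r, both) == (cadd_ok and acmg_ok)


def test_cadd_acmg_missing_counts_as_failing():
    cfg = FilterConfig()
    assert not passes_cadd_acmg(rec(cadd=None, acmg=None), cfg)
    assert passes_cadd_acmg(rec(cadd=None, acmg=3), cfg)
    assert not passes_cadd_acmg(rec(cadd=None, acmg=3), FilterConfig(rescue_mode="both"))


# ---------------------------------------------------------------------------
# known-gene restriction
# ---------------------------------------------------------------------------

def test_restrict_to_known_genes_fixture():
    from famseg import load_fixture, packaged_tc_genes

    records = load_fixture("table2")
    kept = restrict_to_known_genes(records, packaged_tc_genes())
    assert len(kept) == 7
    assert {r.gene for r in kept} == {"MSH6", "FOXM1", "EpCAM", "HOOK3", "BMP1", "TG", "NTRK1"}


def test_restrict_case_insensitive():
    records = [rec(gene="EpCAM")]
    assert len(restrict_to_known_genes(records, {"EPCAM"})) == 1
    assert records[0].known_tc_gene


def test_restrict_empty_gene_set_rejected():
    with pytest.raises(ConfigError):
        restrict_to_known_genes([rec()], set())


# ---------------------------------------------------------------------------
# the cascade as a whole
# ---------------------------------------------------------------------------

def test_cascade_empty_input(small_family):
    empty = GenotypeMatrix([], [], np.empty((0, 0), dtype=np.int8))
    report = run_cascade([], [], empty, small_family.pedigree)
    assert all(c == 0 for c in report.counts.values())


def test_cascade_thresholds_disabled(small_family):
    """With every threshold open, only the consequence rule removes."""
    cfg = FilterConfig(
        maf_max=1.0, af_min=0.0, cadd_min=0.0, acmg_min=1, splice_window=float("inf")
    )
    fd = small_family
    report = run_cascade(fd.variants, fd.annotations, fd.genotypes, fd.pedigree, cfg)
    n = len(fd.variants)
    n_nonsyn = sum(v.consequence is not Consequence.SYNONYMOUS for v in fd.variants)
    assert n_nonsyn < n  # the generator produced synonymous variants
    assert report.counts["total"] == n
    assert report.counts["maf_le_threshold"] == n
    assert report.counts["nonsynonymous_exonic_splicing"] == n_nonsyn
    assert report.counts["allelic_fraction"] == n_nonsyn
    assert report.counts["cadd_acmg"] == n_nonsyn


def test_cascade_monotone_and_matches_brute_force(small_family):
    """Survivors nest along stages and equal a single-pass predicate
    conjunction written independently of the cascade code."""
    fd = small_family
    cfg = FilterConfig()
    report = run_cascade(fd.variants, fd.annotations, fd.genotypes, fd.pedigree, cfg)
    stage_ids = [report.survivors[s] for s in
                 ("total", "maf_le_threshold", "nonsynonymous_exonic_splicing",
                  "allelic_fraction", "cadd_acmg")]
    for earlier, later in zip(stage_ids, stage_ids[1:]):
        assert set(later) <= set(earlier)

    # independent oracle: direct transcription of the four rules
    by_id_r = {r.variant_id: r for r in fd.annotations}
    affected = [m.individual_id for m in fd.pedigree.members if m.affected]
    expected = set()
    for v in fd.variants:
        r = by_id_r[v.variant_id]
        if r.maf is not None and r.maf > 0.001:
            continue
        nonsyn = v.consequence.value in {"missense", "nonsense", "frameshift", "inframe_indel"}
        if v.consequence.value == "synonymous":
            continue
        if not nonsyn and v.distance_to_exon > 30:
            continue
        fracs = []
        for s in affected:
            if fd.genotypes.genotype(v.variant_id, s) in (1, 2):
                ar, aa = fd.genotypes.depths(v.variant_id, s)
                if ar >= 0 and aa >= 0 and ar + aa > 0:
                    fracs.append(aa / (ar + aa))
        if fracs and max(fracs) < 0.30:
            continue
        cadd_ok = r.cadd_phred is not None and r.cadd_phred >= 20
        acmg_ok = r.acmg_class is not None and r.acmg_class >= 3
        if not (cadd_ok or acmg_ok):
            continue
        expected.add(v.variant_id)
    assert set(report.survivors["cadd_acmg"]) == expected


def test_cascade_stage_order_invariance(small_family):
    """Applying the four pure predicates in any order yields the same
    final survivor set."""
    fd = small_family
    cfg = FilterConfig()
    by_id_v = {v.variant_id: v for v in fd.variants}
    by_id_r = {r.variant_id: r for r in fd.annotations}

    def apply(stage, ids):
        if stage == "maf":
            return [i for i in ids if passes_maf(by_id_r[i], cfg)]
        if stage == "csq":
            return [i for i in ids if passes_consequence(by_id_v[i], cfg)]
        if stage == "af":
            return [
                i for i in ids
                if passes_allelic_fraction(i, fd.genotypes, fd.pedigree, cfg)[0]
            ]
        return [i for i in ids if passes_cadd_acmg(by_id_r[i], cfg)]

    final_sets = set()
    for order in itertools.permutations(["maf", "csq", "af", "cadd"]):
        ids = [v.variant_id for v in fd.variants]
        for stage in order:
            ids = apply(stage, ids)
        final_sets.add(frozenset(ids))
    assert len(final_sets) == 1


def test_cascade_orphan_ids_rejected(small_family):
    fd = small_family
    with pytest.raises(ValueError, match="orphan"):
        run_cascade(fd.variants[:-1], fd.annotations, fd.genotypes, fd.pedigree)
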