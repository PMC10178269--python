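"""Generator correctness: gene dropping, affection model, annotations,
dataset writing and determinism."""

import filecmp
import json

import numpy as np
import pytest
from scipy.stats import binom, norm

from famseg import (
    Individual,
    Pedigree,
    SimulationConfig,
    consensus_call,
    count_mendelian_violations,
    gene_drop,
    simulate_annotations,
    simulate_dataset,
    simulate_family,
    simulate_pedigree,
    write_dataset,
)
from famseg.models import Consequence, GT_REF_ALT, GT_REF_REF, Variant
from famseg.simulate import SimulationError


# ---------------------------------------------------------------------------
# pedigree + affection model
# ---------------------------------------------------------------------------

def test_full_penetrance_affected_equals_carriers(rng):
    cfg = SimulationConfig(penetrance=1.0, phenocopy_rate=0.0)
    ped, truth = simulate_pedigree(cfg, rng)
    affected = {m.individual_id for m in ped.members if m.affected}
    assert affected == truth.carriers


def test_zero_penetrance_fails_resampling(rng):
    cfg = SimulationConfig(penetrance=0.0, phenocopy_rate=0.0, max_pedigree_retries=5)
    with pytest.raises(SimulationError, match="penetrance"):
        simulate_pedigree(cfg, rng)


def test_penetrance_monte_carlo_ci(rng):
    """Unconditioned draws: carrier-affection rate matches penetrance
    within a 99% binomial CI."""
    f = 0.9
    # target 1 keeps ascertainment conditioning negligible (the founder
    # carrier alone is unaffected with probability 0.1^C, C >= 1)
    cfg = SimulationConfig(penetrance=f, phenocopy_rate=0.0, n_affected_target=1)
    n_carriers = n_affected_carriers = 0
    for _ in range(500):
        ped, truth = simulate_pedigree(cfg, rng)
        affected = {m.individual_id for m in ped.members if m.affected}
        n_carriers += len(truth.carriers)
        n_affected_carriers += len(truth.carriers & affected)
    z = norm.ppf(0.995)
    half = z * np.sqrt(f * (1 - f) / n_carriers)
    assert abs(n_affected_carriers / n_carriers - f) < half


def test_truth_mechanism_labels(rng):
    cfg = SimulationConfig(penetrance=0.6, phenocopy_rate=0.2, n_affected_target=2)
    ped, truth = simulate_pedigree(cfg, rng)
    for iid, mech in truth.mechanism.items():
        assert ped.member(iid).affected
        assert (iid in truth.carriers) == (mech == "genetic")


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _couple_with_children(n_children):
    members = [
        Individual("F", sex=1, affected=True),
        Individual("M", sex=2, affected=False),
    ]
    members += [
        Individual(f"C{i}", father_id="F", mother_id="M") for i in range(n_children)
    ]
    return Pedigree("F1", members)


def test_gene_drop_mendelian_closure(rng):
    ped = _couple_with_children(50)
    col = gene_drop(ped, {"F": GT_REF_REF, "M": GT_REF_REF}, rng)
    assert all(g == GT_REF_REF for g in col.values())


def test_gene_drop_maf_zero_absent_everywhere(rng):
    ped = _couple_with_children(20)
    col = gene_drop(ped, 0.0, rng)
    assert set(col.values()) == {GT_REF_REF}


def test_het_transmission_fraction(rng):
    """het x ref over 10,000 meioses: transmitted fraction inside the
    99% binomial CI of 1/2."""
    ped = _couple_with_children(10_000)
    col = gene_drop(ped, {"F": GT_REF_ALT, "M": GT_REF_REF}, rng)
    transmitted = sum(col[f"C{i}"] == GT_REF_ALT for i in range(10_000))
    lo = binom.ppf(0.005, 10_000, 0.5)
    hi = binom.ppf(0.995, 10_000, 0.5)
    assert lo <= transmitted <= hi


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _mk_variants(n, csq=Consequence.MISSENSE):
    return [
        Variant(f"v{i}", "chr1", 1000 + i, "A", "G", f"G{i}", csq)
        for i in range(n)
    ]


def test_causal_cadd_respects_floor(rng):
    cfg = SimulationConfig()
    variants = _mk_variants(200)
    recs = simulate_annotations(
        variants, {v.variant_id for v in variants}, cfg, rng,
        {v.variant_id: None for v in variants},
    )
    assert all(r.cadd_phred >= cfg.causal_cadd_floor for r in recs)
    assert all(r.acmg_class >= 3 for r in recs)


def test_truncating_missingness_binomial_ci(rng):
    """SIFT missing on truncating variants ~ Bernoulli(0.9) over 1,000
    draws (99% CI)."""
    cfg = SimulationConfig()
    variants = _mk_variants(1000, csq=Consequence.NONSENSE)
    recs = simulate_annotations(
        variants, set(), cfg, rng, {v.variant_id: None for v in variants}
    )
    n_missing = sum("SIFT" not in r.tool_scores for r in recs)
    assert binom.ppf(0.005, 1000, 0.9) <= n_missing <= binom.ppf(0.995, 1000, 0.9)


def test_background_candidate_rate_matches_binomial_oracle(rng):
    """Missense background: all seven tools informative, six Bernoulli(p)
    plus CADD with its mixture exceedance; the consensus-candidate rate
    must sit inside the 99% binomial CI of the exact tail computed from
    those components."""
    cfg = SimulationConfig()
    n = 4000
    variants = _mk_variants(n)
    recs = simulate_annotations(
        variants, set(), cfg, rng, {v.variant_id: None for v in variants}
    )
    observed = sum(consensus_call(r).is_candidate for r in recs)
    # CADD >= 20 probability under the background mixture (scores are
    # rounded to one decimal, hence the 19.95 threshold)
    w = cfg.background_cadd_high_weight
    p_cadd = w * norm.sf(19.95, 23.0, 3.0) + (1 - w) * norm.sf(19.95, 10.0, 5.0)
    p = cfg.background_damaging_prob
    # candidate needs >= ceil(0.6 * 7) = 5 damaging of 7 available
    p_cand = sum(
        binom.pmf(j, 6, p) * (
            (1.0 if j >= 5 else 0.0) * (1 - p_cadd)
            + (1.0 if j >= 4 else 0.0) * p_cadd
        )
        for j in range(7)
    )
    lo = binom.ppf(0.005, n, p_cand)
    hi = binom.ppf(0.995, n, p_cand)
    assert lo <= observed <= hi


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def test_mendelian_consistency_exhaustive(small_family):
    assert count_mendelian_violations(small_family.genotypes, small_family.pedigree) == 0


def test_same_seed_byte_identical_output(tmp_path):
    cfg = SimulationConfig(n_families=2, n_background_variants=100, seed=5)
    for d in ("a", "b"):
        write_dataset(tmp_path / d, simulate_dataset(cfg))
    for name in ("variants.vcf", "families.ped", "annotations.tsv", "truth.json"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)


def test_truth_json_one_causal_per_family(tmp_path):
    cfg = SimulationConfig(n_families=3, n_background_variants=50, seed=9)
    paths = write_dataset(tmp_path, simulate_dataset(cfg))
    truth = json.loads(paths["truth"].read_text())
    assert len(truth) == 3
    assert len({t["causal_variant_id"] for t in truth}) == 3


def test_written_vcf_round_trips_genotypes(tmp_path):
    from famseg import read_vcf

    cfg = SimulationConfig(n_families=1, n_background_variants=60, seed=3)
    fams = simulate_dataset(cfg)
    paths = write_dataset(tmp_path, fams)
    _, matrix = read_vcf(paths["vcf"])
    fd = fams[0]
    sub = matrix.subset_samples(fd.genotypes.sample_ids)
    idx = [sub.variant_ids.index(v) for v in fd.genotypes.variant_ids]
    assert np.array_equal(sub.gt[idx], fd.genotypes.gt)
    assert np.array_equal(sub.ad_ref[idx], fd.genotypes.ad_ref)
    assert np.array_equal(sub.ad_alt[idx], fd.genotypes.ad_alt)


def test_background_survivors_monotone_in_maf_threshold():
    """Tightening the rarity cutoff never adds cascade survivors."""
    from famseg import FilterConfig
    from famseg.pipeline import analyze_simulated_family

    cfg = SimulationConfig(n_background_variants=400, seed=17)
    fd = simulate_family(cfg, np.random.default_rng(17), "F")
    previous = None
    for maf_max in (0.01, 0.001, 0.0001):
        fcfg = FilterConfig(maf_max=maf_max)
        report, _ = analyze_simulated_family(fd, fcfg)
        n = report.counts["cadd_acmg"]
        if previous is not None:
            assert n <= previous
        previous = n


def test_larger_families_leave_fewer_background_survivors():
    """Fixed seeds: mean non-causal survivors after segregation is no
    larger in three-generation families than in the smaller nuclear
    template."""
    from famseg.pipeline import analyze_simulated_family

    means = {}
    for template in ("nuclear_extended", "three_generation"):
        counts = []
        for seed in range(12):
            cfg = SimulationConfig(
                pedigree_template=template,
                n_background_variants=300,
                penetrance=1.0,
                phenocopy_rate=0.0,
                n_affected_target=2,
                seed=seed,
            )
            fd = simulate_family(cfg, np.random.default_rng(seed), "F")
            report, _ = analyze_simulated_family(fd)
            seg = set(report.survivors["segregating"])
            counts.append(len(seg - {fd.truth.causal_variant_id}))
        means[template] = np.mean(counts)
    assert means["three_generation"] <= means["nuclear_extended"]
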