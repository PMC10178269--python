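# Methods

This note documents the models, rules and numerical choices behind
`famseg`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The package targets the standard design for gene discovery in multiplex
families with a dominantly inherited phenotype: exome-sequence two or
more affected members (plus an unaffected relative where available),
annotate the called variants, and prioritize those that are rare,
protein-relevant, well supported by reads, computationally or clinically
deleterious, and co-segregating with disease. The phenotype is modelled
as autosomal dominant with incomplete penetrance; phenocopies are
allowed. Recessive, X-linked and de novo models are out of scope.

## Filter cascade

Stages are pure per-variant predicates, so the final survivor set is
invariant to stage order (property-tested); the funnel report lists
counts in the order the stages execute and can render them in the
column layout conventional for cohort summaries (rarity columns before
consequence).

* **Rarity** (`maf_max`, default 10⁻³). A missing MAF means the variant
  is absent from population databases ("novel") and always passes.
  `novel_only=True` gives the stricter first-pass rule (MAF exactly 0 or
  unobserved); studies typically relax it to 10⁻³ when strict novelty
  leaves families empty-handed.
* **Consequence** (`splice_window`, default 30, valid 20–30). Missense,
  nonsense, frameshift and in-frame indels pass unconditionally. Exonic
  synonymous changes are removed outright. Splice-region and noncoding
  variants pass only within `splice_window` bases of an exon. The
  default sits at the permissive end of the conventional 20–30 bp range;
  it is a recall-preserving choice and is configurable.
* **Read support** (`af_min`, default 0.30). A variant is kept when at
  least one sequenced affected carrier shows an alternate-allele read
  fraction ≥ `af_min`. The "at least one" reading is deliberate:
  requiring every carrier to clear the threshold would let a single
  poorly covered sample veto a genuine germline variant. Variants with
  no usable depth in any affected carrier are kept and flagged
  `af_unassessed` — absence of depth information is not evidence
  against the variant.
* **Deleteriousness** (`cadd_min` 20, `acmg_min` 3, `rescue_mode`
  `either`). The default keeps a variant passing the CADD *or* the ACMG
  clause (OR-rescue). This is the reading consistent with observed
  practice — likely-benign variants with CADD above 20 do survive such
  cascades — while `rescue_mode="both"` provides the strict conjunction.
  ACMG classes map onto the ordinal B=1, LB=2, VUS=3, LP=4, P=5; missing
  CADD or ACMG simply fails its own clause.

## Segregation

Under the dominant model, "compatible with the inheritance pattern" is
operationalized as carrier status (het or hom-alt). A variant segregates
iff every *genotyped* affected individual is a carrier and the number of
genotyped unaffected carriers is at most `max_unaffected_carriers`
(default 1 — exactly one healthy carrier is tolerated because penetrance
is incomplete; hom-ref unaffecteds never count against a variant).
Individuals with unknown phenotype are excluded from both criteria.
Missing genotypes in affecteds are ignored by default (the individual
drops out of the "all affecteds" universe) rather than treated as
counter-evidence; `treat_missing_affected="fail"` gives the strict
behavior. Families with fewer than `min_genotyped_affected` (default 2)
informative cases cannot refute segregation: their variants pass the
prefilter with verdict `insufficient_data` and a logged warning.

The two-stage structure mirrors practice: `pedigree_prefilter` assesses
the exome-sequenced subset, `full_family_segregation` re-assesses
survivors once all members with available DNA are typed (emulating
confirmatory single-site genotyping). Extending the genotyped set can
only eliminate candidates, never rescue them — property-tested by random
matrix extension. Obligate carriers inferred from descendants are not
counted; only observed genotypes enter the tally.

## Consensus pathogenicity

Per-tool damaging rules follow each predictor's documentation: SIFT
≤ 0.05; PolyPhen-2 ≥ 0.85 (labels PD and P damaging); LoFtool percentile
≤ 0.5 (labels PD/D damaging — lower percentile = more intolerant gene);
MutationAssessor functional-impact labels M and H damaging, L not
(score fallback ≥ 1.9, the medium-impact band); MutationTaster
disease-causing labels (DC, DC_automatic); FATHMM ≤ −1.5; CADD phred
≥ 20 (score only — the tool has no label vocabulary). Printed labels
take precedence over numeric re-thresholding: published tables
occasionally misdescribe a tool's scale in prose while the labels are
internally consistent, so the label is the authoritative call.

A variant is a consensus candidate when damaging verdicts reach
`fraction_min` (default 0.60, inclusive — 3 of 5 qualifies) of the
denominator. Two denominators are first-class: `available` (tools that
returned a prediction; the permissive and default reading) and
`all_seven` (strict; penalizes truncating variants that substitution
scorers cannot assess). Published candidate totals in this literature
are not always recoverable under either convention alone, so
`classify_all` reports both and flags calls supported by fewer than 3
informative tools as `low_support`. One packaged LoFtool cell carries a
value outside the tool's 0–1 percentile range; it is transcribed
verbatim, flagged `loftool_suspect`, and only its label is interpreted.

## Enrichment

One-sided hypergeometric (Fisher-exact, enrichment side) tests, the
statistic underlying the common enrichment portals. The default
background is the union of genes in the supplied GMT sets (no genome
annotation is bundled; a genome-wide background can be supplied as a
set file or via `background="user_list"`). Retention uses the raw p
(< 0.01) together with overlap ≥ 3 and enrichment factor
k/(n·K/N) > 1.5; adjusted values (Bonferroni, BH, BY via statsmodels)
are reported alongside. Retained terms are linked when the Cohen's
kappa of their gene memberships over the background exceeds 0.3, and
clusters are the connected components of that graph — the simplest rule
consistent with a similarity-threshold edge definition; agglomerative
refinements used by specific portals are intentionally not imitated.
Ordering is deterministic (p ascending, term id tiebreak).

## Synthetic family-WES generator

The generator emulates the study conditions the analysis assumes, not
raw sequencing:

* **Pedigrees.** A three-generation template (founder couple, three
  married children, six grandchildren; 14 members) and a smaller
  nuclear-extended template (9 members). One founder carries the causal
  allele heterozygously; affection is Bernoulli(penetrance = 0.9) for
  carriers and Bernoulli(phenocopy = 0.01) otherwise, redrawn (bounded)
  until the family reaches its ascertainment target (default 3
  affected). All cases plus one unaffected relative are marked
  exome-sequenced, matching the typical design.
* **Genotypes.** Founders draw background genotypes from Hardy-Weinberg
  at each variant's MAF; children inherit one allele per parent
  uniformly — no de novo or mosaic events. Depth is Poisson(150); het
  allelic fractions are Beta(20, 20) (mean 0.5, sd ≈ 0.078), so the 30%
  read-support rule clips a small, seed-stable tail; hom calls get a
  small cross-contamination error rate (0.1%).
* **Background variation** (default 5,000 variants/family) mixes common
  (U(0.01, 0.5), weight 0.70), rare (U(10⁻⁴, 10⁻³), 0.20) and novel
  (MAF 0, 0.10) variants — an exome-like profile in which a few percent
  of protein-relevant variants survive the rarity filter — over a
  consequence mix dominated by missense. Real per-exome totals are two
  orders of magnitude larger; funnel shapes are therefore qualitative,
  not quantitative, matches, and the recovery experiments in the
  acceptance script use 400 background variants per family (causal
  recovery does not depend on background size).
* **Annotations.** Causal variants: CADD ~ N(30, 3) truncated at 20,
  ACMG ∈ {VUS, LP, P} (0.4/0.4/0.2), per-tool damaging probability 0.9.
  Background: CADD from a mixture favoring sub-threshold scores (85%
  N(10, 5) clipped at 0, 15% N(23, 3)), mostly benign ACMG classes,
  per-tool damaging probability 0.15. Labels and scores are generated
  jointly so they are consistent under the consensus module's own
  thresholds. Truncating variants lose SIFT/PolyPhen-2/
  MutationAssessor/FATHMM independently with probability 0.9,
  reproducing the missingness pattern of substitution scorers. Scores
  are conditionally independent across tools given causal status —
  sufficient to exercise the ≥ 60% rule; inter-tool correlation is out
  of scope.
* **Determinism.** Every draw flows from one `numpy` Generator seeded
  from the config; identical seeds give byte-identical output files.

What passing tests on synthetic data do *not* show: robustness to
annotation errors, pedigree misspecification, somatic contamination,
population stratification, or correlated predictor errors — none of
which the generator models.

## Numerical and scale choices

Exact hypergeometric tails come from `scipy.stats.hypergeom.sf(k-1, …)`
and are verified in tests against a combinatorial enumeration oracle
(all instances with N ≤ 25) and a literal draw-enumeration ground truth
at small N. P-value adjustment wraps `statsmodels.multipletests`,
cross-checked against hand-coded step-up references on 1,000 random
vectors. The acceptance experiments use 100 simulated families for
recovery, 10,000 meioses for the transmission check (99% binomial CI),
and two independent regenerations for the determinism contract; these
sizes keep the whole script under a minute while leaving the
Monte-Carlo intervals narrow. Monte-Carlo tests are seeded and
hypothesis-based property tests use bounded example counts, so the
suite is deterministic.

## Known limitations

Only the dominant segregation model is implemented. ACMG classes and
predictor scores are consumed annotations — nothing is recomputed from
sequence. Coordinates are 1-based VCF-style with no liftover. HGVS
strings are carried, not validated. The enrichment module does not
bundle gene-set databases, and term clustering is deliberately simpler
than portal-specific agglomerative schemes.
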