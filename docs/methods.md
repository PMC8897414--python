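# Methods

This note records the models, conventions and numerical choices behind
`varprio`, in the order data flows through the toolkit.

## Score harmonization

Prediction tools disagree on orientation and scale. All ranking statistics
are computed on harmonized scores (higher = more deleterious):

* lower-is-risk tools (SIFT, MAPP) are **negated** for ranking. Negation is
  the minimal strictly monotone order-reversal; since ROC curves and the
  Mann–Whitney AUC depend only on ranks, any other monotone conversion
  would give identical curves. Filter cutoffs are always reported back on
  the native scale with the native direction (e.g. SIFT ≤ 0.175), because
  that is how users and annotation pipelines consume them.
* splice-site-strength tools (SSF, MaxEnt, NNSplice) are summarized as the
  **percent loss of strength**, 100·(wt − var)/wt. Positive values mean the
  variant weakens the site; wt = 0 or a missing input yields a missing
  score (the ratio is undefined).
* SpliceAI contributes the **maximum of its four delta scores**
  (acceptor/donor × gain/loss), each validated to [0, 1].

Missing values are first-class throughout: a missing score stays missing
through every transform, and each consumer declares its policy explicitly.

## ROC, AUC, and DeLong inference

Per tool, rows without a score are deleted (per-tool deletion) and the ROC
is evaluated at every distinct observed score with inclusive pass
predicates (≥ for higher-is-risk after mapping back, ≤ for lower-is-risk).
The AUC is computed from DeLong structural components with midranks, so it
equals exhaustive concordant-pair counting (ties count ½) to machine
precision — the test suite asserts agreement to 1e−12 with both a
brute-force pair count and scikit-learn's rank-based AUC. The variance is
S₁₀/m + S₀₁/n over the per-positive and per-negative components; the 95%
interval is the normal (Wald) interval clipped to [0, 1]. Splicing-family
tools are evaluated on the splicing-subset rows only; non-splicing tools on
the full table.

Two tools are compared on the rows scored by **both** (pairwise deletion)
with the paired DeLong z-test; a rank-identical pair returns Δ = 0, p = 1
without attempting a 0/0 division.

Caveat recorded for CI users: the Wald interval is known to undercover as
the AUC approaches 1 (we observe ≈91% empirical coverage at AUC ≈ 0.92
with 500 + 500 samples, against ≈95% at AUC ≈ 0.76). The coverage property
test therefore runs at unit class separation; this is a property of the
interval shape, not of the variance estimator.

## Cutoff strategies and tie-breaks

Three operating-point rules, all scanning observed thresholds only:

* **Youden**: maximize Se + Sp − 1;
* **Se = Sp**: minimize |Se − Sp|;
* **sensitivity floor** (default, target 0.90): the strictest threshold
  whose sensitivity still reaches the target. Specificity is then maximal
  subject to the floor because specificity is monotone in strictness.

Where an objective ties across thresholds, the rule prefers higher
sensitivity, then the stricter cutoff. The tie-break is a convention of
this package (the operating-point literature leaves it open) and is applied
identically in the implementation and in the brute-force oracle tests.

## Combination models

A combination is a conjunction of member filters with pass-if-missing
semantics: a variant passes iff every member's score is missing or beyond
its cutoff. This mirrors the cascade's "≤ c or missing" filters, which keep
high-missingness tools (MAPP is absent for over half of substitutions)
usable without discarding unscored variants. Rates on a labeled table:

* TP (FP) rate = percent of pathogenic-like (benign-like) variants passing,
  computed over rows with **at least one** non-missing member score;
* missing rate = percent of rows where **all** member scores are missing.

With this denominator convention, adding a member always shrinks the set of
passing variants (asserted as a property test), but the TP/FP *rates* are
guaranteed non-increasing only while the scored-row denominator is fixed —
e.g. whenever a fully observed tool such as CADDv1.6 is a member. Default
selection criteria are TP ≥ 85%, FP ≤ 35%, missing ≤ 30%; qualifying
models are ranked by ascending FP, then descending TP, then fewer members.
The candidate list is configuration-driven (a YAML list of member sets);
without a file, all non-empty within-family subsets are enumerated.

## The discovery cascade

Stage order and conventions (all coordinates 1-based VCF):

1. **recurrence** — drop variants homozygous or hemizygous for the ALT in
   any unaffected individual; unaffected members of the other families act
   as pseudo-controls. Heterozygous carriage never disqualifies.
2. **multiallelic** — drop records at sites with more than one ALT
   (site-level, before any splitting).
3. **frequency** — keep gnomAD AF ≤ 0.01 or absent (absent = rare).
4. **branches** — non-splicing: CADDv1.6 ≥ 22.25 is a mandatory gate
   (missing fails), then MAPP ≤ 0.098, Grantham ≥ 28, SIFT ≤ 0.175 each
   pass-if-missing; splicing: SpliceAI max ΔS ≥ 0.405 gate, then
   NNSplice ≥ 62.73 pass-if-missing. The **ClinVar rescue** lane hangs off
   the pre-frequency set and retains Pathogenic / Likely_pathogenic /
   combined entries regardless of scores; variant identity for the lookup
   is (chrom, pos, ref, alt) after suffix-then-prefix trimming
   (left normalization).
5. **union** — keyed by (chrom, pos, ref, alt), provenance tags merged;
   every emitted variant carries at least one tag.
6. **pedigree filter** — per family:
   * AR-hom: biallelic-ALT in every affected, in no unaffected member;
   * AR-comp-het: ≥ 2 heterozygous variants in one gene in the index, with
     no unaffected member carrying both of a qualifying pair — the standard
     phase-free approximation, chosen because short-read WGS rarely phases
     distant variants;
   * AD: heterozygous in every affected; unaffected must be hom-ref or
     missing (a missing genotype never disqualifies — lenient by design,
     since cohort merging leaves uncalled sites);
   * XL: hemizygous-ALT affected males, homozygous-ALT affected females;
     unaffected males must not carry the ALT hemizygously, unaffected
     females may be carriers.
   Under a consanguineous model, homozygous fits are listed first.
7. optional **zero-homozygote** post-filter (gnomAD nhomalt = 0 or absent).

Every stage appends (name, survivor count) to a trace; counts are
non-increasing along each linear branch and reruns are byte-identical.

Structural variants use four commuting pure predicates — REFCN:CN genotype
code ∈ {2:0, 2:1, 2:3, 2:4, 1:2, 1:0}, ≤ 3 carriers (events merged by
exact (chrom, start, end, type) before counting; no reciprocal-overlap
fuzziness, noted as an extension point), AF ≤ 0.01 or absent, and ≥ 1
exonic base of closed-interval overlap (BED input converted from 0-based
half-open) — plus PASS-quality and the same recurrence bound for mobile
element insertions.

## Gene constraint

LOEUF is benchmarked lower-is-risk (strong selection against
loss-of-function ⇒ low LOEUF) by ROC between a disease gene set and an
unconstrained control set, reusing the ROC machinery; the
sensitivity-at-90% rule then yields an inclusive ≤ cutoff and
`classify_gene` labels query genes constraint-compatible or not. Gene
symbols match exactly, case-insensitively; alias resolution is out of
scope.

## Synthetic data

The generators are pure functions of (spec, seed) with one
`numpy.random.default_rng` per call and no global state.

* **Score tables** default to the training-set design: 942 variants
  (247 pathogenic-like / 695 benign-like) with a 99-row splicing subset
  (34/65). Each tool's classes are equal-variance Gaussians: the pathogenic
  mean sits z₀.₉·σ above (below, for lower-is-risk) the tool's configured
  cutoff — so a sensitivity-at-90% calibration recovers the cutoff — and
  the class separation is d = √2·Φ⁻¹(AUC) for the tool's nominal AUC, with
  per-tool missing rates (e.g. MAPP 54.78%, SIFT/Grantham 44.48%, CADDv1.6
  0%). σ is set per score scale and bounded scales are clipped, which
  piles realistic point masses at the bounds (SIFT at 0) but slightly
  perturbs quantiles; parameter-recovery tests therefore use unbounded
  specs. Splicing tools are scored only on splicing-subset rows.
* **Cohorts** default to seven families / 14 genomes (9 affected, 5
  unaffected) with one AR-homozygous causal plant carrying gate-passing
  annotations; genotypes of planted variants follow their inheritance
  model (affected homozygous, relatives carriers, other families
  reference), and background variants draw a log-uniform AF on
  [10⁻⁵, 0.5] with Hardy–Weinberg genotypes, benign-leaning scores, and a
  5% multiallelic fraction. VCFs are minimal valid 4.2 with GT-only
  FORMAT.
* **Validation fixtures** (`gen_validation_scores`, `gen_curation_cohort`)
  plant stated pass/fail compositions: n causal variants of which a stated
  number carry sub-gate CADD scores, and a curation cohort whose decoy
  candidates pass literature cutoffs (CADD ≥ 20) but not re-calibrated ones
  (CADD ≥ 22.25). These drive the retention/enrichment/workload numbers
  recomputed by `scripts/acceptance.py`.
* **Constraint sets** default to 207 disease vs 374 control genes with
  lognormal LOEUF (log-means log 0.7 / log 1.8, log-sd 0.5 / 0.35), chosen
  so the implied discrimination (AUC ≈ 0.94) and disease-set 90th
  percentile (≈ 1.3) resemble a real recessive-disease-vs-olfactory-gene
  benchmark and admit closed-form checks.

What passing tests on these fixtures do **not** show: real score
distributions are neither Gaussian nor independent across tools (CADD is
itself an ensemble over several member features), missingness is
consequence-dependent rather than Bernoulli, cohort LD/haplotype structure
is absent, and multiallelic or complex representation issues are only
minimally modeled. The fixtures validate the statistics and the filtering
logic, not tool performance on real genomes.

## Problem sizes and determinism

Defaults were chosen so the full test suite and the acceptance script each
complete in well under a minute on a single core: training-scale tables of
942 rows, simulation studies of 30–100 seeds at n ≤ 5000 per class,
cohorts of a few hundred background variants. Every stochastic step takes
an explicit integer seed; the CLI exposes it, and identical (inputs,
config, seed) reproduce identical outputs byte-for-byte.

## Known limitations

* The SIFT/MAPP harmonization preserves ranks only; native-scale dot-plot
  comparability with any specific annotation platform's internal conversion
  is not attempted.
* Comp-het detection is phase-free and can retain cis pairs no unaffected
  relative happens to carry.
* ClinVar matching is exact after left normalization; MNV decomposition is
  not performed.
* CNV identity across samples is exact-coordinate; fuzzy reciprocal
  overlap would be needed for caller-to-caller comparisons.
* The Wald DeLong CI undercovers near AUC = 1 (see above); a logit-scale
  interval would be a natural extension.
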