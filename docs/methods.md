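# Methods

## Mutation spectra

Somatic single-nucleotide variants are read from TCGA-dialect MAF (or
single-sample VCF, multi-allelic rows split per ALT) and classified into
the de facto standard 96-channel layout: substitution-class blocks C>A,
C>G, C>T, T>A, T>C, T>G with flanking bases in alphabetical order, all
read on the pyrimidine strand. Purine-reference mutations are folded onto
the reverse complement (a plus-strand G>A in context TGA counts as
T[C>T]A). Coordinates are 1-based throughout, matching both source
dialects.

Integrity rules, chosen to fail loudly rather than silently repair:

* a record whose FASTA base disagrees with its stated reference allele is
  dropped and counted, never corrected — silent correction hides liftover
  errors;
* a site whose trinucleotide contains N, or that sits at a contig end
  (context undefined), is excluded from spectra and from motif
  denominators;
* non-SNV rows are skipped with a logged count, and for any input
  `used + rejected = records read`, asserted in the tests and echoed in
  the pipeline run log.

## APOBEC enrichment and minimum load

Per sample, over pyrimidine-normalized C>T and C>G mutations only (C>A is
deliberately excluded from the denominator, exactly as the statistic is
defined):

    E = [ (TCW→TGW + TCW→TTW) / (C→G + C→T) ] / [ TCW / C ]

The context fractions TCW and C are counted over the ±`flank` (default
20 nt) reference window around each mutated cytosine, on both strands.
Two conventions matter and are fixed as follows:

* overlapping windows of nearby mutations are each counted in full — the
  denominator is per-window, not a deduplicated union;
* a cytosine inside the window keeps its *genomic* trinucleotide: motif
  status is evaluated from the reference with one base of padding beyond
  the window, so a cytosine at the window edge is not artificially denied
  TCW status. (Evaluating the motif strictly inside the window biases E
  upward by roughly the edge fraction 2/(2·flank+1); the repeated-TCAA
  null test exposes this, giving E = 3 instead of 1.) A cytosine at a
  contig end has undefined context and never counts as TCW.

The minimum APOBEC load is `(TCW→TGW + TCW→TTW) × (E−1)/E`, rounded half
away from zero and clamped below at 0 (so min_load = 0 whenever E ≤ 1).
At the conventional enrichment threshold E > 2 (exposed as
`APOBEC_ENRICHED_MIN = 2.0`) the attributed fraction (E−1)/E exceeds ½.
When a sample has no qualifying mutations or no context cytosines, E is
NaN and the load 0.

Per-sample significance is an auxiliary one-sided Fisher exact test of
(mutations at TCW vs other C) against (context TCW vs other C), with
Benjamini–Hochberg q-values across the cohort; the enrichment statistic
itself, not the test, is the primary quantity.

## Bayesian NMF with automatic relevance determination

The cohort catalog V (samples × 96, transposed internally to channels ×
samples) is factorized as V ≈ WH under the generalized Kullback–Leibler
divergence — the MAP objective for Poisson counts, which mutation
catalogs are. Each component k carries exponential (L1) priors on its
signature and exposure entries with a shared scale λ_k, and λ_k an
inverse-gamma(a, b) hyperprior. The penalized objective

    C = D_KL(V ‖ WH) + Σ_k [ (‖w_k‖₁ + ‖h_k‖₁ + b)/λ_k + (F+N+a+1) log λ_k ]

is minimized by multiplicative majorization–minimization updates for W and
H and a closed-form update for λ, so C is non-increasing every iteration
(asserted per-iteration in a test). Relevance scales of unneeded
components collapse toward b/(F+N+a+1); components with λ_k below 1% of
the largest (or with vanishing mass) are pruned after convergence, and the
retained count is the selected rank.

Defaults: a = 10 (stiff enough that empty components are driven out
decisively), b = √((a−1)(a−2)·mean(V))/K (a data-driven scale so the
prior is comparable to one component's share of the data), tolerance
1e-7 on the relative objective change checked every 10 iterations,
max_iter 100 000 (typical runs converge in a few hundred iterations;
40 × 96 catalogs factorize in ~40 ms). Rank selection on well-separated
three-signature simulations is insensitive to a over at least 2.5–20.
Signatures are L1-normalized with the scale absorbed into exposures, and
relabeled W1…Wk by decreasing total exposure. Ties between
equal-divergence restarts are broken by the lowest seed.

`stability` reruns the factorization with consecutive seeds and reports
the rank histogram; restarts-with-distinct-seeds is the implemented
notion of recurrence (a sample-bootstrap is easy to add but is not
claimed to be equivalent). Cosine matching against a COSMIC-v2-layout
reference TSV is a plain dot-product on L2-normalized rows; the real
COSMIC table is user-supplied, never bundled.

## Biomarker statistics

* **Logistic regression** is fitted by IRLS (statsmodels GLM/binomial).
  Complete or quasi-complete separation is detected (perfect
  classification with |linear predictor| > 15) and flagged rather than
  raised, since a separated fit still orders samples.
* **Hosmer–Lemeshow**: samples are cut at the g-quantiles (default
  g = 10) of the fitted probabilities, ties inseparable, so fewer bins
  can result; bins with zero expected events or non-events are merged
  with a neighbor and marked. χ² = Σ (O−E)²/E over events and
  non-events, df = bins − 2. Small p means poor calibration. Note the
  test measures calibration, not discrimination: a fitted
  constant-probability model on an uninformative predictor is also
  calibrated, so H-L p-values alone do not rank predictors — the report
  therefore also carries slopes, standard errors and fold changes.
* **Quartile grouping** uses linear-interpolation quantiles with strict
  inequalities (UP strictly above Q3, DOWN strictly below Q1); boundary
  membership depends on the quantile convention, which is why it is
  pinned and documented.
* **Two-group comparison** encodes the convention that preprocessed
  expression values are treated as normal (t-test) and mutation counts
  as non-normal (Wilcoxon rank-sum): `auto` routes integer-valued input
  to Wilcoxon. The routing is deterministic rather than based on a
  per-call normality test, trading adaptivity for reproducibility; the
  method used is recorded in the result.
* **Fold change** is the ratio of group arithmetic means. DCB/NDB labels
  are consumed from input; the underlying 6-month response rule is
  documentation only. Benjamini–Hochberg adjustment is the standard
  step-up (monotone, capped at 1 — and not idempotent, which is a
  property of the procedure, not a bug).
* **Immune score** is the per-sample mean of log2 expression over a
  user-supplied gene set (missing genes reported); its association with
  per-signature exposures is Spearman rank correlation, a deliberately
  assumption-light stand-in since no particular parametric link is
  defensible.

## Synthetic cohorts

The generator emulates a pembrolizumab-treated NSCLC cohort well enough
to exercise every stage:

* **Reference**: single contig (default 100 kb), uniform base
  composition with a motif planting/destroying knob tuned by bisection
  until the realized TCW-per-cytosine fraction is within ±10% relative
  of the target (default 0.15, near the genome-wide order of magnitude).
* **Catalogs**: per sample and signature, mutation counts are
  gamma-Poisson — defaults: APOBEC mean 23 with shape 0.5 (matching the
  cohort's reported mean APOBEC load and its heavy right skew, loads
  ranging to ~200), smoking mean 170 and MMR mean 75 with shape 1.5
  (together giving a total burden near 270). Dispersion also provides
  the across-sample variation in signature proportions that makes the
  factorization identifiable. Each mutation draws a 96-channel from its
  signature and lands uniformly on an unused matching reference
  position (no duplicate positions within a sample).
* **Signatures**: APOBEC-like (85% of mass on T[C>T/G]A/T), smoking-like
  (80% on C>A), MMR-like (50% CpG C>T + 30% T>C) — well-separated
  caricatures of signatures 2/13, 4 and 6.
* **Labels**: P(DCB) = logistic(β0 + β1·APOBEC exposure), defaults
  β0 = −1.5, β1 = 0.08 chosen to give a DCB prevalence near 45% (the
  cohort's 14/31) with strong but imperfect separation.
* **Expression**: log2-scale Normal(5, 1) background, a 60-gene immune
  module and an APOBEC3B gene each shifted by effect_size × standardized
  APOBEC exposure (default 1.0).

All randomness flows from the single spec seed through named substreams
(reference, catalog, labels, expression), so each stage is independently
reproducible and two runs of the pipeline with one seed are byte-identical.

What the generator does *not* emulate — real base composition and
replication-timing structure, gene lengths, kataegis clustering, subclonal
copy-number, germline contamination, caller-specific artifacts — bounds
what passing tests show: they validate the statistics and the machinery,
not performance on real tumors.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by choice:
cohorts of 5–60 samples on 10–100 kb references, 40-sample
three-signature catalogs at ~180 mutations/sample, 50 NMF restarts,
1000 replicates for H-L calibration and 2000 for two-group type-I error.
ε-guards of 1e-12 protect divisions in the NMF updates; spectra and
catalogs are integer arrays end to end; enrichment arithmetic is exact
rational until the final division.

## Known limitations

* No YTCA/RTCA subclassification (APOBEC3A vs 3B) and no kataegis
  detection; the enrichment statistic aggregates all TCW activity.
* No hypermutator exclusion at the cohort level; callers should filter
  upstream if desired.
* Signature extraction offers no refitting of exposures against a fixed
  external catalog; exposures come from the factorization itself.
* The Fisher-exact per-sample p-value treats context cytosines as
  independent trials, which overlapping windows violate mildly; it is
  labelled auxiliary for that reason.
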