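# Methods

This note records the models and procedures the package implements, the
parameters that matter, and the places where the design was genuinely
open and a choice had to be made.

## Data model

A *cohort* is one study's gene × sample matrix of normalized log2
expression with a binary tumor/non-tumor label per sample. Cohorts are
never merged at the sample level; heterogeneity between studies
(platform, processing, population) is treated as irreducible, and the
pipeline is built so that only rank-level summaries cross cohort
boundaries. Inputs are assumed already normalized and log2-scaled;
raw-array processing is out of scope. Probe-level matrices are
collapsed to gene level by keeping, per gene, the probe with the largest
inter-quartile range (Q3 − Q1, linear-interpolation quantiles; ties
broken by file order so the result is reproducible).

## Ranking and aggregation

Within each cohort, genes are scored by one of three criteria:

- `abs_log2fc` (default): |mean(log2 expr | tumor) − mean(log2 expr | non-tumor)|.
  Plain group means are used rather than a moderated linear-model
  statistic: the formula is fully specified, package-free, and the
  quantity the rank aggregation is defined on.
- `pvalue`: two-sided Welch t-test (smaller = more informative).
- `svm_weight`: |weight| of a linear SVM on the z-scored cohort.

Ranks (1 = best, ties broken lexicographically by gene ID — never by a
seed) are normalized as normR = (R − 1)/(max R − 1), which maps each
cohort's ranking onto [0, 1] regardless of how many genes the platform
measures, and aggregated as the arithmetic mean across training
cohorts. Aggregation is restricted to the intersection of the training
cohorts' gene universes: the mean with a fixed denominator is otherwise
undefined for genes missing from some cohorts, and no rule for such
genes is prescribed by the aggregation formula itself. When a gene set
is subsequently *evaluated* on a cohort that does not measure some of
its genes, those genes are skipped and the next-ranked measurable gene
moves up; cross-platform absence is the norm, not an error.

## Classification protocol

A gene set's discriminative value on a cohort is the AUC of an
RBF-kernel SVM in a stratified ("balanced") 10-fold cross-validation
(folds reduced to the minority class size when necessary). Per outer
fold, features are z-scored with training-fold statistics and (C, γ)
are chosen by grid search maximizing AUC in an inner stratified 3-fold
CV of the training fold. Defaults: C ∈ {2⁻³, 2⁻¹, …, 2⁷},
γ ∈ {2⁻⁷, 2⁻⁵, …, 2³} (6 × 6 log2 grid), inner fold count 3 — the grid
and inner fold count are conventional choices exposed as arguments.
Decision values of all outer test folds are pooled into a single ROC
(trapezoid AUC); the 95% CI uses DeLong's variance estimate.

Two properties anchor the implementation: the pooled-ROC trapezoid AUC
equals the normalized Mann–Whitney U statistic of the pooled decision
values (checked against `scipy.stats.mannwhitneyu`), and AUC is
invariant under per-evaluation monotone transforms of the scores.

**Known limitation.** DeLong's variance assumes independent scores;
pooled CV decision values are not independent (each fold's classifier
differs), so the interval is mildly anti-conservative. Under a null
simulation (labels independent of features, 30+30 samples) the nominal
95% interval covered 0.5 in roughly 76% of runs while the AUC itself
stayed centered on 0.5. The CI should be read as a within-evaluation
precision summary, not a calibrated frequentist interval for the CV
procedure.

### SVM solver

The nested design performs on the order of 10⁵ small SVM fits per
pipeline run (tens of samples, dozens of features each). The package
therefore ships a compact SMO solver (`_svm.py`, numba-JIT) for the
standard soft-margin C-SVC dual with libsvm's working-set selection and
stopping tolerance (1e-3). It is exact for the same optimization
problem libsvm solves; the test suite asserts agreement of decision
values with `sklearn.svm.SVC` to 5e-3 across random problems. A fit
costs ~20 µs versus ~1 ms through the full estimator API, which is what
makes the permutation control and the nested gene-count optimization
desk-scale.

## Gene-count optimization and the outer loop

For each held-out cohort, the remaining cohorts form the training set.
The signature size n ∈ {5, 10, …, 50} is optimized in an inner
leave-one-cohort-out loop *within the training set*: for each inner
holdout, rankings are re-aggregated over the remaining training cohorts
(mirroring the outer structure, so no cohort ever contributes to a
ranking it is evaluated on), the top-n genes are scored on the inner
holdout with the full 10-fold SVM protocol, and n's score is the mean
over inner holdouts. Ties go to the smallest n (parsimony). The top-n
of the full training aggregate is then evaluated once on the held-out
cohort.

Per-holdout gene sets combine into the union (the classifier gene list)
and the intersection (*core* genes, selected in every round); the core
can be further filtered to genes whose clusters carry survival signal.
The held-out cohort influences nothing upstream of its own test AUC —
asserted by a test that replaces a held-out cohort's values with noise
and checks the selection for that round is unchanged.

Note an interaction between parsimony and the core set: when the
planted (or true) signal is strong enough that five genes already give
inner AUC = 1.0, the tie rule fixes n = 5 for every holdout and the
core can never exceed five genes, however many informative genes exist.
Core-gene counts are therefore informative about signature *stability*,
not about the total number of informative genes.

## Single-cohort baseline

The contrast case selects a signature from one cohort alone: outer
stratified 10-fold CV; per outer training split, genes are ranked by
|log2FC| of the training samples only and n ∈ {1..10} is chosen by an
inner 3-fold CV of the training samples; the top-n SVM predicts the
outer fold. Because folds select different genes, the result reports
per-fold selections plus a cross-fold selection-frequency table rather
than forcing a single list; `signature_genes` consolidates by frequency
(gene count = median of per-fold counts) when a concrete list is needed
for cross-cohort transfer experiments.

## Consensus clustering

Classifier genes are clustered on co-expression. Multi-cohort
expression is combined by z-scoring each gene within each cohort and
concatenating samples — removing platform location/scale while using
all samples (a per-cohort consensus average is the documented
alternative). Per resample, ⌈0.8·S⌉ sample columns are drawn without
replacement (250 resamples by default; genes are never resampled, so
the consensus denominator is the resample count), gene–gene distance is
1 − Spearman ρ, and Ward linkage is cut at k. The consensus matrix is
the co-clustering frequency; the reported assignment is a Ward cut on
1 − consensus.

k is selected from the empirical CDF of off-diagonal consensus values:
with A(k) the area under the CDF, Δ(2) = A(2) and
Δ(k) = (A(k) − A(k−1))/A(k−1), and k_best is the largest k with
Δ(k) > 0.1. The threshold replaces visual CDF inspection with a fixed
rule. If the chosen clustering leaves more than 30% of gene pairs with
ambiguous consensus (between 0.1 and 0.9) the result is flagged
unstable — the signature of data without reproducible cluster
structure. Genes constant across all samples are rejected by name
(Spearman undefined); a gene constant only within one subsample
contributes zero correlation for that resample.

## Survival analysis

For one gene cluster, patients are clustered on their z-scored
expression profiles (Ward, Euclidean) and cut at three groups, named
low / intermediate / high by ascending mean z-scored expression —
per-gene z-scoring prevents high-variance genes from dominating the
distance, and the naming rule makes group labels deterministic. Fewer
than three distinct patient profiles raise rather than silently forcing
a 3-split. Kaplan–Meier estimation and the k-group log-rank test are
delegated to lifelines; the KM estimator is verified against a
first-principles product-limit computation and the no-censoring
empirical survival identity. The 5-year rate reads the curve at the
last step at or before five years (time unit days by default,
365.25 days/year; a years scale is available) and flags truncation when
follow-up ends earlier.

## qPCR utility

Relative expression by the comparative Ct method: ΔCt = Ct(target) −
mean Ct(references) per record, ΔΔCt = ΔCt(sample) − ΔCt(calibrator),
reported as log2 fold change −ΔΔCt (fold = 2^−ΔΔCt). Multiple
reference genes are combined by the arithmetic mean of their Cts
(averaging Cts, not fold changes — the geometric-mean-of-expression
convention on the log scale). Amplification efficiency is assumed
ideal. A one-sided t-test against log2FC = 0 is provided for
elevation reporting.

## Synthetic data generator

The generator defines the regime the pipeline is validated in:

| parameter | default | meaning |
|---|---|---|
| `n_cohorts` | 4 | independent studies |
| `genes_per_cohort` | 1000 | features measured per study |
| `overlap_fraction` | 0.9 | expected pairwise universe overlap |
| `samples_per_class` | 30 | per class, per cohort |
| `n_planted` | 10 | truly differential genes |
| `effect_mean` / `effect_sd` | 2.0 / 0.5 | log2 shift in tumor class; cross-cohort spread |
| `noise_sd` | 1.0 | log2 residual noise |
| `batch_sd` | 0.5 | per cohort × gene offset |
| `n_blocks` / `block_size` / `block_rho` | 4 / 15 / 0.7 | co-expressed gene blocks |
| `baseline_hazard` / `censoring_rate` | 0.1 / 0.05 per year | exponential survival and censoring |
| `survival_beta` | 0.8 | hazard coefficient on block-1 genes |

Baselines are N(7, 2) log2 units (typical microarray intensity range);
effect heterogeneity across cohorts is on by default because the
non-transfer of single-study signatures is precisely the phenomenon the
meta-analysis addresses; `disjoint_planted` gives each cohort private
signal genes to reproduce that failure mode deliberately. Planted and
block genes are present in every cohort universe so that ground truth
is well defined; block genes share a per-sample latent factor giving
exact pairwise correlation ρ on the Pearson scale (≈ (6/π)·asin(ρ/2) on
the Spearman scale, checked empirically). Survival times are
exponential with hazard λᵢ = h₀·exp(Σ β_g z_ig) and independent
exponential censoring.

What the generator does *not* emulate: count-based noise, probe-level
artifacts, dye/batch interactions, non-exponential survival,
informative censoring, or class imbalance. Passing tests demonstrate
the machinery recovers planted structure under Gaussian log2 noise;
they do not certify performance on any real platform's quirks.

## Problem sizes and determinism

Validation simulations use desk-scale conditions chosen to keep the
whole suite fast while leaving the conclusions unambiguous: the
permutation-null control runs 6 cohorts × 2,000 genes × 40 samples with
10 permutations of the complete pipeline (a few minutes); signal
recovery uses 4 cohorts × 1,000 genes × 60 samples over 5 seeds;
consensus recovery uses 4 blocks of 15 genes over 10 seeds. Every
stochastic step (fold shuffling, subsampling, permutation, simulation)
is driven by an explicit integer seed, and pipeline results are
bit-reproducible given (inputs, seed). All seeds derived internally
stay below 2³¹.
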