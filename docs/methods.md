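# Methods

## Problem

The package stratifies heart-failure-with-preserved-ejection-fraction
(HFpEF) patients into good / poor 3-year survival groups from bulk gene
expression. The positive class is the **poor** outcome (death from
cardiovascular disease within 3 years) — the minority class at roughly 28%
prevalence — so sensitivity always refers to detecting the rare death class.
The cohort that motivates the defaults (n = 149, 42 poor / 107 good,
~17,000 genes) is access-restricted, so every analysis here runs on
synthetic cohorts drawn with the same statistical structure.

## Pipeline

1. **Preprocessing.** Raw intensities are log2(x+1)-transformed and each
   gene is standardized to mean 0, SD 1 (sample SD, n−1). Zero-variance
   genes cannot be standardized and are dropped with a warning.
2. **Sure independence screening (SIS).** The d = ⌊2n / log10 n⌋ genes with
   the largest marginal utility are kept (d = 137 at n = 149). The utility
   is the absolute two-sample t statistic; on standardized expression with a
   binary response this ranks genes identically to absolute marginal Pearson
   correlation (a property test asserts the equivalence). The bracket is
   read as floor and the logarithm as base 10: these are the only readings
   under which 2·149/log(149) yields 137 rather than 59 (natural log) or
   138 (ceiling).
   By default screening runs once on the full cohort before any
   train/test splitting, matching the sequencing of the original protocol;
   this leaks outcome information into the feature set and measurably
   inflates all downstream holdout metrics. A `screen_within_split` switch
   repeats the screen inside each training part instead for a leakage-free
   comparison. Both modes are tested; the default reproduces the protocol
   as described, not as one might prefer it.
3. **GA-KPLS.** The core classifier is kernel partial least squares with a
   Gaussian kernel K(xi, xj) = exp(−‖xi−xj‖² / 2σ²), fit by dual NIPALS:
   score vectors are extracted from the doubly-centered training kernel,
   with symmetric two-sided kernel deflation (I − ttᵀ)K(I − ttᵀ) and
   response deflation per component; predictions are linear in the centered
   test kernel through dual coefficients B = U(TᵀKU)⁻¹Tᵀy. The outcome is
   coded {0,1} and thresholded at 0.5. With a linear kernel this reproduces
   classical primal PLS fitted values to machine precision (the primal–dual
   equivalence test pins the deflation variant). The bandwidth σ is the one
   tuned parameter, optimized by a real-coded genetic algorithm; the
   component count defaults to 3 (fixed, overridable) since only σ is
   treated as free.
4. **Genetic algorithm.** Chromosomes are log10 multipliers of the median
   pairwise Euclidean distance of the training data (median heuristic), so
   the search window [−2, 3] is scale-free. Fitness is mean stratified
   k-fold CV MCC of the resulting KPLS model, with fold assignment frozen
   per optimizer call so fitness is a deterministic function of a
   chromosome. Tournament selection (size 2), arithmetic blend crossover
   (rate 0.8), Gaussian log-scale mutation (rate 0.1, SD 0.25), elitism 1
   (making the best-fitness trace non-decreasing), early stop after 10
   stalled generations. All GA hyperparameters are package defaults —
   declared, logged, and config-exposed; none is inherited from prior work.
   A 50-point log-grid search over the same range and folds serves as the
   brute-force benchmark: the GA must land within 0.05 CV fitness of it.
5. **Baselines.** Lasso and ridge are L1/L2-penalized *logistic* models
   (the outcome is binary) with the penalty chosen by 10-fold CV over a
   100-value log grid descending four decades from λ_max (the smallest
   penalty zeroing all lasso coefficients). The SVM is RBF at C = 1,
   γ = 1/p; the random forest uses 500 trees, mtry = ⌊√p⌋, unlimited depth,
   vote-fraction scores; plain logistic regression falls back to a
   negligible ridge penalty (1e−8) under complete separation. These are
   pinned numerically rather than left to library defaults so results do
   not drift across versions.
6. **Protocol.** Each repeat draws a stratified 80:20 split with train size
   = ceil(0.8 n) — at n = 149 exactly 120 train / 29 test, and only the
   ceiling convention gives that split. Stratification is a package choice:
   with 28% prevalence and 29 test samples, unstratified splits would
   frequently degenerate (a `stratify=False` switch restores plain
   splitting). Every model is refit per repeat; GA-KPLS re-tunes σ inside
   each repeat's training data. Summaries are arithmetic means over
   repeats; per-repeat AUC is averaged, not pooled.
7. **Model comparison.** One-way ANOVA on the per-repeat AUC columns, then
   Dunnett's many-to-one test against GA-KPLS. Adjusted p-values are
   two-sided max-|t| tail probabilities of the balanced equicorrelated
   (ρ = ½) multivariate t, estimated by seeded Monte Carlo with 1e5 draws
   (tolerance ~0.005 at that size; tests cross-check against an independent
   Dunnett implementation). Treating 1,000 overlapping-split repeats as
   independent ANOVA replicates is the original protocol's choice,
   reproduced as such.
8. **Differential expression (SAM).** Moderated statistic
   d_i = (mean_poor − mean_good) / (s_i + s0), with s_i the pooled SE of
   the mean difference and s0 the percentile of {s_i} (searched over
   0, 5, …, 100) minimizing the coefficient of variation of the per-bin MAD
   of d across s-quantile bins. q-values: labels are permuted (default
   1,000 times, exact enumeration when fewer distinct permutations exist;
   s0 held fixed), each gene's raw FDR is the median null exceedance count
   over its observed exceedance count, then q is monotonized BH-style so it
   never increases with |d|. The good-outcome group is the control: "up"
   means elevated in poor-outcome patients. SAM runs on the screened gene
   set, mirroring the original workflow (116 of 137 screened genes called
   there); because screening selects on the same contrast, calls on the
   screened set inherit its selection optimism — the null-calibration test
   therefore runs SAM on unscreened null matrices.
9. **Survival.** Kaplan-Meier product-limit curves and the two-group
   log-rank test (lifelines backend; hand-computed product-limit examples
   pin the conventions). Ties follow the standard simultaneous-risk-set
   rule; censoring ties at an event time count as at-risk through it. The
   3-year horizon defines the outcome label, not a curve truncation.

## Synthetic cohorts

Defaults reproduce the study conditions: n = 149 samples, poor prevalence
0.2819, 2,000 genes (scalable), 116 DE genes split 70 up : 46 down with
standardized shift `effect_size` (default 1.0) in the poor group, all other
genes i.i.d. N(0, 1) in both groups. Expression is generated directly on the
post-preprocessing scale by default; a raw mode emits positive intensities
2^(z+7) − 1 so the log2(x+1) path is exercised and recovers the latent
values exactly. Survival is exponential per group (means 6 y good / 1.5 y
poor — chosen so the poor group's median falls well inside the 3-year
window) with independent uniform censoring whose upper bound is solved
numerically to hit the requested censoring rate (default 0.2).

**Nonlinear signal.** With `signal="nonlinear"` a latent subset of 20 genes
is drawn class-conditionally: poor N(0.3, 0.2²) per gene versus good
N(0, 1). The class boundary is therefore radial (a tight poor-class sphere
inside the good cloud): no linear rule is Bayes-optimal, while a Gaussian
kernel can exploit the spread difference. Two competing constraints shaped
these numbers. The latent genes must survive |t|-based screening, which only
sees mean shifts — hence the small 0.3 offset. And the radial structure must
remain visible to a kernel whose distances are summed over all ~137 screened
dimensions: concentrating the signal in very few genes (2–5) makes the
kernel contrast vanish inside the noise dimensions, and the measured
KPLS-over-logistic margin flips sign across cohort draws; spreading it over
20 genes keeps the margin positive in every probed draw. Small pure-sphere
fixtures (no mean shift, no noise dimensions) are still used in module-level
tests, where logistic AUC collapses toward 0.5 and KPLS does not.

What the generator does **not** emulate: gene–gene correlation, family/
pedigree structure (samples are exchangeable), informative censoring,
heavy-tailed intensity noise, batch effects. Passing tests therefore show
the pipeline's operating characteristics under a clean factorized model,
not performance on real cohort data — in particular the headline metrics of
the motivating study are not reproducible without its restricted data, and
no test pretends otherwise.

## Numerical choices

- Component extraction stops when a score vector's norm falls below 1e−10
  (rank exhaustion), recording the achieved count; huge-bandwidth kernels
  centered to ~0 trigger this legitimately during GA exploration.
- Screening ties break by gene index ascending, making selections
  reproducible under permutation of samples.
- Metric edge cases: MCC = 0 when any confusion marginal is zero; F = 0
  when precision + sensitivity = 0; AUC uses midranks for score ties.
- One master seed spawns per-stage generators keyed by stage name (CRC32),
  so a fixed seed reproduces every output byte-identically (the run log
  records all resolved parameters) and stages can be rerun in isolation.
- CSV outputs carry 6 significant digits; cohort files written for reuse
  carry %.17g (exact double round-trip).

## Problem sizes used

Tests and the acceptance script scale the protocol down from the original
1,000 repeats: benchmark smoke runs use 10–50 repeats on 400–500-gene
cohorts, GA populations of 8–10 over ≤ 12 generations with 3-fold CV
fitness, and SAM with 150–1,000 permutations. These sizes were chosen so
the full suite exercises every code path at stable tolerances; summary
means on these synthetic cohorts stabilize well before 1,000 repeats.

## Known limitations

- Full-cohort screening (the default, matching the original ordering) is
  optimistically biased; absolute metric levels under it should not be read
  as generalization estimates. Use `screen_within_split` for honest ones.
- The Dunnett Monte Carlo assumes a balanced design (equal repeats per
  model), which the protocol guarantees; it is not valid for ragged input.
- `choose_s0` needs ≥ 20 genes for stable quantile bins and falls back to
  s0 = 0 when all SEs are identical.
- The GA optimizes σ only; joint tuning of (σ, components, threshold) is
  deliberately out of scope.
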