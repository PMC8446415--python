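# Methods

## The pair model

The unit of modeling is the ordered gene pair. For genes X and Y and a
sample s, the indicator is S = 1 if expr_s(X) > expr_s(Y), else 0 — ties
fall in the 0 branch, which matters for FPKM data where both genes can
be 0. Pairs are stored in canonical orientation (X before Y
lexicographically); the Cox coefficients absorb orientation, and
reversing a pair flips the sign of its coefficient without changing the
model's partial likelihood (tested).

Because S is a within-sample rank comparison, the entire downstream
pipeline — pair matrix, risk scores, risk groups, every survival and
association statistic — is invariant under independent strictly
increasing transformations applied per sample. This is the property
that makes pair signatures portable across platforms and normalization
schemes, and it is asserted bit-for-bit in the acceptance suite.

The prevalence screen removes pairs whose indicator mean across the
cohort lies outside the open interval (0.2, 0.8). The screen is
two-sided: a pair that is 1 in 95% of samples is as uninformative as one
that is 1 in 5%. A one-sided variant (drop only low prevalence) is
available by setting the upper bound above 1.

## Statistical components

* **Immune screen.** Pearson correlation on log2(FPKM+1) between each
  lncRNA and each immune gene; retained if some immune gene gives
  |r| > 0.4 with two-sided p < 0.001 (t-transform of r). Spearman and a
  positive-only sign convention are configurable. Constant rows have
  undefined correlations and are skipped with a report.
* **Moderated t.** Two-group comparison on log2(FPKM+1). Gene-wise
  residual variances s²_g (pooled, d = n₁+n₂−2 df) receive a scaled
  inverse-chi-square prior (d₀, s₀²) fitted across genes by the
  method of moments on log s² (digamma/trigamma matching, Newton
  inversion of the trigamma). Posterior variances
  (d₀s₀² + d s²_g)/(d₀+d) give a t statistic on d₀+d df (normal when
  d₀ = ∞, which the fit returns for homogeneous variances). The
  implementation reproduces Bioconductor limma 3.58.1 on frozen
  fixtures to 1e-8; exact zeros are excluded from the prior fit rather
  than offset as limma does, so constant rows get t = 0, p = 1 through
  the shrunk variance. No quantile normalization and no precision
  weights are applied. The DE filter is strict: FDR < 0.05 and
  |log2FC| > 1, with FDR from an in-package Benjamini–Hochberg step-up
  that matches the textbook formula exactly.
* **Cox machinery.** All partial likelihoods use the Efron tie
  correction — day-resolution survival times make ties routine. The
  one-covariate fits that run thousands of times (per-pair univariate
  screen, per-cutpoint dichotomized fits) use a dedicated Newton solver
  on the Efron likelihood with step halving; monotone likelihoods
  (complete separation, |β| exceeding 15) are reported as
  non-convergent rather than returned. Multivariable fits (stepwise
  refits, clinical models) go through lifelines with tightened
  convergence (precision 1e-11) and are cross-checked in tests against
  a brute-force maximizer of the written-out likelihood.
* **Repeated Lasso.** The L1 path is fitted once per cohort
  (scikit-survival Coxnet, 40 penalties, ratio 0.05). Each of the
  n_repeats cycles draws its own 10-fold split from a deterministic
  per-cycle substream of the master seed, refits the path on each
  training fold and scores penalties by the Verweij–van Houwelingen
  cross-validated deviance (full-data minus training-data deviance at
  the training coefficients). The penalty minimizing the summed CV
  deviance defines that cycle's selected set (nonzero coefficients of
  the full-data fit). Pairs selected in strictly more than count_min
  cycles survive; count_min defaults to 10% of n_repeats, matching the
  100-of-1000 convention at full scale. The CV minimum (not the
  1-standard-error rule) is used deliberately: per-cycle sensitivity is
  what the frequency count then stabilizes. Indicators are left
  unstandardized — all covariates are 0/1 on a common scale.
* **Stepwise Cox.** Bidirectional search from the full selected set,
  one drop-or-add move per iteration, accepting the move that most
  reduces AIC = 2k − 2·logPL, until no move improves. Candidate fits
  that fail to converge are skipped with a warning.
* **Time-dependent ROC.** Cumulative-case/dynamic-control definition
  with IPCW: cases (event by t) weighted by 1/G(T⁻), controls (at risk
  beyond t) by 1/G(t), where G is the Kaplan–Meier estimator of the
  censoring distribution. Deterministic and bandwidth-free; with no
  censoring it equals the classical empirical ROC exactly (tested).
  AUC is the trapezoidal integral over the stored points.
* **AIC cutpoint.** Candidate cutoffs are midpoints of consecutive
  sorted unique scores; each candidate's AIC is 2 − 2·logPL of the
  one-covariate Cox fit on the dichotomized cohort, using the complete
  follow-up. The minimizing cutoff is returned (ties toward the smaller
  value) along with the full trace, so other cutpoint rules can be
  applied by the caller. Note that "optimal" here means best-fitting
  two-group Cox model; with finitely many subjects the trace is locally
  flat near a true boundary and the minimum can sit a few subjects off
  it — cluster membership, not the exact boundary subject, is the
  recoverable quantity.
* **Group/feature statistics.** Wilcoxon rank-sum contrasts are exact
  (enumeration) for combined n ≤ 20 without ties, otherwise a
  tie-corrected normal approximation without continuity correction.
  The rank-sum test is used for all between-group feature contrasts,
  including drug-IC50 comparisons: risk groups are independent samples,
  so a signed-rank (paired) test would be misspecified. Chi-square
  association uses Pearson's statistic without continuity correction
  and the star coding *** p<0.001, ** p<0.01, * p<0.05. Spearman
  correlations use tie-corrected average ranks. Ordered staging
  variables (T/N/M/stage) enter Cox models ordinally (1, 2, ...), which
  yields a single hazard ratio per variable; survival probabilities are
  S₀(t)^exp(lp) with the Breslow cumulative baseline hazard. Horizons
  beyond follow-up return the last-event probability with a warning.

## The synthetic cohort generator

The generator is first-class code: it defines the statistical structure
every downstream stage assumes, plus full ground truth.

* **Expression.** log2 abundances follow a latent-factor model. Each
  immune-related lncRNA k shares one standard-normal factor with a
  dedicated partner immune gene at loading a (default 0.7638), with
  independent N(0, noise_sd²) noise (noise_sd = 0.5), giving population
  correlation a²/(a²+noise_sd²) = 0.7. Stored values are
  max(0, 2^log2 − 1) — FPKM-like skew with a point mass of ties at 0.
  DE genes get a +de_log2fc (default 2) mean shift in tumor samples.
  That shift adds tumor/normal mixture variance to DE lncRNAs but not
  to their partner genes, attenuating their observed correlation to
  roughly 0.55 at the default settings — one reason the default
  loading targets 0.7 rather than sitting near the 0.4 screening
  threshold. DE genes draw their base means tightly (sd 0.25 vs 1.0
  for other genes) so true-pair indicators are balanced rather than
  near-constant and survive the prevalence screen.
* **Survival.** True pairs are disjoint (each gene in at most one
  pair), drawn among the DE genes; tumor survival times are exponential
  with hazard h₀·exp(Σ βᵢZᵢ), where the Zᵢ are the true-pair
  indicators computed from the generated expression — i.e. the
  generator implements exactly the proportional-hazards pair-score
  model the pipeline fits. The default h₀ = 3e-4/day was chosen by
  closed-form analysis: under the reference conditions (5 pairs,
  β = 1, prevalence ≈ 0.5) the population 5-year AUC of the true score
  is 0.922, reflecting the strongly discriminative regime the method
  targets, while leaving a usable fraction of 5-year survivors as ROC
  controls. The score is integer-valued, so ties cap the attainable
  AUC; below h₀ ≈ 2e-4 the 5-year AUC of even the true model drops
  under 0.9.
* **Censoring.** Independent Uniform(0, c) with c calibrated by
  bisection so the expected censored fraction matches censor_rate
  (default 0.15). The default is deliberately modest: uniform censoring
  calibrated to higher rates pulls the censoring horizon below 5 years
  and leaves no dynamic controls for the 5-year ROC. Realized censoring
  stays within ±0.1 of the target (tested).
* **Clinical covariates.** Categorical marginals resemble a large
  breast-carcinoma cohort (e.g. 97.8% M0, 48.3% N0); staging variables
  are drawn through a latent-Gaussian ordinal model whose mean shifts
  with the standardized prognostic linear predictor (stage_link,
  default 0.5), so stage associates with risk without being part of the
  survival model. Age is N(58, 13²) clipped to [25, 90].
* **Reproducibility.** One master seed drives five named substreams
  (structure, expression, survival, censoring, clinical), so enlarging
  the gene panel does not perturb survival draws. A separate
  structure_seed lets train and test cohorts share gene structure
  (base means, true pairs) while sampling independently — this is how
  out-of-sample concordance and AUC are measured.

What the generator does **not** emulate: breast-cancer subtype biology,
batch effects, matched tumor/normal pairing (normals are independent
draws; the DE test is unpaired), library-size artifacts, and
copy-number confounding. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that real cohorts
satisfy those assumptions.

## Problem sizes and test design

The reference evaluation uses cohorts of 300 tumors + 50 normals with
150 lncRNAs (15 DE), 60 immune genes and 5 true pairs (β = 1), giving
~105 candidate pairs; recovery is assessed over 10 replicate seeds with
100 Lasso cycles each (frequency threshold 10%), and test-set metrics on
independent 1000-tumor cohorts. The acceptance script runs one such
discovery at the full 1000-cycle setting. Recall is assessed per seed;
concordance and 5-year AUC as means over the replicates, since a single
cohort retains only a few dozen 5-year controls and its AUC estimate
carries ±0.05 sampling noise.

## Known limitations

* The Lasso path is computed once per cohort and evaluated on shared
  penalty grids across folds; folds with truncated paths reuse the
  nearest fitted penalty.
* The exact Wilcoxon branch requires tie-free data; tied small samples
  fall back to the tie-corrected normal approximation.
* The AIC cutpoint is reported as a single value; when the trace is
  flat near the minimum, scientifically distinct cutoffs can be
  statistically indistinguishable (the exported trace makes this
  visible).
* Survival prediction beyond the last observed event time is clamped,
  not extrapolated.
* limma-style array weights, covariate-adjusted DE designs, and paired
  tumor/normal tests are out of scope.
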