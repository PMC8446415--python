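# irpair — immune-related lncRNA pair signatures for survival risk

`irpair` builds prognostic signatures from the **relative ordering** of
immune-related long non-coding RNAs (lncRNAs) within each sample, rather
than from their absolute expression levels. It is aimed at computational
biologists who want a tested, reproducible implementation of the
rank-pair modeling strategy used in tumor transcriptomics — most
prominently for invasive breast carcinoma cohorts with RNA-seq (FPKM)
expression, overall-survival follow-up and clinicopathological
covariates.

## The method

1. **Immune-related lncRNA screen.** A lncRNA is immune-related when it
   co-expresses with a curated immune gene: |r| > 0.4 with p < 0.001
   (Pearson on log2(FPKM+1) by default).
2. **Differential expression.** Tumor vs normal with an empirical-Bayes
   moderated t statistic (variances shrunk toward a method-of-moments
   prior, verified against Bioconductor limma); keep FDR < 0.05 and
   |log2FC| > 1.
3. **Pair encoding.** For every gene pair (X, Y), the per-sample
   indicator is

   ```
   S(X,Y) = 1  if  expr(X) > expr(Y),   else 0
   ```

   Because S depends only on the within-sample ranking, the signature is
   invariant to any strictly increasing per-sample distortion of
   expression — no cross-sample normalization is needed. Pairs whose
   indicator is nearly constant (prevalence outside (0.2, 0.8)) carry no
   usable rank and are dropped.
4. **Selection.** Univariate Cox screen (Efron ties, p < 0.01), then
   1000 cycles of 10-fold cross-validated Lasso-Cox; a pair is kept only
   if it receives a nonzero coefficient in more than 100 cycles
   (selection-frequency stability), then a bidirectional AIC-minimizing
   stepwise Cox fit gives the final coefficients.
5. **Risk score and cutoff.** riskScore = Σᵢ βᵢ·Sᵢ. The cohort is split
   at the cutpoint whose dichotomized one-covariate Cox model has
   minimal AIC (evaluated over the 5-year ROC's candidate thresholds).
6. **Validation.** Time-dependent ROC/AUC with inverse-probability-of-
   censoring weights, Kaplan–Meier + log-rank, chi-square and Wilcoxon
   contrasts against clinical covariates, univariate/multivariable Cox
   (is the score an independent predictor?), Breslow-baseline survival
   prediction, and rank-sum/Spearman association of risk groups with
   external per-sample features (immune-cell fractions, drug IC50,
   checkpoint genes, immunophenoscores).

A synthetic-cohort generator (`irpair.simulate`) produces
tumor/normal expression with latent-factor immune co-expression, DE
shifts, proportional-hazards survival driven by known true pair
indicators, calibrated uniform censoring and clinical covariates —
with full ground truth, so the whole pipeline is testable end to end
with no downloads.

## Worked example

```python
from irpair import (SimConfig, simulate_cohort, synthetic_gene_groups,
                    discover_signature, find_cutoff_by_aic, assign_risk_groups,
                    km_logrank, time_dependent_roc, truth_report)

cfg = SimConfig(n_tumor=300, n_normal=50, n_lnc=150, n_irgene=60,
                n_other_coding=50, n_de_lnc=15, n_true_pairs=5,
                true_beta=(1.0,) * 5, seed=1)
expr, clinical, truth = simulate_cohort(cfg)
lnc, irgenes, _ = synthetic_gene_groups(expr)

result = discover_signature(lnc, irgenes, clinical, n_repeats=100, seed=1)
recovery = truth_report(truth, result.model.pairs, result.model.betas)
cut = find_cutoff_by_aic(result.scores, clinical)
groups = assign_risk_groups(result.scores, cut.chosen_cutoff)
km = km_logrank(groups, clinical)
```

Output:

```
immune-related lncRNAs: 31
differentially expressed: 15 (15 up, 0 down)
candidate pairs after screens: 105
final model: 12 pairs, concordance 0.750
true-pair recall 1.00, precision 0.42
AIC cutoff 0.926: 183 high / 117 low risk
log-rank chi2 112.4 (p = 2.90e-26)
5-year AUC 0.955
```

Reading this: of 150 simulated lncRNAs, 31 pass the immune
co-expression screen and 15 are differentially expressed, giving
C(15,2) = 105 candidate pairs. The repeated-Lasso + stepwise fit keeps
12 pairs, including all 5 truly prognostic ones (recall 1.00). The
AIC-optimal cutoff splits the cohort 183/117, and the two groups have
sharply different survival (log-rank p ≈ 3e-26); the riskScore
discriminates 5-year outcomes with AUC 0.955.

The same stages are exposed as shell commands (`irpair simulate`,
`split`, `cohort`, `immune-filter`, `de`, `pair`, `select`, `score`,
`roc`, `cutoff`, `validate`, `associate`); see `irpair --help`.

## Documentation

`docs/methods.md` describes the statistical model, the simulator and
its calibration, numerical choices and known limitations.
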