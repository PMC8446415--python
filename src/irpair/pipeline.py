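"""End-to-end discovery pipeline: from expression to a fitted pair model.

Chains the stages in their canonical order — immune-related lncRNA
screen, tumor/normal differential expression, 0/1 pair encoding with the
prevalence screen, univariate Cox screen, repeated cross-validated
Lasso-Cox stability selection, stepwise Cox — and scores cohorts with
the resulting model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de import filter_de, moderated_de
from .immune import ImmuneFilterConfig, identify_irlncrna
from .io import ClinicalTable, ExpressionMatrix
from .pairs import PairMatrix, build_pair_matrix, filter_pairs_by_prevalence
from .select import (
    RiskModel,
    compute_risk_score,
    repeated_lasso_select,
    stepwise_cox_fit,
    univariate_cox_screen,
)

__all__ = ["DiscoveryResult", "discover_signature", "score_cohort"]


@dataclass
class DiscoveryResult:
    irlnc: set[str]
    de_up: set[str]
    de_down: set[str]
    pair_matrix: PairMatrix  # after the prevalence screen, tumor samples
    n_candidate_pairs: int  # pairs entering the selection stage
    univariate_candidates: list[str]
    selection_counts: pd.Series
    model: RiskModel
    scores: pd.Series  # training-cohort risk scores

    @property
    def de_genes(self) -> set[str]:
        return self.de_up | self.de_down


def discover_signature(
    lnc: ExpressionMatrix,
    irgenes: ExpressionMatrix,
    clin: ClinicalTable,
    *,
    immune_cfg: ImmuneFilterConfig | None = None,
    fdr_max: float = 0.05,
    abs_log2fc_min: float = 1.0,
    prevalence_low: float = 0.2,
    prevalence_high: float = 0.8,
    p_max: float = 0.01,
    n_repeats: int = 1000,
    folds: int = 10,
    count_min: int | None = None,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full discovery pipeline on one cohort.

    ``lnc`` and ``irgenes`` are the lncRNA and immune-gene expression
    matrices over the same samples (tumor and normal); survival modeling
    uses the tumor samples present in ``clin``.
    """
    irlnc, _ = identify_irlncrna(lnc, irgenes, immune_cfg)
    if not irlnc:
        raise ValueError("no immune-related lncRNA passed the co-expression screen")
    de_table = moderated_de(lnc.subset_genes(sorted(irlnc)))
    _, up, down = filter_de(de_table, fdr_max=fdr_max, abs_log2fc_min=abs_log2fc_min)
    de_genes = up | down
    if len(de_genes) < 2:
        raise ValueError(
            f"only {len(de_genes)} differentially expressed irlncRNA; "
            "cannot form pairs"
        )
    tumor = lnc.subset_samples(lnc.tumor_samples())
    pm = build_pair_matrix(tumor, de_genes)
    pm = filter_pairs_by_prevalence(pm, low=prevalence_low, high=prevalence_high)
    candidates, _ = univariate_cox_screen(pm, clin, p_max=p_max)
    if not candidates:
        raise ValueError("no pair passed the univariate Cox screen")
    cand_pm = pm.subset_pairs(candidates)
    chosen, counts = repeated_lasso_select(
        cand_pm,
        clin,
        n_repeats=n_repeats,
        folds=folds,
        count_min=count_min,
        seed=seed,
    )
    if not chosen:
        raise ValueError("no pair exceeded the selection-frequency threshold")
    model = stepwise_cox_fit(cand_pm, clin, selected=chosen)
    model.selection_counts = counts
    scores = compute_risk_score(model, pm)
    return DiscoveryResult(
        irlnc=irlnc,
        de_up=up,
        de_down=down,
        pair_matrix=pm,
        n_candidate_pairs=pm.n_pairs,
        univariate_candidates=candidates,
        selection_counts=counts,
        model=model,
        scores=scores,
    )


def score_cohort(model: RiskModel, expr: ExpressionMatrix) -> pd.Series:
    """riskScores of a new cohort: rebuild the model pairs' indicators
    from the cohort's expression and apply the fitted coefficients."""
    genes = sorted({g for p in model.pairs for g in p.split("|", 1)})
    pm = build_pair_matrix(expr, genes).subset_pairs(model.pairs)
    return compute_risk_score(model, pm)
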