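"""Prognostic pair selection and the risk-score model.

Pipeline stage order:

1. :func:`univariate_cox_screen` — per-pair single-covariate Cox fits
   (Efron ties), keeping pairs with Wald p below 0.01;
2. :func:`repeated_lasso_select` — repeated cross-validated L1-penalized
   Cox regression; a pair enters the model only when it receives a
   nonzero coefficient in more than a fixed fraction of the cycles
   (selection-frequency stability, by default > 100 of 1000);
3. :func:`stepwise_cox_fit` — bidirectional AIC-minimizing stepwise Cox
   on the stabilized set, giving the final unpenalized coefficients;
4. :func:`compute_risk_score` — riskScore = sum_i beta_i * S_i, with S_i
   the 0/1 indicator of pair i.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import (
    SurvData,
    efron_log_partial_likelihood,
    efron_log_partial_likelihood_multi,
    fit_single_cox,
)
from .io import ClinicalTable
from .pairs import PairMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "univariate_cox_screen",
    "repeated_lasso_select",
    "stepwise_cox_fit",
    "compute_risk_score",
]


@dataclass
class RiskModel:
    """Final pair signature: pair ids, Cox coefficients and fit statistics."""

    pairs: list[str]
    betas: np.ndarray
    selection_counts: pd.Series | None = None
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.pairs) != len(self.betas) or len(self.pairs) == 0:
            raise ValueError("pairs and betas must be non-empty and equal length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": self.pairs,
                "betas": self.betas.tolist(),
                "selection_counts": None
                if self.selection_counts is None
                else self.selection_counts.to_dict(),
                "fit_stats": self.fit_stats,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str | Path) -> "RiskModel":
        if isinstance(text, Path):
            text = text.read_text()
        obj = json.loads(text)
        counts = obj.get("selection_counts")
        return cls(
            pairs=list(obj["pairs"]),
            betas=np.asarray(obj["betas"], dtype=float),
            selection_counts=None if counts is None else pd.Series(counts),
            fit_stats=obj.get("fit_stats", {}),
        )


def _align(pm: PairMatrix, surv: ClinicalTable) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Restrict the pair matrix and survival data to their common samples."""
    common = [s for s in pm.sample_ids if s in surv.data.index]
    if not common:
        raise ValueError("pair matrix and clinical table share no samples")
    ind = pm.indicator[common]
    sub = surv.data.loc[common]
    time = sub["os_time"].to_numpy(dtype=float)
    event = sub["os_event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the aligned cohort")
    return ind, time, event


def univariate_cox_screen(
    pm: PairMatrix, surv: ClinicalTable, p_max: float = 0.01
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fit per pair; keep Wald p < ``p_max``.

    Pairs whose indicator is constant within the aligned cohort have a
    degenerate risk model and are skipped (reported in the table with
    ``status="constant"``).  Returns the retained pair ids (input order)
    and the per-pair table with beta, HR, p and status.
    """
    ind, time, event = _align(pm, surv)
    sd = SurvData.prepare(time, event)
    rows = []
    for pid in ind.index:
        z = ind.loc[pid].to_numpy(dtype=float)
        if z.min() == z.max():
            rows.append({"pair_id": pid, "beta": np.nan, "hr": np.nan, "p": np.nan, "status": "constant"})
            continue
        fit = fit_single_cox(z, time, event, sd=sd)
        if fit is None:
            rows.append({"pair_id": pid, "beta": np.nan, "hr": np.nan, "p": np.nan, "status": "non-convergent"})
            continue
        rows.append(
            {
                "pair_id": pid,
                "beta": fit["beta"],
                "hr": float(np.exp(fit["beta"])),
                "p": fit["p"],
                "status": "ok",
            }
        )
    table = pd.DataFrame(rows).set_index("pair_id")
    n_skipped = int((table["status"] != "ok").sum())
    if n_skipped:
        logger.info("univariate screen skipped %d degenerate/non-convergent pairs", n_skipped)
    retained = [p for p in table.index if table.loc[p, "status"] == "ok" and table.loc[p, "p"] < p_max]
    return retained, table


def _cv_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[k::folds] for k in range(folds)]


def repeated_lasso_select(
    pm: PairMatrix,
    surv: ClinicalTable,
    n_repeats: int = 1000,
    folds: int = 10,
    count_min: int | None = None,
    seed: int = 0,
    n_alphas: int = 40,
    alpha_min_ratio: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Stability selection by repeated cross-validated Lasso-Cox.

    Each cycle draws its own fold split (derived deterministically from
    ``seed``), fits the L1 path on the full data, picks the penalty that
    minimizes the cross-validated partial-likelihood deviance (verweij /
    van-houwelingen form: full-data minus training-data deviance at the
    training coefficients), and records which pairs carry a nonzero
    coefficient at that penalty.  Pairs selected in strictly more than
    ``count_min`` cycles are returned; ``count_min`` defaults to 10% of
    ``n_repeats`` (100 of 1000).
    """
    if pm.n_pairs < 2:
        raise ValueError("repeated Lasso needs at least 2 candidate pairs")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if count_min is None:
        count_min = int(round(0.1 * n_repeats))
    if count_min > n_repeats:
        raise ValueError("count_min exceeds n_repeats")

    ind, time, event = _align(pm, surv)
    X = ind.to_numpy(dtype=float).T  # samples x pairs
    y = Surv.from_arrays(event.astype(bool), time)
    n = X.shape[0]

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
    )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    coef_path = path.coef_  # features x alphas

    counts = pd.Series(0, index=ind.index, dtype=int)
    sd_full = SurvData.prepare(time, event)
    for cycle in range(n_repeats):
        rng = np.random.default_rng([seed, cycle])
        cv_dev = np.zeros(len(alphas))
        ok = True
        for test_idx in _cv_folds(n, folds, rng):
            train = np.ones(n, dtype=bool)
            train[test_idx] = False
            if event[train].sum() == 0:
                ok = False
                break
            try:
                fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
                fold_fit.fit(X[train], y[train])
            except (ValueError, ArithmeticError):
                ok = False
                break
            fold_alphas = np.asarray(fold_fit.alphas_)
            # map each requested penalty to the closest fitted one (the
            # solver may truncate the path on a fold)
            col = np.argmin(
                np.abs(np.log(fold_alphas[None, :] / alphas[:, None])), axis=1
            )
            B = fold_fit.coef_[:, col]  # features x alphas
            LP = X @ B  # samples x alphas
            ll_full = efron_log_partial_likelihood_multi(time, event, LP, sd=sd_full)
            ll_train = efron_log_partial_likelihood_multi(
                time[train], event[train], LP[train]
            )
            cv_dev += -2.0 * (ll_full - ll_train)
        if not ok:
            logger.warning("lasso cycle %d skipped (degenerate fold)", cycle)
            continue
        best = int(np.argmin(cv_dev))
        nonzero = np.flatnonzero(coef_path[:, best])
        counts.iloc[nonzero] += 1

    selected = [p for p in ind.index if counts[p] > count_min]
    if counts.sum() == 0:
        raise ValueError("no pair received a nonzero coefficient in any cycle")
    return selected, counts


def _fit_cox(
    ind: pd.DataFrame, time: np.ndarray, event: np.ndarray, pairs: Sequence[str]
) -> CoxPHFitter:
    df = ind.loc[list(pairs)].T.astype(float)
    df.columns = [f"v{i}" for i in range(len(pairs))]  # guard odd pair-id chars
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph


def _model_stats(cph: CoxPHFitter) -> dict:
    return {
        "log_partial_likelihood": float(cph.log_likelihood_),
        "aic": float(cph.AIC_partial_),
        "concordance": float(cph.concordance_index_),
    }


def stepwise_cox_fit(
    pm: PairMatrix, surv: ClinicalTable, selected: Sequence[str] | None = None
) -> RiskModel:
    """Bidirectional stepwise Cox search minimizing AIC = 2k - 2 logPL.

    Starts from the full set of ``selected`` pairs (default: every pair of
    ``pm``) and alternates removal/re-addition moves until no single move
    lowers the AIC.  Coefficients of the final model are unpenalized.
    """
    ind, time, event = _align(pm, surv)
    current = list(selected) if selected is not None else list(ind.index)
    if not current:
        raise ValueError("stepwise fit needs at least one selected pair")

    def aic_of(pairs: Sequence[str]) -> float:
        if not pairs:
            # null model: no parameters
            return -2.0 * efron_log_partial_likelihood(time, event, np.zeros(len(time)))
        try:
            return float(_fit_cox(ind, time, event, pairs).AIC_partial_)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("stepwise candidate %s skipped: %s", pairs, exc)
            return np.inf

    dropped: list[str] = []
    best_aic = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str]] = []
        for p in current:
            trial = [q for q in current if q != p]
            if trial:
                moves.append((aic_of(trial), "drop", p))
        for p in dropped:
            moves.append((aic_of(current + [p]), "add", p))
        if not moves:
            break
        moves.sort(key=lambda m: m[0])
        cand_aic, action, p = moves[0]
        if cand_aic < best_aic - 1e-10:
            best_aic = cand_aic
            if action == "drop":
                current.remove(p)
                dropped.append(p)
            else:
                dropped.remove(p)
                current.append(p)
            improved = True

    if not current:
        raise ValueError("stepwise search emptied the model")
    cph = _fit_cox(ind, time, event, current)
    betas = cph.params_.to_numpy()
    return RiskModel(pairs=current, betas=betas, fit_stats=_model_stats(cph))


def compute_risk_score(model: RiskModel, pm: PairMatrix) -> pd.Series:
    """riskScore = sum_i beta_i * S_i per sample, as a float Series."""
    missing = [p for p in model.pairs if p not in pm.indicator.index]
    if missing:
        raise KeyError(f"model pairs absent from pair matrix: {missing[:5]}")
    S = pm.indicator.loc[model.pairs].to_numpy(dtype=float)
    scores = model.betas @ S
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")
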