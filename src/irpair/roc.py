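"""Time-dependent ROC curves and the AIC-optimal risk-score cutoff.

ROC curves use the cumulative-case / dynamic-control definition: at
horizon t, cases are subjects with an observed event by t and controls are
subjects still event-free beyond t.  Right censoring is handled by inverse
probability of censoring weighting (IPCW) with weights from the
Kaplan-Meier estimator of the censoring distribution; with no censoring
the estimator reduces exactly to the classical empirical ROC.

The high/low risk threshold is the dichotomization whose induced one-
covariate Cox model has minimal AIC over all candidate cutpoints (the
best-fitting two-group split of the 5-year curve); the full AIC trace is
returned so alternative rules can be applied downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._cox import SurvData, fit_single_cox
from .io import ClinicalTable

__all__ = [
    "YEAR_DAYS",
    "ROCCurve",
    "CutoffResult",
    "time_dependent_roc",
    "find_cutoff_by_aic",
    "assign_risk_groups",
]

YEAR_DAYS = 365.25


@dataclass
class ROCCurve:
    horizon_years: float
    thresholds: np.ndarray  # descending; +/- inf endpoints included
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class CutoffResult:
    candidate_cutoffs: np.ndarray
    aic_trace: np.ndarray
    chosen_cutoff: float
    n_high: int
    n_low: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.candidate_cutoffs, "aic": self.aic_trace})


def _align_scores(scores: pd.Series, surv: ClinicalTable):
    common = [s for s in scores.index if s in surv.data.index]
    if not common:
        raise ValueError("scores and clinical table share no samples")
    sc = scores.loc[common].to_numpy(dtype=float)
    sub = surv.data.loc[common]
    return common, sc, sub["os_time"].to_numpy(dtype=float), sub["os_event"].to_numpy(dtype=int)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    return km


def time_dependent_roc(
    scores: pd.Series, surv: ClinicalTable, horizon_years: float
) -> ROCCurve:
    """IPCW cumulative/dynamic ROC of a continuous marker at one horizon."""
    _, sc, time, event = _align_scores(scores, surv)
    t = horizon_years * YEAR_DAYS
    is_case = (time <= t) & (event == 1)
    is_control = time > t
    if not is_case.any():
        raise ValueError(f"no events before the {horizon_years}-year horizon")
    if not is_control.any():
        raise ValueError(f"no subject remains at risk beyond {horizon_years} years")

    km = _censoring_survival(time, event)
    # G(T-): censoring survival just before each case's event time
    g_case = km.predict(np.maximum(time[is_case] - 1e-8, 0.0)).to_numpy(dtype=float)
    g_t = float(km.predict(t))
    if g_t <= 0:
        raise ValueError(
            f"censoring survival is zero at {horizon_years} years; horizon "
            "exceeds the follow-up range"
        )
    usable = g_case > 0
    if not usable.all():
        warnings.warn("dropping cases with zero censoring-survival weight")
    w_case = np.where(usable, 1.0 / np.where(g_case > 0, g_case, 1.0), 0.0)
    sc_case = sc[is_case]
    sc_control = sc[is_control]
    w_control = np.full(sc_control.shape, 1.0 / g_t)

    uniq = np.unique(sc)[::-1]
    thresholds = np.concatenate(([np.inf], uniq, [-np.inf]))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    wc_total = w_case.sum()
    wq_total = w_control.sum()
    for i, c in enumerate(thresholds):
        sens[i] = w_case[sc_case > c].sum() / wc_total
        spec[i] = w_control[sc_control <= c].sum() / wq_total
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(horizon_years, thresholds, sens, spec, auc)


def _dichotomized_aic(
    sc: np.ndarray, sd: SurvData, cutoff: float
) -> float:
    """AIC (= 2 - 2 logPL) of the one-covariate Cox fit on score > cutoff."""
    high = (sc > cutoff).astype(float)
    if high.min() == high.max():
        return np.inf
    fit = fit_single_cox(high, sd.time, sd.event, sd=sd)
    if fit is None:
        return np.inf
    return 2.0 - 2.0 * fit["log_likelihood"]


def find_cutoff_by_aic(
    scores: pd.Series, surv: ClinicalTable, horizon_years: float = 5.0
) -> CutoffResult:
    """Best-fitting dichotomization of the riskScore by two-group Cox AIC.

    Candidate cutoffs are the midpoints of consecutive sorted unique
    scores; for each candidate the cohort is split at the cutoff and a
    one-covariate Cox model on the group indicator is scored by AIC.  The
    minimizing cutoff is returned (ties broken toward the smaller value)
    together with the full trace.  ``horizon_years`` documents the curve
    the cutpoints summarize; the Cox fits use the complete follow-up.
    """
    _, sc, time, event = _align_scores(scores, surv)
    uniq = np.unique(sc)
    if len(uniq) < 2:
        raise ValueError("all risk scores identical; no cutoff exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    sd = SurvData.prepare(time, event)
    trace = np.array([_dichotomized_aic(sc, sd, c) for c in candidates])
    if not np.isfinite(trace).any():
        raise ValueError("no candidate cutoff produced a valid two-group fit")
    chosen = float(candidates[int(np.argmin(trace))])  # argmin takes first = smallest
    n_high = int((sc > chosen).sum())
    n_low = int((sc <= chosen).sum())
    return CutoffResult(candidates, trace, chosen, n_high, n_low)


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """Label samples ``high`` (score > cutoff) or ``low`` (score <= cutoff)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    labels = np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low")
    return pd.Series(labels, index=scores.index, name="risk_group")
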