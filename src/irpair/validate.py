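"""Survival and clinical association statistics for the risk groups.

Covers Kaplan-Meier curves with the two-group log-rank test, chi-square
association between risk group and clinicopathological categories (with
the ***/**/* star coding), Wilcoxon rank-sum contrasts of the riskScore
across clinical categories, univariate and multivariable Cox regression
(the independence check for the signature), Breslow-baseline survival
probability prediction (the computation behind a prognostic nomogram) and
Table-1-style cohort summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import CLINICAL_CATEGORICAL, ClinicalTable
from .roc import YEAR_DAYS

__all__ = [
    "km_logrank",
    "chi_square_association",
    "significance_stars",
    "rank_sum_by_category",
    "multivariable_cox",
    "predict_survival_probability",
    "cohort_summary",
    "ORDINAL_LEVELS",
]

#: Ordered clinical variables and their level order, encoded 1, 2, ... for Cox.
ORDINAL_LEVELS: dict[str, tuple[str, ...]] = {
    "t_stage": ("T1", "T2", "T3", "T4"),
    "n_stage": ("N0", "N1", "N2", "N3"),
    "m_stage": ("M0", "M1"),
    "stage": ("I", "II", "III", "IV"),
}


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # per group: index time, column survival
    chi2: float
    p: float
    df: int


def km_logrank(groups: pd.Series, surv: ClinicalTable) -> KMResult:
    """Product-limit curves per group and the log-rank test across groups."""
    common = [s for s in groups.index if s in surv.data.index]
    if not common:
        raise ValueError("groups and clinical table share no samples")
    g = groups.loc[common]
    sub = surv.data.loc[common]
    levels = [lv for lv in pd.unique(g)]
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    curves = {}
    for lv in levels:
        mask = (g == lv).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {lv!r} has no subjects")
        km = KaplanMeierFitter()
        km.fit(sub["os_time"][mask], sub["os_event"][mask], label=str(lv))
        curves[str(lv)] = km.survival_function_
    res = multivariate_logrank_test(sub["os_time"], g, sub["os_event"])
    return KMResult(curves, float(res.test_statistic), float(res.p_value), len(levels) - 1)


def significance_stars(p: float) -> str:
    """Star coding: p < 0.001 -> ***, < 0.01 -> **, < 0.05 -> *, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def chi_square_association(
    groups: pd.Series, covariate: pd.Series
) -> tuple[float, int, float, str]:
    """Pearson chi-square (no continuity correction) on the contingency
    table of risk group versus a categorical covariate.

    Returns ``(chi2, df, p, stars)``.  Missing covariate values are
    dropped before tabulation.
    """
    df = pd.DataFrame({"g": groups, "c": covariate}).dropna()
    table = pd.crosstab(df["g"], df["c"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table is degenerate (needs >= 2x2)")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p), significance_stars(float(p))


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact by enumeration when the combined
    sample is small and tie-free, tie-corrected normal approximation
    otherwise.  Returns ``(U statistic of x, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_sum_by_category(
    scores: pd.Series, covariate: pd.Series
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum contrasts of the riskScore between every
    two levels of a clinical category.

    Returns one row per level pair with the U statistic, p and stars.
    """
    df = pd.DataFrame({"s": scores, "c": covariate}).dropna()
    levels = sorted(df["c"].unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two non-empty categories")
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            xa = df.loc[df["c"] == a, "s"].to_numpy()
            xb = df.loc[df["c"] == b, "s"].to_numpy()
            u, p = _rank_sum(xa, xb)
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "statistic": u,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def _encode_covariates(clin: ClinicalTable, covariates: list[str], extra: pd.Series | None) -> pd.DataFrame:
    out = pd.DataFrame(index=clin.data.index)
    for cov in covariates:
        col = clin.data[cov]
        if cov in ORDINAL_LEVELS:
            mapping = {lv: i + 1 for i, lv in enumerate(ORDINAL_LEVELS[cov])}
            out[cov] = col.map(mapping)
        elif col.dtype == object:
            levels = sorted(col.dropna().unique(), key=str)
            if len(levels) > 2:
                raise ValueError(
                    f"covariate {cov!r} has {len(levels)} unordered levels; "
                    "encode it explicitly before the Cox fit"
                )
            out[cov] = col.map({levels[0]: 0, levels[-1]: 1})
        else:
            out[cov] = pd.to_numeric(col)
    if extra is not None:
        out[extra.name or "risk_score"] = extra.reindex(out.index)
    return out


def multivariable_cox(
    surv: ClinicalTable,
    covariates: list[str],
    scores: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate and multivariable Cox regression over clinical covariates.

    Ordered staging variables are encoded ordinally (one hazard ratio per
    variable); binary categoricals are encoded 0/1; ``scores`` adds the
    riskScore as a continuous covariate.  Complete cases only.  Returns
    ``(univariate, multivariable)`` tables with HR, 95% CI and Wald p per
    covariate; the multivariable table carries the model concordance in
    ``attrs["concordance"]``.
    """
    X = _encode_covariates(surv, covariates, scores)
    base = pd.DataFrame(
        {"time": surv.data["os_time"], "event": surv.data["os_event"]}, index=surv.data.index
    )
    full = pd.concat([X, base], axis=1).dropna()
    if len(full) < 10 * X.shape[1]:
        warnings.warn(
            f"only {len(full)} complete cases for {X.shape[1]} covariates; "
            "estimates may be unstable"
        )

    def fit(cols: list[str]) -> CoxPHFitter:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                full[cols + ["time", "event"]],
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-11, "max_steps": 500},
            )
        return cph

    def table(cph: CoxPHFitter) -> pd.DataFrame:
        s = cph.summary
        out = pd.DataFrame(
            {
                "hr": s["exp(coef)"],
                "ci_low": s["exp(coef) lower 95%"],
                "ci_high": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
        out["stars"] = [significance_stars(p) for p in out["p"]]
        return out

    uni_rows = []
    for col in X.columns:
        cph = fit([col])
        uni_rows.append(table(cph).loc[col])
    uni = pd.DataFrame(uni_rows)
    multi_fit = fit(list(X.columns))
    multi = table(multi_fit)
    multi.attrs["concordance"] = float(multi_fit.concordance_index_)
    multi.attrs["model"] = multi_fit
    return uni, multi


def predict_survival_probability(
    fitted: CoxPHFitter,
    covariates: pd.DataFrame,
    years: tuple[float, ...] = (3.0, 5.0, 7.0),
) -> pd.DataFrame:
    """Predicted S(t | x) at the requested horizons from a fitted Cox model.

    Uses the Breslow cumulative baseline hazard: S(t | x) = S0(t)^exp(lp).
    Horizons beyond the last observed event time return the probability at
    the last event time, with a warning.
    """
    times = np.array([y * YEAR_DAYS for y in years])
    last = float(fitted.baseline_cumulative_hazard_.index.max())
    if (times > last).any():
        warnings.warn(
            f"horizon beyond last observed time ({last:.0f} days); "
            "returning the probability at the last observed time"
        )
        times = np.minimum(times, last)
    sf = fitted.predict_survival_function(covariates, times=times)
    out = sf.T  # subjects x times
    out.columns = [f"{y:g}y" for y in years]
    return out


def cohort_summary(clin: ClinicalTable, continuous: tuple[str, ...] = ("age",)) -> pd.DataFrame:
    """Table-1-style summary: per category count and percentage of the
    non-missing total (1 decimal), plus median (IQR) for continuous
    variables."""
    rows = []
    df = clin.data
    for var in [c for c in CLINICAL_CATEGORICAL if c in df.columns]:
        col = df[var].dropna()
        total = len(col)
        if total == 0:
            continue
        counts = col.value_counts()
        order = [
            lv for lv in ORDINAL_LEVELS.get(var, tuple(sorted(counts.index, key=str)))
            if lv in counts.index
        ]
        for lv in order:
            n = int(counts[lv])
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "n": n,
                    "percent": round(100.0 * n / total, 1),
                }
            )
    for var in continuous:
        if var not in df.columns:
            continue
        col = pd.to_numeric(df[var], errors="coerce").dropna()
        if col.empty:
            continue
        q1, med, q3 = col.quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "variable": var,
                "level": f"median (IQR) {med:g} ({q1:g}, {q3:g})",
                "n": len(col),
                "percent": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["variable", "level", "n", "percent"])
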