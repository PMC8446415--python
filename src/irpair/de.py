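"""Tumor-versus-normal differential expression with moderated t statistics.

The test operates on log2(value + 1).  Per-gene residual variances are
shrunk toward a common prior fitted across genes by the empirical-Bayes
method of moments for a scaled inverse-chi-square prior (prior variance
``s0^2`` with prior degrees of freedom ``d0``), and the group-mean
difference is tested with the moderated t statistic on ``d0 + d`` degrees
of freedom.  Multiple testing is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix

__all__ = ["moderated_de", "filter_de", "fit_variance_prior", "benjamini_hochberg"]


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values: p_(i) * m / i with a step-up cumulative min."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class VariancePrior:
    """Empirical-Bayes prior for gene-level residual variances."""

    df_prior: float  # may be inf when variances are homogeneous
    var_prior: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Method-of-moments fit of (df_prior, var_prior) across gene variances.

    Works on log variances: if s2 ~ s0^2 * chi2_d / d scaled by a gene
    variance with an inverse-chi-square prior, log(s2) has known digamma /
    trigamma moments; matching the observed mean and spread of log(s2)
    yields the prior degrees of freedom and prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    # exact zeros carry no information about the continuous variance prior
    positive = s2[s2 > 0]
    if positive.size < 2:
        return VariancePrior(np.inf, float(np.median(s2)) if s2.size else 0.0)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        var_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        var_prior = float(np.exp(emean))
    return VariancePrior(df_prior, var_prior)


def moderated_de(
    expr: ExpressionMatrix, df_prior_override: float | None = None
) -> pd.DataFrame:
    """Moderated two-group t test, tumor minus normal, on log2(value + 1).

    Returns a DataFrame indexed by gene id with columns ``log2fc``,
    ``t_mod``, ``p``, ``fdr`` and ``direction``.  Passing
    ``df_prior_override=0`` recovers the ordinary two-sample pooled t test.
    """
    tumor = expr.tumor_samples()
    normal = expr.normal_samples()
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >=2 samples per class, got {len(tumor)} tumor / "
            f"{len(normal)} normal"
        )
    log = expr.log2p1()
    X1 = log[tumor].to_numpy()
    X0 = log[normal].to_numpy()
    n1, n0 = X1.shape[1], X0.shape[1]
    diff = X1.mean(axis=1) - X0.mean(axis=1)
    rss = ((X1 - X1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (X0 - X0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n1 + n0 - 2
    s2 = rss / df_resid
    v = 1.0 / n1 + 1.0 / n0

    if df_prior_override is not None:
        prior = VariancePrior(
            df_prior_override,
            fit_variance_prior(s2, df_resid).var_prior if df_prior_override else 0.0,
        )
    else:
        prior = fit_variance_prior(s2, df_resid)

    if np.isinf(prior.df_prior):
        s2_post = np.full_like(s2, prior.var_prior)
        df_total = np.inf
    else:
        s2_post = (prior.df_prior * prior.var_prior + df_resid * s2) / (
            prior.df_prior + df_resid
        )
        df_total = prior.df_prior + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / np.sqrt(s2_post * v)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0: no change, no evidence
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "direction": np.where(diff >= 0, "up", "down"),
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def filter_de(
    table: pd.DataFrame, fdr_max: float = 0.05, abs_log2fc_min: float = 1.0
) -> tuple[set[str], set[str], set[str]]:
    """Apply FDR and fold-change thresholds (both strict, as stated rules).

    Returns ``(selected, up, down)`` gene id sets where ``selected`` is the
    union and up/down split by the sign of log2fc.
    """
    keep = (table["fdr"] < fdr_max) & (table["log2fc"].abs() > abs_log2fc_min)
    sub = table[keep]
    up = set(sub.index[sub["log2fc"] > 0])
    down = set(sub.index[sub["log2fc"] < 0])
    return up | down, up, down
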