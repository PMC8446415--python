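"""Cox partial-likelihood machinery with Efron handling of tied times.

The screening stages evaluate thousands of one-covariate Cox fits and
partial likelihoods, so the Efron log partial likelihood is implemented
here in vectorized form (grouped by event time via ``np.add.reduceat``)
together with a Newton fit for a single covariate.  Multivariable fits
elsewhere in the package go through lifelines; these routines are
cross-checked against it and against a brute-force likelihood oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvData",
    "efron_log_partial_likelihood",
    "efron_log_partial_likelihood_multi",
    "fit_single_cox",
]


@dataclass
class SurvData:
    """Survival data pre-sorted and grouped by distinct time."""

    time: np.ndarray  # sorted ascending
    event: np.ndarray  # bool, aligned with time
    order: np.ndarray  # original -> sorted permutation
    starts: np.ndarray  # first index of each distinct-time group
    n_events: np.ndarray  # events per group
    max_ties: int

    @classmethod
    def prepare(cls, time: np.ndarray, event: np.ndarray) -> "SurvData":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        order = np.argsort(time, kind="stable")
        ts, es = time[order], event[order]
        starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
        n_events = np.add.reduceat(es.astype(int), starts)
        max_ties = int(n_events.max()) if len(n_events) else 0
        return cls(ts, es, order, starts, n_events, max_ties)


def _ll_groups(sd: SurvData, LP: np.ndarray) -> np.ndarray:
    """Efron log partial likelihood for each column of LP (n x K), where
    LP rows follow the *original* subject order."""
    LP = LP[sd.order]
    shift = LP.max(axis=0, keepdims=True)
    ELP = np.exp(LP - shift)
    seg = np.add.reduceat(ELP, sd.starts, axis=0)  # groups x K
    s_risk = np.cumsum(seg[::-1], axis=0)[::-1]
    Ev = np.where(sd.event[:, None], ELP, 0.0)
    s_tie = np.add.reduceat(Ev, sd.starts, axis=0)
    lp_ev = np.where(sd.event[:, None], LP - shift, 0.0)
    ll = np.add.reduceat(lp_ev, sd.starts, axis=0).sum(axis=0)
    d = sd.n_events.astype(float)
    for ell in range(sd.max_ties):
        mask = sd.n_events > ell
        frac = np.zeros_like(d)
        frac[mask] = ell / d[mask]
        ll -= np.where(mask[:, None], np.log(s_risk - frac[:, None] * s_tie), 0.0).sum(
            axis=0
        )
    return ll


def efron_log_partial_likelihood_multi(
    time: np.ndarray, event: np.ndarray, LP: np.ndarray, sd: SurvData | None = None
) -> np.ndarray:
    """Log partial likelihood per column of an (n x K) linear-predictor matrix."""
    if sd is None:
        sd = SurvData.prepare(time, event)
    LP = np.asarray(LP, dtype=float)
    if LP.ndim == 1:
        LP = LP[:, None]
    return _ll_groups(sd, LP)


def efron_log_partial_likelihood(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray, sd: SurvData | None = None
) -> float:
    """Efron log partial likelihood at a fixed linear predictor."""
    return float(efron_log_partial_likelihood_multi(time, event, np.asarray(lp), sd)[0])


def _grad_hess(sd: SurvData, z: np.ndarray, beta: float) -> tuple[float, float, float]:
    """(ll, gradient, hessian) of the single-covariate Efron likelihood."""
    z = z[sd.order]
    lp = beta * z
    shift = lp.max()
    lp = lp - shift  # the -shift per event cancels the +shift in each log phi
    r = np.exp(lp)
    zr = z * r
    zzr = z * zr
    ev = sd.event
    seg_r = np.add.reduceat(r, sd.starts)
    seg_zr = np.add.reduceat(zr, sd.starts)
    seg_zzr = np.add.reduceat(zzr, sd.starts)
    s_r = np.cumsum(seg_r[::-1])[::-1]
    s_zr = np.cumsum(seg_zr[::-1])[::-1]
    s_zzr = np.cumsum(seg_zzr[::-1])[::-1]
    t_r = np.add.reduceat(np.where(ev, r, 0.0), sd.starts)
    t_zr = np.add.reduceat(np.where(ev, zr, 0.0), sd.starts)
    t_zzr = np.add.reduceat(np.where(ev, zzr, 0.0), sd.starts)
    ll = float(np.add.reduceat(np.where(ev, lp, 0.0), sd.starts).sum())
    grad = float(np.add.reduceat(np.where(ev, z, 0.0), sd.starts).sum())
    hess = 0.0
    d = sd.n_events.astype(float)
    for ell in range(sd.max_ties):
        mask = sd.n_events > ell
        frac = np.where(mask, ell / np.where(d > 0, d, 1.0), 0.0)
        phi = s_r - frac * t_r
        dphi = s_zr - frac * t_zr
        ddphi = s_zzr - frac * t_zzr
        with np.errstate(divide="ignore", invalid="ignore"):
            ll -= float(np.where(mask, np.log(phi), 0.0).sum())
            g = np.where(mask, dphi / phi, 0.0)
            h = np.where(mask, ddphi / phi - (dphi / phi) ** 2, 0.0)
        grad -= float(g.sum())
        hess -= float(h.sum())
    return ll, grad, hess


def fit_single_cox(
    z: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    sd: SurvData | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> dict | None:
    """Newton fit of a one-covariate Cox model (Efron ties).

    Returns ``{"beta", "se", "p", "log_likelihood"}`` with a two-sided
    Wald p, or None when the covariate is constant or the fit diverges
    (monotone likelihood).
    """
    z = np.asarray(z, dtype=float)
    if sd is None:
        sd = SurvData.prepare(time, event)
    if z.min() == z.max():
        return None
    beta = 0.0
    ll, grad, hess = _grad_hess(sd, z, beta)
    for _ in range(max_iter):
        if hess >= 0:
            return None
        step = -grad / hess
        # step-halving keeps the likelihood increasing
        new_beta = beta + step
        new_ll, new_grad, new_hess = _grad_hess(sd, z, new_beta)
        halves = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _grad_hess(sd, z, new_beta)
            halves += 1
            if halves > 30:
                return None
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(beta) > 15:  # monotone likelihood / complete separation
            return None
        if abs(step) < tol * (1.0 + abs(beta)):
            break
    if hess >= 0 or abs(beta) > 15:
        return None
    se = float(1.0 / np.sqrt(-hess))
    wald = beta / se
    p = float(2.0 * stats.norm.sf(abs(wald)))
    return {"beta": float(beta), "se": se, "p": p, "log_likelihood": float(ll)}
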