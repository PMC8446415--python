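"""Immune-related lncRNA screening by co-expression with immune genes.

A lncRNA is called immune-related when it correlates with at least one
curated immune gene with |r| above a threshold (default 0.4) at a two-sided
p-value below a threshold (default 0.001).  Correlations are computed on
log2(FPKM + 1) values; Pearson is the default coefficient, Spearman is
available for heavy-tailed data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ImmuneFilterConfig", "identify_irlncrna"]


@dataclass
class ImmuneFilterConfig:
    cor_threshold: float = 0.4
    p_threshold: float = 0.001
    method: str = "pearson"  # or "spearman"
    absolute: bool = True  # screen on |r|; set False for positive-only

    def __post_init__(self) -> None:
        if not 0 < self.cor_threshold < 1:
            raise ValueError("cor_threshold must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")


def _cor_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-distribution transform of a correlation."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    df = n - 2
    p = 2.0 * special.stdtr(df, -np.abs(t))
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return p


def identify_irlncrna(
    lnc: ExpressionMatrix,
    irgenes: ExpressionMatrix,
    cfg: ImmuneFilterConfig | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Screen lncRNAs for co-expression with immune genes.

    Returns the retained lncRNA id set and a table with, per retained
    lncRNA, its best-correlated immune gene and the corresponding r and p.
    Constant-expression rows have undefined correlations; they are skipped
    and logged.
    """
    cfg = cfg or ImmuneFilterConfig()
    if list(lnc.sample_ids) != list(irgenes.sample_ids):
        if set(lnc.sample_ids) != set(irgenes.sample_ids):
            raise ValueError("lncRNA and immune-gene matrices cover different samples")
        irgenes = irgenes.subset_samples(lnc.sample_ids)
    n = lnc.n_samples
    if n < 3:
        raise ValueError("co-expression screen needs at least 3 samples")

    L = lnc.log2p1().to_numpy()
    G = irgenes.log2p1().to_numpy()
    if cfg.method == "spearman":
        L = stats.rankdata(L, axis=1)
        G = stats.rankdata(G, axis=1)

    l_sd = L.std(axis=1)
    g_sd = G.std(axis=1)
    const_lnc = [g for g, s in zip(lnc.gene_ids, l_sd) if s == 0]
    const_ir = [g for g, s in zip(irgenes.gene_ids, g_sd) if s == 0]
    if const_lnc or const_ir:
        logger.warning(
            "identify_irlncrna: skipped %d constant lncRNA rows and %d "
            "constant immune-gene rows",
            len(const_lnc),
            len(const_ir),
        )

    Lz = (L - L.mean(axis=1, keepdims=True))
    Gz = (G - G.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Lz @ Gz.T) / n / np.outer(l_sd, g_sd)
    R[np.array([s == 0 for s in l_sd]), :] = np.nan
    R[:, np.array([s == 0 for s in g_sd])] = np.nan

    screened = np.abs(R) if cfg.absolute else R
    rows = []
    retained: set[str] = set()
    for i, gid in enumerate(lnc.gene_ids):
        row = screened[i]
        if np.all(np.isnan(row)):
            continue
        j = int(np.nanargmax(row))
        r_best = R[i, j]
        p_best = float(_cor_pvalues(np.array([r_best]), n)[0])
        passes = (row[j] > cfg.cor_threshold) and (p_best < cfg.p_threshold)
        if passes:
            retained.add(gid)
            rows.append(
                {
                    "lncrna": gid,
                    "immune_gene": irgenes.gene_ids[j],
                    "cor": float(r_best),
                    "p": p_best,
                }
            )
    table = pd.DataFrame(rows, columns=["lncrna", "immune_gene", "cor", "p"])
    return retained, table
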