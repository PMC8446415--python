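"""Risk-group association tests for externally computed sample features.

Immune-cell fractions from deconvolution, predicted drug IC50 values,
checkpoint-gene expression and immunophenoscores all arrive as per-sample
feature tables computed by external tools; this module defines their
tabular contract and the two statistics applied to them: per-feature
Wilcoxon rank-sum contrasts between risk groups (BH-adjusted across
features) and Spearman correlation of each feature with the continuous
riskScore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .validate import _rank_sum, significance_stars

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "group_feature_test", "score_feature_correlation"]

FEATURE_KINDS = ("infiltration", "ic50", "checkpoint", "ips")


@dataclass
class FeatureMatrix:
    """Per-sample real-valued features (features x samples), tagged by kind."""

    values: pd.DataFrame
    kind: str = "infiltration"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature id")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "infiltration") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, kind)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def group_feature_test(features: FeatureMatrix, groups: pd.Series) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast of every feature between two risk groups.

    Returns per feature: the two-sided p, the direction (which group has
    the larger median) and the BH-adjusted q across all tested features.
    Features with fewer than 2 non-missing values in either group are
    skipped and reported with ``status="insufficient"``.
    """
    levels = list(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a, b = sorted(levels, key=str)
    common = [s for s in features.sample_ids if s in groups.index]
    vals = features.values[common]
    g = groups.loc[common]
    rows = []
    for fid in vals.index:
        xa = vals.loc[fid, g == a].dropna().to_numpy(dtype=float)
        xb = vals.loc[fid, g == b].dropna().to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"feature": fid, "p": np.nan, "direction": "", "status": "insufficient"})
            continue
        _, p = _rank_sum(xa, xb)
        med_diff = float(np.median(xa) - np.median(xb))
        if med_diff > 0:
            direction = f"higher in {a}"
        elif med_diff < 0:
            direction = f"higher in {b}"
        else:
            direction = "equal medians"
        rows.append({"feature": fid, "p": p, "direction": direction, "status": "ok"})
    out = pd.DataFrame(rows).set_index("feature")
    tested = out["status"] == "ok"
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    n_skip = int((~tested).sum())
    if n_skip:
        logger.info("group_feature_test skipped %d features with insufficient data", n_skip)
    return out


def score_feature_correlation(
    scores: pd.Series, features: FeatureMatrix, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of each feature with the riskScore.

    Tie-corrected ranks, two-sided p.  Constant features have undefined
    correlation and are reported with ``status="constant"``.  The
    ``significant`` column applies the p < ``p_threshold`` convention.
    """
    common = [s for s in features.sample_ids if s in scores.index]
    vals = features.values[common]
    sc = scores.loc[common].to_numpy(dtype=float)
    rows = []
    for fid in vals.index:
        x = vals.loc[fid].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 3:
            rows.append({"feature": fid, "rho": np.nan, "p": np.nan, "status": "insufficient"})
            continue
        if np.unique(x[ok]).size < 2 or np.unique(sc[ok]).size < 2:
            rows.append({"feature": fid, "rho": np.nan, "p": np.nan, "status": "constant"})
            continue
        rho, p = stats.spearmanr(sc[ok], x[ok])
        rows.append({"feature": fid, "rho": float(rho), "p": float(p), "status": "ok"})
    out = pd.DataFrame(rows).set_index("feature")
    out["significant"] = (out["p"] < p_threshold) & (out["status"] == "ok")
    return out
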