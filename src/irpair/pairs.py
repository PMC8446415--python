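"""Rank-based 0/1 pair encoding of expression and the prevalence screen.

For every unordered gene pair (X, Y) with X < Y lexicographically, the
per-sample indicator is 1 when expression(X) > expression(Y) and 0
otherwise (ties included in the 0 branch).  Because the indicator depends
only on the within-sample ordering of the two genes, it is invariant to
any strictly increasing per-sample transformation of expression — the
property that makes pair signatures portable across platforms and
normalizations.  Pairs whose indicator is nearly constant across the
cohort carry no discriminative ranking and are removed by the prevalence
screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PairMatrix", "pair_id", "build_pair_matrix", "filter_pairs_by_prevalence"]

PAIR_SEP = "|"


def pair_id(x: str, y: str) -> str:
    return f"{x}{PAIR_SEP}{y}"


@dataclass
class PairMatrix:
    """Binary pair-indicator matrix, pairs x samples.

    ``indicator`` is indexed by pair id ``"X|Y"`` (X < Y lexicographically)
    with one column per sample.
    """

    indicator: pd.DataFrame

    def __post_init__(self) -> None:
        if self.indicator.index.duplicated().any():
            raise ValueError("duplicate pair id")
        arr = self.indicator.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair indicators must be 0 or 1")
        self.indicator = self.indicator.astype(np.int8)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(p.split(PAIR_SEP, 1)) for p in self.indicator.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.columns)

    @property
    def n_pairs(self) -> int:
        return self.indicator.shape[0]

    @property
    def prevalence(self) -> pd.Series:
        return self.indicator.mean(axis=1)

    def subset_pairs(self, pair_ids: Iterable[str]) -> "PairMatrix":
        ids = list(pair_ids)
        missing = [p for p in ids if p not in self.indicator.index]
        if missing:
            raise KeyError(f"pairs absent from matrix: {missing[:5]}")
        return PairMatrix(self.indicator.loc[ids].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "PairMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.indicator.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return PairMatrix(self.indicator[ids].copy())


def build_pair_matrix(expr: ExpressionMatrix, genes: Iterable[str]) -> PairMatrix:
    """All C(k, 2) pair indicators over ``genes`` on raw expression values.

    Pairs are oriented canonically (first id sorts before the second); the
    model's coefficients absorb orientation, so the choice is a convention,
    not a loss of information.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    vals = expr.values.loc[genes].to_numpy()
    idx = {g: i for i, g in enumerate(genes)}
    rows = []
    ids = []
    for x, y in combinations(genes, 2):
        rows.append((vals[idx[x]] > vals[idx[y]]).astype(np.int8))
        ids.append(pair_id(x, y))
    indicator = pd.DataFrame(rows, index=pd.Index(ids, name="pair_id"), columns=expr.sample_ids)
    return PairMatrix(indicator)


def filter_pairs_by_prevalence(
    pm: PairMatrix, low: float = 0.2, high: float = 0.8
) -> PairMatrix:
    """Keep pairs with ``low < prevalence < high`` (strict on both sides).

    A pair whose indicator is 1 in (almost) every sample — or in (almost)
    none — has no certain rank to exploit and cannot separate outcomes, so
    both extremes are screened out.  Pass ``high=1.01`` for the one-sided
    variant that only removes low-prevalence pairs.
    """
    prev = pm.prevalence
    keep = (prev > low) & (prev < high)
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "prevalence screen removed %d of %d pairs (band %g-%g)",
            removed,
            pm.n_pairs,
            low,
            high,
        )
    if not keep.any():
        raise ValueError(
            f"prevalence screen ({low}, {high}) removed every pair; "
            "relax the band"
        )
    return PairMatrix(pm.indicator[keep].copy())
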