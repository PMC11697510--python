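"""Entropy-based descriptor ranking and correlation redundancy filtering.

Descriptors are ranked by the mutual information (in bits) between a
discretized descriptor and the binary activity class, then filtered by a
greedy pass in rank order that keeps a descriptor only when its Pearson
correlation with every already-kept descriptor lies strictly inside
(-0.7, +0.7), stopping after a target count (15 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedDescriptor",
    "mi_dse_rank",
    "pcc_filter",
    "select_descriptors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedDescriptor:
    name: str
    score: float  # bits
    rank: int


def _discretize(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; columns with few distinct values keep them as bins."""
    uniq = np.unique(column)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, column)
    qs = np.quantile(column, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, column, side="right")


def _mutual_information_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Discrete mutual information of two label arrays, in bits."""
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px @ py))
    return float(np.nansum(terms))


def mi_dse_rank(d_table: pd.DataFrame, labels: pd.Series | np.ndarray,
                max_bins: int = 10) -> list[RankedDescriptor]:
    """Rank descriptors by mutual information with the class label.

    Discretization uses equal-frequency bins, ceil(sqrt(n)) of them capped
    at ``max_bins``.  Constant descriptors score 0.  Ties in score are
    broken alphabetically by name so the ranking is a total order.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ranking needs at least two classes in the labels")
    n = len(y)
    n_bins = min(max_bins, math.ceil(math.sqrt(n)))
    scored = []
    for name in d_table.columns:
        col = d_table[name].to_numpy(dtype=float)
        if np.all(col == col[0]):
            scored.append((name, 0.0))
            continue
        scored.append((name, _mutual_information_bits(_discretize(col, n_bins), y)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [RankedDescriptor(name=nm, score=sc, rank=i + 1)
            for i, (nm, sc) in enumerate(scored)]


def pcc_filter(ranked: list[RankedDescriptor], d_table: pd.DataFrame,
               bound: float = 0.7, n_keep: int = 15) -> list[str]:
    """Greedy redundancy filter in rank order.

    A descriptor is kept iff |PCC| with every already-kept descriptor is
    strictly below ``bound``; the pass stops once ``n_keep`` descriptors
    are kept.  If fewer survive, a warning is logged and the survivors are
    returned.
    """
    if not ranked:
        raise ValueError("ranked descriptor list is empty")
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    for rd in ranked:
        col = d_table[rd.name].to_numpy(dtype=float)
        if np.std(col) == 0:
            continue
        ok = True
        for other in kept_cols:
            pcc = np.corrcoef(col, other)[0, 1]
            if not (-bound < pcc < bound):
                ok = False
                break
        if ok:
            kept.append(rd.name)
            kept_cols.append(col)
            if len(kept) == n_keep:
                return kept
    logger.warning("pcc_filter: only %d of the requested %d descriptors survive",
                   len(kept), n_keep)
    return kept


def select_descriptors(d_table: pd.DataFrame, labels, bound: float = 0.7,
                       n_keep: int = 15, max_bins: int = 10
                       ) -> tuple[list[str], list[RankedDescriptor]]:
    """mi_dse_rank + pcc_filter in one call; returns (kept, full ranking)."""
    ranked = mi_dse_rank(d_table, labels, max_bins=max_bins)
    return pcc_filter(ranked, d_table, bound=bound, n_keep=n_keep), ranked
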