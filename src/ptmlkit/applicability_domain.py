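"""Descriptor-range applicability domain.

For each selected condition-perturbation descriptor the training split
defines a closed interval [min, max].  A query case earns a local score of
1 per descriptor whose value lies inside its interval (boundary inclusive)
and 0 otherwise; the total score TSAD is the sum of local scores, and a
case belongs to the domain only when TSAD equals the descriptor count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ADBounds", "ADScore", "fit_bounds", "score", "score_table"]


@dataclass(frozen=True)
class ADBounds:
    """Per-descriptor closed [min, max] intervals from the training split."""

    lower: pd.Series
    upper: pd.Series

    def __post_init__(self):
        if not (self.lower.index.equals(self.upper.index)):
            raise ValueError("lower and upper bounds cover different descriptors")
        if (self.lower > self.upper).any():
            raise ValueError("lower bound exceeds upper bound")

    @property
    def descriptors(self) -> list[str]:
        return list(self.lower.index)

    def save_csv(self, path) -> None:
        pd.DataFrame({"min": self.lower, "max": self.upper}) \
            .rename_axis("descriptor").to_csv(path)

    @classmethod
    def load_csv(cls, path) -> "ADBounds":
        df = pd.read_csv(path, index_col="descriptor")
        return cls(lower=df["min"], upper=df["max"])


@dataclass(frozen=True)
class ADScore:
    locals: pd.Series  # 0/1 per descriptor
    tsad: int
    in_domain: bool


def fit_bounds(training_d_table: pd.DataFrame) -> ADBounds:
    """Componentwise min/max of the training D-descriptor table."""
    if training_d_table.empty:
        raise ValueError("cannot fit applicability-domain bounds on an empty table")
    return ADBounds(lower=training_d_table.min(axis=0),
                    upper=training_d_table.max(axis=0))


def score(case_values: pd.Series, bounds: ADBounds) -> ADScore:
    """Local scores, TSAD and the in-domain flag for one case."""
    missing = [d for d in bounds.descriptors if d not in case_values.index]
    if missing:
        raise KeyError(f"case lacks descriptors required by the AD: {missing}")
    vals = case_values[bounds.descriptors].astype(float)
    local = ((vals >= bounds.lower) & (vals <= bounds.upper)).astype(int)
    tsad = int(local.sum())
    return ADScore(locals=local, tsad=tsad,
                   in_domain=tsad == len(bounds.descriptors))


def score_table(d_table: pd.DataFrame, bounds: ADBounds) -> pd.DataFrame:
    """TSAD and in-domain flag for every row of a D-descriptor table."""
    missing = [d for d in bounds.descriptors if d not in d_table.columns]
    if missing:
        raise KeyError(f"table lacks descriptors required by the AD: {missing}")
    vals = d_table[bounds.descriptors].to_numpy(dtype=float)
    lo = bounds.lower.to_numpy(dtype=float)
    hi = bounds.upper.to_numpy(dtype=float)
    local = (vals >= lo) & (vals <= hi)
    tsad = local.sum(axis=1)
    return pd.DataFrame({"TSAD": tsad,
                         "in_domain": tsad == len(bounds.descriptors)},
                        index=d_table.index)
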