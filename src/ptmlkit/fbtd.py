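"""Quantitative substrate of fragment-based topological design (FBTD).

Three artefacts support the design interpretation of a trained model:

* **Sensitivity values (SVs)** — relative importance of each input
  descriptor, computed as the ratio (model error with that input replaced
  by its training mean) / (full-model error).  Inputs the model relies on
  have SV well above 1; pure-noise inputs sit near 1.
* **Class-based means and propensities** — for each descriptor, the mean
  over correctly-classified training actives and over correctly-classified
  training inactives; the propensity is Increase when the active mean is
  the larger, Decrease when it is the smaller (the direction a designer
  should push the descriptor to favour activity).
* **Guideline report** — a readable table merging ranks, SVs and
  propensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SensitivityReport",
    "PropensityTable",
    "sensitivity_values",
    "class_based_means",
    "propensity_label",
    "guideline_report",
]

logger = logging.getLogger(__name__)


@dataclass
class SensitivityReport:
    """Per-descriptor SV and rank (rank 1 = most influential)."""

    table: pd.DataFrame  # columns: sv, rank; index: descriptor


@dataclass
class PropensityTable:
    table: pd.DataFrame  # columns: active_mean, inactive_mean, propensity


def sensitivity_values(bundle, d_table: pd.DataFrame, truth) -> SensitivityReport:
    """Mean-substitution sensitivity values on the given evaluation data.

    For each selected descriptor the column is replaced by its training
    mean and the misclassification rate re-measured; SV = perturbed error /
    full error.  A full error of zero is floored at 1/(2n) so ratios stay
    finite (logged).
    """
    y = np.asarray(truth)
    X = d_table[bundle.descriptors].copy()
    full_err = float(np.mean(bundle.predict_class(X) != y))
    n = len(y)
    if full_err == 0.0:
        logger.info("sensitivity_values: zero full-model error, flooring at 1/(2n)")
        full_err = 1.0 / (2 * n)
    means = bundle.training_means
    if means is None:
        means = X.mean(axis=0)
    rows = {}
    for d in bundle.descriptors:
        X_mod = X.copy()
        X_mod[d] = float(means[d])
        err = float(np.mean(bundle.predict_class(X_mod) != y))
        rows[d] = err / full_err
    sv = pd.Series(rows, name="sv")
    rank = sv.rank(ascending=False, method="first").astype(int)
    return SensitivityReport(table=pd.DataFrame({"sv": sv, "rank": rank}))


def propensity_label(active_mean: float, inactive_mean: float) -> str:
    """Increase when actives average higher, Decrease when lower, None on a tie."""
    if active_mean > inactive_mean:
        return "Increase"
    if active_mean < inactive_mean:
        return "Decrease"
    return "None"


def class_based_means(d_table: pd.DataFrame, truth, predictions) -> PropensityTable:
    """Class-based descriptor means over correctly-classified training cases.

    ``d_table`` holds the selected descriptors for the training split;
    ``truth`` and ``predictions`` are aligned +1/-1 vectors.  Raises if
    either class has no correctly classified case.
    """
    y = np.asarray(truth)
    pred = np.asarray(predictions)
    correct = y == pred
    act = correct & (y == 1)
    inact = correct & (y == -1)
    if not act.any():
        raise ValueError("no correctly-classified active training cases")
    if not inact.any():
        raise ValueError("no correctly-classified inactive training cases")
    a_means = d_table[act].mean(axis=0)
    i_means = d_table[inact].mean(axis=0)
    prop = [propensity_label(a, i) for a, i in zip(a_means, i_means)]
    return PropensityTable(table=pd.DataFrame({
        "active_mean": a_means, "inactive_mean": i_means, "propensity": prop,
    }))


def guideline_report(sensitivity: SensitivityReport,
                     propensity: PropensityTable) -> str:
    """Human-readable design-guideline table ordered by sensitivity rank."""
    header = f"{'descriptor':<28} {'rank':>4} {'SV':>10} {'propensity':>10}"
    lines = [header, "-" * len(header)]
    merged = sensitivity.table.join(propensity.table, how="left")
    for name, row in merged.sort_values("rank").iterrows():
        prop = row.get("propensity")
        prop = prop if isinstance(prop, str) else "n/a"
        lines.append(f"{name:<28} {int(row['rank']):>4} {row['sv']:>10.4f} {prop:>10}")
    return "\n".join(lines)
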