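"""The condition-perturbation (Box-Jenkins moving-average) transform.

Raw topological indices TBI are converted into condition-dependent
descriptors D[TBI]cj measuring how far a molecule sits from the average
active compound tested under the same element of the experimental
condition cj = (target protein tp, assay information ai):

    avg[TBI]cj = mean of TBI over training cases labeled active that share
                 the condition element (tp or ai),
    D[TBI]cj   = ((TBI - avg[TBI]cj) / Std[TBI]) * sqrt(p(cj)),

where Std[TBI] is the standard deviation of TBI over all training cases
and p(cj) an a-priori probability of the condition element.  The transform
is applied to tp and ai separately, so each raw descriptor yields two D
columns per case.  Despite the name this has nothing to do with ARIMA
modelling; it is a grouped centering/scaling transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENT_KINDS",
    "BoxJenkinsReference",
    "fit_reference",
    "transform",
    "transform_table",
    "dataset_frequency_probability",
]

logger = logging.getLogger(__name__)

#: the two condition-element kinds (columns of the case table)
ELEMENT_KINDS = ("tp", "ai")


def dataset_frequency_probability(cases: pd.DataFrame, kind: str) -> pd.Series:
    """p(element) = (cases annotated with the element) / (total cases)."""
    return cases[kind].value_counts() / len(cases)


@dataclass
class BoxJenkinsReference:
    """Frozen statistics of the transform, fit on the training split.

    ``avg``: (descriptor, element-label) -> mean over training actives.
    ``std``: descriptor -> sample standard deviation over all training cases.
    ``p``:   element-label -> a-priori probability.
    ``n``:   element-label -> number of training actives behind the mean.
    """

    descriptors: tuple[str, ...]
    avg: dict[tuple[str, str], float] = field(repr=False)
    std: dict[str, float] = field(repr=False)
    p: dict[str, float]
    n: dict[str, int]
    element_kind: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        """Flat (descriptor, element, avg, std, p, n) table for auditing."""
        rows = []
        for (desc, elem), avg in self.avg.items():
            rows.append({
                "descriptor": desc, "element": elem, "kind": self.element_kind[elem],
                "avg": avg, "std": self.std[desc], "p": self.p[elem], "n": self.n[elem],
            })
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BoxJenkinsReference":
        descriptors = tuple(dict.fromkeys(frame["descriptor"]))
        avg = {(r.descriptor, r.element): float(r.avg) for r in frame.itertuples()}
        std = {r.descriptor: float(r.std) for r in frame.itertuples()}
        p = {r.element: float(r.p) for r in frame.itertuples()}
        n = {r.element: int(r.n) for r in frame.itertuples()}
        kind = {r.element: str(r.kind) for r in frame.itertuples()}
        return cls(descriptors=descriptors, avg=avg, std=std, p=p, n=n,
                   element_kind=kind)

    @classmethod
    def load_csv(cls, path) -> "BoxJenkinsReference":
        return cls.from_frame(pd.read_csv(path))


def fit_reference(
    cases: pd.DataFrame,
    descriptor_table: pd.DataFrame,
    probability: Callable[[pd.DataFrame, str], pd.Series] = dataset_frequency_probability,
) -> BoxJenkinsReference:
    """Fit the transform's reference statistics.

    ``cases`` must carry molecule_id, tp, ai, IA and split columns (the
    full labeled table; only rows tagged ``training`` shape avg and Std,
    so the reference cannot leak test-set information).
    ``descriptor_table`` is indexed by molecule_id with one column per raw
    descriptor.  Zero-variance descriptors are dropped with a log message.
    ``probability`` is the pluggable p(cj) strategy; the default is the
    dataset frequency of each condition element.
    """
    train = cases[cases["split"] == "training"]
    if train.empty:
        raise ValueError("no training cases to fit the reference on")
    desc_names = list(descriptor_table.columns)

    tbi_train = np.ascontiguousarray(
        descriptor_table.loc[train["molecule_id"]].to_numpy(dtype=float))
    std_all = pd.Series(np.std(tbi_train, axis=0, ddof=1), index=desc_names)
    keep = [d for d in desc_names if std_all[d] > 0 and np.isfinite(std_all[d])]
    dropped = sorted(set(desc_names) - set(keep))
    if dropped:
        logger.info("fit_reference: dropped %d zero-variance descriptors: %s",
                    len(dropped), dropped[:8])
    if not keep:
        raise ValueError("every descriptor has zero variance on the training split")

    actives = train[train["IA"] == 1]
    avg: dict[tuple[str, str], float] = {}
    n: dict[str, int] = {}
    p: dict[str, float] = {}
    kind_of: dict[str, str] = {}
    for kind in ELEMENT_KINDS:
        probs = probability(cases, kind)
        for elem in cases[kind].unique():
            grp = actives[actives[kind] == elem]
            if grp.empty:
                raise ValueError(
                    f"condition element {elem!r} ({kind}) has no active training "
                    "cases; cannot form its reference mean"
                )
            # contiguous copy: summation order (hence the reference) must not
            # depend on the caller's memory layout
            block = np.ascontiguousarray(
                descriptor_table.loc[grp["molecule_id"], keep].to_numpy(dtype=float))
            means = block.mean(axis=0)
            for i, d in enumerate(keep):
                avg[(d, elem)] = float(means[i])
            n[elem] = len(grp)
            p[elem] = float(probs[elem])
            kind_of[elem] = kind

    return BoxJenkinsReference(
        descriptors=tuple(keep),
        avg=avg,
        std={d: float(std_all[d]) for d in keep},
        p=p, n=n, element_kind=kind_of,
    )


def transform(case: pd.Series, descriptors: pd.Series,
              reference: BoxJenkinsReference) -> dict[str, float]:
    """D values for one case: one entry per (descriptor, element kind).

    Keys follow the ``D[<descriptor>]<kind>`` grammar, e.g. ``D[SM(Hyd)1]tp``.
    Raises KeyError for a condition element absent from the reference (the
    case lies outside the modelled conditions).
    """
    out: dict[str, float] = {}
    for kind in ELEMENT_KINDS:
        elem = case[kind]
        if elem not in reference.p:
            raise KeyError(
                f"condition element {elem!r} ({kind}) was not present when the "
                "reference was fit"
            )
        sqrt_p = reference.p[elem] ** 0.5
        for d in reference.descriptors:
            val = (float(descriptors[d]) - reference.avg[(d, elem)]) / reference.std[d]
            out[f"D[{d}]{kind}"] = val * sqrt_p
    return out


def transform_table(cases: pd.DataFrame, descriptor_table: pd.DataFrame,
                    reference: BoxJenkinsReference) -> pd.DataFrame:
    """Vectorized :func:`transform` over a whole case table.

    Returns a DataFrame aligned with ``cases`` (same index), columns
    ``D[<descriptor>]tp`` and ``D[<descriptor>]ai``.
    """
    descs = list(reference.descriptors)
    tbi = descriptor_table.loc[cases["molecule_id"], descs].to_numpy(dtype=float)
    std = np.array([reference.std[d] for d in descs])
    blocks = {}
    for kind in ELEMENT_KINDS:
        elems = cases[kind].to_numpy()
        unknown = [e for e in np.unique(elems) if e not in reference.p]
        if unknown:
            raise KeyError(f"condition elements outside the modelled set: {unknown}")
        avg = np.array([[reference.avg[(d, e)] for d in descs] for e in elems])
        sqrt_p = np.array([reference.p[e] ** 0.5 for e in elems])[:, None]
        blocks[kind] = (tbi - avg) / std * sqrt_p
    data = np.hstack([blocks[k] for k in ELEMENT_KINDS])
    cols = [f"D[{d}]{k}" for k in ELEMENT_KINDS for d in descs]
    return pd.DataFrame(data, index=cases.index, columns=cols)
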