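"""Multilayer-perceptron classifier search, metrics, and consensus calls.

The primary learner is a single-hidden-layer MLP over the selected
condition-perturbation descriptors.  Candidate topologies (hidden-layer
size H and activation) are sampled within a configured range, each checked
against the anti-overfitting rule

    rho = T / [(I + 1) H + (H + 1) O] > 3

with T training cases, I input nodes and O = 2 output nodes, and scored by
the mean of training and test nMCC (normalized Matthews correlation,
nMCC = (MCC + 1) / 2, 0.5 for a random predictor).  Thin adapters for
LDA / SVM / random-forest comparisons reuse the same evaluation path.

A molecule tested under several conditions receives one prediction per
condition; per-protein consensus rules (e.g. active in at least 3 of 4
conditions, or probability > 50% in at least 2 of 4) fold these into a
single call.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .applicability_domain import ADBounds
from .box_jenkins import BoxJenkinsReference

__all__ = [
    "rho",
    "NetworkTopology",
    "TrainingConfig",
    "MetricsReport",
    "metrics_from_counts",
    "evaluate",
    "local_metrics",
    "train",
    "train_comparison",
    "ModelBundle",
    "predict_table",
    "consensus_call",
    "ConsensusRule",
    "CLASS_RULE_PRESET",
    "PROBABILITY_RULE_PRESET",
]

logger = logging.getLogger(__name__)


def rho(T: int, I: int, H: int, O: int) -> float:
    """Topology ratio T / [(I+1)H + (H+1)O]; values > 3 indicate no overfitting."""
    for name, v in (("T", T), ("I", I), ("H", H), ("O", O)):
        if v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    return T / ((I + 1) * H + (H + 1) * O)


@dataclass(frozen=True)
class NetworkTopology:
    T: int
    I: int
    H: int
    O: int = 2

    @property
    def rho(self) -> float:
        return rho(self.T, self.I, self.H, self.O)

    @property
    def acceptable(self) -> bool:
        return self.rho > 3


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameter budget for the MLP search.

    Defaults mirror the published protocol (500 epochs, hidden sizes
    15-70, 3000 candidates of which 250 retained); pipelines typically
    scale the candidate budget down.  ``activations`` are the candidate
    hidden-layer activations offered to the search.
    """

    epochs: int = 500
    hidden_range: tuple[int, int] = (15, 70)
    n_candidates: int = 3000
    n_retained: int = 250
    activations: tuple[str, ...] = ("logistic", "tanh")
    seed: int = 0
    min_rho: float = 3.0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics for one evaluation split."""

    n_active: int
    cc_active: int
    n_inactive: int
    cc_inactive: int
    sn: float        # sensitivity, %
    sp: float        # specificity, %
    accuracy: float  # %
    mcc: float
    nmcc: float

    def as_dict(self) -> dict:
        return asdict(self)


def metrics_from_counts(n_active: int, cc_active: int,
                        n_inactive: int, cc_inactive: int) -> MetricsReport:
    """Metrics from the four confusion counts.

    Sn = CC_Active / N_Active, Sp = CC_Inactive / N_Inactive (percent),
    accuracy over all cases, MCC from the implied confusion matrix and
    nMCC = (MCC + 1) / 2.  A zero MCC denominator yields MCC = 0
    (nMCC = 0.5), logged.
    """
    tp, fn = cc_active, n_active - cc_active
    tn, fp = cc_inactive, n_inactive - cc_inactive
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("correctly-classified counts exceed class totals")
    sn = 100.0 * tp / n_active if n_active else math.nan
    sp = 100.0 * tn / n_inactive if n_inactive else math.nan
    accuracy = 100.0 * (tp + tn) / (n_active + n_inactive)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.info("metrics: degenerate confusion matrix, MCC set to 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricsReport(n_active=n_active, cc_active=cc_active,
                         n_inactive=n_inactive, cc_inactive=cc_inactive,
                         sn=sn, sp=sp, accuracy=accuracy,
                         mcc=mcc, nmcc=(mcc + 1) / 2)


def evaluate(predictions: Sequence[int], truth: Sequence[int]) -> MetricsReport:
    """Metrics from aligned +1/-1 prediction and truth vectors."""
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    if pred.shape != y.shape:
        raise ValueError("prediction and truth vectors differ in length")
    n_active = int((y == 1).sum())
    n_inactive = int((y == -1).sum())
    cc_active = int(((y == 1) & (pred == 1)).sum())
    cc_inactive = int(((y == -1) & (pred == -1)).sum())
    return metrics_from_counts(n_active, cc_active, n_inactive, cc_inactive)


def local_metrics(predictions: Sequence[int], truth: Sequence[int],
                  groups: Sequence) -> pd.DataFrame:
    """Per-group Sn/Sp: :func:`evaluate` restricted to each group label.

    Groups with no actives (or no inactives) report NaN for the undefined
    metric rather than a silent 0; empty groups are absent.
    """
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    grp = np.asarray(groups)
    rows = []
    for g in pd.unique(grp):
        mask = grp == g
        rep = evaluate(pred[mask], y[mask])
        rows.append({"group": g, "n_active": rep.n_active,
                     "n_inactive": rep.n_inactive, "sn": rep.sn, "sp": rep.sp})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to reuse it.

    Carries the fitted estimator, the selected descriptor names, the frozen
    Box-Jenkins reference, the applicability-domain bounds, the metrics of
    both splits and the winning topology.
    """

    classifier: object
    descriptors: list[str]
    topology: NetworkTopology | None
    reference: BoxJenkinsReference | None = None
    ad_bounds: ADBounds | None = None
    metrics: dict = field(default_factory=dict)
    config: TrainingConfig | None = None
    training_means: pd.Series | None = None

    def predict_class(self, X: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict(X[self.descriptors].to_numpy())

    def predict_probability(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the active class, in percent."""
        proba = self.classifier.predict_proba(X[self.descriptors].to_numpy())
        active_col = list(self.classifier.classes_).index(1)
        return 100.0 * proba[:, active_col]

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, d / "classifier.joblib")
        (d / "descriptors.txt").write_text("\n".join(self.descriptors) + "\n")
        if self.reference is not None:
            self.reference.save_csv(d / "reference.csv")
        if self.ad_bounds is not None:
            self.ad_bounds.save_csv(d / "ad_bounds.csv")
        if self.training_means is not None:
            self.training_means.to_csv(d / "training_means.csv", header=["mean"])
        meta = {"metrics": self.metrics}
        if self.topology is not None:
            meta["topology"] = asdict(self.topology)
        (d / "metrics.json").write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        d = Path(directory)
        clf = joblib.load(d / "classifier.joblib")
        descriptors = (d / "descriptors.txt").read_text().split()
        meta = json.loads((d / "metrics.json").read_text())
        topo = NetworkTopology(**meta["topology"]) if "topology" in meta else None
        ref = (BoxJenkinsReference.load_csv(d / "reference.csv")
               if (d / "reference.csv").exists() else None)
        bounds = (ADBounds.load_csv(d / "ad_bounds.csv")
                  if (d / "ad_bounds.csv").exists() else None)
        means = None
        if (d / "training_means.csv").exists():
            means = pd.read_csv(d / "training_means.csv", index_col=0)["mean"]
        return cls(classifier=clf, descriptors=descriptors, topology=topo,
                   reference=ref, ad_bounds=bounds, metrics=meta.get("metrics", {}),
                   training_means=means)


def _candidate_topologies(T: int, I: int, config: TrainingConfig,
                          rng: np.random.Generator) -> list[tuple[int, str]]:
    lo, hi = config.hidden_range
    feasible = [h for h in range(lo, hi + 1)
                if rho(T, I, h, 2) > config.min_rho]
    if not feasible:
        raise ValueError(
            f"no hidden-layer size in {config.hidden_range} satisfies "
            f"rho > {config.min_rho} for T={T}, I={I}; reduce H or add cases"
        )
    n = min(config.n_candidates, len(feasible) * len(config.activations))
    pairs = [(h, a) for h in feasible for a in config.activations]
    idx = rng.choice(len(pairs), size=n, replace=False) if n < len(pairs) else range(len(pairs))
    return [pairs[i] for i in idx]


def train(d_table: pd.DataFrame, cases: pd.DataFrame, selected: list[str],
          config: TrainingConfig | None = None) -> ModelBundle:
    """Search (H, activation) candidates under the rho rule and keep the best.

    ``d_table`` holds the condition-perturbation descriptors aligned with
    ``cases`` (which carries IA and split columns); only ``selected``
    columns enter the model.  Candidates violating rho > 3 are never
    trained.  The winner maximizes the mean of training and test nMCC;
    deterministic given ``config.seed``.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)
    train_mask = (cases["split"] == "training").to_numpy()
    X = d_table[selected].to_numpy(dtype=float)
    y = cases["IA"].to_numpy(dtype=int)
    X_tr, y_tr = X[train_mask], y[train_mask]
    X_te, y_te = X[~train_mask], y[~train_mask]
    T, I = len(y_tr), len(selected)

    candidates = _candidate_topologies(T, I, config, rng)
    scored: list[tuple[float, MLPClassifier, NetworkTopology, dict]] = []
    for h, act in candidates:
        clf = MLPClassifier(hidden_layer_sizes=(h,), activation=act,
                            max_iter=config.epochs,
                            random_state=int(rng.integers(2**31 - 1)))
        clf.fit(X_tr, y_tr)
        rep_tr = evaluate(clf.predict(X_tr), y_tr)
        rep_te = evaluate(clf.predict(X_te), y_te)
        score = 0.5 * (rep_tr.nmcc + rep_te.nmcc)
        scored.append((score, clf, NetworkTopology(T=T, I=I, H=h, O=2),
                       {"training": rep_tr.as_dict(), "test": rep_te.as_dict()}))
    scored.sort(key=lambda t: -t[0])
    retained = scored[: config.n_retained]
    best_score, best_clf, best_topo, best_metrics = retained[0]
    logger.info("train: best H=%d act=%s score=%.3f rho=%.2f (%d candidates)",
                best_topo.H, best_clf.activation, best_score, best_topo.rho,
                len(candidates))
    means = pd.Series(X_tr.mean(axis=0), index=selected)
    return ModelBundle(classifier=best_clf, descriptors=list(selected),
                       topology=best_topo, metrics=best_metrics, config=config,
                       training_means=means)


_COMPARISON_FACTORIES = {
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
    "SVM": lambda seed: SVC(kernel="rbf", probability=True, random_state=seed),
    "RF": lambda seed: RandomForestClassifier(n_estimators=65, max_depth=10,
                                              random_state=seed),
}


def train_comparison(d_table: pd.DataFrame, cases: pd.DataFrame,
                     selected: list[str], seed: int = 0,
                     models: Sequence[str] = ("LDA", "SVM", "RF")
                     ) -> dict[str, ModelBundle]:
    """Thin adapters fitting the alternative learners on the same data."""
    train_mask = (cases["split"] == "training").to_numpy()
    X = d_table[selected].to_numpy(dtype=float)
    y = cases["IA"].to_numpy(dtype=int)
    out = {}
    for name in models:
        clf = _COMPARISON_FACTORIES[name](seed)
        clf.fit(X[train_mask], y[train_mask])
        rep_tr = evaluate(clf.predict(X[train_mask]), y[train_mask])
        rep_te = evaluate(clf.predict(X[~train_mask]), y[~train_mask])
        out[name] = ModelBundle(
            classifier=clf, descriptors=list(selected), topology=None,
            metrics={"training": rep_tr.as_dict(), "test": rep_te.as_dict()})
    return out


def predict_table(bundle: ModelBundle, d_table: pd.DataFrame,
                  cases: pd.DataFrame) -> pd.DataFrame:
    """Per-case predictions: PredIA (+1/-1) and ProbAct (%) columns.

    The class call is +1 iff the active-class probability exceeds 50%.
    """
    prob = bundle.predict_probability(d_table)
    pred = np.where(prob > 50.0, 1, -1)
    out = cases[["molecule_id", "tp", "ai"]].copy()
    out["PredIA"] = pred
    out["ProbAct"] = prob
    return out


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusRule:
    """Per-protein consensus over a molecule's per-condition predictions.

    ``thresholds`` maps protein -> minimum number of active calls;
    ``use_probability`` counts conditions with probability > 50% instead
    of class calls.
    """

    thresholds: Mapping[str, int]
    use_probability: bool = False

    def n_required(self, protein: str) -> int:
        return self.thresholds[protein]


#: active in at least 3 of NET's 4 conditions / 1 of SERT's 2 (class calls)
CLASS_RULE_PRESET = ConsensusRule(thresholds={"NET": 3, "SERT": 1})
#: probability > 50% in at least 2 of NET's 4 conditions / 1 of SERT's 2
PROBABILITY_RULE_PRESET = ConsensusRule(thresholds={"NET": 2, "SERT": 1},
                                        use_probability=True)


def consensus_call(predictions: pd.DataFrame, rule: ConsensusRule,
                   expected_conditions: Mapping[str, int] | None = None
                   ) -> dict[str, int]:
    """Fold one molecule's per-condition predictions into per-protein calls.

    ``predictions`` needs tp plus PredIA and/or ProbAct columns; the
    result maps protein -> +1/-1.  If ``expected_conditions`` gives the
    number of conditions per protein, missing conditions raise.
    """
    out: dict[str, int] = {}
    for protein, grp in predictions.groupby("tp"):
        if expected_conditions is not None:
            want = expected_conditions.get(str(protein))
            if want is not None and len(grp) != want:
                raise ValueError(
                    f"protein {protein}: expected {want} conditions, got {len(grp)}"
                )
        if rule.use_probability:
            n_active = int((grp["ProbAct"] > 50.0).sum())
        else:
            n_active = int((grp["PredIA"] == 1).sum())
        out[str(protein)] = 1 if n_active >= rule.n_required(str(protein)) else -1
    return out
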