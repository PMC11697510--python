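import numpy as np
import pandas as pd
import pytest

from ptmlkit import ptml_model as pm


# ---------------------------------------------------------------------------
# topology rule
# ---------------------------------------------------------------------------


def test_rho_worked_example():
    assert round(pm.rho(2742, 15, 26, 2), 2) == 5.83


def test_rho_boundary_exactly_three_rejected():
    # denominator (15+1)*26 + (26+1)*2 = 470
    assert pm.rho(470 * 3, 15, 26, 2) == pytest.approx(3.0)
    assert not pm.NetworkTopology(T=470 * 3, I=15, H=26, O=2).acceptable


def test_rho_below_threshold():
    assert pm.rho(940, 15, 26, 2) == pytest.approx(2.0)
    assert not pm.NetworkTopology(T=940, I=15, H=26, O=2).acceptable


@pytest.mark.parametrize("args", [(0, 15, 26, 2), (100, -1, 26, 2), (100, 15, 0, 2)])
def test_rho_rejects_nonpositive(args):
    with pytest.raises(ValueError):
        pm.rho(*args)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_metrics_perfect_predictions():
    rep = pm.evaluate([1, 1, -1, -1], [1, 1, -1, -1])
    assert rep.sn == rep.sp == rep.accuracy == 100.0
    assert rep.nmcc == 1.0


def test_metrics_degenerate_confusion_gives_half_nmcc():
    rep = pm.evaluate([1, 1, 1, 1], [1, 1, -1, -1])  # all predicted active
    assert rep.mcc == 0.0
    assert rep.nmcc == 0.5


def test_metrics_counts_validated():
    with pytest.raises(ValueError):
        pm.metrics_from_counts(10, 12, 10, 5)


def test_random_predictor_nmcc_near_half():
    rng = np.random.default_rng(0)
    y = rng.choice([1, -1], size=4000)
    pred = rng.choice([1, -1], size=4000)
    assert pm.evaluate(pred, y).nmcc == pytest.approx(0.5, abs=0.03)


def test_local_metrics_single_group_equals_global():
    rng = np.random.default_rng(1)
    y = rng.choice([1, -1], size=50)
    pred = rng.choice([1, -1], size=50)
    local = pm.local_metrics(pred, y, ["NET"] * 50)
    rep = pm.evaluate(pred, y)
    assert local.loc["NET", "sn"] == pytest.approx(rep.sn)
    assert local.loc["NET", "sp"] == pytest.approx(rep.sp)


def test_local_metrics_hand_built_groups():
    y = [1, 1, -1, -1, 1, -1]
    pred = [1, -1, -1, 1, 1, -1]
    groups = ["a", "a", "a", "a", "b", "b"]
    local = pm.local_metrics(pred, y, groups)
    assert local.loc["a", "sn"] == pytest.approx(50.0)
    assert local.loc["a", "sp"] == pytest.approx(50.0)
    assert local.loc["b", "sn"] == pytest.approx(100.0)
    assert local.loc["b", "sp"] == pytest.approx(100.0)


def test_local_metrics_group_without_actives_reports_nan():
    local = pm.local_metrics([-1, -1], [-1, -1], ["a", "a"])
    assert np.isnan(local.loc["a", "sn"])
    assert local.loc["a", "sp"] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def make_training_data(n=240, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
    y = np.where(X["a"] + 0.5 * X["b"] + rng.normal(scale=0.4, size=n) > 0, 1, -1)
    cases = pd.DataFrame({
        "molecule_id": [f"M{i}" for i in range(n)],
        "tp": ["NET"] * n,
        "ai": ["x"] * n,
        "IA": y,
        "split": ["training" if i % 4 != 3 else "test" for i in range(n)],
    })
    return X, cases


SMALL_CONFIG = pm.TrainingConfig(epochs=200, hidden_range=(3, 8),
                                 n_candidates=3, n_retained=3, seed=1)


def test_train_learns_planted_signal():
    X, cases = make_training_data()
    bundle = pm.train(X, cases, list("abcd"), SMALL_CONFIG)
    assert bundle.metrics["training"]["nmcc"] > 0.75
    assert bundle.metrics["test"]["nmcc"] > 0.7
    assert bundle.topology.rho > 3


def test_train_deterministic_given_seed():
    X, cases = make_training_data()
    b1 = pm.train(X, cases, list("abcd"), SMALL_CONFIG)
    b2 = pm.train(X, cases, list("abcd"), SMALL_CONFIG)
    assert b1.metrics == b2.metrics
    np.testing.assert_array_equal(b1.predict_class(X), b2.predict_class(X))


def test_train_rejects_unattainable_rho():
    X, cases = make_training_data(n=40)
    config = pm.TrainingConfig(hidden_range=(60, 70), n_candidates=2,
                               epochs=50, seed=0)
    with pytest.raises(ValueError, match="rho"):
        pm.train(X, cases, list("abcd"), config)


def test_train_comparison_adapters_fit():
    X, cases = make_training_data()
    bundles = pm.train_comparison(X, cases, list("abcd"), seed=0)
    assert set(bundles) == {"LDA", "SVM", "RF"}
    for b in bundles.values():
        assert b.metrics["training"]["nmcc"] > 0.6


def test_bundle_roundtrip(tmp_path):
    X, cases = make_training_data()
    bundle = pm.train(X, cases, list("abcd"), SMALL_CONFIG)
    bundle.save(tmp_path / "model")
    back = pm.ModelBundle.load(tmp_path / "model")
    assert back.descriptors == bundle.descriptors
    assert back.topology == bundle.topology
    np.testing.assert_allclose(back.predict_probability(X),
                               bundle.predict_probability(X))


def test_predict_table_threshold():
    X, cases = make_training_data()
    bundle = pm.train(X, cases, list("abcd"), SMALL_CONFIG)
    preds = pm.predict_table(bundle, X, cases)
    assert ((preds["PredIA"] == 1) == (preds["ProbAct"] > 50.0)).all()
    assert preds["ProbAct"].between(0, 100).all()


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def conditions_frame(protein, calls=None, probs=None):
    n = len(calls) if calls is not None else len(probs)
    df = pd.DataFrame({"tp": [protein] * n, "ai": [f"a{i}" for i in range(n)]})
    if calls is not None:
        df["PredIA"] = calls
    if probs is not None:
        df["ProbAct"] = probs
    return df


def test_consensus_three_of_four_class_calls():
    preds = conditions_frame("NET", calls=[1, 1, 1, -1])
    assert pm.consensus_call(preds, pm.CLASS_RULE_PRESET) == {"NET": 1}


def test_consensus_sert_all_inactive():
    preds = conditions_frame("SERT", calls=[-1, -1])
    assert pm.consensus_call(preds, pm.CLASS_RULE_PRESET) == {"SERT": -1}


def test_consensus_probability_rule_two_of_four():
    preds = conditions_frame("NET", probs=[66.32, 45.16, 81.34, 30.67])
    assert pm.consensus_call(preds, pm.PROBABILITY_RULE_PRESET) == {"NET": 1}


def test_consensus_missing_condition_raises():
    preds = conditions_frame("NET", calls=[1, 1, 1])
    with pytest.raises(ValueError, match="expected 4"):
        pm.consensus_call(preds, pm.CLASS_RULE_PRESET,
                          expected_conditions={"NET": 4})


def test_consensus_threshold_extremes_are_and_or():
    for calls in ([1, 1, 1, 1], [1, -1, -1, -1], [-1, -1, -1, -1]):
        preds = conditions_frame("NET", calls=calls)
        all_rule = pm.ConsensusRule(thresholds={"NET": 4})
        any_rule = pm.ConsensusRule(thresholds={"NET": 1})
        expect_and = 1 if all(c == 1 for c in calls) else -1
        expect_or = 1 if any(c == 1 for c in calls) else -1
        assert pm.consensus_call(preds, all_rule) == {"NET": expect_and}
        assert pm.consensus_call(preds, any_rule) == {"NET": expect_or}
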