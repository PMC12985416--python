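"""Nested cross-validation, final fitting, Shapley attributions and ablation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from structvep import modelcore
from structvep.modelcore import (
    GRADIENT_BOOSTING,
    RANDOM_FOREST,
    SMALL_SPACES,
    ModelBundle,
    ablation_compare,
    fit_final,
    nested_cv,
    predict_proba,
    shap_importance,
    shap_values,
)
from structvep.tpe import Categorical, Int, TPEOptimizer, Uniform
from structvep.treeshap import (
    _from_sklearn_tree,
    brute_force_shap,
    forest_shap_values,
    tree_shap_single,
)

TINY_SPACE = {
    "n_estimators": Int(30, 60),
    "max_depth": Int(3, 8),
}


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(5)
    n = 200
    X = rng.normal(size=(n, 6))
    logit = 2.0 * X[:, 0] - 1.5 * X[:, 2] + rng.normal(0, 0.8, n)
    y = (logit > 0).astype(int)
    return X, y


def test_nested_cv_structure_and_determinism(toy_data):
    X, y = toy_data
    r1 = nested_cv(X, y, RANDOM_FOREST, outer_k=5, inner_k=2, n_trials=2, seed=3,
                   space=TINY_SPACE)
    r2 = nested_cv(X, y, RANDOM_FOREST, outer_k=5, inner_k=2, n_trials=2, seed=3,
                   space=TINY_SPACE)
    assert len(r1.fold_metrics) == 5
    assert [m.auroc for m in r1.fold_metrics] == [m.auroc for m in r2.fold_metrics]
    assert r1.best_params == r2.best_params


def test_outer_test_folds_partition_the_data(toy_data):
    X, y = toy_data
    report = nested_cv(X, y, RANDOM_FOREST, outer_k=5, inner_k=2, n_trials=1,
                       seed=0, space=TINY_SPACE)
    seen = np.concatenate(report.outer_test_indices)
    assert len(seen) == len(y)
    assert len(np.unique(seen)) == len(y)  # no index in two outer test folds


def test_nested_cv_input_validation(toy_data):
    X, y = toy_data
    with pytest.raises(ValueError):
        nested_cv(X, y, RANDOM_FOREST, n_trials=0, space=TINY_SPACE)
    with pytest.raises(ValueError):
        nested_cv(X[:8], np.r_[np.ones(6), np.zeros(2)].astype(int), RANDOM_FOREST,
                  outer_k=5, space=TINY_SPACE)


def test_final_fit_resubstitution_and_roundtrip(toy_data, tmp_path):
    from sklearn.metrics import roc_auc_score

    X, y = toy_data
    report = nested_cv(X, y, RANDOM_FOREST, outer_k=3, inner_k=2, n_trials=2,
                       seed=1, space=TINY_SPACE)
    bundle = fit_final(X, y, RANDOM_FOREST, report.best_params[0], seed=1)
    resub = roc_auc_score(y, predict_proba(bundle, X))
    assert resub >= report.mean["auroc"] - 0.02  # training optimism
    bundle.save(tmp_path / "m")
    loaded = ModelBundle.load(tmp_path / "m")
    assert np.array_equal(predict_proba(loaded, X), predict_proba(bundle, X))
    assert loaded.training_manifest["n_train"] == len(y)


def test_schema_mismatch_rejected(toy_data):
    X, y = toy_data
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
    bundle = fit_final(frame, y, RANDOM_FOREST, {"n_estimators": 20}, seed=0)
    with pytest.raises(ValueError, match="schema"):
        predict_proba(bundle, frame.iloc[:, :4])
    with pytest.raises(ValueError, match="schema"):
        predict_proba(bundle, X[:, :4])


def test_predictions_are_probabilities(toy_data):
    X, y = toy_data
    bundle = fit_final(X, y, GRADIENT_BOOSTING, {"n_estimators": 30}, seed=0)
    p = predict_proba(bundle, X)
    assert np.all((p >= 0) & (p <= 1))
    doubled = predict_proba(bundle, np.vstack([X[:1], X[:1]]))
    assert doubled[0] == doubled[1]  # pointwise function


def test_planted_signal_scores_separate(small_features):
    X, y, _ = small_features
    bundle = fit_final(X, y, RANDOM_FOREST, {"n_estimators": 100}, seed=0)
    p = predict_proba(bundle, X)
    assert p[y == 1].mean() > p[y == 0].mean()


# --- Shapley attributions --------------------------------------------------


def test_tree_shap_matches_brute_force(toy_data):
    """The path recursion agrees with explicit subset enumeration on small trees."""
    X, y = toy_data
    rf = RandomForestClassifier(n_estimators=4, max_depth=3, random_state=0).fit(X, y)
    for est in rf.estimators_:
        arrays = _from_sklearn_tree(est)
        for i in range(6):
            fast = tree_shap_single(arrays, X[i], 6)
            slow = brute_force_shap(arrays, X[i], 6)
            assert np.allclose(fast, slow, atol=1e-10)


@pytest.mark.parametrize("algorithm", [RANDOM_FOREST, GRADIENT_BOOSTING])
def test_local_accuracy_identity(toy_data, algorithm):
    """Base value plus attributions reproduces the model output per row."""
    X, y = toy_data
    bundle = fit_final(X, y, algorithm, {"n_estimators": 25}, seed=2)
    phi, base, output = shap_values(bundle, X[:50])
    assert np.allclose(base + phi.sum(axis=1), output, atol=1e-6)


def test_constant_feature_gets_null_attribution(toy_data):
    X, y = toy_data
    X = X.copy()
    X[:, 5] = 3.14  # zero variance
    bundle = fit_final(X, y, RANDOM_FOREST, {"n_estimators": 40}, seed=0)
    ranking = shap_importance(bundle, X[:60])
    row = ranking.set_index("feature").loc["f5"]
    assert row["mean_abs_shap"] == pytest.approx(0.0, abs=1e-12)


def test_single_informative_feature_ranked_first():
    rng = np.random.default_rng(9)
    n = 400
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["plddt", "sasa", "rasa", "blosum62"])
    y = (X["rasa"] + rng.normal(0, 0.3, n) > 0).astype(int)
    bundle = fit_final(X, y, RANDOM_FOREST, {"n_estimators": 60}, seed=0)
    ranking = shap_importance(bundle, X.iloc[:100])
    assert ranking.iloc[0]["feature"] == "rasa"


# --- ablation --------------------------------------------------------------


def test_identity_ablation_is_zero(small_features):
    X, y, _ = small_features
    res = ablation_compare(X, X, y, hyperparameters={"n_estimators": 60}, seed=0)
    assert res["delta"] == pytest.approx(0.0, abs=1e-12)


def test_ablation_requires_nested_columns(small_features):
    X, y, _ = small_features
    other = X.rename(columns={"rasa": "not_a_feature"})
    with pytest.raises(ValueError):
        ablation_compare(X, other, y)


# --- TPE -------------------------------------------------------------------


def test_tpe_deterministic_and_converges():
    def run(seed):
        opt = TPEOptimizer(
            {"x": Uniform(-2, 2), "k": Int(1, 20), "c": Categorical(["lo", "hi"])},
            seed=seed, n_startup=6,
        )
        for _ in range(40):
            p = opt.suggest()
            value = -(p["x"] - 0.7) ** 2 - 0.01 * abs(p["k"] - 5) + (
                0.2 if p["c"] == "hi" else 0.0
            )
            opt.observe(p, value)
        return opt.best

    (p1, v1), (p2, v2) = run(4), run(4)
    assert p1 == p2 and v1 == v2
    assert abs(p1["x"] - 0.7) < 0.5  # concentrates near the optimum
    # and beats the pure start-up (random) phase
    opt = TPEOptimizer({"x": Uniform(-2, 2)}, seed=4, n_startup=40)
    best_random = max(
        -(opt.suggest()["x"] - 0.7) ** 2 for _ in range(12)
    )
    assert v1 >= best_random - 0.2


def test_tpe_respects_bounds():
    opt = TPEOptimizer({"n": Int(2, 7), "lr": Uniform(0.1, 0.4)}, seed=0, n_startup=3)
    for _ in range(25):
        p = opt.suggest()
        assert 2 <= p["n"] <= 7
        assert 0.1 <= p["lr"] <= 0.4
        opt.observe(p, p["lr"])
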