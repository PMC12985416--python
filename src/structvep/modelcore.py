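"""Tree-ensemble training with nested cross-validation and SMBO tuning.

Two algorithms are supported: a random forest (scikit-learn) and extreme
gradient boosting (xgboost).  Performance estimation uses nested
cross-validation -- a stratified outer loop scoring held-out folds, wrapping
an inner stratified loop whose mean AUROC is the objective of a seeded
tree-structured Parzen estimator search.  Hyperparameter search never touches
outer-test rows; the winning configuration is refit on the outer-training
fold before scoring.  After model selection the estimator is refit on the
full training set into a serializable bundle that locks the feature schema.

Interpretability uses exact tree-Shapley attributions: the package's own
path-dependent TreeSHAP for forests and xgboost's native contribution
predictions (margin space) for boosted trees.  Global importance ranks
features by mean absolute attribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evalbench import MetricsReport, compute_metrics
from .tpe import Categorical, Int, LogUniform, ParamSpec, TPEOptimizer, Uniform
from .treeshap import forest_shap_values

logger = logging.getLogger(__name__)

RANDOM_FOREST = "RANDOM_FOREST"
GRADIENT_BOOSTING = "GRADIENT_BOOSTING"

# max_depth upper sentinel 31 maps to None (unrestricted depth)
_RF_DEPTH_NONE = 31

DEFAULT_SPACES: dict[str, dict[str, ParamSpec]] = {
    RANDOM_FOREST: {
        "n_estimators": Int(100, 1000),
        "max_depth": Int(3, _RF_DEPTH_NONE),
        "min_samples_leaf": Int(1, 10),
        "max_features": Categorical(["sqrt", "log2", 0.3, 0.5, 0.7, 1.0]),
    },
    GRADIENT_BOOSTING: {
        "n_estimators": Int(100, 1000),
        "learning_rate": LogUniform(1e-3, 0.3),
        "max_depth": Int(2, 10),
        "subsample": Uniform(0.5, 1.0),
        "colsample_bytree": Uniform(0.5, 1.0),
    },
}

# compact spaces for desk-scale runs (tests, examples, smoke pipelines)
SMALL_SPACES: dict[str, dict[str, ParamSpec]] = {
    RANDOM_FOREST: {
        "n_estimators": Int(50, 200),
        "max_depth": Int(3, 15),
        "min_samples_leaf": Int(1, 5),
        "max_features": Categorical(["sqrt", 0.5]),
    },
    GRADIENT_BOOSTING: {
        "n_estimators": Int(50, 200),
        "learning_rate": LogUniform(0.01, 0.3),
        "max_depth": Int(2, 6),
        "subsample": Uniform(0.6, 1.0),
        "colsample_bytree": Uniform(0.6, 1.0),
    },
}


def make_estimator(algorithm: str, params: dict, seed: int):
    params = dict(params)
    if algorithm == RANDOM_FOREST:
        if params.get("max_depth") == _RF_DEPTH_NONE:
            params["max_depth"] = None
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == GRADIENT_BOOSTING:
        return xgb.XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            **params,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class ModelBundle:
    algorithm: str
    estimator: object
    feature_names: list[str]
    hyperparameters: dict
    decision_threshold: float = 0.5
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must be in (0, 1)")

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, directory / "model.joblib")
        manifest = {
            "format_version": 1,
            "algorithm": self.algorithm,
            "feature_names": self.feature_names,
            "hyperparameters": self.hyperparameters,
            "decision_threshold": self.decision_threshold,
            "training_manifest": self.training_manifest,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        return cls(
            algorithm=manifest["algorithm"],
            estimator=joblib.load(directory / "model.joblib"),
            feature_names=manifest["feature_names"],
            hyperparameters=manifest["hyperparameters"],
            decision_threshold=manifest["decision_threshold"],
            training_manifest=manifest["training_manifest"],
        )


def _as_matrix(X, feature_names: list[str]) -> np.ndarray:
    """Validate a feature matrix against a bundle's schema."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in feature_names if c not in X.columns]
        extra = [c for c in X.columns if c not in feature_names]
        if missing or extra:
            raise ValueError(
                f"feature-schema mismatch: missing={missing} unexpected={extra}"
            )
        return X[feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"feature-schema mismatch: expected {len(feature_names)} columns, "
            f"got {X.shape[1]}"
        )
    return X


def predict_proba(bundle: ModelBundle, X) -> np.ndarray:
    """Pathogenicity score in [0, 1] per row (positive-class probability)."""
    mat = _as_matrix(X, bundle.feature_names)
    return bundle.estimator.predict_proba(mat)[:, 1]


def predict_calls(bundle: ModelBundle, X) -> np.ndarray:
    return (predict_proba(bundle, X) > bundle.decision_threshold).astype(int)


@dataclass
class NestedCvReport:
    algorithm: str
    fold_metrics: list[MetricsReport]
    best_params: list[dict]
    outer_test_indices: list[np.ndarray]
    n_trials: int
    seed: int

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([getattr(f, m) for f in self.fold_metrics]))
            for m in ("auroc", "f1", "precision", "recall", "mcc", "accuracy")
        }

    @property
    def sd(self) -> dict[str, float]:
        return {
            m: float(np.std([getattr(f, m) for f in self.fold_metrics], ddof=1))
            for m in ("auroc", "f1", "precision", "recall", "mcc", "accuracy")
        }

    def summary(self) -> pd.DataFrame:
        mean, sd = self.mean, self.sd
        return pd.DataFrame({"mean": mean, "sd": {k: sd[k] for k in mean}})


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 7919 + fold * 104729 + 1) % (2**31 - 1)


def _inner_objective(X, y, algorithm, params, inner_k, seed):
    from sklearn.metrics import roc_auc_score

    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = make_estimator(algorithm, params, seed)
        est.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], est.predict_proba(X[te])[:, 1]))
    return float(np.mean(aucs))


def nested_cv(
    X,
    y,
    algorithm: str = RANDOM_FOREST,
    outer_k: int = 5,
    inner_k: int = 3,
    n_trials: int = 150,
    seed: int = 0,
    space: dict[str, ParamSpec] | None = None,
) -> NestedCvReport:
    """Nested cross-validation: outer loop for performance estimation, inner
    loop exclusively for hyperparameter selection (TPE, mean inner AUROC as
    the objective).  Fully reproducible for a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < outer_k:
        raise ValueError(
            f"need at least outer_k={outer_k} members per class, got {counts}"
        )
    space = space if space is not None else DEFAULT_SPACES[algorithm]
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    fold_metrics, best_params, test_indices = [], [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        fseed = _fold_seed(seed, fold)
        opt = TPEOptimizer(space, seed=fseed)
        for _ in range(n_trials):
            params = opt.suggest()
            value = _inner_objective(X[tr], y[tr], algorithm, params, inner_k, fseed)
            opt.observe(params, value)
        params, inner_auc = opt.best
        est = make_estimator(algorithm, params, fseed)
        est.fit(X[tr], y[tr])
        scores = est.predict_proba(X[te])[:, 1]
        fold_metrics.append(compute_metrics(y[te], scores))
        best_params.append(params)
        test_indices.append(te.copy())
        logger.info(
            "outer fold %d: inner AUROC %.3f, outer AUROC %.3f",
            fold, inner_auc, fold_metrics[-1].auroc,
        )
    return NestedCvReport(algorithm, fold_metrics, best_params, test_indices, n_trials, seed)


def fit_final(
    X,
    y,
    algorithm: str,
    hyperparameters: dict,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ModelBundle:
    """Refit on the full training set with fixed hyperparameters."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    est = make_estimator(algorithm, hyperparameters, seed)
    est.fit(X, y)
    counts = np.bincount(y, minlength=2)
    return ModelBundle(
        algorithm=algorithm,
        estimator=est,
        feature_names=feature_names,
        hyperparameters=dict(hyperparameters),
        training_manifest={
            "n_train": int(len(y)),
            "class_counts": {"benign": int(counts[0]), "pathogenic": int(counts[1])},
            "seed": int(seed),
        },
    )


def shap_values(bundle: ModelBundle, X) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact per-feature Shapley attributions.

    Returns ``(phi, base_value, model_output)`` where
    ``base_value + phi.sum(axis=1) == model_output`` row-wise (probability
    space for the forest, margin/log-odds space for gradient boosting).
    The reference distribution is the path-dependent training cover; no
    explicit background matrix is needed.
    """
    mat = _as_matrix(X, bundle.feature_names)
    if bundle.algorithm == RANDOM_FOREST:
        phi, base = forest_shap_values(bundle.estimator, mat)
        output = bundle.estimator.predict_proba(mat)[:, 1]
        return phi, base, output
    if bundle.algorithm == GRADIENT_BOOSTING:
        booster = bundle.estimator.get_booster()
        contribs = booster.predict(xgb.DMatrix(mat), pred_contribs=True)
        phi, base = contribs[:, :-1], float(contribs[0, -1])
        output = bundle.estimator.predict(mat, output_margin=True)
        return phi, base, np.asarray(output, dtype=float)
    raise TypeError(f"unsupported model for tree-Shapley: {bundle.algorithm}")


def shap_importance(bundle: ModelBundle, X_explain, background=None) -> pd.DataFrame:
    """Global feature ranking by mean |Shapley attribution|.

    ``background`` is accepted for API symmetry but unused: path-dependent
    tree-Shapley conditions on the training cover stored in the trees.
    """
    phi, _, _ = shap_values(bundle, X_explain)
    frame = pd.DataFrame(
        {
            "feature": bundle.feature_names,
            "mean_abs_shap": np.abs(phi).mean(axis=0),
            "mean_shap": phi.mean(axis=0),
        }
    ).sort_values("mean_abs_shap", ascending=False, ignore_index=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def ablation_compare(
    X_full: pd.DataFrame,
    X_reduced: pd.DataFrame,
    y,
    algorithm: str = RANDOM_FOREST,
    hyperparameters: dict | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Same-fold CV comparison of the full and reduced feature schemas.

    Both matrices are scored with the identical stratified fold assignment and
    fixed hyperparameters, so the AUROC delta is attributable to the feature
    set alone.  Requires the reduced columns to be a subset of the full ones.
    """
    if not set(X_reduced.columns).issubset(set(X_full.columns)):
        raise ValueError("reduced feature columns must be a subset of the full schema")
    if len(X_full) != len(X_reduced):
        raise ValueError("fold mismatch: matrices must cover the same rows")
    y = np.asarray(y, dtype=int)
    params = hyperparameters or {"n_estimators": 300}
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X_full, y))

    def cv_auc(X: pd.DataFrame) -> float:
        from sklearn.metrics import roc_auc_score

        mat = X.to_numpy(dtype=float)
        aucs = []
        for tr, te in folds:
            est = make_estimator(algorithm, params, seed)
            est.fit(mat[tr], y[tr])
            aucs.append(roc_auc_score(y[te], est.predict_proba(mat[te])[:, 1]))
        return float(np.mean(aucs))

    auc_full = cv_auc(X_full)
    auc_reduced = cv_auc(X_reduced)
    return {
        "auc_full": auc_full,
        "auc_reduced": auc_reduced,
        "delta": auc_full - auc_reduced,
    }
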