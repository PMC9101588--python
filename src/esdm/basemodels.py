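"""The nine base model families behind a uniform fit/predict contract.

Every family consumes a numeric design matrix (continuous covariates plus
one-hot encoded categorical columns, built upstream in ``sampling``) and
returns probability-of-presence in [0, 1].  Standard statistical-learning
estimators (scikit-learn) stand behind the contract; the family-specific
feature constructions (quadratic and hinge bases, the mixture-discriminant
posterior) are defined here.

Families
--------
GLM     logistic regression with linear + quadratic terms for continuous
        covariates, effectively unpenalized
SVM     RBF support-vector classifier with Platt-scaled probabilities
RF      random forest (class-frequency votes)
BRT     gradient-boosted trees, learning rate 0.01, early stop on held-out
        deviance
MARS    piecewise-linear hinge basis expansion with a logistic link
MAXENT  L1-regularized logistic regression on linear + quadratic + hinge
        features of presences vs. background (the pseudo-absences)
CART    depth-limited classification tree returning leaf class frequencies
FDA     discriminant analysis on a flexible (quadratic) basis
MDA     mixture discriminant analysis: per-class Gaussian mixtures with
        Bayes-rule posterior probabilities
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Any

import lightgbm as lgb
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FittedModel",
    "FitError",
    "registry_default",
    "fit_model",
    "predict_model",
]

FAMILIES = ("GLM", "SVM", "RF", "BRT", "MARS", "MAXENT", "CART", "FDA", "MDA")

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "GLM": {"C": 1e6, "max_iter": 2000},
    "SVM": {"C": 1.0, "gamma": "scale", "calibration_folds": 3},
    "RF": {"n_estimators": 100, "min_samples_leaf": 1},
    "BRT": {
        "n_estimators": 500,
        "learning_rate": 0.01,
        "max_depth": 3,
        "min_child_samples": 5,
        "validation_fraction": 0.2,
        "n_iter_no_change": 10,
    },
    "MARS": {"n_knots": 3, "C": 1.0, "max_iter": 2000},
    "MAXENT": {"n_knots": 3, "C": 1.0},
    "CART": {"max_depth": 5, "min_samples_leaf": 2},
    "FDA": {},
    "MDA": {"n_components": 2, "reg_covar": 1e-2},
}

_DEFAULT_MIN_N = {family: 10 for family in FAMILIES}
_DEFAULT_MIN_N["BRT"] = 20  # boosted trees need enough rows for a validation split


class FitError(RuntimeError):
    """A base model could not be fitted; the caller drops it from the ensemble."""

    def __init__(self, family: str, cause: str):
        super().__init__(f"{family}: {cause}")
        self.family = family
        self.cause = cause


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    min_n: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        merged = copy.deepcopy(_DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged
        if self.min_n <= 0:
            self.min_n = _DEFAULT_MIN_N[self.family]


@dataclass
class FittedModel:
    spec: ModelSpec
    predictor: Any
    feature_names: list[str]
    fit_diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def family(self) -> str:
        return self.spec.family


def registry_default(
    families: list[str] | None = None,
    overrides: dict[str, dict[str, Any]] | None = None,
) -> list[ModelSpec]:
    """The default model registry: all nine families, optionally subset/re-tuned."""
    names = list(families) if families is not None else list(FAMILIES)
    unknown = [f for f in names if f not in FAMILIES]
    if unknown:
        raise ValueError(f"unknown families {unknown}; valid: {FAMILIES}")
    if len(set(names)) != len(names):
        raise ValueError("duplicate family in configuration")
    overrides = overrides or {}
    bad = [f for f in overrides if f not in FAMILIES]
    if bad:
        raise ValueError(f"hyperparameter overrides for unknown families {bad}")
    return [ModelSpec(family=f, hyperparameters=overrides.get(f, {})) for f in names]


# ---------------------------------------------------------------------------
# feature constructions
# ---------------------------------------------------------------------------

class _BasisExpansion(TransformerMixin, BaseEstimator):
    """Append quadratic and/or two-sided hinge features of continuous columns.

    Hinge knots are placed at training-set quantiles, the classic reflected
    pair max(0, x - k), max(0, k - x) per knot.
    """

    def __init__(self, continuous_mask, quadratic=False, n_knots=0):
        self.continuous_mask = continuous_mask
        self.quadratic = quadratic
        self.n_knots = n_knots

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.cont_idx_ = np.flatnonzero(np.asarray(self.continuous_mask, bool))
        self.knots_ = {}
        if self.n_knots:
            qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
            for j in self.cont_idx_:
                self.knots_[int(j)] = np.quantile(X[:, j], qs)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        parts = [X]
        if self.quadratic:
            parts.append(X[:, self.cont_idx_] ** 2)
        for j, knots in self.knots_.items():
            col = X[:, j][:, None]
            parts.append(np.maximum(0.0, col - knots[None, :]))
            parts.append(np.maximum(0.0, knots[None, :] - col))
        return np.hstack(parts)


class _BoostedTrees(ClassifierMixin, BaseEstimator):
    """Gradient-boosted trees with early stopping on held-out deviance.

    A stratified validation fraction is split off the training data and
    boosting stops once its binomial deviance has not improved for
    ``n_iter_no_change`` rounds.
    """

    def __init__(self, n_estimators=500, learning_rate=0.01, max_depth=3,
                 min_child_samples=5, validation_fraction=0.2,
                 n_iter_no_change=10, random_state=0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_child_samples = min_child_samples
        self.validation_fraction = validation_fraction
        self.n_iter_no_change = n_iter_no_change
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.random_state)
        val_idx = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            k = max(1, int(round(self.validation_fraction * len(idx))))
            val_idx.append(rng.permutation(idx)[:k])
        val_idx = np.concatenate(val_idx)
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        booster = lgb.LGBMClassifier(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            num_leaves=2**self.max_depth,
            min_child_samples=self.min_child_samples,
            random_state=self.random_state,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
        booster.fit(
            X[train_mask], y[train_mask],
            eval_set=[(X[val_idx], y[val_idx])],
            eval_metric="binary_logloss",
            callbacks=[lgb.early_stopping(self.n_iter_no_change, verbose=False)],
        )
        self.booster_ = booster
        self.classes_ = booster.classes_
        return self

    def predict_proba(self, X):
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names on ndarray input
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            return self.booster_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _MixtureDiscriminant(ClassifierMixin, BaseEstimator):
    """Per-class Gaussian mixtures with Bayes-rule posterior probabilities."""

    def __init__(self, n_components=2, reg_covar=1e-2, random_state=None):
        self.n_components = n_components
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.mixtures_ = []
        self.log_priors_ = []
        for cls in self.classes_:
            rows = X[y == cls]
            # cap components so each has a few rows to estimate from
            k = max(1, min(self.n_components, len(rows) // 5))
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=self.reg_covar,
                random_state=self.random_state,
                n_init=1,
            ).fit(rows)
            self.mixtures_.append(gm)
            self.log_priors_.append(np.log(len(rows) / len(X)))
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        log_joint = np.column_stack(
            [gm.score_samples(X) + lp for gm, lp in zip(self.mixtures_, self.log_priors_)]
        )
        log_joint -= log_joint.max(axis=1, keepdims=True)
        joint = np.exp(log_joint)
        return joint / joint.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _build_estimator(spec: ModelSpec, continuous_mask: np.ndarray, seed: int):
    hp = spec.hyperparameters
    fam = spec.family
    if fam == "GLM":
        return Pipeline([
            ("basis", _BasisExpansion(continuous_mask, quadratic=True)),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=hp["C"], max_iter=hp["max_iter"])),
        ])
    if fam == "SVM":
        svc = SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], random_state=seed)
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(
                svc, method="sigmoid", cv=hp["calibration_folds"], ensemble=False)),
        ])
    if fam == "RF":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
        )
    if fam == "BRT":
        return _BoostedTrees(
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            max_depth=hp["max_depth"],
            min_child_samples=hp["min_child_samples"],
            validation_fraction=hp["validation_fraction"],
            n_iter_no_change=hp["n_iter_no_change"],
            random_state=seed,
        )
    if fam == "MARS":
        return Pipeline([
            ("basis", _BasisExpansion(continuous_mask, n_knots=hp["n_knots"])),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=hp["C"], max_iter=hp["max_iter"])),
        ])
    if fam == "MAXENT":
        return Pipeline([
            ("basis", _BasisExpansion(
                continuous_mask, quadratic=True, n_knots=hp["n_knots"])),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(
                solver="liblinear", l1_ratio=1.0, C=hp["C"], random_state=seed)),
        ])
    if fam == "CART":
        return DecisionTreeClassifier(
            max_depth=hp["max_depth"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
        )
    if fam == "FDA":
        return Pipeline([
            ("basis", _BasisExpansion(continuous_mask, quadratic=True)),
            ("scale", StandardScaler()),
            ("clf", LinearDiscriminantAnalysis()),
        ])
    if fam == "MDA":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", _MixtureDiscriminant(
                n_components=hp["n_components"],
                reg_covar=hp["reg_covar"],
                random_state=seed,
            )),
        ])
    raise ValueError(f"unknown family {fam!r}")  # pragma: no cover


def fit_model(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
    continuous_mask: np.ndarray | None = None,
) -> FittedModel:
    """Fit one family on a numeric design matrix; probability output guaranteed.

    Raises :class:`FitError` when the sample is below the family's minimum
    usable size, a class is missing, or the underlying estimator fails.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(X) < spec.min_n:
        raise FitError(spec.family, f"n={len(X)} below family minimum min_n={spec.min_n}")
    if len(np.unique(y)) < 2:
        raise FitError(spec.family, "only one class present")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if continuous_mask is None:
        continuous_mask = np.ones(X.shape[1], dtype=bool)
    estimator = _build_estimator(spec, np.asarray(continuous_mask, bool), seed)
    try:
        estimator.fit(X, y)
    except Exception as exc:  # noqa: BLE001 - converted to a structured error
        raise FitError(spec.family, f"fit failed: {exc}") from exc
    classes = list(getattr(estimator, "classes_", [0, 1]))
    diagnostics = {"n": len(X), "n_presence": int(y.sum()), "seed": seed}
    return FittedModel(
        spec=spec,
        predictor=(estimator, classes.index(1)),
        feature_names=list(feature_names),
        fit_diagnostics=diagnostics,
    )


def predict_model(model: FittedModel, X: np.ndarray,
                  feature_names: list[str] | None = None) -> np.ndarray:
    """Probability of presence for each row of ``X``.

    If ``feature_names`` is given it must match the names fixed at fit time.
    """
    if feature_names is not None and list(feature_names) != model.feature_names:
        missing = [n for n in model.feature_names if n not in feature_names]
        extra = [n for n in feature_names if n not in model.feature_names]
        raise ValueError(
            f"feature mismatch for {model.family}: missing {missing}, extra {extra}"
        )
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {len(model.feature_names)}"
        )
    estimator, pos_col = model.predictor
    prob = estimator.predict_proba(X)[:, pos_col]
    return np.clip(prob, 0.0, 1.0)
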