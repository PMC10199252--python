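"""Uniform contract over the classifier families.

Four families share one fit/predict surface:

``logistic_regression``
    Unpenalized logistic regression with an automatic light ridge (1e-6)
    fallback when the classes are perfectly separable.
``random_forest``
    500 trees, sqrt(p) candidate variables per split.  Its importance score
    is the classic out-of-bag permutation importance: the mean decrease in a
    tree's accuracy on its own out-of-bag rows when one variable is permuted.
``elastic_net``
    Logistic elastic net (mixing 0.5) with the regularization strength chosen
    by inner 5-fold cross-validation on standardized predictors; importance
    is the absolute standardized coefficient.
``bayesian_regression_tree``
    A sum-of-trees classifier.  The environment provides no posterior-sampling
    tree ensemble, so this slot is backed by gradient boosting with shallow
    trees; its importance is the proportion of trees that split on a variable
    (the ensemble analogue of a variable-inclusion proportion).  The backend
    is recorded in the fitted model's metadata.

Balanced accuracy — the mean of sensitivity and specificity, 0.5 being
chance for any class mix — is the performance metric throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import balanced_accuracy_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._seeding import child_rng, child_seed
from .errors import (
    ContractError,
    DegenerateInputError,
    InsufficientDataError,
    UndefinedMetricError,
    UnsupportedOperationError,
)

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "FittedModel",
    "fit",
    "predict",
    "importance",
    "balanced_accuracy",
]

FAMILIES = (
    "logistic_regression",
    "random_forest",
    "bayesian_regression_tree",
    "elastic_net",
)

#: Per-family hyperparameter schema with packaged defaults.
_DEFAULTS: dict[str, dict[str, float | int | str]] = {
    "logistic_regression": {"max_iter": 1000, "fallback_ridge": 1e-6},
    "random_forest": {"n_estimators": 500, "max_features": "sqrt"},
    "bayesian_regression_tree": {"n_estimators": 50, "max_depth": 2, "learning_rate": 0.1},
    "elastic_net": {"l1_ratio": 0.5, "n_cs": 8, "inner_cv": 5, "max_iter": 3000},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus whether the variable filter precedes it."""

    family: str
    filtered: bool = False
    hyperparameters: Mapping[str, float | int | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ContractError(f"unknown classifier family {self.family!r}")
        schema = _DEFAULTS[self.family]
        unknown = [k for k in self.hyperparameters if k not in schema]
        if unknown:
            raise ContractError(
                f"unknown hyperparameters for {self.family}: {unknown}"
            )

    def hyper(self, name: str):
        return self.hyperparameters.get(name, _DEFAULTS[self.family][name])

    @property
    def label(self) -> str:
        return f"{self.family}[{'filtered' if self.filtered else 'unfiltered'}]"


@dataclass
class FittedModel:
    """Opaque fitted state plus the contract metadata predict() enforces."""

    spec: ClassifierSpec
    variables: tuple[str, ...]
    estimator: object
    classes: tuple
    seed: int
    meta: dict = field(default_factory=dict)
    _train_X: np.ndarray | None = None
    _train_y: np.ndarray | None = None

    @property
    def positive_class(self):
        return self.classes[1]


def _as_matrix(X, variables: Sequence[str] | None = None):
    """Return (matrix, variable names); align DataFrame columns if given."""
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        if variables is not None:
            missing = [v for v in variables if v not in cols]
            extra = [c for c in cols if c not in variables]
            if missing:
                raise ContractError(f"missing variables at predict time: {missing}")
            if extra:
                raise ContractError(f"unknown variables at predict time: {extra}")
            X = X[list(variables)]
            cols = list(variables)
        return np.asarray(X, dtype=float), cols
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        arr = arr.reshape(len(arr), -1)
    if variables is not None:
        if arr.shape[1] != len(variables):
            raise ContractError(
                f"expected {len(variables)} variables, got {arr.shape[1]}"
            )
        return arr, list(variables)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _build_estimator(spec: ClassifierSpec, seed: int):
    if spec.family == "logistic_regression":
        return LogisticRegression(C=np.inf, max_iter=int(spec.hyper("max_iter")))
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(spec.hyper("n_estimators")),
            max_features=spec.hyper("max_features"),
            random_state=seed,
        )
    if spec.family == "bayesian_regression_tree":
        return GradientBoostingClassifier(
            n_estimators=int(spec.hyper("n_estimators")),
            max_depth=int(spec.hyper("max_depth")),
            learning_rate=float(spec.hyper("learning_rate")),
            random_state=seed,
        )
    # elastic_net: standardize, then CV over the regularization path
    n_cs = int(spec.hyper("n_cs"))
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "enet",
                LogisticRegressionCV(
                    Cs=np.logspace(-3, 2, n_cs),
                    l1_ratios=[float(spec.hyper("l1_ratio"))],
                    solver="saga",
                    cv=int(spec.hyper("inner_cv")),
                    scoring="neg_log_loss",
                    max_iter=int(spec.hyper("max_iter")),
                    tol=1e-3,
                    random_state=seed,
                    use_legacy_attributes=False,
                ),
            ),
        ]
    )


def fit(spec: ClassifierSpec, X, y, seed: int = 0) -> FittedModel:
    """Fit one classifier; deterministic given ``seed``.

    Raises :class:`DegenerateInputError` for single-class labels and
    :class:`InsufficientDataError` when a class has fewer than 2 episodes.
    """
    mat, variables = _as_matrix(X)
    y = np.asarray(y)
    if mat.shape[0] != len(y):
        raise ContractError("X and y lengths differ")
    if np.isnan(mat).any():
        raise ContractError("X contains missing values; use complete cases")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateInputError("y contains a single class")
    if len(classes) > 2:
        raise ContractError("only binary contrasts are supported")
    if counts.min() < 2:
        raise InsufficientDataError("need at least 2 episodes per class")

    est = _build_estimator(spec, child_seed(seed, 0))
    if spec.family == "logistic_regression":
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(mat, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            # perfect separation: fall back to a light ridge
            ridge = float(spec.hyper("fallback_ridge"))
            est = LogisticRegression(C=1.0 / ridge, max_iter=int(spec.hyper("max_iter")))
            est.fit(mat, y)
            meta = {"fallback_ridge": ridge}
        else:
            meta = {}
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(mat, y)
        meta = {}
    if spec.family == "bayesian_regression_tree":
        meta["backend"] = "gradient_boosting"

    return FittedModel(
        spec=spec,
        variables=tuple(variables),
        estimator=est,
        classes=tuple(classes),
        seed=seed,
        meta=meta,
        _train_X=mat,
        _train_y=y,
    )


def predict(model: FittedModel, X) -> np.ndarray:
    """Predict binary labels; X must carry exactly the training variables."""
    if isinstance(X, pd.DataFrame) or (np.asarray(X).size > 0):
        mat, _ = _as_matrix(X, model.variables)
    else:
        mat = np.empty((0, len(model.variables)))
    if mat.shape[0] == 0:
        return np.array([], dtype=np.asarray(model.classes).dtype)
    return model.estimator.predict(mat)


def _oob_masks(forest: RandomForestClassifier, n: int) -> np.ndarray:
    """Boolean (tree x sample) matrix of out-of-bag membership.

    Bootstrap indices are re-derived from each tree's stored seed with the
    same draw the forest used at fit time (verified against the forest's own
    ``oob_decision_function_`` in the test suite).
    """
    masks = np.ones((len(forest.estimators_), n), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        idx = np.random.RandomState(tree.random_state).randint(0, n, n)
        masks[t, idx] = False
    return masks


def _rf_oob_permutation_importance(model: FittedModel) -> np.ndarray:
    forest: RandomForestClassifier = model.estimator
    X, y = model._train_X, model._train_y
    n, p = X.shape
    masks = _oob_masks(forest, n)
    rng = child_rng(model.seed, 1)
    scores = np.zeros(p)
    for t, tree in enumerate(forest.estimators_):
        oob = np.flatnonzero(masks[t])
        if oob.size == 0:
            continue
        Xo = X[oob]
        base = np.mean(tree.predict(Xo) == y[oob])
        perm = rng.permutation(oob.size)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            scores[j] += base - np.mean(tree.predict(Xp) == y[oob])
    return scores / len(forest.estimators_)


def importance(model: FittedModel) -> dict[str, float]:
    """Variable -> informativeness score; higher = more informative.

    Available for the three filter algorithms only; logistic regression
    raises :class:`UnsupportedOperationError`.
    """
    family = model.spec.family
    if family == "logistic_regression":
        raise UnsupportedOperationError(
            "importance is defined for random_forest, bayesian_regression_tree "
            "and elastic_net only"
        )
    if family == "elastic_net":
        enet = model.estimator.named_steps["enet"]
        scores = np.abs(np.ravel(enet.coef_))
    elif family == "random_forest":
        scores = _rf_oob_permutation_importance(model)
    else:  # bayesian_regression_tree
        gbm: GradientBoostingClassifier = model.estimator
        counts = np.zeros(len(model.variables))
        for tree in gbm.estimators_.ravel():
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            counts[used] += 1
        scores = counts / len(gbm.estimators_)
    if not np.all(np.isfinite(scores)):
        raise UnsupportedOperationError("non-finite importance scores")
    return dict(zip(model.variables, (float(s) for s in scores)))


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2.

    Requires both classes in ``y_true``; an all-one-class *prediction* is
    fine and scores exactly 0.5.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ContractError("y_true and y_pred lengths differ")
    if len(np.unique(y_true)) < 2:
        raise UndefinedMetricError("balanced accuracy undefined for single-class truth")
    return float(balanced_accuracy_score(y_true, y_pred))
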