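"""Candidate estimator and feature-selection registries.

The default contender registry mixes linear, instance-based, tree-ensemble,
kernel and neural learners plus a dummy mean/majority baseline — the
baseline is mandatory in external validation so that models failing to beat
a constant predictor are never reported as externally valid.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.feature_selection import (
    SelectFromModel,
    SelectKBest,
    f_classif,
    f_regression,
)
from sklearn.linear_model import Lasso, LogisticRegression, RidgeCV
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

__all__ = [
    "regression_registry",
    "classification_registry",
    "selection_strategies",
    "DUMMY_NAME",
]

DUMMY_NAME = "dummy"


class _BoundedKBest(SelectKBest):
    """SelectKBest that clips k to the available column count."""

    def fit(self, X, y=None):
        if isinstance(self.k, int):
            self.k = min(self.k, X.shape[1])
        return super().fit(X, y)


def regression_registry(seed: int = 42, subset: list[str] | None = None) -> dict:
    reg = {
        DUMMY_NAME: DummyRegressor(strategy="mean"),
        "ridge": RidgeCV(alphas=np.logspace(-3, 3, 13)),
        "knn": KNeighborsRegressor(),
        "random_forest": RandomForestRegressor(n_estimators=200, random_state=seed),
        "gradient_boosting": GradientBoostingRegressor(random_state=seed),
        "xgboost": XGBRegressor(
            n_estimators=200, random_state=seed, verbosity=0, n_jobs=1
        ),
        "svm": SVR(),
        "mlp": MLPRegressor(
            hidden_layer_sizes=(64,), max_iter=1000, random_state=seed
        ),
    }
    return _subset(reg, subset)


def classification_registry(seed: int = 42, subset: list[str] | None = None) -> dict:
    reg = {
        DUMMY_NAME: DummyClassifier(strategy="most_frequent"),
        "logistic": LogisticRegression(max_iter=2000),
        "knn": KNeighborsClassifier(),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
        "xgboost": XGBClassifier(
            n_estimators=200, random_state=seed, verbosity=0, n_jobs=1,
            eval_metric="logloss",
        ),
        "svm": SVC(probability=True, random_state=seed),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=1000, random_state=seed
        ),
    }
    return _subset(reg, subset)


def _subset(reg: dict, subset: list[str] | None) -> dict:
    if subset is None:
        return reg
    unknown = [s for s in subset if s not in reg]
    if unknown:
        raise KeyError(f"unknown estimators {unknown}; known: {sorted(reg)}")
    return {name: reg[name] for name in subset}


def selection_strategies(
    task: str = "regression",
    seed: int = 42,
    k_best: int = 50,
    subset: list[str] | None = None,
) -> dict[str, Callable]:
    """Feature-selection strategy factories.

    Each value is a zero-argument factory returning a fresh selector (or
    ``None`` for the no-selection baseline) so that fitting happens
    independently inside every CV block.
    """
    score_fn = f_regression if task == "regression" else f_classif
    if task == "regression":
        embedded_tree = lambda: SelectFromModel(  # noqa: E731
            RandomForestRegressor(n_estimators=100, random_state=seed)
        )
        embedded_linear = lambda: SelectFromModel(  # noqa: E731
            Lasso(alpha=0.01, max_iter=5000, random_state=seed)
        )
    else:
        embedded_tree = lambda: SelectFromModel(  # noqa: E731
            RandomForestClassifier(n_estimators=100, random_state=seed)
        )
        embedded_linear = lambda: SelectFromModel(  # noqa: E731
            LogisticRegression(penalty="l1", solver="liblinear", C=1.0,
                               random_state=seed)
        )
    strategies = {
        "none": lambda: None,
        "filter_kbest": lambda: _BoundedKBest(score_fn, k=k_best),
        "embedded_tree": embedded_tree,
        "embedded_linear": embedded_linear,
    }
    return _subset(strategies, subset)
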