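"""Cross-conformal (CV+) calibration.

Regression: k fold models are trained on fold complements; each training
sample i keeps the absolute residual R_i from the one model that never saw
it.  For a query x the (1-alpha) interval takes order statistics of
{mu_{-fold(i)}(x) - R_i} and {mu_{-fold(i)}(x) + R_i}:

    lo = floor(alpha (n+1))-th smallest lower score,
    hi = ceil((1-alpha)(n+1))-th smallest upper score,

which carries the distribution-free marginal coverage guarantee
>= 1 - 2*alpha (and close to 1 - alpha in practice).

Classification: nonconformity is 1 - p_hat(y); a label enters the
prediction set when its CV+ p-value exceeds alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold

__all__ = [
    "ConformalRegressor",
    "ConformalClassifier",
    "cvplus_fit",
    "cvplus_fit_classifier",
    "predict_interval",
    "predict_set",
]


class SmallSampleWarning(UserWarning):
    pass


class LabelError(KeyError):
    pass


@dataclass
class ConformalRegressor:
    fold_models: list
    oof_residuals: np.ndarray  # one absolute residual per training sample
    fold_of: np.ndarray  # training sample -> index into fold_models
    k: int
    seed: int

    def __post_init__(self) -> None:
        if (self.oof_residuals < 0).any():
            raise ValueError("residuals must be nonnegative")


@dataclass
class ConformalClassifier:
    fold_models: list
    oof_scores: np.ndarray  # 1 - p_hat_{-fold(i)}(y_i)
    fold_of: np.ndarray
    classes: np.ndarray
    k: int
    seed: int


def _as_array(X) -> np.ndarray:
    return X.to_numpy(float) if hasattr(X, "to_numpy") else np.asarray(X, float)


def _fold_assignment(n: int, k: int, seed: int):
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=int)
    splits = list(kf.split(np.zeros((n, 1))))
    for f, (_, held) in enumerate(splits):
        fold_of[held] = f
    return splits, fold_of


def cvplus_fit(estimator, X, y, k: int = 5, seed: int = 42) -> ConformalRegressor:
    """Fit the k leave-fold-out models and collect out-of-fold residuals."""
    Xa, ya = _as_array(X), np.asarray(y, float)
    splits, fold_of = _fold_assignment(len(ya), k, seed)
    models, resid = [], np.empty(len(ya))
    for f, (tr, held) in enumerate(splits):
        m = clone(estimator)
        m.fit(Xa[tr], ya[tr])
        resid[held] = np.abs(ya[held] - m.predict(Xa[held]))
        models.append(m)
    return ConformalRegressor(models, resid, fold_of, k, seed)


def predict_interval(cr: ConformalRegressor, X, alpha: float = 0.1) -> pd.DataFrame:
    """CV+ point predictions and (1-alpha) marginal intervals.

    The point prediction is the mean of fold-model predictions.  lo <= hi is
    enforced; lo <= point <= hi is not guaranteed by the theory.  When n is
    too small for the requested alpha the interval widens to the score range
    with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    Xa = _as_array(X)
    preds = np.vstack([m.predict(Xa) for m in cr.fold_models])  # k x m
    point = preds.mean(axis=0)
    per_sample = preds[cr.fold_of]  # n x m: mu_{-fold(i)}(x_j)
    n = len(cr.oof_residuals)
    lower = np.sort(per_sample - cr.oof_residuals[:, None], axis=0)
    upper = np.sort(per_sample + cr.oof_residuals[:, None], axis=0)
    l_idx = int(np.floor(alpha * (n + 1)))
    u_idx = int(np.ceil((1 - alpha) * (n + 1)))
    if l_idx < 1 or u_idx > n:
        warnings.warn(
            f"n={n} too small for alpha={alpha}; interval widened to the "
            "score range",
            SmallSampleWarning,
            stacklevel=2,
        )
        lo, hi = lower[0], upper[-1]
    else:
        lo, hi = lower[l_idx - 1], upper[u_idx - 1]
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return pd.DataFrame({"point": point, "lower": lo, "upper": hi})


def cvplus_fit_classifier(
    estimator, X, y, k: int = 5, seed: int = 42
) -> ConformalClassifier:
    """Classification analogue: out-of-fold nonconformity 1 - p_hat(y_i)."""
    Xa = _as_array(X)
    ya = np.asarray(y)
    classes = np.unique(ya)
    splits, fold_of = _fold_assignment(len(ya), k, seed)
    models, scores = [], np.empty(len(ya))
    for f, (tr, held) in enumerate(splits):
        m = clone(estimator)
        m.fit(Xa[tr], ya[tr])
        proba = m.predict_proba(Xa[held])
        col = {c: i for i, c in enumerate(m.classes_)}
        for row, j in enumerate(held):
            scores[j] = 1.0 - proba[row, col[ya[j]]]
        models.append(m)
    return ConformalClassifier(models, scores, fold_of, classes, k, seed)


def predict_set(
    cc: ConformalClassifier,
    X,
    alpha: float = 0.1,
    labels=None,
    allow_empty: bool = False,
) -> pd.DataFrame:
    """CV+ prediction sets: label y is included when its p-value
    (1 + #{i : s_i >= s_{-fold(i)}(x, y)}) / (n+1) exceeds alpha.

    Empty sets are disallowed by default: the top-probability label is kept
    and the row flagged in ``forced_singleton``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if labels is None:
        labels = list(cc.classes)
    unseen = [l for l in labels if l not in set(cc.classes)]
    if unseen:
        raise LabelError(f"labels never seen in training: {unseen}")
    Xa = _as_array(X)
    n = len(cc.oof_scores)
    # proba[f][:, class] per fold model
    probas = []
    for m in cc.fold_models:
        p = m.predict_proba(Xa)
        col = {c: i for i, c in enumerate(m.classes_)}
        probas.append(np.column_stack([p[:, col[l]] for l in labels]))
    probas = np.stack(probas)  # k x m x L
    mean_proba = probas.mean(axis=0)
    per_sample = probas[cc.fold_of]  # n x m x L
    cand_scores = 1.0 - per_sample
    counts = (cc.oof_scores[:, None, None] >= cand_scores).sum(axis=0)
    pvals = (1.0 + counts) / (n + 1.0)  # m x L
    rows = []
    for j in range(Xa.shape[0]):
        members = [labels[l] for l in range(len(labels)) if pvals[j, l] > alpha]
        forced = False
        if not members and not allow_empty:
            members = [labels[int(np.argmax(mean_proba[j]))]]
            forced = True
        rows.append({
            "set": members,
            "set_size": len(members),
            "forced_singleton": forced,
        })
    return pd.DataFrame(rows)
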