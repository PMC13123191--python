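"""Applicability-domain (AD) estimation.

Three training-only novelty detectors — mean distance to the k nearest
neighbors, Local Outlier Factor in novelty mode, and a one-class SVM with
an RBF kernel (gamma from the median-pairwise-distance heuristic) — score
each query; the per-sample in/out flag comes from comparing the score
against the (100 * rate_of_outliers) percentile of the training score
distribution.  Scores are thresholded on a unified orientation (larger =
more inlying); the emitted ``ad_score`` keeps each method's natural units
(kNN: mean neighbor distance, larger = more novel; LOF/OCSVM: decision
score, larger = more inlying).

AD operates in the same frozen post-preprocessing feature space as the
estimator, and flags are pointwise: independent of what else is in the
query batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors
from sklearn.svm import OneClassSVM

__all__ = ["ADModel", "ad_fit", "ad_flag"]

METHODS = ("knn", "lof", "ocsvm")


class ConfigurationError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class ADModel:
    method: str
    params: dict
    columns: list[str] | None
    training_scores: np.ndarray  # oriented: larger = more inlying
    threshold: float
    rate_of_outliers: float
    detector: object
    natural_sign: int  # ad_score = natural_sign * oriented score

    def training_flags(self) -> np.ndarray:
        """In/out flags of the training points from their stored
        (leave-self-out) novelty scores; by construction the out fraction
        tracks ``rate_of_outliers`` to within the percentile granularity."""
        return np.where(self.training_scores < self.threshold, "out", "in")


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d2 = pdist(X, "sqeuclidean")
    med = np.median(d2[d2 > 0]) if (d2 > 0).any() else 1.0
    return 1.0 / med


def ad_fit(
    features_train,
    method: str = "lof",
    params: dict | None = None,
    rate_of_outliers: float = 0.01,
) -> ADModel:
    """Fit a novelty detector on training features only and store the
    percentile threshold of its training score distribution.

    ``rate_of_outliers`` in [0, 0.5): with rate 0 the threshold sits just
    below the minimum training score, so no training point is flagged.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown AD method {method!r}; known {METHODS}")
    if not 0 <= rate_of_outliers < 0.5:
        raise ConfigurationError("rate_of_outliers must be in [0, 0.5)")
    params = dict(params or {})
    columns = list(features_train.columns) if hasattr(features_train, "columns") else None
    X = (
        features_train.to_numpy(float)
        if hasattr(features_train, "to_numpy")
        else np.asarray(features_train, float)
    )
    n = X.shape[0]
    if method == "knn":
        k = int(params.get("k", 5))
        if k >= n:
            raise ConfigurationError(f"k={k} must be < n={n}")
        nn = NearestNeighbors(n_neighbors=k + 1,
                              metric=params.get("metric", "euclidean")).fit(X)
        dist, _ = nn.kneighbors(X)
        scores = -dist[:, 1:].mean(axis=1)  # exclude self; negate => inlying
        detector, natural_sign = nn, -1
    elif method == "lof":
        k = int(params.get("k", 5))
        if k >= n:
            raise ConfigurationError(f"k={k} must be < n={n}")
        lof = LocalOutlierFactor(n_neighbors=k, novelty=True,
                                 metric=params.get("metric", "euclidean")).fit(X)
        scores = lof.negative_outlier_factor_.copy()
        detector, natural_sign = lof, +1
    else:
        gamma = params.get("gamma", "median")
        if gamma == "median":
            gamma = _median_heuristic_gamma(X)
        oc = OneClassSVM(kernel="rbf", gamma=gamma,
                         nu=float(params.get("nu", 0.1))).fit(X)
        scores = oc.decision_function(X)
        detector, natural_sign = oc, +1
        params["gamma"] = float(gamma)
    if rate_of_outliers == 0:
        threshold = float(np.min(scores)) - max(1e-9, 1e-9 * np.ptp(scores))
    else:
        threshold = float(np.quantile(scores, rate_of_outliers))
    return ADModel(
        method=method,
        params=params,
        columns=columns,
        training_scores=np.asarray(scores, float),
        threshold=threshold,
        rate_of_outliers=rate_of_outliers,
        detector=detector,
        natural_sign=natural_sign,
    )


def _oriented_scores(model: ADModel, X: np.ndarray) -> np.ndarray:
    if model.method == "knn":
        k = int(model.params.get("k", 5))
        dist, _ = model.detector.kneighbors(X, n_neighbors=k)
        return -dist.mean(axis=1)
    if model.method == "lof":
        return model.detector.score_samples(X)
    return model.detector.decision_function(X)


def ad_flag(model: ADModel, features_query) -> pd.DataFrame:
    """Score queries with the frozen detector and emit per-row flags.

    Returns columns ``ad_score`` (the method's natural score) and
    ``ad_flag`` in {"in", "out"}; a row is out iff its oriented score falls
    strictly below the training-percentile threshold.
    """
    if hasattr(features_query, "columns"):
        if model.columns is not None and list(features_query.columns) != model.columns:
            raise SchemaError("query columns do not match training columns")
        X = features_query.to_numpy(float)
        index = features_query.index
    else:
        X = np.asarray(features_query, float)
        index = pd.RangeIndex(len(X))
    oriented = _oriented_scores(model, X)
    flags = np.where(oriented < model.threshold, "out", "in")
    return pd.DataFrame(
        {"ad_score": model.natural_sign * oriented, "ad_flag": flags}, index=index
    )
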