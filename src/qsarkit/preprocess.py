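"""Deterministic, leakage-free preprocessing chain.

Every handler follows a strict fit/transform contract: ``fit`` consumes
training rows only and stores its learned state in ``fitted_params``;
``transform`` applies that frozen state and never removes rows.  Row-dropping
remediations (duplicate merging, outlier-row removal) happen only in
``fit_transform`` on the training block.  A :class:`PreprocessChain` runs
handlers in declaration order and validates that scaling, when present,
comes after outlier handling.

Quantile convention: linear interpolation between order statistics
(numpy default) everywhere — IQR fences, robust scaling, binning — so all
derived quantities share one definition.
"""

from __future__ import annotations

import json
import pickle
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.covariance import EllipticEnvelope
from sklearn.ensemble import IsolationForest
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer
from sklearn.neighbors import LocalOutlierFactor
from sklearn.preprocessing import (
    KBinsDiscretizer,
    MinMaxScaler,
    QuantileTransformer,
    RobustScaler,
    StandardScaler,
)
from sklearn.svm import OneClassSVM

__all__ = [
    "DuplicateHandler",
    "MissingHandler",
    "LowVarianceHandler",
    "UnivariateOutlierHandler",
    "MultivariateOutlierHandler",
    "KBinHandler",
    "Scaler",
    "PreprocessChain",
    "default_chain",
]

IQR_MULTIPLIER = 1.5


class NotFittedError(RuntimeError):
    pass


class EmptyMatrixError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class Handler:
    """Base fit/transform transformer over (features DataFrame, target Series)."""

    kind: str = "base"

    def __init__(self) -> None:
        self.fitted_params: dict[str, Any] | None = None
        self.log: list[dict] = []

    # -- contract -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: pd.Series) -> "Handler":
        raise NotImplementedError

    def transform(
        self, X: pd.DataFrame, y: pd.Series | None = None
    ) -> tuple[pd.DataFrame, pd.Series | None]:
        self._check_fitted()
        return self._apply(X), y

    def fit_transform(
        self, X: pd.DataFrame, y: pd.Series
    ) -> tuple[pd.DataFrame, pd.Series]:
        self.fit(X, y)
        return self.transform(X, y)

    def _apply(self, X: pd.DataFrame) -> pd.DataFrame:
        raise NotImplementedError

    def _check_fitted(self) -> None:
        if self.fitted_params is None:
            raise NotFittedError(f"{type(self).__name__} used before fit")

    def fitted_state(self) -> bytes:
        """Canonical byte serialization of the learned state (leakage checks)."""
        self._check_fitted()
        return pickle.dumps(self.fitted_params)

    def _log(self, action: str, **info) -> None:
        self.log.append({"step": self.kind, "action": action, **info})


class DuplicateHandler(Handler):
    """Merge training rows with identical feature vectors.

    Policies: keep_max / keep_min / mean / median on the target, or
    consensus (categorical targets: keep only when all labels agree,
    otherwise drop the whole group).  Transform on new data is the identity —
    deduplication is a training-set remediation.
    """

    kind = "duplicate"
    POLICIES = {"keep_max", "keep_min", "mean", "median", "consensus"}

    def __init__(self, policy: str = "keep_max") -> None:
        super().__init__()
        if policy not in self.POLICIES:
            raise ConfigurationError(f"unknown duplicate policy {policy!r}")
        self.policy = policy

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "DuplicateHandler":
        self.fitted_params = {"policy": self.policy}
        return self

    def fit_transform(self, X, y):
        self.fit(X, y)
        key = pd.util.hash_pandas_object(X, index=False)
        keep_idx: list = []
        new_targets: dict = {}
        for _, grp in X.groupby(key.values, sort=False):
            members = grp.index.tolist()
            if len(members) == 1:
                keep_idx.append(members[0])
                continue
            t = y.loc[members]
            if self.policy == "consensus":
                if t.nunique() == 1:
                    keep_idx.append(members[0])
                else:
                    self._log("dropped_conflicting_group", ids=list(map(str, members)))
                continue
            rep = members[0]
            if self.policy == "keep_max":
                new_targets[rep] = float(t.max())
            elif self.policy == "keep_min":
                new_targets[rep] = float(t.min())
            elif self.policy == "mean":
                new_targets[rep] = float(t.mean())
            else:
                new_targets[rep] = float(t.median())
            keep_idx.append(rep)
            self._log("merged", ids=list(map(str, members)), kept=str(rep))
        Xo = X.loc[keep_idx]
        yo = y.loc[keep_idx].copy()
        for k, v in new_targets.items():
            yo.loc[k] = v
        if Xo.empty:
            warnings.warn("deduplication removed every row", stacklevel=2)
        return Xo, yo

    def _apply(self, X):
        return X


class MissingHandler(Handler):
    """Drop columns whose training missing fraction exceeds a threshold
    (default 0.4), then impute remaining gaps with training statistics."""

    kind = "missing"
    IMPUTERS = {"mean", "median", "mode", "knn", "iterative"}

    def __init__(self, drop_threshold: float = 0.4, impute: str = "mean") -> None:
        super().__init__()
        if not 0 <= drop_threshold <= 1:
            raise ConfigurationError("drop_threshold must be in [0,1]")
        if impute not in self.IMPUTERS:
            raise ConfigurationError(f"unknown imputer {impute!r}")
        self.drop_threshold = drop_threshold
        self.impute = impute
        self._sk = None

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "MissingHandler":
        frac = X.isna().mean()
        drop = frac.index[frac > self.drop_threshold].tolist()
        keep = [c for c in X.columns if c not in drop]
        if not keep:
            raise EmptyMatrixError("all columns exceed the missing-value threshold")
        Xk = X[keep]
        if self.impute == "mean":
            fill = Xk.mean().to_dict()
        elif self.impute == "median":
            fill = Xk.median().to_dict()
        elif self.impute == "mode":
            fill = {c: Xk[c].mode(dropna=True).iloc[0] if Xk[c].notna().any() else 0.0
                    for c in keep}
        else:
            fill = None
            self._sk = (
                KNNImputer() if self.impute == "knn"
                else IterativeImputer(random_state=0, max_iter=10)
            )
            self._sk.fit(Xk.to_numpy(float))
        self.fitted_params = {
            "dropped": drop,
            "kept": keep,
            "impute": self.impute,
            "fill": fill,
            "sk_state": pickle.dumps(self._sk) if self._sk is not None else None,
        }
        if drop:
            self._log("dropped_columns", columns=drop)
        return self

    def _apply(self, X):
        p = self.fitted_params
        Xk = X[p["kept"]]
        if p["fill"] is not None:
            return Xk.fillna(pd.Series(p["fill"]))
        out = self._sk.transform(Xk.to_numpy(float))
        return pd.DataFrame(out, index=Xk.index, columns=Xk.columns)


class LowVarianceHandler(Handler):
    """Remove columns with training variance <= threshold (population
    variance, matching the common variance-threshold convention)."""

    kind = "low_variance"

    def __init__(self, var_threshold: float = 0.0) -> None:
        super().__init__()
        if var_threshold < 0:
            raise ConfigurationError("var_threshold must be >= 0")
        self.var_threshold = var_threshold

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "LowVarianceHandler":
        var = X.var(ddof=0)
        keep = var.index[var > self.var_threshold].tolist()
        if not keep:
            raise EmptyMatrixError("every column is (near-)constant")
        dropped = [c for c in X.columns if c not in keep]
        self.fitted_params = {"kept": keep, "dropped": dropped}
        if dropped:
            self._log("dropped_columns", columns=dropped)
        return self

    def _apply(self, X):
        return X[self.fitted_params["kept"]]


def iqr_fences(col: pd.Series, k: float = IQR_MULTIPLIER) -> tuple[float, float]:
    """Tukey fences [Q1 - k*IQR, Q3 + k*IQR] with linear-interpolated quartiles."""
    q1, q3 = np.quantile(col.dropna().to_numpy(float), [0.25, 0.75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


class UnivariateOutlierHandler(Handler):
    """Per-column IQR-fence outlier remediation.

    Methods: remove_rows (training rows only), winsorize (cap at fences),
    to_nan_impute (mask then mean-impute with training stats),
    transform_normal / transform_uniform (rank-based distributional
    transform), kbin (quantile discretization).  Test rows are never removed,
    only transformed.
    """

    kind = "univariate_outlier"
    METHODS = {
        "remove_rows",
        "winsorize",
        "to_nan_impute",
        "transform_normal",
        "transform_uniform",
        "kbin",
    }

    def __init__(self, method: str = "winsorize", n_bins: int = 5) -> None:
        super().__init__()
        if method not in self.METHODS:
            raise ConfigurationError(f"unknown outlier method {method!r}")
        self.method = method
        self.n_bins = n_bins
        self._sk = None

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "UnivariateOutlierHandler":
        fences = {c: iqr_fences(X[c]) for c in X.columns}
        fill = None
        if self.method == "to_nan_impute":
            masked = X.copy()
            for c, (lo, hi) in fences.items():
                masked.loc[(masked[c] < lo) | (masked[c] > hi), c] = np.nan
            fill = masked.mean().to_dict()
        elif self.method in ("transform_normal", "transform_uniform"):
            dist = "normal" if self.method == "transform_normal" else "uniform"
            self._sk = QuantileTransformer(
                output_distribution=dist,
                n_quantiles=min(1000, len(X)),
                random_state=0,
            ).fit(X.to_numpy(float))
        elif self.method == "kbin":
            self._sk = KBinsDiscretizer(
                n_bins=self.n_bins, encode="ordinal", strategy="quantile",
                quantile_method="linear",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._sk.fit(X.to_numpy(float))
        self.fitted_params = {
            "method": self.method,
            "fences": fences,
            "fill": fill,
            "sk_state": pickle.dumps(self._sk) if self._sk is not None else None,
        }
        return self

    def _outlier_mask(self, X: pd.DataFrame) -> pd.DataFrame:
        fences = self.fitted_params["fences"]
        mask = pd.DataFrame(False, index=X.index, columns=X.columns)
        for c, (lo, hi) in fences.items():
            mask[c] = (X[c] < lo) | (X[c] > hi)
        return mask

    def fit_transform(self, X, y):
        self.fit(X, y)
        if self.method == "remove_rows":
            bad = self._outlier_mask(X).any(axis=1)
            if bad.any():
                self._log("removed_rows", ids=list(map(str, X.index[bad])))
            return X.loc[~bad], y.loc[~bad]
        return self.transform(X, y)

    def _apply(self, X):
        p = self.fitted_params
        if self.method in ("remove_rows",):
            return X  # never remove non-training rows
        if self.method == "winsorize":
            out = X.copy()
            for c, (lo, hi) in p["fences"].items():
                out[c] = out[c].clip(lo, hi)
            return out
        if self.method == "to_nan_impute":
            out = X.copy()
            for c, (lo, hi) in p["fences"].items():
                out.loc[(out[c] < lo) | (out[c] > hi), c] = np.nan
            return out.fillna(pd.Series(p["fill"]))
        arr = self._sk.transform(X.to_numpy(float))
        return pd.DataFrame(arr, index=X.index, columns=X.columns)


class MultivariateOutlierHandler(Handler):
    """Multivariate novelty-based row removal on the training block only.

    Detectors: LOF, Isolation Forest, one-class SVM, elliptic envelope.
    The only remediation is removal of flagged training rows; transform on
    validation/test data is the identity.
    """

    kind = "multivariate_outlier"
    DETECTORS = {"lof", "isolation_forest", "ocsvm", "elliptic_envelope"}

    def __init__(
        self, detector: str = "isolation_forest", contamination: float = 0.05,
        n_neighbors: int = 20,
    ) -> None:
        super().__init__()
        if detector not in self.DETECTORS:
            raise ConfigurationError(f"unknown detector {detector!r}")
        if not 0 < contamination <= 0.5:
            raise ConfigurationError("contamination must be in (0, 0.5]")
        self.detector = detector
        self.contamination = contamination
        self.n_neighbors = n_neighbors

    def _make(self):
        if self.detector == "lof":
            return LocalOutlierFactor(
                n_neighbors=self.n_neighbors, contamination=self.contamination
            )
        if self.detector == "isolation_forest":
            return IsolationForest(contamination=self.contamination, random_state=0)
        if self.detector == "ocsvm":
            return OneClassSVM(nu=self.contamination)
        return EllipticEnvelope(contamination=self.contamination, random_state=0)

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "MultivariateOutlierHandler":
        det = self._make()
        arr = X.to_numpy(float)
        if self.detector == "lof":
            flags = det.fit_predict(arr)
        else:
            flags = det.fit(arr).predict(arr)
        removed = X.index[flags == -1]
        self.fitted_params = {
            "detector": self.detector,
            "contamination": self.contamination,
            "removed_train_ids": list(map(str, removed)),
        }
        if len(removed):
            self._log("removed_rows", ids=list(map(str, removed)))
        return self

    def fit_transform(self, X, y):
        self.fit(X, y)
        drop = set(self.fitted_params["removed_train_ids"])
        keep = [i for i in X.index if str(i) not in drop]
        return X.loc[keep], y.loc[keep]

    def _apply(self, X):
        return X


class KBinHandler(Handler):
    """Quantile discretization of every column (default 5 ordinal bins)."""

    kind = "kbin"

    def __init__(self, n_bins: int = 5) -> None:
        super().__init__()
        self.n_bins = n_bins
        self._sk = None

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "KBinHandler":
        self._sk = KBinsDiscretizer(
            n_bins=self.n_bins, encode="ordinal", strategy="quantile",
            quantile_method="linear",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._sk.fit(X.to_numpy(float))
        self.fitted_params = {"n_bins": self.n_bins, "edges": [e.tolist() for e in self._sk.bin_edges_]}
        return self

    def _apply(self, X):
        arr = self._sk.transform(X.to_numpy(float))
        return pd.DataFrame(arr, index=X.index, columns=X.columns)


class Scaler(Handler):
    """Per-column affine scaling with training-learned parameters.

    minmax maps the training range to [0,1] (constant columns to 0, with a
    warning); standard centers/standardizes; robust uses median and IQR.
    Values outside the training range extrapolate — no clipping.
    """

    kind = "scale"
    SCHEMES = {"minmax", "standard", "robust"}

    def __init__(self, scheme: str = "standard") -> None:
        super().__init__()
        if scheme not in self.SCHEMES:
            raise ConfigurationError(f"unknown scaling scheme {scheme!r}")
        self.scheme = scheme
        self._sk = None

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "Scaler":
        if self.scheme == "minmax":
            self._sk = MinMaxScaler()
            rng = X.max() - X.min()
            if (rng == 0).any():
                warnings.warn(
                    f"zero-range columns mapped to 0: "
                    f"{rng.index[rng == 0].tolist()[:5]}",
                    stacklevel=2,
                )
        elif self.scheme == "standard":
            self._sk = StandardScaler()
        else:
            self._sk = RobustScaler()
        self._sk.fit(X.to_numpy(float))
        self.fitted_params = {"scheme": self.scheme,
                              "sk_state": pickle.dumps(self._sk)}
        return self

    def _apply(self, X):
        arr = self._sk.transform(X.to_numpy(float))
        return pd.DataFrame(arr, index=X.index, columns=X.columns)


_ORDER_RANK = {
    "duplicate": 0,
    "missing": 1,
    "low_variance": 2,
    "univariate_outlier": 3,
    "multivariate_outlier": 4,
    "kbin": 5,
    "scale": 6,
}


class PreprocessChain:
    """An ordered transformer chain fitted on training rows only.

    ``fit_transform`` runs handlers in declaration order on the training
    block (handlers may drop or merge rows there); ``transform`` applies the
    frozen states row-preservingly.  The constructor rejects chains where
    scaling precedes outlier handling.
    """

    def __init__(self, handlers: list[Handler]):
        kinds = [h.kind for h in handlers]
        if kinds.count("scale") > 1:
            raise ConfigurationError("at most one scaling step")
        if "scale" in kinds and kinds.index("scale") != len(kinds) - 1:
            raise ConfigurationError(
                "scaling must be the last step (after imputation and outlier "
                "remediation)"
            )
        self.handlers = handlers
        self._fitted = False

    def fit_transform(
        self, X: pd.DataFrame, y: pd.Series
    ) -> tuple[pd.DataFrame, pd.Series]:
        for h in self.handlers:
            h.log.clear()
            X, y = h.fit_transform(X, y)
        self._fitted = True
        return X, y

    def transform(
        self, X: pd.DataFrame, y: pd.Series | None = None
    ) -> tuple[pd.DataFrame, pd.Series | None]:
        if not self._fitted:
            raise NotFittedError("chain used before fit")
        for h in self.handlers:
            X, y = h.transform(X, y)
        return X, y

    @property
    def fit_log(self) -> list[dict]:
        return [entry for h in self.handlers for entry in h.log]

    def write_fit_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.fit_log:
                fh.write(json.dumps(entry) + "\n")

    def fitted_state(self) -> bytes:
        return pickle.dumps([h.fitted_params for h in self.handlers])


def default_chain(
    *,
    duplicate_policy: str = "keep_max",
    missing_threshold: float = 0.4,
    impute: str = "mean",
    var_threshold: float = 0.0,
    outlier_method: str = "winsorize",
    multivariate_detector: str | None = None,
    contamination: float = 0.05,
    scaling: str | None = "standard",
    binary_features: bool = False,
) -> PreprocessChain:
    """The standard chain: dedup -> missing -> low-variance -> univariate
    outliers -> (multivariate outliers) -> scaling.

    For binary fingerprint features the outlier and scaling steps are
    meaningless and are omitted.
    """
    handlers: list[Handler] = [
        DuplicateHandler(duplicate_policy),
        MissingHandler(missing_threshold, impute),
        LowVarianceHandler(var_threshold),
    ]
    if not binary_features:
        handlers.append(UnivariateOutlierHandler(outlier_method))
        if multivariate_detector:
            handlers.append(
                MultivariateOutlierHandler(multivariate_detector, contamination)
            )
        if scaling:
            handlers.append(Scaler(scaling))
    return PreprocessChain(handlers)
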