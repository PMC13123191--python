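"""Joint model + hyperparameter search with a Tree-structured Parzen
Estimator (TPE) sampler.

The search space is tree-structured: a categorical choice over candidate
estimators at the root, with an independent parameter subspace per
estimator.  The objective J(theta) is the mean oriented cross-validated
score over the shared split family; the sampler maximizes J.

The TPE sampler here is a compact, seeded implementation of the standard
scheme: after a random startup phase, observed trials are split at a
quantile gamma into "good" and "bad" sets; numeric parameters are sampled
from a Gaussian kernel-density estimate of the good set and ranked by the
density ratio l(x)/g(x); categorical parameters use add-one-smoothed
frequency ratios.  Fixed seed + fixed budget => identical trial history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import clone

from .resample import METRICS, Metric, ScoreMatrix, SplitFamily, score_contenders

__all__ = [
    "Float",
    "Int",
    "Categorical",
    "OptimizerResult",
    "TPESampler",
    "tune",
    "default_search_spaces",
]


class OptimizationError(RuntimeError):
    def __init__(self, msg: str, history: pd.DataFrame | None = None):
        super().__init__(msg)
        self.history = history


@dataclass(frozen=True)
class Float:
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Int:
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __init__(self, choices):
        object.__setattr__(self, "choices", tuple(choices))


@dataclass
class OptimizerResult:
    """Best configuration found, its objective value and the trial history."""

    best_config: dict
    best_score: float
    history: pd.DataFrame

    @property
    def best_estimator_name(self) -> str:
        return self.best_config["estimator"]


class TPESampler:
    """Minimal seeded TPE over flat parameter dicts."""

    def __init__(
        self,
        seed: int = 42,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    # -- random draws -------------------------------------------------------
    def _draw(self, dist):
        if isinstance(dist, Categorical):
            return dist.choices[self.rng.integers(len(dist.choices))]
        if isinstance(dist, Float):
            if dist.log:
                return float(
                    np.exp(self.rng.uniform(np.log(dist.low), np.log(dist.high)))
                )
            return float(self.rng.uniform(dist.low, dist.high))
        if isinstance(dist, Int):
            if dist.log:
                v = np.exp(self.rng.uniform(np.log(dist.low), np.log(dist.high + 1)))
                return int(min(dist.high, max(dist.low, int(v))))
            return int(self.rng.integers(dist.low, dist.high + 1))
        raise TypeError(f"unknown distribution {dist!r}")

    # -- TPE proposal for one parameter ------------------------------------
    @staticmethod
    def _kde_logpdf(x: np.ndarray, obs: np.ndarray, bw: float) -> np.ndarray:
        # shared-bandwidth Gaussian KDE; l(x) and g(x) must use the same bw
        # or the wider of the two artificially flattens its cluster density
        diff = (x[:, None] - obs[None, :]) / bw
        log_k = -0.5 * diff**2 - math.log(bw * math.sqrt(2 * math.pi))
        return np.logaddexp.reduce(log_k, axis=1) - math.log(len(obs))

    def _propose_numeric(self, dist, good: np.ndarray, bad: np.ndarray):
        to_internal = (lambda v: np.log(v)) if dist.log else (lambda v: v)
        from_internal = (lambda v: float(np.exp(v))) if dist.log else float
        lo, hi = to_internal(dist.low), to_internal(np.asarray(dist.high, float))
        g = to_internal(good.astype(float))
        span = float(hi - lo) or 1.0
        bw = max(1.06 * g.std() * len(g) ** -0.2, 0.05 * span, 1e-12)
        idx = self.rng.integers(len(g), size=self.n_candidates)
        cand = np.clip(g[idx] + self.rng.normal(0, bw, self.n_candidates), lo, hi)
        score = self._kde_logpdf(cand, g, bw)
        if len(bad):
            score = score - self._kde_logpdf(
                cand, to_internal(bad.astype(float)), bw
            )
        best = from_internal(cand[int(np.argmax(score))])
        if isinstance(dist, Int):
            best = int(min(dist.high, max(dist.low, round(best))))
        return best

    def _propose_categorical(self, dist: Categorical, good, bad):
        choices = list(dist.choices)
        pg = np.array([1.0 + sum(1 for v in good if v == c) for c in choices])
        pb = np.array([1.0 + sum(1 for v in bad if v == c) for c in choices])
        ratio = (pg / pg.sum()) / (pb / pb.sum())
        weights = pg / pg.sum() * ratio  # favor frequent-in-good, rare-in-bad
        weights /= weights.sum()
        return choices[int(self.rng.choice(len(choices), p=weights))]

    def suggest(self, space: Mapping[str, object], trials: list[tuple[dict, float]]):
        """Propose a parameter dict for ``space`` given (params, value)
        history; values are maximized."""
        finished = [(p, v) for p, v in trials if np.isfinite(v)]
        if len(finished) < self.n_startup:
            return {k: self._draw(d) for k, d in space.items()}
        finished.sort(key=lambda t: -t[1])
        n_good = max(1, int(np.ceil(self.gamma * len(finished))))
        good = [p for p, _ in finished[:n_good]]
        bad = [p for p, _ in finished[n_good:]]
        out = {}
        for key, dist in space.items():
            g = [p[key] for p in good if key in p]
            b = [p[key] for p in bad if key in p]
            if not g:
                out[key] = self._draw(dist)
            elif isinstance(dist, Categorical):
                out[key] = self._propose_categorical(dist, g, b)
            else:
                out[key] = self._propose_numeric(dist, np.array(g), np.array(b))
        return out


def default_search_spaces(task: str = "regression") -> dict[str, dict]:
    """Per-estimator hyperparameter spaces (keyed by registry name)."""
    spaces: dict[str, dict] = {
        "dummy": {},
        "knn": {"n_neighbors": Int(1, 30), "weights": Categorical(["uniform", "distance"])},
        "random_forest": {
            "n_estimators": Int(50, 400),
            "max_depth": Int(2, 24),
            "min_samples_leaf": Int(1, 8),
        },
        "gradient_boosting": {
            "n_estimators": Int(50, 400),
            "learning_rate": Float(1e-3, 0.3, log=True),
            "max_depth": Int(1, 8),
        },
        "xgboost": {
            "n_estimators": Int(50, 400),
            "learning_rate": Float(1e-3, 0.3, log=True),
            "max_depth": Int(1, 8),
            "subsample": Float(0.5, 1.0),
        },
        "svm": {"C": Float(1e-2, 1e2, log=True), "gamma": Float(1e-4, 1.0, log=True)},
        "mlp": {
            "alpha": Float(1e-6, 1e-1, log=True),
            "learning_rate_init": Float(1e-4, 1e-1, log=True),
        },
    }
    if task == "regression":
        spaces["ridge"] = {}
    else:
        spaces["logistic"] = {"C": Float(1e-3, 1e2, log=True)}
    return spaces


def tune(
    candidates: Mapping[str, object],
    search_spaces: Mapping[str, Mapping],
    X: pd.DataFrame,
    y: pd.Series,
    family: SplitFamily,
    metric: Metric | str,
    budget: int = 30,
    seed: int = 42,
    chain_factory: Callable | None = None,
) -> OptimizerResult:
    """Maximize the mean oriented CV score over estimators and their
    hyperparameters with the TPE sampler; full history is retained."""
    if isinstance(metric, str):
        metric = METRICS[metric]
    if budget < 1:
        raise OptimizationError("budget must be >= 1")
    sampler = TPESampler(seed=seed)
    names = list(candidates)
    root_space = {"estimator": Categorical(names)}
    trials: list[tuple[dict, float]] = []
    rows = []
    for t in range(budget):
        root = sampler.suggest(root_space, [(p, v) for p, v in trials])
        est_name = root["estimator"]
        sub_space = dict(search_spaces.get(est_name, {}))
        sub_trials = [
            ({k: p[k] for k in sub_space if k in p}, v)
            for p, v in trials
            if p.get("estimator") == est_name
        ]
        params = sampler.suggest(sub_space, sub_trials) if sub_space else {}
        est = clone(candidates[est_name]).set_params(**params)
        try:
            sm = score_contenders(
                {est_name: est}, X, y, family, metric, chain_factory
            )
            complete = sm.complete_blocks()
            if complete.empty:
                raise RuntimeError("estimator failed on every block")
            value = float(sm.block_means().iloc[0])
        except Exception as exc:
            value = float("-inf")
            rows.append({"trial": t, "estimator": est_name, "value": np.nan,
                         "error": repr(exc), **params})
            trials.append(({"estimator": est_name, **params}, value))
            continue
        rows.append({"trial": t, "estimator": est_name, "value": value,
                     "error": "", **params})
        trials.append(({"estimator": est_name, **params}, value))
    history = pd.DataFrame(rows)
    finite = [(p, v) for p, v in trials if np.isfinite(v)]
    if not finite:
        raise OptimizationError("all trials failed", history)
    best_params, best_value = max(finite, key=lambda t: t[1])
    return OptimizerResult(best_config=best_params, best_score=best_value,
                           history=history)
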