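"""Repeated k-fold resampling and paired contender scoring.

A :class:`SplitFamily` is the fixed family of k x R cross-validation blocks
shared by every contender (feature-selection strategy, estimator, or
descriptor scheme), so that downstream comparisons are paired: every
contender is scored on the identical blocks, eliminating split-induced
variance.  Metrics carry an orientation s(m) in {+1, -1} so that the
oriented score s(m)*m is always higher-is-better; selection is the argmax
of oriented block means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "Metric",
    "METRICS",
    "SplitFamily",
    "ScoreMatrix",
    "make_split_family",
    "score_contenders",
    "select_best",
    "feature_select_stage",
]


class ConfigurationError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class Metric:
    """A scalar validation metric with its orientation (+1 higher-is-better)."""

    name: str
    orientation: int
    needs_proba: bool = False

    def compute(self, estimator, X, y_true) -> float:
        if self.needs_proba:
            proba = estimator.predict_proba(X)
            score_in = proba[:, 1] if proba.shape[1] == 2 else proba
            if self.name == "roc_auc":
                return float(roc_auc_score(y_true, score_in, multi_class="ovr"))
            return float(average_precision_score(y_true, score_in))
        y_pred = estimator.predict(X)
        if self.name == "r2":
            return float(r2_score(y_true, y_pred))
        if self.name == "rmse":
            return float(np.sqrt(mean_squared_error(y_true, y_pred)))
        if self.name == "mae":
            return float(mean_absolute_error(y_true, y_pred))
        if self.name == "accuracy":
            return float(accuracy_score(y_true, y_pred))
        if self.name == "f1":
            return float(f1_score(y_true, y_pred, average="macro"))
        raise ConfigurationError(f"unknown metric {self.name}")


METRICS: dict[str, Metric] = {
    "r2": Metric("r2", +1),
    "rmse": Metric("rmse", -1),
    "mae": Metric("mae", -1),
    "roc_auc": Metric("roc_auc", +1, needs_proba=True),
    "pr_auc": Metric("pr_auc", +1, needs_proba=True),
    "accuracy": Metric("accuracy", +1),
    "f1": Metric("f1", +1),
}


@dataclass
class SplitFamily:
    """The fixed resampling family: R seeded shufflings each split k ways.

    ``blocks`` holds ``k*R`` (train_idx, val_idx) pairs labelled (fold i,
    repeat r); within each repeat the validation folds partition the sample
    index set.  Regeneration from the same parameters is bit-identical.
    """

    n_samples: int
    k: int
    R: int
    seed: int
    stratified: bool
    blocks: list[tuple[np.ndarray, np.ndarray]]
    labels: list[tuple[int, int]]  # (fold, repeat)

    @property
    def n_blocks(self) -> int:
        return self.k * self.R

    def spec(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "k": self.k,
            "R": self.R,
            "seed": self.seed,
            "stratified": self.stratified,
        }


def make_split_family(
    n_samples: int,
    k: int = 5,
    R: int = 5,
    seed: int = 42,
    stratified: bool = False,
    labels: Sequence | None = None,
) -> SplitFamily:
    """Build the k x R block family; stratified mode needs class labels."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n_samples:
        raise ConfigurationError(f"k={k} exceeds n_samples={n_samples}")
    if stratified and labels is None:
        raise ConfigurationError("stratified splitting requires labels")
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    block_labels: list[tuple[int, int]] = []
    X_dummy = np.zeros((n_samples, 1))
    for r in range(R):
        if stratified:
            cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
            split_iter = cv.split(X_dummy, np.asarray(labels))
        else:
            cv = KFold(n_splits=k, shuffle=True, random_state=seed + r)
            split_iter = cv.split(X_dummy)
        for i, (tr, va) in enumerate(split_iter):
            blocks.append((tr, va))
            block_labels.append((i, r))
    return SplitFamily(n_samples, k, R, seed, bool(stratified), blocks, block_labels)


@dataclass
class ScoreMatrix:
    """Paired per-block scores m_b(h) for a contender set under one metric."""

    contenders: list[str]
    metric: Metric
    scores: pd.DataFrame  # rows: MultiIndex (fold, repeat); columns: contenders

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.contenders):
            raise ValueError("score columns must match contender order")

    def oriented(self) -> pd.DataFrame:
        return self.scores * self.metric.orientation

    def complete_blocks(self) -> pd.DataFrame:
        """Pairwise-complete rows over contenders that scored at least one
        block (a contender that failed everywhere is excluded, not allowed
        to empty the paired design)."""
        usable = self.scores.dropna(axis=1, how="all")
        return usable.dropna(axis=0, how="any")

    def block_means(self) -> pd.Series:
        """Oriented mean per contender over pairwise-complete blocks;
        all-failed contenders get NaN."""
        means = (self.complete_blocks() * self.metric.orientation).mean(axis=0)
        return means.reindex(self.contenders)

    def to_csv(self, path: str | Path) -> None:
        long = self.scores.stack().rename("score").reset_index()
        long.columns = ["block_i", "block_r", "contender", "score"]
        long.insert(0, "metric", self.metric.name)
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreMatrix":
        long = pd.read_csv(path)
        metric = METRICS[long["metric"].iloc[0]]
        wide = long.pivot(index=["block_i", "block_r"], columns="contender",
                          values="score")
        wide = wide[sorted(wide.columns, key=list(long["contender"]).index)]
        return cls(list(wide.columns), metric, wide)


def _fit_score_block(
    estimator, chain_factory, selector_factory, X, y, tr, va, metric
) -> float:
    X_tr, y_tr = X.iloc[tr], y.iloc[tr]
    X_va, y_va = X.iloc[va], y.iloc[va]
    if chain_factory is not None:
        chain = chain_factory()
        X_tr, y_tr = chain.fit_transform(X_tr, y_tr)
        X_va, _ = chain.transform(X_va)
    if selector_factory is not None:
        sel = selector_factory()
        if sel is not None:
            sel.fit(X_tr.to_numpy(float), y_tr.to_numpy())
            mask = sel.get_support()
            if not mask.any():
                raise ValueError("strategy selected zero features")
            X_tr = X_tr.loc[:, mask]
            X_va = X_va.loc[:, mask]
    est = clone(estimator)
    est.fit(X_tr.to_numpy(float), y_tr.to_numpy())
    return metric.compute(est, X_va.to_numpy(float), y_va.to_numpy())


def score_contenders(
    contenders: Mapping[str, object],
    X: pd.DataFrame,
    y: pd.Series,
    family: SplitFamily,
    metric: Metric | str,
    chain_factory: Callable | None = None,
    fail_log: list | None = None,
) -> ScoreMatrix:
    """Score every contender on the identical block list (paired design).

    The preprocessing chain, when given, is re-fitted inside every block on
    that block's training rows — the leakage contract.  A contender failure
    on a block records a missing score; comparisons then use
    pairwise-complete blocks.
    """
    if isinstance(metric, str):
        metric = METRICS[metric]
    if not contenders:
        raise EmptyInputError("no contenders")
    names = list(contenders)
    index = pd.MultiIndex.from_tuples(family.labels, names=["fold", "repeat"])
    mat = pd.DataFrame(np.nan, index=index, columns=names)
    for name, est in contenders.items():
        for (tr, va), lab in zip(family.blocks, family.labels):
            try:
                mat.loc[lab, name] = _fit_score_block(
                    est, chain_factory, None, X, y, tr, va, metric
                )
            except Exception as exc:  # failed block -> missing, logged
                if fail_log is not None:
                    fail_log.append({"contender": name, "block": lab,
                                     "error": repr(exc)})
    return ScoreMatrix(names, metric, mat)


def select_best(score_matrix: ScoreMatrix, tie_log: list | None = None) -> str:
    """Argmax of oriented block means; exact ties go to the first-declared
    contender (logged)."""
    means = score_matrix.block_means()
    if means.empty or means.isna().all():
        raise EmptyInputError("no finite scores to select from")
    best = means.max()
    winners = [
        c
        for c in score_matrix.contenders
        if pd.notna(means.get(c)) and means[c] == best
    ]
    if len(winners) > 1 and tie_log is not None:
        tie_log.append({"tie_between": winners, "chosen": winners[0]})
    return winners[0]


def feature_select_stage(
    strategies: Mapping[str, Callable],
    X: pd.DataFrame,
    y: pd.Series,
    family: SplitFamily,
    metric: Metric | str,
    canonical_estimator,
    chain_factory: Callable | None = None,
    fail_log: list | None = None,
) -> tuple[str, ScoreMatrix]:
    """Stage 1 of the selection cascade: pick the feature-selection strategy.

    Each strategy is a zero-argument factory returning either ``None`` (the
    no-selection baseline) or a fitted-per-block sklearn selector exposing
    ``fit``/``get_support``.  Utility is the canonical estimator's paired
    score; the winner is chosen by :func:`select_best`.
    """
    if isinstance(metric, str):
        metric = METRICS[metric]
    names = list(strategies)
    index = pd.MultiIndex.from_tuples(family.labels, names=["fold", "repeat"])
    mat = pd.DataFrame(np.nan, index=index, columns=names)
    for name, factory in strategies.items():
        for (tr, va), lab in zip(family.blocks, family.labels):
            try:
                mat.loc[lab, name] = _fit_score_block(
                    canonical_estimator, chain_factory, factory, X, y, tr, va,
                    metric,
                )
            except Exception as exc:
                if fail_log is not None:
                    fail_log.append({"strategy": name, "block": lab,
                                     "error": repr(exc)})
    sm = ScoreMatrix(names, metric, mat)
    return select_best(sm), sm
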