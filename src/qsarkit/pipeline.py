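"""Single-entry pipeline: descriptor-first evaluation, optimization,
finalization into a checksummed fit-and-use bundle, and deterministic
inference.

The flow mirrors the modular pieces: ingest and standardize; one external
train/test partition; for every descriptor scheme run preprocessing,
feature selection and model benchmarking on a split family shared across
schemes; pick the scheme whose winning contender has the best mean oriented
score (optionally after a formal cross-scheme comparison); tune the winner
with TPE; refit on the full training set; calibrate a cross-conformal
predictor and fit an applicability-domain detector; evaluate once on the
external test set (always including the dummy baseline); archive everything
with per-member checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import pickle
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .chem import FeatureMatrix, FeatureScheme, SchemeError, featurize, load_dataset
from .conformal import (
    ConformalClassifier,
    ConformalRegressor,
    cvplus_fit,
    cvplus_fit_classifier,
    predict_interval,
    predict_set,
)
from .domain import ADModel, ad_fit, ad_flag
from .models import (
    DUMMY_NAME,
    classification_registry,
    regression_registry,
    selection_strategies,
)
from .preprocess import PreprocessChain, default_chain
from .resample import (
    METRICS,
    Metric,
    ScoreMatrix,
    SplitFamily,
    make_split_family,
    score_contenders,
    select_best,
)
from .split import (
    Partition,
    butina_split,
    random_or_stratified_split,
    scaffold_split,
)
from .stats import compare
from .tuning import OptimizerResult, default_search_spaces, tune
from . import chem as _chem

__all__ = [
    "PipelineConfig",
    "PipelineBundle",
    "OptimalDatasetResult",
    "optimal_dataset",
    "finalize",
    "infer",
    "report",
]


class IntegrityError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Fully serializable run recipe; reloading reproduces an identical run."""

    data_path: str
    smiles_col: str = "smiles"
    target_col: str = "target"
    id_col: str | None = "id"
    task: str = "regression"
    schemes: tuple[str, ...] = tuple(_chem.SCHEME_REGISTRY)
    n_bits: int = 2048
    split_strategy: str = "random"  # random | stratified | scaffold | butina
    test_fraction: float = 0.2
    butina_cutoff: float = 0.35
    k: int = 5
    R: int = 5
    seed: int = 42
    metric: str | None = None  # default: r2 (regression) / roc_auc (classification)
    preprocess: dict = field(default_factory=dict)  # kwargs for default_chain
    feature_strategies: tuple[str, ...] | None = None
    canonical_estimator: str = "random_forest"
    candidates: tuple[str, ...] | None = None
    budget: int = 30
    pre_gate_budget: int = 0  # 0 = gate off
    compare_schemes: bool = True
    conformal_alphas: tuple[float, ...] = (0.1, 0.32)
    ad_method: str = "lof"
    ad_k: int = 5
    ad_rate_of_outliers: float = 0.01
    output_dir: str = "qsarkit_run"

    def metric_obj(self) -> Metric:
        name = self.metric or ("r2" if self.task == "regression" else "roc_auc")
        return METRICS[name]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        kwargs = dict(raw)
        for key in ("schemes", "feature_strategies", "candidates", "conformal_alphas"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# helpers

def _registry(config: PipelineConfig):
    if config.task == "regression":
        return regression_registry(config.seed, list(config.candidates) if config.candidates else None)
    return classification_registry(config.seed, list(config.candidates) if config.candidates else None)


def _strategies(config: PipelineConfig):
    subset = list(config.feature_strategies) if config.feature_strategies else None
    return selection_strategies(config.task, config.seed, subset=subset)


def _chain_factory(config: PipelineConfig, scheme: FeatureScheme):
    binary = scheme.is_hashed
    opts = dict(config.preprocess)
    return lambda: default_chain(binary_features=binary, **opts)


class _FrozenSelector:
    """Column mask learned once on the training matrix, applied by name."""

    def __init__(self, columns: list[str]):
        self.columns = columns

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.columns]


class _ChainWithSelector:
    """Preprocess chain + per-block feature selector, presented as a chain."""

    def __init__(self, chain: PreprocessChain, selector_factory):
        self.chain = chain
        self.selector_factory = selector_factory
        self.frozen: _FrozenSelector | None = None

    def fit_transform(self, X, y):
        X, y = self.chain.fit_transform(X, y)
        sel = self.selector_factory() if self.selector_factory else None
        if sel is None:
            self.frozen = _FrozenSelector(list(X.columns))
            return X, y
        sel.fit(X.to_numpy(float), y.to_numpy())
        mask = sel.get_support()
        if not mask.any():
            raise ValueError("feature selection left zero columns")
        self.frozen = _FrozenSelector(list(X.columns[mask]))
        return X.loc[:, mask], y

    def transform(self, X, y=None):
        X, y = self.chain.transform(X, y)
        return self.frozen.transform(X), y


def _make_partition(config: PipelineConfig, records) -> Partition:
    ok = [r for r in records if r.status == "ok"]
    if config.split_strategy == "scaffold":
        return scaffold_split(ok, config.test_fraction)
    if config.split_strategy == "butina":
        fm = featurize(ok, FeatureScheme("ecfp4", config.n_bits))
        return butina_split(ok, fm.X.to_numpy(), config.test_fraction,
                            config.butina_cutoff)
    return random_or_stratified_split(
        ok, config.test_fraction, config.seed,
        stratify=(config.split_strategy == "stratified"),
    )


def _external_metrics(task: str, y_true, y_pred, proba=None) -> dict:
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        mean_absolute_error,
        mean_squared_error,
        r2_score,
        roc_auc_score,
    )

    if task == "regression":
        return {
            "r2": float(r2_score(y_true, y_pred)),
            "rmse": float(np.sqrt(mean_squared_error(y_true, y_pred))),
            "mae": float(mean_absolute_error(y_true, y_pred)),
        }
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, average="macro")),
    }
    if proba is not None and len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, proba[:, 1]))
    return out


# ---------------------------------------------------------------------------
# descriptor-first evaluation

@dataclass
class OptimalDatasetResult:
    psi_star: str
    scheme_scores: ScoreMatrix  # one column per scheme (winning contender's blocks)
    per_scheme: dict  # scheme -> {"strategy", "model", "score_matrix": ScoreMatrix}
    records: list
    partition: Partition
    family: SplitFamily
    features: dict  # scheme -> FeatureMatrix over all ok records
    skipped: list


def optimal_dataset(config: PipelineConfig, outdir: str | Path | None = None) -> OptimalDatasetResult:
    """Descriptor-first loop: for every available scheme run
    preprocess -> feature selection -> model benchmarking on the shared
    split family; the scheme whose winner has the best mean oriented score
    becomes psi*.  The hyperparameter optimizer is deliberately not run at
    this stage."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, std_log = load_dataset(
        config.data_path, config.smiles_col, config.target_col,
        task=config.task, id_col=config.id_col,
    )
    std_log.to_csv(outdir / "standardization_log.csv", index=False)
    partition = _make_partition(config, records)
    partition.save(outdir / "split.csv", outdir / "split.json")

    ok = {r.id: r for r in records if r.status == "ok"}
    train_records = [ok[i] for i in partition.train_ids]
    metric = config.metric_obj()
    y_train = pd.Series([r.target for r in train_records],
                        index=[r.id for r in train_records])
    family = make_split_family(
        len(train_records), config.k, config.R, config.seed,
        stratified=(config.task == "classification"),
        labels=y_train.to_numpy() if config.task == "classification" else None,
    )
    registry = _registry(config)
    strategies = _strategies(config)
    canonical = registry.get(config.canonical_estimator) or _registry(
        dataclasses.replace(config, candidates=None)
    )[config.canonical_estimator]

    per_scheme: dict = {}
    features: dict = {}
    skipped: list = []
    scheme_cols: dict[str, pd.Series] = {}
    all_records = list(ok.values())
    for name in config.schemes:
        try:
            scheme = FeatureScheme(name, config.n_bits)
            fmat = featurize(all_records, scheme)
        except SchemeError as exc:
            skipped.append({"scheme": name, "reason": str(exc)})
            continue
        features[name] = fmat
        fmat.to_csv(outdir / f"features_{name}.csv")
        X_tr = fmat.X.loc[partition.train_ids]
        chain_factory = _chain_factory(config, scheme)

        from .resample import feature_select_stage

        strat_name, strat_sm = feature_select_stage(
            strategies, X_tr, y_train, family, metric, canonical, chain_factory,
        )
        strat_sm.to_csv(outdir / f"feature_selection_{name}.csv")
        winner_factory = strategies[strat_name]
        combined = lambda cf=chain_factory, wf=winner_factory: _ChainWithSelector(cf(), wf)  # noqa: E731
        model_sm = score_contenders(
            registry, X_tr, y_train, family, metric, combined,
        )
        model_sm.to_csv(outdir / f"model_development_{name}.csv")
        model_name = select_best(model_sm)
        per_scheme[name] = {
            "strategy": strat_name,
            "model": model_name,
            "score_matrix": model_sm,
        }
        scheme_cols[name] = model_sm.scores[model_name]
    if not per_scheme:
        raise SchemeError("no usable descriptor scheme (all skipped)")
    scheme_names = list(scheme_cols)
    scheme_scores = ScoreMatrix(
        scheme_names, metric, pd.DataFrame(scheme_cols)[scheme_names]
    )
    scheme_scores.to_csv(outdir / "scheme_scores.csv")
    psi_star = select_best(scheme_scores)
    if config.compare_schemes and len(scheme_names) > 1:
        assumptions, comp = compare(scheme_scores, plot_dir=outdir / "plots")
        comp.to_files(outdir / "scheme_comparison")
        with open(outdir / "scheme_assumptions.json", "w") as fh:
            json.dump(dataclasses.asdict(assumptions), fh, indent=2)
    with open(outdir / "optimal_dataset.json", "w") as fh:
        json.dump(
            {
                "psi_star": psi_star,
                "per_scheme": {
                    s: {"strategy": d["strategy"], "model": d["model"],
                        "mean_oriented": float(d["score_matrix"].block_means()[d["model"]])}
                    for s, d in per_scheme.items()
                },
                "skipped": skipped,
            },
            fh,
            indent=2,
        )
    return OptimalDatasetResult(
        psi_star, scheme_scores, per_scheme, records, partition, family,
        features, skipped,
    )


# ---------------------------------------------------------------------------
# bundle

@dataclass
class PipelineBundle:
    """Frozen fit-and-use artifact; every member is checksummed on save and
    verified on load."""

    scheme: FeatureScheme
    chain: PreprocessChain
    selector: _FrozenSelector
    estimator: object
    conformal: ConformalRegressor | ConformalClassifier | None
    ad_model: ADModel | None
    partition: Partition
    family_spec: dict
    config: dict
    manifest: dict = field(default_factory=dict)

    _MEMBERS = ("scheme", "chain", "selector", "estimator", "conformal",
                "ad_model", "partition", "family_spec")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        members: dict[str, bytes] = {
            f"{name}.pkl": pickle.dumps(getattr(self, name)) for name in self._MEMBERS
        }
        members["config.json"] = json.dumps(self.config, sort_keys=True).encode()
        checksums = {
            name: hashlib.sha256(blob).hexdigest() for name, blob in members.items()
        }
        import sklearn

        self.manifest = {
            "checksums": checksums,
            "versions": {
                "qsarkit": _pkg_version,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "seed": self.config.get("seed"),
            "timestamps": {"saved_at": pd.Timestamp.now().isoformat()},
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name, blob in members.items():
                zf.writestr(zipfile.ZipInfo(name), blob)
            zf.writestr(
                zipfile.ZipInfo("manifest.json"),
                json.dumps(self.manifest, indent=2, sort_keys=True).encode(),
            )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineBundle":
        path = Path(path)
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            blobs = {n: zf.read(n) for n in zf.namelist() if n != "manifest.json"}
        for name, blob in blobs.items():
            expect = manifest["checksums"].get(name)
            got = hashlib.sha256(blob).hexdigest()
            if expect != got:
                raise IntegrityError(
                    f"checksum mismatch for bundle member {name!r}"
                )
        missing = set(manifest["checksums"]) - set(blobs)
        if missing:
            raise IntegrityError(f"bundle members missing: {sorted(missing)}")
        parts = {name: pickle.loads(blobs[f"{name}.pkl"]) for name in cls._MEMBERS}
        return cls(
            config=json.loads(blobs["config.json"]), manifest=manifest, **parts
        )


def finalize(
    config: PipelineConfig,
    result: OptimalDatasetResult | None = None,
    outdir: str | Path | None = None,
    scheme: str | None = None,
) -> tuple[PipelineBundle, pd.DataFrame]:
    """Tune on psi*, refit on the full training set, calibrate conformal
    and AD layers, evaluate once on the external test set (dummy baseline
    always included), and archive the bundle.

    Returns the bundle and the external-validation table.
    """
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result is None:
        if scheme is None:
            raise ValueError("need optimal_dataset result or an explicit scheme")
        cfg_one = dataclasses.replace(config, schemes=(scheme,),
                                      compare_schemes=False)
        result = optimal_dataset(cfg_one, outdir)
    psi = scheme or result.psi_star
    fscheme = FeatureScheme(psi, config.n_bits)
    fmat = result.features[psi]
    partition = result.partition
    metric = config.metric_obj()
    X_tr = fmat.X.loc[partition.train_ids]
    y_tr = fmat.y.loc[partition.train_ids]

    registry = _registry(config)
    strategies = _strategies(config)
    strat_name = result.per_scheme[psi]["strategy"]
    chain_factory = _chain_factory(config, fscheme)
    combined_factory = lambda: _ChainWithSelector(chain_factory(), strategies[strat_name])  # noqa: E731

    spaces = default_search_spaces(config.task)
    if config.pre_gate_budget > 0:
        gate = tune(registry, spaces, X_tr, y_tr, result.family, metric,
                    budget=config.pre_gate_budget, seed=config.seed,
                    chain_factory=combined_factory)
        ranked = (
            gate.history.dropna(subset=["value"])
            .groupby("estimator")["value"].max().sort_values(ascending=False)
        )
        keep = list(ranked.index[: max(2, len(ranked) // 2)])
        registry = {k: v for k, v in registry.items() if k in keep or k == DUMMY_NAME}
    opt = tune(
        registry, spaces, X_tr, y_tr, result.family, metric,
        budget=config.budget, seed=config.seed, chain_factory=combined_factory,
    )
    opt.history.to_csv(outdir / "optimizer_history.csv", index=False)

    # final refit on all training rows
    from sklearn.base import clone

    final_tf = _ChainWithSelector(chain_factory(), strategies[strat_name])
    Xp, yp = final_tf.fit_transform(X_tr, y_tr)
    best_name = opt.best_config["estimator"]
    params = {k: v for k, v in opt.best_config.items() if k != "estimator"}
    estimator = clone(registry[best_name]).set_params(**params)
    estimator.fit(Xp.to_numpy(float), yp.to_numpy())

    if config.task == "regression":
        conf = cvplus_fit(clone(registry[best_name]).set_params(**params),
                          Xp, yp, k=min(config.k, len(yp)), seed=config.seed)
    else:
        conf = cvplus_fit_classifier(
            clone(registry[best_name]).set_params(**params),
            Xp, yp, k=min(config.k, len(yp)), seed=config.seed,
        )
    ad_model = ad_fit(
        Xp, config.ad_method,
        {"k": min(config.ad_k, len(Xp) - 1)}, config.ad_rate_of_outliers,
    )

    # external validation: evaluated exactly once, after finalization
    X_te = fmat.X.loc[partition.test_ids]
    y_te = fmat.y.loc[partition.test_ids]
    Xq, _ = final_tf.transform(X_te)
    rows = []
    dummy = clone(_registry(dataclasses.replace(config, candidates=None))[DUMMY_NAME])
    dummy.fit(Xp.to_numpy(float), yp.to_numpy())
    for label, est in ((best_name, estimator), (DUMMY_NAME, dummy)):
        pred = est.predict(Xq.to_numpy(float))
        proba = est.predict_proba(Xq.to_numpy(float)) if config.task != "regression" else None
        rows.append({"model": label,
                     **_external_metrics(config.task, y_te.to_numpy(), pred, proba)})
    external = pd.DataFrame(rows)
    external.to_csv(outdir / "external_validation.csv", index=False)

    bundle = PipelineBundle(
        scheme=fscheme,
        chain=final_tf.chain,
        selector=final_tf.frozen,
        estimator=estimator,
        conformal=conf,
        ad_model=ad_model,
        partition=partition,
        family_spec=result.family.spec(),
        config=config.as_dict(),
    )
    bundle.save(outdir / "bundle.zip")
    return bundle, external


# ---------------------------------------------------------------------------
# inference

def infer(bundle: PipelineBundle, smiles_list, alphas=None) -> pd.DataFrame:
    """Predict for raw SMILES with the frozen pipeline.

    Every input row appears in the output: rows that fail standardization
    carry their status and empty predictions; valid rows get the point
    prediction, conformal bounds/sets for each alpha, and AD score/flag.
    """
    from .chem import standardize

    alphas = list(alphas or bundle.config.get("conformal_alphas", (0.1,)))
    task = bundle.config.get("task", "regression")
    records = [standardize(s, id=str(i)) for i, s in enumerate(smiles_list)]
    base = pd.DataFrame(
        {
            "smiles": list(smiles_list),
            "smiles_canonical": [r.smiles_canonical for r in records],
            "status": [r.status for r in records],
        }
    )
    ok_idx = [i for i, r in enumerate(records) if r.status == "ok"]
    base["prediction"] = np.nan
    for a in alphas:
        if task == "regression":
            base[f"lower_{1 - a:g}"] = np.nan
            base[f"upper_{1 - a:g}"] = np.nan
        else:
            base[f"set_{1 - a:g}"] = None
            base[f"set_size_{1 - a:g}"] = np.nan
    base["ad_score"] = np.nan
    base["ad_flag"] = ""
    if not ok_idx:
        return base
    ok_records = [records[i] for i in ok_idx]
    fmat = featurize(ok_records, bundle.scheme)
    Xq, _ = bundle.chain.transform(fmat.X)
    Xq = bundle.selector.transform(Xq)
    arr = Xq.to_numpy(float)
    pos = base.index[ok_idx]
    if task == "regression":
        base.loc[pos, "prediction"] = bundle.estimator.predict(arr)
        for a in alphas:
            iv = predict_interval(bundle.conformal, Xq, a)
            base.loc[pos, f"lower_{1 - a:g}"] = iv["lower"].to_numpy()
            base.loc[pos, f"upper_{1 - a:g}"] = iv["upper"].to_numpy()
    else:
        base.loc[pos, "prediction"] = bundle.estimator.predict(arr)
        for a in alphas:
            ps = predict_set(bundle.conformal, Xq, a)
            base.loc[pos, f"set_{1 - a:g}"] = pd.Series(
                [",".join(map(str, s)) for s in ps["set"]], index=pos
            )
            base.loc[pos, f"set_size_{1 - a:g}"] = ps["set_size"].to_numpy()
    flags = ad_flag(bundle.ad_model, Xq)
    base.loc[pos, "ad_score"] = flags["ad_score"].to_numpy()
    base.loc[pos, "ad_flag"] = flags["ad_flag"].to_numpy()
    return base


# ---------------------------------------------------------------------------
# report

_ARTIFACTS = [
    ("Standardization log", "standardization_log.csv"),
    ("Split membership and seeds", ["split.csv", "split.json"]),
    ("Per-scheme cross-validation tables", "model_development_*.csv"),
    ("Scheme comparison", ["scheme_scores.csv", "scheme_comparison.omnibus.json"]),
    ("Optimizer history", "optimizer_history.csv"),
    ("External validation", "external_validation.csv"),
    ("Bundle", "bundle.zip"),
]


def report(run_dir: str | Path) -> str:
    """Write a human-readable summary (report.md) linking every artifact a
    completed run produces; missing stages are marked as gaps."""
    run_dir = Path(run_dir)
    lines = ["# Run report", ""]
    for title, patterns in _ARTIFACTS:
        if isinstance(patterns, str):
            patterns = [patterns]
        found: list[str] = []
        for pat in patterns:
            found.extend(sorted(p.name for p in run_dir.glob(pat)))
        if found:
            lines.append(f"- **{title}**: " + ", ".join(f"`{f}`" for f in found))
        else:
            lines.append(f"- **{title}**: _missing (stage skipped or incomplete)_")
    opt_json = run_dir / "optimal_dataset.json"
    if opt_json.exists():
        info = json.loads(opt_json.read_text())
        lines += ["", f"Selected scheme: `{info['psi_star']}`", ""]
        for s, d in info["per_scheme"].items():
            lines.append(
                f"- {s}: strategy `{d['strategy']}`, model `{d['model']}`, "
                f"mean oriented score {d['mean_oriented']:.4f}"
            )
    ext = run_dir / "external_validation.csv"
    if ext.exists():
        lines += ["", "## External validation", "", pd.read_csv(ext).to_string(index=False)]
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
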