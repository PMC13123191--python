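"""Split families, paired scoring, selection cascade and TPE tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression, Ridge

from qsarkit.models import regression_registry, selection_strategies
from qsarkit.resample import (
    ConfigurationError,
    METRICS,
    feature_select_stage,
    make_split_family,
    score_contenders,
    select_best,
)
from qsarkit.tuning import Categorical, Float, TPESampler, tune


def _linear_data(n=40, p=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    y = pd.Series(X.iloc[:, 0] * 2.0 + rng.normal(0, noise, n))
    return X, y


class TestSplitFamily:
    def test_validation_folds_partition_the_sample_set(self):
        fam = make_split_family(10, k=5, R=1, seed=0)
        assert fam.n_blocks == 5
        vals = np.concatenate([va for _, va in fam.blocks])
        assert sorted(vals) == list(range(10))
        assert all(len(va) == 2 for _, va in fam.blocks)

    def test_default_shape_is_25_blocks(self):
        fam = make_split_family(50)
        assert (fam.k, fam.R, fam.n_blocks) == (5, 5, 25)

    def test_regeneration_is_bit_identical(self):
        a = make_split_family(30, 5, 3, seed=7)
        b = make_split_family(30, 5, 3, seed=7)
        for (ta, va), (tb, vb) in zip(a.blocks, b.blocks):
            assert (ta == tb).all() and (va == vb).all()

    def test_stratified_preserves_fold_class_proportions(self):
        labels = np.array([0] * 20 + [1] * 10)
        fam = make_split_family(30, 3, 1, seed=1, stratified=True, labels=labels)
        for _, va in fam.blocks:
            assert np.isclose((labels[va] == 1).mean(), 1 / 3, atol=0.1)

    def test_k_larger_than_n_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            make_split_family(3, k=5)


class TestScoring:
    def test_noise_free_linear_fit_scores_zero_rmse_everywhere(self):
        X, y = _linear_data()
        fam = make_split_family(len(y), 4, 1, seed=0)
        sm = score_contenders({"lin": LinearRegression()}, X, y, fam, "rmse")
        assert (sm.scores["lin"] < 1e-10).all()

    def test_train_mean_predictor_has_nonpositive_heldout_r2(self):
        X, y = _linear_data(noise=1.0)
        fam = make_split_family(len(y), 4, 2, seed=0)
        sm = score_contenders({"dummy": DummyRegressor()}, X, y, fam, "r2")
        assert (sm.scores["dummy"] <= 1e-12).all()

    def test_all_contenders_share_the_same_blocks(self):
        X, y = _linear_data()
        fam = make_split_family(len(y), 5, 5, seed=3)
        sm = score_contenders(
            {"lin": LinearRegression(), "dummy": DummyRegressor()}, X, y, fam, "r2"
        )
        assert sm.scores.shape == (25, 2)
        assert sm.scores.notna().all().all()

    def test_failing_contender_records_missing_scores(self):
        class Exploder:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                raise RuntimeError("boom")

        X, y = _linear_data()
        fam = make_split_family(len(y), 3, 1, seed=0)
        log = []
        sm = score_contenders(
            {"bad": Exploder(), "lin": LinearRegression()}, X, y, fam, "r2",
            fail_log=log,
        )
        assert sm.scores["bad"].isna().all()
        assert sm.scores["lin"].notna().all()
        assert len(log) == 3

    def test_score_matrix_csv_round_trip(self, tmp_path, sm_factory):
        sm = sm_factory(np.random.default_rng(0).normal(size=(6, 3)), "rmse")
        sm.to_csv(tmp_path / "s.csv")
        from qsarkit.resample import ScoreMatrix

        back = ScoreMatrix.from_csv(tmp_path / "s.csv")
        assert back.metric.name == "rmse"
        assert np.allclose(back.scores.to_numpy(), sm.scores.to_numpy())


class TestSelectBest:
    def test_single_contender_returns_itself(self, sm_factory):
        assert select_best(sm_factory(np.ones((3, 1)))) == "h0"

    def test_loss_orientation_prefers_smaller_mean(self, sm_factory):
        sm = sm_factory(np.array([[0.5, 0.7]] * 4), "rmse", ["a", "b"])
        assert select_best(sm) == "a"

    def test_exact_tie_resolved_by_declaration_order_and_logged(self, sm_factory):
        sm = sm_factory(np.ones((4, 2)), "r2", ["first", "second"])
        log = []
        assert select_best(sm, tie_log=log) == "first"
        assert log and log[0]["tie_between"] == ["first", "second"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed, sm_factory):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(8, 4))
        metric = ["r2", "rmse"][seed % 2]
        sm = sm_factory(arr, metric)
        sign = METRICS[metric].orientation
        expect = f"h{int(np.argmax(sign * arr.mean(axis=0)))}"
        assert select_best(sm) == expect


class TestFeatureSelectStage:
    def test_embedded_selection_beats_baseline_on_sparse_signal(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 51)),
                         columns=[f"x{i}" for i in range(51)])
        y = pd.Series(3.0 * X["x0"])  # one informative, 50 noise columns
        fam = make_split_family(30, 3, 2, seed=0)
        strategies = selection_strategies("regression", seed=0,
                                          subset=["none", "embedded_linear"])
        winner, sm = feature_select_stage(
            strategies, X, y, fam, "r2", LinearRegression()
        )
        means = sm.block_means()
        assert means["embedded_linear"] >= means["none"] - 1e-9
        assert winner == "embedded_linear"

    def test_zero_feature_strategy_fails_blocks_not_the_run(self):
        class NullSelector:
            def fit(self, X, y):
                return self

            def get_support(self):
                return np.zeros(3, dtype=bool)

        X, y = _linear_data()
        fam = make_split_family(len(y), 3, 1, seed=0)
        winner, sm = feature_select_stage(
            {"none": lambda: None, "null": lambda: NullSelector()},
            X, y, fam, "r2", LinearRegression(),
        )
        assert sm.scores["null"].isna().all()
        assert winner == "none"


class TestTune:
    def _setup(self, n=40):
        X, y = _linear_data(n=n, noise=0.2)
        fam = make_split_family(n, 3, 1, seed=0)
        cands = regression_registry(seed=0, subset=["ridge", "knn"])
        spaces = {"ridge": {}, "knn": {"n_neighbors": (None,)}}
        from qsarkit.tuning import Int

        spaces["knn"] = {"n_neighbors": Int(1, 15)}
        return X, y, fam, cands, spaces

    def test_budget_one_returns_the_single_evaluated_config(self):
        X, y, fam, cands, spaces = self._setup()
        res = tune(cands, spaces, X, y, fam, "r2", budget=1, seed=5)
        assert len(res.history) == 1
        assert res.best_config["estimator"] == res.history["estimator"].iloc[0]

    def test_same_seed_and_budget_reproduce_the_best_config(self):
        X, y, fam, cands, spaces = self._setup()
        a = tune(cands, spaces, X, y, fam, "r2", budget=8, seed=7)
        b = tune(cands, spaces, X, y, fam, "r2", budget=8, seed=7)
        assert a.best_config == b.best_config
        assert a.best_score == b.best_score
        pd.testing.assert_frame_equal(a.history, b.history)

    def test_best_score_is_the_maximum_of_the_history(self):
        X, y, fam, cands, spaces = self._setup()
        res = tune(cands, spaces, X, y, fam, "r2", budget=10, seed=1)
        assert res.best_score == pytest.approx(res.history["value"].max())

    def test_tpe_sampler_concentrates_on_the_good_region(self):
        # 1-d quadratic objective: after warmup, proposals should cluster
        # near the optimum at 0.3 more tightly than uniform draws
        sampler = TPESampler(seed=0, n_startup=8)
        space = {"x": Float(0.0, 1.0)}
        trials = []
        for _ in range(60):
            params = sampler.suggest(space, trials)
            trials.append((params, -(params["x"] - 0.3) ** 2))
        late = np.array([p["x"] for p, _ in trials[40:]])
        assert np.median(np.abs(late - 0.3)) < 0.15
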