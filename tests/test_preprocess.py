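"""Leakage-free preprocessing chain behavior.

The IQR worked example used throughout: column [1..9, 100] with
linear-interpolated quartiles gives Q1=3.25, Q3=7.75, IQR=4.5 and Tukey
fences [-3.5, 14.5]; 100 is the single outlier.
"""

import pickle

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarkit.preprocess import (
    ConfigurationError,
    DuplicateHandler,
    EmptyMatrixError,
    KBinHandler,
    LowVarianceHandler,
    MissingHandler,
    MultivariateOutlierHandler,
    NotFittedError,
    PreprocessChain,
    Scaler,
    UnivariateOutlierHandler,
    iqr_fences,
)

IQR_COL = list(range(1, 10)) + [100]


def df(data, **kw):
    return pd.DataFrame(data, **kw)


def target(n):
    return pd.Series(np.arange(n, dtype=float))


class TestDuplicate:
    def test_mean_policy_merges_identical_rows(self):
        X = df({"a": [1.0, 1.0, 2.0]})
        y = pd.Series([1.0, 3.0, 5.0])
        Xo, yo = DuplicateHandler("mean").fit_transform(X, y)
        assert len(Xo) == 2
        assert yo.iloc[0] == 2.0

    def test_no_duplicates_is_identity(self):
        X = df({"a": [1.0, 2.0, 3.0]})
        y = target(3)
        Xo, yo = DuplicateHandler("median").fit_transform(X, y)
        assert Xo.equals(X) and yo.equals(y)

    def test_consensus_drops_conflicting_label_groups(self):
        X = df({"a": [1.0, 1.0, 1.0, 2.0]})
        y = pd.Series([0, 0, 1, 1])
        h = DuplicateHandler("consensus")
        Xo, yo = h.fit_transform(X, y)
        assert len(Xo) == 1 and Xo["a"].iloc[0] == 2.0
        assert any(e["action"] == "dropped_conflicting_group" for e in h.log)

    def test_transform_on_new_data_preserves_rows(self):
        h = DuplicateHandler("mean")
        h.fit_transform(df({"a": [1.0, 1.0]}), pd.Series([0.0, 2.0]))
        Xq = df({"a": [5.0, 5.0]})
        Xo, _ = h.transform(Xq)
        assert len(Xo) == 2


class TestMissing:
    def test_column_above_threshold_is_dropped(self):
        X = df({"half": [1.0, np.nan, 2.0, np.nan], "full": [1.0, 2, 3, 4]})
        h = MissingHandler(drop_threshold=0.4)
        Xo, _ = h.fit_transform(X, target(4))
        assert list(Xo.columns) == ["full"]

    def test_mean_imputation_uses_training_statistics(self):
        Xtr = df({"a": [1.0, 2.0, 3.0]})
        h = MissingHandler(impute="mean").fit(Xtr, target(3))
        Xq, _ = h.transform(df({"a": [np.nan]}))
        assert Xq["a"].iloc[0] == 2.0

    def test_no_missing_values_is_identity(self):
        X = df({"a": [1.0, 2.0]})
        Xo, _ = MissingHandler().fit_transform(X, target(2))
        assert Xo.equals(X)

    def test_all_columns_dropped_is_an_error(self):
        X = df({"a": [np.nan, np.nan, 1.0]})
        with pytest.raises(EmptyMatrixError):
            MissingHandler(drop_threshold=0.4).fit(X, target(3))


class TestLowVariance:
    def test_constant_column_removed_at_zero_threshold(self):
        X = df({"c": [7.0, 7.0, 7.0], "v": [1.0, 2.0, 3.0]})
        Xo, _ = LowVarianceHandler(0.0).fit_transform(X, target(3))
        assert list(Xo.columns) == ["v"]

    def test_balanced_binary_column_survives_small_threshold(self):
        X = df({"b": [0.0, 1.0, 0.0, 1.0]})  # population variance 0.25
        Xo, _ = LowVarianceHandler(0.1).fit_transform(X, target(4))
        assert list(Xo.columns) == ["b"]

    def test_all_constant_is_an_error(self):
        with pytest.raises(EmptyMatrixError):
            LowVarianceHandler(0.0).fit(df({"c": [1.0, 1.0]}), target(2))


class TestUnivariateOutliers:
    def test_fences_match_hand_computation(self):
        lo, hi = iqr_fences(pd.Series(IQR_COL, dtype=float))
        assert lo == pytest.approx(-3.5)
        assert hi == pytest.approx(14.5)

    def test_winsorize_caps_at_the_upper_fence(self):
        X = df({"a": IQR_COL}, dtype=float)
        h = UnivariateOutlierHandler("winsorize")
        Xo, _ = h.fit_transform(X, target(10))
        assert Xo["a"].max() == pytest.approx(14.5)
        assert (Xo["a"] >= -3.5).all() and (Xo["a"] <= 14.5).all()

    def test_all_equal_column_flags_nothing(self):
        X = df({"a": [5.0] * 6})
        h = UnivariateOutlierHandler("remove_rows")
        Xo, _ = h.fit_transform(X, target(6))
        assert len(Xo) == 6

    def test_remove_rows_drops_training_outliers_only(self):
        X = df({"a": IQR_COL}, dtype=float)
        h = UnivariateOutlierHandler("remove_rows")
        Xo, _ = h.fit_transform(X, target(10))
        assert len(Xo) == 9 and 100.0 not in Xo["a"].values
        Xq, _ = h.transform(df({"a": [200.0]}))  # test rows never removed
        assert len(Xq) == 1 and Xq["a"].iloc[0] == 200.0

    def test_to_nan_impute_replaces_outlier_with_inlier_mean(self):
        X = df({"a": IQR_COL}, dtype=float)
        h = UnivariateOutlierHandler("to_nan_impute")
        Xo, _ = h.fit_transform(X, target(10))
        assert Xo["a"].iloc[-1] == pytest.approx(5.0)  # mean of 1..9

    def test_unknown_method_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            UnivariateOutlierHandler("clip_to_zero")

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=5,
            max_size=40,
        )
    )
    def test_winsorized_outputs_always_inside_fences(self, values):
        X = df({"a": values}, dtype=float)
        h = UnivariateOutlierHandler("winsorize")
        Xo, _ = h.fit_transform(X, target(len(values)))
        lo, hi = h.fitted_params["fences"]["a"]
        assert ((Xo["a"] >= lo - 1e-9) & (Xo["a"] <= hi + 1e-9)).all()


class TestMultivariateOutliers:
    def test_lof_removes_the_gross_outlier(self):
        rng = np.random.default_rng(0)
        X = df(rng.normal(0, 1, size=(20, 2)), columns=["x", "y"])
        X.loc[20] = [50.0, 50.0]
        h = MultivariateOutlierHandler("lof", contamination=0.05, n_neighbors=5)
        Xo, _ = h.fit_transform(X, target(21))
        assert "20" in h.fitted_params["removed_train_ids"]

    def test_test_rows_are_never_removed(self):
        rng = np.random.default_rng(1)
        X = df(rng.normal(size=(30, 2)))
        h = MultivariateOutlierHandler("isolation_forest", 0.1)
        h.fit_transform(X, target(30))
        Xq = df(np.full((3, 2), 100.0))
        Xo, _ = h.transform(Xq)
        assert len(Xo) == 3

    def test_contamination_validation_and_usage_before_fit(self):
        with pytest.raises(ConfigurationError):
            MultivariateOutlierHandler("lof", contamination=0.9)
        with pytest.raises(NotFittedError):
            MultivariateOutlierHandler("lof", 0.1).transform(df({"a": [1.0]}))


class TestScaler:
    def test_minmax_maps_training_range_and_extrapolates(self):
        h = Scaler("minmax").fit(df({"a": [0.0, 5.0, 10.0]}), target(3))
        Xo, _ = h.transform(df({"a": [0.0, 5.0, 10.0, 20.0]}))
        assert list(Xo["a"]) == pytest.approx([0.0, 0.5, 1.0, 2.0])

    def test_standard_scaling_centers_training_data(self):
        X = df({"a": [1.0, 2.0, 3.0, 4.0]})
        h = Scaler("standard")
        Xo, _ = h.fit_transform(X, target(4))
        assert Xo["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert Xo["a"].std(ddof=0) == pytest.approx(1.0)

    def test_robust_scaling_uses_median_and_iqr(self):
        X = df({"a": IQR_COL}, dtype=float)
        h = Scaler("robust")
        Xo, _ = h.fit_transform(X, target(10))
        # center 5.5, scale 4.5 -> value 1 maps to -1.0
        assert Xo["a"].iloc[0] == pytest.approx(-1.0)

    def test_zero_range_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-range"):
            h = Scaler("minmax").fit(df({"a": [3.0, 3.0]}), target(2))
        Xo, _ = h.transform(df({"a": [3.0]}))
        assert Xo["a"].iloc[0] == 0.0


class TestKBin:
    def test_quantile_bins_are_ordinal(self):
        X = df({"a": np.arange(20.0)})
        h = KBinHandler(n_bins=5)
        Xo, _ = h.fit_transform(X, target(20))
        assert set(Xo["a"]) == {0.0, 1.0, 2.0, 3.0, 4.0}


class TestChain:
    def _chain(self):
        return PreprocessChain(
            [
                DuplicateHandler("mean"),
                MissingHandler(),
                LowVarianceHandler(),
                UnivariateOutlierHandler("winsorize"),
                Scaler("standard"),
            ]
        )

    def _data(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = df(rng.normal(size=(n, 4)), columns=list("abcd"))
        X["const"] = 1.0
        return X, pd.Series(rng.normal(size=n))

    def test_scaling_must_be_last(self):
        with pytest.raises(ConfigurationError):
            PreprocessChain([Scaler("standard"), LowVarianceHandler()])

    def test_chain_equals_sequential_application(self):
        X, y = self._data()
        chain = self._chain()
        Xc, yc = chain.fit_transform(X.copy(), y.copy())
        Xs, ys = X.copy(), y.copy()
        for h in self._chain().handlers:
            Xs, ys = h.fit_transform(Xs, ys)
        pd.testing.assert_frame_equal(Xc, Xs)
        pd.testing.assert_series_equal(yc, ys)

    def test_fitted_state_is_independent_of_test_rows(self):
        X, y = self._data()
        chain_a, chain_b = self._chain(), self._chain()
        chain_a.fit_transform(X.copy(), y.copy())
        chain_b.fit_transform(X.copy(), y.copy())
        # arbitrary perturbation of "test" data touches nothing fitted
        Xq = X.copy() * 1e6 + 123.0
        chain_b.transform(Xq)
        assert chain_a.fitted_state() == chain_b.fitted_state()

    def test_serialization_round_trip_gives_identical_transforms(self):
        X, y = self._data(seed=3)
        chain = self._chain()
        chain.fit_transform(X, y)
        Xq, _ = self._data(seed=9)
        before, _ = chain.transform(Xq)
        revived = pickle.loads(pickle.dumps(chain))
        after, _ = revived.transform(Xq)
        pd.testing.assert_frame_equal(before, after)

    def test_fit_log_records_dropped_columns(self):
        X, y = self._data()
        chain = self._chain()
        chain.fit_transform(X, y)
        assert any(
            e["step"] == "low_variance" and "const" in e["columns"]
            for e in chain.fit_log
        )
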