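"""The paired comparison cascade against independent oracles.

Direct-formula oracles are coded here (one-way ANOVA on absolute
deviations for Levene, explicit sum-of-squares decomposition for the
repeated-measures ANOVA, rank-sum formulas for Friedman) so the
implementation and the check never share code paths; scipy/statsmodels
serve as additional independent references.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from qsarkit.stats import (
    average_percentile_ranks,
    compare,
    conover_posthoc,
    friedman,
    holm_adjust,
    levene,
    rm_anova,
    tukey_hsd,
)


# ---------------------------------------------------------------------------
# independent oracles

def oracle_levene(groups):
    """One-way ANOVA on absolute deviations from group means."""
    dev = [np.abs(g - g.mean()) for g in groups]
    k = len(dev)
    N = sum(len(d) for d in dev)
    grand = np.concatenate(dev).mean()
    ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in dev)
    ssw = sum(((d - d.mean()) ** 2).sum() for d in dev)
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return F, ss.f.sf(F, k - 1, N - k)


def oracle_rm_anova(arr):
    """Explicit two-way decomposition, subject = block."""
    n, q = arr.shape
    grand = arr.mean()
    ss_treat = n * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_subj = q * ((arr.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((arr - grand) ** 2).sum() - ss_treat - ss_subj
    F = (ss_treat / (q - 1)) / (ss_err / ((q - 1) * (n - 1)))
    return F, ss.f.sf(F, q - 1, (q - 1) * (n - 1))


def oracle_friedman(arr):
    """Tie-corrected Friedman chi-square from within-block ranks."""
    n, q = arr.shape
    ranks = np.vstack([ss.rankdata(row) for row in arr])
    R = ranks.sum(axis=0)
    A1 = (ranks**2).sum()
    C1 = n * q * (q + 1) ** 2 / 4
    chi2 = (q - 1) * ((R - n * (q + 1) / 2) ** 2).sum() / (A1 - C1)
    return chi2, ss.chi2.sf(chi2, q - 1)


# ---------------------------------------------------------------------------

class TestWorkedCases:
    def test_rm_anova_3x2_matrix(self, sm_factory):
        sm = sm_factory(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]]))
        res = rm_anova(sm)
        assert res.F == pytest.approx(3.0)
        assert (res.df_treat, res.df_err) == (1, 2)

    def test_friedman_consistent_ranks_over_4_blocks(self, sm_factory):
        sm = sm_factory(np.tile([1.0, 2.0, 3.0], (4, 1)))
        res = friedman(sm)
        assert res.chi2 == pytest.approx(8.0)
        assert res.dof == 2

    def test_holm_stepdown_worked_example(self):
        assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])

    def test_levene_two_group_hand_case(self, sm_factory):
        g1 = np.array([0.0, 0.0, 10.0, 10.0])
        g2 = np.array([4.0, 5.0, 5.0, 6.0])
        sm = sm_factory(np.column_stack([g1, g2]))
        F, p = levene(sm)
        F_expect, p_expect = oracle_levene([g1, g2])
        assert F == pytest.approx(F_expect, abs=1e-10)
        assert p == pytest.approx(p_expect, abs=1e-10)


class TestDegenerateLimits:
    def test_identical_columns_are_null_everywhere(self, sm_factory):
        sm = sm_factory(np.tile([[1.0], [2.0], [3.0]], (1, 3)))
        assert levene(sm) == (0.0, 1.0)
        res = rm_anova(sm)
        assert (res.F, res.p) == (0.0, 1.0)
        fr = friedman(sm)
        assert (fr.chi2, fr.p) == (0.0, 1.0)
        tk = tukey_hsd(sm)
        assert (tk["adj_p"] == 1.0).all()
        assert ((tk["ci_low"] <= 0) & (tk["ci_high"] >= 0)).all()

    def test_constant_offset_columns_trip_the_degeneracy_flag(self, sm_factory):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        sm = sm_factory(np.column_stack([base, base + 1.0]))
        res = rm_anova(sm)
        assert res.degenerate and res.p == 0.0

    def test_conover_identical_rank_sums_give_unit_p(self, sm_factory):
        sm = sm_factory(np.tile([[1.0], [2.0], [3.0]], (1, 2)))
        out = conover_posthoc(sm)
        assert out["statistic"].iloc[0] == 0.0
        assert out["adj_p"].iloc[0] == 1.0

    def test_single_pair_holm_is_identity(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_levene_rm_anova_friedman_match_direct_formulas(self, seed, sm_factory):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(25, 4))
        sm = sm_factory(arr)
        F, p = levene(sm)
        Fo, po = oracle_levene([arr[:, j] for j in range(4)])
        assert F == pytest.approx(Fo, abs=1e-10)
        res = rm_anova(sm)
        Fo, po = oracle_rm_anova(arr)
        assert res.F == pytest.approx(Fo, abs=1e-10)
        assert res.p == pytest.approx(po, abs=1e-10)
        fr = friedman(sm)
        c_o, p_o = oracle_friedman(arr)
        assert fr.chi2 == pytest.approx(c_o, abs=1e-10)
        assert fr.p == pytest.approx(p_o, abs=1e-10)

    def test_friedman_matches_scipy_with_ties(self, sm_factory):
        rng = np.random.default_rng(3)
        arr = np.round(rng.normal(size=(20, 4)), 1)  # induces rank ties
        fr = friedman(sm_factory(arr))
        chi2, p = ss.friedmanchisquare(*[arr[:, j] for j in range(4)])
        assert fr.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_rm_anova_matches_statsmodels(self, sm_factory):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        arr = rng.normal(size=(12, 3))
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 3),
                "cond": np.tile(["a", "b", "c"], 12),
                "y": arr.ravel(),
            }
        )
        expected = AnovaRM(long, "y", "subj", within=["cond"]).fit()
        res = rm_anova(sm_factory(arr))
        assert res.F == pytest.approx(expected.anova_table["F Value"].iloc[0],
                                      abs=1e-8)

    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=8)
        assert holm_adjust(p) == pytest.approx(
            multipletests(p, method="holm")[1], abs=1e-12
        )

    def test_two_contender_tukey_reduces_to_paired_t(self, sm_factory):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(15, 2))
        tk = tukey_hsd(sm_factory(arr))
        t, p = ss.ttest_rel(arr[:, 0], arr[:, 1])
        assert tk["adj_p"].iloc[0] == pytest.approx(p, abs=1e-9)


class TestRanksAndOrientation:
    def test_everywhere_best_contender_has_unit_mean_percentile(self, sm_factory):
        arr = np.column_stack([np.full(6, 3.0), np.full(6, 2.0), np.full(6, 1.0)])
        r = average_percentile_ranks(sm_factory(arr))
        assert r["h0"] == 1.0 and r["h2"] == 0.0

    def test_fully_tied_pair_shares_the_midpoint(self, sm_factory):
        r = average_percentile_ranks(sm_factory(np.ones((5, 2))))
        assert (r == 0.5).all()

    def test_known_rank_table_hand_enumeration(self, sm_factory):
        arr = np.array([[3.0, 2.0, 1.0], [1.0, 3.0, 2.0], [3.0, 2.0, 1.0]])
        r = average_percentile_ranks(sm_factory(arr))
        # per-block percentiles h0: 1, 0, 1; h1: .5, 1, .5; h2: 0, .5, 0
        assert r.to_numpy() == pytest.approx([2 / 3, 2 / 3, 1 / 6])

    def test_orientation_flip_leaves_the_report_invariant(self, sm_factory):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(20, 3)) * 0.2 + np.array([0.0, 0.5, 1.0])
        loss = sm_factory(arr, "rmse")
        gain = sm_factory(-arr, "r2")
        a_l, rep_l = compare(loss)
        a_g, rep_g = compare(gain)
        assert a_l.levene_F == pytest.approx(a_g.levene_F)
        assert rep_l.omnibus_statistic == pytest.approx(rep_g.omnibus_statistic)
        pd.testing.assert_series_equal(rep_l.average_ranks, rep_g.average_ranks)
        assert rep_l.pairwise["adj_p"].to_numpy() == pytest.approx(
            rep_g.pairwise["adj_p"].to_numpy()
        )

    def test_column_permutation_leaves_friedman_invariant(self, sm_factory):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(10, 4))
        a = friedman(sm_factory(arr))
        b = friedman(sm_factory(arr[:, ::-1]))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)


class TestHolmProperties:
    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-8, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_adjusted_p_dominates_raw_and_is_monotone(self, pvals):
        p = np.array(pvals)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCascade:
    def test_heteroscedastic_scores_choose_the_nonparametric_branch(self):
        from qsarkit.fixtures import gen_score_matrix

        sm = gen_score_matrix(25, ["a", "b", "c"], [0.5, 0.5, 0.5],
                              hetero=True, seed=0)
        assumptions, rep = compare(sm)
        assert assumptions.decision == "nonparametric"
        assert rep.omnibus_test == "friedman"

    def test_homoscedastic_gaussian_scores_choose_the_parametric_branch(self):
        from qsarkit.fixtures import gen_score_matrix

        sm = gen_score_matrix(25, ["a", "b", "c"], [0.3, 0.5, 0.7],
                              noise_sd=0.05, seed=1)
        assumptions, rep = compare(sm)
        assert assumptions.decision == "parametric"
        assert rep.omnibus_test == "rm_anova"
        assert rep.rejected and {"ci_low", "ci_high"} <= set(rep.pairwise.columns)

    def test_identical_columns_stop_at_the_omnibus(self, sm_factory):
        sm = sm_factory(np.tile([[0.1], [0.2], [0.3], [0.4]], (1, 3)))
        assumptions, rep = compare(sm)
        assert not rep.rejected
        assert rep.pairwise["adj_p"].isna().all()
        assert (rep.pairwise["note"] == "omnibus n.s.").all()

    def test_pairwise_table_covers_every_pair(self, sm_factory):
        rng = np.random.default_rng(11)
        sm = sm_factory(rng.normal(size=(15, 5)))
        _, rep = compare(sm)
        assert len(rep.pairwise) == 10
        assert rep.significance.shape == (5, 5)
        pd.testing.assert_frame_equal(rep.significance, rep.significance.T)

    def test_plot_artifacts_are_written(self, sm_factory, tmp_path):
        from qsarkit.fixtures import gen_score_matrix

        sm = gen_score_matrix(20, ["a", "b", "c"], [0.1, 0.5, 0.9], seed=2)
        compare(sm, plot_dir=tmp_path)
        assert (tmp_path / "significance_heatmap.svg").exists()
        assert any(tmp_path.glob("*.svg"))
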