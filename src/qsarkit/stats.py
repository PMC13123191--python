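"""Paired statistical comparison of contenders over a shared block family.

The cascade mirrors standard repeated-measures practice: assumption checks
(variance-ratio + Levene) decide between the parametric branch
(repeated-measures ANOVA with contender as within-subject factor and the
CV block as subject, followed by Tukey HSD) and the nonparametric branch
(Friedman on within-block ranks, followed by Conover-Iman pairwise tests
with Holm step-down correction).  All tests consume oriented scores, so a
loss metric and its negated gain twin produce identical reports.

Ranks use average-rank tie handling; the Friedman statistic carries the
standard tie correction.  For q contenders and n pairwise-complete blocks:

    chi2_F = (q - 1) * sum_j (R_j - n(q+1)/2)^2 / (A1 - C1),

with A1 the sum of squared within-block ranks and C1 = n q (q+1)^2 / 4 —
algebraically equal to the classic 12/(nq(q+1)) * sum R_j^2 - 3n(q+1) form
divided by the tie-correction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as ss

from .resample import ScoreMatrix

__all__ = [
    "AssumptionReport",
    "ComparisonReport",
    "levene",
    "rm_anova",
    "tukey_hsd",
    "friedman",
    "conover_posthoc",
    "holm_adjust",
    "average_percentile_ranks",
    "compare",
]

_EPS = 1e-12


class InsufficientDataError(ValueError):
    pass


def _oriented(sm: ScoreMatrix) -> pd.DataFrame:
    ori = sm.complete_blocks() * sm.metric.orientation
    return ori


@dataclass
class AssumptionReport:
    levene_F: float
    levene_p: float
    variance_ratio: float
    normality_flag: str  # pass | fail | visual_only
    decision: str  # parametric | nonparametric
    alpha_assume: float


@dataclass
class RMAnovaResult:
    F: float
    p: float
    df_treat: int
    df_err: int
    ms_error: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.F, self.p))


@dataclass
class FriedmanResult:
    chi2: float
    dof: int
    p: float

    def __iter__(self):
        return iter((self.chi2, self.dof, self.p))


@dataclass
class ComparisonReport:
    omnibus_test: str
    omnibus_statistic: float
    omnibus_dof: tuple
    omnibus_p: float
    rejected: bool
    pairwise: pd.DataFrame  # pair, diff, raw_p, adj_p, significant (+CI cols)
    average_ranks: pd.Series
    significance: pd.DataFrame  # symmetric boolean matrix

    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.pairwise.to_csv(prefix.with_suffix(".pairwise.csv"), index=False)
        import json

        with open(prefix.with_suffix(".omnibus.json"), "w") as fh:
            json.dump(
                {
                    "test": self.omnibus_test,
                    "statistic": self.omnibus_statistic,
                    "dof": list(self.omnibus_dof),
                    "p": self.omnibus_p,
                    "rejected": bool(self.rejected),
                    "average_ranks": self.average_ranks.to_dict(),
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# individual tests

def levene(sm: ScoreMatrix, center: str = "mean") -> tuple[float, float]:
    """Classic (mean-centered) Levene test for equal variances across
    contender score groups."""
    data = _oriented(sm)
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise InsufficientDataError("need >=2 contenders and >=2 blocks")
    cols = [data[c].to_numpy(float) for c in data.columns]
    center_fn = np.mean if center == "mean" else np.median
    all_dev = np.concatenate([np.abs(c - center_fn(c)) for c in cols])
    if np.ptp(all_dev) < _EPS:
        return 0.0, 1.0  # every deviation identical -> no spread to compare
    F, p = ss.levene(*cols, center=center)
    return float(F), float(p)


def variance_ratio(sm: ScoreMatrix) -> float:
    v = _oriented(sm).var(axis=0, ddof=1)
    vmin = float(v.min())
    return float(v.max() / vmin) if vmin > 0 else np.inf


def rm_anova(sm: ScoreMatrix) -> RMAnovaResult:
    """One-way repeated-measures ANOVA: contender within-subject, block as
    subject.  F = MS_treat / MS_error, dof (q-1, (q-1)(n-1))."""
    data = _oriented(sm).to_numpy(float)
    n, q = data.shape
    if q < 2 or n < 2:
        raise InsufficientDataError("need >=2 contenders and >=2 blocks")
    grand = data.mean()
    ss_treat = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = q * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = max(ss_total - ss_treat - ss_subj, 0.0)
    df_treat, df_err = q - 1, (q - 1) * (n - 1)
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    if ms_err <= _EPS * max(ms_treat, 1.0):
        if ms_treat <= _EPS:
            return RMAnovaResult(0.0, 1.0, df_treat, df_err, 0.0)
        # zero error variance with a nonzero treatment effect
        return RMAnovaResult(np.inf, 0.0, df_treat, df_err, 0.0, degenerate=True)
    F = ms_treat / ms_err
    p = float(ss.f.sf(F, df_treat, df_err))
    return RMAnovaResult(float(F), p, df_treat, df_err, float(ms_err))


def tukey_hsd(sm: ScoreMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise table on block means, using MS_error and its dof
    from the repeated-measures decomposition (studentized-range based
    simultaneous CIs and adjusted p-values)."""
    data = _oriented(sm)
    n, q = data.shape
    res = rm_anova(sm)
    means = data.mean(axis=0)
    se = np.sqrt(res.ms_error / n)
    rows = []
    names = list(data.columns)
    for a_i in range(q):
        for b_i in range(a_i + 1, q):
            a, b = names[a_i], names[b_i]
            diff = float(means[a] - means[b])
            if se <= _EPS:
                p_adj = 1.0 if abs(diff) <= _EPS else 0.0
                half = 0.0
            else:
                q_stat = abs(diff) / se
                p_adj = float(ss.studentized_range.sf(q_stat, q, res.df_err))
                q_crit = float(ss.studentized_range.ppf(1 - alpha, q, res.df_err))
                half = q_crit * se
            rows.append(
                {
                    "contender_a": a,
                    "contender_b": b,
                    "diff": diff,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                    "adj_p": min(1.0, p_adj),
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def _block_ranks(sm: ScoreMatrix) -> pd.DataFrame:
    """Within-block average ranks of oriented scores (higher score = higher
    rank)."""
    return _oriented(sm).rank(axis=1, method="average")


def friedman(sm: ScoreMatrix) -> FriedmanResult:
    """Friedman chi-square on within-block ranks, with tie correction."""
    ranks = _block_ranks(sm)
    n, q = ranks.shape
    if n < 2:
        raise InsufficientDataError("need >=2 blocks")
    if q < 2:
        raise InsufficientDataError("need >=2 contenders")
    R = ranks.sum(axis=0).to_numpy(float)
    A1 = float((ranks.to_numpy(float) ** 2).sum())
    C1 = n * q * (q + 1) ** 2 / 4.0
    denom = A1 - C1
    dof = q - 1
    if denom <= _EPS:
        return FriedmanResult(0.0, dof, 1.0)  # every block fully tied
    chi2 = (q - 1) * float(((R - n * (q + 1) / 2.0) ** 2).sum()) / denom
    return FriedmanResult(float(chi2), dof, float(ss.chi2.sf(chi2, dof)))


def holm_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjustment: sort ascending, multiply by (m - i),
    enforce monotonicity, cap at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adj[idx] = running
    return adj


def conover_posthoc(sm: ScoreMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons on Friedman rank sums with Holm
    correction.  t = |R_p - R_q| / sqrt(2n(A1-C1)(1 - chi2/(n(q-1))) /
    ((n-1)(q-1))), df = (n-1)(q-1)."""
    ranks = _block_ranks(sm)
    n, q = ranks.shape
    R = ranks.sum(axis=0)
    A1 = float((ranks.to_numpy(float) ** 2).sum())
    C1 = n * q * (q + 1) ** 2 / 4.0
    fr = friedman(sm)
    df = (n - 1) * (q - 1)
    scale2 = (
        2.0 * n * (A1 - C1) * max(0.0, 1.0 - fr.chi2 / (n * (q - 1)))
        / ((n - 1) * (q - 1))
    )
    names = list(ranks.columns)
    rows = []
    for a_i in range(q):
        for b_i in range(a_i + 1, q):
            a, b = names[a_i], names[b_i]
            dif = abs(float(R[a] - R[b]))
            if scale2 <= _EPS:
                raw_p = 1.0 if dif <= _EPS else 0.0
                t = 0.0 if dif <= _EPS else np.inf
            else:
                t = dif / np.sqrt(scale2)
                raw_p = float(2.0 * ss.t.sf(t, df))
            rows.append({"contender_a": a, "contender_b": b,
                         "diff_rank_sum": float(R[a] - R[b]),
                         "statistic": float(t), "raw_p": min(1.0, raw_p)})
    out = pd.DataFrame(rows)
    out["adj_p"] = holm_adjust(out["raw_p"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    return out


def average_percentile_ranks(sm: ScoreMatrix) -> pd.Series:
    """Mean per-block percentile rank in [0, 1] per contender (1 = always
    best; ties share average ranks)."""
    ranks = _block_ranks(sm)
    q = ranks.shape[1]
    if q == 1:
        return pd.Series(1.0, index=ranks.columns)
    pct = (ranks - 1.0) / (q - 1.0)
    return pct.mean(axis=0)


# ---------------------------------------------------------------------------
# cascade

def _significance_matrix(names: list[str], pairwise: pd.DataFrame) -> pd.DataFrame:
    mat = pd.DataFrame(False, index=names, columns=names)
    for row in pairwise.itertuples():
        sig = bool(row.significant)
        mat.loc[row.contender_a, row.contender_b] = sig
        mat.loc[row.contender_b, row.contender_a] = sig
    return mat


def _empty_pairwise(names: list[str]) -> pd.DataFrame:
    rows = [
        {"contender_a": names[i], "contender_b": names[j], "diff": np.nan,
         "raw_p": np.nan, "adj_p": np.nan, "significant": False,
         "note": "omnibus n.s."}
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return pd.DataFrame(rows)


def compare(
    sm: ScoreMatrix,
    alpha_assume: float = 0.05,
    alpha_omnibus: float = 0.05,
    shapiro_gate: bool = False,
    plot_dir: str | Path | None = None,
) -> tuple[AssumptionReport, ComparisonReport]:
    """Run the full cascade: assumption checks -> branch -> omnibus ->
    post-hoc; optionally write a significance heatmap plus a CI plot
    (parametric) or critical-difference diagram (nonparametric).

    Normality is by default treated as a visual diagnostic only and the
    branch decision is Levene-driven; an optional Shapiro-Wilk gate can
    force the nonparametric branch.
    """
    lev_F, lev_p = levene(sm)
    vr = variance_ratio(sm)
    normality = "visual_only"
    if shapiro_gate:
        data = _oriented(sm)
        resid = (data - data.mean(axis=0)).to_numpy().ravel()
        if np.ptp(resid) < _EPS:
            normality = "pass"
        else:
            _, sw_p = ss.shapiro(resid)
            normality = "pass" if sw_p >= alpha_assume else "fail"
    nonparametric = lev_p < alpha_assume or normality == "fail"
    assumptions = AssumptionReport(
        levene_F=lev_F,
        levene_p=lev_p,
        variance_ratio=vr,
        normality_flag=normality,
        decision="nonparametric" if nonparametric else "parametric",
        alpha_assume=alpha_assume,
    )
    names = list(sm.contenders)
    avg_ranks = average_percentile_ranks(sm)
    if nonparametric:
        fr = friedman(sm)
        rejected = fr.p < alpha_omnibus
        pairwise = (
            conover_posthoc(sm, alpha_omnibus) if rejected else _empty_pairwise(names)
        )
        report = ComparisonReport(
            "friedman", fr.chi2, (fr.dof,), fr.p, rejected, pairwise, avg_ranks,
            _significance_matrix(names, pairwise),
        )
    else:
        an = rm_anova(sm)
        rejected = an.p < alpha_omnibus
        pairwise = (
            tukey_hsd(sm, alpha_omnibus) if rejected else _empty_pairwise(names)
        )
        report = ComparisonReport(
            "rm_anova", an.F, (an.df_treat, an.df_err), an.p, rejected, pairwise,
            avg_ranks, _significance_matrix(names, pairwise),
        )
    if plot_dir is not None:
        try:  # plots are artifacts; rendering failures never abort the run
            _render_plots(sm, report, Path(plot_dir))
        except Exception:
            pass
    return assumptions, report


def _render_plots(sm: ScoreMatrix, report: ComparisonReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    names = list(sm.contenders)

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(names), 1 + 0.6 * len(names)))
    ax.imshow(report.significance.to_numpy(), cmap="Reds", vmin=0, vmax=1)
    ax.set_xticks(range(len(names)), names, rotation=90)
    ax.set_yticks(range(len(names)), names)
    ax.set_title("pairwise significance")
    fig.tight_layout()
    fig.savefig(out / "significance_heatmap.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 1 + 0.4 * len(names)))
    if report.omnibus_test == "rm_anova" and "ci_low" in report.pairwise.columns:
        pw = report.pairwise.dropna(subset=["diff"])
        labels = [f"{r.contender_a} - {r.contender_b}" for r in pw.itertuples()]
        ax.errorbar(
            pw["diff"], range(len(pw)),
            xerr=np.vstack([pw["diff"] - pw["ci_low"], pw["ci_high"] - pw["diff"]]),
            fmt="o",
        )
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_yticks(range(len(pw)), labels)
        ax.set_title("Tukey HSD simultaneous CIs")
        fname = "ci_plot.svg"
    else:
        ranks = report.average_ranks.sort_values()
        ax.hlines(0, 0, 1, color="k", lw=0.8)
        for name, r in ranks.items():
            ax.plot([r], [0], "o")
            ax.annotate(name, (r, 0), textcoords="offset points", xytext=(0, 8),
                        rotation=45, ha="left")
        sig = report.significance
        level = -0.02
        for i, a in enumerate(ranks.index):
            for b in ranks.index[i + 1:]:
                if not sig.loc[a, b] and report.rejected:
                    ax.plot([ranks[a], ranks[b]], [level, level], lw=2)
                    level -= 0.015
        ax.set_ylim(level - 0.02, 0.12)
        ax.set_yticks([])
        ax.set_xlabel("average percentile rank (1 = best)")
        ax.set_title("critical-difference diagram")
        fname = "critical_difference.svg"
    fig.tight_layout()
    fig.savefig(out / fname)
    plt.close(fig)
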