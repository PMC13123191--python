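# Methods

This note documents the models, procedures and defaults implemented in
qsarkit, the assumptions behind them, and the design choices made where the
design was genuinely open.

## Structure standardization

Standardization is a fixed sequence: parse → keep the largest organic
fragment → neutralize charges → canonicalize the tautomer → assign
stereochemistry → emit canonical SMILES. The operations themselves are
standard; the *order* is fixed here because determinism requires one, and
because this order makes re-standardization of a canonical SMILES a fixed
point (tested). Tautomer canonicalization uses RDKit's
`TautomerEnumerator` ruleset — the choice of ruleset is a documented
convention, not a claim that it is uniquely correct. Inputs that fail to
parse are recorded as `unparseable`; inputs whose organic part vanishes
after salt stripping (no carbon-containing fragment survives) as
`empty_after_strip`. Failed records are excluded from modeling but kept in
the standardization log for audit.

## Featurization

Fourteen scheme names are registered: ECFP2/4/6 and FCFP2/4/6 (Morgan
fingerprints, plain and feature-invariant, radius = n/2 by the community
convention, default 2048 bits), MACCS keys (167 bits), RDK5/6/7 (RDKit
path-based fingerprints with max path length 5/6/7), Avalon fingerprints,
and the RDKit physicochemical descriptor suite (`rdkdes`). `mordred` and
`pubchem` remain in the registry but raise a clear "provider not installed"
error, keeping configuration errors distinct from availability errors.
Non-finite descriptor values are stored as missing and handled by the
preprocessing chain, never silently replaced. The `Ipc` descriptor is
excluded from `rdkdes`: it grows super-exponentially with molecule size and
destroys downstream scaling long before it overflows to non-finite.

## Splitting

The external partition supports random, stratified (categorical targets,
proportions preserved within one item per class; singleton classes go to
train with a warning), Bemis–Murcko scaffold, and Butina-cluster
strategies. Group-aware splits fill the train side greedily with groups
sorted by size descending (ties broken by first occurrence), until train
reaches ⌈(1−f)·N⌉; remaining groups form the test set. Largest-first
filling is the common benchmark convention and guarantees whole groups
never straddle the boundary. Butina clustering ranks candidates by neighbor
count (Tanimoto distance ≤ cutoff) descending, ties by ascending row index
(the original description leaves the tie-break open); every member is
within the cutoff of its centroid, and the implementation is tested against
an O(n³) brute-force reference. Default external test fraction 0.2; default
clustering space ECFP4/2048, cutoff 0.35. Split membership, group keys and
seeds are persisted (CSV + JSON) and reload bit-identically.

## Preprocessing

A chain of stateful transformers, each with a strict contract: `fit`
consumes training rows only; `transform` applies the frozen state and never
removes rows; row-dropping remediations (duplicate merging, outlier-row
removal) run only on the training block. Default order: deduplication →
missing-value handling → low-variance filter → univariate outliers →
(multivariate outliers) → scaling; the chain constructor rejects scaling
anywhere but last. For binary fingerprints the outlier and scaling steps
are meaningless and are omitted by the default-chain builder.

Numerical conventions, chosen once and used everywhere (fences, robust
scaling, binning): quantiles by linear interpolation between order
statistics; Tukey fences at Q1 − 1.5·IQR, Q3 + 1.5·IQR (multiplier
configurable); variance threshold on population variance. Missing-value
default: drop columns with > 40% training missingness, mean-impute the
rest (median/mode/kNN/iterative available). Univariate outlier remediation
options: row removal (train only — test rows are transformed, never
dropped; this is an explicit interpretation choice), winsorization at the
fences, mask-and-impute, rank-based normal/uniform transforms, quantile
binning (default 5 ordinal bins). Multivariate detection (LOF, isolation
forest, one-class SVM, elliptic envelope) remediates by training-row
removal only. Duplicates are detected by exact feature-vector equality
after featurization, so hash collisions merge deliberately.

## Resampling and selection

The split family S (k×R blocks, default 5×5; stratified for
classification) is generated once per run and shared by every contender —
descriptor schemes, feature-selection strategies, estimators — so that all
downstream statistics are paired. Metrics carry an orientation (RMSE and
MAE are −1, all others +1); selection is always the argmax of oriented
block means, with exact ties resolved by declaration order and logged. A
contender that fails on a block gets a missing score; comparisons use
pairwise-complete blocks, and a contender that failed everywhere is
excluded rather than allowed to empty the paired design.

The selection cascade: (1) feature-selection strategies (no-selection
baseline, univariate F-score filter, tree- and L1-embedded selectors)
scored with a fixed canonical estimator (default: random forest,
configurable); (2) the estimator registry (dummy mean/majority baseline,
regularized linear, kNN, random forest, two gradient-boosting
implementations — scikit-learn and XGBoost — SVM, MLP) benchmarked on the
refined space; (3) joint model+hyperparameter search maximizing the mean
oriented CV score. The dummy baseline is mandatory in external validation:
a model that cannot beat a constant predictor is not externally valid.

The optimizer is a compact seeded Tree-structured Parzen Estimator: random
startup trials, then a good/bad split of the history at the γ = 0.25
quantile; numeric parameters are proposed from a Gaussian KDE over the good
set and ranked by the density ratio l(x)/g(x) with a *shared* bandwidth for
both densities (an asymmetric bandwidth flattens the bad-set density around
its own cluster and traps the search — this failure mode is covered by a
convergence test); categorical parameters use add-one-smoothed frequency
ratios. The space is tree-structured: a categorical root over estimators,
an independent subspace per estimator. Fixed seed + budget ⇒ identical
trial history. An optional small-budget pre-optimization gate can screen
the registry before the full search (off by default).

## Statistical comparison

Assumption checks: mean-centered Levene test (center configurable) plus the
max/min group-variance ratio. Normality is, by default, a visual-only
diagnostic (histograms/Q–Q belong to the analyst); the branch decision is
Levene-driven at α = 0.05, with an optional Shapiro–Wilk gate (off by
default) for pipelines that want an automated normality veto.

Parametric branch: one-way repeated-measures ANOVA with the contender as
within-subject factor and the CV block as subject; F = MS_treat/MS_error
with dof (q−1, (q−1)(n−1)). Zero error variance with a nonzero treatment
effect is reported as p = 0 with a degeneracy flag rather than an
exception. Post-hoc: Tukey HSD using MS_error and its dof from the
repeated-measures decomposition — studentized-range adjusted p-values and
simultaneous CIs; for two contenders this reduces exactly to the paired
t-test (tested).

Nonparametric branch: Friedman's test on within-block average ranks with
the standard tie correction, computed as
χ² = (q−1)·Σ_j (R_j − n(q+1)/2)² / (A₁ − C₁) with A₁ the sum of squared
ranks and C₁ = nq(q+1)²/4 (algebraically the classic statistic divided by
the tie-correction factor). Post-hoc: Conover–Iman t statistics on the rank
sums with df (n−1)(q−1), Holm step-down adjustment. Average percentile
ranks ((rank−1)/(q−1), averaged over blocks) summarize the ordering.

All tests consume oriented scores, so negating a loss metric and flipping
its orientation leaves every report identical (tested). The whole cascade's
omnibus type-I error under the null is verified by Monte-Carlo (1000
replicates) to sit in [0.03, 0.07] at α = 0.05. Plots (significance
heatmap; CI plot or critical-difference diagram) are artifacts written as
SVG; rendering failures never abort a run.

## Conformal prediction (CV+)

Regression: k leave-fold-out models; each training sample keeps the
absolute residual from the model that never saw it. For a query, the bounds
are the ⌊α(n+1)⌋-th smallest of {μ̂₋fold(i)(x) − R_i} and the
⌈(1−α)(n+1)⌉-th smallest of {μ̂₋fold(i)(x) + R_i} — the CV+ construction
with its ≥ 1−2α marginal coverage guarantee (empirically ≈ 1−α in the
well-specified case; verified by simulation). The point prediction is the
mean of fold-model predictions, so the calibrator needs no extra full-data
refit; the pipeline's final estimator supplies the headline prediction and
the conformal layer supplies bounds. lo ≤ hi is enforced; lo ≤ point is
not guaranteed by the theory. When n is too small for the requested α the
interval widens to the score range with a warning.

Classification: nonconformity 1 − p̂(y) (the simplest standard choice); a
label enters the set when its CV+ p-value exceeds α. Empty sets are
disallowed by default (decision-support context): the top-probability label
is kept and the row flagged. Default report levels α ∈ {0.1, 0.32}.

## Applicability domain

Three training-only novelty detectors: mean distance to the k nearest
neighbors (k = 5), LOF in novelty mode (the package default), and a
one-class SVM with RBF kernel whose γ comes from the median
pairwise-squared-distance heuristic. Scores are thresholded at the
(100·rate_of_outliers) percentile of the training score distribution under
a unified orientation (larger = more inlying; kNN distances are negated
internally), which makes the percentile rule unambiguous. The emitted
`ad_score` keeps each method's natural units. Training scores are
leave-self-out (a training point's own row never counts as its neighbor),
so the flagged-out training fraction tracks the configured rate to within
the percentile granularity; query scoring is pointwise and batch-
independent. Rate 0 places the threshold just below the minimum training
score. AD operates in the same frozen post-preprocessing feature space as
the estimator.

## Automated pipeline and bundle

Descriptor-first loop: per scheme, featurize (persisted as CSV), then
preprocess → feature-select → model-develop on the shared family; the
per-scheme score vector entering cross-scheme comparison is the winning
contender's paired block scores, so schemes are compared on identical
blocks. ψ\* is the argmax of mean oriented score, optionally preceded by
the formal comparison cascade. The hyperparameter optimizer is deliberately
excluded from this stage (cost control); it runs once, on ψ\*, during
finalization. Unavailable schemes are skipped with a log entry, never
fatal unless all schemes are unavailable.

The bundle is a single ZIP archive of pickled components (chain, selector,
estimator, conformal calibrator, AD model, partition, family spec) plus a
JSON config and a manifest holding per-member SHA-256 checksums, package
versions and seeds. Timestamps are isolated in one manifest field so
determinism checks can exclude them. Loading verifies every checksum;
tampering raises an integrity error. The external test set is evaluated
exactly once, after finalization, and no selection statistic ever reads a
test-row target (regression-tested by poisoning test targets and asserting
byte-identical training-fitted components).

## Synthetic data

The molecule generator enumerates valid SMILES from closed-form templates
(alkyl chains plus seven ring cores: benzene, naphthalene, pyridine,
cyclohexane, furan, indole, thiophene), so scaffold families are known by
construction and no rejection sampling is needed. Targets are linear in
heavy-atom count (default slope 1), constant, or a classification margin on
heavy-atom count, plus Gaussian noise (default σ = 0.5 in target units) —
so the achievable error floor is exactly the noise level. The score-matrix
generator produces contender effect + block effect + Gaussian noise, with
an optional 5× noise inflation on one contender to induce variance
heterogeneity.

What this emulates — and what it does not: the generator provides known
scaffold structure, a known signal-to-noise ratio and exact determinism,
which is what the correctness and hygiene properties need. It does *not*
emulate activity cliffs, assay heteroscedasticity, label censoring, or the
descriptor-correlation structure of real chemical series; a passing suite
demonstrates that the machinery is correct and leak-free, not that any
particular accuracy transfers to a real assay.

## Problem sizes in the shipped tests

The test and acceptance workloads use deliberately compact configurations
chosen as the smallest sizes at which each property is sharply testable:
25×4 score matrices for the statistical oracles (1000 Monte-Carlo
replicates for the type-I rate), n = 200/500 with 20 repeats for CV+
coverage, ~100 molecules for AD self-consistency, n ≤ 15 over 50 seeds for
the Butina brute-force cross-check, and a 300-molecule noise-free fixture
with two schemes, a 3×2 family and three candidate estimators for the
end-to-end determinism and signal-recovery run.

## Known limitations

- Single-task learning only; no multi-task heads or transfer learning.
- No Mondrian/class-conditional conformal and no locally-weighted
  (normalized) residuals; intervals are marginal, not conditional.
- AD detectors are density/novelty based; leverage (Williams-plot) and
  bounding-box domains are out of scope.
- The TPE implementation is intentionally minimal (no multivariate KDE, no
  pruning, no parallel ask/tell); for very large search spaces a dedicated
  optimization framework will outperform it.
- Deduplication keys on exact feature equality; near-duplicates in
  descriptor space are not merged.
- Reports and bundles assume everything fits in memory; there is no
  streaming or distributed execution.
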