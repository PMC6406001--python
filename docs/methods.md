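# Methods

## Directed feedback estimation

For each ordered node pair the package fits, by ordinary least squares with
intercept, a restricted autoregression of the target on its own `l` past
values and the full bivariate model adding the source's `l` past values.
Residual variances use maximum-likelihood scaling (RSS / n), and the
feedback is `F = ln(T1/T2)`, the log ratio of restricted to full innovation
variance, in nats.  Both fits use the identical effective sample — rows with
at least `l` within-run past values — so the restricted design is a column
subset of the full design and the estimated F is non-negative by
construction (no clipping is ever actually needed; reported values are
floored at 0 anyway for safety).

**Concatenated runs.**  Panels are concatenations of independent runs.
Lagged design rows that would reach across a run boundary are dropped rather
than treating the concatenation as one continuous series; with runs of ~1200
samples and lags ≤ 10 this discards well under 1% of rows.  Each series is
demeaned per run before fitting.  F itself is invariant to separate affine
rescaling of each series (asserted numerically to 1e-8 in the tests), so no
variance normalization is applied.

**Lag adaptation.**  The order is chosen per pair by minimizing
`AIC(l) = n·ln det(Σ̂_l) + 2k`, where `Σ̂_l` is the 2×2 ML residual
covariance of the full bivariate fit and `k = 2(2l+1)` counts estimated
coefficients.  All candidates `l = 1..lag_max` are refit on the common
sample with `lag_max` usable past values so criteria are comparable; exact
ties keep the smallest lag.  `lag_max` defaults to 10 samples.  Because the
criterion scores the joint bivariate fit, both directions of a pair share
one selected lag.  F and p are then recomputed at the selected lag on the
largest sample that lag permits.

**Significance.**  Under the null of no directed influence, `n·F` is
asymptotically χ² with `l` degrees of freedom (likelihood-ratio law).  The
test family is a package choice validated by simulation: over 2000
independent white-noise pairs at T = 1200 the rejection rate at 0.05 falls
inside the exact binomial 99% band and the p-value distribution passes a
Kolmogorov–Smirnov uniformity check (both run in the acceptance suite).
No stationarity pre-test is performed; stationarity is an assumption.

**Implementation.**  The whole-matrix engine computes one Gram-matrix
pyramid per subject (the all-node lag design cross-product, downdated over
boundary-trim levels) and exploits a nested-Cholesky identity — ordering
columns so every candidate lag is a leading block makes one factorization
and one triangular solve yield the RSS of all nested models via cumulative
sums.  The engine is verified bit-compatible with the pairwise reference
implementation in the unit tests and falls back to it on singular designs.

## Group maps

Subject flow matrices are stacked; the group object carries the elementwise
mean F, unbiased (K−1) between-subject variance, and the mean p-value per
directed edge.  Edge selection keeps i→j when the mean p across subjects is
≤ α (inclusive threshold; diagonal always excluded).  Partition summaries
collapse any per-edge map onto anatomic regions or functional networks:
cell (A, B) sums entries from nodes of A to nodes of B; within-unit cells
count ordered node pairs i ≠ j.  The "average" map divides each cell by its
contributing ordered-pair count, making it a proper per-edge mean.
Afferent/efferent flows of a unit sum between-unit inflow/outflow, and net
= afferent − efferent sums to zero over units exactly (conservation,
asserted to 1e-10).

Directionality contrasts compare, per unordered unit pair, each subject's
mean A→B flow against the subjects' mean B→A flows with a one-way ANOVA
(two groups — equivalent to a two-sample t-test), treating subjects, not
edges, as replicates to avoid pseudo-replication.  Variability analysis
reports, per unit, the mean between-subject edge variance into/out of the
unit relative to the whole-brain mean (the denominator includes the unit's
own edges), and between units the antisymmetric log-ratio
`ln(mean var A→B) − ln(mean var B→A)`, with per-comparison ANOVAs on the
per-edge variances.  All families use Holm step-down FWER adjustment.

## Behavioral prediction

Scores are residualized on age and sex by OLS; held-out subjects are always
adjusted with the *training* coefficients (the alternative of entering
covariates per-edge is available via the same design matrix but
residualization is the default because it transfers cleanly to test data).
Within each leave-one-subject-out fold, every candidate edge (restricted to
the group-level selection mask) is Pearson-correlated with the adjusted
scores of the K−1 training subjects; edges with p < 0.005 (strict) are split
by correlation sign, and per-sign regressions ŷ± = β₀± + β₁±·ΣF± are fit on
the training subjects and applied to the holdout.  A fold selecting no edges
of a sign predicts that fold's training mean.  The final model takes the
union of fold-wise edge sets per sign — an edge selected with conflicting
signs keeps the sign of its full-training-sample correlation — and refits
the betas once on all training subjects.  Out-of-sample application freezes
covariate coefficients, edge sets and betas.  Permutation inference reruns
the complete procedure (residualization, screening, fitting, evaluation) on
permuted scores, with p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1).  When a
permutation (or the observed fit) yields an empty positive union, its
statistic is −∞, so unavailable models can never appear significant.

The functional-connectivity baseline applies the *identical* pipeline to
the upper triangle of per-subject Pearson correlation matrices, and the
FC-vs-flow comparison correlates a per-node FC connectedness profile (mean
absolute off-diagonal correlation; a signed variant is available) with the
per-node afferent, efferent and net flow profiles.

## Synthetic testbed

The generator produces stationary VAR panels over a planted sparse directed
graph: per-edge lag and coefficient, AR(1) self-decay 0.3 per node, unit
Gaussian innovations, independent runs (burn-in 200 samples) concatenated
with recorded boundaries, and stationarity of every subject's jittered
coefficient draw enforced via the companion-matrix spectral radius.

The default testbed mirrors the geometry of a large resting-state study at
desk scale: 20 nodes, 30 directed edges with lags in {1, 2, 3} and
coefficients 0.2–0.5 (random sign), per-run length T = 1200 samples, up to
4 runs, and 110 subjects (50 train / 60 test).  Two design choices matter
and are deliberate:

- **Bipartite topology.**  Edges run only from 10 driver nodes to 10
  receiver nodes.  A pairwise feedback measure genuinely detects mediated
  influence, so chained edges (A→B→C) would put real population flow on
  non-planted pairs and make "specificity against the planted adjacency"
  ill-posed.  The bipartite layout keeps planted adjacency ≈ nonzero-flow
  set; the residual confound is weak common-driver flow between receivers
  sharing a driver (population F up to ~0.04 nats on a few dozen pairs),
  which is what keeps measured specificity near 0.95 rather than 1.
- **Structured between-subject variability.**  Each subject's edge
  coefficients are (base + independent jitter, sd 0.05) times a latent
  multiplicative gain (sd 0.25) shared within one of three edge groups.
  Behavioral scores load on the edges of one group, so the predictive
  circuit is coherent across subjects.  This is a substantive assumption:
  with purely independent per-edge jitter, a total score R² of 0.3 spread
  over 10 edges gives per-edge correlations near 0.17, which no p < 0.005
  screen can detect at 50 training subjects — individually detectable
  biomarker edges presuppose correlated strengths.

Scores are intercept 100 plus signed planted strengths, a small age and sex
effect, and Gaussian noise whose variance is set from the generator
parameters so the population strength-level R² is 0.3.  Head motion is
drawn independently (lognormal around 0.06 mm) purely to exercise the
motion-to-score exclusion rule `(HM/score)·10³ > 1` (boundary retained).

**What the generator does not emulate:** hemodynamic convolution,
autocorrelated or non-Gaussian noise, measurement noise on the nodes,
nonstationarity, or empirical fMRI spectra.  Passing recovery tests
therefore demonstrates correctness of the estimators and the absence of
information leakage — not that real fMRI at TR ≈ 0.7 s carries recoverable
lag-level directed structure, which remains the method's central empirical
assumption.

## Validation study sizes and expected behavior

The acceptance suite runs: oracle equivalence (bivariate VAR(1),
T = 200 000, estimated F within 0.01 nats of the closed-form Yule–Walker
projection value); null calibration (2000 pairs, T = 1200); lag-3 recovery
(coefficient 0.4, T = 1200, 100 seeded simulations — recovery ≥ 90/100 with
the frozen seed set; across arbitrary seed families the rate is roughly
0.8–0.9, as AIC trades detection against parsimony at this effect size);
edge recovery (50 subjects, 4 runs — sensitivity 1.0, specificity ≈ 0.95);
and a 20-replicate prediction study (single-run panels, 50/60 split,
n_perm = 200) with matched null replicates and leakage sentinels.  These
problem sizes keep the full suite around three minutes.

## Numerical notes and limitations

- Degenerate inputs (constant or collinear series) raise typed errors;
  whole-matrix computation reports all failing pairs in one summary error.
- Zero full-model residual variance (deterministically dependent series) is
  an explicit infinite-feedback error, not an inf.
- Pairwise conditioning only: the measure does not condition on the rest of
  the network (no conditional/multivariate Granger causality, no spectral
  decomposition, no instantaneous-feedback term).
- The χ² test is asymptotic; at very short runs a finite-sample F-test
  would differ.  Calibration is verified at the run lengths the package
  targets.
- Age may be supplied in years or ordinal band codes; it is treated as a
  numeric covariate either way.
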