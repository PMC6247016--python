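# Methods

`longvol` analyses longitudinal and paired-sample microbiome data: it
takes per-sample metadata (with a numeric *state* column, usually time,
and a *subject* column), optionally a feature table (samples ×
taxa/sequence variants) and/or a precomputed beta-diversity distance
matrix, and provides within-subject transforms, control-chart
("volatility") statistics, paired tests, linear mixed-effects (LME)
models, and a supervised-regression screen for temporally informative
features.  This note records the models, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not demonstrate.

## Temporal transforms

For a metric Y observed on subject i at time t, the **first difference**
is ΔY_t = Y_t − Y_{t−1}, the incremental change between successive time
points.  The **first distance** is the analogous quantity for beta
diversity: the entry d(s_t, s_{t−1}) of a distance matrix for the
subject's successive samples.  Both admit a **baseline** variant,
ΔY_t = Y_t − Y_baseline, against a fixed state, and a **static-reference**
variant where each subject is compared against a linked non-longitudinal
sample (e.g. an infant's samples against the mother's sample).

**Gap rule.** Sampling is treated as occurring on a fixed grid: the
ordered set of distinct states present in the metadata.  A successive
delta at state t is emitted only when the subject was observed at both t
and the grid predecessor of t.  A subject who misses one month therefore
contributes no delta at that month *or the next* — deltas never silently
span multi-interval gaps, which would conflate a long elapsed interval
with a single step.  Baseline and static-reference modes have no such
restriction (every observed non-baseline state yields a delta).

States are matched by exact numeric equality after parsing; encode
states consistently.  Deltas are keyed by the later (or moving) sample's
ID so they can be merged back into the metadata and fed onward to the
LME and volatility modules.  Replicates (same subject and state) raise
an error by default; `drop` removes the affected state, `mean` averages
the metric (differences mode only — averaging rows of a distance matrix
has no defined meaning here).  Deltas are raw changes, not per-unit-time
rates; unequal intervals are not normalized.

## Paired tests

For two chosen states, subjects observed at both contribute either the
difference Y_state2 − Y_state1 of a metric or the distance between their
two samples.  Within groups the median difference is tested against 0 by
Wilcoxon signed-rank (zero differences dropped, count reported; the
parametric alternative is a one-sample t-test).  Between groups the
differences (or distances) are compared by Kruskal-Wallis plus pairwise
two-sided Mann-Whitney U (parametric: ANOVA plus pairwise t-tests), with
Benjamini-Hochberg FDR correction of the pairwise P values — FDR rather
than Bonferroni because these are exploratory comparisons; raw and
corrected P are both reported.  All tests are two-sided at α = 0.05.
In distance mode no within-group location test is run: within-pair
distances are nonnegative, so a test against 0 is vacuous, and only the
between-group comparison is meaningful.

## Linear mixed-effects model

y_ij = X′_ij β + Z_ij b_i + ε_ij, with y_ij the j-th measurement on
subject i, X_ij the fixed-effect covariates (time, group, sex,
interactions), b_i ~ N(0, Σ) the per-subject random effects and
ε_ij ~ N(0, σ²) independent residuals.  The default random structure is
a random intercept; a random slope on the state column can be added,
giving the 2×2 Σ with intercept variance, slope variance and their
covariance, all reported explicitly along with σ².

Estimation is REML (the standard choice when variance components are of
interest; ML is available for nested-model likelihood comparisons) via
statsmodels `mixedlm`.  Each fixed-effect P value is computed two-tailed
from the coefficient's Z-score against the standard normal — an
asymptotic Wald test, adequate at the subject counts these designs carry
but anti-conservative for very few subjects.  Categorical covariates are
treatment-coded against the lexicographically first level and labeled
`name [T.level]`.  Non-convergence or a boundary fit is a *reported
state* (`converged=False` plus a warning suggesting dropping the random
slope), not an exception, because boundary variance estimates are
routine in longitudinal microbiome data.  Term pruning ("fit all
interactions, drop the insignificant ones") is deliberately left to the
user; automated stepwise selection is out of scope.

## Volatility charts

For a chosen metric, the global mean and sample (n−1) SD are computed
across **all** samples; warning limits sit at ±2 SD and control limits
at ±3 SD around the mean.  Limits are global even when a grouping column
is active, so all groups are judged against one common band.  Per-(group,
state) means ± SD (SEM optional) and per-subject spaghetti trajectories
overlay the band; every sample is flagged if it exceeds the warning or
control limits.  Under an in-control Gaussian process ~4.6% of samples
fall outside the warning limits and ~0.27% outside the control limits;
excursions beyond that suggest disturbance, disease or contamination.
The chart is emitted as a deterministic declarative JSON document (one
layer per group mean, per subject, and per horizontal rule) plus a
static matplotlib figure; interactive rendering is out of scope, but the
JSON retains the fields an interactive grammar would need.

## Feature volatility

The feature-volatility pipeline regresses the state (time) on feature
abundances with a machine-learning regressor — random forest by default
(100 trees, scikit-learn defaults otherwise); extra-trees, gradient
boosting and elastic-net are alternatives.  Stages, in order: a seeded
random 4:1 train/test split; optional cross-validated grid-search tuning
on the training set; cross-validated recursive feature elimination
(5-fold, removing 5% of the features per round) on the training set,
keeping the subset with the best CV score; a final model on the selected
features; importances extracted and normalized to sum to 1; MSE and R²
on the untouched test set; per-feature descriptive statistics; and a
combined plot document (volatility chart per top feature + an
importance/statistics bar chart).  "Important features" means the
features retained by RFE in the final model.  High importance does not
imply statistical significance — only that the feature helped an
accurate model discriminate time points; models with poor held-out R²
should not be interpreted at all.

The default split is random at the sample level.  Samples from one
subject then appear in both train and test, which can leak
subject-level information and flatter the accuracy; `group_by_subject`
switches to a subject-wise split and is recommended whenever prediction
on *new* subjects is the question.  Counts can be closed to per-sample
relative frequencies first via `relative_frequency`; abundances are
otherwise used as given.

**Descriptive statistics.** Per feature: mean, median, sample variance
and SD, and coefficient of variation (SD/mean, reported as missing when
the mean is 0) over all samples; and, from the per-state mean abundances
m_f(t) in ascending state order, the net average change
m_f(t_k) − m_f(t_1), the cumulative average increase Σ max(0, step) and
the cumulative average decrease Σ min(0, step), so increase + decrease
equals net (to floating-point summation accuracy, ~1e-15; tests assert
1e-9).  Change statistics use global per-state means rather than
averages of per-subject first differences; the two coincide for balanced
designs and differ only under informative missingness.

## Jaccard helper

Jaccard distance between two samples is the proportion of observed
features not shared: 1 − |P_a ∩ P_b| / |P_a ∪ P_b| with P_s the set of
features strictly above the detection threshold (default 0, i.e. plain
presence/absence, hence invariant to rescaling any sample).  Two empty
samples are at distance 0.  This is the helper used to track shared
features over time, e.g. between infants' samples and their mothers'.

## Synthetic cohorts

`simulate_cohort` draws metadata from the same generative mixed model
the LME module fits — y_ij = β₀ + β₁t + group effects + u_i0 + u_i1·t +
ε_ij — plus a feature table of Dirichlet-multinomial counts around
state-dependent mean compositions (planted features trend monotonically
in log-composition; the rest are exchangeable), and a Jaccard or
Euclidean distance matrix.  The `ecam_like` preset mirrors a published
early-childhood design: 43 subjects, monthly sampling over months 0-24,
two delivery-mode and two diet groups, 10% dropout.
`planted_feature_table` instead plants additive Gaussian trends with an
exact effect-to-noise ratio (default 3× the noise SD per state step,
50 subjects × 8 states, 5 planted among 100 features), which is the
right benchmark when the regressor's detection threshold must be
controlled precisely.

What the simulators do **not** emulate: overdispersion beyond the
Dirichlet-multinomial, phylogenetic structure, zero-inflation beyond
compositional sampling, autocorrelated within-subject noise, and
informative (non-random) dropout.  Passing benchmarks therefore show the
methods are correctly implemented and calibrated under their own model
assumptions — not that any particular real data set satisfies those
assumptions.

## Numerical and reproducibility choices

- Sample (ddof=1) SDs everywhere; symmetric matrices are validated to
  1e-8 and re-symmetrized by averaging; TSV writers emit 10 significant
  digits with LF terminators, enough for a lossless decimal round trip
  of doubles at that precision.
- Every stochastic routine takes an explicit seed (`numpy`
  `default_rng` / scikit-learn `random_state`); same seed + same input
  gives byte-identical tables, importances and serialized plot specs
  (JSON is dumped with sorted keys and fixed separators).
- Ties in top-N importance displays break by feature ID.
- Degenerate inputs: constant response → error; constant metric →
  limits collapse to the mean, nothing flagged; a subject with one
  usable sample → empty series with a warning; all-subject exclusions →
  hard error.
- Benchmark sizes used by the test suite and `scripts/acceptance.py`:
  transform oracles at 200 subjects × 8 states with 30% missingness;
  LME Wald coverage at 100 subjects × 10 states (100 replicates in the
  suite, 50 in the script); control-limit tail rates at 10,000 samples;
  feature-volatility recovery at 50 subjects × 8 states × 100 features
  (10 signal + 5 null seeds in the suite, 8 + 4 in the script).  These
  sizes keep full runs in the minutes range while leaving the binomial
  error of each estimated rate well inside the asserted bands.

## Known limitations

Gaussian responses only (no GLMMs, no zero-inflation); no automated
model selection; no interpolation of missing states; distance-mode
paired tests assume one sample per subject per state; BIOM support is
read-only (v2.1); UniFrac and other phylogenetic distances must be
computed upstream — the package consumes distance matrices, it does not
build them (except Jaccard).
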