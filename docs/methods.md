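# Methods

This note documents the models, defaults, and design choices behind
`bvpredict`, and what the synthetic cohorts do and do not establish.

## Cohort and outcome

A couple contributes one baseline penile sample and the woman's Nugent
scores (integers 0–10) at month 0 and scheduled follow-ups at months 1, 6
and 12; unscheduled visits are out of scope. Outcome derivation is a strict
precedence chain: baseline 7–10 → excluded (prevalent BV); in sensitivity
mode baseline 4–6 → excluded (intermediate flora may be misclassified or
developing BV); no attended follow-up → excluded (cannot contribute
incidence); otherwise *incident* at the earliest follow-up scoring 7–10,
else *persistent negative*. Only the first incident visit defines the
label; later episodes are ignored. Incidence is reported as the simple
retained-cohort proportion.

## Preprocessing

- **Taxon filter**: keep taxa whose column sum is ≥ `min_fraction`
  (default 10⁻⁴, i.e. 0.01%) of the table's grand total. The threshold is
  inclusive, and the basis is the whole table (one anatomic site per
  table), not per-sample totals — a per-sample rule would not make "0.01%
  of the total sequence reads" well defined. Filtering precedes
  imputation, so the filtering decision depends only on raw counts and is
  idempotent; imputing first would let pseudo-counts perturb the rule.
- **Zero imputation**: each zero cell independently receives a draw from
  Uniform(0.5, 0.95). The draw is below any true count (counts are
  integers ≥ 1), so imputation only breaks the log's singularity. The
  half-open [0.5, 0.95) of the standard generator is immaterial (endpoint
  mass zero).
- **CLR**: natural logarithm. The base only rescales columns and is
  absorbed by min-max, but fixing it keeps intermediate files comparable.
  Rows sum to zero within 1e-9.
- **Min-max**: per feature over *all* samples, the default reproducing the
  original procedure (statistics computed before resampling or
  cross-validation). A constant column maps to 0 rather than dividing by
  zero. `strict_normalization` defers scaling to cross-validation time and
  fits the statistics on each training partition only; held-out values are
  not clipped and may fall slightly outside [0, 1]. Strict mode requires
  within-fold resampling, since SMOTE's distances are defined on the
  scaled features.
- **Circumcision status** is appended after normalization as a 0/1 column
  (already in range), labelled `Circumcised`.

## Rebalancing

SMOTE with `k_neighbors = 5`, the canonical default — the source analysis
names the technique but not k. The number of synthetic points is
round(`smote_percent`/100 × minority size); base points cycle through the
minority class so 100% uses each minority sample exactly once, reproducing
the published arithmetic (52 → 104, 24 → 48). Distances are Euclidean on
the min-max-scaled features (the stated motivation for scaling). Majority
undersampling targets `"balanced"` (the augmented minority size) by
default; the published 116 → 105 and 54 → 50 reductions do not follow from
any single spread parameter, so an explicit integer target is accepted
where the printed counts must be reproduced.

Two placements are provided. `pre_cv` (default, faithful): rebalance the
full training set once, then cross-validate the resampled set. This leaks
information — synthetic points interpolate minority pairs that end up on
both sides of a fold boundary — and measurably inflates null performance.
`within_fold`: rebalance each training partition only, so every held-out
sample is an original observation. Calibration experiments (the null and
planted-signal suites below) therefore use `within_fold`; `pre_cv` exists
to reproduce the published procedure, not to certify generalization.

## Classifiers, cross-validation, evaluation

Stratified 10-fold cross-validation (stratification keeps ~31% positives
in every fold at n ≈ 200), repeated with fresh fold assignments; per-repeat
seeds are `base_seed + repeat`, making repeats independent but the run
reproducible. Tuning, when grids have more than one point, is nested: an
inner 5-fold grid search on each training partition, ties keeping the
first grid point. Default grids: RF 500 trees with features-per-split in
{√p, p/4, p/2}; SVM (RBF) C ∈ {0.1, 1, 10, 100} × γ ∈ {1, 2, 4}/p; KNN
odd k ∈ {3, …, 15}. The `desk` preset fixes single points (RF 300
trees/√p, SVM C = 1 γ = scale, KNN k = 5) so simulation studies run in
minutes on one CPU; it is the preset used by the acceptance suite.

Scores are positive-class probabilities in [0, 1]: tree-vote fraction
(RF), a logistic transform of the decision value (SVM — any monotone
transform gives the same AUC), neighbour-vote fraction (KNN); predicted
label is score ≥ 0.5, which for the SVM coincides with the decision sign.
The ensemble label is the 2-of-3 majority (no ties are possible); the
ensemble score is the mean of the three scores, with the discrete
vote-fraction alternative available behind `vote_fraction_auc` because the
original ensemble-score construction is not specified. Metrics are pooled
across folds within a repeat (micro-average; per-fold AUC on ~20 samples
is too unstable to macro-average) and point estimates are means over
repeats, retaining the per-repeat AUC vectors.

## Importance

Computed once on the fully resampled training set, as the single published
ranking implies, not per fold. RF: permutation importance — mean decrease
in held-out accuracy over 5 stratified folds, 10 shuffles per feature.
SVM: backward recursive elimination removing, at each step, the feature
whose removal least degrades 3-fold cross-validated accuracy; elimination
order reversed gives the ranks. KNN: leave-one-feature-out degradation of
5-fold cross-validated accuracy. The KNN criterion is a defined, testable
surrogate — the originally cited "support criterion" is not
reconstructable from its description. Voting rank sorts by mean of the
three ranks, breaking ties by the minimum single-classifier rank and then
label order; this tie-break uniquely reproduces all three tied pairs in
the published top-20 table.

## Permutation test

Welch (unequal-variance) t on two AUC vectors, two-sided, group labels
permuted B = 1000 times by default; p = (1 + #{|t*| ≥ |t|})/(1 + B), so
p ≥ 1/(B+1) > 0. The pooled vector is sorted before permuting, making the
p-value invariant to input ordering (and to swapping equal-length groups).
Degenerate permuted splits (zero within-group variance) are counted as
extreme, which is conservative. Constant pooled input is an error. The
repeat-level AUC vectors are treated as the exchangeable units.

## Synthetic cohorts

`generate_cohort` emulates the study conditions: incidence 0.31,
59% circumcised partners, ~50 taxa, one baseline sample per couple.
Compositions are Dirichlet-multinomial: default concentrations follow a
power-law rank-abundance profile (αᵢ ∝ i^−1.2, total concentration 3),
which reproduces the observed shape — a dominant taxon near 20% mean
relative abundance and mid-ranked taxa absent from a substantial fraction
of samples. Sequencing depth is log-normal with μ = ln(median) and
σ = ln(q₃/q₁)/(2 z₀.₇₅) solved from the published median 25,997 and IQR
19,524–33,779. Effects multiply the Dirichlet concentrations of chosen
taxa by exp(shift) in incident couples, preserving compositional closure;
no per-taxon penile-taxon → BV effect sizes are asserted, they are free
parameters. Nugent scores are synthesized only as far as the analysis
reads them (category 0–3 with probability 0.845, else 4–6 at baseline;
incident couples score 7–10 at one uniformly chosen follow-up).

The generator does **not** emulate taxon–taxon correlation beyond
compositional closure, contaminant or chimera structure, longitudinal
penile dynamics, missing visits, or annotation error. Passing the
calibration suites therefore shows the *pipeline* is unbiased and can
recover planted compositional signal — not that real penile taxa carry
that signal.

## Problem sizes and acceptance experiments

The simulation experiments run at desk scale, chosen so the whole suite
completes in minutes on one CPU: cohorts of 200 couples × 50 taxa, 10-fold
CV × 50 repeats, `desk` classifier preset, within-fold rebalancing.
The planted-signal experiment (five taxa shifted 1.5 log-units) must reach
voting AUC ≥ 0.80 and place ≥ 3 of 5 planted taxa in the importance
top 10; the null experiment (no shifts) must keep mean voting AUC within
[0.45, 0.55]; 200 replicate null permutation tests must reject at α = 0.05
between 2% and 9%. `paper_scale: true` switches to 1,000 repeats.

## Known limitations

- `pre_cv` resampling reproduces the original procedure but optimistically
  biases cross-validated estimates; use `within_fold` when the estimate,
  not fidelity, is the goal.
- The KNN importance criterion is a surrogate (above).
- RFE is O(p²) model fits; at a few hundred features it becomes the
  slowest stage.
- Minority classes of ≤ k samples cannot be SMOTE-resampled (the error
  suggests lowering k).
- AUC repeats are treated as independent by the permutation test, though
  repeated CV on one dataset induces correlation between repeats; the test
  compares distributions, it does not certify independence.
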