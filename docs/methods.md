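# Methods

## Problem setting

A training table of N records × M features (continuous or discrete,
coded as integers), a categorical class label, and missing cells confined
to the training partition. The package studies how the *order* of two
preprocessing steps — supervised discretization and missing-value
imputation — affects downstream classification, under the MCAR
(missing-completely-at-random) mechanism, where the probability a cell is
masked is independent of all values and labels.

Missingness is represented as an explicit boolean mask alongside the
value matrix, never as a sentinel value, so continuous features may take
any real value without collision.

## The two combination orders

Both orders begin identically: inject MCAR missingness into the training
set and partition it into the *complete* subset (no missing cells) and
the *incomplete* subset (at least one).

**Order A (discretize → impute).** Cut points are fitted on the complete
subset only; both subsets are coded with them (missing cells untouched);
the imputer is fitted on the coded complete subset and fills the coded
incomplete subset, so estimates are interval codes by construction; the
subsets are recombined in original record order. The test fold is coded
with the complete-subset cut points.

**Order B (impute → discretize).** The imputer is fitted on the
continuous complete subset and fills continuous values; the completed
training set is recombined; cut points are then fitted on *all* of it and
applied, and the same cut points code the test fold.

The orders genuinely differ: A's cuts see only the complete subset while
B's see imputed values, and B's continuous estimates can land on either
side of a cut that A's coded estimate is forced onto. The no-leakage
contract — schemes and imputers are identical whether or not a test set
exists — is asserted by test.

Baselines: (1) untouched continuous data; (2) discretization of the full
complete training set, no missingness; (3) missingness plus continuous
imputation, no discretization. At a missing rate of zero, orders A and B
and baseline 2 coincide exactly (tested).

The per-record imputation loop fits the imputer once on the complete
subset rather than once per record; the complete subset does not change
inside the loop, so the results are identical and the single fit is
purely an efficiency choice.

## Discretizers

Both are univariate, deterministic, and produce strictly increasing cut
points defining left-open right-closed intervals with unbounded extremes:
value v gets code i with d_i < v ≤ d_{i+1}, so any unseen test value maps
to a valid code. The shared-endpoint convention (a value equal to a cut
belongs to the *left* interval) is fixed here once; interval codes are
ordinal by construction.

**MDLP** (Fayyad–Irani). Candidate cuts are midpoints between adjacent
distinct sorted values whose value-blocks are not pure in the same single
class — equal values can never be separated, and cutting inside a
single-class run cannot strictly minimise entropy. The candidate
minimising weighted child entropy (leftmost on exact ties) is accepted
iff

    Gain(A,T;S) > log2(N−1)/N + Δ/N,
    Δ = log2(3^c − 2) − [c·Ent(S) − c1·Ent(S1) − c2·Ent(S2)],

with class counts c, c1, c2 of the node and children, logs base 2;
recursion continues independently in each accepted child. The test suite
checks exact agreement with a brute-force oracle that re-derives every
quantity with plain Python loops.

**ChiMerge** (Kerber). One initial interval per distinct value; the
adjacent pair with the smallest chi-square (leftmost on ties) merges
until every pair's χ² exceeds the critical value at significance α
(default 0.05, configurable) with df = (classes present in the pair) − 1,
floored at 1; classes absent from both intervals are skipped (zero
expected count). An optional `max_intervals` cap forces continued
merging. Cut points are midpoints between adjacent surviving intervals'
boundary values. α and the cap are declared defaults — conventional for
this algorithm — not values with any external provenance.

## Imputers

All are fitted on the complete subset only and impute each missing
feature independently from the record's observed features (single pass,
no chained iteration). The class label is never a predictor: it would not
be available for incoming records in deployment.

* **mean/mode** — column mean for continuous targets, mode for discrete
  (ties → smallest code).
* **KNN** — HEOM distance: per observed feature, |a−b|/range for
  continuous (range from the fitting set; zero-range features score 0/1
  on mismatch), 0/1 mismatch for discrete; root-sum-of-squares overall.
  k = 5 by default. Equal distances break by reference index, vote ties
  by smallest code. Verified against an exhaustive-search oracle.
* **CART** — one tree per feature (target = that feature, predictors =
  the rest), regression for continuous and Gini classification for
  discrete targets, `min_samples_leaf=5`, no pruning, seeded. Backed by
  scikit-learn's tree estimators. Unobserved predictors are routed with
  the fitting-set mean/mode of that column.

## Missingness simulator

`rate` is interpreted per *record* by default: exactly `round(rate·N)`
records are drawn uniformly and `per_record_features` (default 1)
features are masked in each. This keeps the complete subset usable even
at a 50% rate; a per-*cell* Bernoulli unit is available as an option (at
50% cell-wise on 10+ features essentially no complete records survive,
which would make complete-subset fitting infeasible). Per-repetition
seeds derive from `SeedSequence(base_seed, (rate, rep))`, so any grid
cell reruns in isolation. An MCAR sanity test checks that masked-record
class frequencies match the overall class distribution (chi-square,
pooled seeds).

## Classifiers and comparison

* SVM with RBF kernel, C = 1, gamma = "scale" (1/(M·var)); continuous
  features are train-standardised; discrete interval codes are fed as
  ordinal integers (they are ordered by construction), with one-hot as a
  config option.
* The second classifier is an entropy-criterion binary tree with
  minimal-cost-complexity pruning (`ccp_alpha=0.01`) — an approximation
  of C4.5-style trees, whose multiway splits and error-based pruning are
  out of scope.
* Arms are compared with a two-sided Wilcoxon rank-sum test; the reported
  statistic is the rank sum W of the first arm, the p-value is exact
  (Mann–Whitney) where sample sizes allow. Identical constant samples
  return p = 1 with a warning.

## Synthetic data generator

Labels are Bernoulli(class prior); informative continuous features are
class-conditional Gaussians with unit variance and means
boundary ± effect_size/2, so the Bayes-optimal single cut per feature is
the known midpoint — a ground truth real benchmark tables cannot offer;
noise features are class-independent Gaussians; discrete features have 3
categories with a mild class association (none when effect_size = 0, so
a zero-effect table carries no signal anywhere). Defaults: 500 records,
5 informative + 3 noise continuous + 2 discrete features, balanced
classes, effect size 2.

What passing on this generator does *not* show: real clinical tables
have correlated features, non-Gaussian marginals, class imbalance and
informative missingness; results here certify algorithmic correctness
and the leakage/ordering contracts, not expected accuracy on any real
dataset.

## Numerical choices and problem sizes

* Entropy and the MDL threshold use exact class counts; ties in cut
  selection and merging resolve leftmost; all comparisons are strict, so
  fits are permutation-invariant and fully deterministic.
* Cut-recovery validation uses n = 2000 records at effect size 4 with a
  0.25 SD tolerance on the nearest cut. At these conditions the
  empirical entropy-minimising split sits in a low-density valley
  between the class means and its sampling spread is of the same order
  as the tolerance, so single-draw checks near the band edge can fall on
  either side; the noise-feature check (no cut in ≥ 90% of 20 runs) is
  pooled and stable.
* The end-to-end ordering study runs ChiMerge + KNN + SVM on 500-record
  tables over 10 seeds, one held-out fold per seed, at 10% and 50%
  missing rates — sizes chosen to exercise every stage while keeping a
  full run in tens of seconds.

## Known limitations

* MCAR only; MAR/NMAR mechanisms are out of scope.
* Single-pass imputation; no chained/iterative (MICE-style) estimation.
* The tree classifier approximates, not reproduces, C4.5.
* Multi-class inputs are accepted by every stage, but the synthetic
  suite exercises two-class problems only.
* ARFF support covers the numeric/nominal attribute declarations of
  ARFF 2.x as read by scipy.
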