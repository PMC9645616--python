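# Methods

This note documents the models and procedures implemented in `perfcast`,
the defaults and the reasoning behind choices the problem left open.

## The synthetic expression model

Each simulated dataset imitates a two-group microarray experiment on the
log2 scale. A *part* is a homogeneous block of features with one parameter
setting; a configuration is an ordered list of parts sharing the sample
layout (`n_train` samples, `n_group1` in group 1).

For a part with `d` features the per-subject feature vector is

    x = b + mean(e_1 ... e_nRep) + z * log2(delta) * 1[group 2]

* `b ~ MVN(0, sdB² · R)` — biological variation with a block-diagonal
  exchangeable correlation matrix `R`. Block sizes are drawn uniformly in
  `[bsMin, 3·bsMin]` (the last block truncated to fit) and each block's
  common correlation uniformly in `[rhoMin, rhoMax]` (defaults 0.2–0.8;
  the fixed-correlation variation S7 sets both to 0.8). Exchangeable blocks
  with ρ ≥ 0 are positive semi-definite by construction; ρ < −1/(m−1) is
  rejected.
* `e_k ~ N(0, sdW²)` iid — technical replicate error; the delivered value
  is the mean over `nRep` replicates, so the marginal variance of a feature
  is `sdB² + sdW²/nRep`. This variance-components identity is tested
  against Monte-Carlo simulation.
* Discriminating parts (`diffExpr = 1`) shift group-2 samples by
  `z · log2(delta)` per feature, with the fold change
  `delta ~ N(foldMin, sigma²)` truncated below at `foldMin` (equivalently
  `foldMin + |N(0, sigma²)|`, mean `foldMin + sigma·√(2/π)`) and
  `z` uniform on {−1, +1} for up-/down-regulation.

**Effect-size scale.** `foldMin` is a fold-change *ratio*: `foldMin = 2`
produces a one-log2-unit group shift. This choice is pinned down by the
behavior of the simulation variations: with ratio scaling, "smaller fold
changes" settings (fold changes of 1.5 or 1.0) degrade datasets toward
chance-level separability and collapse the meta-regression's explainable
variance, which is exactly the qualitative pattern the S5/S9 variations are
designed to show. Treating `foldMin = 2` as a two-log2-unit shift instead
makes every variation almost equally easy and erases those contrasts. A
side effect worth knowing: a part with `foldMin = 1` and `diffExpr = 1` is
a null part (log2(1) = 0, up to `sigma` jitter).

**Which group is shifted** is immaterial: the labels are exchangeable and
every downstream quantity depends only on the group difference.

## Study collections

A *study collection* draws one sub-collection of single-part datasets per
configuration part — the reference configuration yields 50-feature
strong-discriminator datasets, 20-feature discriminator datasets and
20-feature pure-noise datasets (error ≈ 0.5) in equal numbers. The spread
in difficulty across parts is the signal the meta-regression explains; a
collection of part-concatenated datasets (also available,
`generate_collection`) is nearly homogeneous in difficulty — its error
variation is mostly cross-validation measurement noise, which no regression
can predict — and is therefore not used for the study. Reproducibility:
dataset `i` of part `p` uses the RNG stream seeded by `(seed, p, i)`, so
collections are pure functions of (configuration, seed) and independent of
generation order.

The registry's nine variations modify the reference configuration: S2
halves the sample count, S3 the dataset count, S4/S5 reduce fold changes
((2, 1.5, 1) and (1.5, 1, 0.5)), S6 halves the discriminator counts, S7
fixes ρ = 0.8, S8 raises `sdB` to (4, 4, 2), and S9 combines S8's variation
with S5's fold changes. Where the variation descriptions are qualitative,
the concrete values above are the package's reading; S9 takes S5's fold
changes because "smaller fold changes overall" is the stronger reduction.

## Meta-features (Step I)

All entries of the characteristic vector are finite by construction so the
meta-dataset needs no imputation. Conventions for degenerate cases: a
feature with zero variance in both groups gets t = 0, p = 1; constant
scores get skew = kurtosis = 0; an edgeless correlation graph gets diameter
and mean distance 0; reciprocity is identically 1 for undirected graphs
(and is dropped later as a zero-variance column).

* **t statistics** — pooled-variance two-sample Student t (not Welch),
  two-sided p-values with n − 2 df.
* **Information gain** — class entropy minus conditional entropy given the
  feature discretized by equal-frequency binning into `min(10, ⌈√n⌉)` bins;
  in bits, bounded by H(y).
* **ReliefF** — every instance is an anchor (m = n), k = 10 neighbors
  (reduced with a warning when a class is smaller), range-normalized
  Manhattan distances, miss contributions weighted by class priors;
  weights in [−1, 1]. Verified against a brute-force reference on toy data.
* **Summaries** — per filter: n, mean, 10%-trimmed mean, median, sd, MAD
  (×1.4826), min, max, range, skew, excess kurtosis, se, and percentiles
  at {2, 5, 10, 25, 50, 75, 90, 92, 95, 98} (suffix `pc`).
* **P-value counts** — features with raw/BH-adjusted p below
  {0.001, 0.01, 0.05, 0.1} (strict <); `npthTotal` sums the raw counts,
  `npthTotalSum` raw plus adjusted.
* **Correlation network** — edge where |Pearson r| ≥ τ (default τ = 0.7,
  exposed); density, reciprocity, transitivity, diameter and mean shortest
  path over reachable pairs.
* **Cluster indices** — k-means (k-means++, 10 restarts) for k ∈ {2, 3, 4}
  on the samples; eight indices per k. The k-means seed is an explicit
  parameter (default 0) rather than derived from the data, keeping vectors
  deterministic and the non-cluster features invariant to sample order;
  for data with real cluster structure the indices are order-invariant too.

The default vector has 105 named entries; after dropping zero-variance
columns the reference meta-dataset has p = 104 predictors. The meta-feature
count is a design outcome, not a constant of the method — the `mtry` grid
always spans 2 … p of the assembled meta-dataset.

## Classification protocol (Step II)

Stratified 10-fold cross-validation (fold count reduced to the smallest
class if needed), identical folds for all four classifiers, error = plain
misclassification rate — adequate because all study datasets have balanced
classes. Standard implementations are used for the classifiers; the module
owns the protocol and hyperparameters: RF 500 trees and √d features per
split; SVM with RBF kernel, C = 1, kernel width 1/(d·Var(X)); KNN k = 5;
LDA with an automatic-shrinkage covariance estimator whenever the
fold-train sample count does not exceed the feature count (the pooled
covariance is singular there). Features are standardized inside the CV
loop by training-fold mean/sd for SVM, KNN and LDA; trees see raw values.

## Meta-regression (Step III)

25% of the meta-dataset rows (⌈0.25·n⌉) are held out at random. Per
classifier-error target:

* **linear** — OLS with rank-aware pivoting. When p ≥ n − 2 the fit keeps
  the first `min(rank, n − 2)` pivoted columns and scores the rest as
  aliased (coefficient and t-statistic 0); the cap preserves residual
  degrees of freedom so the |t| importances stay finite.
* **rf** — random forest, 500 trees by default; `mtry` tuned over 5 evenly
  spaced values from 2 to p (floored, matching the conventional grid
  layout), each scored by 10-fold CV on the training split (per-fold RMSE
  and R², mean ± sd reported); best mean R² wins and is refit on the full
  training split.
* **bayes_glm** — Bayesian linear regression with Gaussian priors fitted by
  evidence maximization on internally standardized predictors.

**R² convention.** R² is the squared Pearson correlation between predicted
and observed errors, with 0 for constant predictions. This matches the
convention of mainstream resampling frameworks and keeps near-zero values
non-negative where 1 − SSres/SStot would go negative; the latter is exposed
as a secondary diagnostic (`coefficient_of_determination`). The convention
is deliberately sign-blind: a perfectly anti-linear predictor also scores 1.

**Importance.** |t| for the linear model, accumulated impurity decrease for
the forest, both min–max scaled to [0, 100]; ties in rankings break
lexicographically. Because the univariate-discriminability meta-features
(t-statistic summaries, p-value counts, information-gain and ReliefF
summaries) are strongly correlated with one another — and, through the
sample-dispersion signal, with the Ball-Hall cluster indices — impurity
importance spreads over this family rather than concentrating on a single
member; which representative tops the list varies with scale and seed,
while the family as a whole reliably occupies the highest ranks. Cross-simulation similarity is the Spearman correlation
of full importance vectors (top-k lists would tie and truncate), computed
on the meta-features common to all simulations (zero-variance drops can
differ) with the linear model's importances averaged over the four targets.
The rf-vs-linear model comparison pools hold-out R² over (simulation ×
target) pairs and tests the paired difference with a Wilcoxon signed-rank
test (p = 1 when all differences vanish).

## Real-data ingestion

Delimited matrices with a class column. Inclusion requires exactly two
classes and ≥ 10 control samples (control = explicit label, else a label
containing "control"/"normal", else the lexicographically first). Values
are log2-transformed unless the maximum is below 30 (already-log
heuristic); non-positive values are shifted by min + 1 first (logged). The
⌈10%·G⌉ most variable genes post-log are kept. Class balancing augments
the minority class by a smoothed bootstrap: resample with replacement and
jitter with per-feature Gaussian noise of bandwidth
`sd_j · (4/((d+2)·n_min))^(1/(d+4))` (a Silverman-type rule), so synthetic
samples stay within the minority class's kernel support.

## Problem sizes and numerical choices

Default ensemble sizes are 500 trees (base RF classifier and meta-forest).
The bundled study runs use reduced sizes chosen once as the package's
desk-scale configuration: the acceptance recomputation uses 80 datasets per
part for S1 (240 datasets) and 30 per part for S9 (90), with 150-tree base
classifiers and a 300-tree meta-forest; the test suite uses 90/20 datasets
per part for S1/S9 and 8 per part for the seven other simulations, with
100–300 trees. The S1 sizes are chosen so the 75% training split exceeds
the meta-feature count and the linear meta-regression is full rank — as it
is at full scale — since OLS hold-out R² collapses when p approaches the
training size. Misclassification-rate means are insensitive to tree count
beyond ~100 trees, and hold-out R² at these sizes is stable to roughly
±0.05; quantities are therefore compared against full-scale reference
values with absolute tolerances of 0.1. At the smallest scales (the seven
8-per-part simulations) the linear model remains rank-deficient, so its
hold-out values and importances there are reported but intrinsically noisy.

What the simulator does *not* emulate: non-Gaussian noise, batch effects,
missing values, feature counts in the thousands (real arrays are reduced to
the top-10% variable genes before the workflow sees them), or
platform-specific normalization artifacts. Passing tests on synthetic
collections therefore demonstrate that the workflow recovers the
characteristics-to-performance mapping under its own generative
assumptions; on real microarray collections the attainable R² is expected
to be lower and the t-test-based meta-features to carry most of the signal.

## Known limitations

* The linear meta-regression is rank-deficient whenever p ≥ n; its
  hold-out R² is then highly variable (visible as near-zero values for
  some targets) and its importances cover only the pivoted columns.
* Cluster-index meta-features depend on the k-means restart seed for data
  without clear cluster structure; the seed is fixed and documented.
* The Bayesian model shares the linear model's additive-linearity
  assumption and mainly differs through shrinkage; it is not a substitute
  for a full posterior treatment.
* `run_usecase` mirrors the leave-datasets-out protocol on any meta-dataset
  (synthetic or ingested); the real-microarray numbers depend on external
  data collections and are not recomputed here.
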