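# Methods

## Model and procedure

The package classifies subjects described by functional-connectivity (FC)
feature vectors: for an `R`-region atlas, one Pearson correlation per
unordered region pair, flattened in row-major order over the strict upper
triangle (`(0,1), (0,2), …`). Correlations are raw `r`; no Fisher z
transform is applied. Constant region traces are an error rather than a
silent NaN, because a zero-variance signal makes the correlation
undefined and almost always indicates an upstream extraction fault.

The classifier is a random-subspace ensemble. From a training set of
`N₁` subjects, each of `k` base learners receives an independent uniform
draw, without replacement, of `n` subjects and `m` features. Sampling
without replacement follows from the defining draw of 45 subjects out of
48. Prediction is an unweighted majority vote; an exact tie (possible when
`k` is even) deterministically resolves to the control class (+1) so that
repeated runs are reproducible. Subject draws that land in a single class
are rejected and redrawn (at most 100 attempts) since a one-class
training set is untrainable.

Feature selection interprets the ensemble as a screening experiment: a
learner whose test accuracy exceeds the significance threshold (strictly
greater than 0.6) vouches for the `m` features it drew, and features are
ranked by their occurrence count across significant learners. Count ties
are broken by ascending feature index — a ranking must be a deterministic
permutation. The count total always equals
(#significant learners) × `m`, which the pipeline asserts on every run.
The candidate-size scan rebuilds ensembles restricted to top-`c` feature
pools for `c` in 140…240 (step 10); every candidate reuses the same
master seed so candidates differ only by their feature pool, and an
accuracy tie picks the smallest `c` (parsimony). Regions are weighted by
selected-edge incidence; the weight filter is strict (`weight >
min_weight`) and exposed as a parameter.

## Base learners

The default learner (`"mlp"`) is a one-hidden-layer feed-forward
classifier: 10 hidden units, L-BFGS optimization of the cross-entropy
objective, L2 penalty `alpha = 0.1`, at most 200 iterations, with
per-feature z-scoring fitted on each learner's own training rows and
re-applied at prediction. L-BFGS suits the tiny per-learner problems
(45 × 120); the relatively strong penalty counteracts overfitting when
features outnumber subjects roughly 3:1. Hitting the iteration cap is
logged, not raised — an unconverged learner is still a valid (weak)
ensemble member. A logistic-regression learner (`"logistic"`) is
registered for fast large-`k` runs, and `register_learner` accepts any
estimator with `fit`/`predict` over ±1 labels, which is how recurrent,
probabilistic or vector-quantization variants would be plugged in.

Per-learner significance is, by default, evaluated on the same held-out
test set that scores the ensemble, which is faithful to the original
protocol but leaks test labels into feature selection. An out-of-bag mode
(`evaluate_learners_oob`, `PipelineConfig(oob_evaluation=True)`) scores
each learner on the training subjects it never saw; with the default
45-of-48 draw that is only 3 subjects, so out-of-bag estimates are noisy
and the leaky mode remains the default, documented as a limitation.

## Randomness and determinism

A single master seed spawns one `SeedSequence` substream per learner;
subject draw, feature draw and learner initialization all consume that
learner's stream. The cohort split and each synthetic subject use further
dedicated streams. Identical (data, config, seed) therefore reproduce
identical subsets, accuracies, reports and CSV bytes, and a learner's
draws do not depend on `k`.

## Synthetic cohort

`simulate_cohort` draws each subject's `T × R` series as independent
multivariate-normal samples (Cholesky of the group correlation matrix):
the simplest generative model whose Pearson FC matches the analysis
assumptions. Defaults mirror the motivating study conditions: 36 controls
and 25 patients (61 subjects), 90 regions, `T = 130` timepoints (a
typical resting-state scan length after discarding initial volumes), 20
planted edges, background correlation `base_r = 0.1`, group difference
`delta = 0.4`. The patient group's correlation is `base_r + delta` on
planted edges. If the requested pattern is not positive semi-definite it
is repaired by eigenvalue clipping and re-normalization to unit diagonal;
a repair that moves any planted entry by more than `delta/4` raises a
configuration error instead of silently weakening the signal.
`simulate_feature_matrix` skips the time-series stage and emits FC-like
features directly (`base_r` + Gaussian noise, `noise_sd = 0.1` ≈ the
sampling scatter of a Pearson estimate near `T ≈ 100`, clipped to
[−1, 1]) for fast unit tests.

What the generator does **not** emulate: temporal autocorrelation and
hemodynamics, head motion, scanner noise, site effects, or realistic
anatomical covariance structure. Passing tests on this cohort demonstrate
that the machinery (draws, voting, filtering, counting, scanning,
weighting) behaves as specified — not that the method attains any
particular accuracy on real patient data.

## Problem sizes in the shipped checks

Desk-scale runs use `k = 200` learners (the acceptance script) or less
(unit tests and examples), against the library default of `k = 1000`; a
learner's behaviour does not depend on `k`, and ensemble accuracy at
`k = 200` is already stable on the synthetic cohort. The scan inside
small runs uses `scan_k` to decouple scan cost from the initial build.

## Known statistical limitation of the selection protocol

At desk scale the frequency ranking has low power, and this is a property
of the protocol rather than of the implementation. Two effects compound:

1. **Sparse counts.** A given feature is drawn by a learner with
   probability `m/E = 120/4005 ≈ 0.03`, so at `k = 200` each feature
   appears in only ~6 learners and occurrence counts carry Poisson-scale
   noise.
2. **A permissive significance filter.** On a 13-subject test set, a
   completely uninformative learner exceeds accuracy 0.6 whenever it gets
   ≥ 8/13 right — probability ≈ 0.29 for a fair coin, and higher with a
   majority-class bias on the unbalanced 8:5 test split. In practice
   half or more of all learners pass, so noise features accumulate counts
   almost as fast as planted ones.

Consequently, with 20 planted edges, `delta = 0.4` and `k = 200`, only
~6 % of planted edges reach the top 40 of the ranking (measured over five
seeds), even though learners containing planted edges are individually
far more accurate than chance. The enrichment is real but shallow — which
is why the downstream scan, which pools hundreds of top-ranked features,
still reaches perfect held-out accuracy while the top-40 overlap stays
near chance. Recovering most planted edges at the top of the ranking
would require either far more learners per feature (larger `k` or smaller
`E`) or a significance filter evaluated on more than 13 subjects. The
acceptance suite states the strong recovery property at the stated desk
scale and is expected to fail there; the chance-level control (`delta =
0`, overlap ≈ 40/4005) passes.

## Numerical and edge-case choices

- Train size is `floor(train_fraction · n)` — 61 subjects at 8:2 give
  exactly 48/13.
- Splits are redrawn (bounded) until the training set contains both
  classes; the test set may legitimately be single-class.
- Feature correlations are clipped to [−1, 1] to guard float round-off.
- An empty significant-learner set aborts the pipeline with guidance to
  lower the threshold rather than returning an empty ranking.
- Scan candidates larger than the number of features with nonzero counts
  are capped with a warning.
- Duplicate selected-edge indices are rejected in region weighting: the
  ranked selection cannot produce them, so they indicate a caller bug.
- BrainNet `.node` files encode the region weight as both color and size
  columns; both are plain integers and can be post-processed freely.
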