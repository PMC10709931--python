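# Methods

This note documents the models, parameters and design decisions behind
`mealtrace`, in the order the pipeline runs them.

## Signal model and grid conventions

The glucose signal is treated as a regular 5-minute grid anchored at the
first reading. A *gap* is a grid position with no reading (stored as NaN);
readings off the grid are snapped to the nearest position (ties keep the
first reading). Indices are 0-based and a window of length *n* starting at
*i* covers positions *i … i+n−1* inclusive. All subsequence machinery
(response extraction, distance profiles, feature windows) requires
contiguity: any window containing a gap is excluded rather than imputed,
because an imputed shape would be matched against learned response shapes
and could fabricate candidates.

Events are synchronized to the grid by assigning each logged timestamp the
index of the nearest *existing* reading (equidistant ties to the earlier
one, matching the tendency to log just before eating); events falling more
than one interval outside the covered range are dropped with a warning.

## Train / validation / test split

The split is by time span, not sample count: the final `test_span` is the
test set, the equal span before it is validation, and the remainder is
training. With `test_span` equal to a quarter of the record this yields
the familiar 50–25–25 layout. Splitting by span keeps whole days together,
which the per-day evaluation needs, and the boundaries partition both
samples and events exactly once.

## Response patterns

A meal response is the 2-hour window (`Δ_response`, 24 samples) starting
at a synchronized meal's grid index. Responses are z-normalized
(population sd; windows with sd < 1e-8 are flagged degenerate and
excluded) and clustered into `|P| = 3` groups by agglomerative clustering
with average linkage on Euclidean distance between shapes. Each pattern is
its cluster's **medoid** — the member with minimal summed distance to the
rest — so every search query is a shape the participant actually produced.
Centroid averaging was the alternative; medoids were chosen because
averaged shapes blur the timing of the peak, which is exactly what
distinguishes response types. Clustering is deterministic given input
order; the `seed` argument exists for interface uniformity.

## Distance profiles

For each pattern the z-normalized Euclidean distance to every subsequence
of T is computed with the MASS identity: with the query z-normalized, the
squared distance at offset *j* is `2n − 2·dot_j/sd_j`, where the sliding
dot product comes from one FFT convolution and the window means/sds from
cumulative sums. Profiles are computed per contiguous gap-free segment and
stitched with `+inf` sentinels at positions whose window would cross a
gap, overrun a segment, or has zero variance — this implements the
non-contiguous-candidate exclusion upstream of selection. Finite values
lie in `[0, 2√n]`. A brute-force O(m·n) oracle (explicit z-normalization
per window) is kept in the package and the two routes are required to
agree within 1e-6; in practice they agree to ~1e-13.

## Candidate selection

Two parameters drive selection: `d_cutoff = 4` (on the z-normalized
distance scale for n = 24, where a noise-only window sits near √(2n) ≈ 6.9)
and `Δ_valley = 2 h` (24 samples).

*Valley picking*, per pattern: candidate positions are strict local
minima of the profile below `d_cutoff` (plateaus take the leftmost index;
segment-boundary positions count when lower than their inner neighbour).
Minima are accepted greedily in ascending distance (ties to the earlier
position) while any remaining minimum strictly closer than 24 samples to
an accepted one is suppressed, so accepted positions are always at least
`Δ_valley` apart.

*Global grouping*, across patterns: accepted candidates are clustered on
their start times with 1-D agglomerative average-linkage clustering, the
dendrogram cut at `Δ_valley`, and each cluster reduced to its
minimum-distance member (ties: earlier time, then lower pattern id).
Grouping operates on the whole split at once rather than per day. The cut
threshold is unified with `Δ_valley` by default but independently
settable.

A static per-pattern top-n selection (no suppression, no grouping) is
included as the baseline this dynamic procedure improves on.

## Features, labels and the training table

Each candidate window yields nine features (glucose at start, forward
difference over one grid step as the derivative estimate — causal and
in-window —, hours since local midnight, and min/max over the window with
their delays in minutes and mean slopes in mg/dl/min, slopes defined as 0
when the extremum is the start itself; argmin/argmax ties take the
earliest sample). A candidate is labeled Meal when its start lies in the
closed interval ±`δ_margin = 1 h` around any logged meal.

The training table contains all labeled candidates **plus** one positive
row per logged meal that is matched by at least one Meal candidate,
featurized at the meal's own synchronized grid index (skipped when that
window is gapped). Meals matched by no candidate ("dangling") contribute
nothing: the classifier's job is to judge candidates, and a meal the
selection never reached gives it nothing to judge. A candidate within the
margin of two meals is one row, and each matched meal adds at most one
augmentation row.

## Classifiers and model selection

Six stock scikit-learn classifiers (AdaBoost, decision tree, gradient
boosting, Gaussian naive Bayes, MLP, random forest) are fitted with
library-default hyperparameters — each is a replaceable tool, not a tuned
contribution — with stochastic estimators seeded and the parameters echoed
to the run log. The MLP may stop at its default iteration cap; that is
accepted as part of the default-parameter contract.

Selection is per participant and *event-level*: each model's positive
candidates on the validation split are matched to logged meals within
`δ_margin` and scored with F2 (β = 2 weights recall, since a missed meal
costs more than a spurious reminder). Ties break on F1, then on a fixed
roster order, so the winner does not depend on model list order. With
tp = 0 all scores are 0 by convention.

## Evaluation

Matching is one-to-one greedy nearest-time within `δ_margin` (ties: earlier
prediction, then earlier meal), which guarantees the count identities
`tp + fp = predictions` and `tp + fn = meals`. Per-day reports partition
events and predictions at local midnight and evaluate days independently
(a prediction within margin of a meal across a midnight boundary is not
matched; this is a documented convention). Two aggregations are provided
and always labeled: **pooled** (sum counts, then compute metrics) and
**macro** (arithmetic mean of per-day counts and per-day metrics) — they
genuinely differ on unbalanced days, so both exist.

Reference confusion-count tables with known rounded metric values are
frozen in `mealtrace._reference`; tests recompute every cell from the raw
counts with exact rational arithmetic and half-even decimal rounding.

## Synthetic data generator

The generator emulates the statistical structure the method assumes and
nothing more:

* **baseline** — mean 120 mg/dl, ±10 mg/dl circadian sinusoid, plus a slow
  mean-reverting (Ornstein–Uhlenbeck) wander with stationary sd 15 mg/dl
  and 3 h correlation time, standing in for everything non-meal that moves
  the baseline (insulin sensitivity, stress, activity);
* **meal responses** — additive kernels: smooth sine-squared rise to an
  amplitude at the peak, exponential decay with a half-life, optional
  early dip, truncated smoothly to zero at 4 h. The default library has
  three deliberately distinct shapes (fast 80 mg/dl spike peaking at
  30 min; dipped mixed-meal response peaking at 80 min; slow 45 mg/dl
  response peaking at ~2 h), chosen so pairwise z-normalized shape
  distances exceed the within-shape distance induced by sensor noise —
  the separability precondition for pattern identification, asserted by a
  test;
* **schedule** — breakfast/lunch/dinner windows at 95% daily probability
  plus an optional afternoon snack at 30%;
* **imperfections** — Gaussian sensor noise (sd 5 mg/dl), values clipped
  to the 40–400 mg/dl sensor range, dropout in geometric-length runs
  (2% of samples by default, exercising the contiguity handling),
  self-report jitter (sd 5 min) and optional missed log entries.

The generator is **not** a physiological simulator: responses add
linearly, insulin dynamics, exercise and carbohydrate content are absent,
and baseline wander is stationary. Passing tests on it show that the
pipeline recovers recurring response shapes under noise, dropout and
imperfect logging — not that it achieves any particular accuracy on
clinical CGM data, where response shapes drift and confounds correlate
with mealtimes.

Default study conditions for end-to-end checks: 28 simulated days
(≈ 8 000 grid positions, ~100 meals), 50–25–25 split (7-day test span).
At these sizes the whole suite runs in seconds.

## Numerical choices and degenerate inputs

* z-normalization epsilon: sd < 1e-8 → degenerate (all-zero shape,
  excluded from clustering; `+inf` in profiles).
* Squared distances are clamped at 0 before the square root to absorb
  FFT round-off.
* An all-gap detection span yields zero candidates; its meals are counted
  as false negatives against raw timestamps.
* `f_beta` raises on all-zero counts rather than returning a silent 0.

## Known limitations

* Pattern count `|P|` is fixed (default 3), not selected from data.
* Selection is offline (whole-split); no streaming mode for real-time
  control loops.
* Per-day evaluation ignores cross-midnight matches.
* The classifier roster is deliberately untuned; on hard participants the
  selection can only pick the least-bad default model.
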