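# Methods

This note records the modelling choices, defaults and numerical
conventions behind `strsa`, and what the synthetic-study tests do and do
not establish about real recordings.

## Analysis conventions

* **Time.** All time coordinates are milliseconds relative to stimulus
  onset.  A window labelled *t* covers the half-open interval
  [*t*, *t* + *w*); windows are truncated at the epoch end and must retain
  at least 3 samples, otherwise they are skipped (NaN in the series, with
  a logged notice) and excluded from every summary.
* **RDMs.** Dissimilarity is `1 − Spearman ρ` with average ranks for ties
  (the standard convention; the dissimilarity scale is [0, 2]).  The
  diagonal is conceptually undefined; it is stored as 0 and never
  consumed — analyses read only the lower triangle, in row-major order
  (row *i*, columns *j* < *i*).  A zero-variance response vector raises a
  `DegenerateInputError` naming the offending category rather than
  silently propagating NaN, because silent NaNs would corrupt permutation
  nulls downstream.
* **Joint "variance explained".** OLS R² of the rank-transformed neural
  lower-triangle vector on the rank-transformed layer vectors plus an
  intercept.  The rank transform keeps the joint model on the same scale
  as the Spearman-based single-layer comparisons.  A rank-deficient layer
  set is fitted through the pseudoinverse with a logged collinearity
  warning — correlated layer RDMs are the expected situation, not an
  error.
* **Residual sign convention.** Residual = observed − fitted
  *dissimilarity*, rescaled from rank units back to dissimilarity units by
  the ratio of raw to rank standard deviations.  Negative residuals
  therefore mean the model predicted the categories to be *more
  dissimilar* than the brain shows.  Residual summaries average over
  50–250 ms and participants, then block-average into the 3 × 3
  superordinate matrix; within-block cells use only that block's
  off-diagonal pairs.
* **Permutation inference.** The second-level null draws one independent
  full relabeling per participant per permutation and stores the
  group-mean statistic (permutation 0 is the identity, so the observed
  statistic is element 0 of its own null).  Tests are one-sided.
  Pointwise thresholds use the (1 − α/m) null quantile, where the
  Bonferroni divisor m defaults to the number of units tested
  simultaneously; cluster extent requires a suprathreshold run strictly
  longer than the (1 − α) quantile of the null's maximum run length.
* **Noise ceiling.** Upper: mean Spearman correlation of each
  participant's vector with the group mean (including that participant —
  an overestimate by construction).  Lower: leave-one-participant-out.
  Degenerate participant vectors are excluded with a logged notice; at
  least 3 participants are required.
* **Scalp clustering.** z(e, t) = (V − baseline mean) / baseline SD per
  electrode; two-sided point threshold (default p < .001).  Because a
  closed-form random-field test is ill-defined on an irregular sensor
  graph, the cluster-size threshold is calibrated by Monte-Carlo on
  Gaussian noise fields smoothed on the adjacency graph to match the
  baseline's neighbor correlation — the same inferential contract, with
  explicit calibration.  Components are tracked across consecutive time
  points by Jaccard overlap > 0.5 (the persistence criterion needs a
  tracking rule, and set overlap is the simplest one); tracks must outlast
  20 ms.  A cluster's electrode set is its *core* membership — electrodes
  present in at least half of the track's time slices, restricted to the
  largest connected component — so a one-off noise electrode that brushes
  the component for a single slice does not join the cluster.
* **Preprocessing.** Artifact screening is strict (|V| > threshold); a
  sample exactly at ±100 μV survives.  A participant retaining fewer than
  half of their trials is excluded with an explicit error.  Rejection and
  baseline correction are idempotent.  The band-pass is a 4th-order
  zero-phase Butterworth (applied forward–backward, so stop-band
  attenuation doubles in dB), with the per-trial mean removed explicitly
  first: an 850 ms epoch is far shorter than the 0.1 Hz settling time, so
  the recursive filter alone cannot remove DC within an epoch.  The
  pipeline leaves the band-pass off by default for generated data —
  zero-phase high-passing of brief epochs smears evoked energy into a slow
  undershoot that contaminates the post-stimulus baseline, and filtering
  belongs to continuous-recording ingestion.  Average re-referencing is
  available but off by default for the same reason: synthetic data are
  generated reference-free.
* **Sub-average bootstrapping.** Each valid trial of a category with n_c
  valid trials is replaced by the mean of ⌈fraction · n_c⌉ distinct valid
  same-category trials.  The anchor trial is always included — this keeps
  every surrogate tied to one real trial and makes fraction = 1/n_c
  degenerate to the identity, and fraction = 1 to the category mean.
  Surrogates are drawn once per participant with sampling keyed to
  (participant, category, within-category ordinal) derived from the master
  seed, so a surrogate depends only on its anchor's position among the
  category's valid trials.
* **Decoding.** One-vs-rest linear SVM (C = 1, default regularization)
  with per-dimension standardization fitted on training folds only;
  stratified 5-fold splits are shared across layers so layer accuracies
  are directly comparable.

## The synthetic study

The generator emulates the design the package targets: 30 scene
categories (10 indoor, 10 urban outdoor, 10 natural outdoor) × 75
exemplars, 8 feature layers of increasing category separability, 256
electrodes at 1000 Hz, 100 ms baseline + 750 ms stimulus epochs, 13
participants ("study" preset).  The "desk" preset scales this to 10
exemplars, 32 electrodes, 250 Hz and 5 participants so calibration
Monte-Carlos run on one CPU.

**Category geometry.** Each layer holds a latent category embedding
(default 4 dimensions).  Embeddings follow an autoregressive chain across
layers — `E_l = √c · rotate(E_{l−1}) + √(1−c) · innovation`, coupling
c = 0.35 — so neighboring layers' RDMs correlate (as consecutive stages
of a real hierarchy do, which exercises the joint model's collinearity
handling) while distant layers decorrelate.  A chain is used rather than
pure shared-plus-rotation structure because rotations preserve pairwise
distances, which would make all layer RDMs essentially identical and
unrecoverable.  Exemplar activations are random projections of the
embeddings scaled by the layer's separability plus unit-variance noise;
larger separability means higher decodability.

**Forward model.** Voltage at electrode e, time t, for a trial of
category c:

    V = Σ_l loading_l(e) · env_l(t) · [offset + Σ_j m_lj(t) s_lj(c)/√q] · A + noise

`env_l` is a Gaussian bump at the layer's planted latency (FWHM 60 ms,
centers 70, 95, …, 245 ms — spaced so summary statistics land in the
onset range a fast visual hierarchy produces), zero before stimulus
onset.  `loading_l` is a binary spatial region: alternating angular
sectors of the outer disc, assigned round-robin so the two layers sharing
a region are 100 ms apart and their envelopes barely overlap.  The
category signal is *rank-q* (q = 4): q standardized projections of the
layer embedding, each driven by a fixed random band-limited (3–22 Hz)
temporal modulator under the envelope.  A rank-1 (single scalar) signal
would let a sliding-window RDM see only the sign structure of one
projection — a binary geometry that correlates weakly and unspecifically
with every layer's RDM — whereas the rank-q signal writes the layer's
actual category geometry into the window.  The offset term is the
category-unspecific evoked deflection that scalp clustering detects.
Noise is white Gaussian by default (1/f optional, for realism demos
only).

**Noise and amplitude defaults.** No per-trial SNR is available to anchor
these, so they are set once to values a scalp-EEG practitioner would call
realistic and kept: trial noise 10 μV and evoked amplitude 8 μV for the
desk/study presets — large enough to be realistic, small enough that
Gaussian noise stays ≥ ~6 SD below the ±100 μV artifact threshold, so
injected-spike screening is exact across millions of samples.  The
"ordered" preset used for parameter-recovery checks runs at amplitude
5 μV / noise 6 μV with separability 0.8–3.0: at much lower noise every
envelope tail is detected almost immediately and onsets compress toward
stimulus onset; at much higher noise layers drop out.  The recovery
checks are only informative in this calibrated regime, which is a
statement about the synthetic test harness, not about real data.

**What the synthetic tests show — and don't.** Passing tests establish
that the implementation recovers structure it planted: oracle-exact RDMs,
calibrated false-positive control of the cluster-corrected mask, correct
ordering of planted latencies, recovery of planted scalp regions, ordered
noise ceilings, decoder chance calibration, and bitwise reproducibility.
They do not show that real recordings satisfy the forward model: real
EEG has correlated, non-stationary noise, volume conduction, eye and
muscle artifacts beyond simple voltage spikes, and category signals that
are not low-rank products of envelopes and loadings.  Quantities measured
on real data (onsets, peak latencies, ceiling heights, cluster layouts)
will differ from the synthetic values.

## Problem sizes

Desk-scale analyses step the sliding window at 4 ms (one sample at
250 Hz) for pipeline runs, 8 ms for the 10-seed recovery study and 12 ms
for the 200-run false-positive Monte-Carlo; permutation counts are 1000
for pipeline runs and 100–200 for the Monte-Carlos.  These are
problem-size choices for the bundled studies; the study-scale defaults
(1 ms step, 1000 permutations) remain the package defaults wherever a
single dataset is analysed.

## Known limitations

* The whole-scalp unit averages per-electrode RDM vectors rather than
  averaging per-electrode encoding traces; the two agree in the regimes
  tested but are not identical estimators.
* Cluster tracking is greedy in time (best Jaccard match per step); it
  does not split or merge tracks.
* The Monte-Carlo cluster-size calibration matches first-order neighbor
  correlation only, not the full spatial covariance.
* Electrode positions live on an abstract unit disc; no head geometry,
  conductivity or source model is implied.
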