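# Methods

This note documents the models, parameter choices and numerical conventions
behind `s1pop`, and what the synthetic cohorts do and do not establish about
real recordings.

## Signal model and preprocessing

Raw fluorescence is a cells × frames matrix in arbitrary units at a fixed
frame period (default 0.229 s/frame, the acquisition rate the pipeline was
designed around). Per cell, the baseline F₀ is the mean of the
floor(0.3·N) smallest samples (at least one sample) — a deterministic
reading of "the lowest 30 %" that needs no interpolation. A baseline ≤ 0
raises a degenerate-baseline error, since ΔF/F₀ = (F − F₀)/F₀ is undefined
there; note this can happen even when some samples are positive (e.g. a
trace that sits at zero for over 30 % of frames).

Trial peaks P*ᵢⱼₖ* are window maxima of ΔF/F₀ over
[onset, onset + duration + post_window), frames 0-based and windows
half-open. The post-window (default 2 s of frames) exists because the
GCaMP6s indicator decays with τ ≈ 1.5 s, so the transient outlasts stimulus
offset. Max*ᵢ* is taken over the cell's entire recording by default
(`max_scope="trace"`), which guarantees PI ∈ [0, 1]; a `"windows"` scope is
available. A cell is a responder when any trial peak strictly exceeds the
0.30 threshold; the same strict threshold defines response fidelity (the
fraction of supra-threshold trials). The responder rule is evaluated on
peaks within stimulus windows, not anywhere in the trace — the conservative
choice when inter-stimulus noise is appreciable. Trial means that fall
below zero (a window entirely under baseline) are clipped to PI = 0.

## Tuning indexes and categories

PI*ᵢⱼ* = mean*ₖ*(P*ᵢⱼₖ*)/Max*ᵢ*; tuned iff PI*ᵢⱼ* > 0.8 · mean PI of the
cell (strict, so an all-zero row is tuned to nothing); tuned to every
stimulus = broadly tuned. Venn categories are the seven non-empty subsets of
a three-stimulus session. In the 2×2 texture × dynamics design, a cell is
texture-discriminative when its tuned set is *exactly* one same-texture pair
(and dynamics-discriminative analogously); this exact-set reading is the
strictest formalization of "preferentially responsive to both, regardless of
the other feature", and a superset-matching relaxation is available via
`mode="superset"`. Population percentages are computed per mouse first and
then averaged, so the reported mean ± s.e.m. is across animals.

Intensity profiles use the same index across graded pinch levels.
Categories: `intensity_coding` when every adjacent step rises by more than
the tolerance, `inverse` when every step falls, `invariant` when all
pairwise differences stay inside the tolerance, else `irregular`. The
tolerance defaults to 10 % of the cell's grand-mean amplitude — a "similar
amplitude" band that has no canonical value; 10 % is tight enough to keep
intensity-coding cells out of `invariant` and loose enough to absorb
trial-mean noise at low noise levels. A known consequence: with five trials
per level, genuine invariant cells are misclassified as irregular whenever
one of six pairwise differences exceeds the band (~40–50 % of them at trial
cv 0.1), so the invariant percentage is an undercount; the intensity-coding
class, whose steps are several times the tolerance, is recovered almost
perfectly.

## State-space geometry

Frames × cells ΔF/F₀ is mean-centered per cell only (ΔF/F₀ is already a
per-cell normalized unit; variance scaling is available but off by default)
and projected with exact-SVD PCA onto 3 components by default. Frames are
labelled stimulus / pre-stimulus (2 s before onset) / inter-stimulus, with
stimulus response windows (including the post-window) taking precedence.
Condition separation is the mean Euclidean distance over all cross-condition
frame pairs, with the s.e.m. over pooled pair distances. Multi-mouse
cohorts project each mouse separately (cells are not shared across animals)
and pool pair distances afterwards. Stimuli are clustered by their cell-PI
columns with average-linkage Euclidean agglomeration; linkage and metric are
recorded in the output and configurable, since no canonical choice exists.

## Selectivity permutation test

For a stimulus pair, each non-broadly-tuned responder contributes a point
(PI*ₐ*, PI*_b*); the observed statistic is the mean perpendicular distance
|PI*ₐ* − PI*_b*|/√2 to the equally-tuned diagonal. The null reshuffles the
pairing: PI*_b* is permuted across cells (both marginals preserved, all
association destroyed), and the null distribution is taken over
per-reshuffle *mean* distances, so z = (observed − null mean)/null s.d.
measures displacement of the population mean; a pooled-pair null (over
individual reshuffled distances) is selectable by config. Broadly tuned
cells are excluded before the test — they sit near the diagonal for any
pair by construction. Default 10,000 reshuffles: the Monte-Carlo s.e. of
the null mean is then ~1 % of the null s.d., ample for a z statistic, and
the empirical two-sided p = (r + 1)/(R + 1) resolves to 10⁻⁴ before
Bonferroni adjustment over the tested pairs. A null with (numerically)
zero spread — e.g. one margin constant, or one margin entirely dominating
the other so every pairing gives the same mean distance — raises a
degenerate-null error rather than returning an unbounded z.

## Decoding

Trial vectors are per-trial population peak patterns; multi-mouse
pseudo-populations concatenate cells across sessions at matched trial index
(sessions must share trial counts). Classification is k-NN (k = 5,
Euclidean) with deterministic tie-breaking: neighbors ordered by (distance,
training index), vote ties resolved by smaller mean neighbor distance, then
lower class index — predictions never depend on a seed. Folds are
stratified with seed-controlled round-robin assignment; with 5 trials per
class and 10 folds this degenerates to leave-one-out, which is accepted.
No feature scaling is applied (peaks share ΔF/F₀ units); z-scoring is
available. The label-permutation p counts permuted cross-validation runs
reaching the observed accuracy, +1-corrected. With 5 trials per class,
permutations preserving the class partition (probability 2·(5!)²/10! ≈
0.79 %) reproduce perfect accuracy, so the p-value for a perfect decoder
saturates near 0.009 no matter how many permutations are run; sessions with
10 trials per class push that floor to ~10⁻⁵.

## The synthetic cohorts

The simulator renders F(t) = F₀·(1 + Σ a·kernel(t − onset)) + ε with a
unit-peak difference-of-exponentials kernel (rise τ 0.18 s, decay τ 1.5 s —
GCaMP6s-like), lognormal trial amplitudes (mean-preserving, cv default 0.3)
and i.i.d. Gaussian frame noise proportional to F₀ (photon noise scales
with brightness; σ default 0.1). Baselines are uniform 80–120 a.u.; evoked
amplitudes uniform 0.6–2.0 ΔF/F₀. Stimulus order is shuffled per trial
block; ISIs are uniform in 15–20 s (20 s for pinches); times floor to
frames.

Four population factories define the study conditions, with class mixtures
assigned by largest-remainder rounding (exact counts, no sampling noise):

* **Brush/Press/Pinch** (4 mice × 55 cells): seven Venn subsets among
  responders — 17.0 % brush-specific, 0.92 % press-specific, 5.99 %
  pinch-specific, 13.4 % press∩pinch, 50.2 % broadly tuned, and the two
  remaining subsets splitting the residual 12.49 % evenly; plus 10 %
  silent cells.
* **2×2 texture × dynamics** (4 mice × 52 cells): 20 % texture-, 3 %
  dynamics-discriminative, 50 % broad, 27 % other (tuned to exactly one or
  three stimuli).
* **Graded pinch P0..P3** (6 mice × 33 cells): 21.93 % intensity-coding
  (level gains 0.12/0.2/0.32/0.5, chosen so threshold crossings spread
  across levels and recruitment rises monotonically), 15.30 % invariant,
  1.53 % inverse, 61.24 % irregular (supra-threshold non-monotone gain
  orders, so they add amplitude scatter rather than recruitment noise).
* **Feature contrasts** (6 mice × 24 cells): 20 % brush-exclusive cells,
  52 % forceps-responsive cells whose F-pinch amplitude is 1.5× their
  F-press amplitude with tight per-cell jitter (sd 0.1) and whose F-stroke
  amplitude tracks press loosely (sd 0.3), 28 % broadly tuned. The pinch
  gain makes the noxiousness contrast a systematic population-pattern
  difference (hence decodable) while keeping per-cell tuning co-varying
  (hence negative z); the looser stroke jitter does the same for dynamics
  with a less negative z.

Analysis conditions: recovery-style analyses (tuning categories, intensity
classes) run at σ = 0.05 and trial cv = 0.1. Both noise sources feed the
0.8·mean-PI rule — at trial cv 0.3 the rule alone misclassifies ~16 % of
genuinely broad cells, so class-mixture recovery is only meaningful at low
trial variability. The feature-contrast session runs at σ = 0.05, trial
cv = 0.2, the regime in which 5-trial k-NN decoding of its pattern
differences is reliably perfect. The generator default σ = 0.1 is retained
for general use but sits near the responder threshold: with i.i.d. frame
noise, the lowest-30 % baseline is biased low by ~1.16 σ and a ~30-frame
window maximum adds ~2 σ, so silent cells approach the 0.30 peak threshold.

What the simulator does *not* emulate: correlated (shared) trial-to-trial
variability, slow drift and bleaching, neuropil contamination, spiking
nonlinearity and indicator saturation, overlapping ROIs, or behavioural
state changes. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under its stated assumptions, not the
biological conclusions one would draw from real recordings.

## Determinism

Every stochastic step takes an explicit seed; cohort seeds are spawned from
a single root via `SeedSequence`. The pipeline runner regenerates all
numeric outputs byte-identically under a fixed configuration. Problem
sizes throughout (cells per mouse, 10,000 reshuffles, 1,000 label
permutations) are desk-scale choices that keep a full cohort run in
seconds while leaving Monte-Carlo error negligible for the statistics
reported.
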