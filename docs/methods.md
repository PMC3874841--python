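# Methods

This note documents the models, estimators and design choices implemented
in `tensionlab`, in the order a user meets them: time alignment, feature
quantification, the trend-salience tension model, window optimization,
activity analysis, and the synthetic data generator. Statements about
behavior (calibration, recovery rates, runtimes) refer to quantities the
test suite and `scripts/acceptance.py` themselves compute.

## Time alignment (`timebase`)

A performance with expressive timing maps nonlinearly between clock time
(seconds) and metrical time (measures). The map is built from marked note
onsets: the clock time of every 1/36 of a measure is linearly interpolated
between the nearest onsets with known metrical positions. 1/36 is the
coarsest grid containing both the quadruple (1/12-measure) and triple
(1/9-measure) subdivisions of the quarter notes of a 3/4-type measure.
Choices:

- Measures and in-measure positions are 0-based; measure ranges are
  inclusive. Display conventions that count from "m. 1" are a +1 offset.
- Nearest-neighbor resampling resolves ties to the *earlier* sample
  (deterministic, causality-friendly).
- Onsets sharing a metrical position (chords across voices) collapse to
  their mean clock time before interpolation.
- Missing samples are explicit NaN; `extract_excerpt` fills measures absent
  from a shortened variant (e.g. a harmonic reduction) either by linear
  interpolation or by NaN blocks (`gap_mode`), never silently.
- The linear-interpolation error between onsets is far below the window
  durations (≥ 0.5 s) any downstream analysis uses.

## Feature quantification (`features`)

Seven descriptors, all eventually step functions resampled onto the 10 Hz
rating clock and Z-scored (n−1 denominator; the fitted mean/std are stored
on the series):

- **loudness** — consumed as a precomputed perceptual loudness series in
  sones; the package does not compute loudness from audio.
- **onset frequency** — (maximum inter-onset duration) − (current
  inter-onset duration), on onsets pooled across voices with events closer
  than 30 ms merged; denser music scores higher, the longest event scores 0.
  The reference maximum defaults to the maximum observed duration.
- **tempo** — 60 / inter-beat interval (BPM) held between beats; beats
  without onsets are recovered by linear interpolation of metrical position
  against clock time over all onsets.
- **pitch height** (melody, inner, bass) — MIDI pitch held between each
  voice's onsets, NaN where the voice is inactive. The three voices share
  one pooled normalization so register differences survive scaling.
- **harmony** — the mean tension rating of a harmonic reduction sampled
  2 s after each chord's reduction onset (compensating response delay;
  sample times past the series end clamp to the last sample, with a
  warning, rather than dropping the final chord), held from each
  performance onset of that chord; chords the reduction omits reuse the
  preceding chord's value.

## Trend-salience model (`trend_model`)

Per feature *f* with windows (d_att, d_mem), on the h = 0.25 s grid:

1. s_f(t): OLS slope of the feature over [t − d_att, t]. A zero-duration
   attentional window extracts no trend (the feature contributes a zero
   curve). Startup windows (t < d_att) are truncated and renormalized;
   windows with < 2 non-missing samples yield NaN, which propagates.
2. Memory comparison: the slope over [t − d_att − d_mem, t − d_att] (the
   interval *immediately preceding* the attentional window — this adjacency
   is the implemented reading of the memory term). If both slopes exceed
   1e-12 in magnitude and share a sign, s_f is multiplied by β (default 5).
   The 1e-12 sign floor prevents β from firing on numerical noise.
3. S_f(t) = Σ_{τ=0}^{m−1} s′_f(t − τh) k_τ with m = d_att/h steps and
   decaying weights k_τ ∝ r^τ, r = 0.75, normalized to sum 1 (the exact
   decay profile is unconstrained by the model statement beyond Σk = 1 and
   recency weighting; geometric decay is the package default and `uniform`
   is available in the configuration). Early/missing terms renormalize over
   the available weights.
4. F_f(t) = h Σ_{i<t/h} S_f(i), with F(0) = 0 exactly; NaN contributions
   integrate as 0 (the curve holds level across gaps).

Final stage: the per-feature curves F_f enter one more pass of the same
machinery with d_att = 1 s, d_mem = 0 and equal weights 1/N (feature
weights are deliberately unused — timescales alone differentiate the
features), producing F_ten. With every d_mem = 0 the whole model is a
linear operator; the test suite asserts additivity and homogeneity to 1e-9.

## Window optimization (`optimizer`)

Objective: Spearman rank correlation between F_ten sampled at beat times
and the mean response sampled at beats + 2 s (response lag). Beat sampling
avoids the massive autocorrelation of 10 Hz samples; Spearman is used
because feature and response distributions are not normal.

Search: 10 variables — five window groups (the three pitch voices share
one group, on the assumption their timescales are identical) × {attentional,
memory} — on a 0–20 s grid in 0.5 s steps, starting from all-zero
durations. Phase 1 takes one variable at a time in a fixed, documented
order (loudness, pitch, harmony, onset frequency, tempo; attentional before
memory) and moves it to the peak of its 1-D correlation profile; sweeps over
all variables repeat until a full pass moves nothing. Phase 2 perturbs each
variable ±2 grid steps and accepts improvements, bounded to 5 sweeps.
Within-phase ties (Δρ < 1e-12) prefer the shorter duration; non-finite
correlations (constant predictions) rank below everything. The trace of
every evaluation is returned, and accepted steps never decrease the
objective.

An earlier variant stopped each variable at the *first* local maximum
while incrementing. That rule stalls on sub-1e-3 dips: on a noiseless
model-generated target whose true harmony window is 8.5 s it stopped at
0.5 s. Full 1-D scans with repeated sweeps are still step-wise coordinate
ascent (no joint or gradient search) and strictly dominate it; they are
the default.

### Identifiability: what fitted windows mean

On model-generated targets the generating windows are the global optimum
(ρ = 1.0 exactly, noiseless) and a locally strict peak. The surface is
nonetheless severely multimodal: features can compensate for one another,
and within a feature long-attentional/short-memory combinations mimic
short-attentional/long-memory ones, because the final cumulative
integration makes rank correlations insensitive to changes in the
smoothing scale of the differentiated series. Coordinate ascent — even
strengthened with multiple starts and per-feature 2-D refinements —
regularly converges to basins at ρ 0.97–0.999 with windows many grid steps
from the generating ones. The window-recovery test in the suite asserts
strict ±0.5 s recovery of all ten durations and documents this
quantitatively — it fails, and is expected to fail, under any bounded
step-wise search; fitted windows from any such search should be interpreted
as one member of a family of near-equivalent timescale assignments, not as
point identification.

## Activity analysis (`activity`)

**Change events.** Sample-to-sample differences accumulate; an event fires
when the accumulated change in the requested direction since the last
event (or since the last direction reversal — the accumulator clamps at
zero when the slider moves the other way) reaches 1.0 rating units (1% of
the 0–100 scale); the accumulator then resets to zero.

**Coordination score.** For every distinct slicing of the timeline into
adjacent frames of fixed duration (one slicing per sample offset), the
histogram of per-frame active-rater counts is tested against independence
with each rater active at its own empirical frame rate: the null count
distribution is Poisson-binomial, expected counts below 5 are merged into
adjacent bins (greedy, left to right), and a Pearson chi-square p results.
The score is the mean of −log₁₀ p over slicings, with both the per-slicing
values and the mean clamped to [0, 16] (so a single astronomically small
slicing p cannot dominate). Score 2 ⇔ p = 0.01. This reconstruction of the
goodness-of-fit procedure (per-rater rates rather than one pooled rate —
strictly more conservative — and the ≥5-expected merging rule) follows
standard chi-square practice; a pooled-rate variant is one flag away.
Under simulated independence (25 raters, 235 one-second frames, ~0.2
activity), the score's 95th percentile across 200 replicates is ≈ 0.6–0.7,
comfortably below 2; the acceptance script recomputes this.

**Alternation score.** Per slicing, frames are cross-classified by
high/low increase activity × high/low decrease activity and tested for
independence (2×2 chi-square). The high/low split is at the median,
preferring the strict split (count > median) and falling back to the
inclusive one when the median coincides with an extreme (near-binary count
sequences); a slicing with no valid split contributes p = 1.

**Local coordination.** Each shuffle draws one uniform shift per rater
from [−5, 5] s (rounded to the 0.1 s grid), rotates that rater's point
process circularly (ends looped, conserving event counts and serial
structure), and recomputes per-frame activity levels; 1000 shuffles per
analysis, one RNG seed. The per-frame p is the mid-rank of the observed
level among the alternatives (fraction above + half the tied fraction);
levels are discrete multiples of 1/n_raters, so ties are heavy and a
strict-exceedance rank would realize size ≈ 0.03 instead of the nominal
0.05 — mid-rank restores ≈ 0.05 ± 0.02, which the acceptance test checks.
Frames with p < 0.05 are flagged. A single-rater collection gets p = 1
everywhere (rotation cannot change a one-rater level's rank meaningfully).

**Summaries.** `collection_summary` reports the mean rating, the std over
time of the across-rater mean series, and the STD ratio (that std divided
by the time-average across-rater std; near 0 = noise or contradiction,
near 1 = strong common shape; undefined, with a warning, when raters are
identical).

## Synthetic data (`synthetic`)

The generator emulates the conditions of a continuous tension-rating
study: 25 raters, 10 Hz, 0–100 slider, ~10 s orienting period, per-rater
response lags of 1–3 s, rating-change threshold 1% of scale, and 1 s-frame
activity rates around 0.2.

- **Stimulus**: ~60 BPM, three beats per measure, smooth rubato (beat
  period modulated with ~2-beat correlation time plus 1% motor jitter —
  real rubato is smooth, not white), 0–2 melody subdivisions per beat, bass
  on downbeats, an inner voice only over the middle third. Loudness is a
  smooth positive arc (~1.5 s correlation time); harmony a mean-reverting
  step function changing every ~5.5 s. A `correlation` knob blends one
  shared smooth component into all Z-scored features (pairwise ρ → knob²);
  at 0 the features are independent with chance |ρ| ≲ 0.2.
- **Latent tension**: the trend-salience model run forward on the features
  with known windows, affinely rescaled to [20, 80] of the slider (rank
  preserving), giving recovery tests a ground truth.
- **Coordinated raters**: each rater tracks the lagged latent curve
  through gain/offset distortion about mid-scale, slow idiosyncratic drift
  (shape disagreement between raters), a movement dead zone of 3 rating
  units with per-sample action probability 0.35 (producing stepwise slider
  trajectories and realistic event sparsity), motor noise on movements,
  clipping to [0, 100], and an orienting ramp from slider position 0 over
  the first 10 s (the interface start position is taken as 0).
- **Null raters**: increase and decrease events are independent
  stationary gamma renewal processes (shape 2 — more regular than Poisson,
  preserving the serial structure circular-shift tests respect), calibrated
  by bisection on long simulated realizations so the 1 s-frame activity
  rate matches the request (±0.03); the slider steps ±1.1 units per event
  so binarization recovers the generated events exactly.

What the generator does *not* emulate: verse/phrase structure and
repetition effects, lyric semantics, timbre, feature cross-correlations
beyond a single shared component, time-varying lags, or rater drop-out.
Passing tests therefore demonstrate the statistical machinery — null
calibration, score bounds, linearity, recovery behavior — not fidelity to
any particular musical corpus.

## Problem sizes and determinism

Analyses and tests run at study scale: 235 s stimuli, 25 raters, 200
replicates for null calibration, 1000 shuffles for local coordination, 20
seeded replicates for window recovery. Every stochastic stage takes an
explicit seed; identical seeds reproduce byte-identical outputs (the
pipeline writes its seed and a resolved configuration next to every run).
Times are serialized at 6 decimals; CSV is the only interchange format.
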