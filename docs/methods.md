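# Methods

This note documents the model implemented by `remsacc`, the defaults and
why they hold, the synthetic-data world used for validation, and the
numerical choices a user re-running or extending the package should know
about.

## Signal model and preprocessing

The analysis channel is a single periocular EOG lead (EOG1). Eye
rotations displace the corneo-retinal dipole, so a saccade appears as a
step-like deflection: a rapid rise (tens of milliseconds), a brief
plateau at the peak, and a deceleration onto a new resting level. Blinks
are slower, larger, monophasic deflections that return to baseline;
non-ocular artifacts are broadband bursts or slow wobbles.

Processing is restricted to REM intervals taken from an epoch-based
hypnogram (30 s epochs by default; maximal runs of REM epochs become
half-open sample intervals). Within each interval, in fixed order:

1. **Baseline removal** — subtraction of a centred moving average
   (default 1.5 s, rounded to an odd sample count; shrinking windows at
   the edges preserve length without phase shift).
2. **Band-pass** — zero-phase (forward–backward) 2nd-order Butterworth,
   1–10 Hz. Saccadic energy lives in this band; drift and EMG are
   attenuated.
3. **Normalisation** — z-score with the interval's own mean and
   *population* standard deviation (no Bessel correction; the choice is
   immaterial at REM-interval lengths but is fixed for reproducibility).
   A flat interval (SD < 1e−12) is flagged degenerate and zeroed.

Statistics never mix REM with surrounding stages, which keeps the
amplitude scale comparable across subjects and hours of the night.

## Hybrid segmentation

Two complementary per-sample scores are computed on the normalised
signal and min–max scaled to [0, 1] within the interval:

* **Amplitude score.** The absolute first difference
  d(t) = |x(t) − x(t−1)| is thresholded at T_amp = k_MAD·MAD(d)
  (default k_MAD = 3; MAD floored at 1e−12 for degenerate inputs).
  Supra-threshold samples contribute their derivative magnitude
  (`amp_score_mode="magnitude"`, the default) or a binary indicator.
* **Morphology score.** The maximum absolute inner product between the
  signal window and a unit-energy saccade prototype over temporal shifts
  within ±50 ms — a matched filter made jitter-tolerant by a sliding
  maximum. Positions whose whole shift window falls outside the valid
  correlation support score zero. The implementation (cross-correlation
  plus a maximum filter) is exactly equivalent to the brute-force double
  loop; the test suite asserts agreement to 1e−9.

The fused score S(t) = α·S_amp + (1−α)·S_morph (default α = 0.5)
is thresholded at its interval mean plus three standard deviations
(strict exceedance; a constant trace yields no candidates). Maximal
supra-threshold runs are the candidate segments.

**Refinement** merges runs separated by less than g = 80 ms, drops runs
shorter than 20 ms, and moves each boundary to the argmax of |dx/dt|
within ±40 ms, clipping at the midpoint when two segments would collide.
Merging precedes dropping by default (`refine_order="merge_first"`):
dropping first can destroy a true event whose threshold crossing is
split; the opposite order remains available as a configuration switch.

Two defaults deserve their rationale spelled out:

* **Minimum duration 20 ms, although no saccade is shorter than
  ~30 ms.** The gate applies to the *supra-threshold run*, which is
  strictly shorter than the event that produces it; a 30 ms gate
  systematically deletes correctly detected 30–45 ms saccades whose runs
  span only 3–6 samples. 20 ms stays above the correlation scale of
  10 Hz-low-passed noise, so noise blips do not survive.
* **Kernel length 0.10 s.** The matched-filter score is indexed by
  window start and the prototype's peak is centred, so a kernel much
  longer than the events it matches responds up to (L − dur)/2 *before*
  a short saccade — beyond the reach of the ±40 ms boundary refinement,
  which in early experiments produced merged neighbouring events and
  ~100 ms onset bias. At the physiological mean saccade duration
  (0.10 s) the response is aligned with the event.

## The saccade prototype

`build_saccade_kernel` averages verified saccade waveforms: each is
normalised to unit peak, resampled to a common length by linear
interpolation, circularly shifted so its largest-magnitude sample sits
at the centre, sign-aligned so the peak is positive, averaged, and
L2-normalised. The shipped default kernel is built from 200 synthetic
three-phase saccades, each **band-limited (1–10 Hz) before averaging**:
the prototype must live in the same passband as the signal it is
correlated with, otherwise its DC content makes the matched filter
respond to residual drift. The kernel is persisted as plain text with a
one-line header (length and reference rate).

The classification templates are rising and falling logistic steps
(default steepness 12, midpoint 0.5), mean-removed and unit-energy, so a
flat segment correlates to exactly zero and correlations with
unit-energy segments are bounded by 1. With midpoint 0.5 the falling
template is the exact negative of the rising one and the two absolute
correlations coincide; the direction label then defaults to "rising" and
is not used downstream.

## Segment classification

Each candidate segment yields two features: peak-to-peak amplitude
(z-units) divided by duration (s) — a main-sequence proxy — and the
larger absolute template correlation of the resampled, mean-removed,
unit-energy segment. A soft-margin RBF SVM (C = 10, γ = "scale",
one-vs-one, features standardised with training-set statistics only)
separates saccade / blink / artifact.

Two training entry points exist, for two different jobs:

* `train_default_classifier` follows the balanced published design:
  equal per-class waveform banks split 2.33:1 (per-class train count
  round(0.6995·n), reproducing 298 train / 128 validation from 426 per
  class; classes first downsampled to the minority count; one segment
  never appears in both splits).
* `train_pipeline_classifier` trains on **segments produced by the
  segmentation itself**, run over small annotated synthetic nights, with
  each segment labelled by its best ground-truth overlap (artifact if it
  overlaps nothing). Detected segments are the thresholded steep
  portions of events — a different distribution from idealised whole
  waveforms — and a classifier deployed on segmentation output must be
  trained on the same distribution. Here classes are weighted inversely
  to frequency instead of downsampled, because spurious detections (the
  artifact class) are rare on clean synthetic recordings.

`tune_hyperparameters` provides a seeded random/grid search over any
objective (the event-level tuning objective rewards correct detections
and penalises fragmentation and merging at double weight, with a timing
term on boundary MAE); the backend is deliberately pluggable.

## Burst grouping and microstructure

Saccade-labelled segments are ordered; maximal runs form bursts, and
adjacent bursts merge when at most two non-saccadic segments lie between
them. Two additions, both the package's own choices:

* **Temporal continuity guard** (`max_gap`, pipeline default 3 s):
  saccades further apart never share a burst. The segment-count rule
  alone presumes a detector busy enough that "two segments" implies
  temporal proximity; over a quiet stretch with no detections it would
  otherwise bridge arbitrarily long ocularly-silent spans into phasic
  episodes. 3 s matches inter-eye-movement criteria used for burst
  definitions in REM-density work.
* **Span bias correction** (`span_bias_correction=True` in
  `analyze_night`). A burst span measured from the first to the last
  *detected* saccade is negatively biased when the detector catches only
  a subset of the burst's events. If detections subsample the event
  train roughly uniformly, the expected lost margin on each side equals
  the mean gap between consecutive detections. The true inter-event slot
  is estimated by the 25th percentile of inter-detection onset spacings
  (gaps containing no missed event; robust to the miss-inflated upper
  tail), and each burst with ≥3 members is extended on both sides by
  (mean − p25) of its spacings, capped at half the continuity guard and
  clipped to the interval and to midpoints between bursts. The
  underlying `reconstruct_phasic_tonic` stays a pure union/complement:
  phasic and tonic intervals tile each REM interval exactly.

Per-subject aggregation is duration-weighted (durations summed over
intervals, then converted to minutes and percentages), not a mean of
per-interval percentages; the phasic/tonic ratio is NaN when a night
contains no tonic REM.

## Evaluation

Segmentation is scored per ground-truth event: **correct** (exactly one
overlapping prediction, which overlaps no other GT event), **fragmented**
(≥2 overlapping predictions), **merged** (its sole prediction also
overlaps another GT event), **missed** (none) — a partition, asserted by
property tests. Percentages are GT-denominated; the detected-to-GT ratio
reports over-segmentation separately; onset/offset MAE is computed over
correct pairs and a strict variant additionally requires both deviations
within ±20 ms. A predicted saccade counts as a classification true
positive when it overlaps a GT event by at least 20 ms (boundary
inclusive, with a 1 ns float guard). Cohen's κ is computed from the full
3×3 table as (P_o − P_e)/(1 − P_e) and cross-checked against
scikit-learn in the tests. Pointwise (per-sample) metrics are
deliberately not provided: they reward partial overlap and hide
fragmentation.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (configuration, seed). Defaults:
sampling 250 Hz; saccade durations 30–150 ms and peak amplitudes 1.5–3.0
z-units with a settling level at 0.6 of peak; blinks 0.2–0.4 s at 2.5×
saccade amplitude (wake-like recordings) or saccade-comparable amplitude
inside REM nights — blinking is suppressed during REM, where residual
non-saccadic events are twitch-scale; artifacts are enveloped noise
bursts or half-sine wobbles; background is white Gaussian noise
(0.3 z) plus a 20 s-period drift sinusoid (1 z). Events are inserted
additively and the annotation covers exactly the event support; the
abrupt return at the event offset stands in for the AC-coupled return of
a real recording. Benchmark recordings place ~100 saccades in clustered
bursts over 10 minutes (10 movements/min, mid-range of physiological REM
eye-movement density). Full nights alternate N2 padding with REM bouts
whose bursts (8–25 saccades, 0.2–0.5 s intervals, ≥5 s between bursts)
are laid down until they cover the target phasic fraction (default
0.318) to within ±0.02; tonic stretches receive ≥3 spaced blinks.

What the generator does **not** emulate: coloured/EMG-structured noise,
electrode impedance shifts and slow nonstationarities, the main-sequence
correlation between saccade amplitude and duration (drawn
independently), slow eye movements of sleep onset, REM-behaviour-disorder
pathology, or EEG/EMG channels. Passing the synthetic benchmarks
therefore demonstrates correctness of the algorithmic chain under the
stated morphology and noise model — not clinical-grade performance on
real PSG, which varies with hardware, montage and scoring practice.

## Problem sizes and determinism

The shipped benchmarks run 20 recordings × 600 s for event-level rates,
a 426-per-class waveform bank for classification, and 10 nights × 80 min
REM for phasic recovery — sizes at which every check completes in
seconds on one CPU while keeping ≥2000 scored events per run. All
randomness flows through explicit integer seeds; reported quantities are
reproducible bit-for-bit for a fixed seed and stable to ±~0.5 points
across seeds.

## Known limitations

* The mean+3SD boundary rule adapts to the interval's activity level: in
  densely phasic intervals the threshold floats into the middle of the
  saccade score distribution and per-event sensitivity drops to ~60%,
  which is why the span bias correction exists. Recordings dominated by
  a few very large events compress the min–max normalised scores of the
  rest.
* The classifier is only as good as its training distribution;
  applying `train_default_classifier` (whole-waveform bank) to
  segmentation output mislabels blink flanks as saccades. Use
  `train_pipeline_classifier` for pipeline deployment.
* Single-channel design: no binocular confirmation, no montage
  re-referencing, no multichannel voting.
* Hypnogram quality bounds everything downstream; REM intervals are
  taken as given.
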