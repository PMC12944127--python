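# remsacc

Detection of saccadic eye movements in single-channel EOG during REM
sleep, and reconstruction of the phasic/tonic REM microstructure.

REM sleep is not homogeneous: brief clusters of rapid eye movements
(**phasic REM**) alternate with ocularly quiet stretches (**tonic REM**),
and the two sub-states differ in cortical activation, sensory gating and
memory-related physiology. Quantifying them at scale requires detecting
individual saccades in overnight polysomnographic EOG — a signal full of
drift, blinks and muscle artifact, where fixed-threshold or wavelet
detectors fit real saccade morphology poorly. `remsacc` implements a
morphology-aware detection pipeline for sleep researchers working with
standard PSG recordings (EDF or plain text, one EOG channel, an
epoch-based hypnogram).

## Method

For each expert-scored REM interval, the EOG channel x(t) is detrended
(1.5 s moving average), band-passed (zero-phase 2nd-order Butterworth,
1–10 Hz) and z-scored with the interval's own statistics,
x_norm(t) = (x(t) − μ_REM)/σ_REM. Two per-sample scores are then fused:

* **Amplitude score** S_amp(t): the absolute first derivative
  d(t) = |x(t) − x(t−1)| gated at a robust threshold
  T_amp = k_MAD · MAD(d), so only rapid voltage transitions contribute;
* **Morphology score** S_morph(t) = max_{τ∈T} |Σ_k x(t+k+τ) h_sac(k)|,
  the maximum absolute correlation with a unit-energy saccade prototype
  h_sac over a small shift window — a matched filter tolerant to jitter.

Both scores are min–max normalised within the interval and combined as
S(t) = α·S_amp(t) + (1−α)·S_morph(t). Candidate segments are maximal
runs where S(t) exceeds its REM-level mean by more than three standard
deviations; refinement merges segments separated by less than a gap g,
drops sub-physiological fragments, and snaps boundaries onto local
extrema of |dx/dt|.

Each candidate segment is reduced to two features — the
amplitude–duration ratio (the saccadic main sequence) and the larger of
its absolute correlations with rising/falling log-sigmoid templates —
and labelled *saccade*, *blink* or *artifact* by an RBF-kernel SVM.
Consecutive saccades are grouped into bursts (with a temporal continuity
criterion), phasic REM is the union of burst spans, tonic REM its
complement, and per-subject durations, proportions and the phasic/tonic
ratio are aggregated over the night.

A synthetic-data module generates the full study world — three-phase
log-sigmoid saccades, blinks, artifacts, drift and noise, burst-structured
REM intervals and whole nights with a controllable phasic fraction — so
every stage is testable against known ground truth. Event-level accuracy
is scored GT-centrically (correct / fragmented / merged / missed, ±20 ms
temporal tolerance for the strict variant), classification with
precision, recall, specificity, F1 and Cohen's κ.

## Worked example

Detect saccades in a synthetic 10-minute REM recording with 100
scheduled saccades, moderate noise and drift, and score the result
against the ground truth:

```python
import numpy as np
from remsacc import (SynthConfig, REMInterval, default_kernel, make_burst_schedule,
                     synth_rem_recording, detect_segments_interval, match_events)

fs = 250.0
cfg = SynthConfig(fs=fs, seed=1)                      # noise 0.3 z, drift on
schedule = make_burst_schedule(duration_s=600.0, n_saccades=100, seed=1)
signal, truth = synth_rem_recording(cfg, schedule, duration_s=600.0)

kernel = default_kernel(fs)                            # unit-energy saccade prototype
interval = REMInterval(0, signal.size, fs)             # treat the recording as one REM bout
_, segments = detect_segments_interval(signal, fs, interval, kernel)

result = match_events([(e.onset_s, e.offset_s) for e in truth],
                      [(s.start / fs, s.end / fs) for s in segments])
print(f"events: {len(truth)} true, {len(segments)} detected")
print(f"correct {result.correct_pct:.1f}%  fragmented {result.fragmented_pct:.1f}%  "
      f"missed {result.missed_pct:.1f}%")
print(f"onset MAE {result.onset_mae_ms:.1f} ms, offset MAE {result.offset_mae_ms:.1f} ms")
```

Output:

```
events: 100 true, 100 detected
correct 100.0%  fragmented 0.0%  missed 0.0%
onset MAE 38.5 ms, offset MAE 6.5 ms
```

Every true saccade was recovered by exactly one detected segment, none
was split or merged, and segment edges sit a few tens of milliseconds
from the annotated boundaries. For a whole night, `analyze_night`
returns the labelled segments per REM interval plus a
`MicrostructureSummary` (phasic/tonic minutes, percentages and ratio).

The same workflows are available from the shell:

```sh
remsacc simulate night --seed 1 --out-prefix scratch/night
remsacc reconstruct --signal scratch/night.signal.csv --fs 250 \
    --hypnogram scratch/night.hypnogram.txt --out scratch/micro.csv
remsacc evaluate --gt gt.csv --pred pred.csv --tol-ms 20
```

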