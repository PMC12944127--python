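"""Self-contained benchmark runs on synthetic ground truth.

These drive the package end to end under reproducible conditions: seeded
recordings with known saccade schedules for event-level segmentation
accuracy, a balanced waveform bank for classifier accuracy, and full
synthetic nights for phasic-fraction recovery.
"""

from __future__ import annotations

import numpy as np

from .classify import features_from_waveform, make_training_sets, predict_labels, train_classifier
from .evaluation import classification_metrics, match_events
from .io import REMInterval
from .kernel import SaccadeKernel, default_kernel
from .pipeline import (
    analyze_night,
    default_templates,
    detect_segments_interval,
    train_pipeline_classifier,
)
from .segmentation import SegmentationParams
from .synth import SynthConfig, make_burst_schedule, synth_full_night, synth_labeled_segments, synth_rem_recording

#: Recording length for ~100 scheduled saccades: 10 eye movements per
#: minute, the midpoint of physiological REM eye-movement density.
RECORDING_DURATION_S = 600.0


def segmentation_benchmark(
    seeds: list[int],
    n_saccades: int = 100,
    duration_s: float = RECORDING_DURATION_S,
    noise_sd: float = 0.3,
    fs: float = 250.0,
    kernel: SaccadeKernel | None = None,
    params: SegmentationParams | None = None,
) -> dict[str, float]:
    """Event-level segmentation accuracy over seeded synthetic recordings.

    Each recording carries burst-structured saccades with drift and white
    noise; the full preprocess + hybrid segmentation + refinement chain
    runs at the given (default) parameters and is scored with GT-centric
    matching.  Returns per-metric means over recordings.
    """
    kernel = kernel or default_kernel(fs)
    rows = []
    for seed in seeds:
        cfg = SynthConfig(fs=fs, seed=seed, noise_sd=noise_sd)
        sched = make_burst_schedule(duration_s, n_saccades, seed=seed)
        x, events = synth_rem_recording(cfg, sched, duration_s=duration_s)
        interval = REMInterval(0, x.size, fs)
        _, segs = detect_segments_interval(x, fs, interval, kernel, params)
        gt = [(e.onset_s, e.offset_s) for e in events]
        pred = [(s.start / fs, s.end / fs) for s in segs]
        r = match_events(gt, pred)
        rows.append(
            (r.correct_pct, r.fragmented_pct, r.missed_pct, r.merged_pct, r.detected_gt_ratio)
        )
    m = np.mean(rows, axis=0)
    sd = np.std(rows, axis=0)
    return {
        "correct_pct": float(m[0]),
        "fragmented_pct": float(m[1]),
        "missed_pct": float(m[2]),
        "merged_pct": float(m[3]),
        "detected_gt_ratio": float(m[4]),
        "correct_pct_sd": float(sd[0]),
        "n_recordings": len(seeds),
        "n_events_per_recording": n_saccades,
    }


def classification_benchmark(seed: int = 0, n_per_class: int = 426, fs: float = 250.0) -> dict[str, float]:
    """Saccade-class metrics of the SVM on the balanced waveform bank.

    426 labelled waveforms per class split 2.33:1 into the balanced
    894-segment training and 384-segment validation sets; metrics are
    one-vs-rest for the saccade class plus Cohen's kappa over all three.
    """
    cfg = SynthConfig(fs=fs, seed=seed)
    rising, falling = default_templates(L=int(round(0.1 * fs)))
    labeled = [
        (features_from_waveform(w, fs, rising, falling), lab)
        for w, lab in synth_labeled_segments(cfg, n_per_class, seed=seed)
    ]
    train, val = make_training_sets(labeled, seed=seed)
    clf = train_classifier(train, seed=seed)
    classes = ("saccade", "blink", "artifact")
    y = [lab for _, lab in val]
    p = predict_labels(clf, [f for f, _ in val])
    cm = np.zeros((3, 3))
    for t, q in zip(y, p):
        cm[classes.index(t), classes.index(q)] += 1
    m = classification_metrics(cm)
    return {
        "f1": m.f1,
        "precision_pct": m.precision_pct,
        "recall_pct": m.recall_pct,
        "specificity_pct": m.specificity_pct,
        "kappa": m.kappa,
        "n_train": len(train),
        "n_val": len(val),
    }


def phasic_recovery_benchmark(
    seeds: list[int],
    n_rem_intervals: int = 4,
    interval_len_s: float = 1200.0,
    fs: float = 250.0,
    classifier_seed: int = 0,
) -> dict[str, float]:
    """Full-pipeline phasic-REM percentage on synthetic nights.

    Nights are generated at the default phasic-fraction target (0.318);
    the pipeline segments, classifies, burst-groups and reconstructs, and
    the estimated phasic percentages are averaged across nights.
    """
    kernel = default_kernel(fs)
    clf = train_pipeline_classifier(seed=classifier_seed, kernel=kernel)
    est, true = [], []
    for seed in seeds:
        night = synth_full_night(
            SynthConfig(fs=fs, seed=seed), n_rem_intervals=n_rem_intervals, interval_len_s=interval_len_s
        )
        res = analyze_night(night.signal, night.fs, night.hypnogram, kernel=kernel, classifier=clf)
        est.append(res.summary.phasic_pct)
        true.append(100.0 * night.true_phasic_fraction)
    return {
        "phasic_pct_mean": float(np.mean(est)),
        "phasic_pct_sd": float(np.std(est)),
        "true_phasic_pct_mean": float(np.mean(true)),
        "n_nights": len(seeds),
        "rem_minutes_per_night": n_rem_intervals * interval_len_s / 60.0,
    }
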