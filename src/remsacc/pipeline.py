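"""End-to-end convenience layer: recording + hypnogram in, microstructure out.

Chains the preprocessing, hybrid segmentation, SVM labelling, burst
grouping and phasic/tonic reconstruction stages over every REM interval
of a night.  Each stage remains individually usable; this module only
wires them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    SegmentFeatures,
    TrainedClassifier,
    extract_features,
    features_from_waveform,
    make_training_sets,
    predict_labels,
    train_classifier,
)
from .io import EventAnnotation, Hypnogram, REMInterval, extract_rem_intervals
from .kernel import SaccadeKernel, SigmoidTemplate, default_kernel, log_sigmoid_template
from .microstructure import (
    Burst,
    MicrostructureSummary,
    correct_span_bias,
    group_bursts,
    reconstruct_phasic_tonic,
    summarize_subject,
)
from .preprocess import PreprocessedSignal, preprocess_interval
from .segmentation import Segment, SegmentationParams, segment_interval
from .synth import SynthConfig, synth_labeled_segments


def default_templates(L: int, steepness: float = 12.0, midpoint: float = 0.5) -> tuple[SigmoidTemplate, SigmoidTemplate]:
    """Rising and falling log-sigmoid templates matched to the kernel length."""
    return (
        log_sigmoid_template("rising", L, steepness, midpoint),
        log_sigmoid_template("falling", L, steepness, midpoint),
    )


def train_default_classifier(
    seed: int = 0,
    n_per_class: int = 426,
    config: SynthConfig | None = None,
    C: float = 10.0,
    gamma: float | str = "scale",
) -> TrainedClassifier:
    """Train the segment classifier on balanced synthetic labelled waveforms.

    426 waveforms per class split 2.33:1 reproduce the balanced
    298-train / 128-validation per-class design; only the training portion
    is used for fitting.
    """
    cfg = config or SynthConfig(seed=seed)
    rising, falling = default_templates(L=int(round(0.1 * cfg.fs)))
    labeled = [
        (features_from_waveform(w, cfg.fs, rising, falling), lab)
        for w, lab in synth_labeled_segments(cfg, n_per_class, seed=seed)
    ]
    train, _ = make_training_sets(labeled, seed=seed)
    return train_classifier(train, C=C, gamma=gamma, seed=seed)


def label_segments_by_overlap(
    segs: list[Segment],
    events: list[EventAnnotation],
    fs: float,
    offset: int = 0,
) -> list[str]:
    """Ground-truth label per detected segment: class of the best-overlapping event.

    Segments intersecting no annotated event are labelled ``artifact`` —
    they are spurious detections by definition.
    """
    out: list[str] = []
    for seg in segs:
        a, b = (offset + seg.start) / fs, (offset + seg.end) / fs
        best_lab, best_ov = "artifact", 0.0
        for ev in events:
            ov = min(b, ev.offset_s) - max(a, ev.onset_s)
            if ov > best_ov:
                best_ov, best_lab = ov, ev.label
        out.append(best_lab)
    return out


def train_pipeline_classifier(
    seed: int = 0,
    kernel: SaccadeKernel | None = None,
    params: SegmentationParams | None = None,
    config: SynthConfig | None = None,
    n_nights: int = 2,
    n_rem_intervals: int = 2,
    interval_len_s: float = 600.0,
    C: float = 10.0,
    gamma: float | str = "scale",
) -> TrainedClassifier:
    """Train the SVM on segments produced by the segmentation itself.

    Small annotated synthetic nights are segmented and every candidate
    segment is labelled by its ground-truth overlap (saccade / blink when
    it intersects such an event, artifact otherwise).  Training on
    segmentation output from the same dense-REM regime the classifier will
    see in deployment matters: detected segments are the thresholded steep
    portions of events, not idealised whole-event waveforms, and their
    feature distribution depends on the event density of the interval.
    Classes are weighted inversely to frequency instead of downsampled —
    spurious detections (the artifact class) are rare in clean recordings.
    """
    from dataclasses import replace

    from .synth import synth_full_night

    cfg = config or SynthConfig(seed=seed)
    kernel = kernel or default_kernel(cfg.fs)
    rising, falling = default_templates(kernel.L)
    labeled: list[tuple[SegmentFeatures, str]] = []
    for i in range(n_nights):
        night = synth_full_night(
            replace(cfg, seed=seed * 1009 + 7 + i),
            n_rem_intervals=n_rem_intervals,
            interval_len_s=interval_len_s,
        )
        for interval in extract_rem_intervals(night.hypnogram, cfg.fs):
            pre, segs = detect_segments_interval(night.signal, cfg.fs, interval, kernel, params)
            labels = label_segments_by_overlap(segs, night.annotations, cfg.fs, offset=interval.start)
            for seg, lab in zip(segs, labels):
                labeled.append((extract_features(seg, pre.x, cfg.fs, rising, falling), lab))
    return train_classifier(labeled, C=C, gamma=gamma, seed=seed, class_weight="balanced")


@dataclass
class IntervalResult:
    """Everything the pipeline derived from one REM interval."""

    interval: REMInterval
    preprocessed: PreprocessedSignal
    segments: list[Segment]  # interval-local coordinates, labelled
    phasic: list[tuple[int, int]]  # global sample coordinates
    tonic: list[tuple[int, int]]


@dataclass
class NightResult:
    """Pipeline output for a whole night."""

    intervals: list[IntervalResult]
    summary: MicrostructureSummary

    def saccade_events(self, fs: float) -> list[EventAnnotation]:
        """Detected saccades as annotations in seconds from recording start."""
        out = []
        for res in self.intervals:
            off = res.interval.start
            for seg in res.segments:
                if seg.label == "saccade":
                    out.append(
                        EventAnnotation(
                            onset_s=round((off + seg.start) / fs, 3),
                            offset_s=round((off + seg.end) / fs, 3),
                            label="saccade",
                        )
                    )
        return out


def detect_segments_interval(
    signal: np.ndarray,
    fs: float,
    interval: REMInterval,
    kernel: SaccadeKernel,
    params: SegmentationParams | None = None,
) -> tuple[PreprocessedSignal, list[Segment]]:
    """Preprocess one REM interval and run the hybrid segmentation on it."""
    pre = preprocess_interval(signal, fs, interval)
    if pre.degenerate:
        return pre, []
    segs, _ = segment_interval(pre.x, fs, kernel, params)
    return pre, segs


def analyze_night(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    kernel: SaccadeKernel | None = None,
    classifier: TrainedClassifier | None = None,
    params: SegmentationParams | None = None,
    templates: tuple[SigmoidTemplate, SigmoidTemplate] | None = None,
    burst_max_gap_s: float = 3.0,
    span_bias_correction: bool = True,
) -> NightResult:
    """Run the full detection pipeline over every REM interval of a night.

    ``burst_max_gap_s`` is the temporal continuity criterion for burst
    membership: saccades further apart never share a burst.
    ``span_bias_correction`` widens each detected burst span by its mean
    inter-detection gap, compensating the loss of burst margins when only
    a subset of the burst's saccades clears the detection threshold.
    """
    kernel = kernel or default_kernel(fs)
    classifier = classifier or train_pipeline_classifier(kernel=kernel, params=params)
    rising, falling = templates or default_templates(kernel.L)
    intervals = extract_rem_intervals(hypnogram, fs)
    if not intervals:
        raise ValueError("hypnogram contains no REM epochs")
    results: list[IntervalResult] = []
    for interval in intervals:
        pre, segs = detect_segments_interval(signal, fs, interval, kernel, params)
        feats = [extract_features(s, pre.x, fs, rising, falling) for s in segs]
        labels = predict_labels(classifier, feats)
        labeled = [Segment(s.start, s.end, label=lab) for s, lab in zip(segs, labels)]
        bursts = group_bursts(labeled, max_gap=int(round(burst_max_gap_s * fs)))
        # shift burst spans to global coordinates for reconstruction
        global_bursts = [
            Burst(
                member_segments=[
                    Segment(m.start + interval.start, m.end + interval.start, m.label)
                    for m in b.member_segments
                ]
            )
            for b in bursts
        ]
        if span_bias_correction:
            global_bursts = correct_span_bias(
                global_bursts,
                interval.start,
                interval.end,
                max_extend=int(round(burst_max_gap_s * fs / 2)),
            )
        phasic, tonic = reconstruct_phasic_tonic(global_bursts, interval)
        results.append(
            IntervalResult(interval=interval, preprocessed=pre, segments=labeled, phasic=phasic, tonic=tonic)
        )
    summary = summarize_subject([(r.phasic, r.tonic) for r in results], fs)
    return NightResult(intervals=results, summary=summary)
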