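"""Synthetic EOG generator: saccades, blinks, artifacts, REM recordings, nights.

Every generator is a pure function of its configuration and seed.  The
emulated physiology:

* **Saccades** are step-like displacements of the corneo-retinal dipole —
  a rapid log-sigmoid rise, a short plateau at peak (slight overshoot), and
  a log-sigmoid deceleration onto a new resting level.  Direction (left /
  right eye movement) flips the sign.
* **Blinks** are longer, larger monophasic raised-cosine deflections that
  return to baseline.
* **Artifacts** are broadband noise bursts (EMG intrusion) or slow
  half-sine wobbles (movement / electrode drift).
* Background is white Gaussian noise plus a slow sinusoidal baseline
  drift; REM intervals carry burst-structured saccade trains, tonic
  stretches carry occasional isolated blinks.

Amplitudes are expressed in the z-units the preprocessing stage produces;
defaults put saccade peaks an order of magnitude above the noise floor, as
in clinical-grade periocular EOG.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import EventAnnotation, Hypnogram


@dataclass
class SynthConfig:
    """Parameters of the synthetic EOG world.

    Durations in seconds, amplitudes in z-units.  ``phasic_fraction_target``
    is the fraction of REM time the generated saccadic bursts should cover
    in a full synthetic night.
    """

    fs: float = 250.0
    saccade_dur_range_s: tuple[float, float] = (0.03, 0.15)
    saccade_amp_range: tuple[float, float] = (1.5, 3.0)
    saccade_rest_frac: float = 0.6
    saccade_steepness: float = 12.0
    blink_dur_range_s: tuple[float, float] = (0.2, 0.4)
    blink_amp_scale: float = 2.5
    artifact_dur_range_s: tuple[float, float] = (0.1, 0.5)
    artifact_amp_range: tuple[float, float] = (0.8, 2.0)
    noise_sd: float = 0.3
    drift_amp: float = 1.0
    drift_period_s: float = 20.0
    burst_saccades: tuple[int, int] = (8, 25)
    intra_burst_isi_s: tuple[float, float] = (0.2, 0.5)
    min_burst_gap_s: float = 5.0
    tonic_blink_rate_hz: float = 0.3
    # blinking is suppressed in REM sleep: non-saccadic tonic events are
    # eyelid twitches of saccade-comparable amplitude, not wake-scale blinks
    tonic_blink_amp_scale: float = 1.0
    phasic_fraction_target: float = 0.318
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.saccade_dur_range_s,
            self.saccade_amp_range,
            self.blink_dur_range_s,
            self.artifact_dur_range_s,
            self.artifact_amp_range,
            self.intra_burst_isi_s,
        ):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")
        if not (0 < self.phasic_fraction_target < 1):
            raise ValueError("phasic_fraction_target must lie in (0, 1)")


def synth_saccade(
    fs: float,
    dur_s: float,
    amp: float,
    direction: int = 1,
    rest_frac: float = 0.6,
    steepness: float = 12.0,
) -> np.ndarray:
    """Three-phase saccade waveform: sigmoid rise, plateau, sigmoid deceleration.

    The rise occupies 40% of the duration, the plateau 20%, and the fall
    40%, settling at ``rest_frac`` of the peak (a new eye position with a
    slight overshoot at the peak).  Peak magnitude equals ``amp``;
    ``direction`` = -1 negates the waveform.
    """
    if dur_s <= 0:
        raise ValueError("duration must be positive")
    if amp == 0:
        raise ValueError("amplitude must be nonzero")
    n = max(int(round(dur_s * fs)), 5)
    n_rise = max(int(round(0.4 * n)), 2)
    n_fall = max(int(round(0.4 * n)), 2)
    n_plat = max(n - n_rise - n_fall, 1)

    def _sig(m: int) -> np.ndarray:
        k = np.arange(m, dtype=float)
        s = 1.0 / (1.0 + np.exp(-steepness * (k / (m - 1) - 0.5)))
        return (s - s[0]) / (s[-1] - s[0])  # exactly 0 -> 1

    rise = _sig(n_rise)
    plateau = np.ones(n_plat)
    fall = 1.0 - (1.0 - rest_frac) * _sig(n_fall)
    w = np.concatenate([rise, plateau, fall])[:n]
    return float(np.sign(direction)) * abs(amp) * w


def synth_blink(fs: float, dur_s: float, amp: float, direction: int = 1) -> np.ndarray:
    """Monophasic raised-cosine blink deflection returning to baseline."""
    if dur_s <= 0:
        raise ValueError("duration must be positive")
    n = max(int(round(dur_s * fs)), 5)
    k = np.arange(n, dtype=float)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n - 1)))
    return float(np.sign(direction)) * abs(amp) * w


def synth_artifact(fs: float, dur_s: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Non-ocular artifact: EMG-like noise burst or a slow movement wobble."""
    n = max(int(round(dur_s * fs)), 5)
    k = np.arange(n, dtype=float)
    envelope = np.sin(np.pi * k / (n - 1))
    if rng.random() < 0.5:
        w = rng.normal(0.0, 1.0, n) * envelope
        peak = float(np.max(np.abs(w)))
        return amp * w / peak if peak > 0 else w
    return amp * envelope * (1.0 if rng.random() < 0.5 else -1.0)


def _draw_event(kind: str, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    direction = 1 if rng.random() < 0.5 else -1
    if kind == "saccade":
        dur = rng.uniform(*cfg.saccade_dur_range_s)
        amp = rng.uniform(*cfg.saccade_amp_range)
        return synth_saccade(
            cfg.fs, dur, amp, direction, rest_frac=cfg.saccade_rest_frac, steepness=cfg.saccade_steepness
        )
    if kind == "blink":
        dur = rng.uniform(*cfg.blink_dur_range_s)
        amp = cfg.blink_amp_scale * rng.uniform(*cfg.saccade_amp_range)
        return synth_blink(cfg.fs, dur, amp, direction)
    if kind == "artifact":
        dur = rng.uniform(*cfg.artifact_dur_range_s)
        amp = rng.uniform(*cfg.artifact_amp_range)
        return synth_artifact(cfg.fs, dur, amp, rng)
    raise ValueError(f"unknown event kind {kind!r}")


def synth_rem_recording(
    config: SynthConfig,
    schedule: list[tuple[float, str]],
    duration_s: float | None = None,
) -> tuple[np.ndarray, list[EventAnnotation]]:
    """Render a single REM-interval recording from a schedule of events.

    ``schedule`` lists (onset_s, kind) pairs; event durations and amplitudes
    are drawn from the configured ranges.  Events are inserted additively on
    top of a slow drift sinusoid plus white noise.  Scheduled events must
    not overlap; the returned annotations match the schedule exactly.
    """
    rng = np.random.default_rng(config.seed)
    schedule = sorted(schedule)
    events: list[EventAnnotation] = []
    rendered: list[tuple[int, np.ndarray]] = []
    last_offset = 0.0
    for onset_s, kind in schedule:
        if onset_s < last_offset:
            raise ValueError("scheduled events overlap")
        w = _draw_event(kind, config, rng)
        offset_s = onset_s + w.size / config.fs
        rendered.append((int(round(onset_s * config.fs)), w))
        events.append(EventAnnotation(onset_s=round(onset_s, 3), offset_s=round(offset_s, 3), label=kind))
        last_offset = offset_s
    if duration_s is None:
        duration_s = (last_offset if events else 0.0) + 2.0
    n = int(round(duration_s * config.fs))
    t = np.arange(n) / config.fs
    phase = rng.uniform(0, 2 * np.pi)
    x = config.drift_amp * np.sin(2 * np.pi * t / config.drift_period_s + phase)
    x += rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    for i0, w in rendered:
        if i0 + w.size > n:
            raise ValueError("scheduled event extends past the recording end")
        x[i0 : i0 + w.size] += w
    return x, events


def make_burst_schedule(
    duration_s: float,
    n_saccades: int,
    seed: int,
    burst_size: tuple[int, int] = (3, 8),
    isi_range_s: tuple[float, float] = (0.15, 0.4),
    event_slot_s: float = 0.16,
    margin_s: float = 1.0,
) -> list[tuple[float, str]]:
    """Place ``n_saccades`` saccade onsets in clustered bursts within a recording.

    Bursts of ``burst_size`` saccades separated by intra-burst intervals
    from ``isi_range_s`` are spread over the recording with random
    inter-burst gaps.  ``event_slot_s`` reserves room for the longest event.
    """
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    left = n_saccades
    while left > 0:
        k = min(int(rng.integers(burst_size[0], burst_size[1] + 1)), left)
        counts.append(k)
        left -= k
    worst_span = [(k - 1) * (isi_range_s[1] + event_slot_s) + event_slot_s for k in counts]
    free = duration_s - 2 * margin_s - sum(worst_span)
    if free < 0:
        raise ValueError("recording too short for the requested saccade count")
    gaps = rng.dirichlet(np.ones(len(counts) + 1)) * free
    schedule: list[tuple[float, str]] = []
    t = margin_s + gaps[0]
    for k, g_next in zip(counts, gaps[1:]):
        for j in range(k):
            schedule.append((round(t, 3), "saccade"))
            t += event_slot_s + (rng.uniform(*isi_range_s) if j < k - 1 else 0.0)
        t += g_next
    return schedule


def add_distractors(
    schedule: list[tuple[float, str]],
    duration_s: float,
    n_blinks: int,
    n_artifacts: int,
    seed: int,
    min_separation_s: float = 0.6,
    margin_s: float = 1.0,
) -> list[tuple[float, str]]:
    """Scatter isolated blinks and artifacts into the free time of a schedule.

    Candidate onsets are drawn uniformly and rejected when closer than
    ``min_separation_s`` to any already-scheduled event, so the returned
    schedule stays non-overlapping.
    """
    rng = np.random.default_rng(seed)
    out = sorted(schedule)
    onsets = [t for t, _ in out]
    placed = 0
    want = [("blink", n_blinks), ("artifact", n_artifacts)]
    for kind, n in want:
        placed = 0
        attempts = 0
        while placed < n and attempts < 200 * max(n, 1):
            attempts += 1
            t = float(rng.uniform(margin_s, duration_s - margin_s - min_separation_s))
            if all(abs(t - o) >= min_separation_s for o in onsets):
                out.append((round(t, 3), kind))
                onsets.append(t)
                placed += 1
    return sorted(out)


@dataclass
class SyntheticNight:
    """A full synthetic night with ground truth."""

    signal: np.ndarray
    fs: float
    hypnogram: Hypnogram
    annotations: list[EventAnnotation]
    burst_spans_s: list[tuple[float, float]]
    true_phasic_fraction: float


def synth_full_night(
    config: SynthConfig,
    n_rem_intervals: int = 4,
    interval_len_s: float = 1200.0,
    epoch_s: float = 30.0,
) -> SyntheticNight:
    """Generate a night whose REM bouts carry bursts at a known phasic fraction.

    The hypnogram alternates wake/N2 padding with ``n_rem_intervals`` REM
    bouts.  Saccadic bursts are placed inside REM until the time they cover
    reaches ``phasic_fraction_target`` of total REM time (realised fraction
    within +-0.02 of the target); tonic stretches receive isolated blinks so
    the microstructure between bursts is not silent.
    """
    if n_rem_intervals < 1:
        raise ValueError("need at least one REM interval")
    cfg = config
    fs = cfg.fs
    rng = np.random.default_rng(cfg.seed)
    rem_epochs = int(round(interval_len_s / epoch_s))
    if rem_epochs < 1:
        raise ValueError("interval_len_s must cover at least one epoch")
    interval_len_s = rem_epochs * epoch_s

    stages: list[str] = ["W"]
    rem_starts_s: list[float] = []
    for _ in range(n_rem_intervals):
        stages += ["N2"] * 4
        rem_starts_s.append(len(stages) * epoch_s)
        stages += ["REM"] * rem_epochs
    stages += ["W"]
    hypnogram = Hypnogram(stages=stages, epoch_s=epoch_s)

    total_rem_s = n_rem_intervals * interval_len_s
    target_cov_s = cfg.phasic_fraction_target * total_rem_s
    mean_isi = float(np.mean(cfg.intra_burst_isi_s))
    mean_dur = float(np.mean(cfg.saccade_dur_range_s))
    mean_burst_k = float(np.mean(cfg.burst_saccades))
    approx_span = (mean_burst_k - 1) * mean_isi + mean_dur
    n_bursts_est = target_cov_s / approx_span
    if target_cov_s + (n_bursts_est + 1) * cfg.min_burst_gap_s > total_rem_s:
        raise ValueError("phasic fraction target infeasible at the configured burst geometry")

    schedule: list[tuple[float, str]] = []
    burst_spans: list[tuple[float, float]] = []
    covered = 0.0
    per_interval_target = target_cov_s / n_rem_intervals
    for rem_start in rem_starts_s:
        cursor = rem_start + rng.uniform(1.0, 3.0)
        interval_end = rem_start + interval_len_s
        interval_cov = 0.0
        slot = mean_isi + mean_dur
        while interval_cov < per_interval_target - 0.5 * approx_span:
            k = int(rng.integers(cfg.burst_saccades[0], cfg.burst_saccades[1] + 1))
            remaining = per_interval_target - interval_cov
            k = min(k, max(cfg.burst_saccades[0], int(remaining / slot) + 1))
            onsets = []
            t = cursor
            for j in range(k):
                dur = rng.uniform(*cfg.saccade_dur_range_s)
                onsets.append((t, dur))
                t += dur + rng.uniform(*cfg.intra_burst_isi_s)
            span_end = onsets[-1][0] + onsets[-1][1]
            if span_end > interval_end - 1.0:
                break
            for onset, _ in onsets:
                schedule.append((round(onset, 3), "saccade"))
            burst_spans.append((onsets[0][0], span_end))
            interval_cov += span_end - onsets[0][0]
            gap = cfg.min_burst_gap_s + rng.exponential(cfg.min_burst_gap_s)
            # blinks in the tonic stretch between bursts
            n_blinks = max(3, int(round(gap * cfg.tonic_blink_rate_hz)))
            blink_lo = span_end + 1.0
            blink_hi = min(span_end + gap - 1.0, interval_end - 1.5)
            width = blink_hi - blink_lo
            if width > 0:
                n_fit = min(n_blinks, max(1, int(width / 1.0)))
                # jittered even spacing keeps every blink >= 0.6 s from its
                # neighbours so the rendered events never overlap
                centers = blink_lo + (np.arange(n_fit) + 0.5) * width / n_fit
                jitter = rng.uniform(-0.15, 0.15, n_fit) * width / n_fit
                for bt in centers + jitter:
                    schedule.append((round(float(bt), 3), "blink"))
            cursor = span_end + gap
            if cursor > interval_end - approx_span - 1.0:
                break
        covered += interval_cov

    realized = covered / total_rem_s
    total_s = len(stages) * epoch_s
    x, events = synth_rem_recording(
        replace(cfg, seed=cfg.seed + 1, blink_amp_scale=cfg.tonic_blink_amp_scale),
        sorted(schedule),
        duration_s=total_s,
    )
    return SyntheticNight(
        signal=x,
        fs=fs,
        hypnogram=hypnogram,
        annotations=events,
        burst_spans_s=sorted(burst_spans),
        true_phasic_fraction=realized,
    )


def synth_labeled_segments(
    config: SynthConfig, n_per_class: int, seed: int | None = None
) -> list[tuple[np.ndarray, str]]:
    """Balanced labelled waveforms for classifier training and validation.

    Each waveform is a clean event plus white observation noise at the
    configured ``noise_sd``; classes alternate deterministically so the
    list order is reproducible.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: list[tuple[np.ndarray, str]] = []
    for _ in range(n_per_class):
        for label in ("saccade", "blink", "artifact"):
            w = _draw_event(label, config, rng)
            if config.noise_sd > 0:
                w = w + rng.normal(0.0, config.noise_sd, w.size)
            out.append((w, label))
    return out
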