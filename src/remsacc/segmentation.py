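"""Hybrid adaptive segmentation of the preprocessed EOG signal.

Two complementary per-sample scores are fused into one decision trace:

* an **amplitude score** from the absolute first derivative, thresholded
  at ``k_mad`` times its median absolute deviation (robust to drift and
  heavy-tailed noise);
* a **morphology score**, the maximum absolute correlation of the signal
  with the unit-energy saccade kernel over a small set of temporal shifts
  (a matched filter tolerant to jitter).

Both are min–max normalised within the REM interval so the fusion weight
``alpha`` mixes commensurate quantities.  Candidate segments are maximal
runs where the fused score exceeds its interval mean by more than
``boundary_sd_mult`` standard deviations; refinement merges near-adjacent
segments, drops sub-physiological ones and snaps boundaries onto local
extrema of the derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .kernel import SaccadeKernel

MAD_FLOOR = 1e-12


@dataclass
class SegmentationParams:
    """Tunable knobs of the hybrid segmentation (durations in seconds)."""

    k_mad: float = 3.0
    alpha: float = 0.5
    # min_dur_s gates the *supra-threshold run*, which is always shorter
    # than the event producing it; it must sit below the run width of the
    # shortest physiological saccade (~30 ms), not at it
    min_dur_s: float = 0.02
    gap_s: float = 0.08
    shift_window_s: float = 0.05
    refine_radius_s: float = 0.04
    boundary_sd_mult: float = 3.0
    amp_score_mode: str = "magnitude"  # or "binary"
    refine_order: str = "merge_first"  # or "drop_first"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.k_mad <= 0:
            raise ValueError("k_mad must be positive")
        for v in (self.min_dur_s, self.gap_s, self.shift_window_s, self.refine_radius_s):
            if v < 0:
                raise ValueError("durations must be non-negative")
        if self.amp_score_mode not in ("magnitude", "binary"):
            raise ValueError("amp_score_mode must be 'magnitude' or 'binary'")
        if self.refine_order not in ("merge_first", "drop_first"):
            raise ValueError("refine_order must be 'merge_first' or 'drop_first'")


@dataclass
class Segment:
    """Half-open sample interval [start, end), optionally labelled."""

    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment start must precede end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ScoreTrace:
    """Per-sample scores for one REM interval (each min–max normalised to [0, 1])."""

    s_amp: np.ndarray
    s_morph: np.ndarray
    s_fused: np.ndarray


def derivative_series(x: np.ndarray) -> np.ndarray:
    """Absolute first difference, zero-padded at the first sample."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    d = np.empty_like(x)
    d[0] = 0.0
    d[1:] = np.abs(np.diff(x))
    return d


def mad_threshold(d: np.ndarray, k_mad: float) -> float:
    """Amplitude threshold ``k_mad * MAD(d)`` with a floor for flat inputs."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty derivative series")
    mad = float(np.median(np.abs(d - np.median(d))))
    return k_mad * max(mad, MAD_FLOOR)


def _minmax(r: np.ndarray) -> np.ndarray:
    hi = float(np.max(r))
    lo = float(np.min(r))
    if hi - lo < 1e-15:
        return np.zeros_like(r)
    return (r - lo) / (hi - lo)


def amplitude_score(d: np.ndarray, t_amp: float, mode: str = "magnitude") -> np.ndarray:
    """Supra-threshold derivative magnitude (or mask), min–max normalised."""
    if t_amp < 0:
        raise ValueError("threshold must be non-negative")
    d = np.asarray(d, dtype=float)
    mask = d > t_amp
    r = mask.astype(float) if mode == "binary" else d * mask
    if not mask.any():
        return np.zeros_like(d)
    return _minmax(r)


def morphology_raw(x: np.ndarray, h: SaccadeKernel, shift_window_s: float, fs: float) -> np.ndarray:
    """Raw matched-filter score: max |correlation| over shifts within +-W samples.

    ``m(t) = max_{tau in [-W, W]} |sum_k x(t + k + tau) h(k)|`` with the shift
    range clipped at the signal edges; positions whose entire shift window
    falls outside the valid correlation support score zero.
    """
    x = np.asarray(x, dtype=float)
    L = h.L
    if x.size < L:
        raise ValueError("signal shorter than the kernel")
    c = np.abs(np.correlate(x, h.h, mode="valid"))  # c[t] for t in [0, N-L]
    W = int(round(shift_window_s * fs))
    if W > 0:
        # windowed max over [t-W, t+W]; pad so positions beyond the valid
        # support still see their clipped window
        padded = np.concatenate([c, np.zeros(x.size - c.size)])
        m = maximum_filter1d(padded, size=2 * W + 1, mode="constant", cval=0.0)
        # positions near the start: maximum_filter handles clipping via cval=0
    else:
        m = np.concatenate([c, np.zeros(x.size - c.size)])
    return m


def morphology_score(x: np.ndarray, h: SaccadeKernel, shift_window_s: float, fs: float) -> np.ndarray:
    """Min–max normalised matched-filter score over the REM interval."""
    return _minmax(morphology_raw(x, h, shift_window_s, fs))


def fuse_scores(s_amp: np.ndarray, s_morph: np.ndarray, alpha: float) -> np.ndarray:
    """Pointwise convex combination ``alpha * s_amp + (1 - alpha) * s_morph``."""
    if len(s_amp) != len(s_morph):
        raise ValueError("score lengths differ")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * np.asarray(s_amp, dtype=float) + (1.0 - alpha) * np.asarray(s_morph, dtype=float)


def detect_boundaries(s_fused: np.ndarray, boundary_sd_mult: float = 3.0) -> list[Segment]:
    """Maximal runs where the fused score strictly exceeds mean + k * SD."""
    s = np.asarray(s_fused, dtype=float)
    if s.size == 0:
        raise ValueError("empty score trace")
    theta = float(np.mean(s)) + boundary_sd_mult * float(np.std(s))
    above = s > theta
    segs: list[Segment] = []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]] + 1) if edges.size else []
    if above.size and above[0]:
        starts = [0] + starts
    if above.size and above[-1]:
        ends = ends + [above.size]
    for a, b in zip(starts, ends):
        segs.append(Segment(start=int(a), end=int(b)))
    return segs


def _merge_close(segs: list[Segment], gap_samples: float) -> list[Segment]:
    out: list[Segment] = []
    for seg in segs:
        if out and seg.start - out[-1].end < gap_samples:
            out[-1] = Segment(start=out[-1].start, end=max(out[-1].end, seg.end))
        else:
            out.append(Segment(start=seg.start, end=seg.end))
    return out


def refine_segments(
    segs: list[Segment], x: np.ndarray, params: SegmentationParams, fs: float
) -> list[Segment]:
    """Merge near-adjacent segments, drop short ones, snap edges to derivative extrema.

    Merging and dropping order follows ``params.refine_order``; boundary
    alignment then moves each edge to the windowed argmax of the absolute
    derivative within ``refine_radius_s``, clipping at the midpoint when two
    refined segments would collide.
    """
    x = np.asarray(x, dtype=float)
    segs = sorted(segs, key=lambda s: s.start)
    gap = params.gap_s * fs
    min_len = params.min_dur_s * fs
    if params.refine_order == "merge_first":
        segs = _merge_close(segs, gap)
        segs = [s for s in segs if len(s) >= min_len]
    else:
        segs = [s for s in segs if len(s) >= min_len]
        segs = _merge_close(segs, gap)
    if not segs:
        return []
    d = derivative_series(x) if x.size >= 2 else np.zeros_like(x)
    r = int(round(params.refine_radius_s * fs))

    def snap(b: int) -> int:
        lo = max(0, b - r)
        hi = min(d.size, b + r + 1)
        if hi <= lo:
            return b
        return lo + int(np.argmax(d[lo:hi]))

    refined: list[Segment] = []
    for seg in segs:
        a, b = snap(seg.start), snap(seg.end)
        if a >= b:  # both edges snapped to the same extremum; keep original span
            a, b = seg.start, seg.end
        refined.append(Segment(start=a, end=b))
    # resolve collisions introduced by snapping: clip at the midpoint
    for i in range(1, len(refined)):
        prev, cur = refined[i - 1], refined[i]
        if cur.start < prev.end:
            mid = (prev.end + cur.start) // 2
            mid = max(prev.start + 1, min(mid, cur.end - 1))
            refined[i - 1] = Segment(start=prev.start, end=mid)
            refined[i] = Segment(start=mid, end=cur.end)
    return refined


def segment_interval(
    x: np.ndarray,
    fs: float,
    kernel: SaccadeKernel,
    params: SegmentationParams | None = None,
) -> tuple[list[Segment], ScoreTrace]:
    """Full hybrid segmentation of one preprocessed REM interval.

    Returns refined segments (interval-local sample coordinates) together
    with the score traces used to find them.
    """
    if params is None:
        params = SegmentationParams()
    d = derivative_series(x)
    t_amp = mad_threshold(d, params.k_mad)
    s_amp = amplitude_score(d, t_amp, mode=params.amp_score_mode)
    s_morph = morphology_score(x, kernel, params.shift_window_s, fs)
    s_fused = fuse_scores(s_amp, s_morph, params.alpha)
    segs = detect_boundaries(s_fused, params.boundary_sd_mult)
    segs = refine_segments(segs, x, params, fs)
    return segs, ScoreTrace(s_amp=s_amp, s_morph=s_morph, s_fused=s_fused)
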