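"""Saccadic-burst grouping and phasic/tonic REM reconstruction.

Within each REM interval, consecutive saccade-labelled segments form
bursts; bursts separated by at most two non-saccadic segments are merged
(short interruptions do not break a phasic episode).  Phasic REM is the
union of burst spans; tonic REM is its complement within the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import REMInterval
from .segmentation import Segment


@dataclass
class Burst:
    """An ordered run of saccade segments; span covers first onset to last offset.

    ``span_override`` lets a caller widen the nominal span, e.g. to correct
    the negative bias of first-to-last-detection spans when the detector
    only sees a subset of the burst's saccades.
    """

    member_segments: list[Segment]
    span_override: tuple[int, int] | None = None

    @property
    def span(self) -> tuple[int, int]:
        if self.span_override is not None:
            return self.span_override
        return self.member_segments[0].start, self.member_segments[-1].end


def correct_span_bias(bursts: list[Burst], interval_start: int, interval_end: int, max_extend: int | None = None) -> list[Burst]:
    """Widen detected burst spans to correct partial-detection bias.

    A detector that catches only ``m`` of a burst's saccades sees a span
    whose leading and trailing margins are lost; if detections subsample
    the true event train roughly uniformly, the expected size of each lost
    margin equals the mean gap between consecutive detections (all are
    mean gaps of the same uniform partition of the true span).  Each burst
    with at least two members is therefore extended on both sides by its
    own mean inter-member gap, capped at ``max_extend`` samples, clipped
    to the REM interval and to the midpoint between neighbouring bursts.
    """
    if not bursts:
        return []
    spans = []
    for b in bursts:
        a, z = b.member_segments[0].start, b.member_segments[-1].end
        onsets = np.array([m.start for m in b.member_segments], dtype=float)
        ext = 0
        if onsets.size >= 3:
            spac = np.diff(onsets)
            # a low quantile of the inter-detection spacing estimates the
            # true inter-event slot (gaps that contain no missed event,
            # robust to the miss-inflated upper tail); the mean-over-slot
            # excess then estimates the expected margin of events lost
            # beyond each edge of the detected span
            slot = float(np.percentile(spac, 25))
            ext = int(round(max(0.0, float(np.mean(spac)) - slot)))
            if max_extend is not None:
                ext = min(ext, max_extend)
        spans.append((a - ext, z + ext))
    out: list[Burst] = []
    for i, (b, (a, z)) in enumerate(zip(bursts, spans)):
        lo = interval_start if i == 0 else (bursts[i - 1].member_segments[-1].end + b.member_segments[0].start) // 2
        hi = interval_end if i == len(bursts) - 1 else (b.member_segments[-1].end + bursts[i + 1].member_segments[0].start) // 2
        out.append(Burst(member_segments=b.member_segments, span_override=(max(a, lo), min(z, hi))))
    return out


@dataclass
class MicrostructureSummary:
    """Per-subject phasic/tonic durations (minutes), proportions and ratio."""

    phasic_min: float
    tonic_min: float
    total_rem_min: float
    phasic_pct: float
    tonic_pct: float
    phasic_tonic_ratio: float


def group_bursts(
    labeled_segments: list[Segment],
    max_interrupting: int = 2,
    min_saccades_per_burst: int = 1,
    max_gap: int | None = None,
) -> list[Burst]:
    """Group saccade-labelled segments into bursts.

    Maximal runs of consecutive saccade segments seed the bursts; adjacent
    bursts merge, iteratively left to right, whenever at most
    ``max_interrupting`` non-saccade segments lie between them.  A single
    isolated saccade counts as a burst unless ``min_saccades_per_burst``
    says otherwise.  Idempotent: re-grouping the saccade members of the
    output changes nothing.

    ``max_gap`` (samples) adds a temporal continuity guard: two saccade
    segments further apart than this never share a burst, however few
    detections lie between them.  The segment-count rule alone presumes a
    detector busy enough that "two segments" implies temporal proximity;
    on quiet stretches it would otherwise bridge arbitrarily long
    ocularly-silent spans into phasic episodes.
    """
    segs = sorted(labeled_segments, key=lambda s: s.start)
    runs: list[list[Segment]] = []
    gaps: list[int] = []  # gaps[i] = non-saccade segments between runs[i] and runs[i+1]
    pending_gap = 0

    def too_far(prev: Segment, nxt: Segment) -> bool:
        return max_gap is not None and nxt.start - prev.end > max_gap

    for seg in segs:
        if seg.label == "saccade":
            if runs and pending_gap == 0 and not too_far(runs[-1][-1], seg):
                runs[-1].append(seg)
            else:
                if runs:
                    gaps.append(pending_gap if not too_far(runs[-1][-1], seg) else max_interrupting + 1)
                runs.append([seg])
            pending_gap = 0
        elif runs:
            pending_gap += 1
    bursts: list[list[Segment]] = []
    for i, run in enumerate(runs):
        if bursts and i - 1 < len(gaps) and gaps[i - 1] <= max_interrupting:
            bursts[-1].extend(run)
        else:
            bursts.append(list(run))
    return [Burst(member_segments=b) for b in bursts if len(b) >= min_saccades_per_burst]


def reconstruct_phasic_tonic(
    bursts: list[Burst], interval: REMInterval
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a REM interval into phasic (burst union) and tonic (complement).

    Burst spans are clipped-checked against the interval; overlapping spans
    are merged.  Both lists are sorted, disjoint, half-open, and together
    partition the interval exactly.
    """
    spans = sorted(b.span for b in bursts)
    merged: list[tuple[int, int]] = []
    for a, b in spans:
        if not (interval.start <= a < b <= interval.end):
            raise ValueError("burst span outside the REM interval")
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    tonic: list[tuple[int, int]] = []
    cursor = interval.start
    for a, b in merged:
        if a > cursor:
            tonic.append((cursor, a))
        cursor = b
    if cursor < interval.end:
        tonic.append((cursor, interval.end))
    return merged, tonic


def summarize_subject(
    per_interval: list[tuple[list[tuple[int, int]], list[tuple[int, int]]]], fs: float
) -> MicrostructureSummary:
    """Aggregate phasic/tonic intervals over a night into a subject summary.

    Durations are summed over all REM intervals (duration-weighted, not a
    mean of per-interval percentages) and converted to minutes; the ratio
    is NaN when the night contains no tonic REM.
    """
    if not per_interval:
        raise ValueError("need at least one REM interval")
    phasic_samp = sum(b - a for phasic, _ in per_interval for a, b in phasic)
    tonic_samp = sum(b - a for _, tonic in per_interval for a, b in tonic)
    total_samp = phasic_samp + tonic_samp
    if total_samp == 0:
        raise ValueError("zero total REM duration")
    phasic_min = phasic_samp / fs / 60.0
    tonic_min = tonic_samp / fs / 60.0
    total_min = total_samp / fs / 60.0
    ratio = phasic_min / tonic_min if tonic_min > 0 else float("nan")
    return MicrostructureSummary(
        phasic_min=phasic_min,
        tonic_min=tonic_min,
        total_rem_min=total_min,
        phasic_pct=100.0 * phasic_min / total_min,
        tonic_pct=100.0 * tonic_min / total_min,
        phasic_tonic_ratio=ratio,
    )
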