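"""Event-level segmentation metrics, classification metrics, tuning objective.

Segmentation quality is judged per ground-truth (GT) event, not per sample:
each GT event is exactly one of

* **correct** — overlapped by exactly one prediction that overlaps no other
  GT event;
* **fragmented** — overlapped by two or more predictions;
* **merged** — its sole overlapping prediction also overlaps another GT
  event;
* **missed** — overlapped by nothing.

Percentages are GT-denominated; the detected-to-GT ratio quantifies
over-segmentation separately.  Boundary error (onset/offset MAE) is
measured over correct pairs, and a stricter temporal-accuracy variant
additionally requires both deviations within a +-20 ms tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import EventAnnotation


@dataclass
class EventMatchResult:
    """GT-denominated segmentation accuracy for one recording."""

    correct_pct: float
    fragmented_pct: float
    merged_pct: float
    missed_pct: float
    detected_gt_ratio: float
    onset_mae_ms: float
    offset_mae_ms: float
    correct_within_tol_pct: float
    gt_outcomes: list[str] = field(default_factory=list, repr=False)


@dataclass
class ClassMetrics:
    """One-vs-rest metrics for the positive class plus multi-class kappa."""

    precision_pct: float
    recall_pct: float
    specificity_pct: float
    f1: float
    kappa: float


def _check_sorted_disjoint(events: Sequence[tuple[float, float]], name: str) -> None:
    for i in range(1, len(events)):
        if events[i][0] < events[i - 1][1]:
            raise ValueError(f"{name} events must be sorted and non-overlapping")


def _as_intervals(events: Sequence) -> list[tuple[float, float]]:
    out = []
    for ev in events:
        if isinstance(ev, EventAnnotation):
            out.append((ev.onset_s, ev.offset_s))
        else:
            a, b = ev
            out.append((float(a), float(b)))
    return sorted(out)


def match_events(
    gt: Sequence, pred: Sequence, tol_ms: float = 20.0
) -> EventMatchResult:
    """Match predicted segments against ground truth and score the outcome.

    Accepts :class:`EventAnnotation` lists or plain (onset_s, offset_s)
    pairs, both sorted and internally non-overlapping.  Any nonzero
    temporal intersection counts as overlap; ``tol_ms`` governs only the
    stricter ``correct_within_tol_pct`` variant and boundary MAE is
    reported in milliseconds over correct pairs.
    """
    g = _as_intervals(gt)
    p = _as_intervals(pred)
    _check_sorted_disjoint(g, "gt")
    _check_sorted_disjoint(p, "pred")
    if not g:
        raise ValueError("empty ground truth")

    # bipartite overlap counts (sweep; both lists are sorted)
    gt_hits: list[list[int]] = [[] for _ in g]
    pred_hits: list[list[int]] = [[] for _ in p]
    j0 = 0
    for i, (ga, gb) in enumerate(g):
        j = j0
        while j < len(p) and p[j][1] <= ga:
            j += 1
        j0 = j
        while j < len(p) and p[j][0] < gb:
            if min(gb, p[j][1]) - max(ga, p[j][0]) > 0:
                gt_hits[i].append(j)
                pred_hits[j].append(i)
            j += 1

    outcomes: list[str] = []
    onset_err: list[float] = []
    offset_err: list[float] = []
    n_tol = 0
    for i, hits in enumerate(gt_hits):
        if len(hits) == 0:
            outcomes.append("missed")
        elif len(hits) >= 2:
            outcomes.append("fragmented")
        elif len(pred_hits[hits[0]]) > 1:
            outcomes.append("merged")
        else:
            outcomes.append("correct")
            j = hits[0]
            e_on = abs(p[j][0] - g[i][0]) * 1000.0
            e_off = abs(p[j][1] - g[i][1]) * 1000.0
            onset_err.append(e_on)
            offset_err.append(e_off)
            if e_on <= tol_ms and e_off <= tol_ms:
                n_tol += 1

    n = len(g)
    counts = {k: outcomes.count(k) for k in ("correct", "fragmented", "merged", "missed")}
    return EventMatchResult(
        correct_pct=100.0 * counts["correct"] / n,
        fragmented_pct=100.0 * counts["fragmented"] / n,
        merged_pct=100.0 * counts["merged"] / n,
        missed_pct=100.0 * counts["missed"] / n,
        detected_gt_ratio=len(p) / n,
        onset_mae_ms=float(np.mean(onset_err)) if onset_err else float("nan"),
        offset_mae_ms=float(np.mean(offset_err)) if offset_err else float("nan"),
        correct_within_tol_pct=100.0 * n_tol / n,
        gt_outcomes=outcomes,
    )


def overlap_correct_saccade(
    gt: Sequence, pred_saccades: Sequence, min_overlap_ms: float = 20.0
) -> list[bool]:
    """True-positive flag per predicted saccade: >= ``min_overlap_ms`` overlap with some GT."""
    g = _as_intervals(gt)
    p = _as_intervals(pred_saccades)
    min_overlap_s = min_overlap_ms / 1000.0 - 1e-9  # tolerate float rounding at the boundary
    flags: list[bool] = []
    for pa, pb in p:
        ok = any(min(pb, gb) - max(pa, ga) >= min_overlap_s for ga, gb in g)
        flags.append(ok)
    return flags


def classification_metrics(
    confusion: np.ndarray, classes: Sequence[str] = ("saccade", "blink", "artifact"), positive_class: str = "saccade"
) -> ClassMetrics:
    """One-vs-rest metrics for ``positive_class`` and Cohen's kappa of the full table.

    ``confusion[i, j]`` counts items of true class ``classes[i]`` predicted
    as ``classes[j]``.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = list(classes).index(positive_class)
    tp = cm[k, k]
    fn = cm[k].sum() - tp
    fp = cm[:, k].sum() - tp
    tn = total - tp - fn - fp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    po = np.trace(cm) / total
    pe = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1))) / total**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    return ClassMetrics(
        precision_pct=100.0 * precision,
        recall_pct=100.0 * recall,
        specificity_pct=100.0 * specificity,
        f1=float(f1),
        kappa=float(kappa),
    )


def tuning_objective(
    gt: Sequence,
    pred: Sequence,
    w_correct: float = 1.0,
    w_fragmented: float = 2.0,
    w_merged: float = 2.0,
    w_timing: float = 0.5,
    tol_ms: float = 20.0,
) -> float:
    """Hyperparameter-tuning reward: localisation is rewarded, splitting penalised.

    ``J = w_c * correct% - w_f * fragmented% - w_m * merged% -
    w_t * (onset MAE + offset MAE in ms)``.  Fragmentation and merging are
    penalised more strongly than over-detection by default; missed events
    earn nothing.
    """
    for w in (w_correct, w_fragmented, w_merged, w_timing):
        if w < 0:
            raise ValueError("weights must be non-negative")
    r = match_events(gt, pred, tol_ms=tol_ms)
    timing = 0.0
    if np.isfinite(r.onset_mae_ms):
        timing = r.onset_mae_ms + r.offset_mae_ms
    return (
        w_correct * r.correct_pct
        - w_fragmented * r.fragmented_pct
        - w_merged * r.merged_pct
        - w_timing * timing
    )
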