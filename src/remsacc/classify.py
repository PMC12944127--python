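"""Two-feature segment classification with an RBF support vector machine.

Each candidate segment is reduced to two physiologically grounded numbers:

* the **amplitude–duration ratio** (peak-to-peak amplitude in z-units over
  duration in seconds), a proxy for the saccadic main sequence;
* the **morphology correlation**, the larger of the absolute inner
  products between the normalised segment and the rising / falling
  log-sigmoid templates.

A soft-margin RBF SVM (one-vs-one multi-class, features standardised with
training-set statistics only) separates saccades from blinks and
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .kernel import SigmoidTemplate, _resample_linear
from .segmentation import Segment

CLASSES = ("saccade", "blink", "artifact")

#: Train fraction reproducing a 2.33:1 split (894 of 1278 segments).
TRAIN_FRACTION = 894 / 1278


@dataclass
class SegmentFeatures:
    """Feature vector of one candidate segment."""

    amp_dur_ratio: float
    morph_corr: float
    chosen_direction: str

    def as_array(self) -> np.ndarray:
        return np.array([self.amp_dur_ratio, self.morph_corr])


@dataclass
class TrainedClassifier:
    """Fitted 3-class SVM plus its training-set feature scaler."""

    model: SVC
    scaler: StandardScaler
    classes: tuple[str, ...]
    C: float
    gamma: float | str
    train_accuracy: float

    def predict(self, features: Sequence[SegmentFeatures]) -> list[str]:
        return predict_labels(self, features)


def features_from_waveform(
    w: np.ndarray,
    fs: float,
    rising: SigmoidTemplate,
    falling: SigmoidTemplate,
) -> SegmentFeatures:
    """Features of a raw segment waveform (already cut out of the signal)."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty segment")
    if w.size == 1:  # degenerate sliver from collision clipping
        return SegmentFeatures(amp_dur_ratio=0.0, morph_corr=0.0, chosen_direction="rising")
    dur_s = w.size / fs
    ptp = float(np.max(w) - np.min(w))
    seg = _resample_linear(w, rising.L)
    seg = seg - seg.mean()
    energy = float(np.sqrt(np.sum(seg**2)))
    if energy < 1e-12:
        return SegmentFeatures(amp_dur_ratio=ptp / dur_s, morph_corr=0.0, chosen_direction="rising")
    seg = seg / energy
    c_rise = abs(float(np.dot(seg, rising.w)))
    c_fall = abs(float(np.dot(seg, falling.w)))
    if c_rise >= c_fall:
        return SegmentFeatures(amp_dur_ratio=ptp / dur_s, morph_corr=c_rise, chosen_direction="rising")
    return SegmentFeatures(amp_dur_ratio=ptp / dur_s, morph_corr=c_fall, chosen_direction="falling")


def extract_features(
    seg: Segment,
    x: np.ndarray,
    fs: float,
    rising: SigmoidTemplate,
    falling: SigmoidTemplate,
) -> SegmentFeatures:
    """Features of one segment of a preprocessed interval signal."""
    if not (0 <= seg.start < seg.end <= len(x)):
        raise ValueError("segment outside the signal")
    return features_from_waveform(np.asarray(x, dtype=float)[seg.start : seg.end], fs, rising, falling)


def make_training_sets(
    labeled: Sequence[tuple[SegmentFeatures, str]], seed: int
) -> tuple[list[tuple[SegmentFeatures, str]], list[tuple[SegmentFeatures, str]]]:
    """Stratified, class-balanced 2.33:1 train/validation split.

    Classes are first downsampled to the minority count so both splits are
    exactly balanced; the per-class train count is ``round(0.6995 * n)``
    (which yields 298 train / 128 validation from 426 per class).
    Deterministic for a fixed seed; no segment appears in both splits.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[tuple[SegmentFeatures, str]]] = {c: [] for c in CLASSES}
    for feat, lab in labeled:
        if lab not in by_class:
            raise ValueError(f"unknown label {lab!r}")
        by_class[lab].append((feat, lab))
    n_min = min(len(v) for v in by_class.values())
    if n_min < 2:
        raise ValueError("every class needs at least 2 members")
    n_train = int(np.floor(TRAIN_FRACTION * n_min + 0.5))
    train: list[tuple[SegmentFeatures, str]] = []
    val: list[tuple[SegmentFeatures, str]] = []
    for c in CLASSES:
        items = by_class[c]
        order = rng.permutation(len(items))[:n_min]
        train.extend(items[i] for i in order[:n_train])
        val.extend(items[i] for i in order[n_train:])
    return train, val


def train_classifier(
    train: Sequence[tuple[SegmentFeatures, str]],
    C: float = 10.0,
    gamma: float | str = "scale",
    seed: int = 0,
    class_weight: str | dict | None = None,
) -> TrainedClassifier:
    """Fit the 3-class RBF SVM on standardised features.

    ``class_weight`` is passed through to the SVM; use ``"balanced"`` when
    the training set is not class-balanced by construction.
    """
    if not train:
        raise ValueError("empty training set")
    labels = [lab for _, lab in train]
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes to train")
    X = np.array([f.as_array() for f, _ in train])
    scaler = StandardScaler().fit(X)
    model = SVC(
        C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo",
        class_weight=class_weight, random_state=seed,
    )
    model.fit(scaler.transform(X), labels)
    acc = float(np.mean(model.predict(scaler.transform(X)) == np.array(labels)))
    return TrainedClassifier(
        model=model, scaler=scaler, classes=CLASSES, C=C, gamma=gamma, train_accuracy=acc
    )


def predict_labels(clf: TrainedClassifier, features: Sequence[SegmentFeatures]) -> list[str]:
    """Label segments with the fitted model (training-set standardisation)."""
    if not features:
        return []
    X = np.array([f.as_array() for f in features])
    return list(clf.model.predict(clf.scaler.transform(X)))


def tune_hyperparameters(
    objective: Callable[..., float],
    search_space: dict[str, object],
    budget: int,
    seed: int = 0,
    log_scale: bool = True,
) -> tuple[dict[str, float], list[tuple[dict[str, float], float]]]:
    """Seeded derivative-free search maximising ``objective``.

    Each search-space entry is either a ``(lo, hi)`` tuple (continuous
    range, sampled log-uniformly when positive) or a list of candidate
    values (a grid dimension).  An all-grid space is enumerated
    exhaustively up to ``budget`` evaluations; otherwise random search is
    used.  Returns the best parameter dict and the full (params, score)
    trace.  The backend is deliberately simple and pluggable; any
    derivative-free optimiser can replace it by consuming the same
    objective.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if not search_space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    names = list(search_space)
    all_grid = all(isinstance(search_space[n], list) for n in names)
    candidates: list[dict[str, float]] = []
    if all_grid:
        from itertools import product

        for combo in product(*(search_space[n] for n in names)):
            candidates.append(dict(zip(names, combo)))
            if len(candidates) >= budget:
                break
    else:
        for _ in range(budget):
            params: dict[str, float] = {}
            for name in names:
                dim = search_space[name]
                if isinstance(dim, list):
                    params[name] = dim[int(rng.integers(len(dim)))]
                else:
                    lo, hi = dim
                    if log_scale and lo > 0:
                        params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                    else:
                        params[name] = float(rng.uniform(lo, hi))
            candidates.append(params)
    trace: list[tuple[dict[str, float], float]] = []
    best: dict[str, float] | None = None
    best_score = -np.inf
    for params in candidates:
        score = float(objective(**params))
        trace.append((params, score))
        if score > best_score:
            best, best_score = params, score
    assert best is not None
    return best, trace
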