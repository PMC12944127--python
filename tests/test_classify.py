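"""Segment features, train/validation splitting, SVM behaviour, tuning."""

import numpy as np
import pytest

from remsacc import (
    Segment,
    SegmentFeatures,
    extract_features,
    make_training_sets,
    predict_labels,
    train_classifier,
    tune_hyperparameters,
)
from remsacc.classify import features_from_waveform
from remsacc.synth import SynthConfig, synth_saccade, synth_labeled_segments


class TestFeatures:
    def test_amp_dur_ratio_quotient(self, fs, templates):
        rising, falling = templates
        w = np.zeros(25)  # 0.1 s at 250 Hz
        w[5:20] = np.linspace(0, 2.0, 15)
        f = features_from_waveform(w, fs, rising, falling)
        assert f.amp_dur_ratio == pytest.approx(2.0 / 0.1)

    def test_rising_template_self_correlation(self, fs, templates):
        rising, falling = templates
        f = features_from_waveform(rising.w, fs, rising, falling)
        assert f.morph_corr == pytest.approx(1.0, abs=1e-9)
        assert f.chosen_direction == "rising"

    def test_falling_profile_prefers_falling_direction(self, fs):
        from remsacc import log_sigmoid_template

        # asymmetric midpoint so rising and falling are not mirror-degenerate
        rising = log_sigmoid_template("rising", 25, midpoint=0.35)
        falling = log_sigmoid_template("falling", 25, midpoint=0.35)
        f = features_from_waveform(falling.w + 0.001, fs, rising, falling)
        assert f.chosen_direction == "falling"
        assert f.morph_corr == pytest.approx(1.0, abs=1e-6)

    def test_polarity_flip_invariant(self, fs, templates):
        rising, falling = templates
        w = synth_saccade(fs, 0.08, 2.0)
        a = features_from_waveform(w, fs, rising, falling)
        b = features_from_waveform(-w, fs, rising, falling)
        assert a.amp_dur_ratio == pytest.approx(b.amp_dur_ratio)
        assert a.morph_corr == pytest.approx(b.morph_corr)

    def test_zero_variance_segment(self, fs, templates):
        rising, falling = templates
        f = features_from_waveform(np.full(30, 1.5), fs, rising, falling)
        assert f.morph_corr == 0.0 and f.amp_dur_ratio == 0.0

    def test_extract_from_signal_bounds_checked(self, fs, templates):
        rising, falling = templates
        x = np.zeros(100)
        with pytest.raises(ValueError):
            extract_features(Segment(90, 120), x, fs, rising, falling)


class TestSplit:
    def _features(self, n, label, rng):
        return [(SegmentFeatures(rng.random() * 10, rng.random(), "rising"), label) for _ in range(n)]

    def test_published_counts_from_426_per_class(self):
        rng = np.random.default_rng(0)
        labeled = sum((self._features(426, lab, rng) for lab in ("saccade", "blink", "artifact")), [])
        train, val = make_training_sets(labeled, seed=1)
        assert len(train) == 894 and len(val) == 384
        for lab in ("saccade", "blink", "artifact"):
            assert sum(1 for _, l in train if l == lab) == 298
            assert sum(1 for _, l in val if l == lab) == 128

    def test_small_class_rounding(self):
        rng = np.random.default_rng(1)
        labeled = sum((self._features(10, lab, rng) for lab in ("saccade", "blink", "artifact")), [])
        train, val = make_training_sets(labeled, seed=1)
        assert sum(1 for _, l in train if l == "blink") == 7
        assert sum(1 for _, l in val if l == "blink") == 3

    def test_deterministic_and_disjoint(self):
        rng = np.random.default_rng(2)
        labeled = sum((self._features(30, lab, rng) for lab in ("saccade", "blink", "artifact")), [])
        t1, v1 = make_training_sets(labeled, seed=7)
        t2, v2 = make_training_sets(labeled, seed=7)
        assert [f.amp_dur_ratio for f, _ in t1] == [f.amp_dur_ratio for f, _ in t2]
        ids_t = {id(f) for f, _ in t1}
        ids_v = {id(f) for f, _ in v1}
        assert not ids_t & ids_v

    def test_downsampled_to_minority(self):
        rng = np.random.default_rng(3)
        labeled = (self._features(50, "saccade", rng) + self._features(20, "blink", rng)
                   + self._features(80, "artifact", rng))
        train, val = make_training_sets(labeled, seed=0)
        per_class = [sum(1 for _, l in train + val if l == lab) for lab in ("saccade", "blink", "artifact")]
        assert per_class == [20, 20, 20]


class TestSVM:
    def _blobs(self, seed=0, n=60, spread=0.1):
        rng = np.random.default_rng(seed)
        data = []
        centers = {"saccade": (5.0, 0.9), "blink": (1.0, 0.5), "artifact": (0.2, 0.1)}
        for lab, (cx, cy) in centers.items():
            for _ in range(n):
                data.append((SegmentFeatures(cx + rng.normal(0, spread), cy + rng.normal(0, spread / 5), "rising"), lab))
        return data

    def test_separable_blobs_perfect_training_accuracy(self):
        clf = train_classifier(self._blobs())
        assert clf.train_accuracy == 1.0

    def test_deterministic_predictions(self):
        data = self._blobs(seed=1)
        c1 = train_classifier(data, seed=3)
        c2 = train_classifier(data, seed=3)
        test = [f for f, _ in self._blobs(seed=9)]
        assert predict_labels(c1, test) == predict_labels(c2, test)

    def test_small_c_underfits_to_majority(self):
        rng = np.random.default_rng(0)

        def blob(c, n, lab):
            return [(SegmentFeatures(c[0] + rng.normal(0, 0.1), c[1] + rng.normal(0, 0.02), "rising"), lab)
                    for _ in range(n)]

        data = blob((5, 0.9), 100, "saccade") + blob((1, 0.5), 10, "blink") + blob((0.2, 0.1), 10, "artifact")
        weak = train_classifier(data, C=1e-8)
        strong = train_classifier(data, C=10.0)
        assert weak.train_accuracy == pytest.approx(100 / 120)
        assert strong.train_accuracy == 1.0

    def test_empty_prediction(self):
        clf = train_classifier(self._blobs())
        assert predict_labels(clf, []) == []

    def test_scaler_fitted_on_train_only(self):
        clf = train_classifier(self._blobs())
        mean_before = clf.scaler.mean_.copy()
        predict_labels(clf, [SegmentFeatures(1e6, 0.5, "rising")])
        np.testing.assert_array_equal(clf.scaler.mean_, mean_before)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        data = [(SegmentFeatures(rng.random(), rng.random(), "rising"), "blink") for _ in range(10)]
        with pytest.raises(ValueError):
            train_classifier(data)

    def test_macro_f1_on_synthetic_segments(self, fs, templates):
        """Waveform-bank surrogate: all three classes separate well."""
        from sklearn.metrics import f1_score

        rising, falling = templates
        cfg = SynthConfig(fs=fs, seed=11)
        labeled = [(features_from_waveform(w, fs, rising, falling), lab)
                   for w, lab in synth_labeled_segments(cfg, 150, seed=11)]
        train, val = make_training_sets(labeled, seed=11)
        clf = train_classifier(train)
        y = [lab for _, lab in val]
        p = predict_labels(clf, [f for f, _ in val])
        assert f1_score(y, p, average="macro") >= 0.9


class TestTuning:
    def test_grid_finds_known_optimum(self):
        best, trace = tune_hyperparameters(
            lambda C, gamma: -((C - 1) ** 2) - (gamma - 1) ** 2,
            {"C": [0.1, 1.0, 10.0], "gamma": [0.1, 1.0, 10.0]},
            budget=9,
        )
        assert best == {"C": 1.0, "gamma": 1.0}
        assert len(trace) == 9

    def test_budget_one_returns_single_point(self):
        best, trace = tune_hyperparameters(lambda C: -C, {"C": (0.1, 10.0)}, budget=1, seed=0)
        assert len(trace) == 1 and best == trace[0][0]

    def test_seeded_reproducibility(self):
        space = {"C": (0.1, 100.0), "gamma": (1e-3, 1.0)}
        obj = lambda C, gamma: -abs(np.log(C)) - abs(np.log(gamma))
        b1, t1 = tune_hyperparameters(obj, space, budget=20, seed=5)
        b2, t2 = tune_hyperparameters(obj, space, budget=20, seed=5)
        assert b1 == b2 and t1 == t2

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(lambda: 0.0, {}, budget=5)
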