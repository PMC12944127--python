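"""EOG preprocessing: baseline removal, band-pass filtering, per-REM z-scoring.

The pipeline order is fixed — baseline removal, then zero-phase band-pass,
then a z-score computed separately inside each expert-scored REM interval —
so that the normalisation statistics never mix REM with surrounding stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import REMInterval

#: Guard below which the REM-interval SD is treated as degenerate (flat signal).
SIGMA_FLOOR = 1e-12


@dataclass
class PreprocessedSignal:
    """One REM interval of the analysis channel after the full pipeline.

    ``x`` is in z-units relative to the interval's own mean ``mu_rem`` and
    population SD ``sigma_rem``.  ``degenerate`` flags a flat interval whose
    SD fell below the numerical floor; its samples are all zero.
    """

    x: np.ndarray
    fs: float
    interval: REMInterval
    mu_rem: float
    sigma_rem: float
    degenerate: bool = False


def remove_baseline(x: np.ndarray, fs: float, window_s: float = 1.5) -> np.ndarray:
    """Subtract a centred moving average to remove slow baseline drift.

    The window is rounded to the nearest odd sample count; at the edges the
    window shrinks symmetrically so the output keeps the input length and no
    phase shift is introduced.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if w % 2 == 0:
        w += 1
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    ma = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return x - ma


def bandpass(x: np.ndarray, fs: float, lo: float = 1.0, hi: float = 10.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward–backward filtering)."""
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    if hi >= fs / 2:
        raise ValueError("upper edge must lie below the Nyquist frequency")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def zscore_rem(x: np.ndarray, fs: float, interval: REMInterval) -> PreprocessedSignal:
    """Z-score one REM interval using only its own samples.

    The mean and population SD are estimated exclusively from the interval;
    a flat interval (SD below ``SIGMA_FLOOR``) is flagged degenerate and
    returned as zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size != len(interval):
        raise ValueError("signal length must equal interval length")
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # population SD, no Bessel correction
    if sigma < SIGMA_FLOOR:
        return PreprocessedSignal(
            x=np.zeros_like(x), fs=fs, interval=interval, mu_rem=mu, sigma_rem=sigma, degenerate=True
        )
    return PreprocessedSignal(x=(x - mu) / sigma, fs=fs, interval=interval, mu_rem=mu, sigma_rem=sigma)


def preprocess_interval(
    signal: np.ndarray,
    fs: float,
    interval: REMInterval,
    baseline_window_s: float = 1.5,
    band_lo_hz: float = 1.0,
    band_hi_hz: float = 10.0,
    filter_order: int = 2,
) -> PreprocessedSignal:
    """Run the full preprocessing chain on one REM interval of a recording.

    ``signal`` is the whole-night analysis channel; the interval is cut out
    first so that detrending, filtering and normalisation see REM samples
    only.
    """
    seg = np.asarray(signal, dtype=float)[interval.start : interval.end]
    seg = remove_baseline(seg, fs, window_s=baseline_window_s)
    seg = bandpass(seg, fs, lo=band_lo_hz, hi=band_hi_hz, order=filter_order)
    return zscore_rem(seg, fs, interval)
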