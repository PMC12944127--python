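"""Saccade morphology kernel and log-sigmoid correlation templates.

The matched-filter kernel is a unit-energy prototype averaged from verified
saccade waveforms: each waveform is peak-normalised, resampled to a common
length, aligned on its largest-magnitude sample and sign-flipped so that
peak is positive before averaging.  Unlike analytic wavelets (Haar, DB4),
the prototype keeps the asymmetric rise / plateau / deceleration structure
of real saccades.

The rising and falling log-sigmoid templates serve the segment classifier:
they are mean-removed and unit-energy, so their correlation with any flat
segment is exactly zero and their inner product with a unit-energy segment
is bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class SaccadeKernel:
    """Unit-energy saccade prototype ``h`` of length ``L`` at rate ``fs_ref``."""

    h: np.ndarray
    fs_ref: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.size < 3:
            raise ValueError("kernel needs at least 3 samples")
        energy = float(np.sum(self.h**2))
        if abs(energy - 1.0) > 1e-9:
            raise ValueError("kernel must be L2-normalized to unit energy")

    @property
    def L(self) -> int:
        return self.h.size


@dataclass
class SigmoidTemplate:
    """Mean-removed, unit-energy logistic step template, rising or falling."""

    direction: str
    w: np.ndarray
    steepness: float
    midpoint: float

    @property
    def L(self) -> int:
        return self.w.size


def _resample_linear(w: np.ndarray, L: int) -> np.ndarray:
    """Resample to L samples by linear interpolation over the same support."""
    w = np.asarray(w, dtype=float)
    if w.size == L:
        return w.copy()
    old = np.linspace(0.0, 1.0, w.size)
    new = np.linspace(0.0, 1.0, L)
    return np.interp(new, old, w)


def build_saccade_kernel(waveforms: list[np.ndarray], L: int, fs_ref: float = 250.0) -> SaccadeKernel:
    """Average verified saccade waveforms into a unit-energy prototype.

    Each waveform is normalised to unit peak magnitude, resampled to ``L``
    by linear interpolation, circularly shifted so its largest-magnitude
    sample sits at ``L // 2``, and sign-aligned so that peak is positive.
    The pointwise mean is then L2-normalised.
    """
    if not waveforms:
        raise ValueError("need at least one waveform")
    if L < 3:
        raise ValueError("kernel length must be at least 3")
    aligned = np.empty((len(waveforms), L))
    for i, w in enumerate(waveforms):
        w = np.asarray(w, dtype=float)
        if w.size < 3:
            raise ValueError("each waveform needs at least 3 samples")
        peak = float(np.max(np.abs(w)))
        if peak < 1e-12:
            raise ValueError("constant waveform has no peak to align on")
        w = _resample_linear(w / peak, L)
        p = int(np.argmax(np.abs(w)))
        w = np.roll(w, L // 2 - p)
        if w[L // 2] < 0:
            w = -w
        aligned[i] = w
    proto = aligned.mean(axis=0)
    norm = float(np.sqrt(np.sum(proto**2)))
    if norm < 1e-12:
        raise ValueError("waveforms cancelled out; cannot build a kernel")
    return SaccadeKernel(h=proto / norm, fs_ref=fs_ref)


def log_sigmoid_template(
    direction: str, L: int, steepness: float = 12.0, midpoint: float = 0.5
) -> SigmoidTemplate:
    """Build a rising or falling logistic-step correlation template.

    The rising profile is ``1 / (1 + exp(-steepness * (k/L - midpoint)))``,
    mean-removed and normalised to unit energy; the falling template is its
    exact time reversal.
    """
    if L < 3:
        raise ValueError("template length must be at least 3")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    if not (0 < midpoint < 1):
        raise ValueError("midpoint must lie in (0, 1)")
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    from scipy.special import expit

    k = np.arange(L, dtype=float)
    s = expit(steepness * (k / L - midpoint))
    if direction == "falling":
        s = s[::-1]
    s = s - s.mean()
    s = s / np.sqrt(np.sum(s**2))
    return SigmoidTemplate(direction=direction, w=s, steepness=steepness, midpoint=midpoint)


def default_kernel_length(fs: float, duration_s: float = 0.10) -> int:
    """Kernel support covering the rise, plateau and fall of a typical saccade.

    The prototype is resampled to a common duration near the middle of the
    physiological saccade range (30-150 ms).  A support much longer than
    the events themselves would make the window-start-indexed matched
    filter respond ahead of short saccades by up to half the kernel
    length, beyond the reach of boundary refinement.
    """
    return max(3, int(round(duration_s * fs)))


def bandlimit_waveform(w: np.ndarray, fs: float, pre_s: float = 0.05, post_s: float = 0.1) -> np.ndarray:
    """Pass an event waveform through the analysis band (1-10 Hz, zero phase).

    The waveform is embedded in a zero baseline with generous margins
    before filtering, then cut back out with a small lead-in and a tail
    that keeps the post-event deflection of the AC-coupled response.
    Verified saccades come from preprocessed recordings, so kernels must
    be built in this band-limited domain to match the signal they will be
    correlated with.
    """
    from .preprocess import bandpass

    w = np.asarray(w, dtype=float)
    margin = max(int(round(0.5 * fs)), w.size)
    padded = np.zeros(2 * margin + w.size)
    padded[margin : margin + w.size] = w
    filt = bandpass(padded, fs)
    a = margin - int(round(pre_s * fs))
    b = margin + w.size + int(round(post_s * fs))
    return filt[a:b]


def default_kernel(fs: float = 250.0, n_waveforms: int = 200, seed: int = 12345) -> SaccadeKernel:
    """Reproducible default prototype built from synthetic three-phase saccades.

    Stands in for a bank of manually verified recordings: the generator's
    saccades carry the same rise / plateau / deceleration morphology, and
    each is band-limited exactly as the preprocessing stage would leave it
    before averaging.
    """
    from .synth import SynthConfig, synth_saccade

    rng = np.random.default_rng(seed)
    cfg = SynthConfig(fs=fs)
    waveforms = []
    for _ in range(n_waveforms):
        dur = rng.uniform(*cfg.saccade_dur_range_s)
        amp = rng.uniform(*cfg.saccade_amp_range)
        direction = 1 if rng.random() < 0.5 else -1
        raw = synth_saccade(
            fs,
            dur,
            amp,
            direction,
            rest_frac=float(np.clip(rng.normal(cfg.saccade_rest_frac, 0.05), 0.3, 0.9)),
            steepness=rng.uniform(10.0, 14.0),
        )
        waveforms.append(bandlimit_waveform(raw, fs))
    return build_saccade_kernel(waveforms, L=default_kernel_length(fs), fs_ref=fs)


def save_kernel(kernel: SaccadeKernel, path: str | Path) -> None:
    """Persist as delimited text: header with L and fs_ref, one value per line."""
    lines = [f"# L={kernel.L} fs_ref={kernel.fs_ref}"]
    lines += [f"{v:.12e}" for v in kernel.h]
    Path(path).write_text("\n".join(lines) + "\n")


def load_kernel(path: str | Path) -> SaccadeKernel:
    lines = Path(path).read_text().splitlines()
    header = lines[0].lstrip("# ").split()
    meta = dict(kv.split("=") for kv in header)
    h = np.array([float(v) for v in lines[1:] if v.strip()])
    if h.size != int(meta["L"]):
        raise ValueError("kernel file length does not match its header")
    return SaccadeKernel(h=h, fs_ref=float(meta["fs_ref"]))
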