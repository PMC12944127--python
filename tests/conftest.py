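"""Shared fixtures: morphology kernel, templates, and a tiny EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from remsacc import SynthConfig, default_kernel, default_templates


@pytest.fixture(scope="session")
def fs() -> float:
    return 250.0


@pytest.fixture(scope="session")
def kernel(fs):
    return default_kernel(fs)


@pytest.fixture(scope="session")
def templates(kernel):
    return default_templates(kernel.L)


@pytest.fixture()
def synth_config(fs):
    return SynthConfig(fs=fs, seed=42)


def write_minimal_edf(path, signals: dict[str, np.ndarray], fs: int) -> None:
    """Write a bare-bones 16-bit EDF file (synthetic test fixture).

    One data record per second, physical range chosen to cover the data.
    Only the fields EDF readers require are populated.
    """
    ns = len(signals)
    labels = list(signals)
    data = [np.asarray(signals[l], dtype=float) for l in labels]
    n_samples = data[0].size
    assert all(d.size == n_samples for d in data)
    n_records = n_samples // fs
    assert n_records * fs == n_samples, "duration must be a whole number of seconds"

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2024 X X X", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    header += b"".join(pad(l, 16) for l in labels)
    header += b"".join(pad("", 80) for _ in labels)
    header += b"".join(pad("uV", 8) for _ in labels)
    header += b"".join(pad(str(phys_min), 8) for _ in labels)
    header += b"".join(pad(str(phys_max), 8) for _ in labels)
    header += b"".join(pad(str(dig_min), 8) for _ in labels)
    header += b"".join(pad(str(dig_max), 8) for _ in labels)
    header += b"".join(pad("", 80) for _ in labels)
    header += b"".join(pad(str(fs), 8) for _ in labels)
    header += b"".join(pad("", 32) for _ in labels)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in data:
                chunk = d[r * fs : (r + 1) * fs]
                dig = np.clip(np.round(chunk / gain), dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())
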