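import numpy as np
import pytest

import gawlab
from gawlab.extraction import CycleSegmentation, GAWRecord


@pytest.fixture(scope="session")
def clean_gaw():
    """Noiseless periodic GAW at 100 Hz, 250 ms, 4 kHz: the textbook case."""
    params = gawlab.GAWSynthesisParams(f0=100.0, duration=0.25, fs=4000.0)
    return gawlab.generate_gaw(params)


@pytest.fixture(scope="session")
def clean_cycles(clean_gaw):
    return gawlab.detect_cycles(clean_gaw.gaw)


@pytest.fixture(scope="session")
def perturbed_gaw():
    """Moderately perturbed GAW with noise and asymmetry (realistic case)."""
    params = gawlab.GAWSynthesisParams(
        f0=120.0,
        duration=0.3,
        fs=4000.0,
        jitter=0.01,
        shimmer=0.04,
        snr_db=30.0,
        gap=0.15,
        phase_lag=0.05,
        seed=42,
    )
    return gawlab.generate_gaw(params)


@pytest.fixture(scope="session")
def perturbed_cycles(perturbed_gaw):
    return gawlab.detect_cycles(perturbed_gaw.gaw)


def sinusoid_gaw(f0=100.0, fs=4000.0, n_cycles=25, amplitude=200.0, offset=250.0):
    """Pure raised sinusoid with an integer number of exact-bin cycles."""
    n = int(n_cycles * fs / f0)
    t = np.arange(n) / fs
    total = offset - amplitude * np.cos(2 * np.pi * f0 * t)
    return GAWRecord(total=total, left=total / 2, right=total / 2, fs=fs)


def sinusoid_cycles(gaw, f0=100.0):
    period = int(gaw.fs / f0)
    boundaries = np.arange(0, gaw.n_samples + 1, period)
    return CycleSegmentation(boundaries=boundaries, fs=gaw.fs)
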