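"""Shared fixtures: tiny synthetic configurations that keep unit tests
fast while exercising the same code paths as a full cohort."""

import numpy as np
import pytest

from spastemg import SynthConfig


@pytest.fixture
def tiny_config() -> SynthConfig:
    """A seconds-scale protocol: 2-s rests, two loops of two 6-s cycles
    (2-s movements), 4-s breaks, 2 patients x 1 trial per grade."""
    return SynthConfig(
        n_patients_per_grade=2,
        trials_per_patient=1,
        rest_duration=2.0,
        cycle_duration=6.0,
        cycles_per_loop=2,
        loops=2,
        break_duration=4.0,
        movement_duration=2.0,
        seed=7,
    )


@pytest.fixture
def rate() -> float:
    return 1024.0


def tone(freq: float, seconds: float, rate: float = 1024.0) -> np.ndarray:
    t = np.arange(int(seconds * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


def steady_amplitude(x: np.ndarray, rate: float = 1024.0) -> float:
    """Peak amplitude over the middle of a signal, away from filter
    transients (drops one second at each end)."""
    n = int(rate)
    return float(np.abs(x[n:-n]).max())
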