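"""Denoising of raw sEMG: 20-450 Hz band-pass plus 48-52 Hz powerline notch.

Surface EMG carries most of its power between roughly 20 and 450 Hz;
below 20 Hz live motion artefacts and baseline drift, and mains
interference sits at 50 Hz.  The default spec therefore combines a
Butterworth band-pass (20-450 Hz) with a narrow IIR notch whose -3 dB
band is 48-52 Hz.  Both stages are applied forward-backward (zero phase)
so that burst timing, which the envelope-area feature depends on, is not
delayed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .recording import EMGRecording, Segment


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Filter parameters; defaults are the standard sEMG settings.

    ``filter_order`` is the Butterworth prototype order of the band-pass
    (a band-pass of prototype order N has 2N poles).  The notch is a
    second-order IIR notch centred between ``notch_low`` and
    ``notch_high`` with that interval as its -3 dB band.
    """

    bandpass_low: float = 20.0
    bandpass_high: float = 450.0
    notch_low: float = 48.0
    notch_high: float = 52.0
    filter_order: int = 4
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ConfigurationError(
                f"need 0 < bandpass_low < bandpass_high, got "
                f"({self.bandpass_low}, {self.bandpass_high})"
            )
        if self.bandpass_high >= nyq:
            raise ConfigurationError(
                f"bandpass_high {self.bandpass_high} Hz requires rate > "
                f"{2 * self.bandpass_high} Hz (got {rate} Hz)"
            )
        if not (
            self.bandpass_low < self.notch_low < self.notch_high < self.bandpass_high
        ):
            raise ConfigurationError(
                f"notch band ({self.notch_low}, {self.notch_high}) must lie "
                f"inside the passband"
            )
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")


DEFAULT_FILTER_SPEC = FilterSpec()


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def bandpass(
    x: np.ndarray, rate: float, spec: FilterSpec = DEFAULT_FILTER_SPEC
) -> np.ndarray:
    """Band-pass filter a signal vector; output has the input's length."""
    spec.validate(rate)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    sos = sps.butter(
        spec.filter_order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        fs=rate,
        output="sos",
    )
    return _apply_sos(sos, x, spec.zero_phase)


def notch(
    x: np.ndarray, rate: float, spec: FilterSpec = DEFAULT_FILTER_SPEC
) -> np.ndarray:
    """Notch out the powerline band; output has the input's length."""
    spec.validate(rate)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    f0 = 0.5 * (spec.notch_low + spec.notch_high)
    bw = spec.notch_high - spec.notch_low
    b, a = sps.iirnotch(f0, f0 / bw, fs=rate)
    if spec.zero_phase:
        return sps.filtfilt(b, a, x)
    return sps.lfilter(b, a, x)


def preprocess_signal(
    x: np.ndarray, rate: float, spec: FilterSpec = DEFAULT_FILTER_SPEC
) -> np.ndarray:
    """Band-pass then notch — the full denoising chain."""
    return notch(bandpass(x, rate, spec), rate, spec)


def preprocess_segment(seg: Segment, spec: FilterSpec = DEFAULT_FILTER_SPEC) -> Segment:
    """Return a new :class:`Segment` with the denoising chain applied;
    all metadata is preserved."""
    return dataclasses.replace(
        seg, samples=preprocess_signal(seg.samples, seg.rate, spec)
    )


def preprocess_recording(
    rec: EMGRecording, spec: FilterSpec = DEFAULT_FILTER_SPEC
) -> EMGRecording:
    """Apply the denoising chain to every channel of a recording."""
    filtered = np.vstack(
        [preprocess_signal(rec.signal[i], rec.rate, spec) for i in range(len(rec.channels))]
    )
    return dataclasses.replace(rec, signal=filtered)
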