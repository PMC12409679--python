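"""Per-segment sEMG features: RMS, iEMG, envelope area, MPF and MF.

Three time-domain features quantify activation amplitude:

* RMS — root mean square of the segment, ``sqrt(mean(x**2))``;
* iEMG — integrated EMG, the sum of absolute sample values;
* EA — envelope area.  All local extrema of the segment are extracted,
  the maxima are interpolated by a cubic spline into an upper envelope
  L(t) and the minima into a lower envelope l(t), and
  ``EA = |∫L(t)dt| + |∫l(t)dt|`` with trapezoidal integration over sample
  indices.  Note the absolute value is taken of the *signed* integral of
  each envelope, not of the envelope itself.

Two frequency-domain features summarise the power spectrum (Welch
averaged periodogram, 1-s Hann windows, 50 % overlap):

* MPF — mean power frequency, the power-weighted spectral centroid
  ``Σ fᵢPᵢ / Σ Pᵢ``;
* MF — median frequency, the smallest frequency at which cumulative
  power reaches half the total.

In spastic muscle, passive stretch elicits reflex bursts whose amplitude
grows with spasticity grade (raising RMS/iEMG/EA) while their spectral
content shifts downward (lowering MPF/MF); these five numbers are the
raw material for the correlation screen and channel fusion downstream.

Features of incommensurate magnitude are put on a common scale by max-min
normalization ``(x - x_min) / (x_max - x_min)`` over the sample
population before any correlation or classification step.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .errors import DegenerateFeatureError, DomainError, UndefinedFeatureError
from .recording import Segment

#: Canonical feature order used in every table.
FEATURES: tuple[str, ...] = ("rms", "iemg", "ea", "mpf", "mf")

#: The time-domain (amplitude) subset, which survives the correlation
#: screen on clinical data.
TIME_DOMAIN_FEATURES: tuple[str, ...] = ("rms", "iemg", "ea")


def rms(x: np.ndarray) -> float:
    """Root mean square amplitude."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("rms of an empty signal is undefined")
    return float(np.sqrt(np.mean(x**2)))


def iemg(x: np.ndarray) -> float:
    """Integrated EMG: sum of absolute sample values."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("iemg of an empty signal is undefined")
    return float(np.sum(np.abs(x)))


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Locate strict local maxima and minima by sign change of the first
    difference, anchoring both lists with the first and last sample.

    Returns ``(maxima_indices, minima_indices)``, each sorted and
    including the endpoint anchors.  Plateaus (zero first difference) are
    not counted as extrema.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise DomainError(f"need at least 3 samples to find extrema, got {n}")
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    maxima = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    minima = np.flatnonzero(falling[:-1] & rising[1:]) + 1
    anchors = np.array([0, n - 1])
    maxima = np.unique(np.concatenate([anchors, maxima]))
    minima = np.unique(np.concatenate([anchors, minima]))
    return maxima, minima


@dataclasses.dataclass
class Envelope:
    """Upper and lower envelope curves evaluated at every sample index."""

    upper: np.ndarray
    lower: np.ndarray


def _spline_through(indices: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.size
    if indices.size < 2:  # pragma: no cover - anchors guarantee >= 2
        raise DomainError("need at least 2 points to interpolate an envelope")
    cs = CubicSpline(indices, x[indices], bc_type="natural")
    return cs(np.arange(n))


def envelope(x: np.ndarray) -> Envelope:
    """Cubic-spline envelopes through the local maxima (upper) and minima
    (lower), with natural end conditions and endpoint anchors."""
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    return Envelope(upper=_spline_through(maxima, x), lower=_spline_through(minima, x))


def envelope_area(x: np.ndarray) -> float:
    """Total envelope area EA = |∫L| + |∫l|, trapezoidal over sample
    indices (dt = 1 sample)."""
    env = envelope(x)
    ea_up = abs(float(np.trapezoid(env.upper)))
    ea_down = abs(float(np.trapezoid(env.lower)))
    return ea_up + ea_down


def power_spectrum(
    x: np.ndarray, rate: float, window_seconds: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density on [0, rate/2].

    Windows of ``window_seconds`` (capped at the signal length) with 50 %
    overlap and a Hann taper.  Requires at least 64 samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise DomainError(f"need at least 64 samples for a spectrum, got {x.size}")
    nperseg = min(int(round(window_seconds * rate)), x.size)
    freqs, psd = welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs, psd


def mpf(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Mean power frequency: the power-weighted spectral centroid."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if not total > 0:
        raise UndefinedFeatureError("MPF undefined for zero spectral power")
    return float(np.sum(freqs * psd) / total)


def mf(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Median frequency: smallest frequency where cumulative power
    reaches half the total."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if not total > 0:
        raise UndefinedFeatureError("MF undefined for zero spectral power")
    cum = np.cumsum(psd)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(freqs[idx])


@dataclasses.dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max over the sample population (for reuse on
    held-out data in fold-safe mode)."""

    x_min: float
    x_max: float

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.x_min) / (
            self.x_max - self.x_min
        )


def normalize(values: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Max-min normalize one feature across samples onto [0, 1].

    The minimum maps to 0, the maximum to 1 and order is preserved.  A
    constant column signals a broken extraction and raises
    :class:`DegenerateFeatureError`.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DomainError("need at least 2 values to normalize")
    x_min, x_max = float(values.min()), float(values.max())
    if x_max == x_min:
        raise DegenerateFeatureError(
            "feature column is constant; max-min normalization undefined"
        )
    params = NormalizationParams(x_min=x_min, x_max=x_max)
    return params.apply(values), params


def extract_features(seg: Segment) -> dict:
    """All five features of one (segment, channel) signal."""
    x = seg.samples
    freqs, psd = power_spectrum(x, seg.rate)
    return {
        "subject_id": seg.subject_id,
        "trial": seg.trial_index,
        "segment": seg.segment_id,
        "channel": seg.channel,
        "rms": rms(x),
        "iemg": iemg(x),
        "ea": envelope_area(x),
        "mpf": mpf(freqs, psd),
        "mf": mf(freqs, psd),
        "mas_label": seg.grade.label,
    }


def extract_all(segments: Iterable[Segment]) -> pd.DataFrame:
    """Feature table with one row per (segment, channel).

    Columns: subject_id, trial, segment, channel, rms, iemg, ea, mpf,
    mf, mas_label — the interchange format between pipeline stages.
    """
    rows = [extract_features(seg) for seg in segments]
    if not rows:
        raise DomainError("no segments supplied")
    return pd.DataFrame(rows)


SAMPLE_KEY = ["subject_id", "trial", "segment"]


def pivot_wide(long_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Reshape the long feature table to one row per sample dataset.

    A *sample dataset* is one (subject, trial, segment) unit carrying all
    three channels.  Returns a wide frame with MultiIndex columns
    ``(channel, feature)`` and a parallel Series of MAS labels.
    """
    wide = long_df.pivot_table(
        index=SAMPLE_KEY, columns="channel", values=list(FEATURES), sort=False
    )
    # pivot gives (feature, channel); swap to (channel, feature)
    wide = wide.swaplevel(axis=1).sort_index(axis=1, level=0)
    labels = long_df.drop_duplicates(SAMPLE_KEY).set_index(SAMPLE_KEY)["mas_label"]
    labels = labels.loc[wide.index]
    return wide, labels


def normalize_wide(
    wide: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[tuple[str, str], NormalizationParams]]:
    """Max-min normalize every (channel, feature) column jointly over the
    sample population; returns the normalized frame and the parameters."""
    out = wide.copy()
    params: dict[tuple[str, str], NormalizationParams] = {}
    for col in wide.columns:
        out[col], params[col] = normalize(wide[col].to_numpy())
    return out, params
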