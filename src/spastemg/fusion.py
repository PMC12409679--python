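"""Correlation screening and correlation-weighted multichannel fusion.

Each feature is measured on three muscles (LB, SB, BR).  Spearman rank
correlation between a feature's normalized values and the MAS ordinal is
computed per channel; features whose correlation magnitude clears a
threshold (default 0.7) on *all* channels are retained.  For a retained
feature with channel correlations r1, r2, r3 the channel weights are

    ωᵢ = rᵢ / (r1 + r2 + r3),   i = 1, 2, 3

so they sum to one, and the fused feature value of a sample is the
weighted sum of its channel values  e = ω1·e1 + ω2·e2 + ω3·e3 — a convex
combination when all correlations share a sign.  Fusing the three
channels this way lets the muscle that tracks spasticity best dominate
while still averaging out channel-specific noise.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateWeightsError,
    DomainError,
    UndefinedCorrelationError,
)
from .features import FEATURES, TIME_DOMAIN_FEATURES
from .recording import CHANNELS, encode_mas


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation (tie-corrected: Pearson on mid-ranks).

    Raises :class:`UndefinedCorrelationError` when either side has zero
    rank variance (a constant vector).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("spearman requires two equal-length vectors")
    if a.size < 3:
        raise DomainError("spearman requires at least 3 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError(
            "rank correlation undefined for a constant vector"
        )
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.325 -> 0.33), the convention used for
    the reported weight and metric tables."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def compute_correlations(
    wide_norm: pd.DataFrame, labels: Sequence[str]
) -> pd.DataFrame:
    """Per-(channel, feature) Spearman correlation against MAS ordinals.

    ``wide_norm`` has MultiIndex columns (channel, feature), one row per
    sample dataset.  Returns a channels x features table.
    """
    ordinals = np.array([encode_mas(lab) for lab in labels], dtype=float)
    table = pd.DataFrame(index=list(CHANNELS), columns=list(FEATURES), dtype=float)
    for ch in CHANNELS:
        for feat in FEATURES:
            table.loc[ch, feat] = spearman(
                wide_norm[(ch, feat)].to_numpy(), ordinals
            )
    return table


def screen(corr: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Retain a feature iff |r| >= threshold on every channel.

    With the correlation pattern seen clinically — amplitude features
    strongly positive, frequency features more weakly negative — this
    keeps RMS, iEMG and EA and drops MPF and MF.
    """
    retained = []
    for feat in corr.columns:
        if (corr[feat].abs() >= threshold).all():
            retained.append(feat)
    return retained


def compute_weights(r1: float, r2: float, r3: float) -> tuple[float, float, float]:
    """Channel weights ωᵢ = rᵢ / (r1 + r2 + r3).

    The correlations enter with their signs; a mixed-sign triple (some
    strictly positive and some strictly negative) has no coherent
    weighting and is rejected, as is a zero denominator.
    """
    r = np.array([r1, r2, r3], dtype=float)
    if (r > 0).any() and (r < 0).any():
        raise DegenerateWeightsError(
            f"mixed-sign correlations {tuple(r)} cannot be weighted coherently"
        )
    denom = r.sum()
    if denom == 0:
        raise DegenerateWeightsError("correlation sum is zero; weights undefined")
    w = r / denom
    return float(w[0]), float(w[1]), float(w[2])


def weight_table(
    corr: pd.DataFrame, retained: Sequence[str], fallback_equal: bool = False
) -> pd.DataFrame:
    """Weights for every retained feature; channels x retained features.
    Each column sums to 1.

    With ``fallback_equal=True`` a feature whose channel correlations are
    incoherent (mixed signs or zero sum — possible on structureless data
    such as a permutation baseline) gets equal weights 1/3 instead of an
    error.
    """
    table = pd.DataFrame(index=list(CHANNELS), columns=list(retained), dtype=float)
    for feat in retained:
        r = [float(corr.loc[ch, feat]) for ch in CHANNELS]
        try:
            table[feat] = compute_weights(*r)
        except DegenerateWeightsError:
            if not fallback_equal:
                raise
            table[feat] = 1.0 / len(CHANNELS)
    return table


def fuse(
    e1: float | np.ndarray,
    e2: float | np.ndarray,
    e3: float | np.ndarray,
    weights: Sequence[float],
) -> float | np.ndarray:
    """Fused feature value e = ω1·e1 + ω2·e2 + ω3·e3."""
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise DegenerateWeightsError(f"weights must sum to 1, got {w.sum()}")
    return w[0] * e1 + w[1] * e2 + w[2] * e3


def build_fused_dataset(
    wide_norm: pd.DataFrame,
    labels: Sequence[str],
    weights: pd.DataFrame,
) -> pd.DataFrame:
    """Fuse the three channels of every retained feature.

    Returns one row per sample dataset with columns ``fused_<feature>``
    for each column of ``weights`` plus ``mas_label`` and ``mas_ordinal``.
    """
    out = pd.DataFrame(index=wide_norm.index)
    for feat in weights.columns:
        w = weights[feat].to_numpy()
        channel_values = [wide_norm[(ch, feat)].to_numpy() for ch in CHANNELS]
        out[f"fused_{feat}"] = fuse(*channel_values, weights=w)
    out["mas_label"] = list(labels)
    out["mas_ordinal"] = [encode_mas(lab) for lab in labels]
    return out


def fuse_time_domain(
    wide_norm: pd.DataFrame, labels: Sequence[str], fallback_equal: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: correlations, weights and fused dataset for the three
    amplitude features (RMS, iEMG, EA), the feature set used by the fused
    classification model."""
    corr = compute_correlations(wide_norm, labels)
    weights = weight_table(corr, TIME_DOMAIN_FEATURES, fallback_equal=fallback_equal)
    fused = build_fused_dataset(wide_norm, labels, weights)
    return corr, weights, fused
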