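"""Data model and text I/O for labelled multichannel sEMG recordings.

A recording holds the raw signal of one passive elbow flexion-extension
trial from three elbow-flexor muscles: the long head of the biceps brachii
(LB, channel 1), the short head of the biceps brachii (SB, channel 2) and
the brachioradialis (BR, channel 3), sampled at 1,024 Hz by default,
together with the clinician's Modified Ashworth Scale (MAS) grade.

The MAS is an ordinal clinical scale of muscle spasticity.  The cohorts
this package targets contain the five grades 0, 1, 1+, 2 and 3 (grade 4,
rigid limbs, does not occur), encoded as ordinals 0..4 so that "1+" sits
between "1" and "2".
"""

from __future__ import annotations

import dataclasses
import string
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, GradeError, ParseError

#: Fixed channel order: channel 1 = LB, channel 2 = SB, channel 3 = BR.
CHANNELS: tuple[str, ...] = ("LB", "SB", "BR")

#: Supported MAS labels in clinical order.
GRADE_LABELS: tuple[str, ...] = ("0", "1", "1+", "2", "3")

_LABEL_TO_ORDINAL = {lab: i for i, lab in enumerate(GRADE_LABELS)}


def encode_mas(label: str) -> int:
    """Map an MAS label to its ordinal (``"0"``→0, ``"1"``→1, ``"1+"``→2,
    ``"2"``→3, ``"3"``→4).

    The ordinal is used both as the ordinal variable in Spearman
    correlation and as the class label in classification.  Labels outside
    the supported set (including "4") raise :class:`GradeError`.
    """
    try:
        return _LABEL_TO_ORDINAL[str(label)]
    except KeyError:
        raise GradeError(
            f"unsupported MAS label {label!r}; expected one of {GRADE_LABELS}"
        ) from None


def decode_mas(ordinal: int) -> str:
    """Inverse of :func:`encode_mas`."""
    if not 0 <= int(ordinal) < len(GRADE_LABELS):
        raise GradeError(f"MAS ordinal out of range: {ordinal}")
    return GRADE_LABELS[int(ordinal)]


@dataclasses.dataclass(frozen=True)
class MASGrade:
    """A Modified Ashworth Scale grade, identified by its clinical label."""

    label: str

    def __post_init__(self) -> None:
        encode_mas(self.label)  # validates

    @property
    def ordinal(self) -> int:
        return encode_mas(self.label)

    @classmethod
    def from_ordinal(cls, ordinal: int) -> "MASGrade":
        return cls(decode_mas(ordinal))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclasses.dataclass
class EMGRecording:
    """One trial's 3-channel raw sEMG signal with its MAS label.

    ``signal`` is a ``(3, n_samples)`` float array in millivolts with rows
    in the fixed order :data:`CHANNELS`.
    """

    subject_id: str
    trial_index: int
    rate: float
    signal: np.ndarray
    grade: MASGrade
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if tuple(self.channels) != CHANNELS:
            raise FormatError(
                f"channels must be {CHANNELS} in order, got {tuple(self.channels)}"
            )
        if self.signal.ndim != 2 or self.signal.shape[0] != len(CHANNELS):
            raise FormatError(
                f"signal must be a ({len(CHANNELS)}, n_samples) matrix, "
                f"got shape {self.signal.shape}"
            )
        if not self.rate > 0:
            raise FormatError(f"rate must be positive, got {self.rate}")
        if self.trial_index < 1:
            raise FormatError(f"trial_index must be >= 1, got {self.trial_index}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.rate


@dataclasses.dataclass
class Segment:
    """One time slice of a recording's active span, for one channel."""

    subject_id: str
    trial_index: int
    segment_id: str
    channel: str
    samples: np.ndarray
    rate: float
    grade: MASGrade

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("segment samples must be a 1-D vector")

    @property
    def n_samples(self) -> int:
        return self.samples.size


def read_recording(
    path: str | Path,
    rate: float,
    grade: str | MASGrade,
    subject_id: str,
    trial_index: int,
) -> EMGRecording:
    """Read a comma-delimited signal file into an :class:`EMGRecording`.

    The file must have exactly the header ``LB,SB,BR`` and one sample per
    row (millivolt floats).  Missing or extra columns raise
    :class:`FormatError`; a non-numeric cell raises :class:`ParseError`
    naming the 0-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = [c.strip() for c in df.columns]
    missing = [c for c in CHANNELS if c not in cols]
    extra = [c for c in cols if c not in CHANNELS]
    if missing or extra:
        raise FormatError(
            f"{path}: expected columns {list(CHANNELS)}; "
            f"missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    df.columns = cols
    data = np.empty((len(CHANNELS), len(df)), dtype=float)
    for i, ch in enumerate(CHANNELS):
        converted = pd.to_numeric(df[ch], errors="coerce")
        bad = converted.isna() & df[ch].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[ch].iloc[row]!r} "
                f"in column {ch}, data row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{path}: empty cell in column {ch}, data row {row}")
        data[i] = converted.to_numpy(dtype=float)
    if not isinstance(grade, MASGrade):
        grade = MASGrade(str(grade))
    return EMGRecording(
        subject_id=subject_id,
        trial_index=trial_index,
        rate=rate,
        signal=data,
        grade=grade,
    )


def write_recording(recording: EMGRecording, path: str | Path) -> None:
    """Write a recording as comma-delimited text readable by
    :func:`read_recording` (header row naming the channels in order)."""
    path = Path(path)
    df = pd.DataFrame(recording.signal.T, columns=list(CHANNELS))
    df.to_csv(path, index=False, float_format="%.9g")


def _segment_labels(n: int) -> list[str]:
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [f"S{i + 1}" for i in range(n)]


def split_segments(
    recording: EMGRecording,
    span: tuple[int, int],
    n_segments: int = 3,
) -> list[Segment]:
    """Split the half-open sample interval ``span = [start, end)`` of every
    channel into ``n_segments`` contiguous, near-equal segments.

    Segment lengths differ by at most one sample; when the span is not
    divisible the remainder goes to the earliest segments.  Segments are
    labelled A, B, C, ... and returned channel-major (all segments of LB,
    then SB, then BR).
    """
    start, end = int(span[0]), int(span[1])
    n = recording.n_samples
    if not (0 <= start <= end <= n):
        raise BoundsError(
            f"span [{start}, {end}) outside recording of {n} samples"
        )
    if n_segments < 1:
        raise BoundsError(f"n_segments must be >= 1, got {n_segments}")
    length = end - start
    base, rem = divmod(length, n_segments)
    labels = _segment_labels(n_segments)
    bounds = [start]
    for i in range(n_segments):
        bounds.append(bounds[-1] + base + (1 if i < rem else 0))
    segments: list[Segment] = []
    for ci, ch in enumerate(CHANNELS):
        for si in range(n_segments):
            segments.append(
                Segment(
                    subject_id=recording.subject_id,
                    trial_index=recording.trial_index,
                    segment_id=labels[si],
                    channel=ch,
                    samples=recording.signal[ci, bounds[si] : bounds[si + 1]],
                    rate=recording.rate,
                    grade=recording.grade,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# Cohort manifest

MANIFEST_COLUMNS = (
    "subject_id",
    "trial_index",
    "path",
    "mas_label",
    "span_start",
    "span_end",
)


def write_manifest(rows: Iterable[dict], path: str | Path) -> None:
    """Write a cohort manifest CSV (one row per recording file)."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest rows missing fields {missing}")
    df[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its columns."""
    df = pd.read_csv(path, dtype={"mas_label": str, "subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    for lab in df["mas_label"]:
        encode_mas(lab)
    return df


def load_cohort(
    manifest: pd.DataFrame, rate: float, base_dir: str | Path | None = None
) -> list[tuple[EMGRecording, tuple[int, int]]]:
    """Load every recording referenced by a manifest, with its active span."""
    base = Path(base_dir) if base_dir is not None else None
    out = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if base is not None and not p.is_absolute():
            p = base / p
        rec = read_recording(
            p,
            rate=rate,
            grade=str(row.mas_label),
            subject_id=str(row.subject_id),
            trial_index=int(row.trial_index),
        )
        out.append((rec, (int(row.span_start), int(row.span_end))))
    return out
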