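"""End-to-end orchestration: signals -> features -> fusion -> k-NN report.

The pipeline mirrors the study design it automates: each trial's active
span is split into three segments, denoised, reduced to five features
per channel, and the balanced sample population (40 sample datasets per
MAS grade by default) is normalized, screened by Spearman correlation,
fused across channels and classified with stratified 10-fold
cross-validation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_K_GRID,
    LabeledDataset,
    compare_models,
    cross_validate,
    metrics,
    select_k,
    EvalReport,
)
from .errors import DataError
from .features import (
    SAMPLE_KEY,
    TIME_DOMAIN_FEATURES,
    extract_all,
    normalize_wide,
    pivot_wide,
)
from .filtering import DEFAULT_FILTER_SPEC, FilterSpec, preprocess_segment
from .fusion import build_fused_dataset, compute_correlations, screen, weight_table
from .recording import EMGRecording, encode_mas, split_segments
from .simulate import SynthConfig, iter_cohort


def extract_recording_features(
    recording: EMGRecording,
    span: tuple[int, int],
    n_segments: int = 3,
    filter_spec: FilterSpec = DEFAULT_FILTER_SPEC,
) -> pd.DataFrame:
    """Segment, denoise and featurize one recording's active span."""
    segs = [preprocess_segment(s, filter_spec) for s in split_segments(recording, span, n_segments)]
    return extract_all(segs)


def extract_cohort_features(
    cohort: Iterable[tuple[EMGRecording, tuple[int, int]]],
    filter_spec: FilterSpec = DEFAULT_FILTER_SPEC,
) -> pd.DataFrame:
    """Long feature table for a cohort of (recording, active span)
    pairs.  Accepts any iterable, in particular the streaming generator
    :func:`spastemg.simulate.iter_cohort`, so a full cohort never needs
    to be resident in memory."""
    frames = [extract_recording_features(rec, span, filter_spec=filter_spec)
              for rec, span in cohort]
    if not frames:
        raise DataError("empty cohort")
    return pd.concat(frames, ignore_index=True)


def select_balanced_samples(
    long_df: pd.DataFrame, per_grade: int = 40, seed: int = 0
) -> pd.DataFrame:
    """Retain exactly ``per_grade`` sample datasets per MAS grade,
    chosen uniformly at random without replacement (seeded).

    The sampling unit is the (subject, trial, segment) triple; all three
    channels of a chosen sample are kept.
    """
    rng = np.random.default_rng(seed)
    samples = long_df.drop_duplicates(SAMPLE_KEY)[SAMPLE_KEY + ["mas_label"]]
    keep = []
    for label, group in samples.groupby("mas_label", sort=True):
        if len(group) < per_grade:
            raise DataError(
                f"grade {label!r} has only {len(group)} sample datasets; "
                f"{per_grade} required"
            )
        picked = rng.choice(len(group), size=per_grade, replace=False)
        keep.append(group.iloc[np.sort(picked)])
    keep_df = pd.concat(keep, ignore_index=True)[SAMPLE_KEY]
    return long_df.merge(keep_df, on=SAMPLE_KEY, how="inner")


@dataclasses.dataclass
class AnalysisResult:
    """Everything the pipeline computes for one cohort."""

    features: pd.DataFrame          # long table, retained samples only
    correlations: pd.DataFrame      # channels x features Spearman table
    weights: pd.DataFrame           # channels x retained features
    retained: list[str]
    fused: pd.DataFrame             # per-sample fused feature vectors
    k: int
    k_accuracies: dict[int, float] | None
    confusion: np.ndarray
    report: EvalReport
    mean_cv_accuracy: float
    comparison: dict[str, float]
    fold_digest: str
    mode: str
    seed: int


def run_analysis(
    long_df: pd.DataFrame,
    seed: int = 0,
    per_grade: int = 40,
    threshold: float = 0.7,
    k: int | None = None,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    folds: int = 10,
    mode: str = "paper_global",
) -> AnalysisResult:
    """Run the statistical pipeline on a long feature table.

    Normalization, Spearman screening (|r| >= ``threshold`` on every
    channel), correlation weighting and fusion are followed by k-NN
    cross-validation.  When ``k`` is None it is selected from ``k_grid``
    by mean CV accuracy.  The fused classifier uses the three amplitude
    features (RMS, iEMG, EA); the screening result is reported so a
    cohort whose frequency features also clear the threshold is visible
    to the caller.
    """
    retained_df = select_balanced_samples(long_df, per_grade=per_grade, seed=seed)
    wide, labels = pivot_wide(retained_df)
    wide_norm, _ = normalize_wide(wide)
    corr = compute_correlations(wide_norm, labels)
    retained = screen(corr, threshold=threshold)
    weights = weight_table(corr, TIME_DOMAIN_FEATURES)
    fused = build_fused_dataset(wide_norm, labels, weights)

    X = fused[[f"fused_{f}" for f in TIME_DOMAIN_FEATURES]].to_numpy()
    y = np.array([encode_mas(lab) for lab in labels])
    ds = LabeledDataset(X, y, ids=list(wide.index))

    k_accs = None
    if k is None:
        k, k_accs = select_k(ds, grid=k_grid, folds=folds, seed=seed)
    cm, mean_acc, _ = cross_validate(ds, k, folds=folds, seed=seed)
    report = metrics(cm)
    comparison, digest = compare_models(
        wide, list(labels), seed=seed, k=k, folds=folds, mode=mode
    )
    return AnalysisResult(
        features=retained_df,
        correlations=corr,
        weights=weights,
        retained=retained,
        fused=fused,
        k=k,
        k_accuracies=k_accs,
        confusion=cm,
        report=report,
        mean_cv_accuracy=mean_acc,
        comparison=comparison,
        fold_digest=digest,
        mode=mode,
        seed=seed,
    )


def run_synthetic_analysis(
    config: SynthConfig | None = None,
    seed: int = 0,
    per_grade: int = 40,
    **kwargs,
) -> AnalysisResult:
    """Generate a synthetic cohort (streaming) and run the full
    analysis.  ``seed`` drives both the generator and every downstream
    random choice."""
    if config is None:
        config = SynthConfig(seed=seed)
    long_df = extract_cohort_features(iter_cohort(config))
    return run_analysis(long_df, seed=seed, per_grade=per_grade, **kwargs)
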