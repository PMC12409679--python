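"""k-NN grade classification, cross-validation and evaluation metrics.

The classifier is a plain Euclidean k-nearest-neighbour majority vote
over low-dimensional feature vectors (3 fused features, or 3 per-channel
features for the baseline models).  It is written in-package because the
evaluation contract pins down deterministic tie-breaking:

* vote ties — among tied classes, the class of the nearest neighbour
  belonging to a tied class wins; exact distance ties fall back to the
  lowest MAS ordinal;
* distance ties at the K boundary — resolved by stable sort order
  (training-sample insertion order).

Model selection follows the standard protocol for a balanced 200-sample
design: stratified 10-fold cross-validation (4 samples per grade per
fold), K swept over the odd values 1..13, fold confusion matrices summed
so every sample is predicted exactly once, and per-class precision /
recall / F1 derived from the aggregated matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections import Counter
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError, FormatError
from .features import TIME_DOMAIN_FEATURES
from .fusion import fuse_time_domain
from .recording import CHANNELS, GRADE_LABELS

N_GRADES = len(GRADE_LABELS)

DEFAULT_K_GRID: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13)


@dataclasses.dataclass
class LabeledDataset:
    """Fixed-dimension feature vectors with MAS ordinals and sample ids."""

    X: np.ndarray
    y: np.ndarray
    ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise DataError("X must be (n_samples, n_features) matching y")
        if self.ids is None:
            self.ids = list(range(len(self.y)))

    @property
    def class_counts(self) -> dict[int, int]:
        return dict(Counter(self.y.tolist()))

    def __len__(self) -> int:
        return len(self.y)


def knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, query: np.ndarray, k: int
) -> int:
    """Majority vote among the k Euclidean-nearest training points.

    See the module docstring for the deterministic tie-break rules.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    query = np.asarray(query, dtype=float)
    n = X_train.shape[0]
    if k < 1 or k > n:
        raise ConfigurationError(f"k={k} outside [1, {n}] for this training set")
    if query.shape[-1] != X_train.shape[1]:
        raise DomainError(
            f"query dimension {query.shape[-1]} != training dimension "
            f"{X_train.shape[1]}"
        )
    dist = np.sqrt(np.sum((X_train - query) ** 2, axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    votes = Counter(y_train[order].tolist())
    top = max(votes.values())
    tied = [lab for lab, c in votes.items() if c == top]
    if len(tied) == 1:
        return int(tied[0])
    # nearest member of each tied class decides; exact ties -> lowest ordinal
    nearest = {lab: min(dist[i] for i in order if y_train[i] == lab) for lab in tied}
    best = min(nearest.values())
    winners = sorted(lab for lab, d in nearest.items() if d == best)
    return int(winners[0])


def knn_predict_batch(
    X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray, k: int
) -> np.ndarray:
    return np.array([knn_predict(X_train, y_train, q, k) for q in np.atleast_2d(X_query)])


def stratified_split(
    data: LabeledDataset,
    train_per_class: int = 36,
    test_per_class: int = 4,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint train/test split with exact per-class counts (default
    36 + 4 per grade, the 9:1 design for a balanced 200-sample set)."""
    rng = np.random.default_rng(seed)
    need = train_per_class + test_per_class
    train_idx: list[int] = []
    test_idx: list[int] = []
    for grade in sorted(set(data.y.tolist())):
        members = np.flatnonzero(data.y == grade)
        if members.size < need:
            raise DataError(
                f"grade ordinal {grade} has {members.size} samples; "
                f"{need} required for the split"
            )
        picked = rng.permutation(members)[:need]
        train_idx.extend(picked[:train_per_class].tolist())
        test_idx.extend(picked[train_per_class:].tolist())
    return (
        LabeledDataset(data.X[train_idx], data.y[train_idx], [data.ids[i] for i in train_idx]),
        LabeledDataset(data.X[test_idx], data.y[test_idx], [data.ids[i] for i in test_idx]),
    )


def stratified_kfold(y: Sequence[int], folds: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``folds`` folds, stratified by class.

    Within each class, samples are shuffled (seeded) and dealt
    round-robin, so a balanced 200-sample set yields 10 folds of 20 with
    exactly 4 of each grade.  Returns an integer fold index per sample.
    """
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ConfigurationError("need at least 2 folds to hold data out")
    if folds > y.size:
        raise ConfigurationError(f"folds={folds} exceeds {y.size} samples")
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    for grade in sorted(set(y.tolist())):
        members = rng.permutation(np.flatnonzero(y == grade))
        assignment[members] = np.arange(members.size) % folds
    return assignment


def fold_hash(assignment: np.ndarray) -> str:
    """Stable digest of a fold assignment, used to assert that competing
    models were evaluated under identical folds."""
    return hashlib.sha256(np.asarray(assignment, dtype=np.int64).tobytes()).hexdigest()


def cross_validate(
    data: LabeledDataset,
    k: int,
    folds: int = 10,
    seed: int = 0,
    assignment: np.ndarray | None = None,
    prepare: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Stratified k-fold cross-validation of the k-NN model.

    Each fold is predicted by a model trained on the other folds; fold
    confusion matrices are summed so every sample is predicted exactly
    once.  ``prepare(train_idx, test_idx) -> (X_train, X_test)`` lets the
    caller recompute fold-dependent transforms (fold-safe normalization /
    fusion) from the training rows only; by default the stored feature
    matrix is used as-is.

    Returns ``(confusion_matrix, mean_fold_accuracy, fold_assignment)``
    with the confusion matrix indexed [true grade, predicted grade] over
    the five MAS ordinals.
    """
    if assignment is None:
        assignment = stratified_kfold(data.y, folds=folds, seed=seed)
    cm = np.zeros((N_GRADES, N_GRADES), dtype=int)
    fold_accs = []
    for fold in sorted(set(assignment.tolist())):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if prepare is not None:
            X_train, X_test = prepare(train_idx, test_idx)
        else:
            X_train, X_test = data.X[train_idx], data.X[test_idx]
        y_train, y_test = data.y[train_idx], data.y[test_idx]
        preds = knn_predict_batch(X_train, y_train, X_test, k)
        for t, p in zip(y_test, preds):
            cm[t, p] += 1
        fold_accs.append(float(np.mean(preds == y_test)))
    return cm, float(np.mean(fold_accs)), assignment


def select_k(
    data: LabeledDataset,
    grid: Sequence[int] = DEFAULT_K_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick K maximizing mean CV accuracy over a grid (odd 1..13 by
    default); ties go to the smallest K.  Returns (best_k, accuracies)."""
    if not grid:
        raise ConfigurationError("K grid is empty")
    assignment = stratified_kfold(data.y, folds=folds, seed=seed)
    accs: dict[int, float] = {}
    for k in grid:
        _, acc, _ = cross_validate(data, k, assignment=assignment)
        accs[int(k)] = acc
    best = max(sorted(accs), key=lambda k: accs[k])
    return int(best), accs


@dataclasses.dataclass
class EvalReport:
    """Aggregated confusion matrix with per-class TP/FN/FP, precision,
    recall, F1 and overall accuracy."""

    confusion: np.ndarray
    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    undefined_precision: np.ndarray  # True where TP+FP == 0

    def to_frame(self) -> pd.DataFrame:
        """Report table: rows TP/FN/FP/Precision/Recall/F1-Score, one
        column per MAS grade."""
        cols = [f"MAS {lab}" for lab in GRADE_LABELS[: self.confusion.shape[0]]]
        return pd.DataFrame(
            [self.tp, self.fn, self.fp, self.precision, self.recall, self.f1],
            index=["TP", "FN", "FP", "Precision", "Recall", "F1-Score"],
            columns=cols,
        )

    def to_dict(self) -> dict:
        frame = self.to_frame()
        return {
            "accuracy": self.accuracy,
            "per_class": {c: frame[c].to_dict() for c in frame.columns},
            "undefined_precision": self.undefined_precision.tolist(),
        }


def metrics(cm: np.ndarray) -> EvalReport:
    """Per-class metrics from a confusion matrix indexed
    [true, predicted].

    precision = TP/(TP+FP) and recall = TP/(TP+FN).  A class that was
    never predicted (TP+FP = 0) has undefined precision; it is reported
    as 0.0 with its ``undefined_precision`` flag set rather than silently
    inflated.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise DomainError(f"confusion matrix must be square and non-empty, got {cm.shape}")
    if (cm < 0).any():
        raise FormatError("confusion matrix counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise DomainError("confusion matrix is all zeros")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    undefined = (tp + fp) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(undefined, 0.0, tp / np.where(undefined, 1.0, tp + fp))
        rec_den = tp + fn
        recall = np.where(rec_den == 0, 0.0, tp / np.where(rec_den == 0, 1.0, rec_den))
        pr = precision + recall
        f1 = np.where(pr == 0, 0.0, 2 * precision * recall / np.where(pr == 0, 1.0, pr))
    return EvalReport(
        confusion=cm.astype(int),
        tp=tp,
        fn=fn,
        fp=fp,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(tp.sum() / total),
        undefined_precision=undefined,
    )



def compare_models(
    wide: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    k: int = 5,
    folds: int = 10,
    mode: str = "paper_global",
) -> tuple[dict[str, float], str]:
    """Mean 10-fold CV accuracy of seven models under identical folds.

    Models: three single-channel baselines (that channel's RMS, iEMG and
    EA), three single-feature baselines (one amplitude feature across
    LB/SB/BR) and the correlation-weighted fused model (fused RMS, iEMG,
    EA).  ``wide`` holds the raw (unnormalized) feature table with
    MultiIndex columns (channel, feature).

    ``mode="global"`` (alias ``"paper_global"``) normalizes and derives
    fusion weights from the full sample population once; ``"fold_safe"``
    recomputes normalization and weights from each training fold only,
    avoiding label leakage into the held-out fold.

    Returns ``(accuracies, fold_digest)`` where the digest certifies that
    all models shared one fold assignment.
    """
    from .features import normalize_wide  # local import to avoid cycle at import time

    if mode not in ("paper_global", "global", "fold_safe"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    labels = list(labels)
    ordinals = np.array([GRADE_LABELS.index(lab) for lab in labels], dtype=int)
    assignment = stratified_kfold(ordinals, folds=folds, seed=seed)
    digest = fold_hash(assignment)
    accs: dict[str, float] = {}

    def run(X: np.ndarray, prepare=None) -> float:
        ds = LabeledDataset(X, ordinals)
        _, acc, _ = cross_validate(ds, k, assignment=assignment, prepare=prepare)
        return acc

    if mode in ("paper_global", "global"):
        wide_norm, _ = normalize_wide(wide)
        for ch in CHANNELS:
            X = np.column_stack(
                [wide_norm[(ch, f)].to_numpy() for f in TIME_DOMAIN_FEATURES]
            )
            accs[f"single_channel_{ch}"] = run(X)
        for f in TIME_DOMAIN_FEATURES:
            X = np.column_stack([wide_norm[(ch, f)].to_numpy() for ch in CHANNELS])
            accs[f"single_feature_{f}"] = run(X)
        _, _, fused = fuse_time_domain(wide_norm, labels, fallback_equal=True)
        X = fused[[f"fused_{f}" for f in TIME_DOMAIN_FEATURES]].to_numpy()
        accs["fused"] = run(X)
    else:
        # fold-safe: every transform re-fit on the training fold only
        def make_prepare(builder):
            def prepare(train_idx, test_idx):
                from .features import NormalizationParams, normalize

                params = {}
                for col in wide.columns:
                    _, params[col] = normalize(wide[col].to_numpy()[train_idx])
                norm = wide.copy()
                for col in wide.columns:
                    norm[col] = params[col].apply(wide[col].to_numpy())
                X = builder(norm, train_idx)
                return X[train_idx], X[test_idx]

            return prepare

        dummy = np.zeros((len(labels), 1))
        for ch in CHANNELS:
            builder = lambda norm, _ti, ch=ch: np.column_stack(
                [norm[(ch, f)].to_numpy() for f in TIME_DOMAIN_FEATURES]
            )
            accs[f"single_channel_{ch}"] = run(dummy, make_prepare(builder))
        for f in TIME_DOMAIN_FEATURES:
            builder = lambda norm, _ti, f=f: np.column_stack(
                [norm[(ch, f)].to_numpy() for ch in CHANNELS]
            )
            accs[f"single_feature_{f}"] = run(dummy, make_prepare(builder))

        def fused_builder(norm, train_idx):
            from .fusion import compute_correlations, weight_table

            train_labels = [labels[i] for i in train_idx]
            corr = compute_correlations(norm.iloc[train_idx], train_labels)
            weights = weight_table(corr, TIME_DOMAIN_FEATURES, fallback_equal=True)
            cols = []
            for f in TIME_DOMAIN_FEATURES:
                w = weights[f].to_numpy()
                cols.append(
                    sum(w[i] * norm[(ch, f)].to_numpy() for i, ch in enumerate(CHANNELS))
                )
            return np.column_stack(cols)

        accs["fused"] = run(dummy, make_prepare(fused_builder))

    return accs, digest
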