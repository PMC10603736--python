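"""Raw-stream ingestion, windowing and split assignment.

Annotated recordings are segmented into fixed-length windows (2 s at 100 Hz
by default) with 50% overlap.  Annotation epochs are half-open
``[start, end)`` sample-index intervals, 0-based; epochs shorter than the
minimum duration are dropped, no window may straddle an epoch boundary, and
only full windows are emitted (epochs between the minimum duration and one
window length therefore yield nothing — no padding scheme is applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datasets import CHANNEL_NAMES, TEST, TRAIN, VAL, DomainDataset, IMUWindow

__all__ = ["AnnotatedStream", "segment_stream", "read_csv_stream",
           "make_folds", "standardize", "Standardizer", "export_folds_csv"]

logger = logging.getLogger(__name__)


@dataclass
class AnnotatedStream:
    """A time-ordered 6-channel recording with single-label epochs."""

    samples: np.ndarray                       # (n_samples, 6)
    fs_hz: float
    annotations: list[tuple[int, int, str]]   # (start, end) half-open, label
    subject_id: str = ""
    domain_tag: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ValueError("samples must be (n, 6) in channel order "
                             + ",".join(CHANNEL_NAMES))
        n = self.samples.shape[0]
        for start, end, label in self.annotations:
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"epoch ({start}, {end}, {label!r}) out of range [0, {n})")
        spans = sorted((s, e) for s, e, _ in self.annotations)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping epochs at samples {s2} < {e1}")


def segment_stream(stream: AnnotatedStream, window_s: float = 2.0,
                   overlap_frac: float = 0.5,
                   min_epoch_s: float = 1.0) -> list[IMUWindow]:
    """Cut every retained epoch into overlapping full windows.

    Windows start every ``round(fs * window_s * (1 - overlap_frac))`` samples
    from the epoch start (stride 100 at the defaults) and only windows lying
    entirely inside the epoch are emitted, so for an epoch of L samples the
    count is 0 if L < T else floor((L - T) / stride) + 1.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    T = int(round(stream.fs_hz * window_s))
    stride = int(round(stream.fs_hz * window_s * (1.0 - overlap_frac)))
    if T < 1 or stride < 1:
        raise ValueError(f"window arithmetic degenerate for fs={stream.fs_hz}, "
                         f"window={window_s}, overlap={overlap_frac}")
    min_len = int(round(stream.fs_hz * min_epoch_s))
    windows: list[IMUWindow] = []
    for start, end, label in stream.annotations:
        length = end - start
        if length < min_len or length < T:
            continue
        for w_start in range(start, end - T + 1, stride):
            windows.append(IMUWindow(
                x=stream.samples[w_start:w_start + T].T.copy(),
                label=label, domain=stream.domain_tag,
                subject=stream.subject_id))
    return windows


_DEFAULT_COLUMNS = {name: name for name in
                    ("timestamp",) + CHANNEL_NAMES + ("label",)}


def read_csv_stream(path, fs_hz: float = 100.0,
                    column_map: dict[str, str] | None = None,
                    subject_id: str = "", domain_tag: str = "",
                    unlabeled: tuple = ("", "unlabeled")) -> AnnotatedStream:
    """Read a long-format CSV (timestamp, ax..gz, label per row).

    Contiguous runs of one label become annotation epochs; rows whose label
    is empty/"unlabeled" break epochs and contribute no annotation.  Missing
    columns, non-monotone timestamps and NaN sensor values are rejected with
    the offending rows named.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype={cols["label"]: str},
                     keep_default_na=False, na_values=["nan", "NaN"])
    missing = [cols[k] for k in _DEFAULT_COLUMNS if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ts = pd.to_numeric(df[cols["timestamp"]], errors="coerce").to_numpy()
    bad_ts = np.flatnonzero(~np.isfinite(ts))
    if bad_ts.size:
        raise ValueError(f"{path}: non-numeric timestamps at rows {bad_ts[:10].tolist()}")
    if np.any(np.diff(ts) <= 0):
        rows = np.flatnonzero(np.diff(ts) <= 0) + 1
        raise ValueError(f"{path}: non-monotone timestamps at rows {rows[:10].tolist()}")
    sensor_cols = [cols[c] for c in CHANNEL_NAMES]
    samples = df[sensor_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    nan_rows = np.flatnonzero(~np.isfinite(samples).all(axis=1))
    if nan_rows.size:
        bad_cols = [sensor_cols[j] for j in
                    np.flatnonzero(~np.isfinite(samples[nan_rows[0]]))]
        raise ValueError(f"{path}: non-finite sensor values at rows "
                         f"{nan_rows[:10].tolist()} (first bad columns {bad_cols})")
    labels = df[cols["label"]].to_numpy()
    annotations = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            if labels[start] not in unlabeled:
                annotations.append((start, i, str(labels[start])))
            start = i
    return AnnotatedStream(samples=samples, fs_hz=fs_hz,
                           annotations=annotations, subject_id=subject_id,
                           domain_tag=domain_tag)


def make_folds(dataset: DomainDataset, n_folds: int = 5, seed: int = 0,
               val_frac: float = 0.25,
               group_by_subject: bool = False) -> DomainDataset:
    """Assign every window to {train, val, test} in each of ``n_folds`` folds.

    The folds' test sets are a class-stratified partition of the dataset
    (each window tests exactly once: an 80/20 rotation at 5 folds); within a
    fold the remaining windows are split 3:1 into train and validation,
    again stratified by class.  ``group_by_subject`` keeps all windows of a
    subject in one fold instead (off by default: the reference protocol
    splits windows, not subjects).
    """
    y = dataset.y
    counts = np.bincount(y, minlength=dataset.n_classes)
    too_few = [dataset.class_names[i] for i in range(dataset.n_classes)
               if 0 < counts[i] < n_folds]
    if too_few:
        raise ValueError(f"classes with fewer than {n_folds} windows: {too_few}")
    n = len(dataset)
    split_matrix = np.full((n_folds, n), TRAIN, dtype=np.uint8)
    if group_by_subject:
        if dataset.subjects is None:
            raise ValueError("group_by_subject requires subject ids")
        subjects = np.unique(dataset.subjects)
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(len(subjects)) % n_folds
        fold_of = {s: f for s, f in zip(subjects, assignment)}
        test_fold = np.array([fold_of[s] for s in dataset.subjects])
        fold_iter = [(None, np.flatnonzero(test_fold == f)) for f in range(n_folds)]
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_iter = list(skf.split(np.zeros(n), y))
    for fold, (_, test_idx) in enumerate(fold_iter):
        split_matrix[fold, test_idx] = TEST
        rest = np.setdiff1d(np.arange(n), test_idx)
        _, val_idx = train_test_split(rest, test_size=val_frac,
                                      random_state=seed + fold,
                                      stratify=y[rest])
        split_matrix[fold, val_idx] = VAL
    dataset.split_matrix = split_matrix
    return dataset


def export_folds_csv(dataset: DomainDataset, path) -> None:
    """Write the fold/split assignment as (window_id, fold, split) rows."""
    names = {TRAIN: "train", VAL: "val", TEST: "test"}
    rows = [(w, f, names[dataset.split_matrix[f, w]])
            for f in range(dataset.n_folds) for w in range(len(dataset))]
    pd.DataFrame(rows, columns=["window_id", "fold", "split"]).to_csv(
        path, index=False)


@dataclass
class Standardizer:
    """Per-channel z-scoring with parameters fitted on source-train only."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(6))
    sd: np.ndarray = field(default_factory=lambda: np.ones(6))

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=(0, 2))
        sd = X.std(axis=(0, 2))
        zero = sd == 0
        if np.any(zero):
            logger.warning("zero-variance channels %s; sd clamped to 1",
                           np.flatnonzero(zero).tolist())
            sd = np.where(zero, 1.0, sd)
        self.sd = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = (X - self.mean[None, :, None]) / self.sd[None, :, None]
        return out.astype(X.dtype, copy=False)


def standardize(train_X: np.ndarray, *apply_to: np.ndarray):
    """Fit per-channel scaling on training windows, apply it everywhere.

    Returns ``(scaler, transformed_train, *transformed_others)``; the same
    source-train parameters are applied to validation/test/target arrays so
    any inter-domain offset is preserved rather than silently removed.
    """
    scaler = Standardizer().fit(train_X)
    out = [scaler.transform(train_X)] + [scaler.transform(X) for X in apply_to]
    return (scaler, *out)
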