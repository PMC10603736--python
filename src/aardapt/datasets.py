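"""Core data containers: sensor windows and per-domain datasets.

The atomic sample is a fixed-length 6-channel IMU window (accelerometer triad
then gyroscope triad, channel order ax, ay, az, gx, gy, gz everywhere).  A
:class:`DomainDataset` holds all windows of one domain as a dense array plus
label/fold bookkeeping, which keeps training fast while still offering a
per-window view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IMUWindow", "DomainDataset", "TRAIN", "VAL", "TEST",
           "CHANNEL_NAMES", "save_pair_npz", "load_pair_npz"]

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")

# split codes used in DomainDataset.split_matrix
TRAIN, VAL, TEST = 0, 1, 2


@dataclass
class IMUWindow:
    """One fixed-length 6-channel sensor segment with its annotations."""

    x: np.ndarray               # (6, T)
    label: str
    domain: str = ""
    subject: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x)
        if self.x.ndim != 2 or self.x.shape[0] != 6:
            raise ValueError(f"window must be (6, T), got {self.x.shape}")


@dataclass
class DomainDataset:
    """All windows from one domain, with class inventory and split assignments.

    ``split_matrix`` (filled in by ``preprocessing.make_folds``) has one row
    per cross-validation fold and one column per window, holding the codes
    TRAIN / VAL / TEST.
    """

    X: np.ndarray                       # (n, 6, T)
    y: np.ndarray                       # (n,) integer class ids
    class_names: list[str]
    domain: str = ""
    subjects: np.ndarray | None = None  # (n,) strings
    split_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 3 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, channels, T) aligned with y")
        if self.X.shape[1] != 6:
            raise ValueError("expected 6 sensor channels")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("labels out of range of class_names")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def window_length(self) -> int:
        return self.X.shape[2]

    @property
    def windows(self) -> list[IMUWindow]:
        subj = self.subjects if self.subjects is not None else [""] * len(self)
        return [IMUWindow(self.X[i], self.class_names[self.y[i]], self.domain,
                          str(subj[i])) for i in range(len(self))]

    @classmethod
    def from_windows(cls, windows: list[IMUWindow], class_names: list[str],
                     domain: str = "") -> "DomainDataset":
        if not windows:
            raise ValueError("cannot build a dataset from zero windows")
        index = {c: i for i, c in enumerate(class_names)}
        X = np.stack([w.x for w in windows])
        y = np.array([index[w.label] for w in windows])
        subjects = np.array([w.subject for w in windows])
        return cls(X=X, y=y, class_names=list(class_names), domain=domain,
                   subjects=subjects)

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.y == i).sum()) for i, c in enumerate(self.class_names)}

    @property
    def n_folds(self) -> int:
        if self.split_matrix is None:
            raise ValueError("folds not assigned; run preprocessing.make_folds first")
        return self.split_matrix.shape[0]

    def split_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (train, val, test) window indices for one fold."""
        row = self.split_matrix[fold]
        return (np.flatnonzero(row == TRAIN), np.flatnonzero(row == VAL),
                np.flatnonzero(row == TEST))


def save_pair_npz(path, source: DomainDataset, target: DomainDataset) -> None:
    """Write a source/target pair as a single NPZ archive.

    Arrays: ``X`` (n, 6, T), ``y`` (n,), ``domain`` (n,; 0 = source,
    1 = target), ``classes`` (shared ordered label set).
    """
    if source.class_names != target.class_names:
        raise ValueError("source and target must share a class inventory")
    X = np.concatenate([source.X, target.X])
    y = np.concatenate([source.y, target.y])
    domain = np.concatenate([np.zeros(len(source), dtype=np.int64),
                             np.ones(len(target), dtype=np.int64)])
    np.savez(path, X=X, y=y, domain=domain,
             classes=np.array(source.class_names),
             domain_tags=np.array([source.domain or "source",
                                   target.domain or "target"]))


def load_pair_npz(path) -> tuple[DomainDataset, DomainDataset]:
    """Read a source/target pair written by :func:`save_pair_npz`."""
    with np.load(path, allow_pickle=False) as f:
        X, y, domain = f["X"], f["y"], f["domain"]
        classes = [str(c) for c in f["classes"]]
        tags = [str(t) for t in f["domain_tags"]] if "domain_tags" in f else \
            ["source", "target"]
    out = []
    for code, tag in zip((0, 1), tags):
        mask = domain == code
        out.append(DomainDataset(X=X[mask], y=y[mask], class_names=classes,
                                 domain=tag))
    return tuple(out)
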