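"""Shared domain types, delimited-text I/O and run configuration.

Every estimator in this package consumes a :class:`BinaryDataset` — an
``N x M`` matrix of 0/1 attribute indicators with an optional categorical
class label per row.  Class labels are kept as opaque strings and mapped to
integer indices internally; for binary validity metrics the "positive" class
defaults to the lexicographically second label unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryDataset",
    "PriorConfig",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "split_train_test",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the 0/1 attribute contract."""


@dataclass(frozen=True)
class BinaryDataset:
    """Binary attribute matrix with an optional class-label vector.

    Parameters
    ----------
    X
        ``(N, M)`` array with entries in ``{0, 1}``.
    y
        Length-``N`` array of string class labels, or ``None`` for
        unlabeled prediction input.
    feature_names
        ``M`` column names.
    class_labels
        Ordered label set; inferred (sorted) from ``y`` when omitted.
    """

    X: np.ndarray
    y: np.ndarray | None = None
    feature_names: tuple[str, ...] = ()
    class_labels: tuple[str, ...] = ()

    def __post_init__(self):
        X = np.asarray(self.X)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise DataValidationError(f"X must be a non-empty 2-D matrix, got shape {X.shape}")
        if not np.isin(X, (0, 1)).all():
            bad = np.argwhere(~np.isin(X, (0, 1)))[0]
            raise DataValidationError(
                f"non-binary attribute value at row {bad[0]}, column "
                f"{self.feature_names[bad[1]] if self.feature_names else bad[1]}: {X[tuple(bad)]!r}"
            )
        object.__setattr__(self, "X", X.astype(np.int8))
        names = tuple(self.feature_names) or tuple(f"f{j + 1}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise DataValidationError("feature_names length does not match number of columns")
        object.__setattr__(self, "feature_names", names)
        if self.y is not None:
            y = np.asarray(self.y, dtype=object).astype(str)
            if y.shape != (X.shape[0],):
                raise DataValidationError("y must have one label per row")
            labels = tuple(self.class_labels) or tuple(sorted(set(y)))
            if not set(y) <= set(labels):
                raise DataValidationError("y contains labels outside class_labels")
            object.__setattr__(self, "y", y)
            object.__setattr__(self, "class_labels", labels)
        else:
            object.__setattr__(self, "class_labels", tuple(self.class_labels))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def y_indices(self) -> np.ndarray:
        """Class labels as integer indices into ``class_labels``."""
        if self.y is None:
            raise ValueError("dataset has no class labels")
        lut = {c: i for i, c in enumerate(self.class_labels)}
        return np.array([lut[c] for c in self.y], dtype=np.int64)

    def subset(self, rows: np.ndarray) -> "BinaryDataset":
        return BinaryDataset(
            X=self.X[rows],
            y=None if self.y is None else self.y[rows],
            feature_names=self.feature_names,
            class_labels=self.class_labels,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryDataset):
            return NotImplemented
        same_y = (self.y is None and other.y is None) or (
            self.y is not None and other.y is not None and (self.y == other.y).all()
        )
        return (
            self.X.shape == other.X.shape
            and (self.X == other.X).all()
            and same_y
            and self.feature_names == other.feature_names
            and self.class_labels == other.class_labels
        )


@dataclass(frozen=True)
class PriorConfig:
    """Conjugate hyperparameters for a G-component Bernoulli mixture.

    ``alpha``/``beta`` are the ``(G, M)`` Beta shapes for the item
    probabilities; ``delta`` is the length-``G`` Dirichlet concentration for
    the mixing weights.  All entries must be strictly positive.
    """

    alpha: np.ndarray
    beta: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        a = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        b = np.atleast_2d(np.asarray(self.beta, dtype=float))
        d = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if a.shape != b.shape:
            raise ValueError("alpha and beta must have identical shapes")
        if d.shape[0] != a.shape[0]:
            raise ValueError("delta length must equal number of components")
        if (a <= 0).any() or (b <= 0).any() or (d <= 0).any():
            raise ValueError("all prior hyperparameters must be strictly positive")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "delta", d)

    @classmethod
    def uniform(cls, G: int, M: int, a: float = 1.0, b: float = 1.0, d: float = 1.0) -> "PriorConfig":
        """Flat conjugate priors; with a=b=d=1 the MAP updates reduce to MLE."""
        return cls(np.full((G, M), a), np.full((G, M), b), np.full(G, d))


@dataclass(frozen=True)
class RunConfig:
    """Optimisation / sampling schedule shared by EM and Gibbs fitters."""

    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-8
    n_restarts: int = 10
    gibbs_iters: int = 5000
    burn_in: int = 1000
    thin: int = 5

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not self.burn_in < self.gibbs_iters:
            raise ValueError("burn_in must be smaller than gibbs_iters")

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def read_dataset(path: str | Path, class_column: str | None = "class", sep: str = ",") -> BinaryDataset:
    """Read a delimited text table with header into a :class:`BinaryDataset`.

    ``class_column`` names the label column; pass ``None`` (or a name absent
    from the header) for unlabeled input.  All remaining columns must contain
    only 0/1 values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise DataValidationError(f"{path}: empty table")
    y = None
    if class_column is not None and class_column in df.columns:
        y = df.pop(class_column).to_numpy()
    if df.shape[1] == 0:
        raise DataValidationError(f"{path}: no attribute columns")
    for col in df.columns:
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise DataValidationError(
                f"{path}: non-binary value {df[col].iloc[row]!r} at row {row}, column {col!r}"
            )
    X = df.to_numpy(dtype=np.int8)
    return BinaryDataset(X=X, y=y, feature_names=tuple(df.columns))


def write_dataset(dataset: BinaryDataset, path: str | Path, class_column: str = "class", sep: str = ",") -> None:
    """Write a dataset as delimited text; inverse of :func:`read_dataset`."""
    df = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    if dataset.y is not None:
        df[class_column] = dataset.y
    df.to_csv(path, sep=sep, index=False)


def split_train_test(
    dataset: BinaryDataset,
    train_fraction: float,
    rng: np.random.Generator,
    stratify: bool = False,
) -> tuple[BinaryDataset, BinaryDataset]:
    """Random disjoint row partition; train gets ``round(N * fraction)`` rows.

    Plain uniform sampling by default; ``stratify=True`` samples the same
    fraction within each class instead.
    """
    if dataset.n < 2:
        raise ValueError("need at least two rows to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if stratify and dataset.y is not None:
        train_idx = []
        for c in dataset.class_labels:
            rows = np.flatnonzero(dataset.y == c)
            k = int(round(len(rows) * train_fraction))
            train_idx.append(rng.permutation(rows)[:k])
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(dataset.n)
        k = int(round(dataset.n * train_fraction))
        train_idx = np.sort(perm[:k])
    mask = np.zeros(dataset.n, dtype=bool)
    mask[train_idx] = True
    return dataset.subset(np.flatnonzero(mask)), dataset.subset(np.flatnonzero(~mask))
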