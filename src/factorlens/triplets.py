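"""Coordinate-encoded matrix samples for symbolic regression.

A factor matrix is flattened into (i, j, value) triplets so that a regression
network can learn the mapping from position to value.  Raw indices are mapped
affinely to normalized coordinates X1, X2 in [-1, 1] per axis, which keeps the
arguments of sin/cos/exp units in a numerically sane range.  An optional
``dy`` column carries the first finite difference of the value along the row
index (central differences inside, one-sided at the edges, index-unit
spacing), exposed as an extra input feature when requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def _normalize(idx: np.ndarray, extent: int) -> np.ndarray:
    """Map 0-based indices on an axis of the given extent to [-1, 1].

    An axis of extent 1 cannot span a range; its single index maps to 0.0.
    """
    if extent == 1:
        return np.zeros(len(idx), dtype=float)
    return -1.0 + 2.0 * idx / (extent - 1)


@dataclass
class TripletDataset:
    """(i, j, value) records with normalized coordinates.

    Invariants: each (i, j) pair appears at most once; 0 <= i < n_rows and
    0 <= j < n_cols; normalized coordinates lie in [-1, 1].
    """

    i: np.ndarray
    j: np.ndarray
    y: np.ndarray
    n_rows: int
    n_cols: int
    dy: Optional[np.ndarray] = None

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.dy is not None:
            self.dy = np.asarray(self.dy, dtype=float)
            if self.dy.shape != self.y.shape:
                raise ValueError("dy must match y in shape")
        if not (len(self.i) == len(self.j) == len(self.y)):
            raise ValueError("i, j, y must have equal length")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("matrix extents must be positive")
        if len(self.i) and (self.i.min() < 0 or self.i.max() >= self.n_rows):
            raise ValueError("row index out of range")
        if len(self.j) and (self.j.min() < 0 or self.j.max() >= self.n_cols):
            raise ValueError("column index out of range")
        flat = self.i * self.n_cols + self.j
        if len(np.unique(flat)) != len(flat):
            raise ValueError("duplicate (i, j) pairs in triplet records")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def x1(self) -> np.ndarray:
        """Normalized row coordinate in [-1, 1]."""
        return _normalize(self.i, self.n_rows)

    @property
    def x2(self) -> np.ndarray:
        """Normalized column coordinate in [-1, 1]."""
        return _normalize(self.j, self.n_cols)

    @property
    def has_derivative(self) -> bool:
        return self.dy is not None

    def features(self, with_derivative: Optional[bool] = None) -> np.ndarray:
        """(N, 2) array [X1, X2], or (N, 3) with the dy feature appended."""
        if with_derivative is None:
            with_derivative = self.has_derivative
        cols = [self.x1, self.x2]
        if with_derivative:
            if self.dy is None:
                raise ValueError("dataset carries no derivative feature")
            cols.append(self.dy)
        return np.column_stack(cols)

    def subset(self, idx) -> "TripletDataset":
        return TripletDataset(
            i=self.i[idx], j=self.j[idx], y=self.y[idx],
            n_rows=self.n_rows, n_cols=self.n_cols,
            dy=None if self.dy is None else self.dy[idx],
        )

    def split(self, train_frac: float = 0.8, seed: int = 0):
        """Seeded uniform shuffle into (train, test) subsets."""
        if not 0.0 < train_frac < 1.0:
            raise ValueError("train_frac must lie strictly between 0 and 1")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(self))
        n_train = int(round(train_frac * len(self)))
        n_train = min(max(n_train, 1), len(self) - 1)
        return self.subset(perm[:n_train]), self.subset(perm[n_train:])

    # -- on-disk form -------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_rows={self.n_rows}\n# n_cols={self.n_cols}\n# origin=0\n")
            cols = {"i": self.i, "j": self.j, "value": self.y}
            if self.dy is not None:
                cols["dvalue"] = self.dy
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TripletDataset":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t")
        if "n_rows" not in meta or "n_cols" not in meta:
            raise ValueError(f"{path}: missing n_rows/n_cols metadata lines")
        origin = int(meta.get("origin", 0))
        return cls(
            i=table["i"].to_numpy() - origin,
            j=table["j"].to_numpy() - origin,
            y=table["value"].to_numpy(),
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
            dy=table["dvalue"].to_numpy() if "dvalue" in table else None,
        )


def matrix_to_triplets(matrix, with_derivative: bool = False) -> TripletDataset:
    """Flatten a 2D matrix into one triplet record per element.

    ``with_derivative`` adds the finite difference of the values along the row
    index (np.gradient convention: central inside, one-sided at the edges,
    unit index spacing).  Non-finite entries are rejected with a report of the
    offending positions.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    n_rows, n_cols = matrix.shape
    if n_rows * n_cols < 2:
        raise ValueError("matrix must contain at least 2 elements "
                         "(a single index cannot be normalized to a range)")
    bad = np.argwhere(~np.isfinite(matrix))
    if len(bad):
        positions = ", ".join(f"({r}, {c})" for r, c in bad[:10])
        more = "" if len(bad) <= 10 else f" and {len(bad) - 10} more"
        raise ValueError(f"non-finite matrix entries at {positions}{more}")
    ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    dy = None
    if with_derivative:
        if n_rows > 1:
            dmat = np.gradient(matrix, axis=0)
        else:
            dmat = np.zeros_like(matrix)
        dy = dmat.ravel()
    return TripletDataset(i=ii.ravel(), j=jj.ravel(), y=matrix.ravel(),
                          n_rows=n_rows, n_cols=n_cols, dy=dy)
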