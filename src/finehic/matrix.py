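"""Symmetric per-chromosome contact matrices.

Two containers are used throughout:

* :class:`ReadCountMatrix` — the raw read-pair count matrix ``RC`` for one
  chromosome, a symmetric matrix of non-negative integers indexed by
  restriction-fragment ordinals.
* :class:`IFMatrix` — a real-valued interaction-frequency estimate (from any
  estimator), carrying a ``normalized`` flag (fragment biases divided out or
  not) and a per-fragment ``mask`` of fragments excluded from estimation.

Matrices are stored dense; the on-disk representation (see :mod:`finehic.io`)
is sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReadCountMatrix", "IFMatrix"]


@dataclass
class ReadCountMatrix:
    """Symmetric non-negative integer RF x RF read-pair count matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("read-count matrix must be square")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(v == np.floor(v)):
                raise ValueError("read counts must be integral")
            v = v.astype(np.int64)
        else:
            v = v.astype(np.int64, copy=False)
        if np.any(v < 0):
            raise ValueError("read counts must be non-negative")
        if not np.array_equal(v, v.T):
            raise ValueError("read-count matrix must be symmetric")
        self.values = v

    @classmethod
    def from_pairs(cls, n: int, i, j, counts) -> "ReadCountMatrix":
        """Build from sparse (i, j, count) triples; duplicates are summed and
        the matrix is symmetrized (each triple sets both orientations)."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        v = np.zeros((n, n), dtype=np.int64)
        np.add.at(v, (i, j), counts)
        off = i != j
        np.add.at(v, (j[off], i[off]), counts[off])
        return cls(v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, ij):
        return self.values[ij]

    def total(self) -> int:
        """Sum over the full symmetric matrix (off-diagonal pairs counted in
        both orientations, diagonal once per orientation)."""
        return int(self.values.sum())

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def n_read_pairs(self) -> int:
        """Number of distinct read pairs (upper triangle incl. diagonal)."""
        return int(np.triu(self.values).sum())


@dataclass
class IFMatrix:
    """Dense symmetric interaction-frequency estimate.

    ``mask`` flags fragments excluded from estimation (e.g. zero coverage);
    entries touching a masked fragment are undefined and held at 0.
    """

    values: np.ndarray
    normalized: bool = True
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("IF matrix must be square")
        self.values = v
        if self.mask is None:
            self.mask = np.zeros(v.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (v.shape[0],):
                raise ValueError("mask must be a per-fragment boolean vector")
        unm = ~self.mask
        if np.any(v[np.ix_(unm, unm)] < 0):
            raise ValueError("IF values must be non-negative at unmasked entries")
        if not np.allclose(v, v.T, rtol=1e-9, atol=1e-12):
            raise ValueError("IF matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, ij):
        return self.values[ij]

    def cell_mask(self) -> np.ndarray:
        """n x n boolean array, True where either fragment is masked."""
        return self.mask[:, None] | self.mask[None, :]

    def copy(self) -> "IFMatrix":
        return IFMatrix(self.values.copy(), self.normalized, self.mask.copy())
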