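"""Fragment-specific bias estimation and matrix normalization.

Fragment size, GC content, and mappability modulate how often each
restriction fragment is observed, independent of true contact frequency.
A single multiplicative bias per fragment is estimated from the matrix
marginals:

    bias_i = (sum_j RC[i, j] / sum_{i', j'} RC[i', j']) * n

with both sums over the full symmetric matrix and ``n`` the number of
fragments with non-zero coverage, so that the mean bias over unmasked
fragments is exactly 1.  Normalization divides each entry by the product of
its two fragment biases: nRC[i, j] = RC[i, j] / (bias_i * bias_j).
Fragments with zero coverage get bias 0 and are masked (never dropped, so
fragment ordinals remain stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import IFMatrix, ReadCountMatrix

__all__ = ["BiasVector", "compute_fragment_bias", "normalize", "denormalize"]


@dataclass
class BiasVector:
    """Per-fragment multiplicative bias; mean 1 over unmasked fragments."""

    bias: np.ndarray
    mask: np.ndarray  # True = masked (zero coverage)

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.bias.shape != self.mask.shape or self.bias.ndim != 1:
            raise ValueError("bias and mask must be 1-D vectors of equal length")
        if np.any(self.bias < 0):
            raise ValueError("bias must be non-negative")

    @property
    def n_fragments(self) -> int:
        return int(self.bias.size)

    def outer(self) -> np.ndarray:
        """bias_i * bias_j matrix (0 at masked rows/columns)."""
        return np.outer(self.bias, self.bias)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#fragment\tbias\n")
            for i, b in enumerate(self.bias):
                fh.write(f"{i}\t{b:.6g}\n")

    @classmethod
    def unit(cls, n: int) -> "BiasVector":
        return cls(np.ones(n), np.zeros(n, dtype=bool))


def compute_fragment_bias(
    rc: ReadCountMatrix, min_row_sum: int = 1
) -> BiasVector:
    """Estimate per-fragment biases from matrix marginals.

    Fragments whose full-matrix row sum is below ``min_row_sum`` (default 1,
    i.e. zero coverage) get bias 0 and are masked.  Raises on an all-zero
    matrix.
    """
    rows = rc.row_sums().astype(np.float64)
    total = rows.sum()
    if total == 0:
        raise ValueError("no reads: cannot estimate fragment bias")
    mask = rows < max(min_row_sum, 1)
    n_unmasked = int((~mask).sum())
    bias = np.where(mask, 0.0, rows / rows[~mask].sum() * n_unmasked)
    return BiasVector(bias, mask)


def normalize(rc: ReadCountMatrix, b: BiasVector) -> IFMatrix:
    """Bias-normalized read counts nRC[i, j] = RC[i, j] / (bias_i * bias_j).

    Entries touching a masked fragment are masked (set to 0).
    """
    if b.n_fragments != rc.n:
        raise ValueError("bias vector length does not match matrix size")
    if np.any((b.bias == 0) & ~b.mask):
        raise RuntimeError("zero bias at an unmasked fragment (masking contract)")
    denom = b.outer()
    out = np.zeros((rc.n, rc.n), dtype=np.float64)
    ok = denom > 0
    out[ok] = rc.values[ok] / denom[ok]
    cell_masked = b.mask[:, None] | b.mask[None, :]
    out[cell_masked] = 0.0
    return IFMatrix(out, normalized=True, mask=b.mask.copy())


def denormalize(ifm: IFMatrix, b: BiasVector) -> IFMatrix:
    """Reapply fragment biases: value[i, j] * bias_i * bias_j.

    Exact inverse of :func:`normalize` at unmasked entries.  Raises if the
    input is already non-normalized.
    """
    if not ifm.normalized:
        raise ValueError("matrix is already non-normalized")
    if b.n_fragments != ifm.n:
        raise ValueError("bias vector length does not match matrix size")
    out = ifm.values * b.outer()
    mask = ifm.mask | b.mask
    out[mask[:, None] | mask[None, :]] = 0.0
    return IFMatrix(out, normalized=False, mask=mask)
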