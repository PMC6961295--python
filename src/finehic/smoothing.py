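"""Density-estimation smoothers for sparse contact matrices.

Four increasingly adaptive estimators of the latent interaction-frequency
matrix operate on the bias-normalized counts ``nRC``:

* fixed binning — block means over runs of ``bin_size`` consecutive RFs;
* fixed-bandwidth Gaussian KDE — every cell replaced by a truncated
  (+-3h) Gaussian-weighted mean of its neighborhood;
* adaptive KDE — the bandwidth at each cell is the smallest h whose
  (6h+1)^2 window holds at least ``minimum_count`` raw reads, so dense
  regions keep fine resolution while sparse ones borrow more strength.

Window read counts are evaluated in O(1) via a summed-area (cumulative)
matrix.  Note the deliberate asymmetry: smoothing averages the normalized
matrix nRC, while adaptive-bandwidth coverage counts use the raw RC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .matrix import IFMatrix, ReadCountMatrix

__all__ = [
    "estimate_fixed_binning",
    "estimate_kde",
    "build_cumulative",
    "CumulativeMatrix",
    "BandwidthField",
    "adaptive_bandwidth",
    "estimate_akde",
]

DEFAULT_MINIMUM_COUNT = 100
DEFAULT_H_MAX = 64


def _as_values(m) -> np.ndarray:
    if isinstance(m, (IFMatrix, ReadCountMatrix)):
        return np.asarray(m.values, dtype=np.float64)
    return np.asarray(m, dtype=np.float64)


def _mask_of(m, n: int) -> np.ndarray:
    if isinstance(m, IFMatrix) and m.mask is not None:
        return m.mask
    return np.zeros(n, dtype=bool)


def estimate_fixed_binning(nrc, bin_size: int) -> IFMatrix:
    """Fixed-binning estimate: bins are consecutive runs of ``bin_size``
    fragments (bin(i) = i // bin_size) and every cell of a bin pair gets the
    mean nRC over that block (a trailing partial bin divides by its actual
    cell count).  ``bin_size == 1`` is the identity.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    v = _as_values(nrc)
    n = v.shape[0]
    edges = np.arange(0, n, bin_size)
    sums = np.add.reduceat(np.add.reduceat(v, edges, axis=0), edges, axis=1)
    widths = np.minimum(edges + bin_size, n) - edges
    means = sums / np.outer(widths, widths)
    bins = np.arange(n) // bin_size
    out = means[np.ix_(bins, bins)]
    return IFMatrix(out, normalized=True, mask=_mask_of(nrc, n))


def _gauss_kernel(h: int) -> np.ndarray:
    r = np.arange(-3 * h, 3 * h + 1)
    return np.exp(-(r[:, None] ** 2 + r[None, :] ** 2) / (2.0 * h * h))


def _kde_values(v: np.ndarray, valid: np.ndarray, h: int) -> np.ndarray:
    """Truncated-Gaussian weighted mean; cells outside the matrix (or
    masked) are excluded from both numerator and denominator."""
    k = _gauss_kernel(h)
    num = fftconvolve(v * valid, k, mode="same")
    den = fftconvolve(valid.astype(np.float64), k, mode="same")
    out = np.zeros_like(num)
    ok = den > 1e-300
    out[ok] = num[ok] / den[ok]
    return np.clip(out, 0.0, None)


def estimate_kde(nrc, h: int) -> IFMatrix:
    """Fixed-bandwidth 2-D Gaussian KDE of nRC with window +-3h.

    A constant matrix is reproduced exactly everywhere, including edges and
    corners, because truncated windows renormalize.
    """
    if h < 1:
        raise ValueError("bandwidth must be >= 1")
    v = _as_values(nrc)
    n = v.shape[0]
    mask = _mask_of(nrc, n)
    valid = ~(mask[:, None] | mask[None, :])
    out = _kde_values(v, valid, int(h))
    out[~valid] = 0.0
    out = (out + out.T) / 2.0  # FFT round-off can break exact symmetry
    return IFMatrix(out, normalized=True, mask=mask)


@dataclass
class CumulativeMatrix:
    """Summed-area table of RC: cum[i, j] = sum_{a<=i, b<=j} RC[a, b]."""

    cum: np.ndarray

    @classmethod
    def from_rc(cls, rc) -> "CumulativeMatrix":
        v = _as_values(rc)
        return cls(np.cumsum(np.cumsum(v, axis=0), axis=1))

    @property
    def n(self) -> int:
        return self.cum.shape[0]

    def _padded(self) -> np.ndarray:
        p = np.zeros((self.n + 1, self.n + 1))
        p[1:, 1:] = self.cum
        return p

    def cov(self, i: int, j: int, h: int) -> float:
        """Window sum over rows/cols within +-3h of (i, j), clamped to the
        matrix edge; equals the brute-force window sum."""
        return float(self.cov_all(h)[i, j])

    def cov_all(self, h: int) -> np.ndarray:
        """Vectorized window sums for every cell at half-width 3h."""
        n = self.n
        p = self._padded()
        idx = np.arange(n)
        lo = np.clip(idx - 3 * h, 0, n)
        hi = np.clip(idx + 3 * h + 1, 0, n)
        return (
            p[np.ix_(hi, hi)]
            - p[np.ix_(lo, hi)]
            - p[np.ix_(hi, lo)]
            + p[np.ix_(lo, lo)]
        )

    def total(self) -> float:
        return float(self.cum[-1, -1])


def build_cumulative(rc) -> CumulativeMatrix:
    return CumulativeMatrix.from_rc(rc)


@dataclass
class BandwidthField:
    """Per-cell adaptive bandwidth h[i, j] with its selection parameters.

    Invariant: 1 <= h <= h_max, and the raw-count coverage at h meets
    ``minimum_count`` unless h == h_max.
    """

    h: np.ndarray
    minimum_count: int
    h_max: int


def adaptive_bandwidth(
    rc,
    minimum_count: int = DEFAULT_MINIMUM_COUNT,
    h_max: int = DEFAULT_H_MAX,
) -> BandwidthField:
    """Smallest integer bandwidth per cell whose +-3h window of RAW counts
    reaches ``minimum_count``, capped at ``h_max``."""
    if minimum_count < 1:
        raise ValueError("minimum_count must be >= 1")
    cumul = build_cumulative(rc)
    n = cumul.n
    h = np.zeros((n, n), dtype=np.int64)
    for hh in range(1, h_max + 1):
        open_cells = h == 0
        if not open_cells.any():
            break
        cov = cumul.cov_all(hh)
        h[open_cells & (cov >= minimum_count)] = hh
    h[h == 0] = h_max
    return BandwidthField(h, minimum_count, h_max)


def estimate_akde(
    rc,
    nrc,
    minimum_count: int = DEFAULT_MINIMUM_COUNT,
    h_max: int = DEFAULT_H_MAX,
    bandwidth_field: BandwidthField | None = None,
) -> IFMatrix:
    """Adaptive-bandwidth KDE: per-cell Gaussian smoothing of nRC at the
    bandwidth chosen by :func:`adaptive_bandwidth` from the raw counts."""
    field = bandwidth_field or adaptive_bandwidth(rc, minimum_count, h_max)
    v = _as_values(nrc)
    n = v.shape[0]
    mask = _mask_of(nrc, n)
    valid = ~(mask[:, None] | mask[None, :])
    out = np.zeros_like(v)
    for hh in np.unique(field.h):
        sel = field.h == hh
        out[sel] = _kde_values(v, valid, int(hh))[sel]
    out[~valid] = 0.0
    out = (out + out.T) / 2.0
    return IFMatrix(out, normalized=True, mask=mask)
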