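"""Sparse-matrix TSV dialect, BEDPE output, and fixed-bin -> RF conversion.

The on-disk matrix format is a TSV with rows ``chrom<TAB>i<TAB>j<TAB>value``
where ``i <= j`` are 0-based fragment ordinals; a header line starting with
``#`` is permitted and ignored.  Counts are written as integers with zeros
omitted; interaction frequencies are written with 6 significant digits.
One chromosome per file; intrachromosomal pairs only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fragments import FragmentMap
from .matrix import IFMatrix, ReadCountMatrix

__all__ = [
    "read_sparse_matrix",
    "write_sparse_matrix",
    "read_if_matrix",
    "convert_fixed_to_rf",
    "write_loops_bedpe",
    "write_boundaries_bed",
]


class SparseMatrixFormatError(ValueError):
    pass


def _parse_sparse_tsv(path, n: int):
    """Yield (i, j, value-string) triples with validation."""
    ii, jj, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SparseMatrixFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns"
                )
            try:
                i, j = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise SparseMatrixFormatError(
                    f"{path}:{lineno}: non-integer fragment index"
                ) from exc
            if i < 0 or j < 0 or i >= n or j >= n:
                raise SparseMatrixFormatError(
                    f"{path}:{lineno}: fragment index out of range (n={n})"
                )
            ii.append(i)
            jj.append(j)
            vals.append(parts[3])
    return np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64), vals


def read_sparse_matrix(path, fmap: FragmentMap) -> ReadCountMatrix:
    """Read a sparse read-count TSV into a :class:`ReadCountMatrix`.

    Duplicate (i, j) rows are summed; unlisted pairs are zero.  Raises on
    indices >= ``fmap.n_fragments`` or negative/non-integer counts.
    """
    i, j, raw = _parse_sparse_tsv(path, fmap.n_fragments)
    counts = np.empty(len(raw), dtype=np.int64)
    for k, s in enumerate(raw):
        try:
            c = int(s)
        except ValueError as exc:
            raise SparseMatrixFormatError(
                f"{path}: non-integer count {s!r}"
            ) from exc
        if c < 0:
            raise SparseMatrixFormatError(f"{path}: negative count {c}")
        counts[k] = c
    return ReadCountMatrix.from_pairs(fmap.n_fragments, i, j, counts)


def read_if_matrix(path, fmap: FragmentMap, normalized: bool = True) -> IFMatrix:
    """Read a sparse TSV of real values into an :class:`IFMatrix`."""
    i, j, raw = _parse_sparse_tsv(path, fmap.n_fragments)
    n = fmap.n_fragments
    v = np.zeros((n, n), dtype=np.float64)
    vals = np.asarray([float(s) for s in raw])
    np.add.at(v, (i, j), vals)
    off = i != j
    np.add.at(v, (j[off], i[off]), vals[off])
    return IFMatrix(v, normalized=normalized)


def write_sparse_matrix(m, path, chrom: str = "chr") -> None:
    """Write a matrix in the sparse TSV dialect.

    Only ``i <= j`` entries are emitted, sorted by (i, j); zeros are omitted.
    Counts are written as integers, interaction frequencies with 6
    significant digits (round-trips within 1e-6 relative error).
    """
    if isinstance(m, ReadCountMatrix):
        values, fmt = m.values, "{:d}"
    elif isinstance(m, IFMatrix):
        values, fmt = m.values, "{:.6g}"
    else:
        raise TypeError(f"cannot write matrix of type {type(m).__name__}")
    iu, ju = np.triu_indices(values.shape[0])
    vv = values[iu, ju]
    nz = vv != 0
    with open(path, "w") as fh:
        fh.write("#chrom\ti\tj\tvalue\n")
        for i, j, v in zip(iu[nz], ju[nz], vv[nz]):
            fh.write(f"{chrom}\t{i}\t{j}\t{fmt.format(v)}\n")


def convert_fixed_to_rf(
    binned: np.ndarray,
    bin_bp: int,
    fmap: FragmentMap,
    scheme: str = "direct",
) -> IFMatrix:
    """Convert a fixed-resolution binned matrix to RF resolution.

    Bins tile the chromosome from coordinate 0 with constant width ``bin_bp``.
    Three schemes:

    * ``direct`` (default, the most robust in practice): each fragment takes
      the value of the bin its 3' end resides in, on both axes.  Total matrix
      mass is NOT conserved.
    * ``counts``: each bin's value is divided by the number of fragment
      3' ends it contains, per axis, before assignment; conserves total mass.
    * ``weighted``: each bin's value is split across fragments in proportion
      to their bp overlap with the bin, per axis; conserves total mass.
    """
    binned = np.asarray(binned, dtype=np.float64)
    if binned.ndim != 2 or binned.shape[0] != binned.shape[1]:
        raise ValueError("binned matrix must be square")
    nbins = binned.shape[0]
    pos = fmap.pos
    # bin of a 3' end; end coordinate e lies in bin floor((e-1)/bin_bp) under
    # half-open tiling, but the field convention is bin(pos) = pos // bin_bp
    # with the chromosome-end coordinate belonging to the last bin.
    b = pos // bin_bp
    b = np.where((b == nbins) & (pos == nbins * bin_bp), nbins - 1, b)
    if np.any(b >= nbins):
        raise ValueError("fragment 3' end beyond last bin")

    if scheme == "direct":
        vals = binned[np.ix_(b, b)]
    elif scheme == "counts":
        cnt = np.bincount(b, minlength=nbins).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            shared = binned / np.where(cnt > 0, cnt, np.inf)[:, None]
            shared = shared / np.where(cnt > 0, cnt, np.inf)[None, :]
        vals = shared[np.ix_(b, b)]
    elif scheme == "weighted":
        # overlap fraction of fragment f with bin k, normalized per bin over
        # all fragments so each bin's mass is fully distributed
        n = fmap.n_fragments
        w = np.zeros((n, nbins))
        for f in range(n):
            k0 = fmap.starts[f] // bin_bp
            k1 = min((fmap.ends[f] - 1) // bin_bp, nbins - 1)
            for k in range(k0, k1 + 1):
                lo = max(fmap.starts[f], k * bin_bp)
                hi = min(fmap.ends[f], (k + 1) * bin_bp)
                w[f, k] = max(hi - lo, 0)
        colsum = w.sum(axis=0)
        w = w / np.where(colsum > 0, colsum, np.inf)[None, :]
        vals = w @ binned @ w.T
    else:
        raise ValueError(f"unknown conversion scheme {scheme!r}")
    return IFMatrix(vals, normalized=True)


def write_loops_bedpe(loops, fmap: FragmentMap, path) -> None:
    """Write loop calls as BEDPE (two anchors, name, score, FDR, scale)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tfdr\tp_bp\tw_bp\n"
        )
        for k, lp in enumerate(loops):
            i, j = lp.anchor
            fh.write(
                f"{fmap.chrom}\t{fmap.starts[i]}\t{fmap.ends[i]}\t"
                f"{fmap.chrom}\t{fmap.starts[j]}\t{fmap.ends[j]}\t"
                f"loop_{k}\t{lp.score:.6g}\t"
                f"{'NA' if lp.fdr is None else format(lp.fdr, '.6g')}\t"
                f"{lp.scale[0]}\t{lp.scale[1]}\n"
            )


def write_boundaries_bed(boundaries, fmap: FragmentMap, path) -> None:
    """Write domain boundaries as BED: interval, |DI'| score, sign as strand."""
    with open(path, "w") as fh:
        for idx, score, sign in zip(
            boundaries.indices, boundaries.scores, boundaries.signs
        ):
            strand = "+" if sign > 0 else "-"
            fh.write(
                f"{fmap.chrom}\t{fmap.starts[idx]}\t{fmap.ends[idx]}\t"
                f"boundary\t{score:.6g}\t{strand}\n"
            )
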