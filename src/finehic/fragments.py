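"""Restriction-fragment maps.

A Hi-C digest partitions each chromosome into restriction fragments (RFs),
the native resolution unit of the assay.  A :class:`FragmentMap` holds the
ordered RF intervals of a single chromosome in BED convention (0-based,
half-open) and exposes ``pos``, the genomic coordinate of each fragment's
3' end on the forward strand, which downstream distance computations are
anchored to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FragmentMap", "load_fragment_map"]


class FragmentMapError(ValueError):
    """Raised when a fragment map violates its ordering/overlap contract."""


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction-fragment intervals for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome identifier (single chromosome per map).
    starts, ends
        0-based half-open interval bounds, sorted by ``starts`` and
        non-overlapping.  Gaps between consecutive fragments are allowed.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.shape != ends.shape or starts.ndim != 1:
            raise FragmentMapError("starts and ends must be 1-D arrays of equal length")
        if starts.size == 0:
            raise FragmentMapError("no fragments")
        if np.any(ends <= starts):
            bad = int(np.argmax(ends <= starts))
            raise FragmentMapError(f"fragment {bad}: end <= start")
        if np.any(np.diff(starts) < 0):
            raise FragmentMapError("fragments not sorted by start")
        if np.any(starts[1:] < ends[:-1]):
            bad = int(np.argmax(starts[1:] < ends[:-1]))
            raise FragmentMapError(f"fragments {bad} and {bad + 1} overlap")

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    def __len__(self) -> int:
        return self.n_fragments

    @property
    def pos(self) -> np.ndarray:
        """3'-end coordinate of each fragment (its ``end`` on the forward
        strand); strictly increasing."""
        return self.ends

    @property
    def sizes(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def extent(self) -> tuple[int, int]:
        """(first start, last end) of the mapped portion of the chromosome."""
        return int(self.starts[0]), int(self.ends[-1])

    @classmethod
    def from_intervals(cls, chrom: str, intervals) -> "FragmentMap":
        arr = np.asarray(sorted(intervals), dtype=np.int64)
        if arr.size == 0:
            raise FragmentMapError("no fragments")
        return cls(chrom, arr[:, 0], arr[:, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.starts, "end": self.ends}
        )

    def write_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def load_fragment_map(path) -> FragmentMap:
    """Read a fragment map from a BED-like file (>= 3 tab-separated columns:
    chrom, start, end; one chromosome per file).

    Lines may appear out of order; the map is sorted on load.  Raises a
    parse error with the offending line number on malformed input and a
    validation error on overlapping or empty fragments.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentMapError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentMapError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            rows.append((parts[0], start, end))
    if not rows:
        raise FragmentMapError(f"{path}: no fragments")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise FragmentMapError(
            f"{path}: fragment map spans multiple chromosomes: {sorted(chroms)}"
        )
    rows.sort(key=lambda r: (r[1], r[2]))
    arr = np.asarray([(r[1], r[2]) for r in rows], dtype=np.int64)
    return FragmentMap(rows[0][0], arr[:, 0], arr[:, 1])
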