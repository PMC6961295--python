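"""Closed-form digestion and sparsity arithmetic.

Back-of-the-envelope quantities for planning a fragment-resolution Hi-C
analysis: how many restriction fragments an enzyme yields, and how thinly a
given sequencing depth spreads over the intrachromosomal fragment-pair
matrix.  Under a uniform base composition, a k-bp recognition site occurs
with probability (1/4)^k per position, so the expected fragment length is
4^k bp (256 bp for a 4-cutter, 4096 bp for a 6-cutter; empirical genome
averages are 434 bp and ~3.7 kb).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "site_probability",
    "expected_fragment_bp",
    "fragment_count_ratio",
    "pair_count_ratio",
    "fragment_counts",
    "expected_pairs_per_entry",
    "HG19_CHROM_LENGTHS",
]

# GRCh37/hg19 assembly chromosome lengths in bp (chr1..22, X, Y)
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}


def site_probability(site_len: int) -> float:
    """Per-position probability of a recognition site of ``site_len`` bases
    under a uniform i.i.d. base model: (1/4)^site_len."""
    if site_len < 1:
        raise ValueError("site_len must be >= 1")
    return 0.25**site_len


def expected_fragment_bp(site_len: int) -> float:
    """Expected fragment length = 1 / site probability."""
    return 1.0 / site_probability(site_len)


def fragment_count_ratio(site_len_a: int = 4, site_len_b: int = 6) -> float:
    """Ratio of expected fragment counts between two enzymes (a 4-cutter
    yields 4^(6-4) = 16x the fragments of a 6-cutter)."""
    return site_probability(site_len_a) / site_probability(site_len_b)


def pair_count_ratio(site_len_a: int = 4, site_len_b: int = 6) -> float:
    """Ratio of fragment-PAIR counts: the square of the fragment ratio."""
    return fragment_count_ratio(site_len_a, site_len_b) ** 2


def fragment_counts(chrom_lengths: dict[str, int], fragment_bp: float) -> np.ndarray:
    """Expected fragments per chromosome at a mean fragment size."""
    return np.asarray([L / fragment_bp for L in chrom_lengths.values()])


def expected_pairs_per_entry(
    chrom_lengths: dict[str, int],
    fragment_bp: float,
    total_pairs: float,
) -> float:
    """Expected read pairs per intrachromosomal fragment-pair matrix entry
    if ``total_pairs`` reads spread uniformly over all intrachromosomal
    pairs (n_c * (n_c + 1) / 2 entries per chromosome)."""
    n = fragment_counts(chrom_lengths, fragment_bp)
    entries = (n * (n + 1) / 2).sum()
    return float(total_pairs / entries)
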