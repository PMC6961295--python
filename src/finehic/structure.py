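"""RF-resolution domain-boundary and chromatin-loop calling.

Domain (TAD/subTAD) boundaries are located with a directionality index:
for each fragment i, ``A`` sums interactions with fragments up to ``delta``
bp upstream and ``B`` downstream, E = (A+B)/2, and

    DI(i)  = sign(B-A) * ((A-E)^2/E   + (B-E)^2/E)
    DI'(i) = sign(B-A) * ((A-E)^2/E^2 + (B-E)^2/E^2)

DI' rescales the squared deviations to relative rates, which tames the
noise of sparse fragment-level data; |DI'| <= 2 whenever A, B >= 0.
Boundaries are strict local extrema of DI' within a centered window of RFs,
ranked by |DI'|.

Loops are called HiCCUPS-style on a distance-normalized matrix IFnorm
(expected value 1 at every genomic-distance stratum): a candidate peak's
mean IFnorm is compared against the surrounding donut, horizontal/vertical
flanks, and lower-left block, all delimited in bp via fragment 3'-end
positions.  Significance is an empirical FDR from gamma fits to the score
distribution of a diagonal-wise permuted matrix, stratified by distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .fragments import FragmentMap
from .matrix import IFMatrix

__all__ = [
    "DIProfile",
    "directionality_profile",
    "DomainBoundarySet",
    "call_domain_boundaries",
    "distance_normalize",
    "PeakScores",
    "score_candidate_peaks",
    "LoopCall",
    "call_loops",
]

DEFAULT_DELTA_BP = 500_000
DEFAULT_DI_WINDOW = 21  # 51 for 4-cutter digests
DEFAULT_EXCLUSION_BP = 2_000_000
DEFAULT_STRATUM_BP = 10_000
DEFAULT_SCALES = ((30_000, 60_000), (50_000, 100_000))
DEFAULT_MIN_SCORE = 1.0
DEFAULT_MIN_DIST_BP = 20_000


# ---------------------------------------------------------------------------
# Directionality index
# ---------------------------------------------------------------------------


@dataclass
class DIProfile:
    """Per-fragment directionality index (raw and scale-normalized)."""

    di: np.ndarray
    di_prime: np.ndarray
    upstream: np.ndarray  # A
    downstream: np.ndarray  # B
    delta: int
    mask: np.ndarray  # True where A + B == 0 (undefined)

    @property
    def n_fragments(self) -> int:
        return int(self.di.size)


def directionality_profile(
    ifm: IFMatrix, fmap: FragmentMap, delta: int = DEFAULT_DELTA_BP
) -> DIProfile:
    """Compute DI and DI' for every fragment.

    ``A`` sums IF[j, i] over fragments j < i whose 3' end lies within
    ``delta`` bp upstream of fragment i's 3' end; ``B`` symmetrically
    downstream.  Fragments with A + B = 0 are masked.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    v = ifm.values
    n = ifm.n
    pos = fmap.pos
    if pos.size != n:
        raise ValueError("fragment map size does not match matrix")
    # column prefix sums: colpre[k, i] = sum_{r < k} IF[r, i]
    colpre = np.zeros((n + 1, n))
    colpre[1:] = np.cumsum(v, axis=0)
    rowpre = np.zeros((n, n + 1))
    rowpre[:, 1:] = np.cumsum(v, axis=1)
    lo = np.searchsorted(pos, pos - delta, side="left")
    hi = np.searchsorted(pos, pos + delta, side="right")
    idx = np.arange(n)
    a = colpre[idx, idx] - colpre[lo, idx]
    b = rowpre[idx, hi] - rowpre[idx, idx + 1]
    e = (a + b) / 2.0
    mask = (a + b) <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (a - e) ** 2 + (b - e) ** 2
        di = np.sign(b - a) * dev / e
        dip = np.sign(b - a) * dev / e**2
    di[mask] = np.nan
    dip[mask] = np.nan
    mask = mask | ifm.mask
    di[ifm.mask] = np.nan
    dip[ifm.mask] = np.nan
    return DIProfile(di, dip, a, b, int(delta), mask)


@dataclass
class DomainBoundarySet:
    """Ranked domain boundaries: fragment index, |DI'|, sign of DI'."""

    indices: np.ndarray
    scores: np.ndarray
    signs: np.ndarray
    window: int
    top_k: int | None = None

    def __len__(self) -> int:
        return int(self.indices.size)


def call_domain_boundaries(
    prof: DIProfile,
    fmap: FragmentMap | None = None,
    window: int = DEFAULT_DI_WINDOW,
    top_k: int | None = None,
    exclusion_bp: int = DEFAULT_EXCLUSION_BP,
    excluded_intervals=None,
    bin_size: int | None = None,
) -> DomainBoundarySet:
    """Strict local extrema of DI' in a centered window of ``window`` RFs.

    Fragments within ``exclusion_bp`` of the chromosome ends (or inside any
    supplied ``excluded_intervals``, e.g. centromere masks) are removed;
    survivors are ranked by |DI'| descending and truncated to ``top_k``.
    With ``bin_size`` set (fixed-binning comparison mode), only fragments at
    the center of their bin are considered.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    dip = prof.di_prime
    n = dip.size
    half = window // 2
    allowed = ~prof.mask
    if fmap is not None and exclusion_bp > 0:
        lo, hi = fmap.extent
        allowed &= (fmap.pos - lo >= exclusion_bp) & (hi - fmap.pos >= exclusion_bp)
    if fmap is not None and excluded_intervals:
        for s, e in excluded_intervals:
            allowed &= ~((fmap.pos >= s - exclusion_bp) & (fmap.pos <= e + exclusion_bp))
    if bin_size is not None:
        allowed &= (np.arange(n) % bin_size) == bin_size // 2
    hits = []
    for i in np.nonzero(allowed)[0]:
        # require a complete centered window: fragments too close to the
        # array ends always look like extrema (one of A/B vanishes there)
        if i < half or i + half >= n:
            continue
        w0, w1 = i - half, i + half + 1
        neigh = np.concatenate([dip[w0:i], dip[i + 1 : w1]])
        neigh = neigh[~np.isnan(neigh)]
        if neigh.size == 0:
            continue
        x = dip[i]
        if x > neigh.max() or x < neigh.min():
            hits.append((i, abs(x), 1.0 if x > 0 else -1.0))
    hits.sort(key=lambda t: (-t[1], t[0]))
    if top_k is not None:
        hits = hits[:top_k]
    if hits:
        idx, sc, sg = map(np.asarray, zip(*hits))
    else:
        idx = np.empty(0, int)
        sc = np.empty(0)
        sg = np.empty(0)
    return DomainBoundarySet(idx.astype(int), sc.astype(float), sg, window, top_k)


# ---------------------------------------------------------------------------
# Distance normalization and donut scoring
# ---------------------------------------------------------------------------


def _strata(fmap: FragmentMap, stratum_bp: int) -> np.ndarray:
    pos = fmap.pos
    return np.abs(pos[None, :] - pos[:, None]) // stratum_bp


def distance_normalize(
    ifm: IFMatrix, fmap: FragmentMap, stratum_bp: int = DEFAULT_STRATUM_BP
) -> IFMatrix:
    """Divide each cell by the mean IF of its genomic-distance stratum
    (strata of ``stratum_bp`` on |pos(j) - pos(i)|); the resulting IFnorm
    has mean exactly 1 within every defined stratum.  Cells in empty or
    zero-mean strata are set to NaN.
    """
    if stratum_bp <= 0:
        raise ValueError("stratum_bp must be positive")
    strata = _strata(fmap, stratum_bp)
    valid = ~ifm.cell_mask()
    flat_s = strata[valid]
    sums = np.bincount(flat_s, weights=ifm.values[valid])
    cnts = np.bincount(flat_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / cnts
    out = np.full_like(ifm.values, np.nan)
    m = means[strata]
    ok = valid & np.isfinite(m) & (m > 0)
    out[ok] = ifm.values[ok] / m[ok]
    res = IFMatrix.__new__(IFMatrix)  # bypass validation: NaNs mark undefined
    res.values = out
    res.normalized = ifm.normalized
    res.mask = ifm.mask.copy()
    return res


@dataclass
class PeakScores:
    """Per-cell donut-filter scores and region means (NaN = undefined)."""

    score: np.ndarray
    peak: np.ndarray
    donut: np.ndarray
    horizontal: np.ndarray
    vertical: np.ndarray
    lower_left: np.ndarray
    p: int
    w: int


def _axis_range(pos: np.ndarray, lo_off: int, hi_off: int, lo_open: bool = False,
                hi_open: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Index bounds [lo, hi) of fragments with pos in the bp interval
    [pos_i + lo_off, pos_i + hi_off] (open ends optional)."""
    lo = np.searchsorted(pos, pos + lo_off, side="right" if lo_open else "left")
    hi = np.searchsorted(pos, pos + hi_off, side="left" if hi_open else "right")
    return lo, hi


def score_candidate_peaks(
    ifnorm: IFMatrix, fmap: FragmentMap, p: int, w: int
) -> PeakScores:
    """Donut-filter scores score = P / max(D, H, V, BL) for every cell.

    Regions are delimited in bp via fragment 3'-end positions (cell counts
    per region vary with fragment sizes): P is the mean IFnorm over the
    square +-p bp around (i, j); D the donut of half-width w excluding the
    peak square and the horizontal/vertical crosses; H and V the left/right
    and top/bottom flanks; BL the lower-left block.  Cells with any empty
    flank region are NaN.
    """
    if p >= w:
        raise ValueError("peak half-width p must be smaller than window w")
    pos = fmap.pos
    v = ifnorm.values
    n = v.shape[0]
    finite = np.isfinite(v)
    vv = np.where(finite, v, 0.0)

    s = np.zeros((n + 1, n + 1))
    s[1:, 1:] = np.cumsum(np.cumsum(vv, 0), 1)
    c = np.zeros((n + 1, n + 1))
    c[1:, 1:] = np.cumsum(np.cumsum(finite.astype(float), 0), 1)

    def rect(pref, rlo, rhi, clo, chi):
        # sum over index rows [rlo, rhi) x cols [clo, chi)
        return (
            pref[np.ix_(rhi, chi)]
            - pref[np.ix_(rlo, chi)]
            - pref[np.ix_(rhi, clo)]
            + pref[np.ix_(rlo, clo)]
        )

    plo, phi = _axis_range(pos, -p, p)
    wlo, whi = _axis_range(pos, -w, w)
    # BL rows: pos in (pos_i, pos_i + w]; BL cols: pos in [pos_j - w, pos_j)
    bl_rlo, bl_rhi = _axis_range(pos, 0, w, lo_open=True)
    bl_clo, bl_chi = _axis_range(pos, -w, 0, hi_open=True)
    # overlap of BL with the peak square
    blp_rlo, blp_rhi = _axis_range(pos, 0, p, lo_open=True)
    blp_clo, blp_chi = _axis_range(pos, -p, 0, hi_open=True)

    def region(rlo, rhi, clo, chi):
        return rect(s, rlo, rhi, clo, chi), rect(c, rlo, rhi, clo, chi)

    peak_s, peak_c = region(plo, phi, plo, phi)
    wrect_s, wrect_c = region(wlo, whi, wlo, whi)
    brow_s, brow_c = region(plo, phi, wlo, whi)  # peak rows x window cols
    bcol_s, bcol_c = region(wlo, whi, plo, phi)
    bl_s, bl_c = region(bl_rlo, bl_rhi, bl_clo, bl_chi)
    blp_s, blp_c = region(blp_rlo, blp_rhi, blp_clo, blp_chi)

    d_s = wrect_s - brow_s - bcol_s + peak_s
    d_c = wrect_c - brow_c - bcol_c + peak_c
    h_s, h_c = brow_s - peak_s, brow_c - peak_c
    v_s, v_c = bcol_s - peak_s, bcol_c - peak_c
    bl_s, bl_c = bl_s - blp_s, bl_c - blp_c

    def mean_of(ss, cc):
        out = np.full_like(ss, np.nan)
        ok = cc > 0.5
        out[ok] = ss[ok] / cc[ok]
        return out

    pm = mean_of(peak_s, peak_c)
    dm = mean_of(d_s, d_c)
    hm = mean_of(h_s, h_c)
    vm = mean_of(v_s, v_c)
    blm = mean_of(bl_s, bl_c)

    background = np.fmax(np.fmax(dm, hm), np.fmax(vm, blm))
    score = np.full_like(pm, np.nan)
    defined = (
        np.isfinite(pm)
        & np.isfinite(dm)
        & np.isfinite(hm)
        & np.isfinite(vm)
        & np.isfinite(blm)
        & (background > 0)
    )
    score[defined] = pm[defined] / background[defined]
    score[~finite] = np.nan
    return PeakScores(score, pm, dm, hm, vm, blm, int(p), int(w))


# ---------------------------------------------------------------------------
# Loop calling
# ---------------------------------------------------------------------------


@dataclass
class LoopCall:
    """A called chromatin loop: representative RF anchor pair, donut score,
    empirical FDR (None if the null fit was not possible), and the (p, w)
    scale that produced it."""

    anchor: tuple[int, int]
    score: float
    fdr: float | None
    scale: tuple[int, int]
    cell: tuple[int, int] = (0, 0)
    distance_bp: int = 0
    fdr_defined: bool = True


def _permute_diagonalwise(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly permute each diagonal of a symmetric matrix independently
    (preserving the fragment-distance of every entry)."""
    n = values.shape[0]
    out = np.empty_like(values)
    for k in range(n):
        d = np.diagonal(values, offset=k).copy()
        rng.shuffle(d)
        idx = np.arange(n - k)
        out[idx, idx + k] = d
        out[idx + k, idx] = d
    return out


def _gamma_fdr_table(null_scores: np.ndarray, null_bins: np.ndarray,
                     min_per_bin: int = 30):
    """Method-of-moments gamma fit per distance bin; bins with fewer than
    ``min_per_bin`` null scores are pooled with neighboring bins.  Returns
    a callable (score, bin) -> upper-tail probability or None."""
    if null_scores.size == 0:
        return lambda score, b: None
    max_bin = int(null_bins.max())
    by_bin = [null_scores[null_bins == b] for b in range(max_bin + 1)]

    def tail(score: float, b: int):
        b = min(max(b, 0), max_bin)
        pool = by_bin[b]
        r = 1
        while pool.size < min_per_bin and r <= max_bin:
            lo, hi = max(b - r, 0), min(b + r, max_bin)
            pool = np.concatenate(by_bin[lo : hi + 1])
            r += 1
        if pool.size < 2:
            return None
        m = pool.mean()
        var = pool.var(ddof=1)
        if not np.isfinite(m) or m <= 0 or var <= 1e-12 * max(m * m, 1.0):
            # degenerate null: all mass at one point
            return 1.0 if score <= m else 0.0
        shape = m * m / var
        scale = var / m
        return float(sps.gamma.sf(score, a=shape, scale=scale))

    return tail


def call_loops(
    ifm: IFMatrix,
    fmap: FragmentMap,
    scales=DEFAULT_SCALES,
    min_score: float = DEFAULT_MIN_SCORE,
    min_dist: int = DEFAULT_MIN_DIST_BP,
    seed: int | None = 0,
    stratum_bp: int = DEFAULT_STRATUM_BP,
    fdr_bin_bp: int = 10_000,
    n_permutations: int = 1,
    min_null_per_bin: int = 30,
) -> list[LoopCall]:
    """Donut-filter loop calling with distance-stratified gamma FDR.

    For each (p, w) scale, cells scoring >= ``min_score`` become candidates;
    each candidate's representative anchor pair is the argmax of IFnorm
    within its peak square; a candidate is eliminated if any higher-scoring
    candidate lies within ``min_dist`` bp (Chebyshev distance on anchor
    positions; ties broken by smaller genomic distance, then smaller
    (i, j)).  FDRs come from gamma fits to scores of a diagonal-wise
    permuted matrix, stratified in ``fdr_bin_bp`` distance bins.  Calls from
    all scales are merged and sorted by FDR.
    """
    if not scales:
        raise ValueError("at least one (p, w) scale is required")
    rng = np.random.default_rng(seed)
    pos = fmap.pos
    n = ifm.n
    ifn = distance_normalize(ifm, fmap, stratum_bp)
    iu, ju = np.triu_indices(n, k=1)
    dist_bp = pos[ju] - pos[iu]

    calls: list[LoopCall] = []
    for p, w in scales:
        ps = score_candidate_peaks(ifn, fmap, p, w)
        sc = ps.score[iu, ju]
        cand = np.isfinite(sc) & (sc >= min_score)
        order = np.lexsort((ju[cand], iu[cand], dist_bp[cand], -sc[cand]))
        ci, cj, cs = iu[cand][order], ju[cand][order], sc[cand][order]

        # greedy scan in priority order; any earlier (higher-priority)
        # candidate within min_dist eliminates the current one
        buckets: dict = {}
        retained = []
        for i, j, s in zip(ci, cj, cs):
            bi, bj = pos[i] // min_dist, pos[j] // min_dist
            hit = False
            for dbi in (-1, 0, 1):
                for dbj in (-1, 0, 1):
                    for (qi, qj) in buckets.get((bi + dbi, bj + dbj), ()):
                        if (
                            abs(int(pos[qi]) - int(pos[i])) <= min_dist
                            and abs(int(pos[qj]) - int(pos[j])) <= min_dist
                        ):
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    break
            buckets.setdefault((bi, bj), []).append((i, j))
            if not hit:
                retained.append((int(i), int(j), float(s)))

        # null score distribution from permuted matrices
        null_scores, null_bins = [], []
        for _ in range(n_permutations):
            perm = _permute_diagonalwise(np.where(ifm.cell_mask(), 0.0, ifm.values), rng)
            perm_if = IFMatrix(perm, normalized=ifm.normalized, mask=ifm.mask.copy())
            perm_n = distance_normalize(perm_if, fmap, stratum_bp)
            nsc = score_candidate_peaks(perm_n, fmap, p, w).score[iu, ju]
            fin = np.isfinite(nsc)
            null_scores.append(nsc[fin])
            null_bins.append(dist_bp[fin] // fdr_bin_bp)
        tail = _gamma_fdr_table(
            np.concatenate(null_scores),
            np.concatenate(null_bins).astype(int),
            min_null_per_bin,
        )

        plo, phi = _axis_range(pos, -p, p)
        vals = np.where(np.isfinite(ifn.values), ifn.values, -np.inf)
        for i, j, s in retained:
            sub = vals[plo[i] : phi[i], plo[j] : phi[j]]
            k = int(np.argmax(sub))
            ai = plo[i] + k // sub.shape[1]
            aj = plo[j] + k % sub.shape[1]
            d = int(pos[j] - pos[i])
            fdr = tail(s, d // fdr_bin_bp)
            calls.append(
                LoopCall(
                    anchor=(int(ai), int(aj)),
                    score=s,
                    fdr=fdr,
                    scale=(int(p), int(w)),
                    cell=(i, j),
                    distance_bp=d,
                    fdr_defined=fdr is not None,
                )
            )
    calls.sort(key=lambda c: (c.fdr if c.fdr is not None else math.inf, -c.score))
    return calls
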