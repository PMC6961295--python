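"""Markov-random-field interaction-frequency estimation.

The latent IF field is given a log-normal prior centered on the median of
each cell's eight neighbors,

    log IF[i, j] ~ Normal(mu = log MedNeigh[i, j], sigma^2 = alpha * log MedNeigh[i, j]),

and the observed counts a Poisson (optionally negative-binomial) likelihood,

    RC[i, j] ~ Poisson(lambda = IF[i, j] * bias_i * bias_j).

The median (rather than the mean) neighborhood prior preserves sharp domain
boundaries; to prevent residual bleed-through, sharp horizontal/vertical
transitions are first located on nRC with a two-sample Kolmogorov-Smirnov
scan and neighbors across such a transition are excluded from the median.
The maximum a posteriori field is found by iterated conditional modes (ICM):
raster sweeps in which each cell is replaced by the best of a small grid of
multiplicative rescalings of its current value.  The joint log-probability
is non-decreasing across sweeps by construction.

sigma^2 is floored at ``sigma2_floor`` because alpha * log MedNeigh is
non-positive whenever MedNeigh <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .bias import BiasVector
from .matrix import IFMatrix, ReadCountMatrix
from .smoothing import (
    DEFAULT_H_MAX,
    DEFAULT_MINIMUM_COUNT,
    build_cumulative,
)

__all__ = [
    "MRFParams",
    "TransitionBoundarySet",
    "detect_transition_boundaries",
    "mrf_local_objective",
    "estimate_mrf",
    "MRFResult",
]

_IF_FLOOR = 1e-6
_LOG_EPS = 1e-6


def default_grid_factors() -> np.ndarray:
    """Multiplicative update candidates: a fine geometric ladder
    2**(k/4), k = -4..4 (0.5x to 2x) plus coarse jumps {1/16, 1/4, 4, 16}
    so cells far from their optimum travel quickly and converge within a
    handful of sweeps."""
    fine = 2.0 ** (np.arange(-4, 5) / 4.0)
    coarse = np.array([1 / 16, 1 / 4, 4.0, 16.0])
    return np.sort(np.concatenate([fine, coarse]))


@dataclass
class MRFParams:
    """Hyperparameters of the MRF estimator.

    alpha
        Prior-strength coefficient; sigma^2 = alpha * log(MedNeigh).  Small
        alpha gives a tight prior (smoother fields), large alpha a weak one.
        Default 0.2.
    likelihood
        "poisson" (default) or "negative-binomial" with variance
        ``variance_multiplier * lambda`` (multiplier 1 recovers Poisson).
    grid_factors
        Multiplicative update candidates for ICM; must contain 1.0.
    tol, max_iter
        Relative joint-log-probability convergence tolerance per sweep and
        the sweep cap.
    ks_threshold, segment_len
        Scaled KS-statistic acceptance threshold (default 1.5) and segment
        length (in cells) of the transition-boundary scan.
    """

    alpha: float = 0.2
    likelihood: str = "poisson"
    variance_multiplier: float = 1.0
    grid_factors: np.ndarray = field(default_factory=default_grid_factors)
    tol: float = 1e-3
    max_iter: int = 50
    ks_threshold: float = 1.5
    segment_len: int = 8
    sigma2_floor: float = 0.01
    update_order: str = "raster"  # or "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        self.grid_factors = np.asarray(self.grid_factors, dtype=np.float64)
        if not np.any(np.isclose(self.grid_factors, 1.0)):
            raise ValueError("grid_factors must contain 1.0")
        if self.likelihood not in ("poisson", "negative-binomial", "nb"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.variance_multiplier < 1.0:
            raise ValueError("variance multiplier must be >= 1")

    @property
    def _lik_code(self) -> int:
        if self.likelihood == "poisson" or self.variance_multiplier <= 1.0:
            return 0
        return 1


# ---------------------------------------------------------------------------
# Transition boundaries (KS scan)
# ---------------------------------------------------------------------------


@dataclass
class TransitionBoundarySet:
    """Accepted sharp transitions between adjacent rows/columns.

    ``boundaries`` holds (orientation, gap index, segment start, segment end,
    scaled KS statistic); ``horizontal[i, c]`` flags a boundary between rows
    i and i+1 at column c, ``vertical[r, j]`` between columns j and j+1 at
    row r.
    """

    boundaries: list
    horizontal: np.ndarray  # (n-1, n) bool
    vertical: np.ndarray  # (n, n-1) bool

    @classmethod
    def empty(cls, n: int) -> "TransitionBoundarySet":
        return cls([], np.zeros((max(n - 1, 0), n), bool), np.zeros((n, max(n - 1, 0)), bool))

    def __len__(self) -> int:
        return len(self.boundaries)


def _ks_windows(a: np.ndarray, b: np.ndarray, seg_len: int) -> np.ndarray:
    """Scaled two-sample KS statistic D * sqrt(nm/(n+m)) for every sliding
    window of length ``seg_len`` over paired sample rows a and b."""
    n = a.size
    nwin = n - seg_len + 1
    if nwin <= 0:
        return np.empty(0)
    aw = np.lib.stride_tricks.sliding_window_view(a, seg_len)
    bw = np.lib.stride_tricks.sliding_window_view(b, seg_len)
    comb = np.concatenate([aw, bw], axis=1)  # (nwin, 2L)
    step = np.concatenate(
        [np.full(seg_len, 1.0 / seg_len), np.full(seg_len, -1.0 / seg_len)]
    )
    order = np.argsort(comb, axis=1, kind="stable")
    svals = np.take_along_axis(comb, order, axis=1)
    steps = step[order]
    cdf_diff = np.cumsum(steps, axis=1)
    # at tied values only the last position of the tie run is a valid
    # evaluation point of |F1 - F2|
    valid = np.ones_like(cdf_diff, dtype=bool)
    valid[:, :-1] = svals[:, 1:] != svals[:, :-1]
    d = np.where(valid, np.abs(cdf_diff), 0.0).max(axis=1)
    return d * math.sqrt(seg_len / 2.0)


def detect_transition_boundaries(
    nrc,
    ks_threshold: float = 1.5,
    segment_len: int = 8,
) -> TransitionBoundarySet:
    """Scan nRC for sharp horizontal/vertical transitions.

    For every adjacent row pair (i, i+1) and every column segment of
    ``segment_len`` cells, the two-sample KS statistic between the rows'
    values over the segment is scaled by sqrt(nm/(n+m)); boundaries are
    accepted greedily from the largest statistic down, skipping segments
    that overlap an already-accepted boundary of the same orientation and
    gap, until the statistic falls below ``ks_threshold``.  Columns are
    handled symmetrically.
    """
    if segment_len < 2:
        raise ValueError("segment_len must be >= 2")
    v = np.asarray(nrc.values if isinstance(nrc, IFMatrix) else nrc, float)
    n = v.shape[0]
    mask = (
        nrc.mask
        if isinstance(nrc, IFMatrix) and nrc.mask is not None
        else np.zeros(n, bool)
    )
    out = TransitionBoundarySet.empty(n)
    candidates = []
    for orientation, vals in (("horizontal", v), ("vertical", v.T)):
        for i in range(n - 1):
            if mask[i] or mask[i + 1]:
                continue
            stats = _ks_windows(vals[i], vals[i + 1], segment_len)
            ok = stats >= ks_threshold
            # drop windows touching masked columns
            if mask.any():
                bad = np.convolve(mask.astype(int), np.ones(segment_len, int))[
                    segment_len - 1 : n
                ]
                ok &= bad == 0
            for j0 in np.nonzero(ok)[0]:
                candidates.append(
                    (float(stats[j0]), orientation, i, int(j0), int(j0) + segment_len)
                )
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    taken: dict = {}
    for stat, orientation, i, j0, j1 in candidates:
        spans = taken.setdefault((orientation, i), [])
        if any(j0 < e and s < j1 for s, e in spans):
            continue
        spans.append((j0, j1))
        out.boundaries.append((orientation, i, j0, j1, stat))
        if orientation == "horizontal":
            out.horizontal[i, j0:j1] = True
        else:
            out.vertical[j0:j1, i] = True
    return out


# ---------------------------------------------------------------------------
# Numba ICM core
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _usable_neighbor(cellmask, hb, vb, i, j, p, q):  # pragma: no cover - numba
    """A neighbor is usable unless masked or separated by a transition
    boundary: any horizontal/vertical gap crossed along either L-shaped
    path between (i, j) and (p, q) excludes it (symmetric in the two
    cells)."""
    if cellmask[p, q]:
        return False
    if p != i:
        g = i if p > i else p
        if hb[g, j] or hb[g, q]:
            return False
    if q != j:
        g = j if q > j else q
        if vb[i, g] or vb[p, g]:
            return False
    return True


@njit(cache=True)
def _collect_neighbors(ifv, cellmask, hb, vb, i, j, skip_p, skip_q, out):
    """Sorted usable-neighbor values of (i, j), optionally skipping cell
    (skip_p, skip_q); returns the count."""  # pragma: no cover - numba
    n = ifv.shape[0]
    cnt = 0
    for p in range(i - 1, i + 2):
        if p < 0 or p >= n:
            continue
        for q in range(j - 1, j + 2):
            if q < 0 or q >= n or (p == i and q == j):
                continue
            if p == skip_p and q == skip_q:
                continue
            if not _usable_neighbor(cellmask, hb, vb, i, j, p, q):
                continue
            out[cnt] = ifv[p, q]
            cnt += 1
    out[:cnt].sort()
    return cnt


@njit(cache=True, inline="always")
def _merged_kth(base, cnt, v, k):  # pragma: no cover - numba
    """k-th smallest of the sorted base[:cnt] merged with value v."""
    pos = 0
    while pos < cnt and base[pos] <= v:
        pos += 1
    if k < pos:
        return base[k]
    if k == pos:
        return v
    return base[k - 1]


@njit(cache=True, inline="always")
def _median_with(base, cnt, v):  # pragma: no cover - numba
    """Median of sorted base[:cnt] plus value v (even count: mean of the
    two central values)."""
    m = cnt + 1
    if m % 2 == 1:
        return _merged_kth(base, cnt, v, m // 2)
    return 0.5 * (
        _merged_kth(base, cnt, v, m // 2 - 1) + _merged_kth(base, cnt, v, m // 2)
    )


@njit(cache=True, inline="always")
def _median_sorted(base, cnt):  # pragma: no cover - numba
    if cnt % 2 == 1:
        return base[cnt // 2]
    return 0.5 * (base[cnt // 2 - 1] + base[cnt // 2])


@njit(cache=True, inline="always")
def _prior_logpdf(x, med, alpha, s2floor):  # pragma: no cover - numba
    """Log-normal neighborhood prior density at log-value x given median
    med; sigma^2 = alpha * log(med) floored at s2floor."""
    mu = math.log(med + _LOG_EPS)
    s2 = alpha * mu
    if s2 < s2floor:
        s2 = s2floor
    return -0.5 * math.log(2.0 * math.pi * s2) - (x - mu) ** 2 / (2.0 * s2)


@njit(cache=True, inline="always")
def _lik_term(k, bp, v, lik_code, vmult):  # pragma: no cover - numba
    lam = v * bp
    if lam < 1e-300:
        lam = 1e-300
    if lik_code == 0:
        return k * math.log(lam) - lam - math.lgamma(k + 1.0)
    r = lam / (vmult - 1.0)
    logp = -math.log(vmult)
    log1mp = math.log(1.0 - 1.0 / vmult)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1.0)
        + r * logp
        + k * log1mp
    )


@njit(cache=True)
def _local_objective(
    ifv, rc, bp, cellmask, hb, vb, alpha, s2floor, lik_code, vmult, i, j, v
):  # pragma: no cover - numba
    """Joint-log-probability terms affected by setting cell (i, j) to v:
    its own prior and likelihood plus the priors of usable neighbors."""
    n = ifv.shape[0]
    buf = np.empty(8)
    tot = _lik_term(rc[i, j], bp[i, j], v, lik_code, vmult)
    cnt = _collect_neighbors(ifv, cellmask, hb, vb, i, j, -1, -1, buf)
    if cnt > 0:
        tot += _prior_logpdf(math.log(v + _LOG_EPS), _median_sorted(buf, cnt),
                             alpha, s2floor)
    base = np.empty(8)
    for p in range(i - 1, i + 2):
        if p < 0 or p >= n:
            continue
        for q in range(j - 1, j + 2):
            if q < 0 or q >= n or (p == i and q == j):
                continue
            if not _usable_neighbor(cellmask, hb, vb, i, j, p, q):
                continue
            bcnt = _collect_neighbors(ifv, cellmask, hb, vb, p, q, i, j, base)
            med = _median_with(base, bcnt, v)
            tot += _prior_logpdf(math.log(ifv[p, q] + _LOG_EPS), med, alpha, s2floor)
    return tot


@njit(cache=True)
def _icm_sweep(
    ifv, rc, bp, cellmask, frozen, hb, vb, alpha, s2floor, lik_code, vmult,
    factors, order,
):  # pragma: no cover - numba
    n = ifv.shape[0]
    nf = factors.size
    buf = np.empty(8)
    nb_base = np.empty((8, 8))
    nb_cnt = np.empty(8, dtype=np.int64)
    nb_logx = np.empty(8)
    n_changed = 0
    for flat in order:
        i = flat // n
        j = flat % n
        if cellmask[i, j] or frozen[i, j]:
            continue
        cur = ifv[i, j]
        # candidate-independent pieces: own-prior median, neighbor bases
        cnt0 = _collect_neighbors(ifv, cellmask, hb, vb, i, j, -1, -1, buf)
        med0 = _median_sorted(buf, cnt0) if cnt0 > 0 else -1.0
        nnb = 0
        for p in range(i - 1, i + 2):
            if p < 0 or p >= n:
                continue
            for q in range(j - 1, j + 2):
                if q < 0 or q >= n or (p == i and q == j):
                    continue
                if not _usable_neighbor(cellmask, hb, vb, i, j, p, q):
                    continue
                nb_cnt[nnb] = _collect_neighbors(
                    ifv, cellmask, hb, vb, p, q, i, j, nb_base[nnb]
                )
                nb_logx[nnb] = math.log(ifv[p, q] + _LOG_EPS)
                nnb += 1
        best = -np.inf
        best_v = cur
        for t in range(nf):
            v = cur * factors[t]
            if v < _IF_FLOOR:
                v = _IF_FLOOR
            obj = _lik_term(rc[i, j], bp[i, j], v, lik_code, vmult)
            if cnt0 > 0:
                obj += _prior_logpdf(math.log(v + _LOG_EPS), med0, alpha, s2floor)
            for t2 in range(nnb):
                med = _median_with(nb_base[t2], nb_cnt[t2], v)
                obj += _prior_logpdf(nb_logx[t2], med, alpha, s2floor)
            if obj > best or (obj == best and v == cur):
                best = obj
                best_v = v
        if best_v != cur:
            ifv[i, j] = best_v
            n_changed += 1
    return n_changed


@njit(cache=True)
def _joint_logp(
    ifv, rc, bp, cellmask, hb, vb, alpha, s2floor, lik_code, vmult
):  # pragma: no cover - numba
    n = ifv.shape[0]
    buf = np.empty(8)
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if cellmask[i, j]:
                continue
            cnt = _collect_neighbors(ifv, cellmask, hb, vb, i, j, -1, -1, buf)
            if cnt > 0:
                tot += _prior_logpdf(
                    math.log(ifv[i, j] + _LOG_EPS), _median_sorted(buf, cnt),
                    alpha, s2floor,
                )
            tot += _lik_term(rc[i, j], bp[i, j], ifv[i, j], lik_code, vmult)
    return tot


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def _prepare(rc, bias, init, params, boundaries):
    rcv = np.asarray(
        rc.values if isinstance(rc, ReadCountMatrix) else rc, np.float64
    )
    n = rcv.shape[0]
    if bias is None:
        bias = BiasVector.unit(n)
    bp = bias.outer()
    mask = bias.mask.copy()
    if isinstance(init, IFMatrix):
        mask |= init.mask
        initv = init.values
    else:
        initv = np.asarray(init, np.float64)
    cellmask = mask[:, None] | mask[None, :]
    ifv = np.where(cellmask, 0.0, np.maximum(initv, _IF_FLOOR))
    if boundaries is None:
        boundaries = TransitionBoundarySet.empty(n)
    return ifv, rcv, bp, cellmask, mask, boundaries


def mrf_local_objective(
    ifm,
    rc,
    bias: BiasVector | None,
    i: int,
    j: int,
    params: MRFParams,
    boundaries: TransitionBoundarySet | None = None,
    value: float | None = None,
) -> float:
    """Joint log-probability terms affected by cell (i, j): its own prior and
    likelihood plus the priors of its eight (unmasked, in-bounds) neighbors,
    evaluated with the cell set to ``value`` (default: its current value).

    Cells with no usable neighbor (all masked or across a boundary) drop the
    prior term and keep only the likelihood.
    """
    ifv, rcv, bp, cellmask, _, bset = _prepare(rc, bias, ifm, params, boundaries)
    if cellmask[i, j]:
        raise ValueError(f"cell ({i}, {j}) is masked")
    v = ifv[i, j] if value is None else max(float(value), _IF_FLOOR)
    return float(
        _local_objective(
            ifv, rcv, bp, cellmask, bset.horizontal, bset.vertical,
            params.alpha, params.sigma2_floor, params._lik_code,
            params.variance_multiplier, i, j, v,
        )
    )


@dataclass
class MRFResult:
    """MRF estimate with ICM diagnostics."""

    if_matrix: IFMatrix
    n_sweeps: int
    logp_trace: np.ndarray
    boundaries: TransitionBoundarySet
    frozen: np.ndarray

    @property
    def converged(self) -> bool:
        return self.n_sweeps < len(self.logp_trace)


def estimate_mrf(
    rc,
    bias: BiasVector | None = None,
    init: IFMatrix | np.ndarray | None = None,
    params: MRFParams | None = None,
    boundaries: TransitionBoundarySet | None = None,
    nrc: IFMatrix | None = None,
    minimum_count: int = DEFAULT_MINIMUM_COUNT,
    h_max: int = DEFAULT_H_MAX,
) -> MRFResult:
    """Maximum a posteriori IF field by ICM.

    ``init`` defaults to the adaptive-KDE estimate of ``nrc`` (computed here
    if not supplied); ``boundaries`` defaults to a KS transition scan of
    ``nrc``, held fixed across sweeps.  Sweeps stop when the relative change
    of the joint log-probability drops below ``params.tol`` or after
    ``params.max_iter`` sweeps.  The joint log-probability is non-decreasing
    across sweeps; this is asserted every sweep.

    Cells whose raw counts are zero everywhere within their maximal
    bandwidth window are frozen at the initialization value and flagged.
    """
    params = params or MRFParams()
    from .bias import compute_fragment_bias, normalize  # cycle-safe import

    if isinstance(rc, np.ndarray):
        rc = ReadCountMatrix(rc)
    if bias is None:
        bias = compute_fragment_bias(rc)
    if nrc is None and (init is None or boundaries is None):
        nrc = normalize(rc, bias)
    if init is None:
        from .smoothing import estimate_akde

        init = estimate_akde(rc, nrc, minimum_count, h_max)
    if boundaries is None:
        boundaries = detect_transition_boundaries(
            nrc, params.ks_threshold, params.segment_len
        )

    ifv, rcv, bp, cellmask, mask, bset = _prepare(rc, bias, init, params, boundaries)
    n = ifv.shape[0]

    # freeze cells with no reads anywhere in their h_max window
    cov = build_cumulative(rc).cov_all(h_max)
    frozen = (cov == 0) & ~cellmask

    order = np.arange(n * n, dtype=np.int64)
    rng = np.random.default_rng(params.seed)
    args = (
        rcv, bp, cellmask, bset.horizontal, bset.vertical,
        params.alpha, params.sigma2_floor, params._lik_code,
        params.variance_multiplier,
    )
    logp = _joint_logp(ifv, *args)
    trace = [logp]
    n_sweeps = 0
    for _ in range(params.max_iter):
        if params.update_order == "random":
            rng.shuffle(order)
        _icm_sweep(
            ifv, rcv, bp, cellmask, frozen, bset.horizontal, bset.vertical,
            params.alpha, params.sigma2_floor, params._lik_code,
            params.variance_multiplier, params.grid_factors, order,
        )
        new_logp = _joint_logp(ifv, *args)
        if new_logp < logp - 1e-6 * max(1.0, abs(logp)):
            raise AssertionError(
                f"ICM joint log-probability decreased: {logp} -> {new_logp}"
            )
        trace.append(new_logp)
        n_sweeps += 1
        if abs(new_logp - logp) < params.tol * max(1.0, abs(logp)):
            logp = new_logp
            break
        logp = new_logp

    out = (ifv + ifv.T) / 2.0
    out[cellmask] = 0.0
    return MRFResult(
        IFMatrix(out, normalized=True, mask=mask),
        n_sweeps,
        np.asarray(trace),
        bset,
        frozen,
    )
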