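"""Interaction-frequency estimators with a scikit-learn-style interface.

Each estimator takes a raw symmetric read-count matrix (``ReadCountMatrix``
or integer ndarray), internally estimates fragment biases, normalizes, and
produces an interaction-frequency estimate:

>>> est = MRFSmoother()
>>> smoothed = est.fit_transform(rc)          # ndarray estimate
>>> est.if_matrix_                            # IFMatrix with mask/flag
>>> est.n_sweeps_, est.logp_trace_            # ICM diagnostics

Estimators are transductive: nothing is carried from one matrix to another,
so ``transform`` simply runs the estimator on its argument.  They follow
the sklearn parameter conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone

from .bias import compute_fragment_bias, denormalize, normalize
from .matrix import IFMatrix, ReadCountMatrix
from .mrf import MRFParams, detect_transition_boundaries, estimate_mrf
from .smoothing import (
    DEFAULT_H_MAX,
    DEFAULT_MINIMUM_COUNT,
    adaptive_bandwidth,
    estimate_akde,
    estimate_fixed_binning,
    estimate_kde,
)

__all__ = [
    "FixedBinning",
    "KDESmoother",
    "AdaptiveKDESmoother",
    "MRFSmoother",
    "make_estimator",
    "clone_estimator",
]


class BaseIFEstimator(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing: bias estimation, normalization, and
    optional re-application of biases to the output (``normalized_output``
    False gives raw-scale estimates for held-out comparison against counts).
    """

    def __init__(self, normalized_output: bool = True, min_row_sum: int = 1):
        self.normalized_output = normalized_output
        self.min_row_sum = min_row_sum

    # -- subclass hook -----------------------------------------------------
    def _estimate(self, rc: ReadCountMatrix, nrc: IFMatrix) -> IFMatrix:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    @staticmethod
    def _as_rc(X) -> ReadCountMatrix:
        if isinstance(X, ReadCountMatrix):
            return X
        return ReadCountMatrix(np.asarray(X))

    def fit(self, X, y=None):
        rc = self._as_rc(X)
        self.n_fragments_ = rc.n
        self.bias_ = compute_fragment_bias(rc, self.min_row_sum)
        self.mask_ = self.bias_.mask
        nrc = normalize(rc, self.bias_)
        ifm = self._estimate(rc, nrc)
        if not self.normalized_output:
            ifm = denormalize(ifm, self.bias_)
        self.if_matrix_ = ifm
        return self

    def transform(self, X) -> np.ndarray:
        """Estimate the IF matrix of ``X`` (transductive; re-runs on X)."""
        if not hasattr(self, "if_matrix_"):
            raise RuntimeError("estimator is not fitted")
        rc = self._as_rc(X)
        return type(self)(**self.get_params()).fit(rc).if_matrix_.values

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).if_matrix_.values


class FixedBinning(BaseIFEstimator):
    """Fixed-binning estimate: mean nRC over blocks of ``bin_size``
    consecutive fragments on each axis; bin_size 1 is the identity."""

    def __init__(self, bin_size: int = 1, normalized_output: bool = True,
                 min_row_sum: int = 1):
        super().__init__(normalized_output, min_row_sum)
        self.bin_size = bin_size

    def _estimate(self, rc, nrc):
        return estimate_fixed_binning(nrc, self.bin_size)


class KDESmoother(BaseIFEstimator):
    """Fixed-bandwidth truncated-Gaussian KDE of nRC (window +-3h)."""

    def __init__(self, bandwidth: int = 1, normalized_output: bool = True,
                 min_row_sum: int = 1):
        super().__init__(normalized_output, min_row_sum)
        self.bandwidth = bandwidth

    def _estimate(self, rc, nrc):
        return estimate_kde(nrc, self.bandwidth)


class AdaptiveKDESmoother(BaseIFEstimator):
    """Adaptive-bandwidth KDE: the smallest per-cell bandwidth whose raw-
    count window coverage reaches ``minimum_count`` (default 100)."""

    def __init__(self, minimum_count: int = DEFAULT_MINIMUM_COUNT,
                 h_max: int = DEFAULT_H_MAX, normalized_output: bool = True,
                 min_row_sum: int = 1):
        super().__init__(normalized_output, min_row_sum)
        self.minimum_count = minimum_count
        self.h_max = h_max

    def _estimate(self, rc, nrc):
        field = adaptive_bandwidth(rc, self.minimum_count, self.h_max)
        self.bandwidth_field_ = field
        return estimate_akde(rc, nrc, bandwidth_field=field)


class MRFSmoother(BaseIFEstimator):
    """Markov-random-field MAP estimate via iterated conditional modes.

    Initialized from the adaptive-KDE estimate; KS transition boundaries
    detected on nRC are held fixed during the sweeps.  Fitted diagnostics:
    ``n_sweeps_``, ``logp_trace_``, ``boundaries_``, ``frozen_``.
    """

    def __init__(self, alpha: float = 0.2, likelihood: str = "poisson",
                 variance_multiplier: float = 1.0, tol: float = 1e-3,
                 max_iter: int = 50, ks_threshold: float = 1.5,
                 segment_len: int = 8,
                 minimum_count: int = DEFAULT_MINIMUM_COUNT,
                 h_max: int = DEFAULT_H_MAX, update_order: str = "raster",
                 random_state: int | None = None,
                 normalized_output: bool = True, min_row_sum: int = 1):
        super().__init__(normalized_output, min_row_sum)
        self.alpha = alpha
        self.likelihood = likelihood
        self.variance_multiplier = variance_multiplier
        self.tol = tol
        self.max_iter = max_iter
        self.ks_threshold = ks_threshold
        self.segment_len = segment_len
        self.minimum_count = minimum_count
        self.h_max = h_max
        self.update_order = update_order
        self.random_state = random_state

    def _params(self) -> MRFParams:
        return MRFParams(
            alpha=self.alpha, likelihood=self.likelihood,
            variance_multiplier=self.variance_multiplier, tol=self.tol,
            max_iter=self.max_iter, ks_threshold=self.ks_threshold,
            segment_len=self.segment_len, update_order=self.update_order,
            seed=self.random_state,
        )

    def _estimate(self, rc, nrc):
        params = self._params()
        init = estimate_akde(rc, nrc, self.minimum_count, self.h_max)
        boundaries = detect_transition_boundaries(
            nrc, self.ks_threshold, self.segment_len
        )
        res = estimate_mrf(
            rc, self.bias_, init=init, params=params, boundaries=boundaries,
            nrc=nrc, minimum_count=self.minimum_count, h_max=self.h_max,
        )
        self.n_sweeps_ = res.n_sweeps
        self.logp_trace_ = res.logp_trace
        self.boundaries_ = res.boundaries
        self.frozen_ = res.frozen
        self.init_ = init
        return res.if_matrix


_SPECS = {
    "fixed": (FixedBinning, "bin_size", int),
    "kde": (KDESmoother, "bandwidth", int),
    "akde": (AdaptiveKDESmoother, "minimum_count", int),
    "mrf": (MRFSmoother, "alpha", float),
}


def make_estimator(spec: str, **kwargs) -> BaseIFEstimator:
    """Build an estimator from a compact spec string such as ``"fixed:4"``,
    ``"kde:2"``, ``"akde"`` or ``"mrf"`` (the optional value after ``:``
    sets the estimator's primary parameter)."""
    name, _, arg = spec.partition(":")
    name = name.strip().lower()
    if name not in _SPECS:
        raise ValueError(f"unknown estimator spec {spec!r}")
    cls, param, conv = _SPECS[name]
    if arg:
        kwargs.setdefault(param, conv(arg))
    return cls(**kwargs)


def clone_estimator(est: BaseIFEstimator, **overrides) -> BaseIFEstimator:
    """Unfitted copy of an estimator with parameter overrides."""
    new = clone(est)
    if overrides:
        new.set_params(**overrides)
    return new
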