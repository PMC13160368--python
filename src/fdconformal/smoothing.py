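"""Neighborhood smoothing: leave-self-out kernel-weighted averaging.

The estimator replaces each response by a weighted mean of the others,
with weights ``K(d(X_i, X_i') / h)`` computed from a distance matrix
between functional predictors — a Nadaraya–Watson scheme on a general
metric space.  Bandwidths are tuned by minimising conformal prediction
interval length, either globally (one h) or locally (one h per time
point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .elastic import InvalidInputError
from .partial import DistanceMatrix

DEFAULT_BETA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


def _kernel(u: np.ndarray, name: str) -> np.ndarray:
    if name == "gaussian":
        return np.exp(-0.5 * u**2)
    if name == "triangular":
        return np.maximum(1.0 - np.abs(u), 0.0)
    raise InvalidInputError(f"unknown kernel {name!r}")


@dataclass
class SmootherConfig:
    """Kernel, bandwidth (or candidate rule) and tuning mode."""

    kernel: str = "gaussian"
    bandwidth: float | None = None
    tuning: str = "local"  # "global" | "local"
    candidate_rule: str = "distance_quantiles"  # or "fixed_grid"
    beta_grid: tuple = DEFAULT_BETA_GRID
    fixed_grid: tuple = ()

    def __post_init__(self):
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise InvalidInputError("bandwidth must be positive")
        if any(not (0.0 < b < 1.0) for b in self.beta_grid):
            raise InvalidInputError("beta values must lie in (0, 1)")


def kernel_weights(D: np.ndarray, h: float, kernel: str = "gaussian") -> np.ndarray:
    """Row-stochastic leave-self-out weight matrix from distances.

    Rows whose kernel weights all underflow fall back to the uniform mean
    of the other rows (degenerate-bandwidth contract), with a warning.
    """
    if h <= 0:
        raise InvalidInputError("bandwidth must be positive")
    K = _kernel(np.asarray(D, dtype=np.float64) / h, kernel)
    np.fill_diagonal(K, 0.0)
    rowsum = K.sum(axis=1)
    bad = rowsum <= 0.0
    if bad.any():
        warnings.warn("kernel weights underflowed; falling back to uniform mean")
        K[bad] = 1.0
        np.fill_diagonal(K, 0.0)
        rowsum = K.sum(axis=1)
    return K / rowsum[:, None]


def smooth_estimate(D: DistanceMatrix | np.ndarray, Y: np.ndarray, config: SmootherConfig) -> np.ndarray:
    """Leave-self-out smoothed responses ``Yhat = W Y`` (applied column-wise)."""
    Dm = D.entries if isinstance(D, DistanceMatrix) else np.asarray(D)
    if config.bandwidth is None:
        raise InvalidInputError("smooth_estimate needs an explicit bandwidth")
    W = kernel_weights(Dm, config.bandwidth, config.kernel)
    return W @ np.asarray(Y, dtype=np.float64)


def candidate_bandwidths(
    D: DistanceMatrix | np.ndarray,
    rule: str = "distance_quantiles",
    beta_grid=DEFAULT_BETA_GRID,
    fixed_grid=(),
) -> np.ndarray:
    """Candidate set of bandwidths.

    ``distance_quantiles`` takes lower-beta quantiles of the strictly-
    upper-triangle distances for a grid of beta; zero/duplicate candidates
    are dropped.
    """
    if rule == "fixed_grid":
        hs = np.asarray(sorted(set(float(h) for h in fixed_grid if h > 0)))
        if hs.size == 0:
            raise InvalidInputError("empty fixed bandwidth grid")
        return hs
    Dm = D.entries if isinstance(D, DistanceMatrix) else np.asarray(D)
    iu = np.triu_indices(Dm.shape[0], k=1)
    vals = Dm[iu]
    if not np.any(vals > 0):
        raise InvalidInputError("all distances are zero; cannot form candidates")
    hs = np.quantile(vals, np.asarray(beta_grid))
    hs = np.unique(hs[hs > 0])
    return hs


def tune_bandwidth(conformal_runner, candidates, mode: str = "global"):
    """Pick the bandwidth(s) minimising prediction-interval length.

    ``conformal_runner(h)`` must return a per-time-point vector of PI
    lengths.  Global mode minimises the time-averaged length; local mode
    minimises per time point.  Ties break toward the smallest candidate;
    all candidate length profiles are returned for audit.
    """
    candidates = np.sort(np.asarray(list(candidates), dtype=np.float64))
    if candidates.size == 0:
        raise InvalidInputError("empty candidate set")
    lengths = np.stack([np.asarray(conformal_runner(h), dtype=np.float64) for h in candidates])
    if mode == "global":
        idx = int(np.argmin(np.nanmean(lengths, axis=1)))
        return candidates[idx], lengths
    if mode == "local":
        idx = np.argmin(lengths, axis=0)
        return candidates[idx], lengths
    raise InvalidInputError(f"unknown tuning mode {mode!r}")
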