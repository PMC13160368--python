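"""Partial functional observations and distances between them.

A complete function may be observed on an initial interval [0, U], on a
union of disjoint fragments, or only at sparse time points.  Neighborhood
smoothing needs a distance between predictors that share one such
observation scheme: L2 or Fisher–Rao on the common sub-domain, the
registration-based amplitude distance, the weighted per-fragment product
distance, or plain Euclidean distance on sparse value vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from . import elastic
from .elastic import FunctionalSample, InvalidInputError

METRICS = ("l2", "fr", "amplitude")


@dataclass(frozen=True)
class RegimeDescriptor:
    """Which part of the domain is observed (the same for every predictor)."""

    regime: str  # "interval" | "fragmented" | "sparse"
    U: float | None = None
    fragments: tuple = ()  # ((lo, hi), ...) disjoint, ordered
    weights: tuple = ()  # lambda_j, sum to 1
    points: tuple = ()  # sparse sample times

    def __post_init__(self):
        if self.regime == "interval":
            if self.U is None or not (0.0 <= self.U <= 1.0):
                raise InvalidInputError("interval regime needs U in [0, 1]")
        elif self.regime == "fragmented":
            frs = tuple((float(a), float(b)) for a, b in self.fragments)
            if not frs:
                raise InvalidInputError("fragmented regime needs fragments")
            for (a, b) in frs:
                if not (0.0 <= a < b <= 1.0):
                    raise InvalidInputError("fragments must be ordered within [0, 1]")
            for (_, b), (a2, _) in zip(frs, frs[1:]):
                if a2 < b:
                    raise InvalidInputError("fragments must be disjoint and ordered")
            w = self.weights or tuple(1.0 / len(frs) for _ in frs)
            w = tuple(float(x) for x in w)
            if len(w) != len(frs) or abs(sum(w) - 1.0) > 1e-8:
                raise InvalidInputError("fragment weights must sum to 1")
            object.__setattr__(self, "fragments", frs)
            object.__setattr__(self, "weights", w)
        elif self.regime == "sparse":
            pts = tuple(float(p) for p in self.points)
            if not pts or any(p < 0 or p > 1 for p in pts) or np.any(np.diff(pts) <= 0):
                raise InvalidInputError("sparse regime needs ordered points in [0, 1]")
            object.__setattr__(self, "points", pts)
        else:
            raise InvalidInputError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class PartialObservation:
    """A function restricted to the observed sub-domain."""

    descriptor: RegimeDescriptor
    # interval: one (subgrid, values) pair; fragmented: one per fragment;
    # sparse: subgrid is the sample points themselves.
    subgrids: tuple = field(default=())
    pieces: tuple = field(default=())

    @property
    def regime(self) -> str:
        return self.descriptor.regime

    def stacked_values(self) -> np.ndarray:
        return np.concatenate(self.pieces)


def restrict(f: FunctionalSample, descriptor: RegimeDescriptor) -> PartialObservation:
    """Cut a complete function down to the observed sub-domain.

    Interval/fragment regimes keep the grid points lying inside the closed
    sub-intervals; the sparse regime interpolates at the listed points.
    """
    t, v = f.grid, f.values
    if descriptor.regime == "interval":
        mask = t <= descriptor.U + 1e-12
        if not mask.any():
            raise InvalidInputError("empty observed set")
        return PartialObservation(
            descriptor=descriptor, subgrids=(t[mask],), pieces=(v[mask],)
        )
    if descriptor.regime == "fragmented":
        grids, pieces = [], []
        for (a, b) in descriptor.fragments:
            mask = (t >= a - 1e-12) & (t <= b + 1e-12)
            if not mask.any():
                raise InvalidInputError(f"fragment [{a}, {b}] contains no grid points")
            grids.append(t[mask])
            pieces.append(v[mask])
        return PartialObservation(
            descriptor=descriptor, subgrids=tuple(grids), pieces=tuple(pieces)
        )
    pts = np.asarray(descriptor.points)
    return PartialObservation(
        descriptor=descriptor, subgrids=(pts,), pieces=(np.interp(pts, t, v),)
    )


def _rescaled_sample(sub_t: np.ndarray, vals: np.ndarray) -> FunctionalSample:
    # affinely map the common sub-domain onto [0,1] so Gamma is well defined
    lo, hi = sub_t[0], sub_t[-1]
    if hi - lo < 1e-12:
        raise InvalidInputError("sub-domain too short for elastic distances")
    return FunctionalSample(grid=(sub_t - lo) / (hi - lo), values=vals)


def _piece_distance(sub_t, v1, v2, metric: str) -> float:
    if metric == "l2":
        return float(np.sqrt(np.trapezoid((v1 - v2) ** 2, sub_t)))
    f1 = _rescaled_sample(sub_t, v1)
    f2 = _rescaled_sample(sub_t, v2)
    if metric == "fr":
        return elastic.fisher_rao_distance(f1, f2)
    if metric == "amplitude":
        d12 = elastic.amplitude_distance(f1, f2)
        d21 = elastic.amplitude_distance(f2, f1)
        return 0.5 * (d12 + d21)
    raise InvalidInputError(f"unknown metric {metric!r}")


def partial_distance(x1: PartialObservation, x2: PartialObservation, metric: str = "l2") -> float:
    """Distance between two observations sharing the same scheme.

    Fragmented observations combine per-fragment distances with the
    descriptor weights; sparse observations use the Euclidean distance on
    the value vectors.  The amplitude metric is symmetrised by averaging
    the two directed registrations.
    """
    if x1.descriptor != x2.descriptor:
        raise InvalidInputError("observations have different schemes")
    if x1.regime == "sparse":
        d = np.asarray(x1.pieces[0]) - np.asarray(x2.pieces[0])
        return float(np.sqrt(np.sum(d**2)))
    if x1.regime == "interval":
        return _piece_distance(x1.subgrids[0], x1.pieces[0], x2.pieces[0], metric)
    acc = 0.0
    for w, sub_t, p1, p2 in zip(x1.descriptor.weights, x1.subgrids, x1.pieces, x2.pieces):
        acc += w * _piece_distance(sub_t, p1, p2, metric)
    return acc


@dataclass(frozen=True)
class DistanceMatrix:
    entries: np.ndarray
    metric_name: str


def _trapezoid_weights(sub_t: np.ndarray) -> np.ndarray:
    w = np.zeros_like(sub_t)
    d = np.diff(sub_t)
    w[:-1] += 0.5 * d
    w[1:] += 0.5 * d
    return w


def distance_matrix(xs: list[PartialObservation], metric: str = "l2") -> DistanceMatrix:
    """Symmetric distance matrix over observations (zero diagonal).

    L2 and sparse distances are weighted-Euclidean and computed in one
    vectorised pass; fr/amplitude fall back to pairwise evaluation.
    """
    n = len(xs)
    if n < 2:
        raise InvalidInputError("need at least two observations")
    regime = xs[0].regime
    if regime == "sparse" or (metric == "l2" and regime in ("interval", "fragmented")):
        if regime == "sparse":
            V = np.stack([x.pieces[0] for x in xs])
            D = squareform(pdist(V))
        elif regime == "interval":
            V = np.stack([x.pieces[0] for x in xs])
            w = _trapezoid_weights(xs[0].subgrids[0])
            D = squareform(pdist(V * np.sqrt(w)))
        else:
            D = np.zeros((n, n))
            for j, (lam, sub_t) in enumerate(zip(xs[0].descriptor.weights, xs[0].subgrids)):
                V = np.stack([x.pieces[j] for x in xs])
                w = _trapezoid_weights(sub_t)
                D += lam * squareform(pdist(V * np.sqrt(w)))
        return DistanceMatrix(entries=D, metric_name=metric)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = partial_distance(xs[i], xs[j], metric)
    return DistanceMatrix(entries=D, metric_name=metric)
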