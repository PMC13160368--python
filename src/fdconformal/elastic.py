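"""Elastic (Fisher–Rao / SRSF) machinery for registration of functions on [0,1].

A function ``f`` is represented by its square-root slope function (SRSF)
``q = sign(f') sqrt(|f'|)``, under which the Fisher–Rao metric reduces to
the ordinary L2 metric and warping acts by the isometric group action
``(q, gamma) -> (q o gamma) sqrt(gamma')``.  Pairwise registration finds
the warping minimising the SRSF L2 distance by dynamic programming;
multiple registration aligns a sample to its Karcher mean template.

Derivatives are estimated with centred finite differences (one-sided at
the boundaries, :func:`numpy.gradient`) consistently everywhere so that
the group action commutes with the SRSF transform up to discretisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._dp import dp_warp

SLOPE_EPS = 1e-8
#: default slope bound for the DP path set; segment slopes lie in [1/K_MAX, K_MAX]
K_MAX = 4


class InvalidInputError(ValueError):
    """Raised for non-finite or structurally inconsistent functional inputs."""


class InvalidWarpingError(ValueError):
    """Raised when a warping violates boundary or monotonicity constraints."""


def uniform_grid(T: int) -> np.ndarray:
    """Uniform grid of ``T`` points on [0, 1]."""
    if T < 2:
        raise InvalidInputError("grid needs at least 2 points")
    return np.linspace(0.0, 1.0, T)


def _check_grid(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    if t.ndim != 1 or t.size < 2:
        raise InvalidInputError("grid must be a 1-d vector with T >= 2")
    if not np.all(np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise InvalidInputError("grid must be finite and strictly increasing")
    if abs(t[0]) > 1e-12 or abs(t[-1] - 1.0) > 1e-12:
        raise InvalidInputError("grid must span [0, 1]")
    return t


@dataclass(frozen=True)
class FunctionalSample:
    """One function's values on a time grid over [0, 1]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = _check_grid(self.grid)
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != t.shape:
            raise InvalidInputError("values and grid lengths differ")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("non-finite function values")
        object.__setattr__(self, "grid", t)
        object.__setattr__(self, "values", v)

    @property
    def T(self) -> int:
        return self.grid.size


@dataclass(frozen=True)
class SRSF:
    """Square-root slope representation; ``origin`` stores f(0) for inversion."""

    grid: np.ndarray
    values: np.ndarray
    origin: float = 0.0


@dataclass(frozen=True)
class Warping:
    """Discretised boundary-preserving diffeomorphism of [0, 1]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = _check_grid(self.grid)
        g = np.asarray(self.values, dtype=np.float64)
        if g.shape != t.shape:
            raise InvalidWarpingError("warping values and grid lengths differ")
        if abs(g[0]) > 1e-9 or abs(g[-1] - 1.0) > 1e-9:
            raise InvalidWarpingError("warping must fix the endpoints 0 and 1")
        if np.any(np.diff(g) / np.diff(t) <= SLOPE_EPS):
            raise InvalidWarpingError("warping slopes must be positive")
        object.__setattr__(self, "grid", t)
        object.__setattr__(self, "values", g)


@dataclass(frozen=True)
class RegistrationResult:
    """Output of pairwise registration of f2 onto f1."""

    warping: Warping
    aligned: FunctionalSample
    amplitude_distance: float
    dp_cost: float = 0.0


@dataclass
class KarcherMeanResult:
    """Template SRSF/function plus per-sample phases and amplitudes."""

    mean_srsf: SRSF
    mean_function: FunctionalSample
    relative_phases: list
    aligned_functions: list
    n_iterations: int
    converged: bool
    objective_trace: list = field(default_factory=list)


def _values(f) -> np.ndarray:
    return f.values if hasattr(f, "values") else np.asarray(f, dtype=np.float64)


def srsf_transform(f: FunctionalSample) -> SRSF:
    """SRSF ``q = sign(f') sqrt(|f'|)`` with derivative by centred differences."""
    v, t = f.values, f.grid
    df = np.gradient(v, t)
    q = np.sign(df) * np.sqrt(np.abs(df))
    return SRSF(grid=t, values=q, origin=float(v[0]))


def srsf_inverse(q: SRSF) -> FunctionalSample:
    """Reconstruct f by cumulative trapezoidal integration of ``q |q|``."""
    integrand = q.values * np.abs(q.values)
    v = q.origin + cumulative_trapezoid(integrand, q.grid, initial=0.0)
    return FunctionalSample(grid=q.grid, values=v)


def identity_warping(t: np.ndarray) -> Warping:
    t = np.asarray(t, dtype=np.float64)
    return Warping(grid=t, values=t.copy())


def warp_function(f: FunctionalSample, gamma: Warping) -> FunctionalSample:
    """Compose ``f o gamma`` by linear interpolation at the warped abscissae."""
    g = np.clip(gamma.values, 0.0, 1.0)
    return FunctionalSample(grid=f.grid, values=np.interp(g, f.grid, f.values))


def invert_warping(gamma: Warping) -> Warping:
    """Numerical inverse by swapping axes and re-interpolating onto the grid."""
    t = gamma.grid
    inv = np.interp(t, gamma.values, t)
    inv[0], inv[-1] = 0.0, 1.0
    return Warping(grid=t, values=inv)


def compose_warpings(g1: Warping, g2: Warping) -> Warping:
    """``g1 o g2`` on the common grid."""
    v = np.interp(g2.values, g1.grid, g1.values)
    v[0], v[-1] = 0.0, 1.0
    return Warping(grid=g1.grid, values=v)


def group_action_srsf(q: SRSF, gamma: Warping) -> SRSF:
    """Isometric action ``(q o gamma) sqrt(gamma')`` on SRSF space."""
    gdot = np.gradient(gamma.values, gamma.grid)
    qg = np.interp(np.clip(gamma.values, 0.0, 1.0), q.grid, q.values)
    return SRSF(grid=q.grid, values=qg * np.sqrt(np.maximum(gdot, 0.0)), origin=q.origin)


def l2_distance(x: np.ndarray, y: np.ndarray, t: np.ndarray) -> float:
    return float(np.sqrt(np.trapezoid((x - y) ** 2, t)))


def _is_degenerate(q: np.ndarray, t: np.ndarray) -> bool:
    return np.trapezoid(q**2, t) < 1e-14


def _dp_warping(q1: np.ndarray, q2: np.ndarray, t: np.ndarray, k_max: int,
                refine: int) -> tuple[np.ndarray, float]:
    """DP-optimal warping, optionally on a ``refine``-times finer grid.

    Refinement reduces the slope-quantisation jitter of the lattice path
    (important near sharp features); the warping is sampled back onto the
    native grid.
    """
    if refine <= 1:
        return dp_warp(q1, q2, t, k_max=k_max)
    Tf = (t.size - 1) * refine + 1
    tf = np.linspace(0.0, 1.0, Tf)
    gv, cost = dp_warp(np.interp(tf, t, q1), np.interp(tf, t, q2), tf, k_max=k_max)
    return np.interp(t, tf, gv), cost


#: slope bound for quality-critical pairwise registration; the inverse of a
#: Beta(a, b) CDF warping has slopes well outside [1/4, 4] near the
#: endpoints, so the pairwise path set is wider than the Karcher default
ALIGN_K_MAX = 6


def pairwise_align(
    f1: FunctionalSample, f2: FunctionalSample, k_max: int = ALIGN_K_MAX,
    dp_refine: int = 2,
) -> RegistrationResult:
    """Register ``f2`` onto ``f1``: the DP-optimal warping, the aligned
    function and the amplitude distance ``d_a``.

    The SRSFs used in the search are built from cubic-spline derivatives
    on a ``dp_refine``-times finer grid: centred differences on the native
    grid leave a discretisation floor in the objective that lets the
    minimiser wander, which shows up as jitter in the aligned function.
    The aligned values are also composed through the spline.  Constant
    (zero-SRSF) inputs carry no slope information; they are returned with
    the identity warping and a warning.
    """
    t = f1.grid
    q1, q2 = srsf_transform(f1), srsf_transform(f2)
    if _is_degenerate(q1.values, t) or _is_degenerate(q2.values, t):
        warnings.warn("degenerate (constant) input; returning identity warping")
        gamma = identity_warping(t)
        dp_cost = float(np.trapezoid((q1.values - q2.values) ** 2, t))
        aligned = warp_function(f2, gamma)
    elif dp_refine <= 1:
        gvals, dp_cost = dp_warp(q1.values, q2.values, t, k_max=k_max)
        gamma = Warping(grid=t, values=gvals)
        aligned = warp_function(f2, gamma)
    else:
        from scipy.interpolate import CubicSpline

        tf = np.linspace(0.0, 1.0, (t.size - 1) * dp_refine + 1)
        cs1, cs2 = CubicSpline(t, f1.values), CubicSpline(t, f2.values)
        d1, d2 = cs1(tf, 1), cs2(tf, 1)
        q1f = np.sign(d1) * np.sqrt(np.abs(d1))
        q2f = np.sign(d2) * np.sqrt(np.abs(d2))
        gvf, dp_cost = dp_warp(q1f, q2f, tf, k_max=k_max)
        gvals = np.interp(t, tf, gvf)
        gvals[0], gvals[-1] = 0.0, 1.0
        gamma = Warping(grid=t, values=gvals)
        aligned = FunctionalSample(grid=t, values=cs2(np.clip(gvals, 0.0, 1.0)))
    q2g = group_action_srsf(q2, gamma)
    return RegistrationResult(
        warping=gamma,
        aligned=aligned,
        amplitude_distance=l2_distance(q1.values, q2g.values, t),
        dp_cost=dp_cost,
    )


def amplitude_distance(f1: FunctionalSample, f2: FunctionalSample, k_max: int = K_MAX) -> float:
    """Warping-invariant distance ``d_a(f1, f2)``; only approximately symmetric
    because registration is directed (f2 onto f1)."""
    return pairwise_align(f1, f2, k_max=k_max).amplitude_distance


def fisher_rao_distance(f1: FunctionalSample, f2: FunctionalSample) -> float:
    """L2 distance between SRSFs (no registration); invariant under
    simultaneous warping of both arguments."""
    q1, q2 = srsf_transform(f1), srsf_transform(f2)
    return l2_distance(q1.values, q2.values, f1.grid)


def _interval_slopes(values: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.diff(values, axis=-1) / np.diff(t)


def warping_distance(g1: Warping | np.ndarray, g2: Warping | np.ndarray, t=None) -> float:
    """Geodesic distance on the warping group.

    Under the SRSF map ``q_gamma = sqrt(gamma')`` warpings live on the unit
    Hilbert sphere, so ``d_w = arccos <q_1, q_2>``.  Slopes are forward
    differences treated as piecewise constant on the grid intervals; the
    inner product is clipped to [-1, 1] before arccos.
    """
    if t is None:
        t = g1.grid
    v1, v2 = _values(g1), _values(g2)
    s1 = np.sqrt(np.maximum(_interval_slopes(v1, t), 0.0))
    s2 = np.sqrt(np.maximum(_interval_slopes(v2, t), 0.0))
    ip = float(np.sum(s1 * s2 * np.diff(t)))
    return float(np.arccos(np.clip(ip, -1.0, 1.0)))


def karcher_mean(
    functions: list,
    max_iter: int = 20,
    tol: float = 1e-2,
    k_max: int = K_MAX,
    dp_refine: int = 1,
) -> KarcherMeanResult:
    """Sample Karcher mean under the elastic metric.

    Alternates aligning every SRSF to the current template with updating
    the template as the cross-sectional mean of the aligned SRSFs, until
    the relative change of the objective ``sum_i ||q_i* - qbar||^2`` drops
    below ``tol``.  The template is initialised at the input SRSF closest
    to the cross-sectional SRSF mean, and the relative phases are centred
    afterwards so their cross-sectional mean is (approximately) the
    identity.
    """
    if len(functions) == 0:
        raise InvalidInputError("need at least one function")
    t = functions[0].grid
    n = len(functions)
    qs = [srsf_transform(f) for f in functions]
    f0_mean = float(np.mean([f.values[0] for f in functions]))

    if n == 1:
        gam = identity_warping(t)
        return KarcherMeanResult(
            mean_srsf=qs[0],
            mean_function=functions[0],
            relative_phases=[gam],
            aligned_functions=[functions[0]],
            n_iterations=0,
            converged=True,
            objective_trace=[0.0],
        )

    qmat = np.stack([q.values for q in qs])
    qbar0 = qmat.mean(axis=0)
    init = int(np.argmin([np.trapezoid((qv - qbar0) ** 2, t) for qv in qmat]))
    mq = qmat[init].copy()

    gammas = [identity_warping(t) for _ in range(n)]
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned_q = np.empty_like(qmat)
        for i in range(n):
            if _is_degenerate(qmat[i], t):
                gammas[i] = identity_warping(t)
                aligned_q[i] = qmat[i]
                continue
            gvals, _ = _dp_warping(mq, qmat[i], t, k_max, dp_refine)
            gammas[i] = Warping(grid=t, values=gvals)
            aligned_q[i] = group_action_srsf(qs[i], gammas[i]).values
        obj = float(np.sum([np.trapezoid((aq - mq) ** 2, t) for aq in aligned_q]))
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - obj) <= tol * max(obj, 1e-12):
            converged = True
            mq = aligned_q.mean(axis=0)
            break
        mq = aligned_q.mean(axis=0)
    if not converged:
        warnings.warn("Karcher mean did not converge; using last iterate")

    # centre phases: compose out the mean warping (identifiability convention)
    mean_gamma = Warping(grid=t, values=np.mean([g.values for g in gammas], axis=0))
    inv_mean = invert_warping(mean_gamma)
    mq = group_action_srsf(SRSF(grid=t, values=mq), inv_mean).values
    gammas = [compose_warpings(g, inv_mean) for g in gammas]
    aligned_f = [warp_function(f, g) for f, g in zip(functions, gammas)]

    mean_q = SRSF(grid=t, values=mq, origin=f0_mean)
    return KarcherMeanResult(
        mean_srsf=mean_q,
        mean_function=srsf_inverse(mean_q),
        relative_phases=gammas,
        aligned_functions=aligned_f,
        n_iterations=it,
        converged=converged,
        objective_trace=trace,
    )
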