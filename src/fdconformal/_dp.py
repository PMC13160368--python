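"""Dynamic-programming kernel for pairwise SRSF alignment.

The warping search space is the set of piecewise-linear monotone lattice
paths on the T x T sample grid whose segments are coprime steps
``(di, dj)`` with ``max(di, dj) <= k_max`` (so segment slopes lie in
``[1/k_max, k_max]``).  The cost of a segment is the trapezoidal
approximation of ``int (q1(t) - q2(gamma(t)) sqrt(gamma'))^2 dt`` sampled
at the native grid points it spans.  Ties are broken toward the identity
diagonal by trying the most diagonal step first and keeping the first
minimum.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def step_set(k_max: int = 4) -> np.ndarray:
    """Coprime step pairs ``(di, dj)`` with components in ``1..k_max``.

    Ordered by distance from the diagonal so that the DP's first-minimum
    tie-break prefers paths hugging the identity.
    """
    steps = []
    for di in range(1, k_max + 1):
        for dj in range(1, k_max + 1):
            if np.gcd(di, dj) == 1:
                steps.append((di, dj))
    steps.sort(key=lambda s: (abs(s[0] - s[1]), s[0] + s[1], s[0]))
    return np.asarray(steps, dtype=np.int64)


@njit(cache=True)
def _segment_cost(q1, q2, t, i0, j0, i1, j1):
    """Cost of the linear path segment (i0,j0) -> (i1,j1).

    Assumes a uniform grid (enforced by the caller): interpolation of q2
    at the warped abscissae indexes directly into the grid.
    """
    T = t.shape[0]
    dt = t[1] - t[0]
    m = (t[j1] - t[j0]) / (t[i1] - t[i0])
    sm = np.sqrt(m)
    npts = i1 - i0 + 1
    prev = 0.0
    acc = 0.0
    for p in range(npts):
        gp = t[j0] + m * dt * p
        pos = gp / dt
        lo = int(pos)
        if lo >= T - 1:
            q2g = q2[T - 1]
        else:
            w = pos - lo
            q2g = (1.0 - w) * q2[lo] + w * q2[lo + 1]
        diff = q1[i0 + p] - q2g * sm
        cur = diff * diff
        if p > 0:
            acc += 0.5 * (prev + cur) * dt
        prev = cur
    return acc


@njit(cache=True)
def _dp_tables(q1, q2, t, steps):
    T = t.shape[0]
    big = np.inf
    E = np.full((T, T), big)
    ptr = np.full((T, T, 2), -1, dtype=np.int64)
    E[0, 0] = 0.0
    for i in range(1, T):
        for j in range(1, T):
            best = big
            bi = -1
            bj = -1
            for s in range(steps.shape[0]):
                i0 = i - steps[s, 0]
                j0 = j - steps[s, 1]
                if i0 < 0 or j0 < 0:
                    continue
                if not np.isfinite(E[i0, j0]):
                    continue
                c = E[i0, j0] + _segment_cost(q1, q2, t, i0, j0, i, j)
                if c < best:
                    best = c
                    bi = i0
                    bj = j0
            E[i, j] = best
            ptr[i, j, 0] = bi
            ptr[i, j, 1] = bj
    return E, ptr


def dp_warp(q1: np.ndarray, q2: np.ndarray, t: np.ndarray, k_max: int = 4):
    """Optimal warping registering ``q2`` to ``q1`` over the lattice path set.

    Returns ``(gamma, cost)`` where ``gamma`` is the warping evaluated on
    ``t`` and ``cost`` the DP objective at the optimum.
    """
    t = np.asarray(t, dtype=np.float64)
    d = np.diff(t)
    if np.max(np.abs(d - d[0])) > 1e-9 * max(d[0], 1e-12):
        raise ValueError("dynamic-programming alignment requires a uniform grid")
    steps = step_set(k_max)
    E, ptr = _dp_tables(
        np.ascontiguousarray(q1, dtype=np.float64),
        np.ascontiguousarray(q2, dtype=np.float64),
        np.ascontiguousarray(t, dtype=np.float64),
        steps,
    )
    T = t.shape[0]
    path_i = [T - 1]
    path_j = [T - 1]
    i, j = T - 1, T - 1
    while (i, j) != (0, 0):
        i, j = int(ptr[i, j, 0]), int(ptr[i, j, 1])
        if i < 0:  # unreachable terminal: fall back to identity
            return t.copy(), float(np.trapezoid((q1 - q2) ** 2, t))
        path_i.append(i)
        path_j.append(j)
    path_i.reverse()
    path_j.reverse()
    gamma = np.interp(t, t[np.asarray(path_i)], t[np.asarray(path_j)])
    return gamma, float(E[T - 1, T - 1])


def brute_force_cost(q1: np.ndarray, q2: np.ndarray, t: np.ndarray, k_max: int = 4) -> float:
    """Exhaustive minimum over the DP's admissible path set (oracle; tiny T only)."""
    steps = step_set(k_max)
    T = t.shape[0]
    q1 = np.asarray(q1, dtype=np.float64)
    q2 = np.asarray(q2, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    best = [np.inf]

    def recurse(i, j, acc):
        if acc >= best[0]:
            return
        if i == T - 1 and j == T - 1:
            best[0] = acc
            return
        for di, dj in steps:
            i1, j1 = i + di, j + dj
            if i1 >= T or j1 >= T:
                continue
            recurse(i1, j1, acc + _segment_cost(q1, q2, t, i, j, i1, j1))

    recurse(0, 0, 0.0)
    return float(best[0])
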