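"""Conformal prediction bands for partially observed functional data.

Three engines share one augmentation scheme.  `FullConformalBand` (FFCP)
predicts a new function pointwise from its truncation and n complete
functions, with no registration.  `SplitConformalBand` (SFCP) first
computes the elastic Karcher mean of a training split, registers the
calibration split to it, and runs the same conformal engine with the
registered amplitudes as responses — the band then targets the amplitude
of the new function.  `SplitConformalPhase` (SFCPP) predicts the new
function's relative phase jointly on a coarse grid, scoring monotone
trial vectors with the geodesic warping distance.

All three give finite-sample marginal coverage at level 1 - alpha for
exchangeable data, by the standard full-conformal rank argument applied
to the leave-self-out neighborhood smoother (which is permutation
symmetric in the augmented sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from . import elastic
from .elastic import FunctionalSample, InvalidInputError
from .partial import (
    PartialObservation,
    RegimeDescriptor,
    distance_matrix,
    restrict,
)
from .smoothing import (
    DEFAULT_BETA_GRID,
    candidate_bandwidths,
    kernel_weights,
    tune_bandwidth,
)

_TIE_EPS = 1e-12


def conformal_quantile(scores: np.ndarray, alpha: float) -> float:
    """Lower (1-alpha) empirical quantile: the ceil((1-alpha) m)-th smallest
    of the m augmented scores."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.size == 0:
        raise InvalidInputError("empty score vector")
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError("alpha must be in (0, 1)")
    k = _quantile_index(s.size, alpha)
    return float(np.partition(s, k - 1)[k - 1])


def _quantile_index(m: int, alpha: float) -> int:
    return min(int(math.ceil((1.0 - alpha) * m)), m)


@dataclass
class TrialGrid:
    """Per-time-point uniform grids of trial response values.

    Each time point gets its own uniform grid spanning the responses
    observed there, padded by ``margin`` times the local range.  A local
    grid is essential: the conformal interval's width scales with the
    response spread at that time point, so a single global grid cannot
    resolve intervals in regions where the sample is nearly flat.
    """

    values: np.ndarray  # (T, n_points)
    n_points: int = 200
    margin: float = 0.25

    @classmethod
    def from_responses(cls, Y: np.ndarray, n_points: int = 200, margin: float = 0.25):
        lo = Y.min(axis=0)
        hi = Y.max(axis=0)
        span = np.maximum(hi - lo, 1e-12)
        grid = np.linspace(lo - margin * span, hi + margin * span, n_points, axis=-1)
        return cls(values=grid, n_points=n_points, margin=margin)


@dataclass
class PredictionBand:
    """Pointwise prediction intervals [lower, upper] at level 1 - alpha."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    lengths: np.ndarray
    alpha: float
    method: str
    empty: np.ndarray  # flags time points with an empty accepted set
    bandwidths: np.ndarray  # per-time-point bandwidth actually used
    trial_grid: np.ndarray | None = None
    accepted: np.ndarray | None = None  # raw accepted mask (T, G) at chosen h

    @property
    def midpoint(self) -> np.ndarray:
        """Point prediction: the per-time-point PI midpoint."""
        return 0.5 * (self.lower + self.upper)


@dataclass
class PhasePredictionSet:
    """Joint conformal prediction set of monotone warping trial vectors."""

    coarse_grid: np.ndarray
    accepted: np.ndarray  # (n_accepted, T_coarse)
    alpha: float
    envelope_lower: np.ndarray
    envelope_upper: np.ndarray
    point_prediction: np.ndarray
    trial_values: np.ndarray  # interior trial grid
    bandwidth: float
    empty: bool


@dataclass
class SplitPlan:
    """Train/calibration partition of n complete functions."""

    n1: int
    n2: int
    train_idx: np.ndarray
    calib_idx: np.ndarray
    seed: int | None = None

    @classmethod
    def make(cls, n: int, n1: int | None = None, rng: np.random.Generator | None = None, seed=None):
        if n1 is None:
            n1 = n // 2
        if not (0 < n1 < n):
            raise InvalidInputError("need 0 < n1 < n")
        rng = rng if rng is not None else np.random.default_rng(seed)
        perm = rng.permutation(n)
        return cls(n1=n1, n2=n - n1, train_idx=np.sort(perm[:n1]),
                   calib_idx=np.sort(perm[n1:]), seed=seed)


# ---------------------------------------------------------------------------
# shared pointwise band engine


def _pointwise_band_engine(D, Y_known, alpha, trial, hs, tuning, kernel, method):
    """Full-conformal acceptance over a trial grid, all rows augmented.

    ``Y_known`` holds the m-1 known response rows; the target row is the
    trial value.  ``trial`` is a (T, G) matrix of per-time-point trial
    grids.  For each bandwidth the smoother weight matrix is formed once
    and acceptance is evaluated for every (t, y) pair in one vectorised
    pass: with leave-self-out weights W, the augmented fit for row i is
    ``A_i(t) + W[i, -1] y`` where A uses the known rows only, so the
    scores are affine in y.
    """
    m = D.shape[0]
    T = Y_known.shape[1]
    G = trial.shape[1]
    hs = np.sort(np.asarray(hs, dtype=np.float64))
    H = hs.size
    k = _quantile_index(m, alpha)
    lower = np.full((H, T), np.nan)
    upper = np.full((H, T), np.nan)
    lengths = np.full((H, T), np.inf)
    accepted = np.zeros((H, T, G), dtype=bool)
    Y0 = np.vstack([Y_known, np.zeros((1, T))])
    rows = np.arange(T)
    for hi, h in enumerate(hs):
        W = kernel_weights(D, h, kernel)
        A = W @ Y0  # (m, T)
        wn = W[:-1, -1]  # weight of the target row in each known row's fit
        resid = Y_known - A[:-1]  # (m-1, T)
        S = np.abs(resid[:, :, None] - wn[:, None, None] * trial[None, :, :])
        S_new = np.abs(trial - A[-1][:, None])  # (T, G)
        allS = np.concatenate([S, S_new[None, :, :]], axis=0)  # (m, T, G)
        thr = np.partition(allS, k - 1, axis=0)[k - 1]  # (T, G)
        acc = S_new <= thr + _TIE_EPS
        accepted[hi] = acc
        any_acc = acc.any(axis=1)
        idx_first = np.argmax(acc, axis=1)
        idx_last = G - 1 - np.argmax(acc[:, ::-1], axis=1)
        lo = np.where(any_acc, trial[rows, idx_first], np.nan)
        up = np.where(any_acc, trial[rows, idx_last], np.nan)
        lower[hi], upper[hi] = lo, up
        lengths[hi] = np.where(any_acc, up - lo, np.inf)

    if H == 1:
        h_idx = np.zeros(T, dtype=int)
    else:
        table = {float(h): lengths[i] for i, h in enumerate(hs)}
        chosen, _ = tune_bandwidth(lambda h: table[float(h)], hs, mode=tuning)
        if tuning == "global":
            h_idx = np.full(T, int(np.searchsorted(hs, chosen)), dtype=int)
        else:
            h_idx = np.searchsorted(hs, chosen).astype(int)
    tk = np.arange(T)
    band = PredictionBand(
        grid=np.linspace(0.0, 1.0, T),
        lower=lower[h_idx, tk],
        upper=upper[h_idx, tk],
        lengths=np.where(np.isfinite(lengths[h_idx, tk]), lengths[h_idx, tk], 0.0),
        alpha=alpha,
        method=method,
        empty=~np.isfinite(lengths[h_idx, tk]),
        bandwidths=hs[h_idx],
        trial_grid=trial,
        accepted=accepted[h_idx, tk],
    )
    return band


def _as_matrix(functions) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(functions, np.ndarray):
        F = np.asarray(functions, dtype=np.float64)
        t = np.linspace(0.0, 1.0, F.shape[1])
        return F, t
    t = functions[0].grid
    return np.stack([f.values for f in functions]), t


def _partialize(x, descriptor, grid):
    if isinstance(x, PartialObservation):
        return x
    f = x if isinstance(x, FunctionalSample) else FunctionalSample(grid=grid, values=np.asarray(x))
    if descriptor is None:
        raise InvalidInputError("need a regime descriptor for a complete function")
    return restrict(f, descriptor)


# ---------------------------------------------------------------------------
# estimators


class _ConformalBase(BaseEstimator):
    def _more_tags(self):  # pragma: no cover
        return {"requires_y": False}

    def _candidates(self, D: np.ndarray) -> np.ndarray:
        if self.bandwidth is not None:
            return np.asarray([float(self.bandwidth)])
        return candidate_bandwidths(D, rule="distance_quantiles", beta_grid=self.beta_grid)


class FullConformalBand(_ConformalBase):
    """Full conformal prediction band without registration (FFCP).

    Fit on n complete functions on a common uniform grid; predict a
    pointwise band for a new function observed only on a sub-domain.
    Responses are the raw function values at each time point, predictors
    are the truncations of every function to the observed sub-domain, and
    the smoother is the leave-self-out kernel average over predictor
    distances.

    Parameters
    ----------
    alpha : miscoverage level of the band.
    metric : distance between partial predictors ("l2", "fr", "amplitude").
    kernel : smoothing kernel ("gaussian" or "triangular").
    tuning : bandwidth selection, "local" (per time point) or "global".
    bandwidth : fixed bandwidth; None tunes over distance quantiles.
    beta_grid : quantile levels generating the candidate bandwidths.
    n_trial, trial_margin : resolution and range margin of the trial grid.
    """

    def __init__(self, alpha=0.1, metric="l2", kernel="gaussian", tuning="local",
                 bandwidth=None, beta_grid=DEFAULT_BETA_GRID, n_trial=200,
                 trial_margin=0.25):
        self.alpha = alpha
        self.metric = metric
        self.kernel = kernel
        self.tuning = tuning
        self.bandwidth = bandwidth
        self.beta_grid = beta_grid
        self.n_trial = n_trial
        self.trial_margin = trial_margin

    def fit(self, X, y=None):
        F, t = _as_matrix(X)
        if F.shape[0] < 2:
            raise InvalidInputError("need at least two training functions")
        if not np.all(np.isfinite(F)):
            raise InvalidInputError("non-finite training values")
        self.F_, self.grid_ = F, t
        return self

    def predict(self, x, descriptor: RegimeDescriptor | None = None) -> PredictionBand:
        x_new = _partialize(x, descriptor, self.grid_)
        obs = [restrict(FunctionalSample(self.grid_, f), x_new.descriptor) for f in self.F_]
        D = distance_matrix(obs + [x_new], metric=self.metric).entries
        Y_known = self.F_
        trial = TrialGrid.from_responses(Y_known, self.n_trial, self.trial_margin).values
        hs = self._candidates(D)
        return _pointwise_band_engine(D, Y_known, self.alpha, trial, hs,
                                      self.tuning, self.kernel, method="ffcp")


class SplitConformalBand(_ConformalBase):
    """Split conformal band with elastic registration (SFCP).

    A random split of the n complete functions yields a training set,
    whose Karcher mean becomes the registration template, and a
    calibration set, registered to that template.  The conformal engine
    then runs on the n2 + 1 system whose responses are the calibration
    amplitudes and whose predictors remain the *unregistered* truncations.
    The band targets the amplitude of the new function (its registration
    to the training template) over the entire domain.
    """

    def __init__(self, alpha=0.1, metric="l2", kernel="gaussian", tuning="local",
                 bandwidth=None, beta_grid=DEFAULT_BETA_GRID, n_trial=200,
                 trial_margin=0.25, n1=None, random_state=0,
                 karcher_max_iter=20, karcher_tol=1e-2):
        self.alpha = alpha
        self.metric = metric
        self.kernel = kernel
        self.tuning = tuning
        self.bandwidth = bandwidth
        self.beta_grid = beta_grid
        self.n_trial = n_trial
        self.trial_margin = trial_margin
        self.n1 = n1
        self.random_state = random_state
        self.karcher_max_iter = karcher_max_iter
        self.karcher_tol = karcher_tol

    def fit(self, X, y=None):
        F, t = _as_matrix(X)
        n = F.shape[0]
        rng = np.random.default_rng(self.random_state)
        self.split_ = SplitPlan.make(n, self.n1, rng=rng)
        train = [FunctionalSample(t, F[i]) for i in self.split_.train_idx]
        self.karcher_ = elastic.karcher_mean(
            train, max_iter=self.karcher_max_iter, tol=self.karcher_tol
        )
        self.template_ = self.karcher_.mean_function
        calib = [FunctionalSample(t, F[i]) for i in self.split_.calib_idx]
        amps, phases = [], []
        for f in calib:
            reg = elastic.pairwise_align(self.template_, f)
            amps.append(reg.aligned.values)
            phases.append(reg.warping)
        self.calib_F_ = np.stack([f.values for f in calib])
        self.amplitudes_ = np.stack(amps)
        self.phases_ = phases
        self.grid_ = t
        return self

    def predict(self, x, descriptor: RegimeDescriptor | None = None) -> PredictionBand:
        x_new = _partialize(x, descriptor, self.grid_)
        obs = [restrict(FunctionalSample(self.grid_, f), x_new.descriptor) for f in self.calib_F_]
        D = distance_matrix(obs + [x_new], metric=self.metric).entries
        Y_known = self.amplitudes_
        trial = TrialGrid.from_responses(Y_known, self.n_trial, self.trial_margin).values
        hs = self._candidates(D)
        return _pointwise_band_engine(D, Y_known, self.alpha, trial, hs,
                                      self.tuning, self.kernel, method="sfcp")

    def oracle_registration(self, f_full) -> elastic.RegistrationResult:
        """Register a *complete* function to the training template.

        Yields the band's target (the amplitude) and the true relative
        phase; available only when the complete function is known, e.g.
        in simulation.
        """
        f = f_full if isinstance(f_full, FunctionalSample) else FunctionalSample(self.grid_, np.asarray(f_full))
        return elastic.pairwise_align(self.template_, f)


def enumerate_monotone_trials(coarse_T: int, values_per_point: int) -> np.ndarray:
    """All strictly increasing trial vectors with endpoints fixed at 0 and 1
    and interior entries drawn from a uniform grid on (0, 1).

    The count is C(g, T-2) for g grid values since ordering is forced.
    """
    if coarse_T < 3:
        raise InvalidInputError("coarse grid needs at least 3 points")
    g = int(values_per_point)
    interior = np.linspace(0.0, 1.0, g + 2)[1:-1]
    combos = np.asarray(list(combinations(range(g), coarse_T - 2)), dtype=int)
    M = combos.shape[0]
    out = np.empty((M, coarse_T))
    out[:, 0] = 0.0
    out[:, -1] = 1.0
    out[:, 1:-1] = interior[combos]
    return out


class SplitConformalPhase(_ConformalBase):
    """Joint conformal prediction of the relative phase (SFCPP).

    Same split-and-register construction as `SplitConformalBand`, but the
    responses are the calibration relative phases sampled on a coarse
    grid, prediction is joint over the whole coarse grid (pointwise
    intervals cannot preserve monotonicity), trial vectors are monotone
    with fixed endpoints, and the nonconformity score is the geodesic
    warping distance d_w.  Bandwidth tuning is global.
    """

    def __init__(self, alpha=0.1, metric="l2", kernel="gaussian",
                 bandwidth=None, beta_grid=DEFAULT_BETA_GRID, coarse_T=5,
                 trials_per_point=100, n1=None, random_state=0,
                 karcher_max_iter=20, karcher_tol=1e-2, chunk_size=40000):
        self.alpha = alpha
        self.metric = metric
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.beta_grid = beta_grid
        self.coarse_T = coarse_T
        self.trials_per_point = trials_per_point
        self.n1 = n1
        self.random_state = random_state
        self.karcher_max_iter = karcher_max_iter
        self.karcher_tol = karcher_tol
        self.chunk_size = chunk_size

    def fit(self, X, y=None):
        helper = SplitConformalBand(
            n1=self.n1, random_state=self.random_state,
            karcher_max_iter=self.karcher_max_iter, karcher_tol=self.karcher_tol,
        ).fit(X)
        self.split_ = helper.split_
        self.karcher_ = helper.karcher_
        self.template_ = helper.template_
        self.calib_F_ = helper.calib_F_
        self.grid_ = helper.grid_
        self.coarse_grid_ = np.linspace(0.0, 1.0, self.coarse_T)
        self.phases_ = np.stack(
            [np.interp(self.coarse_grid_, self.grid_, g.values) for g in helper.phases_]
        )
        self._band_helper = helper
        return self

    def oracle_registration(self, f_full):
        return self._band_helper.oracle_registration(f_full)

    def _dw_scores(self, Yph, A, wn, trials, dt):
        """Warping-distance scores for every (row, trial) pair, chunked.

        Slopes are forward differences, piecewise constant per interval;
        the augmented fit of row i has slopes ``slope(A_i) + wn_i *
        slope(y)``, affine in the trial vector's slopes.
        """
        n2 = Yph.shape[0]
        ry = np.sqrt(np.maximum(np.diff(Yph, axis=1) / dt, 0.0))  # (n2, K)
        sa = np.diff(A, axis=1) / dt  # (n2+1, K)
        st = np.diff(trials, axis=1) / dt  # (M, K)
        M = trials.shape[0]
        S = np.empty((n2, M))
        Snew = np.empty(M)
        ra_new = np.sqrt(np.maximum(sa[-1], 0.0))
        for start in range(0, M, self.chunk_size):
            sl = slice(start, min(start + self.chunk_size, M))
            shat = sa[:n2, None, :] + wn[:n2, None, None] * st[None, sl, :]
            rhat = np.sqrt(np.maximum(shat, 0.0))
            ip = np.einsum("ik,imk,k->im", ry, rhat, dt)
            S[:, sl] = np.arccos(np.clip(ip, -1.0, 1.0))
            ipn = np.sqrt(np.maximum(st[sl], 0.0)) @ (ra_new * dt)
            Snew[sl] = np.arccos(np.clip(ipn, -1.0, 1.0))
        return S, Snew

    def predict(self, x, descriptor: RegimeDescriptor | None = None) -> PhasePredictionSet:
        x_new = _partialize(x, descriptor, self.grid_)
        obs = [restrict(FunctionalSample(self.grid_, f), x_new.descriptor) for f in self.calib_F_]
        D = distance_matrix(obs + [x_new], metric=self.metric).entries
        n2 = self.phases_.shape[0]
        m = n2 + 1
        k = _quantile_index(m, self.alpha)
        trials = enumerate_monotone_trials(self.coarse_T, self.trials_per_point)
        dt = np.diff(self.coarse_grid_)
        hs = self._candidates(D)
        Y0 = np.vstack([self.phases_, np.zeros((1, self.coarse_T))])
        best = None
        for h in np.sort(hs):
            W = kernel_weights(D, h, self.kernel)
            A = W @ Y0
            wn = W[:, -1]
            S, Snew = self._dw_scores(self.phases_, A, wn, trials, dt)
            allS = np.vstack([S, Snew[None, :]])  # (m, M)
            thr = np.partition(allS, k - 1, axis=0)[k - 1]
            acc = Snew <= thr + _TIE_EPS
            if acc.any():
                env_lo = trials[acc].min(axis=0)
                env_hi = trials[acc].max(axis=0)
                score = float(np.mean(env_hi - env_lo))
            else:
                env_lo = np.full(self.coarse_T, np.nan)
                env_hi = np.full(self.coarse_T, np.nan)
                score = np.inf
            if best is None or score < best[0]:
                best = (score, h, acc, env_lo, env_hi, A[-1].copy())
        score, h, acc, env_lo, env_hi, point = best
        interior = np.linspace(0.0, 1.0, self.trials_per_point + 2)[1:-1]
        return PhasePredictionSet(
            coarse_grid=self.coarse_grid_,
            accepted=trials[acc],
            alpha=self.alpha,
            envelope_lower=env_lo,
            envelope_upper=env_hi,
            point_prediction=point,
            trial_values=interior,
            bandwidth=float(h),
            empty=not bool(acc.any()),
        )


# ---------------------------------------------------------------------------
# functional wrappers matching the operation-level interface


def ffcp(train_functions, new_partial, descriptor=None, **config) -> PredictionBand:
    """One-shot FFCP band from complete functions and a partial observation."""
    est = FullConformalBand(**config).fit(train_functions)
    return est.predict(new_partial, descriptor)


def sfcp(functions, new_partial, descriptor=None, split=None, **config) -> PredictionBand:
    """One-shot SFCP band (split + registration + conformal engine)."""
    if split is not None:
        config.setdefault("n1", split.n1)
        config.setdefault("random_state", split.seed)
    est = SplitConformalBand(**config).fit(functions)
    return est.predict(new_partial, descriptor)


def sfcpp(functions, new_partial, descriptor=None, split=None, **config) -> PhasePredictionSet:
    """One-shot SFCPP phase prediction set."""
    if split is not None:
        config.setdefault("n1", split.n1)
        config.setdefault("random_state", split.seed)
    est = SplitConformalPhase(**config).fit(functions)
    return est.predict(new_partial, descriptor)
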