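"""Synthetic two-peak functional populations with Beta-CDF phase variation.

The amplitude population is a homogeneous family of two Gaussian bumps,

    f_i(t) = Z_i1 exp(-(t - 0.25)^2 / 0.07^2) + Z_i2 exp(-(t - 0.75)^2 / 0.07^2),

with coefficients Z_i ~ N(2, 0.1 I_2) i.i.d. (covariance 0.1 I, i.e.
standard deviation sqrt(0.1) per coordinate).  Phase variation is induced
by composing with random warpings gamma_i = F_{a,b}, the Beta(a, b) CDF
with a, b ~ i.i.d. Unif(1, 3).  Observation regimes (truncation interval
[0, U], disjoint fragments, or sparse time points) are drawn from an RNG
stream independent of the function coefficients, so the truncation time
is independent of the functions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .elastic import FunctionalSample, InvalidInputError, Warping, uniform_grid, warp_function
from .partial import RegimeDescriptor

PEAK_CENTERS = (0.25, 0.75)
PEAK_WIDTH = 0.07
COEF_MEAN = 2.0
COEF_VAR = 0.1
AB_RANGE = (1.0, 3.0)


@dataclass
class SimulationConfig:
    """Study conditions for one Monte Carlo experiment."""

    n: int = 100
    T: int = 100
    B: int = 500
    phase_variation: bool = False
    alpha: float = 0.1
    regime: str = "interval"
    U: float = 0.5
    fragments: tuple = ((0.0, 0.2), (0.4, 0.6), (0.8, 1.0))
    fragment_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    sparse_points: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.B < 1 or self.T < 2:
            raise InvalidInputError("need n >= 2, B >= 1, T >= 2")


def two_peak_values(t: np.ndarray, z1: float, z2: float) -> np.ndarray:
    """Deterministic two-bump function for given coefficients."""
    b1 = np.exp(-((t - PEAK_CENTERS[0]) ** 2) / PEAK_WIDTH**2)
    b2 = np.exp(-((t - PEAK_CENTERS[1]) ** 2) / PEAK_WIDTH**2)
    return z1 * b1 + z2 * b2


def generate_two_peak(n: int, T: int, rng: np.random.Generator) -> list[FunctionalSample]:
    """n i.i.d. two-peak functions on the uniform T-grid."""
    t = uniform_grid(T)
    Z = rng.normal(COEF_MEAN, np.sqrt(COEF_VAR), size=(n, 2))
    return [FunctionalSample(grid=t, values=two_peak_values(t, z1, z2)) for z1, z2 in Z]


def generate_beta_warpings(n: int, T: int, rng: np.random.Generator) -> list[Warping]:
    """n random warpings: Beta(a, b) CDFs with a, b ~ Unif(1, 3)."""
    t = uniform_grid(T)
    ab = rng.uniform(*AB_RANGE, size=(n, 2))
    out = []
    for a, b in ab:
        v = beta_dist.cdf(t, a, b)
        v[0], v[-1] = 0.0, 1.0
        out.append(Warping(grid=t, values=v))
    return out


def apply_phase(functions: list[FunctionalSample], warpings: list[Warping]) -> list[FunctionalSample]:
    """Compose each function with its warping, f_i o gamma_i."""
    if len(functions) != len(warpings):
        raise InvalidInputError("functions and warpings must have equal counts")
    return [warp_function(f, g) for f, g in zip(functions, warpings)]


def make_observation_regime(config: SimulationConfig, rng: np.random.Generator | None = None,
                            u_law=None) -> RegimeDescriptor:
    """Observation-scheme descriptor; U may be fixed or drawn from ``u_law``
    using an RNG stream independent of the functions."""
    if config.regime == "interval":
        U = config.U if u_law is None else float(u_law(rng))
        return RegimeDescriptor(regime="interval", U=U)
    if config.regime == "fragmented":
        return RegimeDescriptor(regime="fragmented", fragments=config.fragments,
                                weights=config.fragment_weights)
    if config.regime == "sparse":
        return RegimeDescriptor(regime="sparse", points=config.sparse_points)
    raise InvalidInputError(f"unknown regime {config.regime!r}")


def generate_population(config: SimulationConfig, seed: int | None = None):
    """One replicate: n + 1 functions (the last is the prediction target),
    the true warpings (identity when phase variation is off), and the
    observation descriptor.

    Two independent child streams are used: one for function coefficients
    and phases, one for the observation regime.
    """
    src = config.seed if seed is None else seed
    root = src if isinstance(src, np.random.SeedSequence) else np.random.SeedSequence(src)
    fn_seed, regime_seed = root.spawn(2)
    fn_rng = np.random.default_rng(fn_seed)
    regime_rng = np.random.default_rng(regime_seed)
    funcs = generate_two_peak(config.n + 1, config.T, fn_rng)
    if config.phase_variation:
        warps = generate_beta_warpings(config.n + 1, config.T, fn_rng)
        funcs = apply_phase(funcs, warps)
    else:
        t = uniform_grid(config.T)
        warps = [Warping(grid=t, values=t.copy()) for _ in range(config.n + 1)]
    descriptor = make_observation_regime(config, regime_rng)
    return funcs, warps, descriptor
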