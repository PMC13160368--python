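# Methods

## Model and representation

Functional observations are absolutely continuous functions
`f: [0,1] → R`, discretised on a common uniform grid of `T` points.
Phase is represented by warping functions, the group `Γ` of
orientation-preserving diffeomorphisms of `[0,1]` fixing the endpoints.
Registration uses the square-root slope function (SRSF)
`q = Q(f) = sign(ḟ)√|ḟ|`, under which the Fisher–Rao metric becomes the
ordinary `L2` metric and warping acts by the isometry
`(q, γ) ↦ (q∘γ)√γ̇`.  Pairwise registration of `f2` onto `f1` minimises
`‖q_1 − (q_2∘γ)√γ̇‖₂` over `γ`; the minimised value is the amplitude
distance `d_a`.  Multiple registration aligns a sample to its Karcher
mean, the SRSF minimising the sum of squared elastic distances.

On the warping group the SRSF is `√γ̇`, a point on the unit Hilbert
sphere, and the geodesic distance is
`d_w(γ_i, γ_j) = arccos ∫ √γ̇_i √γ̇_j dt`, used as the nonconformity
score for phase prediction.

## Conformal engine

All three predictors construct exchangeable predictor–response pairs
and apply the full-conformal rank rule with the leave-self-out
neighborhood smoother (Gaussian kernel by default; triangular
available).  Because the augmented fit is affine in the trial value
`y` — `Ŷ_i = A_i + W_{i,n+1} y` with `A` depending only on the known
rows — acceptance over the whole trial grid is evaluated in one
vectorised pass per bandwidth, and the predictor distance matrix is
computed once per problem.

**Trial grids are local.**  Each time point gets its own uniform grid of
`n_trial = 200` values spanning the responses observed at that time
point with a 25% margin on either side.  This is a load-bearing choice:
the conformal interval's width scales with the local response spread,
which for the two-peak population varies by six orders of magnitude
between peaks and flat regions.  A single global grid cannot resolve
intervals in flat regions (every accepted set there would be empty), so
resolution must be relative to the local scale.

**Containment is evaluated against the accepted set, not its hull.**
Accepted trial sets are summarised as `[min, max]` intervals for
reporting and for length (the hull makes length well-defined), but
coverage evaluation snaps the truth to the nearest trial value and
checks membership in the raw accepted set.  With multimodal responses
(phase variation) the accepted set can be disconnected, and hull
containment would overstate coverage relative to the conformal set the
rank rule actually defines.  The same snap rule discretises the
continuous true warping for the joint phase set.

**Quantile rule.**  The threshold is the `⌈(1−α)m⌉`-th smallest of the
`m` augmented scores (lower-quantile convention), which gives marginal
coverage in `[1−α, 1−α+1/m]` for exchangeable continuous scores.

**Bandwidth selection** considers candidates at the lower-β quantiles of
the off-diagonal predictor distances, β ∈ {0.1, …, 0.9}, and picks the
candidate minimising PI length — per time point ("local", the default
for amplitude bands) or averaged over the grid ("global", used for the
joint phase set).  Plain minimisation over ~9 valid candidate sets
erodes marginal coverage by roughly half a point to one point in our
measurements; no selection correction is applied.  The practical effect
and its consequences for whole-function coverage are quantified under
*Limitations*.

## Registration numerics

- Derivatives: centred finite differences with one-sided boundary
  stencils (`numpy.gradient`), used identically in the SRSF transform
  and the group action so the two commute to discretisation accuracy.
- Dynamic programming: monotone lattice paths on the sample grid with
  coprime steps `(di, dj)`, `max ≤ k_max`; segment costs are trapezoidal
  sums at native grid points; ties break toward the identity diagonal by
  trying the most diagonal step first.  On grids with `T ≤ 15` the DP
  optimum equals brute-force enumeration over the same path set (tested).
- Quality-critical pairwise registration (calibration amplitudes, oracle
  targets) runs the DP on a 2× refined grid with SRSFs built from
  cubic-spline derivatives and composes the aligned function through the
  spline, with slope bounds `[1/6, 6]`.  Rationale: centred differences
  at `T = 100` leave a discretisation floor (~0.03) in the alignment
  objective under which the minimiser wanders, visible as jitter of the
  aligned functions near sharp peaks; spline derivatives drop the floor
  by an order of magnitude, and Beta-CDF warpings have inverse slopes
  outside `[1/4, 4]` near the endpoints.  Mean sup-norm alignment error
  on warped two-peak pairs drops from ≈0.074 to ≈0.042.
- Karcher mean: template initialised at the input SRSF closest to the
  cross-sectional SRSF mean; alternating align/average iterations; the
  objective is monotone non-increasing and plateaus after 2–3
  iterations, so the default relative tolerance is 1e-2 with the
  fast native-grid DP (`k_max = 4`) — template roughness is shared by
  all registrations and averages out over the sample.  Relative phases
  are centred afterwards (the mean warping is composed out) so the mean
  relative phase is approximately the identity.
- Warping inverses and compositions: axis swap / re-interpolation,
  linear.  Function composition `f∘γ`: linear interpolation, arguments
  clipped to `[0,1]`.
- `d_w` slopes: forward differences treated as piecewise constant on the
  grid intervals (the only choice available on the 5-point coarse phase
  grid; used on all grids for consistency); inner products clipped to
  `[−1, 1]` before `arccos`.
- Degenerate inputs: constant functions have zero SRSF and carry no
  alignment information; registration returns the identity warping with
  a warning.  Kernel rows whose weights all underflow fall back to the
  uniform leave-one-out mean with a warning.

## Synthetic study conditions

The generator reproduces the simulation design the package is tested
against: two Gaussian bumps centred at 0.25 and 0.75 with width 0.07,
coefficients `Z_i ~ N(2, 0.1 I₂)` (standard deviation `√0.1` per
coordinate); phase variation composes each function with the CDF of a
Beta(a, b), `a, b ~ i.i.d. Unif(1, 3)`; partial observation truncates
the target at a fixed `U ∈ {0.25, 0.5, 0.75}` (default 0.5), or uses
fragments `[0,0.2] ∪ [0.4,0.6] ∪ [0.8,1]` with weights 1/3, or the
sparse grid `{0, 0.1, …, 1}`.  Defaults: `n = 100`, `T = 100`,
`α = 0.1`, `B = 500` replicates at full scale.  Function coefficients
and the observation regime are drawn from independent child RNG
streams, so the truncation time is independent of the functions by
construction (the assumption behind predictor exchangeability), and
this independence is testable.

What the generator does *not* emulate: measurement noise on the grid
values, heterogeneous subpopulations, non-smooth functions, and
observation schemes correlated with the function values.  Passing tests
therefore demonstrate correctness of the machinery and validity under
the stated exchangeability conditions, not robustness to irregular
real-world sampling.

## Problem sizes used in tests and the acceptance script

The test suite runs the Monte Carlo studies at reduced scale — validity
at `B = 60, T = 50`; overall-coverage comparisons at `B = 80`
(full-conformal) and `B = 50` (split); phase prediction at `B = 25`
with 50 trial values per interior coarse-grid point — sizes chosen so
the whole suite completes on one CPU in well under half an hour.  The
acceptance script uses `B = 300` (full-conformal) and `B = 100` (split)
with `n = 100, T = 100`.  Tolerances in the tests combine the published
standard errors with the binomial standard error of the reduced run.

## Limitations

- **Bandwidth-tuning coverage correction.**  The length-minimising
  bandwidth selection is implemented as a plain argmin.  The procedure
  it reconstructs is described as coverage-preserving, but the exact
  correction is not specified in the available material; candidate
  reconstructions (union-bound level splitting, rank-inflation by the
  candidate count) were implemented and measured, and each makes the
  no-phase-variation overall coverage markedly conservative while only
  partially restoring the with-phase levels.  The plain argmin matches
  the published no-phase results closely and erodes pointwise coverage
  by under one point.
- **Whole-function coverage under phase variation.**  With phase
  variation, this implementation's pointwise coverage is nominal
  (≈0.90) but its breach events are weakly dependent across time, so
  the *overall* (all-time-points) coverage for the registration-free
  band, and to a lesser degree the registration-based band, falls well
  below the published values (≈0.03 vs 0.362 and ≈0.25 vs 0.674 at
  reduced scale) while the no-phase rows agree (≈0.72 vs 0.690/0.680).
  The gap is traceable to registration/interval noise that is
  independent across time points rather than concentrated in atypical
  replicates; closing it would require the unavailable tuning
  correction above and/or a higher-fidelity registration than the
  lattice DP provides at `T = 100`.
- **Phase-set lengths.**  Joint phase-prediction coverage matches the
  published levels, but the time-averaged envelope lengths differ by up
  to ±40% and are not monotone in `U`; envelope length is sensitive to
  the bandwidth-candidate grid in a way coverage is not.
- The amplitude distance is directed; it is symmetrised by averaging
  the two directions when used as a predictor metric.
- Conditional (per-predictor) coverage and simultaneous bands over `t`
  are out of scope; the guarantee is marginal and pointwise.
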