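# fdconformal

Joint elastic registration and conformal prediction for partially
observed functional data.

## The problem

Given `n` complete functions `f_1, …, f_n` on `[0, 1]` (daily traffic
curves, growth velocities, ECG complexes, annual temperature profiles)
and a new function `f_{n+1}` observed only on part of its domain — an
initial interval `[0, U]`, a union of fragments, or sparse time points —
predict the unobserved part with *pointwise prediction intervals* that
carry a finite-sample coverage guarantee,

    P( f_{n+1}(t) ∈ I_t ) ≥ 1 − α   for every grid point t,

with no model for the data-generating process.  Functional data mix two
kinds of variation: *amplitude* (values, y-axis) and *phase* (timing of
features, x-axis, encoded by warping functions `γ` with `γ(0)=0`,
`γ(1)=1`, `γ̇>0`).  Ignoring phase inflates prediction intervals badly;
this package integrates elastic registration into the conformal
machinery instead of treating it as preprocessing.

## Methods

Three estimators (scikit-learn style, `fit`/`predict`) share one
conformal engine built on neighborhood smoothing — a Nadaraya–Watson
average over predictor distances,

    Ŷ_i(t) = Σ_{i′≠i} K(d(X_i, X_i′)/h) Y_i′(t) / Σ_{i′≠i} K(d(X_i, X_i′)/h),

with predictors `X_i = f_i` restricted to the observed sub-domain and
the conformal rank rule: a trial value `y` enters `I_t` when its
nonconformity score `|y − Ŷ_{n+1}(t)|` is within the lower `1−α`
quantile of the `n+1` augmented scores.

- **`FullConformalBand`** — full conformal prediction of `f_{n+1}(t)`
  with no registration; valid for exchangeable functions.
- **`SplitConformalBand`** — splits the data, computes the elastic
  (square-root-slope-function) Karcher mean of the training half,
  registers the calibration half to it by dynamic-programming warping,
  and runs the same engine with the registered *amplitudes* as
  responses.  The band targets the amplitude `f_{n+1}∘γ*` of the new
  function and is much tighter in the presence of phase variation.
- **`SplitConformalPhase`** — predicts the *relative phase* `γ*` jointly
  on a coarse grid: monotone trial vectors with fixed endpoints, scored
  by the geodesic distance on the warping group,
  `d_w(γ_1, γ_2) = arccos ∫ √γ̇_1 √γ̇_2 dt`.

The elastic machinery (SRSF transform `q = sign(ḟ)√|ḟ|`, warping group
action `(q∘γ)√γ̇`, pairwise registration by dynamic programming, Karcher
means, amplitude and phase distances) lives in `fdconformal.elastic` and
is usable on its own.

## Worked example

```python
import numpy as np
from fdconformal import (SplitConformalBand, RegimeDescriptor, restrict,
                         SimulationConfig, generate_population)

cfg = SimulationConfig(n=100, T=100, phase_variation=True, seed=7)
funcs, _, _ = generate_population(cfg)          # 101 two-peak functions
train, target = funcs[:100], funcs[100]
desc = RegimeDescriptor("interval", U=0.5)      # observe target on [0, 0.5]

est = SplitConformalBand(alpha=0.1, random_state=0).fit(train)
band = est.predict(restrict(target, desc))
truth = est.oracle_registration(target).aligned  # amplitude of the target

inside = (truth.values >= band.lower) & (truth.values <= band.upper)
print(f"mean PI length {band.lengths.mean():.3f}, "
      f"pointwise containment {inside.mean():.2f}")
```

Output:

```
mean PI length 0.198, pointwise containment 0.93
```

The band covers the amplitude of the held-out function at 93% of the
grid points in this draw, consistent with the 10% nominal pointwise
miscoverage.  The same data through `FullConformalBand` gives a mean PI
length of 0.98 — five times wider — because unregistered responses mix
the two peaks' timing across the sample.

A CLI wraps the library for file-based use:

```bash
fdconformal simulate --n 100 --t 100 --phase --seed 1 --out data.csv
fdconformal predict --method sfcp --data data.csv --partial-spec partial.yaml \
    --alpha 0.1 --out band.csv
fdconformal predict-phase --data data.csv --partial-spec partial.yaml --out phase.csv
fdconformal evaluate --method sfcp --b 100 --phase --seed 1 --out summary.json
```

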