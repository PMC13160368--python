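"""Conformal engines: quantile rule, trial enumeration, band properties,
and naive-loop oracles for FFCP and the phase predictor."""

import math

import numpy as np
import pytest

from fdconformal import (
    FullConformalBand,
    RegimeDescriptor,
    SplitConformalBand,
    SplitConformalPhase,
    SplitPlan,
    Warping,
    conformal_quantile,
    enumerate_monotone_trials,
    restrict,
    uniform_grid,
)
from fdconformal.elastic import InvalidInputError
from fdconformal.simulate import SimulationConfig, generate_population, generate_two_peak
from fdconformal.smoothing import kernel_weights


class TestConformalQuantile:
    def test_order_statistic_oracle(self):
        scores = np.arange(1.0, 11.0)  # 1..10
        # ceil(0.9 * 10) = 9 -> the 9th smallest
        assert conformal_quantile(scores, 0.1) == 9.0

    def test_alpha_to_zero_gives_maximum(self):
        scores = np.array([3.0, 1.0, 7.0, 5.0])
        assert conformal_quantile(scores, 1e-9) == 7.0

    def test_constant_scores(self):
        assert conformal_quantile(np.full(13, 2.5), 0.1) == 2.5

    def test_randomised_against_sorting(self, rng):
        for _ in range(20):
            m = rng.integers(1, 40)
            alpha = rng.uniform(0.01, 0.5)
            s = rng.normal(size=m)
            k = min(math.ceil((1 - alpha) * m), m)
            assert conformal_quantile(s, alpha) == np.sort(s)[k - 1]

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            conformal_quantile(np.array([]), 0.1)


class TestEnumerateTrials:
    def test_single_free_coordinate(self):
        trials = enumerate_monotone_trials(3, 3)
        assert trials.shape == (3, 3)
        assert np.allclose(trials[:, 0], 0.0)
        assert np.allclose(trials[:, -1], 1.0)

    def test_combinatorial_count(self):
        trials = enumerate_monotone_trials(5, 10)
        assert trials.shape[0] == math.comb(10, 3)  # 120

    def test_every_vector_is_a_valid_warping(self):
        grid = np.linspace(0.0, 1.0, 5)
        for v in enumerate_monotone_trials(5, 6):
            Warping(grid, v)  # raises if invalid


def _small_system(n=5, T=11, seed=0, phase=False):
    cfg = SimulationConfig(n=n, T=T, B=1, phase_variation=phase, seed=seed)
    funcs, _, _ = generate_population(cfg)
    desc = RegimeDescriptor("interval", U=0.5)
    return funcs[:n], funcs[n], desc


class TestFFCPBand:
    def test_identical_functions_zero_score_at_truth(self):
        t = uniform_grid(21)
        from fdconformal import FunctionalSample
        from fdconformal.simulate import two_peak_values

        f = FunctionalSample(t, two_peak_values(t, 2.0, 2.0))
        est = FullConformalBand(bandwidth=1.0).fit([f] * 6)
        band = est.predict(restrict(f, RegimeDescriptor("interval", U=0.5)))
        rec_inside = (f.values >= band.lower - 1e-9) & (f.values <= band.upper + 1e-9)
        assert rec_inside.all()

    def test_matches_naive_loop(self):
        train, target, desc = _small_system()
        h = 0.7
        alpha = 0.2
        est = FullConformalBand(alpha=alpha, bandwidth=h, n_trial=40).fit(train)
        x_new = restrict(target, desc)
        band = est.predict(x_new)

        # independent naive recomputation looping over (t, y)
        from fdconformal.partial import distance_matrix

        obs = [restrict(f, desc) for f in train] + [x_new]
        D = distance_matrix(obs).entries
        F = np.stack([f.values for f in train])
        m = len(train) + 1
        k = math.ceil((1 - alpha) * m)
        W = kernel_weights(D, h)
        for tk in range(F.shape[1]):
            accepted = []
            for y in band.trial_grid[tk]:
                Y = np.append(F[:, tk], y)
                S = np.abs(Y - W @ Y)
                thr = np.sort(S)[k - 1]
                if S[-1] <= thr + 1e-12:
                    accepted.append(y)
            if accepted:
                assert band.lower[tk] == pytest.approx(min(accepted))
                assert band.upper[tk] == pytest.approx(max(accepted))
            else:
                assert band.empty[tk]

    def test_permutation_symmetry(self, rng):
        train, target, desc = _small_system(n=8, T=15, seed=4)
        x_new = restrict(target, desc)
        band = FullConformalBand(bandwidth=0.5).fit(train).predict(x_new)
        perm = rng.permutation(len(train))
        band_p = (
            FullConformalBand(bandwidth=0.5)
            .fit([train[i] for i in perm])
            .predict(x_new)
        )
        assert np.allclose(band.lower, band_p.lower, equal_nan=True)
        assert np.allclose(band.upper, band_p.upper, equal_nan=True)

    def test_nested_in_alpha(self):
        train, target, desc = _small_system(n=20, T=15, seed=6)
        x_new = restrict(target, desc)
        b10 = FullConformalBand(alpha=0.1, bandwidth=0.5).fit(train).predict(x_new)
        b20 = FullConformalBand(alpha=0.2, bandwidth=0.5).fit(train).predict(x_new)
        # acceptance at the stricter quantile is a subset pointwise
        assert np.all(b20.accepted <= b10.accepted)

    def test_trial_refinement_moves_endpoints_at_most_one_step(self):
        train, target, desc = _small_system(n=20, T=15, seed=8)
        x_new = restrict(target, desc)
        coarse = FullConformalBand(bandwidth=0.5, n_trial=100).fit(train).predict(x_new)
        fine = FullConformalBand(bandwidth=0.5, n_trial=200).fit(train).predict(x_new)
        step = coarse.trial_grid[:, 1] - coarse.trial_grid[:, 0]
        ok = ~(coarse.empty | fine.empty)
        assert np.all(np.abs(coarse.lower[ok] - fine.lower[ok]) <= step[ok] + 1e-12)
        assert np.all(np.abs(coarse.upper[ok] - fine.upper[ok]) <= step[ok] + 1e-12)

    def test_band_has_lengths_and_midpoint(self):
        train, target, desc = _small_system(n=10, T=11)
        band = FullConformalBand(bandwidth=1.0).fit(train).predict(restrict(target, desc))
        ok = ~band.empty
        assert np.all(band.lengths[ok] == band.upper[ok] - band.lower[ok])
        assert np.allclose(
            band.midpoint[ok], 0.5 * (band.lower + band.upper)[ok]
        )


class TestSplitPlan:
    def test_balanced_default(self):
        plan = SplitPlan.make(100, rng=np.random.default_rng(0))
        assert plan.n1 == 50 and plan.n2 == 50
        assert np.array_equal(
            np.sort(np.concatenate([plan.train_idx, plan.calib_idx])), np.arange(100)
        )

    def test_invalid_split_rejected(self):
        with pytest.raises(InvalidInputError):
            SplitPlan.make(10, n1=10)


class TestSFCP:
    def test_no_phase_band_close_to_ffcp(self):
        cfg = SimulationConfig(n=40, T=31, B=1, phase_variation=False, seed=12)
        funcs, _, _ = generate_population(cfg)
        desc = RegimeDescriptor("interval", U=0.5)
        train, target = funcs[:40], funcs[40]
        x_new = restrict(target, desc)
        ffcp_band = FullConformalBand(bandwidth=0.5).fit(train).predict(x_new)
        sfcp_band = (
            SplitConformalBand(bandwidth=0.5, random_state=1).fit(train).predict(x_new)
        )
        # without phase variation registration is (nearly) a no-op, so the
        # two bands should track each other up to the n vs n2 sample-size
        # difference: midpoints close on the response scale, widths of the
        # same order
        scale = float(np.ptp(target.values))
        assert np.max(np.abs(ffcp_band.midpoint - sfcp_band.midpoint)) < 0.25 * scale
        assert 1 / 3 < sfcp_band.lengths.mean() / ffcp_band.lengths.mean() < 3
        assert sfcp_band.method == "sfcp"

    @pytest.mark.parametrize(
        "desc",
        [
            RegimeDescriptor("fragmented",
                             fragments=((0.0, 0.2), (0.4, 0.6), (0.8, 1.0))),
            RegimeDescriptor("sparse",
                             points=tuple(np.round(np.arange(0, 1.01, 0.1), 10))),
        ],
        ids=["fragmented", "sparse"],
    )
    def test_other_observation_regimes_end_to_end(self, desc):
        cfg = SimulationConfig(n=30, T=41, B=1, phase_variation=True, seed=23)
        funcs, _, _ = generate_population(cfg)
        est = SplitConformalBand(random_state=2).fit(funcs[:30])
        band = est.predict(restrict(funcs[30], desc))
        assert band.lower.shape == (41,)
        ok = ~band.empty
        assert ok.any()
        assert np.all(band.upper[ok] >= band.lower[ok])
        truth = est.oracle_registration(funcs[30]).aligned
        from fdconformal import evaluate_band

        rec = evaluate_band(band, truth)
        assert rec.contained.mean() > 0.5  # bands are informative, not vacuous

    def test_oracle_registration_returns_amplitude(self):
        cfg = SimulationConfig(n=20, T=51, B=1, phase_variation=True, seed=2)
        funcs, _, _ = generate_population(cfg)
        est = SplitConformalBand(random_state=0).fit(funcs[:20])
        reg = est.oracle_registration(funcs[20])
        assert reg.aligned.values.shape == (51,)
        assert reg.amplitude_distance >= 0


class TestSFCPP:
    def test_identity_population_accepts_identity_like_trials(self):
        cfg = SimulationConfig(n=16, T=41, B=1, phase_variation=False, seed=3)
        funcs, _, _ = generate_population(cfg)
        est = SplitConformalPhase(
            coarse_T=5, trials_per_point=9, random_state=0
        ).fit(funcs[:16])
        pred = est.predict(restrict(funcs[16], RegimeDescriptor("interval", U=0.5)))
        assert not pred.empty
        # the point prediction should be close to the identity warping
        assert np.max(np.abs(pred.point_prediction - pred.coarse_grid)) < 0.1
        # identity snapped to the trial grid must be accepted
        ident = pred.coarse_grid
        gi = np.argmin(np.abs(ident[1:-1, None] - pred.trial_values[None, :]), axis=1)
        snapped = pred.trial_values[gi]
        assert any(
            np.allclose(v[1:-1], snapped, atol=1e-9) for v in pred.accepted
        )

    def test_matches_naive_loop(self):
        cfg = SimulationConfig(n=8, T=41, B=1, phase_variation=True, seed=9)
        funcs, _, _ = generate_population(cfg)
        desc = RegimeDescriptor("interval", U=0.5)
        alpha, h, g, Tc = 0.2, 0.6, 5, 3
        est = SplitConformalPhase(
            alpha=alpha, bandwidth=h, coarse_T=Tc, trials_per_point=g, random_state=7
        ).fit(funcs[:8])
        pred = est.predict(restrict(funcs[8], desc))

        # naive recomputation
        from fdconformal.partial import distance_matrix
        from fdconformal.elastic import FunctionalSample

        obs = [
            restrict(FunctionalSample(est.grid_, f), desc) for f in est.calib_F_
        ] + [restrict(funcs[8], desc)]
        D = distance_matrix(obs).entries
        W = kernel_weights(D, h)
        phases = est.phases_
        n2 = phases.shape[0]
        m = n2 + 1
        k = math.ceil((1 - alpha) * m)
        tc = np.linspace(0, 1, Tc)
        dt = np.diff(tc)

        def dw(g1, g2):
            s1 = np.sqrt(np.maximum(np.diff(g1) / dt, 0))
            s2 = np.sqrt(np.maximum(np.diff(g2) / dt, 0))
            return np.arccos(np.clip(np.sum(s1 * s2 * dt), -1, 1))

        trials = enumerate_monotone_trials(Tc, g)
        accepted = []
        for y in trials:
            Y = np.vstack([phases, y])
            Yhat = W @ Y
            S = np.array([dw(Y[i], Yhat[i]) for i in range(m)])
            thr = np.sort(S)[k - 1]
            if S[-1] <= thr + 1e-12:
                accepted.append(y)
        accepted = np.asarray(accepted).reshape(-1, Tc)
        assert accepted.shape == pred.accepted.shape
        assert np.allclose(np.sort(accepted, axis=0), np.sort(pred.accepted, axis=0))
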