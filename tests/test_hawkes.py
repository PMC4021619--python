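"""Hawkes design matrices, cross-correlograms, OLS / lasso / two-step fits."""

import numpy as np
import pytest

from spikegof import (HawkesModel, MultiTrialSet, SpikeTrain, bernstein_weights,
                      build_design, crosscorr_counts, hawkes_compensators,
                      instantaneous_counts, lasso_fit, make_scenario, ols_fit,
                      predict_intensity, simulate_hawkes, two_step_fit)
from spikegof.hawkes import DesignSystem, LassoWeights, kkt_violation


def _mts(trains, t_end=2.0):
    return MultiTrialSet([[SpikeTrain(t, t_end) for t in trial]
                          for trial in trains])


class TestInstantaneousCounts:
    def test_empty_history(self):
        mts = _mts([[[], []]])
        rc = instantaneous_counts(mts[0], 1.0, 0.005, 3)
        assert rc[0] == 1.0 and np.all(rc[1:] == 0.0)

    def test_single_recent_spike_lands_in_first_bin(self):
        mts = _mts([[[0.9975], []]])
        rc = instantaneous_counts(mts[0], 1.0, 0.005, 3)
        assert rc[1] == pytest.approx(0.005 ** -0.5)
        assert np.all(np.delete(rc, [0, 1]) == 0.0)

    def test_spike_at_exact_bin_edge(self):
        # left-closed windows: a spike at t - delta sits in bin 1,
        # equivalently its lag delta falls in the basis bin (0, delta]
        mts = _mts([[[0.995], []]])
        rc = instantaneous_counts(mts[0], 1.0, 0.005, 3)
        assert rc[1] == pytest.approx(0.005 ** -0.5)
        assert rc[2] == 0.0

    def test_requires_full_history(self):
        mts = _mts([[[0.5], []]])
        with pytest.raises(ValueError):
            instantaneous_counts(mts[0], 0.01, 0.005, 3)


class TestBuildDesign:
    def test_no_spikes(self):
        mts = _mts([[[], []]])
        d = build_design(mts, (0.1, 1.5), 0.005, 4)
        G_expected = np.zeros((9, 9))
        G_expected[0, 0] = 1.4
        assert np.allclose(d.G, G_expected)
        assert np.allclose(d.b, 0.0)

    def test_b_first_coordinate_is_target_count(self, rng):
        trains = [[np.sort(rng.uniform(0, 2, 15)), np.sort(rng.uniform(0, 2, 9))]
                  for _ in range(3)]
        mts = _mts(trains)
        d = build_design(mts, (0.1, 1.9), 0.01, 5)
        for m in range(2):
            expected = sum(((t[m] >= 0.1) & (t[m] <= 1.9)).sum() for t in trains)
            assert d.b[m][0] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_G_matches_riemann_oracle(self, seed):
        """Exact segment integration vs a delta/100 midpoint Riemann sum.

        Spike times are drawn on the delta/100 lattice so that every
        breakpoint of the piecewise-constant integrand coincides with an
        oracle cell edge: the midpoint Riemann sum is then itself exact and
        the comparison probes the segment integration, not the oracle's own
        discretisation error."""
        rng = np.random.default_rng(seed)
        delta, K = 0.02, 3
        step = delta / 100
        trains = [[np.unique(rng.integers(0, 5000, 20)) * step,
                   np.unique(rng.integers(0, 5000, 14)) * step]]
        mts = _mts(trains, t_end=1.0)
        d = build_design(mts, (K * delta, 1.0), delta, K)
        from spikegof.hawkes import _window_counts
        ts = np.arange(K * delta + step / 2, 1.0, step)
        C = _window_counts([np.asarray(t) for t in trains[0]], ts, delta, K)
        R = np.concatenate([np.ones((ts.size, 1)), C / np.sqrt(delta)], axis=1)
        G_riemann = R.T @ R * step
        assert np.allclose(d.G, G_riemann, rtol=1e-4, atol=1e-6)

    def test_G_close_to_offgrid_riemann_oracle(self):
        """For generic (off-lattice) spikes the delta/100 midpoint oracle
        carries O(step) straddling error; agreement at the 1% level."""
        rng = np.random.default_rng(7)
        trains = [[np.sort(rng.uniform(0, 1.0, 20)), np.sort(rng.uniform(0, 1.0, 14))]]
        mts = _mts(trains, t_end=1.0)
        delta, K = 0.02, 3
        d = build_design(mts, (K * delta, 1.0), delta, K)
        from spikegof.hawkes import _window_counts
        step = delta / 100
        ts = np.arange(K * delta + step / 2, 1.0, step)
        C = _window_counts([np.asarray(t) for t in trains[0]], ts, delta, K)
        R = np.concatenate([np.ones((ts.size, 1)), C / np.sqrt(delta)], axis=1)
        G_riemann = R.T @ R * step
        assert np.allclose(d.G, G_riemann, rtol=2e-2, atol=2e-2)

    def test_window_validation(self):
        mts = _mts([[[0.5], [0.7]]])
        with pytest.raises(ValueError):
            build_design(mts, (0.0, 2.0), 0.005, 8)   # T1 < K*delta
        with pytest.raises(ValueError):
            build_design(mts, (0.5, 0.4), 0.005, 8)


class TestCrossCorrelogram:
    def test_single_pair_lag(self):
        # x = 1.000 (m), y = 0.996 (l): lag 0.004 in (0, 0.005] -> bin 1
        mts = _mts([[[1.0], [0.996]]])
        cc = crosscorr_counts(mts, (0.04, 2.0), 0.005, 8)
        assert cc[0, 1, 0] == 1 and cc[0, 1, 1:].sum() == 0

    def test_no_self_pairing_at_zero_lag(self):
        mts = _mts([[[0.5, 1.0], []]])
        cc = crosscorr_counts(mts, (0.04, 2.0), 0.005, 8)
        assert cc[0, 0].sum() == 0.0   # lag 0 excluded, 0.5 s gap > K*delta

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_design_b_blocks(self, seed):
        """n_bar identity: pair counting equals the b blocks of the design
        system times delta^{1/2}."""
        rng = np.random.default_rng(seed)
        trains = [[np.sort(rng.uniform(0, 2, 25)), np.sort(rng.uniform(0, 2, 18))]
                  for _ in range(2)]
        mts = _mts(trains)
        window, delta, K = (0.05, 1.97), 0.01, 5
        cc = crosscorr_counts(mts, window, delta, K)
        d = build_design(mts, window, delta, K)
        assert np.allclose(cc, d.crosscorr())


class TestOlsFit:
    def test_hand_solvable_system(self):
        # M=1, K=1: dim 2; synthetic G, b solved by 2x2 elimination
        G = np.array([[2.0, 1.0], [1.0, 4.0]])
        b = np.array([[3.0, 2.0]])
        d = DesignSystem(G=G, b=b, window=(0.0, 2.0), delta=0.25, K=1, M=1,
                         n_trials=1)
        model = ols_fit(d)
        # a = G^{-1} b = ([12-2, 4-3])/7 = (10/7, 1/7)
        assert model.nu[0] == pytest.approx(10 / 7)
        assert model.interactions[0, 0, 0] == pytest.approx((1 / 7) / np.sqrt(0.25))

    def test_empty_neuron_gives_singular_error(self):
        mts = _mts([[np.linspace(0.2, 1.8, 12), []]])
        d = build_design(mts, (0.04, 2.0), 0.005, 8)
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(d)


class TestBernsteinWeights:
    def test_no_nearby_spikes_reduces_to_sup_term(self):
        # l spikes far from any m spike: V = 0, weight = gamma*ln(n(T2-T1))*B/3
        mts = _mts([[[1.5], [0.2]]])
        w = bernstein_weights(mts, (0.04, 2.0), 0.005, 8, gamma=1.0)
        logterm = np.log(1 * (2.0 - 0.04))
        B = 0.005 ** -0.5        # one spike in some sliding window
        # entries for source l=2 (columns 1+8..1+15 for target m=1)
        assert w.d[0][1 + 8] == pytest.approx(logterm * B / 3)

    def test_toy_arithmetic(self):
        # m spike at 1.0, l spikes at 0.996 and 0.993: bin-1 count 1 (0.996),
        # bin-2 count 1 (0.993); V_{m,l,1} = 1/delta, B_{l,1} = 2/sqrt(delta)
        # (both l spikes fit in one 5 ms sliding window)
        mts = _mts([[[1.0], [0.993, 0.996]]])
        delta, K = 0.005, 2
        w = bernstein_weights(mts, (0.04, 2.0), delta, K, gamma=1.0)
        L = np.log(2.0 - 0.04)
        d_expected = np.sqrt(2 * L / delta) + L * (2 / np.sqrt(delta)) / 3
        assert w.d[0][1 + K] == pytest.approx(d_expected)     # l=2, k=1 slot
        assert w.d[0][0] == pytest.approx(np.sqrt(2 * L * 1) + L / 3)

    def test_weights_increase_with_gamma(self, rng):
        trains = [[np.sort(rng.uniform(0, 2, 30)), np.sort(rng.uniform(0, 2, 30))]]
        mts = _mts(trains)
        w1 = bernstein_weights(mts, (0.04, 2.0), 0.005, 8, gamma=1.0)
        w2 = bernstein_weights(mts, (0.04, 2.0), 0.005, 8, gamma=2.0)
        assert np.all(w2.d > w1.d)


class TestLasso:
    def test_zero_weights_reduce_to_ols(self, rng):
        mts = _mts([[np.sort(rng.uniform(0, 2, 40)),
                     np.sort(rng.uniform(0, 2, 35))] for _ in range(6)])
        d = build_design(mts, (0.04, 2.0), 0.005, 8)
        w = LassoWeights(d=np.zeros_like(d.b), gamma=0.0)
        model = lasso_fit(d, w, tol=1e-12)
        ref = ols_fit(d)
        assert np.allclose(model.coefficients(), ref.coefficients(), atol=1e-6)

    def test_full_shrinkage_on_diagonal_system(self):
        G = np.diag([2.0, 3.0])
        b = np.array([[1.0, -0.5]])
        d = DesignSystem(G=G, b=b, window=(0, 1), delta=1.0, K=1, M=1, n_trials=1)
        w = LassoWeights(d=np.array([[2.0, 1.0]]), gamma=1.0)   # d >= |b|
        model = lasso_fit(d, w)
        assert np.all(model.coefficients() == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_kkt_certificate_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        dim = 7          # 1 + M*K with M = 2, K = 3
        A = rng.normal(size=(dim + 3, dim))
        G = A.T @ A
        b = rng.normal(size=(2, dim)) * 3
        dvec = np.abs(rng.normal(size=(2, dim))) + 0.1
        d = DesignSystem(G=G, b=b, window=(0, 1), delta=1.0, K=3,
                         M=2, n_trials=1)
        model = lasso_fit(d, LassoWeights(d=dvec, gamma=1.0))
        a = model.coefficients()
        for m in range(2):
            assert kkt_violation(G, b[m], dvec[m], a[m]) < 1e-6

    def test_objective_nonincreasing_each_sweep(self, rng):
        mts = _mts([[np.sort(rng.uniform(0, 2, 40)),
                     np.sort(rng.uniform(0, 2, 35))] for _ in range(4)])
        d = build_design(mts, (0.04, 2.0), 0.005, 8)
        w = bernstein_weights(mts, (0.04, 2.0), 0.005, 8)
        model = lasso_fit(d, w)
        for path in model.diagnostics["objective_paths"]:
            assert all(a >= b - 1e-9 for a, b in zip(path, path[1:]))

    def test_sparsity_zeroes_absent_interaction(self):
        """The N1 -> N2 interaction is null in the bivariate benchmark; the
        weighted lasso zeroes that whole block in most replicates even at a
        moderate trial count."""
        hits = 0
        reps = 12
        for r in range(reps):
            mts = make_scenario("s-haw", 40, 6000 + r)
            d = build_design(mts, (0.04, 2.0), 0.005, 8)
            w = bernstein_weights(mts, (0.04, 2.0), 0.005, 8, gamma=1.0)
            model = lasso_fit(d, w)
            hits += np.all(model.interactions[1, 0] == 0.0)
        assert hits >= 0.8 * reps


class TestTwoStep:
    def test_full_support_equals_ols(self, rng):
        mts = _mts([[np.sort(rng.uniform(0, 2, 40)),
                     np.sort(rng.uniform(0, 2, 35))] for _ in range(6)])
        d = build_design(mts, (0.04, 2.0), 0.005, 8)
        lasso = lasso_fit(d, LassoWeights(d=np.zeros_like(d.b), gamma=0.0),
                          tol=1e-12)
        two = two_step_fit(d, lasso)
        assert np.allclose(two.coefficients(), ols_fit(d).coefficients(),
                           atol=1e-5)

    def test_empty_support_gives_zero_model(self):
        G = np.diag([2.0, 3.0])
        b = np.array([[1.0, -0.5]])
        d = DesignSystem(G=G, b=b, window=(0, 1), delta=1.0, K=1, M=1, n_trials=1)
        lasso = lasso_fit(d, LassoWeights(d=np.array([[2.0, 1.0]]), gamma=1.0))
        two = two_step_fit(d, lasso)
        assert np.all(two.coefficients() == 0.0)


class TestPredictIntensity:
    def test_zero_interactions_give_spontaneous_rate(self):
        model = HawkesModel(delta=0.005, K=2, nu=np.array([7.0, 3.0]),
                            interactions=np.zeros((2, 2, 2)))
        mts = _mts([[[0.5, 0.6], [0.55]]])
        psi = predict_intensity(model, mts[0], [0.7, 1.0])
        assert np.allclose(psi, [[7.0, 3.0], [7.0, 3.0]])

    def test_linearity(self, rng):
        delta, K = 0.01, 3
        nu = np.array([5.0, 2.0])
        f = rng.normal(size=(2, 2, K)) * 10
        g = rng.normal(size=(2, 2, K)) * 10
        mts = _mts([[np.sort(rng.uniform(0, 2, 20)), np.sort(rng.uniform(0, 2, 20))]])
        ts = [0.5, 1.0, 1.7]
        p_f = predict_intensity(HawkesModel(delta, K, nu, f), mts[0], ts)
        p_g = predict_intensity(HawkesModel(delta, K, nu, g), mts[0], ts)
        p_fg = predict_intensity(HawkesModel(delta, K, 2 * nu, f + g), mts[0], ts)
        assert np.allclose(p_f + p_g, p_fg)

    def test_matches_direct_interaction_sum(self, rng):
        """Cross-module consistency: the design-based predictor equals a
        direct sum of interaction heights over past spikes."""
        from spikegof import s_haw_model
        model = s_haw_model()
        trial = simulate_hawkes(model, 2.0, rng)
        ts = np.linspace(0.1, 1.9, 37)
        psi = predict_intensity(model, trial, ts)
        for j, t in enumerate(ts):
            for m in range(2):
                val = model.nu[m]
                for l in range(2):
                    lags = t - trial[l].times
                    lags = lags[(lags > 0) & (lags <= model.support)]
                    bins = np.ceil(lags / model.delta - 1e-12).astype(int) - 1
                    val += model.interactions[m, l][bins].sum()
                assert psi[j, m] == pytest.approx(val)


class TestCompensators:
    def test_constant_model_compensator_is_linear(self):
        model = HawkesModel(delta=0.005, K=2, nu=np.array([10.0]),
                            interactions=np.zeros((1, 1, 2)))
        mts = _mts([[np.array([0.5, 1.0])]])
        comp = hawkes_compensators(model, mts, 0)[0]
        assert comp(2.0) == pytest.approx(20.0)
        assert comp(0.7) == pytest.approx(7.0)

    def test_inhibition_reduces_compensator(self):
        inter = np.zeros((1, 1, 1))
        inter[0, 0, 0] = -20.0
        model = HawkesModel(delta=0.005, K=1, nu=np.array([20.0]),
                            interactions=inter)
        mts = _mts([[np.array([0.5, 1.0])]])
        comp = hawkes_compensators(model, mts, 0)[0]
        # two dead 5 ms windows: Lambda(2) = 20*2 - 2*20*0.005
        assert comp(2.0) == pytest.approx(40.0 - 0.2)
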