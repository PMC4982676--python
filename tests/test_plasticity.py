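"""Full weight dynamics: competition, adaptive Euler stepping, bounds,
stochastic/deterministic integration."""

import numpy as np
import pytest

from stdpnet import (ConnectivityState, PlasticityConfig, coefficient_table,
                     competition_terms, deterministic_step, effective_connectivity,
                     generate_initial_weights, make_alpha_kernel, make_stdp,
                     run_deterministic, run_stochastic, stationary_rates,
                     truncated_drift)
from stdpnet.motifs import DriftMatrix


def _zero_drift(n):
    d = np.zeros((n, n))
    np.fill_diagonal(d, np.nan)
    return DriftMatrix(d)


class TestCompetitionTerms:
    def test_below_bound_is_zero(self):
        W = np.full((4, 4), 0.1)
        np.fill_diagonal(W, 0.0)
        d_in, d_out = competition_terms(W, W_max=1.0)
        assert np.all(d_in == 0.0) and np.all(d_out == 0.0)

    def test_row_excess(self):
        W = np.zeros((3, 3))
        W[0, 1], W[0, 2] = 0.8, 0.5  # row 0 sums to 1.3
        d_in, d_out = competition_terms(W, W_max=1.0)
        np.testing.assert_allclose(d_in, [0.3, 0.0, 0.0])
        np.testing.assert_allclose(d_out, [0.0, 0.0, 0.0])

    def test_steady_state_sums_respect_bound(self, kernel, antisym):
        # under the full dynamics with large psi, final row/col sums stay
        # within 1% of W_max
        cfg = PlasticityConfig(n=12, M=3, w_max=0.2, psi=5e4, mu=0.0, gamma=225.0,
                               b=15.0, kernel=kernel, stdp=antisym,
                               drift_mode="truncated", truncation_order=2,
                               step_cap=0.01, max_iters=3000)
        st0 = generate_initial_weights(12, 3, 0.2, 1.5, seed=4)
        traj = run_deterministic(st0, cfg)
        W = traj.final_state.W_ex
        assert W.sum(axis=1).max() <= cfg.W_max * 1.01
        assert W.sum(axis=0).max() <= cfg.W_max * 1.01


class TestDeterministicStep:
    def test_all_zero_parameters_freeze_weights(self):
        st = generate_initial_weights(5, 2, 0.5, seed=0)
        cfg = PlasticityConfig(n=5, eta=0.0, psi=0.0, mu=0.0, gamma=0.0,
                               M=2, w_max=0.5)
        new, h, change = deterministic_step(st, cfg, _zero_drift(5))
        np.testing.assert_array_equal(new.W_ex, st.W_ex)
        assert change == 0.0

    def test_pure_growth_until_clip(self):
        st = ConnectivityState(np.full((3, 3), 0.49) * (1 - np.eye(3)), 0.5)
        cfg = PlasticityConfig(n=3, eta=1e-8, psi=0.0, mu=0.0, gamma=10.0,
                               M=3, w_max=0.5, W_max=100.0, step_cap=0.05)
        new, _, change = deterministic_step(st, cfg, _zero_drift(3))
        off = ~np.eye(3, dtype=bool)
        assert np.all(new.W_ex[off] == 0.5)  # uniform growth clipped at w_max
        assert change == pytest.approx(0.01)

    def test_step_cap_sets_max_change(self, kernel, antisym):
        st = generate_initial_weights(6, 2, 0.5, seed=1)
        rates = stationary_rates(effective_connectivity(st), 15.0)
        table = coefficient_table(antisym, kernel, 2)
        drift = truncated_drift(st, rates, table, 2)
        cfg = PlasticityConfig(n=6, M=2, w_max=0.5, psi=0.0, mu=0.0, gamma=0.0,
                               step_cap=0.02)
        new, _, change = deterministic_step(st, cfg, drift)
        assert change == pytest.approx(0.02, rel=1e-9)

    def test_non_finite_drift_aborts(self):
        st = generate_initial_weights(3, 2, 0.5, seed=1)
        bad = DriftMatrix(np.full((3, 3), np.inf))
        cfg = PlasticityConfig(n=3, M=2, w_max=0.5)
        with pytest.raises(RuntimeError):
            deterministic_step(st, cfg, bad)

    def test_adjacency_mask_respected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = True
        st = ConnectivityState(np.zeros((3, 3)), 0.5, adjacency_mask=mask)
        cfg = PlasticityConfig(n=3, M=3, w_max=0.5, psi=0.0, mu=0.0, gamma=10.0,
                               step_cap=0.1)
        new, _, _ = deterministic_step(st, cfg, _zero_drift(3))
        assert new.W_ex[0, 1] > 0.0
        assert np.all(new.W_ex[~mask] == 0.0)


class TestRunDeterministic:
    def test_bounds_hold_on_every_snapshot(self, kernel, antisym):
        cfg = PlasticityConfig(n=10, M=3, w_max=0.25, psi=5e4, mu=0.0, gamma=225.0,
                               b=15.0, kernel=kernel, stdp=antisym,
                               drift_mode="truncated", truncation_order=3,
                               step_cap=0.02, max_iters=400)
        st0 = generate_initial_weights(10, 3, 0.25, 1.5, seed=2)
        traj = run_deterministic(st0, cfg)
        for W in traj.snapshots:
            assert np.all(W >= 0.0) and np.all(W <= 0.25 + 1e-15)
            assert np.all(np.diag(W) == 0.0)

    def test_adaptive_step_matches_fine_step_short_horizon(self, kernel, antisym):
        # integrate the same dynamics with the figure-scale cap and with a
        # 20x smaller cap up to the same model time; trajectories must agree
        st0 = generate_initial_weights(8, 2, 0.3, 1.0, seed=5)
        table = coefficient_table(antisym, kernel, 2)

        def integrate(cap, t_end):
            cfg = PlasticityConfig(n=8, M=2, w_max=0.3, psi=2e3, mu=500.0,
                                   gamma=225.0, b=15.0, kernel=kernel,
                                   stdp=antisym, drift_mode="truncated",
                                   truncation_order=2, step_cap=cap)
            state, t = st0.copy(), 0.0
            while t < t_end:
                rates = stationary_rates(effective_connectivity(state), 15.0)
                drift = truncated_drift(state, rates, table, 2,
                                        W=effective_connectivity(state))
                cfg.step_cap = min(cap, cap)  # fixed cap
                state, h, _ = deterministic_step(state, cfg, drift)
                if h == 0.0:
                    break
                t += h
            return state.W_ex

        t_end = 2e5  # seconds of model time, ~10 coarse steps
        coarse = integrate(0.01, t_end)
        fine = integrate(0.0005, t_end)
        assert np.max(np.abs(coarse - fine)) < 1e-3

    def test_trajectory_reproducible(self, kernel, antisym):
        cfg = dict(n=8, M=2, w_max=0.3, psi=5e4, mu=0.0, gamma=225.0, b=15.0,
                   kernel=kernel, stdp=antisym, drift_mode="truncated",
                   truncation_order=2, step_cap=0.02, max_iters=100)
        t1 = run_deterministic(generate_initial_weights(8, 2, 0.3, seed=3),
                               PlasticityConfig(**cfg))
        t2 = run_deterministic(generate_initial_weights(8, 2, 0.3, seed=3),
                               PlasticityConfig(**cfg))
        np.testing.assert_array_equal(t1.final_state.W_ex, t2.final_state.W_ex)


class TestRunStochastic:
    def test_zero_learning_rate_freezes_weights(self, kernel, antisym):
        cfg = PlasticityConfig(n=6, M=2, w_max=0.3, eta=0.0, psi=5e4, mu=4500.0,
                               gamma=225.0, b=15.0, kernel=kernel, stdp=antisym,
                               duration=5.0, seed=1)
        st0 = generate_initial_weights(6, 2, 0.3, seed=1)
        traj = run_stochastic(st0, cfg)
        np.testing.assert_array_equal(traj.final_state.W_ex, st0.W_ex)

    def test_seed_determinism(self, kernel, antisym):
        cfg = dict(n=6, M=2, w_max=0.3, eta=1e-5, psi=5e4, mu=4500.0, gamma=225.0,
                   b=15.0, kernel=kernel, stdp=antisym, duration=5.0, seed=12)
        st0 = generate_initial_weights(6, 2, 0.3, seed=2)
        t1 = run_stochastic(st0.copy(), PlasticityConfig(**cfg))
        t2 = run_stochastic(st0.copy(), PlasticityConfig(**cfg))
        np.testing.assert_array_equal(t1.final_state.W_ex, t2.final_state.W_ex)
        t3 = run_stochastic(st0.copy(), PlasticityConfig(**{**cfg, "seed": 13}))
        assert not np.array_equal(t1.final_state.W_ex, t3.final_state.W_ex)

    def test_bounds_hold(self, kernel, mexhat):
        # windowed (non-exponential) path: bounds and diagonal invariants
        cfg = PlasticityConfig(n=6, M=2, w_max=0.3, eta=1e-4, psi=1e5, mu=0.0,
                               gamma=0.0, b=5.0, kernel=kernel, stdp=mexhat,
                               duration=5.0, seed=3)
        st0 = generate_initial_weights(6, 2, 0.3, seed=3)
        traj = run_stochastic(st0, cfg)
        for W in traj.snapshots:
            assert np.all(W >= 0.0) and np.all(W <= 0.3 + 1e-12)
            assert np.all(np.diag(W) == 0.0)


class TestGenerateInitialWeights:
    def test_bounds_and_zero_diagonal(self):
        st = generate_initial_weights(20, 5, 4.5, scale=1.5, seed=0)
        assert np.all(np.diag(st.W_ex) == 0.0)
        assert st.W_ex.max() <= 1.5 * 4.5 * 5 / 20  # = 1.6875
        assert st.W_ex.max() > 0.9 * 1.6875  # draws actually span the range

    def test_reproducible(self):
        a = generate_initial_weights(10, 4, 1.0, seed=42).W_ex
        b = generate_initial_weights(10, 4, 1.0, seed=42).W_ex
        np.testing.assert_array_equal(a, b)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            PlasticityConfig(eta=-1.0)
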