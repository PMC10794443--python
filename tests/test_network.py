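"""Network simulator: firing function, critical point, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiketopo import (NetworkParams, NetworkState, critical_point,
                       mean_field_trajectory, phi, simulate, step)
from spiketopo.network import SpikeRaster


@pytest.fixture
def default_params():
    return NetworkParams()


class TestPhi:
    @pytest.mark.parametrize("V,expected", [
        (1.0, 0.0),    # at threshold the Heaviside factors cancel
        (6.0, 1.0),    # saturation potential theta + 1/Gamma
        (3.5, 0.5),    # linear branch: (3.5 - 1) * 0.2
        (0.0, 0.0),    # below threshold
        (100.0, 1.0),  # above saturation
    ])
    def test_piecewise_values(self, V, expected, default_params):
        assert phi(V, default_params) == pytest.approx(expected)

    @given(st.floats(min_value=-10, max_value=20, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_nondecreasing(self, V):
        p = NetworkParams()
        val = phi(V, p)
        assert 0.0 <= val <= 1.0
        assert phi(V + 0.5, p) >= val

    def test_vectorized(self, default_params):
        out = phi(np.array([0.0, 1.0, 3.5, 6.0, 9.0]), default_params)
        np.testing.assert_allclose(out, [0.0, 0.0, 0.5, 1.0, 1.0])


class TestCriticalPoint:
    def test_default_parameters_give_three_halves(self, default_params):
        W_bar_c, g_c = critical_point(default_params)
        assert W_bar_c == pytest.approx(5.0, abs=1e-12)
        assert g_c == pytest.approx(1.5, abs=1e-12)

    def test_balanced_strong_coupling_limit(self):
        # p = q = 1/2 with Gamma*J -> infinity: g_c -> p/q = 1
        p = NetworkParams(p=0.5, q=0.5, J=1e12, Gamma=0.2)
        _, g_c = critical_point(p)
        assert g_c == pytest.approx(1.0, abs=1e-9)

    def test_leaky_case(self):
        p = NetworkParams(mu=0.5)
        _, g_c = critical_point(p)
        # p/q - (1-mu)/(q Gamma J) = 4 - 0.5/0.4
        assert g_c == pytest.approx(2.75, abs=1e-12)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            critical_point(NetworkParams(J=0.0))

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            NetworkParams(p=0.7, q=0.2)
        with pytest.raises(ValueError):
            NetworkParams(Gamma=0.0)
        p = NetworkParams(N=1001)
        assert p.N_E + p.N_I == p.N
        assert p.V_S > p.theta


class TestStep:
    def test_silent_network_stays_silent_without_tonic_drive(self):
        p = NetworkParams(N=50, I_ext=0.0)
        state = NetworkState(V=np.zeros(50), X=np.zeros(50, dtype=bool))
        nxt = step(state, p, np.random.default_rng(0))
        assert not nxt.X.any()
        np.testing.assert_array_equal(nxt.V, 0.0)

    def test_single_excitatory_spike_input(self):
        p = NetworkParams(N=1000, I_ext=0.0)
        X = np.zeros(1000, dtype=bool)
        X[0] = True  # one excitatory spike
        state = NetworkState(V=np.zeros(1000), X=X)
        nxt = step(state, p, np.random.default_rng(0))
        # quiescent neurons all receive J/N = 10/1000
        np.testing.assert_allclose(nxt.V[1:], 0.01)
        assert nxt.V[0] == 0.0  # reset by the (1 - X) factor

    def test_reset_after_firing(self, default_params):
        X = np.ones(default_params.N, dtype=bool)
        state = NetworkState(V=np.full(default_params.N, 3.0), X=X)
        nxt = step(state, default_params, np.random.default_rng(0))
        np.testing.assert_array_equal(nxt.V, 0.0)

    def test_monte_carlo_matches_mean_field_map(self):
        # population rate after one step vs one iteration of the MF map
        p = NetworkParams(N=10_000, g=1.5)
        rho0 = 0.05
        X = np.zeros(p.N, dtype=bool)
        X[:int(rho0 * p.N_E)] = True
        X[p.N_E:p.N_E + int(rho0 * p.N_I)] = True
        state = NetworkState(V=np.full(p.N, p.I_ext), X=X)
        reps = 100
        rng = np.random.default_rng(7)
        rhos = [step(state, p, rng).X.mean() for _ in range(reps)]
        mf = mean_field_trajectory(p, rho0, 1)[0].rho
        se = np.std(rhos, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(rhos) - mf) < 3 * se + 1e-12


class TestMeanField:
    def test_subcritical_decays_to_zero(self):
        traj = mean_field_trajectory(NetworkParams(g=1.8), 0.1, 1000)
        assert traj[-1].rho < 1e-6

    def test_supercritical_reaches_active_state(self):
        p = NetworkParams(g=1.2)
        traj = mean_field_trajectory(p, 0.1, 1000)
        assert traj[-1].rho > 1e-3
        # closed form of the active fixed point: 1 - W_bar_c / W_bar
        assert traj[-1].rho == pytest.approx(1 - 5.0 / p.W_bar, rel=1e-6)

    def test_absorbing_state(self):
        traj = mean_field_trajectory(NetworkParams(g=1.2), 0.0, 100)
        assert all(s.rho == 0.0 for s in traj)

    def test_states_carry_criticals(self):
        s = mean_field_trajectory(NetworkParams(), 0.1, 1)[0]
        assert s.g_c == pytest.approx(1.5, abs=1e-12)
        assert s.W_bar_c == pytest.approx(5.0, abs=1e-12)


class TestSimulate:
    def test_determinism(self):
        p = NetworkParams(N=100, g=1.5, seed=3)
        r1 = simulate(p, 3000, 500)
        r2 = simulate(p, 3000, 500)
        np.testing.assert_array_equal(r1.events, r2.events)
        np.testing.assert_array_equal(r1.drive_times, r2.drive_times)

    def test_drive_guarantees_activity(self):
        p = NetworkParams(N=50, g=5.0, seed=0)  # deep sub-critical
        r = simulate(p, 2001, 2000)
        assert r.T == 1
        assert r.n_spikes >= 1

    def test_activity_at_drive_times(self):
        r = simulate(NetworkParams(N=100, g=1.8, seed=1), 5000, 1000)
        A = r.activity()
        assert r.drive_times.size > 0
        assert (A[r.drive_times] >= 1).all()

    def test_activity_decreases_with_inhibition(self):
        # super > critical > sub, separated by more than across-seed sd
        rates = {}
        for g in (1.2, 1.5, 1.8):
            per_seed = []
            for seed in range(3):
                r = simulate(NetworkParams(N=200, g=g, seed=seed), 20_000, 2_000)
                per_seed.append(r.n_spikes / (r.N * r.T))
            rates[g] = (np.mean(per_seed), np.std(per_seed, ddof=1))
        assert rates[1.2][0] - rates[1.5][0] > max(rates[1.2][1], rates[1.5][1])
        assert rates[1.5][0] - rates[1.8][0] > max(rates[1.5][1], rates[1.8][1])

    def test_rejects_bad_windows(self):
        with pytest.raises(ValueError):
            simulate(NetworkParams(N=10), 0, 0)
        with pytest.raises(ValueError):
            simulate(NetworkParams(N=10), 100, 100)

    def test_raster_round_trip(self, tmp_path):
        r = simulate(NetworkParams(N=50, g=1.5, seed=9), 2000, 500)
        path = tmp_path / "raster.txt"
        r.save(path)
        r2 = SpikeRaster.load(path)
        np.testing.assert_array_equal(r.events, r2.events)
        np.testing.assert_array_equal(r.drive_times, r2.drive_times)
        assert r2.params == r.params
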