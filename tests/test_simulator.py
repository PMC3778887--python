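import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sdcm.model_core import DCMSpec, InputCourse, NeuralConnectivity
from sdcm.simulator import (
    DegenerateSignalError,
    FIXTURE_NAMES,
    SimulationSettings,
    _bold_all,
    _drift,
    add_measurement_noise,
    fixture_network,
    integrate,
    make_fluctuations,
)


def one_region_spec(a=-0.5, c=0.5):
    conn = NeuralConnectivity(A=np.array([[a]]), C=np.array([[c]]),
                              A_mask=np.array([[1]]), C_mask=np.array([[1]]))
    return DCMSpec(connectivity=conn, label="one")


class TestIntegrate:
    def test_rest_stays_at_rest(self):
        spec = one_region_spec(c=0.0)
        t = np.arange(0.0, 60.0, 1.0)
        inp = InputCourse(times=t, u=np.zeros((1, t.size)))
        traj = integrate(spec, inp, SimulationSettings(TR=1.0, duration=60.0))
        assert np.all(traj.x_n == 0)
        assert np.all(traj.y_clean == 0)

    def test_linear_steady_state(self):
        """With constant input c and decay a<0 the neural state settles at
        -c/a within 1% after 10/|a| seconds."""
        a, c = -0.5, 0.4
        spec = one_region_spec(a=a, c=1.0)
        t = np.arange(0.0, 60.0, 1.0)
        inp = InputCourse(times=t, u=np.full((1, t.size), c))
        traj = integrate(spec, inp, SimulationSettings(TR=1.0, duration=60.0))
        target = -c / a
        late = traj.x_n[0, traj.times_micro > 10 / abs(a)]
        assert np.all(np.abs(late - target) < 0.01 * abs(target))

    def test_determinism_and_replay(self, linear_fixture):
        spec, inp, _ = linear_fixture
        spec = spec.copy()
        spec.priors.noise.stochastic = True
        st = SimulationSettings(TR=1.0, duration=120.0, snr_db=10.0,
                                state_noise_var=1e-3, seed=11)
        t1 = integrate(spec, inp, st)
        t2 = integrate(spec, inp, st)
        assert np.array_equal(t1.y, t2.y)
        assert np.array_equal(t1.x_n, t2.x_n)
        # replaying the stored draws reproduces the trajectory exactly
        t3 = integrate(spec, inp, st, replay=(t1.state_noise, t1.hemo_noise, t1.eps))
        assert np.array_equal(t1.y, t3.y)
        assert np.array_equal(t1.x_h, t3.x_h)
        # y - y_clean equals the stored measurement noise exactly
        assert np.array_equal(t1.y - t1.y_clean, t1.eps)

    def test_dt_halving_and_reference_solver(self, linear_fixture, linear_traj):
        spec, inp, _ = linear_fixture
        half = integrate(spec, inp, SimulationSettings(TR=1.0, duration=600.0,
                                                       dt=1 / 32))
        assert np.abs(linear_traj.y_clean - half.y_clean).max() < 0.01 * \
            np.ptp(linear_traj.y_clean)

        n = spec.n_regions
        grid = inp.times

        def rhs(t, z):
            k = min(int(t // 1.0), grid.size - 1)
            return _drift(z, n, spec.connectivity, inp.u[:, k], None, None,
                          spec.hemo)

        sol = solve_ivp(rhs, (0, 600), np.zeros(5 * n),
                        t_eval=linear_traj.times_scan, max_step=0.5,
                        rtol=1e-10, atol=1e-12)
        yref = np.array([_bold_all(sol.y[:, j], n, spec.hemo)
                         for j in range(sol.y.shape[1])]).T
        assert np.abs(linear_traj.y_clean - yref).max() < 1e-3

    def test_quasi_deterministic_convergence(self, linear_fixture, linear_traj):
        """On the linear fixture the stochastic path approaches the
        deterministic one monotonically as state-noise variance shrinks."""
        spec, inp, _ = linear_fixture
        spec = spec.copy()
        spec.priors.noise.stochastic = True
        devs = []
        for var in (1e-2, 1e-4, 1e-6):
            st = SimulationSettings(TR=1.0, duration=600.0,
                                    state_noise_var=var, seed=5)
            traj = integrate(spec, inp, st)
            devs.append(np.abs(traj.x_n - linear_traj.x_n).max())
        assert devs[0] > devs[1] > devs[2]


class TestMeasurementNoise:
    def test_infinite_snr_is_noiseless(self, linear_traj):
        y = add_measurement_noise(linear_traj.y_clean, math.inf, seed=0)
        assert np.array_equal(y, linear_traj.y_clean)

    @pytest.mark.parametrize("target", [1.0, 10.0])
    def test_realized_snr_matches_target(self, linear_traj, target):
        y = add_measurement_noise(linear_traj.y_clean, target, seed=2)
        eps = y - linear_traj.y_clean
        realized = 10 * np.log10(np.mean(linear_traj.y_clean**2) / np.mean(eps**2))
        assert abs(realized - target) < 0.1

    def test_noise_variance_identity(self, linear_traj):
        y = add_measurement_noise(linear_traj.y_clean, 5.0, seed=3)
        eps = y - linear_traj.y_clean
        expected = np.mean(linear_traj.y_clean**2) * 10 ** (-0.5)
        assert np.mean(eps**2) == pytest.approx(expected, rel=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            add_measurement_noise(np.zeros((2, 10)), 1.0, seed=0)


class TestFluctuations:
    def test_target_state_snr(self, linear_fixture):
        _, inp, _ = linear_fixture
        out = make_fluctuations(inp, 2, snr_db=10.0, seed=4)
        realized = 10 * np.log10(np.mean(inp.u**2) / np.mean(out.delta_u**2))
        assert abs(realized - 10.0) < 0.1
        assert out.delta_u.shape == (2, inp.times.size)

    def test_pure_white_noise_mode(self, linear_fixture):
        _, inp, _ = linear_fixture
        out = make_fluctuations(inp, 2, snr_db=10.0, n_sinusoids=0, seed=4)
        target = np.mean(inp.u**2) * 0.1
        assert np.mean(out.delta_u**2) == pytest.approx(target, rel=1e-12)

    def test_same_seed_bit_identical(self, linear_fixture):
        _, inp, _ = linear_fixture
        a = make_fluctuations(inp, 2, seed=9).delta_u
        b = make_fluctuations(inp, 2, seed=9).delta_u
        assert np.array_equal(a, b)

    def test_zero_power_input_rejected(self):
        t = np.arange(10.0)
        inp = InputCourse(times=t, u=np.zeros((1, 10)))
        with pytest.raises(DegenerateSignalError):
            make_fluctuations(inp, 1)


class TestFixtures:
    def test_registry_names(self):
        assert len(FIXTURE_NAMES) == 6
        with pytest.raises(KeyError):
            fixture_network("nope")

    def test_mediated_excludes_direct_route(self):
        spec, _, _ = fixture_network("mediated_3r")
        assert spec.connectivity.A_mask[0, 2] == 0
        assert spec.connectivity.A_mask[2, 0] == 0
        assert spec.connectivity.A[0, 2] == 0.0
        spec_b, _, _ = fixture_network("direct_3r")
        assert spec_b.connectivity.A_mask[0, 2] == 1
        assert spec_b.connectivity.A[0, 2] != 0.0

    def test_linear_pair_is_stable(self):
        spec, _, _ = fixture_network("linear_2r")
        assert np.all(np.linalg.eigvals(spec.connectivity.A).real < 0)

    def test_boxcar_protocol(self):
        _, inp, _ = fixture_network("mediated_3r")
        u = inp.u[0]
        # one-minute boxcars: 60 s on, then off, repeating every 2 minutes
        assert np.all(u[(inp.times % 120) < 60] > 0)
        assert np.all(u[(inp.times % 120) >= 60] == 0)

    def test_limit_cycle_persists(self):
        """A long deterministic run of the gated network keeps oscillating:
        last-quarter amplitude at least 0.9x the second quarter's."""
        spec, _, _ = fixture_network("gating_2r_limit_cycle")
        t = np.arange(0.0, 1200.0, 1.0)
        inp = InputCourse(times=t, u=np.ones((1, t.size)))
        traj = integrate(spec, inp, SimulationSettings(TR=1.0, duration=1200.0))
        q = traj.x_n.shape[1] // 4
        amp2 = np.ptp(traj.x_n[0, q:2 * q])
        amp4 = np.ptp(traj.x_n[0, 3 * q:])
        assert amp4 > 0.3
        assert amp4 >= 0.9 * amp2

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_all_fixtures_simulate(self, name):
        spec, inp, settings = fixture_network(name)
        traj = integrate(spec, inp, settings)
        assert np.all(np.isfinite(traj.y_clean))
        assert traj.y_clean.shape[1] * settings.TR == settings.duration
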