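"""SJ3D neural-mass network: mode reduction, integrator, delays, LFP."""

import numpy as np
import pytest
from scipy import optimize, signal

import dynindep as di
from dynindep.sj3d import (SJ3DParams, default_initial_state, extract_lfp,
                           heun_sde_step, heun_step, make_connectomes,
                           simulate_network, sj3d_derivatives)


@pytest.fixture(scope="module")
def params():
    return SJ3DParams()


class TestModeReduction:
    """Closed-form oracles of the boxcar-mode Galerkin projection."""

    def test_cubic_and_quadratic_coefficients(self, params):
        # disjoint sqrt(3)-boxcars: int V^4 = 3, int V^3 = sqrt(3)
        assert np.allclose(params.a_i, 3 * params.a)
        assert np.allclose(params.b_i, np.sqrt(3) * params.b)
        assert np.allclose(params.d_i, np.sqrt(3) * params.d)
        assert np.allclose(params.e_i, params.a_i)

    def test_mode_mixing_is_mean_field(self, params):
        assert np.allclose(params.A_ik, 1 / 3, atol=1e-12)
        assert np.allclose(params.B_ik, params.A_ik)

    def test_per_mode_currents_are_tercile_means(self, params):
        # E[Z | tercile] = -+ 3 phi(z_{1/3}) for the outer terciles
        from scipy.stats import norm
        c = 3 * norm.pdf(norm.ppf(1 / 3))
        expect = (params.mu + params.sigma * np.array([-c, 0, c])) / np.sqrt(3)
        assert np.allclose(params.IE_i, expect, atol=2e-4)

    def test_slow_variable_offset(self, params):
        expect = params.r * params.s * params.x0 / np.sqrt(3)
        assert np.allclose(params.m_i, expect)


class TestDerivatives:
    def test_shape(self, params):
        state = default_initial_state(params, 5, np.random.default_rng(0))
        d = sj3d_derivatives(state, params)
        assert d.shape == (5, 3, 6)
        assert np.all(np.isfinite(d))

    def test_equilibrium_found_by_root_solver(self, params):
        # uncoupled single node, no noise: a numerically located fixed
        # point has (near-)zero drift
        x0 = default_initial_state(params, 1, np.random.default_rng(1))
        sol = optimize.root(
            lambda v: sj3d_derivatives(v.reshape(1, 3, 6), params).ravel(),
            x0.ravel(), tol=1e-12)
        assert sol.success
        resid = sj3d_derivatives(sol.x.reshape(1, 3, 6), params)
        assert np.linalg.norm(resid) < 1e-8

    def test_afferent_enters_only_xi(self, params):
        state = default_initial_state(params, 3, np.random.default_rng(2))
        aff = np.ones((3, 3))
        d0 = sj3d_derivatives(state, params)
        d1 = sj3d_derivatives(state, params, afferent=aff)
        assert np.allclose(d1[..., 0] - d0[..., 0], 1.0)
        assert np.allclose(d1[..., 1:], d0[..., 1:])

    def test_nonfinite_state_rejected(self, params):
        state = default_initial_state(params, 1, np.random.default_rng(3))
        state[0, 0, 0] = np.inf
        with pytest.raises(FloatingPointError):
            sj3d_derivatives(state, params)


class TestHeun:
    def test_deterministic_second_order_convergence(self):
        # dx/dt = -x on [0, 1]: global error ratio ~ 4 when dt halves
        def run(dt):
            x = np.array(1.0)
            for _ in range(int(round(1 / dt))):
                x = heun_step(lambda v: -v, x, dt)
            return float(x)
        e1 = abs(run(1 / 64) - np.exp(-1))
        e2 = abs(run(1 / 128) - np.exp(-1))
        assert e1 / e2 == pytest.approx(4.0, rel=0.1)

    def test_ou_stationary_variance(self):
        # dX = -theta X dt + sigma dW: var = sigma^2 / (2 theta) = 0.5
        theta, sigma, dt = 1.0, 1.0, 2.0 ** -6
        rng = np.random.default_rng(0)
        nchains, nsteps, burn = 50, 2 * 10 ** 4, 2 * 10 ** 3
        x = np.zeros(nchains)
        acc = []
        for t in range(nsteps):
            noise = sigma * np.sqrt(dt) * rng.standard_normal(nchains)
            x = heun_step(lambda v: -theta * v, x, dt, noise)
            if t >= burn:
                acc.append(x.copy())
        var = np.concatenate(acc).var()
        assert var == pytest.approx(sigma ** 2 / (2 * theta), rel=0.02)

    def test_sj3d_step_reproducible(self, params):
        state = default_initial_state(params, 2, np.random.default_rng(4))
        a = heun_sde_step(state, params, 0.05, 2.0 ** -6,
                          np.random.default_rng(9))
        b = heun_sde_step(state, params, 0.05, 2.0 ** -6,
                          np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_noise_targets_fast_variables_only(self, params):
        # increments enter only xi and alpha; other variables feel noise
        # solely through the O(dt * noise) corrector drift, so at tiny dt
        # their one-step difference vanishes while xi/alpha keep sqrt(dt)
        state = default_initial_state(params, 2, np.random.default_rng(5))
        dt = 1e-10
        stepped = heun_sde_step(state, params, 1.0, dt,
                                np.random.default_rng(10))
        det = heun_sde_step(state, params, 0.0, dt,
                            np.random.default_rng(10))
        diff = np.abs(stepped - det)
        assert diff[..., [0, 3]].max() > 1e-7
        assert diff[..., [1, 2, 4, 5]].max() < 1e-12


class TestNetworkSimulation:
    def test_kernel_matches_reference_step(self, params):
        conn = make_connectomes("coupled")
        traj = simulate_network(conn, params, G=0.1, noise_sigma=0.0,
                                duration_ms=1.0, seed=3)
        rng = np.random.default_rng(3)
        state = default_initial_state(params, 5, rng)
        xbar = (state[:, :, 0] * params.mode_mass).sum(axis=1)
        aff = 0.1 * (conn.weights @ xbar)
        afferent = aff[:, None] * params.mode_mass[None, :]
        ref = heun_step(lambda s: sj3d_derivatives(s, params, afferent),
                        state, 2.0 ** -6)
        assert np.abs(ref[:, :, 0] - traj.xi[0]).max() < 1e-12

    def test_bit_reproducible(self, params):
        conn = make_connectomes("coupled")
        a = simulate_network(conn, params, G=0.1, noise_sigma=0.02,
                             duration_ms=20.0, seed=7).xi
        b = simulate_network(conn, params, G=0.1, noise_sigma=0.02,
                             duration_ms=20.0, seed=7).xi
        assert np.array_equal(a, b)

    def test_zero_coupling_equals_uncoupled(self, params):
        coupled = make_connectomes("coupled")
        uncoupled = make_connectomes("uncoupled")
        a = simulate_network(coupled, params, G=0.0, noise_sigma=0.01,
                             duration_ms=20.0, seed=8).xi
        b = simulate_network(uncoupled, params, G=0.2, noise_sigma=0.01,
                             duration_ms=20.0, seed=8).xi
        assert np.array_equal(a, b)

    def test_uncoupled_nodes_statistically_independent(self, params):
        # slow burst dynamics decorrelate over seconds, so the control run
        # is long enough for the cross-correlation statistic to resolve
        traj = simulate_network(make_connectomes("uncoupled"), params,
                                G=0.1, noise_sigma=0.05,
                                duration_ms=40000.0, seed=9)
        lfp = extract_lfp(traj, discard_ms=500.0).values
        cc = []
        for i in range(5):
            for j in range(i + 1, 5):
                for lag in range(-50, 51):
                    a = lfp[i, max(0, lag):lfp.shape[1] + min(0, lag)]
                    b = lfp[j, max(0, -lag):lfp.shape[1] - max(0, lag)]
                    cc.append(abs(np.mean(a * b)))
        assert np.mean(cc) < 0.05

    def test_blowup_raises_with_cell_info(self, params):
        conn = make_connectomes("coupled")
        with pytest.raises(FloatingPointError, match="G="):
            simulate_network(conn, params, G=1e9, noise_sigma=1e4,
                             duration_ms=50.0, seed=10)

    def test_stationarity_screen_mid_grid(self, params):
        # coupled mid-grid cell: fitted VAR on the LFP is stable
        traj = simulate_network(make_connectomes("coupled"), params,
                                G=0.056, noise_sigma=0.01,
                                duration_ms=3000.0, seed=11)
        lfp = extract_lfp(traj)
        var = di.estimate_var(lfp, 8, "AIC")
        assert var.spectral_radius < 1
        ss = di.estimate_ss(lfp, 6, 6, "AIC")
        assert np.abs(np.linalg.eigvals(ss.A)).max() < 1
        assert np.abs(np.linalg.eigvals(ss.A - ss.K @ ss.C)).max() < 1


class TestLFP:
    def test_output_shape_and_zscore(self, params):
        traj = simulate_network(make_connectomes("uncoupled"), params,
                                G=0.0, noise_sigma=0.01,
                                duration_ms=5000.0, seed=12)
        lfp = extract_lfp(traj)
        assert lfp.values.shape == (5, 1152)       # 4.5 s at 256 Hz
        assert lfp.fs == 256.0
        assert np.abs(lfp.values.mean(axis=1)).max() < 1e-12
        assert np.abs(lfp.values.std(axis=1) - 1).max() < 1e-12

    def test_constant_trajectory_rejected(self, params):
        from dynindep.sj3d import SJ3DTrajectory
        traj = SJ3DTrajectory(np.ones((64000, 2, 3)), 2.0 ** -6, params,
                              np.ones((2, 3, 6)))
        with pytest.raises(ValueError, match="constant"):
            extract_lfp(traj)

    def test_antialias_attenuation(self):
        # decimation filter: >= 40 dB attenuation above the output Nyquist
        h = signal.firwin(8001, 0.8 / 250)   # proxy for resample_poly kernel
        w, H = signal.freqz(h, worN=4096)
        stop = np.abs(H[w > 1.25 * np.pi / 250])
        assert 20 * np.log10(stop.max()) < -40


class TestConnectomes:
    def test_uncoupled_zero_weights_same_tracts(self):
        c = make_connectomes("coupled")
        u = make_connectomes("uncoupled")
        assert np.all(u.weights == 0)
        assert np.array_equal(c.tracts, u.tracts)

    def test_coupled_structure(self):
        c = make_connectomes("coupled")
        assert np.all(np.diag(c.weights) == 0)
        assert np.any(c.weights != c.weights.T)     # directed asymmetry
        assert np.allclose(c.tracts, c.tracts.T)

    def test_delays_at_least_one_step(self):
        c = make_connectomes("coupled")
        steps = c.delay_steps(2.0 ** -6)
        assert np.all(steps[c.weights > 0] >= 1)

    def test_csv_round_trip(self, tmp_path):
        c = make_connectomes("coupled")
        c.to_csv(tmp_path / "conn")
        back = di.Connectome.from_csv(tmp_path / "conn")
        assert np.array_equal(back.weights, c.weights)
        assert back.conduction_speed == c.conduction_speed

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            di.Connectome(np.zeros((2, 2)), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="self-coupling"):
            di.Connectome(np.eye(2), np.zeros((2, 2)))


class TestSweepGrid:
    def test_default_lattice(self):
        g = di.SweepGrid.default()
        assert g.shape == (20, 20)
        assert g.g_values[0] == pytest.approx(0.01)
        assert g.g_values[-1] == pytest.approx(0.31)
        assert g.noise_values[0] == pytest.approx(0.001)
        assert g.noise_values[-1] == pytest.approx(0.1)
        # log spacing: constant ratio
        r = g.g_values[1:] / g.g_values[:-1]
        assert np.allclose(r, r[0])

    def test_cells_iterate_in_order(self):
        g = di.SweepGrid.reduced(3)
        cells = list(g.cells())
        assert len(cells) == 9
        assert cells[0][:2] == (0, 0) and cells[-1][:2] == (2, 2)
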