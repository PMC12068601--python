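"""VAR/state-space representation, simulation, estimation and causal graphs."""

import numpy as np
import pytest

import dynindep as di
from dynindep.linear_models import (DEFAULT_WORKED_EXAMPLE_EDGES,
                                    spectral_grid)


class TestSimulateVar:
    def test_white_noise_covariance(self):
        var = di.VarModel(np.zeros((1, 3, 3)), np.eye(3))
        ts = di.simulate_var(var, 10 ** 5, seed=0)
        cov = ts.values @ ts.values.T / ts.n_samples
        assert np.abs(cov - np.eye(3)).max() < 0.02

    def test_ar1_stationary_variance(self):
        # var = sigma^2 / (1 - a^2) = 1 / (1 - 0.81)
        var = di.VarModel(np.array([[[0.9]]]), np.array([[1.0]]))
        ts = di.simulate_var(var, 2 * 10 ** 5, seed=1)
        target = 1 / (1 - 0.81)
        # autocorrelated series: generous sampling tolerance
        assert ts.values.var() == pytest.approx(target, rel=0.1)

    def test_unstable_model_rejected(self):
        with pytest.raises(ValueError, match="[Nn]on-stationary"):
            di.VarModel(np.array([[[1.1]]]), np.array([[1.0]]))

    def test_reproducible(self, var2):
        a = di.simulate_var(var2, 500, seed=3).values
        b = di.simulate_var(var2, 500, seed=3).values
        assert np.array_equal(a, b)


class TestEstimateVar:
    def test_parameter_recovery(self, var2):
        ts = di.simulate_var(var2, 10 ** 5, seed=1)
        est = di.estimate_var(ts, 6, "AIC")
        assert est.order == 2
        assert np.abs(est.coeffs - var2.coeffs).max() < 0.02

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(2)
        ts = di.TimeSeriesData(rng.standard_normal((3, 10 ** 5)))
        est = di.estimate_var(ts, 4)
        assert np.abs(est.coeffs).max() < 0.02

    @pytest.mark.parametrize("criterion", ["AIC", "BIC"])
    def test_worked_example_order_selected(self, criterion):
        var9 = di.make_worked_example_var(seed=1)
        ts = di.simulate_var(var9, 10 ** 5, seed=11)
        assert di.estimate_var(ts, 12, criterion).order == 8

    def test_matches_statsmodels_ols(self, var2):
        # independent implementation of the same trend-free lagged OLS
        from statsmodels.tsa.api import VAR as SMVAR
        ts = di.simulate_var(var2, 2 * 10 ** 4, seed=21)
        est = di.estimate_var(ts, 2, "AIC")
        x = ts.values - ts.values.mean(axis=1, keepdims=True)
        sm = SMVAR(x.T).fit(maxlags=2, trend="n")
        assert est.order == 2
        assert np.abs(est.coeffs - sm.coefs).max() < 1e-8

    def test_estimation_consistency(self, var2):
        errs = []
        for n in (10 ** 3, 10 ** 4, 10 ** 5):
            ts = di.simulate_var(var2, n, seed=5)
            est = di.estimate_var(ts, 2, "AIC")
            errs.append(np.abs(est.coeffs - var2.coeffs).max())
        assert errs[0] > errs[1] > errs[2]


class TestVarToSS:
    def test_var1_companion_is_itself(self):
        A1 = np.array([[0.5, 0.2], [0.0, 0.3]])
        var = di.VarModel(A1[None], np.eye(2))
        ss = di.var_to_ss(var)
        assert ss.state_dim == 2
        assert np.allclose(ss.A, A1)
        assert np.abs(np.linalg.eigvals(ss.A)).max() == pytest.approx(
            var.spectral_radius)

    def test_spectral_density_matches_var(self, var2):
        ss = di.var_to_ss(var2)
        freqs = spectral_grid(64)
        _, S_ss = di.ss_spectral_density(ss, 64)
        # independent route: S = H V H* with H = (I - sum A_k z^-k)^{-1}
        z = np.exp(-1j * freqs)
        S_var = np.empty_like(S_ss)
        for f, zf in enumerate(z):
            Alam = np.eye(3) - sum(var2.coeffs[k] * zf ** (k + 1)
                                   for k in range(2))
            H = np.linalg.inv(Alam)
            S_var[f] = H @ var2.resid_cov @ H.conj().T
        assert np.abs(S_ss - S_var).max() < 1e-10

    def test_autocovariance_preserved(self, var2):
        ss = di.var_to_ss(var2)
        G = ss.autocov(20)
        # independent Yule-Walker route on the companion form
        from scipy.linalg import solve_discrete_lyapunov
        Acomp = ss.A
        Scomp = np.zeros_like(Acomp)
        Scomp[:3, :3] = var2.resid_cov
        P = solve_discrete_lyapunov(Acomp, Scomp)
        for k in range(21):
            Gk = (np.linalg.matrix_power(Acomp, k) @ P)[:3, :3]
            assert np.abs(G[k] - Gk).max() < 1e-8

    def test_order_zero_rejected(self):
        with pytest.raises(ValueError):
            di.VarModel(np.zeros((0, 2, 2)), np.eye(2))


class TestEstimateSS:
    def test_transfer_function_recovery(self):
        rng = np.random.default_rng(3)
        truth = None
        while truth is None:
            try:
                truth = di.SSModel(0.9 * rng.standard_normal((3, 3)) / np.sqrt(3),
                                   rng.standard_normal((5, 3)),
                                   0.3 * rng.standard_normal((3, 5)),
                                   np.eye(5))
            except ValueError:
                continue
        ts = truth.simulate(10 ** 5, seed=4)
        est = di.estimate_ss(ts, 6, 6, "AIC")
        freqs = spectral_grid(64)
        H1 = truth.transfer_function(freqs)
        S1 = H1 @ truth.V @ H1.conj().transpose(0, 2, 1)
        H2 = est.transfer_function(freqs)
        S2 = H2 @ est.V @ H2.conj().transpose(0, 2, 1)
        assert np.abs(S1 - S2).max() / np.abs(S1).max() < 0.05

    def test_white_noise_low_order(self):
        rng = np.random.default_rng(5)
        ts = di.TimeSeriesData(rng.standard_normal((3, 4 * 10 ** 4)))
        est = di.estimate_ss(ts, 3, 3, "AIC")
        assert est.state_dim <= 1
        assert np.abs(est.V - np.cov(ts.values)).max() < 0.05

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="minimum-phase"):
            di.SSModel(np.array([[0.5]]), np.array([[1.0]]),
                       np.array([[3.0]]), np.array([[1.0]]))


class TestSpectralDensity:
    def test_ar1_closed_form_at_zero(self):
        var = di.VarModel(np.array([[[0.9]]]), np.array([[1.0]]))
        _, S = di.ss_spectral_density(di.var_to_ss(var), 64)
        assert S[0, 0, 0].real == pytest.approx(1 / abs(1 - 0.9) ** 2)
        lam = spectral_grid(64)
        closed = 1 / np.abs(1 - 0.9 * np.exp(-1j * lam)) ** 2
        assert np.abs(S[:, 0, 0].real - closed).max() < 1e-10

    def test_white_noise_flat(self):
        V = np.array([[2.0, 0.3], [0.3, 1.0]])
        ss = di.SSModel(np.zeros((1, 1)), np.zeros((2, 1)),
                        np.zeros((1, 2)), V)
        _, S = di.ss_spectral_density(ss, 16)
        assert np.abs(S - V).max() < 1e-12

    def test_szego_identity(self, var2):
        # grid mean of log det S equals log det V (Kolmogorov identity)
        ss = di.var_to_ss(var2)
        _, S = di.ss_spectral_density(ss, 2 ** 10)
        ld = np.linalg.slogdet(S)[1].real
        w = np.ones(2 ** 10)
        w[0] = w[-1] = 0.5
        mean_ld = w @ ld / w.sum()
        assert mean_ld == pytest.approx(np.linalg.slogdet(var2.resid_cov)[1],
                                        abs=1e-6)


class TestPairwiseGC:
    def test_absent_edge_zero(self):
        # channel 2 does not drive channel 1
        A = np.array([[[0.5, 0.0], [0.4, 0.3]]])
        ss = di.var_to_ss(di.VarModel(A, np.eye(2)))
        gc = di.pairwise_gc_graph(ss)
        assert gc.gc[1, 0] < 1e-10
        assert gc.gc[0, 1] > 1e-3

    def test_worked_example_support_is_planted(self, worked_example):
        _, ss = worked_example
        gc = di.pairwise_gc_graph(ss)
        assert gc.support(1e-8) == set(DEFAULT_WORKED_EXAMPLE_EDGES)

    def test_matches_large_sample_regression(self, var2):
        # brute force: ratio of regression residuals with/without channel 0
        ss = di.var_to_ss(var2)
        gc = di.pairwise_gc_graph(ss)
        ts = di.simulate_var(var2, 10 ** 5, seed=9)
        x = ts.values
        p, T = 6, ts.n_samples
        target = 1
        full = np.concatenate([x[:, p - k:T - k] for k in range(1, p + 1)]).T
        keep = [c for c in range(full.shape[1]) if c % 3 != 0]
        red = full[:, keep]
        y = x[target, p:]
        res = {}
        for name, Z in (("full", full), ("red", red)):
            B, *_ = np.linalg.lstsq(Z, y, rcond=None)
            res[name] = np.mean((y - Z @ B) ** 2)
        emp = 0.5 * np.log(res["red"] / res["full"])
        se = np.sqrt(2 * p + 8 * T * gc.gc[0, 1]) / (2 * T)
        assert abs(emp - gc.gc[0, 1]) < 3 * se

    def test_permutation_equivariance(self, var2):
        ss = di.var_to_ss(var2)
        gc = di.pairwise_gc_graph(ss).gc
        perm = [2, 0, 1]
        P = np.eye(3)[perm]
        var_p = di.VarModel(np.stack([P @ A @ P.T for A in var2.coeffs]),
                            P @ var2.resid_cov @ P.T)
        gc_p = di.pairwise_gc_graph(di.var_to_ss(var_p)).gc
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert gc_p[i, j] == pytest.approx(
                        gc[perm[i], perm[j]], abs=1e-10)


class TestWorkedExampleGenerator:
    def test_default_scale(self, worked_example):
        var, _ = worked_example
        assert var.n_channels == 9 and var.order == 8
        assert var.spectral_radius < 0.95

    def test_empty_edges_diagonal(self):
        var = di.make_worked_example_var(4, 3, edge_list=(), seed=0)
        off = ~np.eye(4, dtype=bool)
        assert np.all(var.coeffs[:, off] == 0)

    def test_planted_source_macro_is_dynamically_independent(
            self, worked_example):
        _, ss = worked_example
        M = di.CoarseGraining.axis_aligned([7, 8], 9)
        assert di.dd_exact(ss, M).value < 1e-10


class TestTimeSeriesIO:
    def test_csv_round_trip(self, tmp_path, var2):
        ts = di.simulate_var(var2, 100, seed=0)
        ts.to_csv(tmp_path / "x.csv")
        back = di.TimeSeriesData.from_csv(tmp_path / "x.csv")
        assert np.allclose(back.values, ts.values)
        assert back.fs == ts.fs

    def test_model_json_round_trip(self, tmp_path, var2):
        var2.to_json(tmp_path / "m.json")
        back = di.VarModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.coeffs, var2.coeffs)
        ss = di.var_to_ss(var2)
        ss.to_json(tmp_path / "s.json")
        ss2 = di.SSModel.from_json(tmp_path / "s.json")
        assert np.allclose(ss2.K, ss.K)

    def test_invariants(self):
        with pytest.raises(ValueError):
            di.TimeSeriesData(np.ones((3, 2)))     # samples < channels
        with pytest.raises(ValueError):
            di.TimeSeriesData(np.full((2, 10), np.nan))
        with pytest.raises(ValueError):
            di.TimeSeriesData(np.ones((2, 10)), fs=0)
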