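"""Global kinetic analysis: compression, variable projection, DAS↔EAS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from photophys import photocycle as pc
from photophys import synthetic as syn


def make_multiexp_dataset(lifetimes, das, times, wavelengths):
    """Direct multiexponential surface Σᵢ DASᵢ(λ)·exp(−t/τᵢ)."""
    tau = np.asarray(lifetimes, dtype=float)
    das = np.asarray(das, dtype=float)
    decays = np.exp(-np.asarray(times)[None, :] / tau[:, None])
    return pc.TransientDataset(times, wavelengths, das.T @ decays)


class TestQuasilogCompress:
    def test_uniform_sampling_yields_points_per_decade(self):
        """32,000 samples at 10 ns spacing compress to ~100 points in each
        densely sampled decade."""
        t = np.arange(1, 32001) * 1e-8  # 10 ns ... 320 µs
        v = np.sin(t * 1e4)
        t_out, v_out = pc.quasilog_compress(t, v, points_per_decade=100)
        assert t_out.size < t.size
        dense = (t_out >= 1e-5) & (t_out < 1e-4)
        assert 95 <= dense.sum() <= 105
        assert np.all(np.diff(t_out) > 0)

    def test_constant_trace_stays_constant(self):
        t = np.arange(1, 1001) * 1e-6
        t_out, v_out = pc.quasilog_compress(t, np.full_like(t, 3.25), 10)
        assert np.allclose(v_out, 3.25)

    def test_at_most_one_point_per_bin_is_identity(self):
        # log spacing 0.2/decade point pitch vs 1/7-decade bins: every bin
        # holds at most one sample, so averaging must return the input
        t = np.logspace(0, 2, 11)
        v = np.random.default_rng(0).normal(size=t.size)
        t_out, v_out = pc.quasilog_compress(t, v, points_per_decade=7)
        assert np.allclose(t_out, t)
        assert np.allclose(v_out, v)

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            pc.quasilog_compress(np.array([0.0, 1.0, 2.0]), np.zeros(3), 10)

    def test_matrix_compression_matches_per_trace(self):
        t = np.arange(1, 5001) * 1e-7
        m = np.vstack([np.cos(t * 1e4), np.exp(-t * 1e3)])
        t_out, m_out = pc.quasilog_compress(t, m, 50)
        for k in range(2):
            _, row = pc.quasilog_compress(t, m[k], 50)
            assert np.allclose(m_out[k], row)


class TestGlobalFit:
    def test_noiseless_biexponential_exact_recovery(self):
        times = np.logspace(-4, 1, 80)
        wl = np.array([450.0, 500.0, 550.0])
        das = np.array([[1.0, -0.5, 0.2], [0.3, 0.8, -0.4]])
        data = make_multiexp_dataset([1e-3, 0.5], das, times, wl)
        fit = pc.fit_global_exponentials(data, 2)
        assert fit.converged
        assert np.allclose(fit.lifetimes, [1e-3, 0.5], rtol=1e-3)
        assert np.allclose(fit.das, das, atol=1e-6)
        assert fit.weighted_residual_sd < 1e-10

    def test_underfitting_raises_residual_sd(self):
        times = np.logspace(-4, 1, 80)
        wl = np.array([450.0, 500.0, 550.0])
        das = np.array([[1.0, -0.5, 0.2], [0.3, 0.8, -0.4]])
        data = make_multiexp_dataset([1e-3, 0.5], das, times, wl)
        sd1 = pc.fit_global_exponentials(data, 1).weighted_residual_sd
        sd2 = pc.fit_global_exponentials(data, 2).weighted_residual_sd
        assert sd1 > sd2

    def test_varpro_equals_brute_force_joint_fit(self):
        """On a small instance, the variable-projection optimum matches a
        joint nonlinear fit of all amplitudes and lifetimes."""
        rng = np.random.default_rng(11)
        times = np.logspace(-3, 0.5, 60)
        wl = np.array([460.0, 520.0, 580.0])
        das_true = rng.normal(size=(2, 3))
        data = make_multiexp_dataset([5e-3, 0.2], das_true, times, wl)
        noisy = pc.TransientDataset(
            times, wl, data.delta_a + rng.normal(0, 0.01, data.delta_a.shape)
        )
        fit = pc.fit_global_exponentials(noisy, 2)

        def joint_resid(x):
            tau = 10.0 ** x[:2]
            amps = x[2:].reshape(2, 3)
            decays = np.exp(-times[None, :] / tau[:, None])
            return (amps.T @ decays - noisy.delta_a).ravel()

        x0 = np.concatenate([np.log10([3e-3, 0.3]), das_true.ravel()])
        sol = least_squares(joint_resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        brute_tau = np.sort(10.0 ** sol.x[:2])
        assert np.allclose(fit.lifetimes, brute_tau, rtol=1e-6)

    def test_fixture_recovery_with_noise(self, noisy_transient):
        fit = pc.fit_global_exponentials(noisy_transient, 3)
        truth = np.array(noisy_transient.truth["spec"].lifetimes)
        assert np.all(np.abs(fit.lifetimes - truth) / truth < 0.10)

    def test_weights_down_weight_corrupted_points(self, photocycle_spec):
        """Zero-weighting a corrupted block of the surface restores the fit."""
        data = syn.gen_transient_dataset(photocycle_spec)
        bad = data.delta_a.copy()
        bad[:5, :10] += 5.0
        w = np.ones_like(bad)
        w[:5, :10] = 0.0
        fit = pc.fit_global_exponentials(
            pc.TransientDataset(data.times, data.wavelengths, bad, w), 3
        )
        truth = np.array(photocycle_spec.lifetimes)
        assert np.all(np.abs(fit.lifetimes - truth) / truth < 0.01)

    def test_degenerate_lifetimes_flagged(self):
        times = np.logspace(-3, 1, 50)
        wl = np.array([450.0, 500.0, 550.0])
        das = np.array([[1.0, 0.5, 0.2], [0.3, 0.8, 0.4]])
        data = make_multiexp_dataset([0.1, 0.102], das, times, wl)
        with pytest.warns(RuntimeWarning):
            fit = pc.fit_global_exponentials(data, 2, initial_lifetimes=[0.09, 0.11])
        assert fit.degenerate

    def test_too_many_parameters_rejected(self):
        data = make_multiexp_dataset([0.1], [[1.0]], np.array([0.1, 0.2]), np.array([500.0]))
        with pytest.raises(ValueError):
            pc.fit_global_exponentials(data, 2)


class TestModelSelection:
    def test_monoexponential_selects_one(self):
        times = np.logspace(-3, 1, 60)
        wl = np.array([450.0, 500.0, 550.0])
        data = make_multiexp_dataset([0.2], [[1.0, -0.5, 0.3]], times, wl)
        noisy = pc.TransientDataset(
            times, wl,
            data.delta_a + np.random.default_rng(2).normal(0, 0.005, data.delta_a.shape),
        )
        assert pc.select_model(noisy, n_max=4).n_components == 1

    def test_unit_tolerance_always_selects_one(self, noisy_transient):
        fit = pc.select_model(noisy_transient, n_max=4, rel_improvement_tol=1.0)
        assert fit.n_components == 1

    def test_fixture_selects_three_components(self, noisy_transient):
        fit = pc.select_model(noisy_transient, n_max=5, rel_improvement_tol=0.05)
        assert fit.n_components == 3
        assert list(fit.sd_trace) == [1, 2, 3, 4]

    def test_sd_trace_nonincreasing(self, noisy_transient):
        fit = pc.select_model(noisy_transient, n_max=5, rel_improvement_tol=0.05)
        sds = [fit.sd_trace[n] for n in sorted(fit.sd_trace)]
        assert all(a >= b - 1e-15 for a, b in zip(sds, sds[1:]))


class TestDasToEas:
    def test_single_component_eas_equals_das(self):
        fit = pc.GlobalFitResult(1, np.array([0.3]), np.array([[1.0, 2.0, 3.0]]),
                                 np.array([450.0, 500.0, 550.0]), 0.0, True)
        scheme = pc.das_to_eas(fit)
        assert np.allclose(scheme.eas, fit.das)

    def test_first_eas_is_das_sum(self):
        """c₁(0) = 1 with all later compartments empty, so EAS₁ must equal
        the t = 0⁺ spectrum Σᵢ DASᵢ."""
        rng = np.random.default_rng(5)
        das = rng.normal(size=(3, 7))
        fit = pc.GlobalFitResult(3, np.array([1e-4, 0.3, 1.5]), das,
                                 np.linspace(400, 640, 7), 0.0, True)
        scheme = pc.das_to_eas(fit)
        assert np.allclose(scheme.eas[0], das.sum(axis=0))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        n=st.integers(min_value=1, max_value=5),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_reconstruction_identity(self, n, seed):
        """Σⱼ cⱼ(t)·EASⱼ(λ) must reproduce Σᵢ DASᵢ(λ)·e^(−t/τᵢ) exactly."""
        rng = np.random.default_rng(seed)
        tau = np.sort(10 ** rng.uniform(-5, 1, n))
        while np.any(tau[1:] / tau[:-1] < 1.5):  # keep rates well separated
            tau = np.sort(10 ** rng.uniform(-5, 1, n))
        wl = np.linspace(400, 640, 7)
        das = rng.normal(size=(n, wl.size))
        t = 10 ** rng.uniform(-6, 1, 100)
        fit = pc.GlobalFitResult(n, tau, das, wl, 0.0, True)
        scheme = pc.das_to_eas(fit, times=t)
        recon = scheme.eas.T @ scheme.concentrations        # (n_wl, n_t)
        direct = das.T @ np.exp(-np.outer(1.0 / tau, t))
        assert np.max(np.abs(recon - direct)) < 1e-10 * max(np.max(np.abs(direct)), 1.0)

    def test_nearly_equal_rates_warn(self):
        das = np.ones((2, 3))
        fit = pc.GlobalFitResult(2, np.array([0.1, 0.101]), das,
                                 np.array([450.0, 500.0, 550.0]), 0.0, True)
        with pytest.warns(RuntimeWarning):
            scheme = pc.das_to_eas(fit)
        assert scheme.condition_warning is not None


class TestIntermediateSpectra:
    def _scheme(self, eas, wl):
        return pc.SequentialScheme(
            rates=np.array([10.0]), bateman=np.array([[1.0]]), eas=eas,
            concentrations=np.ones((1, 2)), times=np.array([0.1, 0.2]), wavelengths=wl,
        )

    def test_zero_eas_returns_ground(self):
        wl = np.linspace(400, 600, 21)
        ground = pc.Spectrum(wl, np.exp(-((wl - 500) ** 2) / 2000))
        specs = pc.intermediate_spectra(self._scheme(np.zeros((1, 21)), wl), ground, 0.5)
        assert np.allclose(specs[0].values, ground.values)

    def test_excited_fraction_linearity(self):
        wl = np.linspace(400, 600, 21)
        ground = pc.Spectrum(wl, np.zeros(21))
        eas = np.ones((1, 21))
        full = pc.intermediate_spectra(self._scheme(eas, wl), ground, 0.4)[0].values
        half = pc.intermediate_spectra(self._scheme(eas, wl), ground, 0.2)[0].values
        assert np.allclose(half, 2 * full)

    def test_zero_excited_fraction_rejected(self):
        wl = np.linspace(400, 600, 21)
        ground = pc.Spectrum(wl, np.zeros(21))
        with pytest.raises(ValueError):
            pc.intermediate_spectra(self._scheme(np.zeros((1, 21)), wl), ground, 0.0)


class TestFindLambdaMax:
    @staticmethod
    def _gauss(wl, center=500.0):
        return np.exp(-((wl - center) ** 2) / (2 * 35.0**2))

    def test_fine_grid_exact(self):
        wl = np.arange(400.0, 601.0, 1.0)
        res = pc.find_lambda_max(pc.Spectrum(wl, self._gauss(wl)))
        assert not res.at_edge
        assert res.wavelength == pytest.approx(500.0, abs=0.01)

    def test_coarse_grid_parabolic_refinement(self):
        """10 nm sampling still localizes the peak within 1 nm, verified
        against the fine-grid maximum as oracle."""
        fine = np.arange(400.0, 600.01, 0.01)
        oracle = fine[np.argmax(self._gauss(fine, center=503.0))]
        coarse = np.arange(400.0, 601.0, 10.0)
        res = pc.find_lambda_max(pc.Spectrum(coarse, self._gauss(coarse, center=503.0)))
        assert abs(res.wavelength - oracle) < 1.0

    def test_window_excludes_protein_band(self):
        wl = np.arange(250.0, 651.0, 5.0)
        v = 3 * self._gauss(wl, 280.0) + self._gauss(wl, 500.0)
        res = pc.find_lambda_max(pc.Spectrum(wl, v), window=(350.0, 650.0))
        assert res.wavelength == pytest.approx(500.0, abs=1.0)

    def test_edge_maximum_flagged(self):
        wl = np.arange(400.0, 501.0, 10.0)
        res = pc.find_lambda_max(pc.Spectrum(wl, wl.copy()))
        assert res.at_edge
        assert res.wavelength == 500.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pc.find_lambda_max(
                pc.Spectrum(np.array([400.0, 500.0, 600.0]), np.ones(3)),
                window=(450.0, 550.0),
            )
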