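"""MVAR fitting, PDC, spectral-power weighting, bands, summed outflow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdcflow.connectivity import (
    DEFAULT_FREQS,
    SpectralPower,
    average_pdc_over_epochs,
    band_average,
    minmax_scale,
    offdiagonal_mask,
    pdc_spectrum,
    roi_spectral_power,
    subject_pdc,
    summed_outflow,
    weight_pdc,
)
from pdcflow.mvar import MVARModel, fit_mvar, simulate_mvar_epochs
from pdcflow.synthetic import (
    GroundTruthNetwork,
    make_random_stable_mvar,
)


class TestFitMVAR:
    def test_white_noise_has_no_spurious_structure(self, rng):
        data = rng.standard_normal((4, 3000))
        m = fit_mvar(data, order=2)
        se = 1.0 / np.sqrt(3000)
        assert np.abs(m.coeffs).max() < 4 * se

    def test_deterministic(self, rng):
        data = rng.standard_normal((3, 500))
        a = fit_mvar(data, order=3)
        b = fit_mvar(data, order=3)
        assert np.array_equal(a.coeffs, b.coeffs)

    def test_rank_deficient_design_raises(self):
        x = np.random.default_rng(0).standard_normal((1, 200))
        dup = np.vstack([x, x])  # identical channels -> collinear lags
        with pytest.raises(np.linalg.LinAlgError):
            fit_mvar(dup, order=2)

    def test_too_short_epoch_raises(self, rng):
        with pytest.raises(ValueError):
            fit_mvar(rng.standard_normal((10, 40)), order=5)

    def test_rmse_improves_with_sqrt_T(self):
        from pdcflow.experiments import coefficient_recovery_rmse

        r_short = coefficient_recovery_rmse(T=1250, seed=0)
        r_long = coefficient_recovery_rmse(T=5000, seed=0)
        assert r_long < 0.7 * r_short  # ~sqrt(4) ideally

    def test_multi_trial_pooling_recovers_coefficients(self):
        net = GroundTruthNetwork(n_rois=3, edges=[(0, 1, 0.4, 1)])
        model = make_random_stable_mvar(3, 5, net, seed=1)
        x = simulate_mvar_epochs(model, n_epochs=120, n_samples=125, seed=2)
        fitted = fit_mvar(x, order=5)
        assert np.sqrt(np.mean((fitted.coeffs - model.coeffs) ** 2)) < 0.05


class TestPDCSpectrum:
    def test_zero_coefficients_give_identity_pattern(self):
        m = MVARModel(coeffs=np.zeros((1, 3, 3)), noise_cov=np.eye(3))
        pdc = pdc_spectrum(m, DEFAULT_FREQS)
        eye = np.eye(3)[:, :, None] * np.ones((1, 1, len(DEFAULT_FREQS)))
        assert np.allclose(pdc, eye, atol=1e-14)

    def test_bivariate_hand_computed_value(self):
        # x2 driven by x1 at lag 1: Abar(0) = [[1,0],[-0.5,1]], so
        # PDC(2<-1) = 0.5/sqrt(1.25), PDC(1<-1) = 1/sqrt(1.25)
        A = np.zeros((1, 2, 2))
        A[0, 1, 0] = 0.5
        m = MVARModel(coeffs=A, noise_cov=np.eye(2))
        pdc = pdc_spectrum(m, np.array([0.0]))
        assert abs(pdc[1, 0, 0] - 0.5 / np.sqrt(1.25)) < 1e-12
        assert abs(pdc[0, 0, 0] - 1.0 / np.sqrt(1.25)) < 1e-12

    def test_column_normalisation_on_random_stable_models(self):
        from pdcflow.experiments import pdc_column_norm_deviation

        assert pdc_column_norm_deviation(n_models=10, seed=4) < 1e-10

    def test_empty_grid_refused(self):
        m = MVARModel(coeffs=np.zeros((1, 2, 2)), noise_cov=np.eye(2))
        with pytest.raises(ValueError):
            pdc_spectrum(m, np.array([]))

    def test_absent_edges_stay_below_surrogate_null(self):
        # planted 5-ROI network: off-edge PDC at theta should sit below
        # the 95th percentile of its white-noise fitted null
        net = GroundTruthNetwork(n_rois=5, edges=[(0, 1, 0.5, 1), (2, 3, 0.5, 1)])
        model = make_random_stable_mvar(5, 5, net, seed=0)
        x = simulate_mvar_epochs(model, 60, 125, seed=1)
        pdc = subject_pdc(x, fs=125.0)
        theta = pdc[:, :, 3:7].mean(axis=2)
        null_vals = []
        for s in range(100):
            noise = np.random.default_rng(10_000 + s).standard_normal((5, 125, 5))
            null_vals.append(subject_pdc(noise, fs=125.0)[:, :, 3:7].mean(axis=2))
        thresh = np.percentile(np.stack(null_vals), 95, axis=0)
        absent = ~np.eye(5, dtype=bool)
        absent[1, 0] = absent[3, 2] = False
        assert (theta[absent] <= thresh[absent] + 0.05).all()
        # the planted edges clear the null decisively
        assert theta[1, 0] > thresh[1, 0] and theta[3, 2] > thresh[3, 2]


class TestAveragePDC:
    def test_identical_and_two_epoch_means(self, rng):
        a = rng.random((3, 3, 5))
        assert np.array_equal(average_pdc_over_epochs([a, a]), a)
        b = rng.random((3, 3, 5))
        assert np.allclose(average_pdc_over_epochs([a, b]), (a + b) / 2)

    def test_grid_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            average_pdc_over_epochs([rng.random((3, 3, 5)), rng.random((3, 3, 6))])

    def test_mean_of_per_epoch_pdc_approaches_analytic(self):
        # bivariate model, 120 simulated epochs, per-epoch fits
        A = np.zeros((1, 2, 2))
        A[0, 1, 0] = 0.4
        A[0, 0, 0] = 0.3
        model = MVARModel(coeffs=A, noise_cov=np.eye(2))
        x = simulate_mvar_epochs(model, 120, 125, seed=7)
        est = subject_pdc(x, fs=125.0, order=1, per_epoch=True)
        truth = pdc_spectrum(model, DEFAULT_FREQS)
        # per-epoch estimates of null edges carry the |z| noise floor
        # E|N(0, se)| ~ 0.8/sqrt(T) ~ 0.07, which averaging over epochs
        # cannot remove; the pooled estimator is an order of magnitude
        # tighter
        assert np.abs(est - truth).max() < 0.09
        pooled = subject_pdc(x, fs=125.0, order=1)
        assert np.abs(pooled - truth).max() < 0.01


class TestSpectralPower:
    def test_zero_input_zero_power(self, small_leadfield):
        from pdcflow.inverse import build_inverse
        from pdcflow.synthetic import assign_rois_to_points

        inv = build_inverse(small_leadfield)
        pl = assign_rois_to_points(small_leadfield, 3, seed=0)
        sp = roi_spectral_power(
            np.zeros((small_leadfield.n_electrodes, 125, 2)),
            125.0, inv, pl.point_indices, np.eye(3)[:, :3][:3],
        )
        assert np.all(sp.values == 0.0)

    def test_single_source_peaks_at_its_frequency(self, small_leadfield):
        from pdcflow.experiments import reconstruct_roi_series
        from pdcflow.inverse import build_inverse
        from pdcflow.synthetic import assign_rois_to_points, project_to_sensors

        inv = build_inverse(small_leadfield)
        pl = assign_rois_to_points(small_leadfield, 3, seed=1)
        t = np.arange(125) / 125.0
        src = np.zeros((3, 125, 4))
        src[0] = np.sin(2 * np.pi * 10 * t)[:, None]
        sens = project_to_sensors(src, small_leadfield, pl, snr=np.inf)
        _, orients = reconstruct_roi_series(sens, inv, pl.point_indices)
        sp = roi_spectral_power(sens, 125.0, inv, pl.point_indices, orients)
        assert sp.freqs[np.argmax(sp.values[0])] == 10.0

    def test_parseval_total_power_matches_time_domain(self, small_leadfield, rng):
        from pdcflow.experiments import reconstruct_roi_series
        from pdcflow.inverse import build_inverse
        from pdcflow.synthetic import assign_rois_to_points, project_to_sensors

        inv = build_inverse(small_leadfield)
        pl = assign_rois_to_points(small_leadfield, 3, seed=2)
        src = rng.standard_normal((3, 125, 3))
        sens = project_to_sensors(src, small_leadfield, pl, snr=np.inf)
        series, orients = reconstruct_roi_series(sens, inv, pl.point_indices)
        T = 125
        full = np.fft.rfftfreq(T, 1 / 125.0)
        sp = roi_spectral_power(
            sens, 125.0, inv, pl.point_indices, orients, freqs=full
        )
        # sum over rfft bins with the one/two-sided weighting equals
        # T * sum(x^2) per epoch (Parseval)
        w = np.ones(len(full)) * 2.0
        w[0] = 1.0
        if T % 2 == 0:
            w[-1] = 1.0
        lhs = (sp.values * w).sum(axis=1)
        rhs = T * (series**2).sum(axis=1).mean(axis=1)
        assert np.abs(lhs - rhs).max() / rhs.max() < 1e-6


class TestMinMaxScale:
    def test_simple_triple(self):
        assert np.allclose(minmax_scale(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_zero_one_data_is_fixed_point(self, rng):
        x = rng.random(20)
        x[0], x[1] = 0.0, 1.0
        assert np.allclose(minmax_scale(x), x)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-20.0, 20.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).random(15)
        x[0], x[1] = x[0] + 1.5, x[1] - 1.5  # guarantee a range
        assert np.allclose(minmax_scale(a * x + b), minmax_scale(x), atol=1e-9)

    def test_constant_input_refused(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_scale(np.full(5, 3.3))


class TestWeightAndBands:
    def test_unit_power_weight_is_identity(self, rng):
        pdc = rng.random((4, 4, 40))
        sp = np.ones((4, 40))
        assert np.array_equal(weight_pdc(pdc, sp), pdc)

    def test_silent_sender_has_zero_outflow(self, rng):
        pdc = rng.random((4, 4, 40))
        sp = np.ones((4, 40))
        sp[2] = 0.0
        w = weight_pdc(pdc, sp)
        out = summed_outflow(band_average(w)["theta"])
        assert out[2] == 0.0

    def test_weighting_matches_loop_oracle(self, rng):
        pdc = rng.random((3, 3, 40))
        sp = rng.random((3, 40))
        w = weight_pdc(pdc, sp)
        for i in range(3):
            for j in range(3):
                for f in range(0, 40, 7):
                    assert w[i, j, f] == pytest.approx(sp[j, f] * pdc[i, j, f])

    def test_band_average_constant_and_single_bin(self):
        const = np.full((2, 2, 40), 0.7)
        bands = band_average(const)
        assert all(np.allclose(v, 0.7) for v in bands.values())
        x = np.zeros((2, 2, 40))
        x[0, 1, 4] = 0.8  # 5 Hz bin on the 1..40 grid
        assert band_average(x)["theta"][0, 1] == pytest.approx(0.8 / 4)

    def test_band_average_matches_loop_oracle(self, rng):
        x = rng.random((3, 3, 40))
        got = band_average(x)["alpha"]
        freqs = DEFAULT_FREQS
        sel = [k for k, f in enumerate(freqs) if 8 <= f <= 12]
        expect = sum(x[:, :, k] for k in sel) / len(sel)
        assert np.allclose(got, expect)

    def test_band_outside_grid_refused(self, rng):
        with pytest.raises(ValueError):
            band_average(rng.random((2, 2, 40)), bands={"hf": (50.0, 60.0)})

    def test_summed_outflow_examples(self):
        assert np.all(summed_outflow(np.zeros((4, 4))) == 0.0)
        m = np.zeros((3, 3))
        m[1, 2], m[0, 2] = 0.2, 0.3
        assert summed_outflow(m)[2] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            summed_outflow(np.zeros((2, 3)))


class TestPipelineProperties:
    def test_permutation_equivariance(self, rng):
        net = GroundTruthNetwork(n_rois=4, edges=[(0, 2, 0.4, 1)])
        model = make_random_stable_mvar(4, 3, net, offdiag_strength=0.05, seed=2)
        perm = np.array([2, 0, 3, 1])
        coeffs_p = model.coeffs[:, perm][:, :, perm]
        model_p = MVARModel(coeffs=coeffs_p, noise_cov=np.eye(4), fs=model.fs)
        pdc = pdc_spectrum(model, DEFAULT_FREQS)
        pdc_p = pdc_spectrum(model_p, DEFAULT_FREQS)
        assert np.allclose(pdc_p, pdc[perm][:, perm], atol=1e-12)
        out = summed_outflow(band_average(pdc)["theta"])
        out_p = summed_outflow(band_average(pdc_p)["theta"])
        assert np.allclose(out_p, out[perm], atol=1e-12)

    def test_wpdc_and_outflow_ranges(self, rng):
        from pdcflow.connectivity import subject_outflow

        net = GroundTruthNetwork(n_rois=5, edges=[(0, 1, 0.4, 1)])
        model = make_random_stable_mvar(5, 5, net, offdiag_strength=0.05, seed=3)
        x = simulate_mvar_epochs(model, 30, 125, seed=4)
        pdc = subject_pdc(x, fs=125.0)
        F = np.abs(np.fft.rfft(x, axis=1)) ** 2
        sp = SpectralPower(values=F.mean(axis=2)[:, 1:41], freqs=DEFAULT_FREQS)
        out = subject_outflow(pdc, sp)
        for vec in out.values():
            assert np.all(vec >= 0.0) and np.all(vec <= 4.0)

    def test_theta_edge_shows_frequency_specificity(self):
        # an edge carried by 6 Hz dynamics: theta-band wPDC on that edge
        # exceeds its beta-band value
        from pdcflow.connectivity import subject_outflow

        net = GroundTruthNetwork(n_rois=4, edges=[(0, 1, 0.5, 1)])
        damp = np.array([0.9, 0.3, 0.3, 0.3])
        cov = np.eye(4)
        cov[0, 0] = 4.0
        model = make_random_stable_mvar(
            4, 5, net, seed=5, osc_freq_hz=6.0, osc_damping=damp, noise_cov=cov
        )
        x = simulate_mvar_epochs(model, 60, 125, seed=6)
        pdc = subject_pdc(x, fs=125.0)
        F = np.abs(np.fft.rfft(x, axis=1)) ** 2
        sp = SpectralPower(values=F.mean(axis=2)[:, 1:41], freqs=DEFAULT_FREQS)
        pdc_scaled = minmax_scale(pdc, pool_mask=offdiagonal_mask(4, 40))
        w = weight_pdc(np.clip(pdc_scaled, 0, 1), minmax_scale(sp.values))
        bands = band_average(w)
        assert bands["theta"][1, 0] > bands["beta"][1, 0]
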