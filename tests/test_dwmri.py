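"""ADC fitting, map building, rendering, and the reporter contrast statistic."""

import numpy as np
import pytest

from reporterdiff.dwmri import (
    ADCEstimate,
    DiffusionSeries,
    SignalDecay,
    aggregate_percent_delta,
    correct_rician_floor,
    effective_bvalue,
    fit_adc,
    fit_adc_map,
    mm2_per_s_to_um2_per_ms,
    percent_delta_diffusivity,
    render_diffusion_map,
    rician_expected_magnitude,
    roi_mean_signal,
    um2_per_ms_to_mm2_per_s,
)
from reporterdiff.synth import Compartment, PelletPhantomSpec, make_pellet_phantom


class TestEffectiveBvalue:
    def test_zero_gradient_gives_zero_b(self):
        assert effective_bvalue(2.675e8, 0.0, 5.0, 300.0) == 0.0

    def test_quadratic_in_gradient_amplitude(self):
        b1 = effective_bvalue(2.675e8, 0.02, 5.0, 300.0)
        b2 = effective_bvalue(2.675e8, 0.04, 5.0, 300.0)
        assert b2 == pytest.approx(4.0 * b1, rel=1e-12)

    def test_dimensional_oracle(self):
        # hand-tracked SI evaluation for the stimulated-echo timing
        # (δ=5 ms, Δ=300 ms) at G = 43.3 mT/m:
        # γ² = 7.155625e16; G² = 1.874890e-3 T²/m²; δ² = 2.5e-5 s²;
        # (Δ − δ/3) = 0.29833... s → b = 1.000609e9 s/m² = 1.000609 ms/µm²
        b = effective_bvalue(2.675e8, 0.0433, 5.0, 300.0)
        assert b == pytest.approx(1.000609, rel=1e-5)

    def test_rejects_bad_timing(self):
        with pytest.raises(ValueError):
            effective_bvalue(2.675e8, 0.04, 5.0, 1.0)  # Delta <= delta/3
        with pytest.raises(ValueError):
            effective_bvalue(-1.0, 0.04, 5.0, 300.0)

    def test_unit_round_trip(self):
        assert mm2_per_s_to_um2_per_ms(um2_per_ms_to_mm2_per_s(1.37)) == 1.37


class TestRoiMeanSignal:
    def test_uniform_image(self):
        b = np.array([1.0, 2.0, 3.0])
        series = DiffusionSeries(np.full((8, 8, 3), 10.0), b)
        decay = roi_mean_signal(series, np.ones((8, 8), bool))
        assert np.allclose(decay.signals, 10.0)
        assert np.array_equal(decay.bvalues, b)

    def test_single_voxel_mask(self, rng):
        stack = rng.uniform(1, 100, (6, 6, 4))
        series = DiffusionSeries(stack, [1.0, 1.5, 2.0, 3.0])
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        decay = roi_mean_signal(series, mask)
        assert np.array_equal(decay.signals, stack[2, 3])

    def test_matches_brute_force(self, rng):
        stack = rng.uniform(1, 100, (10, 12, 4))
        series = DiffusionSeries(stack, [1.0, 1.5, 2.0, 3.0])
        mask = rng.random((10, 12)) > 0.5
        decay = roi_mean_signal(series, mask)
        for k in range(4):
            total, count = 0.0, 0
            for i in range(10):
                for j in range(12):
                    if mask[i, j]:
                        total += stack[i, j, k]
                        count += 1
            assert decay.signals[k] == pytest.approx(total / count)

    def test_empty_and_mismatched_mask(self):
        series = DiffusionSeries(np.ones((4, 4, 2)), [1.0, 2.0])
        with pytest.raises(ValueError):
            roi_mean_signal(series, np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            roi_mean_signal(series, np.ones((3, 4), bool))


class TestFitAdc:
    def test_exact_recovery_on_clean_decay(self):
        b = np.array([1.0, 2.0, 3.0])
        est = fit_adc(SignalDecay(b, 1000.0 * np.exp(-b * 0.8)))
        assert est.D == pytest.approx(0.8, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)
        assert est.S0 == pytest.approx(1000.0, rel=1e-10)

    def test_constant_signal_gives_zero_d(self):
        est = fit_adc(SignalDecay([1.0, 2.0, 3.0], [50.0, 50.0, 50.0]))
        assert est.D == pytest.approx(0.0, abs=1e-14)

    def test_exactness_any_two_bvalues(self):
        # exactness limit holds for any >=2 distinct b-values in range
        for bpair in ([1.0, 3.0], [1.2, 2.1, 2.9], [1.0, 1.1]):
            b = np.array(bpair)
            est = fit_adc(SignalDecay(b, 7.7 * np.exp(-b * 1.43)))
            assert abs(est.D - 1.43) / 1.43 < 1e-10

    def test_nonpositive_signal_names_bvalue(self):
        with pytest.raises(ValueError, match="b=2"):
            fit_adc(SignalDecay([1.0, 2.0, 3.0], [10.0, 0.0, 1.0]))

    def test_nonlinear_agrees_with_log_linear_on_clean_data(self):
        b = np.array([1.0, 1.6667, 2.3333, 3.0])
        decay = SignalDecay(b, 800.0 * np.exp(-b * 1.1))
        d_log = fit_adc(decay, "log-linear").D
        d_nl = fit_adc(decay, "nonlinear").D
        assert d_nl == pytest.approx(d_log, rel=1e-6)

    def test_rician_phantom_recovery(self):
        # D_true = 1.2, SNR 50, 5 averages: noise-floor-corrected ROI fit
        # recovers within 5%
        spec = PelletPhantomSpec(
            compartments=[Compartment((64, 64), 20, 1.2)],
            snr=50.0, averages=5, seed=11)
        series, truth = make_pellet_phantom(spec)
        sigma = 1000.0 / spec.snr
        decay = roi_mean_signal(series, np.isfinite(truth))
        est = fit_adc(decay, noise_sigma=sigma)
        assert est.D == pytest.approx(1.2, rel=0.05)


class TestRicianCorrection:
    def test_mean_matches_monte_carlo(self, rng):
        sigma = 10.0
        for nu in (0.0, 5.0, 30.0, 200.0):
            draws = np.hypot(nu + rng.normal(0, sigma, 200_000),
                             rng.normal(0, sigma, 200_000))
            assert rician_expected_magnitude(nu, sigma) == pytest.approx(
                draws.mean(), rel=5e-3, abs=0.1)

    def test_inversion_round_trip(self):
        sigma = 7.0
        nu = np.array([1.0, 3.0, 10.0, 50.0, 1000.0])
        m = rician_expected_magnitude(nu, sigma)
        assert np.allclose(correct_rician_floor(m, sigma), nu, rtol=1e-3)

    def test_floor_maps_to_zero(self):
        sigma = 5.0
        floor = sigma * np.sqrt(np.pi / 2)
        assert correct_rician_floor(np.array([floor * 0.9]), sigma)[0] == 0.0


class TestFitAdcMap:
    def test_noiseless_piecewise_recovery(self, noiseless_two_compartment):
        _, series, truth = noiseless_two_compartment
        mask = np.isfinite(truth)
        dmap = fit_adc_map(series, mask)
        assert dmap.valid[mask].all()
        assert np.allclose(dmap.D[mask], truth[mask], rtol=1e-10)
        assert np.all(np.isnan(dmap.D[~mask]))

    def test_zero_intensity_voxel_invalidated(self, noiseless_two_compartment):
        _, series, truth = noiseless_two_compartment
        mask = np.isfinite(truth)
        stack = series.stack.copy()
        ij = tuple(np.argwhere(mask)[0])
        stack[ij][1] = 0.0
        broken = DiffusionSeries(stack, series.bvalues)
        dmap = fit_adc_map(broken, mask)
        assert not dmap.valid[ij]
        others = mask.copy()
        others[ij] = False
        assert dmap.valid[others].all()

    def test_oracle_equivalence_with_scalar_fit(self, rng):
        stack = rng.uniform(10, 100, (5, 5, 4))
        series = DiffusionSeries(stack, [1.0, 1.5, 2.0, 3.0])
        mask = np.ones((5, 5), bool)
        dmap = fit_adc_map(series, mask)
        for i in range(5):
            for j in range(5):
                single = fit_adc(SignalDecay(series.bvalues, stack[i, j]))
                assert dmap.D[i, j] == pytest.approx(single.D, rel=1e-10)

    def test_noisy_phantom_median_within_3pct(self):
        spec = PelletPhantomSpec(
            compartments=[Compartment((64, 64), 16, 1.0)],
            snr=50.0, seed=3)
        series, truth = make_pellet_phantom(spec)
        mask = np.isfinite(truth)
        assert mask.sum() >= 500
        dmap = fit_adc_map(series, mask, noise_sigma=1000.0 / spec.snr)
        med = np.median(dmap.D[dmap.valid])
        assert med == pytest.approx(1.0, rel=0.03)

    def test_noiseless_monotone_in_d_true(self):
        # higher D_true -> lower signal at every b > 0 and higher estimate
        b = np.array([1.0, 2.0, 3.0])
        prev_sig, prev_d = None, -1.0
        for d in (0.5, 1.0, 1.5, 2.0):
            s = 1000.0 * np.exp(-b * d)
            if prev_sig is not None:
                assert np.all(s < prev_sig)
            est = fit_adc(SignalDecay(b, s))
            assert est.D > prev_d
            prev_sig, prev_d = s, est.D


class TestRenderDiffusionMap:
    def _const_map(self, value, shape=(6, 6)):
        from reporterdiff.dwmri import DiffusionMap
        D = np.full(shape, float(value))
        return DiffusionMap(D, np.ones(shape, bool), np.array([1.0, 2.0]))

    def test_clamp_endpoints(self):
        low = render_diffusion_map(self._const_map(0.2), 0.2, 2.5, kernel=1)
        high = render_diffusion_map(self._const_map(2.5), 0.2, 2.5, kernel=1)
        assert np.all(low.image == 0)
        assert np.all(high.image == 255)

    def test_kernel_one_is_pure_rescale(self):
        mid = render_diffusion_map(self._const_map(1.35), 0.2, 2.5, kernel=1)
        expected = round((1.35 - 0.2) / 2.3 * 255)
        assert np.all(mid.image == expected)

    def test_outlier_replaced_by_neighborhood_median(self):
        from reporterdiff.dwmri import DiffusionMap
        D = np.full((7, 7), 1.0)
        D[3, 3] = 2.4
        dmap = DiffusionMap(D, np.ones((7, 7), bool), np.array([1.0, 2.0]))
        out = render_diffusion_map(dmap, 0.0, 2.55, kernel=3)
        assert out.image[3, 3] == out.image[0, 0]  # median removes spike

    def test_invalid_voxels_excluded_from_neighborhoods(self):
        from reporterdiff.dwmri import DiffusionMap
        D = np.full((5, 5), 1.0)
        valid = np.ones((5, 5), bool)
        D[2, 2] = np.nan
        valid[2, 2] = False
        out = render_diffusion_map(
            DiffusionMap(D, valid, np.array([1.0, 2.0])), 0.0, 2.0, kernel=3)
        assert out.image.min() >= 0 and out.image.max() <= 255
        assert out.image[1, 1] == out.image[0, 0]

    def test_affine_rescale_invariance(self, rng):
        from reporterdiff.dwmri import DiffusionMap
        D = rng.uniform(0.5, 2.0, (8, 8))
        dmap = DiffusionMap(D, np.ones((8, 8), bool), np.array([1.0, 2.0]))
        a, c = 3.7, 0.9
        dmap2 = DiffusionMap(a * D + c, np.ones((8, 8), bool),
                             np.array([1.0, 2.0]))
        r1 = render_diffusion_map(dmap, 0.2, 2.5, kernel=3)
        r2 = render_diffusion_map(dmap2, a * 0.2 + c, a * 2.5 + c, kernel=3)
        assert np.array_equal(r1.image, r2.image)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            render_diffusion_map(self._const_map(1.0), 0.2, 2.5, kernel=4)


class TestPercentDelta:
    def test_reported_contrast_scales(self):
        # the fold increases reported for the hippocampal and breast-cancer
        # lines: D/D0 of 1.794 and 2.625 against unit baseline
        assert percent_delta_diffusivity(1.794, 1.0) == pytest.approx(79.4)
        assert percent_delta_diffusivity(2.625, 1.0) == pytest.approx(162.5)

    def test_identity_and_errors(self):
        assert percent_delta_diffusivity(1.3, 1.3) == 0.0
        with pytest.raises(ValueError):
            percent_delta_diffusivity(1.0, 0.0)

    def test_replicate_aggregation_uses_sample_sd(self):
        D = np.array([1.8, 1.75, 1.85, 1.9])
        D0 = np.array([1.0, 1.0, 1.0, 1.0])
        mean, sem = aggregate_percent_delta(D, D0)
        pct = 100 * (D - D0) / D0
        assert mean == pytest.approx(pct.mean())
        assert sem == pytest.approx(pct.std(ddof=1) / 2.0)
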