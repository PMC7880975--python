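"""Quantification: conversion, gamma QC, AIF detection, Boxerman, bSVD, maps."""

import dataclasses

import numpy as np
import pytest

import perfstrat as ps
from perfstrat.curves import ConcentrationCurve
from perfstrat.dsc import (
    DscStudy,
    _bsvd_operator,
    boxerman_correct,
    compute_cbv,
    compute_maps,
    compute_mtt,
    deconvolve_bsvd,
    detect_aif,
    fit_gamma_variate,
    qc_first_pass,
    signal_to_concentration,
)
from perfstrat.errors import (
    ConversionError,
    CorrectionError,
    DetectionError,
    NormalizationError,
    ParameterError,
)
from perfstrat.phantom import GroundTruthVoxel, residue_weights, residue_convolve


class TestSignalConversion:
    def test_constant_signal_maps_to_zero(self, timing):
        curve = signal_to_concentration(np.full(timing.n_timepoints, 500.0), timing)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_known_exponential_attenuation_inverts_exactly(self, timing):
        c = 7.3
        s = 500.0 * np.exp(-timing.echo_time * np.r_[
            np.zeros(timing.baseline_points),
            np.full(timing.n_timepoints - timing.baseline_points, c)])
        curve = signal_to_concentration(s, timing)
        np.testing.assert_allclose(
            curve.values[timing.baseline_points:], c, rtol=1e-12)

    def test_nonpositive_sample_names_the_index(self, timing):
        s = np.full(timing.n_timepoints, 500.0)
        s[13] = 0.0
        with pytest.raises(ConversionError, match="13"):
            signal_to_concentration(s, timing)


class TestGammaFitAndQc:
    def test_noiseless_parameters_recovered(self, timing):
        curve = ps.generate_aif_curve(
            timing, {"K": 1.0, "t0": 10.0, "alpha": 2.0, "beta": 1.5})
        fit = fit_gamma_variate(curve)
        assert fit.converged
        assert fit.K == pytest.approx(1.0, rel=1e-3)
        assert fit.t0 == pytest.approx(10.0, rel=1e-3)
        assert fit.alpha == pytest.approx(2.0, rel=1e-3)
        assert fit.beta == pytest.approx(1.5, rel=1e-3)
        assert fit.r_squared > 0.999
        assert qc_first_pass(fit).passed

    def test_all_zero_curve_flags_failure_not_exception(self, timing):
        curve = ConcentrationCurve(np.zeros(timing.n_timepoints), timing.time,
                                   timing.baseline_points)
        fit = fit_gamma_variate(curve)
        assert not fit.converged and fit.r_squared == 0.0
        assert not qc_first_pass(fit).passed

    @pytest.mark.parametrize("r2,expected", [(0.96, True), (0.95, True), (0.40, False)])
    def test_qc_threshold_boundary_is_strict_less_than(self, r2, expected):
        fit = ps.GammaFit(K=1, t0=1, alpha=2, beta=1, r_squared=r2, converged=True)
        res = qc_first_pass(fit)
        assert res.passed is expected
        if not expected:
            assert res.reason == "gamma_r2_below_threshold"

    def test_heavy_noise_fails_qc(self, timing):
        rng = np.random.default_rng(1234)
        base = ps.generate_aif_curve(timing, {"peak": 10.0, "t0": 12.0,
                                              "alpha": 2.0, "beta": 1.0})
        fails = 0
        n = 50
        for _ in range(n):
            noisy = base.values + rng.normal(0, base.values.max() / 2, len(base.values))
            curve = ConcentrationCurve(noisy, timing.time, timing.baseline_points)
            fails += not qc_first_pass(fit_gamma_variate(curve)).passed
        assert fails / n >= 0.9


class TestAifDetection:
    def test_selected_voxels_lie_in_arterial_mask(self, noiseless_phantom, noiseless_study):
        aif = detect_aif(noiseless_study, noiseless_phantom.brain_mask())
        hits = sum(noiseless_phantom.masks["arterial"][v] for v in aif.voxel_indices)
        assert hits / len(aif.voxel_indices) >= 0.8
        assert aif.features["peak_height"] > 0
        assert aif.features["fwhm"] > 0

    def test_detection_robust_to_noise(self, timing):
        ph = ps.generate_phantom(ps.default_layout(baseline_snr=50.0), timing, seed=3)
        study = DscStudy(signal=ph.signal, timing=timing, masks=ph.masks)
        aif = detect_aif(study, ph.brain_mask())
        hits = sum(ph.masks["arterial"][v] for v in aif.voxel_indices)
        assert hits / len(aif.voxel_indices) >= 0.8

    def test_mask_excluding_artery_raises(self, noiseless_phantom, noiseless_study):
        mask = noiseless_phantom.brain_mask() & ~noiseless_phantom.masks["arterial"]
        # without true arterial voxels the best-scoring cluster is still found,
        # but a mask too small to search is a detection error
        small = np.zeros_like(mask)
        small[np.argwhere(mask)[:20, 0], 0, 0] = True
        with pytest.raises(DetectionError):
            detect_aif(noiseless_study, small)

    def test_detection_is_deterministic(self, noiseless_phantom, noiseless_study):
        a1 = detect_aif(noiseless_study, noiseless_phantom.brain_mask())
        a2 = detect_aif(noiseless_study, noiseless_phantom.brain_mask())
        assert a1.voxel_indices == a2.voxel_indices
        np.testing.assert_array_equal(a1.curve.values, a2.curve.values)


class TestBoxermanCorrection:
    def test_leak_free_voxel_k2_near_zero(self, noiseless_phantom, timing):
        ph = noiseless_phantom
        ref = ps.signal_to_concentration(
            ph.signal[ph.masks["white_matter"]].mean(axis=0), timing)
        voxel = tuple(np.argwhere(ph.masks["gray_matter"])[0])
        curve = ps.signal_to_concentration(ph.signal[voxel], timing)
        res = boxerman_correct(curve, ref)
        assert abs(res.k2) < 1e-8
        np.testing.assert_allclose(res.corrected.values, curve.values,
                                   rtol=0.01, atol=1e-10)

    def test_known_leak_recovered_and_k1_near_unity(self, noiseless_phantom, timing):
        ph = noiseless_phantom
        ref = ps.signal_to_concentration(
            ph.signal[ph.masks["white_matter"]].mean(axis=0), timing)
        k2_true = 0.002
        gt = GroundTruthVoxel.from_cbv_mtt(0.02, 4.0, "tumor_LAT", k2_true)
        leaky = ps.synthesize_tissue_curve(ph.aif_truth, gt, timing)
        res = boxerman_correct(leaky, ref)
        assert res.k1 == pytest.approx(1.0, rel=1e-6)
        assert res.k2 == pytest.approx(k2_true, rel=1e-6)
        clean = ps.synthesize_tissue_curve(
            ph.aif_truth, dataclasses.replace(gt, leakage_k2=0.0), timing)
        cbv_corr = compute_cbv(res.corrected)
        cbv_true = compute_cbv(clean)
        cbv_raw = compute_cbv(leaky)
        assert abs(cbv_corr / cbv_true - 1) < 0.05
        assert cbv_raw / cbv_true - 1 < -0.05  # signed uncorrected bias

    def test_degenerate_reference_rejected(self, timing):
        flat = ConcentrationCurve(np.zeros(timing.n_timepoints), timing.time,
                                  timing.baseline_points)
        with pytest.raises(CorrectionError):
            boxerman_correct(flat, flat)


class TestCbvAndMtt:
    def test_zero_curve_integrates_to_zero(self, timing):
        curve = ConcentrationCurve(np.zeros(timing.n_timepoints), timing.time,
                                   timing.baseline_points)
        assert compute_cbv(curve) == 0.0

    def test_unit_rectangle_integrates_to_width(self):
        t = np.arange(20.0)
        v = np.zeros(20)
        v[5:16] = 1.0  # trapezoid: 10 full intervals + 2 half edges
        curve = ConcentrationCurve(v, t, 3)
        assert compute_cbv(curve) == pytest.approx(11.0)

    @pytest.mark.parametrize("cbv,cbf,expected", [(4.0, 2.0, 2.0), (0.0, 1.0, 0.0)])
    def test_central_volume_ratio(self, cbv, cbf, expected):
        assert compute_mtt(cbv, cbf) == expected

    def test_nonpositive_flow_flags_undefined(self):
        assert np.isnan(compute_mtt(4.0, 0.0))
        assert np.isnan(compute_mtt(4.0, -1.0))


class TestBsvdDeconvolution:
    def test_impulse_aif_recovers_residue_exactly(self, timing):
        impulse = ConcentrationCurve(np.eye(timing.n_timepoints)[0],
                                     timing.time, timing.baseline_points)
        gt = GroundTruthVoxel.from_cbv_mtt(8.0, 4.0, "gray_matter")
        tissue = ps.synthesize_tissue_curve(impulse, gt, timing)
        res = deconvolve_bsvd(tissue, impulse, truncation_fraction=0.0)
        assert res.cbf == pytest.approx(gt.cbf, rel=1e-12)
        n = timing.n_timepoints
        expected = gt.cbf * np.exp(-timing.time / gt.mtt)
        np.testing.assert_allclose(res.residue_function[:n], expected, atol=1e-9)

    def test_zero_tissue_gives_zero_flow(self, timing, aif_params):
        aif = ps.generate_aif_curve(timing, aif_params)
        zero = ConcentrationCurve(np.zeros(timing.n_timepoints), timing.time,
                                  timing.baseline_points)
        assert deconvolve_bsvd(zero, aif).cbf == 0.0

    def test_matches_direct_triangular_solve(self, timing):
        # independent oracle: solve the (non-circulant) lower-triangular
        # discretized convolution system directly; needs an input function
        # with a nonzero first sample for the triangular system to be regular
        n = timing.n_timepoints
        dt = timing.repetition_time
        aif_vals = np.exp(-0.5 * ((timing.time - 4.0) / 2.0) ** 2) * 30.0
        aif = ConcentrationCurve(aif_vals, timing.time, timing.baseline_points)
        # short transit time: the residue tail vanishes inside the window, so
        # the zero-padded circulant system and the triangular system agree
        gt = GroundTruthVoxel.from_cbv_mtt(0.03125, 2.5, "gray_matter")
        w = __import__("perfstrat").phantom.residue_weights(gt.mtt, n, dt)
        tissue = aif.copy_with(gt.cbf * residue_convolve(aif_vals, w, dt))
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1):
                A[i, j] = dt * aif_vals[i - j]
        direct = np.linalg.solve(A, tissue.values)
        res = deconvolve_bsvd(tissue, aif, truncation_fraction=0.0)
        np.testing.assert_allclose(res.residue_function[:n], direct,
                                   rtol=1e-6, atol=1e-6 * gt.cbf)

    def test_phantom_flow_within_tolerance_at_default_truncation(
            self, timing, aif_params):
        aif = ps.generate_aif_curve(timing, aif_params)
        gt = GroundTruthVoxel.from_cbv_mtt(0.214, 4.2, "tumor_HAT", 0.0)
        tissue = ps.synthesize_tissue_curve(aif, gt, timing)
        res = deconvolve_bsvd(tissue, aif, truncation_fraction=0.1)
        assert res.cbf == pytest.approx(gt.cbf, rel=0.10)

    def test_delay_insensitive_to_circular_shift(self, timing, aif_params):
        aif = ps.generate_aif_curve(timing, aif_params)
        gt = GroundTruthVoxel.from_cbv_mtt(0.05, 4.0, "gray_matter")
        tissue = ps.synthesize_tissue_curve(aif, gt, timing)
        base = deconvolve_bsvd(tissue, aif, truncation_fraction=0.0).cbf
        for k in (2, 5):
            shifted = tissue.copy_with(np.roll(tissue.values, k))
            cbf = deconvolve_bsvd(shifted, aif, truncation_fraction=0.0).cbf
            assert cbf == pytest.approx(base, rel=0.02)

    @pytest.mark.parametrize("tf", [-0.1, 1.0, 1.5])
    def test_invalid_truncation_rejected(self, timing, aif_params, tf):
        aif = ps.generate_aif_curve(timing, aif_params)
        with pytest.raises(ParameterError):
            deconvolve_bsvd(aif, aif, truncation_fraction=tf)


class TestComputeMaps:
    def test_reference_mean_is_exactly_one(self, noiseless_maps, noiseless_phantom):
        wm = noiseless_phantom.masks["white_matter"]
        assert noiseless_maps.rcbv[wm].mean() == pytest.approx(1.0, abs=1e-12)
        assert noiseless_maps.rcbf[wm].mean() == pytest.approx(1.0, abs=1e-12)

    def test_tumor_hat_relative_cbv_matches_truth(self, noiseless_maps,
                                                  noiseless_phantom, relative_truth):
        rel_cbv, _ = relative_truth("tumor_HAT")
        hat = noiseless_phantom.masks["tumor_HAT"]
        assert np.median(noiseless_maps.rcbv[hat]) == pytest.approx(rel_cbv, rel=0.05)

    def test_mtt_map_consistent_with_cbv_over_cbf(self, noiseless_maps,
                                                  noiseless_phantom):
        wm = noiseless_phantom.masks["white_matter"]
        # relative maps: rcbv/rcbf equals mtt normalized by its reference value
        ratio = noiseless_maps.rcbv[wm] / noiseless_maps.rcbf[wm]
        mtt_norm = noiseless_maps.mtt[wm] * (
            noiseless_maps.reference_region_mean_cbf
            / noiseless_maps.reference_region_mean)
        np.testing.assert_allclose(ratio, mtt_norm, rtol=1e-8)

    def test_deterministic_maps(self, noiseless_study, noiseless_phantom, detected_aif,
                                tumor_mask):
        m1 = compute_maps(noiseless_study, detected_aif,
                          noiseless_phantom.masks["white_matter"], tumor_mask)
        m2 = compute_maps(noiseless_study, detected_aif,
                          noiseless_phantom.masks["white_matter"], tumor_mask)
        np.testing.assert_array_equal(m1.rcbv, m2.rcbv)
        np.testing.assert_array_equal(m1.rcbf, m2.rcbf)

    def test_empty_reference_mask_rejected(self, noiseless_study, detected_aif):
        empty = np.zeros(noiseless_study.signal.shape[:3], dtype=bool)
        with pytest.raises(NormalizationError):
            compute_maps(noiseless_study, detected_aif, empty)

    def test_global_signal_scaling_leaves_relative_maps_unchanged(
            self, noiseless_phantom, detected_aif, tumor_mask, timing):
        # scaling ΔR2* by c scales raw CBV and CBF by c; normalized maps and
        # their ratio (MTT up to reference scale) are invariant
        ph = noiseless_phantom
        study = DscStudy(signal=ph.signal, timing=timing, masks=ph.masks)
        base = compute_maps(study, detected_aif, ph.masks["white_matter"], tumor_mask)
        scaled_signal = ph.signal.copy().astype(float)
        s0 = scaled_signal[..., :timing.baseline_points].mean(axis=-1, keepdims=True)
        # S' = S0 * (S/S0)^2  doubles ΔR2* voxelwise
        scaled_signal = s0 * (scaled_signal / s0) ** 2
        study2 = DscStudy(signal=scaled_signal, timing=timing, masks=ph.masks)
        # unnormalized CBV (raw curve area) scales linearly with ΔR2*
        vox = tuple(np.argwhere(ph.masks["gray_matter"])[0])
        c1 = ps.signal_to_concentration(ph.signal[vox], timing)
        c2 = ps.signal_to_concentration(scaled_signal[vox], timing)
        assert compute_cbv(c2) == pytest.approx(2 * compute_cbv(c1), rel=1e-9)
        # ... while the reference-normalized maps are unchanged
        aif2 = detect_aif(study2, ph.brain_mask())
        doubled = compute_maps(study2, aif2, ph.masks["white_matter"], tumor_mask)
        wm = ph.masks["white_matter"]
        np.testing.assert_allclose(doubled.rcbv[wm], base.rcbv[wm], rtol=1e-6)
        np.testing.assert_allclose(doubled.rcbf[wm], base.rcbf[wm], rtol=1e-6)
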