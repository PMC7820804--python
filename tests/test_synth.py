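"""Generator-level checks: reproducibility and agreement with closed forms."""

import numpy as np
import pytest

from softslb import afm, synth


class TestDiffusionGroundTruth:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            synth.DiffusionGroundTruth(component_D=(1.0, 0.1),
                                       component_fractions=(0.6, 0.6))

    def test_track_length_minimum(self):
        with pytest.raises(ValueError):
            synth.DiffusionGroundTruth(track_length=1)


class TestSimulateTracks:
    def test_reproducible(self):
        gt = synth.DiffusionGroundTruth(n_tracks=5)
        a = synth.simulate_tracks(gt, seed=7)
        b = synth.simulate_tracks(gt, seed=7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.xy, tb.xy)

    def test_step_variance_matches_theory(self):
        # per-axis one-step variance must be 2 D dt + 2 sigma^2
        D, sig, dt = 0.5, 0.04, 0.02
        gt = synth.DiffusionGroundTruth(component_D=(D,), component_fractions=(1.0,),
                                        sigma_loc=sig, frame_interval=dt,
                                        n_tracks=400, track_length=20)
        tracks = synth.simulate_tracks(gt, seed=1)
        steps = np.concatenate([np.diff(t.xy, axis=0).ravel() for t in tracks])
        expected = 2 * D * dt + 2 * sig**2
        se = expected * np.sqrt(2.0 / steps.size)
        assert abs(steps.var() - expected) < 3 * se

    def test_immobile_particles_msd_is_4_sigma_sq(self):
        from softslb import spt

        gt = synth.DiffusionGroundTruth(component_D=(0.0,), component_fractions=(1.0,),
                                        sigma_loc=0.05, n_tracks=400, track_length=15)
        curve = spt.compute_ensemble_msd(synth.simulate_tracks(gt, 3), max_lag=5)
        np.testing.assert_allclose(curve.msd, 0.01, rtol=0.05)

    def test_two_component_assignment(self):
        gt = synth.DiffusionGroundTruth(component_D=(1.0, 0.01),
                                        component_fractions=(0.3, 0.7),
                                        sigma_loc=0.0, n_tracks=500, track_length=5)
        tracks = synth.simulate_tracks(gt, 11)
        # classify tracks by mean step size; fractions ~ binomial
        mean_sq = np.array([t.displacements(1).mean() for t in tracks])
        fast = (mean_sq > 4 * 0.1 * gt.frame_interval).mean()
        assert abs(fast - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 500)


class TestRenderImageStack:
    def test_static_spot_brightest_pixel(self):
        from softslb.spt import Track

        t = Track(0, np.arange(3), np.tile([[1.03, 0.77]], (3, 1)), 0.01)
        stack, truth = synth.render_image_stack(
            [t], shape=(32, 32), pixel_size=0.1, photons_per_spot=1000,
            background_level=0.0, seed=0, poisson_noise=False)
        y, x = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert (y, x) == (8, 10)  # rounded true position (7.7, 10.3)

    def test_out_of_field_spot_clipped_with_warning(self):
        from softslb.spt import Track

        t = Track(0, np.arange(2), np.array([[50.0, 50.0], [50.0, 50.0]]), 0.01)
        with pytest.warns(UserWarning, match="clipped"):
            stack, truth = synth.render_image_stack([t], shape=(16, 16),
                                                    pixel_size=0.1, seed=0)
        assert truth == []

    def test_photons_for_snr_roundtrip(self):
        p = synth.photons_for_snr(7.8, background_level=10.0, psf_sigma=1.3)
        amp = p / (2 * np.pi * 1.3**2)
        assert amp / np.sqrt(10.0) == pytest.approx(7.8)


class TestSimulateFrap:
    def test_asymptote(self):
        gt = synth.FRAPGroundTruth(mobile_fraction_Mf=0.8, baseline_F0=0.25,
                                   noise_sd=0.0)
        tr = synth.simulate_frap_curve(gt, [0.0, 1e9], seed=0)
        assert tr.intensities[-1] == pytest.approx(0.85, abs=1e-6)

    def test_no_bleach_limit(self):
        gt = synth.FRAPGroundTruth(bleach_depth_K=1e-6, mobile_fraction_Mf=1.0,
                                   noise_sd=0.0)
        tr = synth.simulate_frap_curve(gt, [0.0, 1.0, 50.0], seed=0)
        np.testing.assert_allclose(tr.intensities, 1.0, atol=1e-5)

    def test_t0_value_is_series_sum(self):
        # analytic: F(0) = (1 - e^-K)/K for Mf = 1
        gt = synth.FRAPGroundTruth(bleach_depth_K=1.0, mobile_fraction_Mf=1.0,
                                   noise_sd=0.0)
        tr = synth.simulate_frap_curve(gt, [0.0, 1.0], seed=0)
        assert tr.intensities[0] == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_noiseless_monotone_and_bounded(self):
        gt = synth.FRAPGroundTruth(noise_sd=0.0)
        tr = synth.simulate_frap_curve(gt, np.arange(0.0, 120.0), seed=0)
        assert np.all(np.diff(tr.intensities) >= -1e-12)
        bound = gt.mobile_fraction_Mf + (1 - gt.mobile_fraction_Mf) * gt.baseline_F0
        assert np.all(tr.intensities <= bound + 1e-9)

    def test_timepoints_must_start_at_zero(self):
        with pytest.raises(ValueError):
            synth.simulate_frap_curve(synth.FRAPGroundTruth(), [1.0, 2.0], 0)

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            synth.FRAPGroundTruth(bleach_depth_K=0.0)


class TestSimulateCalcium:
    def test_responder_fraction_zero_flat(self):
        gt = synth.CalciumPopulationGroundTruth(n_cells=10, responder_fraction=0.0,
                                                noise_sd=0.5)
        traces, truth = synth.simulate_calcium_population(gt, 0)
        assert all(not t.responder for t in truth)
        for tr in traces:
            assert tr.intensities.std() < 3 * 0.5

    def test_all_responders_single_peak(self):
        gt = synth.CalciumPopulationGroundTruth(
            n_cells=20, responder_fraction=1.0,
            multipeak_fraction_of_responders=0.0)
        _, truth = synth.simulate_calcium_population(gt, 1)
        assert all(t.n_peaks == 1 for t in truth)

    def test_label_counts_binomial(self):
        gt = synth.CalciumPopulationGroundTruth(n_cells=200, responder_fraction=0.7)
        _, truth = synth.simulate_calcium_population(gt, 5)
        n_resp = sum(t.responder for t in truth)
        assert abs(n_resp - 140) < 3 * np.sqrt(200 * 0.7 * 0.3)


class TestSimulateContact:
    @pytest.mark.parametrize("depletion,expected", [(1.0, 0.0), (0.0, 1.0),
                                                    (0.5, 0.5)])
    def test_ground_truth_mask_exclusion(self, depletion, expected):
        gt = synth.ContactGroundTruth(depletion_factor_ch2=depletion)
        img, truth = synth.simulate_contact_image(gt, 0)
        inside = truth["contact_mask"]
        outside = truth["cell_mask"] & ~inside
        excl = 1 - img.channel_probe[inside].mean() / img.channel_probe[outside].mean()
        assert excl == pytest.approx(expected, abs=1e-12)


class TestSimulateForceCurve:
    def test_hertz_closed_form_value(self):
        # sphere R=10 um, nu=0.5, E=3 kPa, delta=1 um -> 1.69e-8 N
        f = afm.hertz_force_sphere(1.0, 3000.0, 10.0, 0.5)
        assert f * 1e-9 == pytest.approx(1.686e-8, rel=1e-3)

    def test_noiseless_passes_through_contact_point(self):
        gt = synth.ForceCurveGroundTruth(noise_sd_nN=0.0, z_jump_nm=0.0)
        cv = synth.simulate_force_curve(gt, 0)
        i = np.searchsorted(cv.z, gt.contact_point_um)
        assert abs(cv.force[i]) < 1e-6
        assert np.all(cv.force[cv.z < gt.contact_point_um] == 0)

    def test_noiseless_continuous_with_flat_bridge(self):
        gt = synth.ForceCurveGroundTruth(noise_sd_nN=0.0, z_jump_nm=3.9)
        cv = synth.simulate_force_curve(gt, 0)
        jumps = np.abs(np.diff(cv.force))
        # matched substrate: bridge is flat, so curve stays continuous
        assert jumps.max() < 0.01

    def test_contact_point_outside_range_error(self):
        with pytest.raises(ValueError):
            synth.simulate_force_curve(
                synth.ForceCurveGroundTruth(contact_point_um=5.0, z_range_um=1.0), 0)

    def test_reproducible(self):
        gt = synth.ForceCurveGroundTruth()
        a = synth.simulate_force_curve(gt, 3)
        b = synth.simulate_force_curve(gt, 3)
        np.testing.assert_array_equal(a.force, b.force)
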