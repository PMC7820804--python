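"""Detection, linking, MSD and jump-distance analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from softslb import spt, synth


def _spot(shape, x, y, sigma=1.3, amp=100.0, bg=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return bg + amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


class TestDetectParticles:
    def test_blank_frame(self):
        assert spt.detect_particles(np.zeros((32, 32)), 10.0) == []

    def test_noiseless_spot_subpixel_accuracy(self):
        frame = _spot((24, 24), 10.3, 7.7)
        locs = spt.detect_particles(frame, 20.0, psf_sigma_guess=1.3)
        assert len(locs) == 1
        assert abs(locs[0].x - 10.3) < 0.05
        assert abs(locs[0].y - 7.7) < 0.05

    def test_two_separated_spots(self):
        frame = _spot((48, 48), 10.0, 10.0) + _spot((48, 48), 30.0, 32.0)
        locs = spt.detect_particles(frame, 20.0, psf_sigma_guess=1.3)
        assert len(locs) == 2

    def test_snr_tracks_photon_budget(self, rng):
        bg = 20.0
        snrs = []
        for target in (5.6, 7.8):
            photons = synth.photons_for_snr(target, bg, 1.3)
            amp = photons / (2 * np.pi * 1.3**2)
            frame = rng.poisson(_spot((32, 32), 15.0, 15.0, amp=amp, bg=bg))
            locs = spt.detect_particles(frame.astype(float), amp * 0.3)
            assert locs, f"spot lost at SNR {target}"
            snrs.append(max(l.snr for l in locs))
        assert snrs[1] > snrs[0]


class TestLinkTracks:
    def test_single_particle_single_track(self):
        pos = [np.array([[1.0 + 0.05 * f, 2.0]]) for f in range(6)]
        tracks = spt.link_tracks(pos, max_displacement=0.2, frame_interval=0.01)
        assert len(tracks) == 1
        assert len(tracks[0]) == 6

    def test_two_static_particles_two_tracks(self):
        pos = [np.array([[1.0, 1.0], [5.0, 5.0]])] * 4
        tracks = spt.link_tracks(pos, 0.5, 0.01)
        assert len(tracks) == 2
        assert all(len(t) == 4 for t in tracks)

    def test_large_jump_splits_track(self):
        pos = [np.array([[1.0, 1.0]]), np.array([[1.05, 1.0]]),
               np.array([[3.0, 1.0]])]
        tracks = spt.link_tracks(pos, max_displacement=0.2, frame_interval=0.01)
        assert sorted(len(t) for t in tracks) == [1, 2]


class TestFilterTracks:
    @pytest.mark.parametrize("length,kept", [(5, 0), (6, 1), (7, 1)])
    def test_longer_than_five_frames_rule(self, length, kept):
        t = spt.Track(0, np.arange(length), np.zeros((length, 2)), 0.01)
        assert len(spt.filter_tracks([t])) == kept

    def test_empty_input(self):
        assert spt.filter_tracks([]) == []

    def test_all_removed_warns(self):
        t = spt.Track(0, np.arange(3), np.zeros((3, 2)), 0.01)
        with pytest.warns(UserWarning):
            assert spt.filter_tracks([t]) == []


class TestEnsembleMSD:
    def test_single_two_frame_track(self):
        t = spt.Track(0, np.array([0, 1]), np.array([[0.0, 0.0], [0.3, 0.4]]), 0.1)
        curve = spt.compute_ensemble_msd([t], max_lag=1)
        assert curve.msd[0] == pytest.approx(0.25)

    def test_brownian_closed_form(self):
        gt = synth.DiffusionGroundTruth(component_D=(1.0,), component_fractions=(1.0,),
                                        sigma_loc=0.0, n_tracks=400, track_length=20)
        curve = spt.compute_ensemble_msd(synth.simulate_tracks(gt, 1), max_lag=5)
        for m, t, s in zip(curve.msd, curve.lag_times, curve.sem):
            assert abs(m - 4.0 * t) < 3 * s

    def test_max_lag_longer_than_every_track(self):
        t = spt.Track(0, np.arange(4), np.zeros((4, 2)), 0.01)
        with pytest.raises(ValueError):
            spt.compute_ensemble_msd([t], max_lag=4)

    def test_mixed_frame_interval_rejected(self):
        a = spt.Track(0, np.arange(5), np.zeros((5, 2)), 0.01)
        b = spt.Track(1, np.arange(5), np.zeros((5, 2)), 0.02)
        with pytest.raises(ValueError):
            spt.compute_ensemble_msd([a, b], max_lag=2)

    @given(st.integers(0, 2**31 - 1))
    def test_time_reversal_symmetry(self, seed):
        gt = synth.DiffusionGroundTruth(n_tracks=10, track_length=8)
        tracks = synth.simulate_tracks(gt, seed)
        rev = [spt.Track(t.particle_id, t.frames, t.xy[::-1], t.frame_interval)
               for t in tracks]
        fwd = spt.compute_ensemble_msd(tracks, 4).msd
        bwd = spt.compute_ensemble_msd(rev, 4).msd
        np.testing.assert_allclose(fwd, bwd, rtol=1e-12)


class TestFitMSD:
    def test_exact_line_recovered(self):
        t = np.arange(1, 7) * 0.01
        curve = spt.MSDCurve(t, 4 * 2.0 * t, np.zeros(6), 10, 0.01)
        fit = spt.fit_msd(curve, n_points=5, exposure_time=0.0)
        assert fit.D == pytest.approx(2.0, abs=1e-12)
        assert fit.sigma_loc == pytest.approx(0.0, abs=1e-9)

    def test_constant_msd_gives_zero_D(self):
        t = np.arange(1, 6) * 0.01
        curve = spt.MSDCurve(t, np.full(5, 0.01), np.zeros(5), 10, 0.01)
        fit = spt.fit_msd(curve, exposure_time=0.0)
        assert fit.D == 0.0
        assert fit.sigma_loc == pytest.approx(0.05)

    def test_exposure_term_shifts_offset(self):
        # MSD = 4 D t + 4 s^2 - (4/3) D tE with known D, s, tE
        D, s, tE = 1.5, 0.04, 0.01
        t = np.arange(1, 6) * 0.01
        curve = spt.MSDCurve(t, 4 * D * t + 4 * s**2 - (4 / 3) * D * tE,
                             np.zeros(5), 10, 0.01)
        fit = spt.fit_msd(curve, exposure_time=tE)
        assert fit.D == pytest.approx(D, rel=1e-9)
        assert fit.sigma_loc == pytest.approx(s, rel=1e-6)
        assert fit.offset == pytest.approx(4 * s**2 - (4 / 3) * D * tE, rel=1e-6)

    def test_lag_model_switch(self):
        D = 0.9
        t = np.arange(1, 6) * 0.01
        curve = spt.MSDCurve(t, (8 / 3) * D * t, np.zeros(5), 10, 0.01)
        fit = spt.fit_msd(curve, model="lag")
        assert fit.D == pytest.approx(D, rel=1e-9)

    def test_unbiased_over_replicates(self):
        D_true, s_true = 1.0, 0.05
        gt = synth.DiffusionGroundTruth(component_D=(D_true,),
                                        component_fractions=(1.0,),
                                        sigma_loc=s_true, n_tracks=200,
                                        track_length=20)
        Ds = [spt.fit_msd(spt.compute_ensemble_msd(
            synth.simulate_tracks(gt, seed), 5), exposure_time=0.0).D
            for seed in range(20)]
        se = np.std(Ds, ddof=1) / np.sqrt(len(Ds))
        assert abs(np.mean(Ds) - D_true) < 3 * se


class TestJumpDistance:
    def test_single_population_recovery(self):
        gt = synth.DiffusionGroundTruth(component_D=(0.1,), component_fractions=(1.0,),
                                        sigma_loc=0.0, frame_interval=0.02,
                                        n_tracks=200, track_length=15)
        fit = spt.jump_distance_fit(synth.simulate_tracks(gt, 2), n_components=1)
        assert fit.fractions[0] == pytest.approx(1.0)
        assert fit.D[0] == pytest.approx(0.1, rel=0.1)

    def test_two_population_recovery(self):
        # D = 0.02 and 0.2 um^2/s at f = 0.5, ~5000 displacements
        gt = synth.DiffusionGroundTruth(component_D=(0.2, 0.02),
                                        component_fractions=(0.5, 0.5),
                                        sigma_loc=0.0, frame_interval=0.031,
                                        n_tracks=300, track_length=18)
        fit = spt.jump_distance_fit(synth.simulate_tracks(gt, 5), n_components=2)
        assert fit.n_steps >= 5000
        assert fit.D[0] == pytest.approx(0.2, rel=0.2)
        assert fit.D[1] == pytest.approx(0.02, rel=0.2)
        assert fit.fractions[0] == pytest.approx(0.5, abs=0.1)

    def test_likelihood_never_decreases(self):
        gt = synth.DiffusionGroundTruth(component_D=(0.3, 0.03),
                                        component_fractions=(0.4, 0.6),
                                        sigma_loc=0.0, n_tracks=100, track_length=10)
        fit = spt.jump_distance_fit(synth.simulate_tracks(gt, 9), n_components=2)
        assert np.all(np.diff(fit.loglik_path) >= -1e-8)

    def test_components_sorted_fast_first(self):
        gt = synth.DiffusionGroundTruth(component_D=(0.01, 0.5),
                                        component_fractions=(0.5, 0.5),
                                        sigma_loc=0.0, n_tracks=150, track_length=12)
        fit = spt.jump_distance_fit(synth.simulate_tracks(gt, 4), n_components=2)
        assert fit.D[0] > fit.D[1]

    def test_too_few_displacements_refused(self):
        t = spt.Track(0, np.arange(10), np.cumsum(
            np.random.default_rng(0).normal(0, 0.1, (10, 2)), axis=0), 0.01)
        with pytest.raises(ValueError, match="displacements"):
            spt.jump_distance_fit([t], n_components=2)

    def test_degenerate_fit_collapses(self):
        gt = synth.DiffusionGroundTruth(component_D=(0.15,),
                                        component_fractions=(1.0,), sigma_loc=0.0,
                                        n_tracks=100, track_length=12)
        fit = spt.jump_distance_fit(synth.simulate_tracks(gt, 6), n_components=2)
        if fit.collapsed:
            assert len(fit.D) == 1 and fit.fractions[0] == 1.0
        else:  # EM kept two components; the dominant one carries the mass
            assert fit.fractions[np.argmax(fit.fractions)] > 0.5

    def test_lsq_mode_cross_checks_mle(self):
        gt = synth.DiffusionGroundTruth(component_D=(0.2,), component_fractions=(1.0,),
                                        sigma_loc=0.0, n_tracks=300, track_length=15)
        tracks = synth.simulate_tracks(gt, 8)
        mle = spt.jump_distance_fit(tracks, 1, method="mle")
        lsq = spt.jump_distance_fit(tracks, 1, method="lsq")
        assert lsq.D[0] == pytest.approx(mle.D[0], rel=0.15)


class TestPipelineEquivalence:
    def test_detect_link_msd_matches_ground_truth(self):
        """Noiseless rendered stack through the full pipeline reproduces the
        track-level MSD within 2%."""
        gt = synth.DiffusionGroundTruth(component_D=(0.05,),
                                        component_fractions=(1.0,), sigma_loc=0.0,
                                        frame_interval=0.02, n_tracks=9,
                                        track_length=10)
        tracks = synth.simulate_tracks(gt, 2)
        for k, t in enumerate(tracks):  # park each walker on a grid cell
            t.xy = t.xy - t.xy[0] + np.array([1.2 + (k % 3) * 1.9,
                                              1.2 + (k // 3) * 1.9])
        stack, _ = synth.render_image_stack(tracks, shape=(64, 64), pixel_size=0.1,
                                            psf_sigma=1.3, photons_per_spot=2000,
                                            background_level=10.0, seed=0,
                                            poisson_noise=False)
        per_frame = []
        for frame in stack:
            locs = spt.detect_particles(frame, min_intensity=50.0,
                                        psf_sigma_guess=1.3)
            per_frame.append(
                np.array([[l.x, l.y] for l in locs]).reshape(-1, 2) * 0.1)
        linked = spt.filter_tracks(spt.link_tracks(per_frame, 0.5, 0.02))
        assert len(linked) == len(tracks)
        msd_pipeline = spt.compute_ensemble_msd(linked, 5).msd
        msd_truth = spt.compute_ensemble_msd(tracks, 5).msd
        np.testing.assert_allclose(msd_pipeline, msd_truth, rtol=0.02)
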