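"""Forward-model physics and determinism of the synthetic generator."""

import math

import numpy as np
import pytest

from endovitals.colorimetry import reflectance_ratio
from endovitals.ppg import extract_ppg
from endovitals.synthetic import (DRSForwardParams, OcclusionProtocol,
                                  VideoScene, drs_reflectance,
                                  generate_drs_timeseries, generate_video,
                                  hemoglobin_table, render_frame, so2_at)


def _round5(x):
    return 5.0 * round(x / 5.0)


class TestSo2Trajectory:
    protocol = OcclusionProtocol(baseline_so2=0.97, occluded_so2=0.20,
                                 intervals=((100.0, 600.0),),
                                 tau_fall_s=5.0, tau_rise_s=5.0)

    def test_baseline_before_first_occlusion(self):
        assert so2_at(self.protocol, 0.0) == 0.97
        assert so2_at(self.protocol, 99.9) == 0.97

    def test_long_occlusion_reaches_floor(self):
        assert so2_at(self.protocol, 100.0 + 10 * 5.0) == pytest.approx(
            0.20, abs=1e-4)

    def test_recovery_closed_form(self):
        # one tau_rise after release of a saturating occlusion:
        # 0.20 + 0.77 * (1 - e^-1)
        expected = 0.20 + 0.77 * (1.0 - math.exp(-1.0))
        assert so2_at(self.protocol, 605.0) == pytest.approx(expected, abs=1e-9)

    def test_trajectory_is_continuous_and_bounded(self):
        t = np.linspace(0.0, 700.0, 14001)
        s = so2_at(self.protocol, t)
        assert np.all((s >= 0.20 - 1e-12) & (s <= 0.97 + 1e-12))
        assert np.max(np.abs(np.diff(s))) < 0.01  # no jumps at 0.05 s steps


class TestForwardModel:
    def test_no_absorber_reduces_to_scattering(self, chromophores, grid_1nm):
        p = DRSForwardParams(c_thb=0.0)
        rec = drs_reflectance(p, chromophores, grid_1nm)
        expected = p.scatter_a * (grid_1nm / 650.0) ** (-p.scatter_b)
        np.testing.assert_allclose(rec.values, expected, rtol=1e-12)

    def test_deoxy_minimum_at_555(self, forward_params, chromophores, grid_1nm):
        rec = drs_reflectance(forward_params, chromophores, grid_1nm, so2=0.0)
        band = (grid_1nm >= 500) & (grid_1nm <= 600)
        wl_min = grid_1nm[band][np.argmin(rec.values[band])]
        assert _round5(wl_min) == 555.0

    def test_oxy_double_minima_at_540_and_575(self, forward_params,
                                              chromophores, grid_1nm):
        rec = drs_reflectance(forward_params, chromophores, grid_1nm, so2=1.0)
        band = (grid_1nm >= 500) & (grid_1nm <= 600)
        v = rec.values[band]
        minima = grid_1nm[band][
            np.flatnonzero((v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])) + 1]
        assert [_round5(w) for w in minima] == [540.0, 575.0]

    def test_monotone_decreasing_in_concentration(self, chromophores, grid_1nm):
        values = [drs_reflectance(DRSForwardParams(), chromophores, grid_1nm,
                                  c_thb=c).values for c in (5e-5, 1e-4, 2e-4)]
        assert np.all(values[1] < values[0])
        assert np.all(values[2] < values[1])

    def test_isosbestic_wavelength_is_so2_insensitive(self, forward_params,
                                                      chromophores):
        # locate the blue-green crossing of the two extinction curves
        wl = chromophores.wavelength_nm
        diff = chromophores.eps_hbo2 - chromophores.eps_hb
        blue = wl < 520
        k = np.flatnonzero(np.diff(np.sign(diff[blue])) != 0)[0]
        # linear root of the extinction difference between grid knots
        w0, w1 = wl[blue][k], wl[blue][k + 1]
        d0, d1 = diff[blue][k], diff[blue][k + 1]
        iso = w0 - d0 * (w1 - w0) / (d1 - d0)
        grid = np.array([iso - 1, iso, iso + 1])
        values = [drs_reflectance(forward_params, chromophores, grid,
                                  so2=s).values[1] for s in (0, 0.5, 1)]
        assert (max(values) - min(values)) / np.mean(values) < 0.01

    def test_nir_reflectance_higher_when_deoxygenated(self, forward_params,
                                                      chromophores):
        grid = np.arange(700.0, 901.0, 1.0)
        r0 = drs_reflectance(forward_params, chromophores, grid, so2=0.0)
        r1 = drs_reflectance(forward_params, chromophores, grid, so2=1.0)
        assert np.all(r0.values > r1.values)

    def test_grid_outside_table_raises(self, forward_params, chromophores):
        with pytest.raises(ValueError):
            drs_reflectance(forward_params, chromophores,
                            np.arange(300.0, 500.0, 1.0))

    def test_extinction_peak_structure(self, chromophores):
        wl = chromophores.wavelength_nm
        band = (wl >= 500) & (wl <= 600)

        def maxima(y):
            return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1

        assert len(maxima(chromophores.eps_hbo2[band])) == 2
        assert len(maxima(chromophores.eps_hb[band])) == 1


class TestDrsTimeseries:
    def test_stationary_model_gives_identical_spectra(self, chromophores):
        p = DRSForwardParams(noise_sd=0.0, pulse_amp=0.0)
        records = generate_drs_timeseries(p, OcclusionProtocol(), 2.0, 12.5,
                                          seed=0, chromophores=chromophores)
        for rec in records[1:]:
            np.testing.assert_array_equal(rec.values, records[0].values)

    def test_seed_determinism(self, chromophores):
        p = DRSForwardParams()
        args = (p, OcclusionProtocol(), 1.0, 12.5)
        a = generate_drs_timeseries(*args, seed=5, chromophores=chromophores)
        b = generate_drs_timeseries(*args, seed=5, chromophores=chromophores)
        c = generate_drs_timeseries(*args, seed=6, chromophores=chromophores)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))
        assert any(not np.array_equal(x.values, y.values)
                   for x, y in zip(a, c))

    def test_occlusion_lowers_the_reflectance_ratio(self, chromophores):
        p = DRSForwardParams(noise_sd=0.0, pulse_amp=0.0)
        protocol = OcclusionProtocol(intervals=((30.0, 90.0),))
        records = generate_drs_timeseries(p, protocol, 120.0, 2.0, seed=0,
                                          chromophores=chromophores)
        t = np.array([r.time_s for r in records])
        ratios = np.array([reflectance_ratio(r) for r in records])
        baseline = ratios[t < 25.0].mean()
        plateau = ratios[(t > 70.0) & (t < 88.0)].mean()
        assert plateau < baseline


class TestVideoGeneration:
    def test_static_scene_renders_identical_frames(self, quiet_scene):
        p = DRSForwardParams(pulse_amp=0.0)
        rng = np.random.default_rng(0)
        frames = [render_frame(quiet_scene, t, 0.97, rng, params=p)[0]
                  for t in (0.0, 0.33, 1.7)]
        for f in frames[1:]:
            np.testing.assert_array_equal(f.pixels, frames[0].pixels)

    def test_rendered_tissue_matches_ground_truth_mask(self, quiet_scene):
        rng = np.random.default_rng(0)
        frame, truth = render_frame(quiet_scene, 0.0, 0.97, rng)
        yy, xx = np.mgrid[0:quiet_scene.height, 0:quiet_scene.width]
        mask = (xx - truth.cx) ** 2 + (yy - truth.cy) ** 2 <= truth.r ** 2
        is_tissue = np.any(
            np.abs(frame.pixels - quiet_scene.wall_value) > 1e-6, axis=2)
        np.testing.assert_array_equal(is_tissue, mask)

    def test_cardiac_modulation_averages_out_over_one_period(self):
        scene = VideoScene(a_c=0.05, a_r=0.0, a_b=0.0, jitter_sd=0.0,
                           incursion_prob=0.0, noise_sd=0.0)
        p = DRSForwardParams(pulse_amp=0.0)
        rng = np.random.default_rng(0)
        period = 60.0 / scene.hr_bpm
        times = np.linspace(0.0, period, 200, endpoint=False)
        v_means = []
        for t in times:
            frame, truth = render_frame(scene, t, 0.97, rng, params=p)
            yy, xx = np.mgrid[0:scene.height, 0:scene.width]
            mask = (xx - truth.cx) ** 2 + (yy - truth.cy) ** 2 <= (truth.r - 2) ** 2
            v_means.append(frame.pixels[mask].max(axis=1).mean())
        baseline_frame, truth = render_frame(scene, 0.0, 0.97, rng,
                                             params=DRSForwardParams(pulse_amp=0.0))
        yy, xx = np.mgrid[0:scene.height, 0:scene.width]
        mask = (xx - truth.cx) ** 2 + (yy - truth.cy) ** 2 <= (truth.r - 2) ** 2
        # the sinusoid averages out: the mean V over a full cardiac period
        # equals the unmodulated V at the phase-zero crossing
        baseline = baseline_frame.pixels[mask].max(axis=1).mean()
        assert np.mean(v_means) == pytest.approx(baseline, abs=1e-3)

    def test_frame_count_and_incursion_extremes(self):
        scene = VideoScene(duration_s=2.0, incursion_prob=0.0)
        video = generate_video(scene, seed=0)
        assert len(video) == 80
        assert not any(video.meta["ground_truth"]["blood"])

        scene_all_blood = VideoScene(duration_s=1.0, incursion_prob=1.0)
        video = generate_video(scene_all_blood, seed=0)
        assert all(video.meta["ground_truth"]["blood"])

    def test_equal_seeds_are_bit_reproducible(self):
        scene = VideoScene(duration_s=1.0)
        a = generate_video(scene, seed=11)
        b = generate_video(scene, seed=11)
        np.testing.assert_array_equal(a.as_array(), b.as_array())
        assert a.meta["ground_truth"]["blood"] == b.meta["ground_truth"]["blood"]

    def test_all_blood_video_has_no_usable_frames(self):
        from endovitals.io_core import AnalysisError
        from endovitals.roi import detect_roi

        scene = VideoScene(duration_s=0.5, incursion_prob=1.0)
        video = generate_video(scene, seed=3)
        circles = [detect_roi(f) for f in video.frames]
        assert not any(c.valid for c in circles)
        with pytest.raises(AnalysisError):
            extract_ppg(video, circles)
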