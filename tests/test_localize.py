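"""Localization accuracy, rendering and width-profiling checks."""

import numpy as np
import pandas as pd
import pytest

from poretrack import diffusion, localize, simkit


def single_emitter_locs(x, y, photons=500.0, frames=1):
    return pd.DataFrame(
        {
            "frame": np.arange(frames),
            "x_um": x,
            "y_um": y,
            "photons": photons,
            "background": 0.0,
            "channel": 0,
        }
    )


class TestDetectAndFit:
    def test_noiseless_spot_fit_is_exact(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=0, field_size_px=16, frame_count=1, background_photons=0.0
        )
        x, y = 0.8133, 0.9241
        stack = simkit.render_movie(single_emitter_locs(x, y), cfg, shot_noise=False)
        out = localize.detect_and_fit(stack, cfg)
        assert len(out) == 1
        px = cfg.pixel_size_um
        assert abs(out["x_um"][0] - x) < 1e-3 * px
        assert abs(out["y_um"][0] - y) < 1e-3 * px

    def test_localization_spread_near_19nm(self):
        # photon count tuned so the empirical spread matches the AF647
        # precision of ~19 nm (Thompson formula inverted at bg=10)
        cfg = simkit.AcquisitionConfig(
            rng_seed=1, field_size_px=16, frame_count=300,
            background_photons=10.0,
        )
        x, y = 0.8133, 0.9241
        locs = single_emitter_locs(x, y, photons=200.0, frames=300)
        stack = simkit.render_movie(locs, cfg)
        out = localize.detect_and_fit(stack, cfg)
        d = np.hypot(out["x_um"] - x, out["y_um"] - y)
        out = out[d < 0.2]  # drop rare spurious detections elsewhere
        assert len(out) > 200
        spread_nm = np.sqrt(0.5 * (out["x_um"].var() + out["y_um"].var())) * 1e3
        assert spread_nm == pytest.approx(19.0, rel=0.3)

    def test_two_emitters_resolved(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=2, field_size_px=24, frame_count=1, background_photons=5.0
        )
        locs = pd.DataFrame(
            {
                "frame": [0, 0],
                "x_um": [0.9, 0.9 + 5 * cfg.pixel_size_um],
                "y_um": [1.1, 1.1],
                "photons": [800.0, 800.0],
                "background": [0.0, 0.0],
                "channel": [0, 0],
            }
        )
        stack = simkit.render_movie(locs, cfg)
        out = localize.detect_and_fit(stack, cfg)
        assert len(out) == 2

    def test_spread_scales_with_inverse_sqrt_photons(self):
        # power-law slope of spread vs photons must be -0.5 +- 0.1
        cfg0 = simkit.AcquisitionConfig(
            rng_seed=3, field_size_px=16, frame_count=150, background_photons=2.0
        )
        x, y = 0.8133, 0.9241
        spreads, levels = [], [300.0, 1000.0, 3000.0]
        for i, n in enumerate(levels):
            cfg = cfg0.with_seed(3 + i)
            stack = simkit.render_movie(
                single_emitter_locs(x, y, photons=n, frames=150), cfg
            )
            out = localize.detect_and_fit(stack, cfg)
            d = np.hypot(out["x_um"] - x, out["y_um"] - y)
            out = out[d < 0.2]
            spreads.append(
                np.sqrt(0.5 * (out["x_um"].var() + out["y_um"].var()))
            )
        slope = np.polyfit(np.log(levels), np.log(spreads), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_empty_stack_no_rows(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=4, field_size_px=16, frame_count=2, background_photons=0.0
        )
        out = localize.detect_and_fit(np.zeros((2, 16, 16)), cfg)
        assert len(out) == 0


class TestMedianImage:
    def test_constant_stack_identity(self):
        stack = np.full((8, 4, 4), 7.0)
        assert np.array_equal(localize.median_image(stack), stack[0])

    def test_outlier_frame_suppressed(self):
        stack = np.zeros((5, 4, 4))
        stack[2] = 100.0
        assert np.all(localize.median_image(stack, 5) == 0.0)

    def test_mobile_emitter_attenuated_vs_immobile(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=5, field_size_px=32, frame_count=5, background_photons=0.0
        )
        immob = single_emitter_locs(0.7, 0.7, photons=500.0, frames=5)
        mobile = pd.DataFrame(
            {
                "frame": np.arange(5),
                "x_um": 0.9 + np.arange(5) * 0.4,  # moves ~4 px per frame
                "y_um": 1.8,
                "photons": 500.0,
                "background": 0.0,
                "channel": 0,
            }
        )
        stack = simkit.render_movie(pd.concat([immob, mobile]), cfg, shot_noise=False)
        med = localize.median_image(stack, 5)
        px = cfg.pixel_size_um
        peak_immob = med[int(0.7 / px), int(0.7 / px)]
        peak_mobile = med[int(1.8 / px), int((0.9 + 2 * 0.4) / px)]
        assert peak_immob > 5 * peak_mobile

    def test_invalid_n_frames(self):
        with pytest.raises(ValueError):
            localize.median_image(np.zeros((3, 4, 4)), 0)


class TestExtractTrace:
    def test_constant_emitter_flat_trace(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=6, field_size_px=24, frame_count=10, background_photons=20.0
        )
        pos = (1.3, 1.3)
        locs = single_emitter_locs(*pos, photons=800.0, frames=10)
        stack = simkit.render_movie(locs, cfg, shot_noise=False)
        trace = localize.extract_trace(stack, pos, cfg)
        assert trace["photons"].std() < 1e-6
        assert trace["photons"].mean() == pytest.approx(800.0, rel=0.05)

    def test_post_bleach_trace_near_zero(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=7, field_size_px=24, frame_count=20, background_photons=20.0
        )
        pos = (1.3, 1.3)
        locs = single_emitter_locs(*pos, photons=800.0, frames=10)  # bleaches at 10
        stack = simkit.render_movie(locs, cfg)
        trace = localize.extract_trace(stack, pos, cfg)
        post = trace["photons"].iloc[10:]
        assert abs(post.mean()) < 30.0

    def test_two_fluorophore_spot_two_levels(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=8, field_size_px=24, frame_count=30, background_photons=10.0
        )
        pos = (1.3, 1.3)
        both = single_emitter_locs(*pos, photons=1000.0, frames=15)
        one = single_emitter_locs(*pos, photons=500.0, frames=30).iloc[15:]
        stack = simkit.render_movie(pd.concat([both, one]), cfg, shot_noise=False)
        trace = localize.extract_trace(stack, pos, cfg)
        assert trace["photons"].iloc[:15].mean() == pytest.approx(
            2 * trace["photons"].iloc[15:].mean(), rel=0.05
        )

    def test_border_position_flagged(self):
        cfg = simkit.AcquisitionConfig(rng_seed=9, field_size_px=16, frame_count=2)
        stack = np.zeros((2, 16, 16))
        trace = localize.extract_trace(stack, (0.05, 0.5), cfg)
        assert trace.attrs["partial"]


class TestRenderTalm:
    def test_single_localization_single_bin(self):
        locs = single_emitter_locs(1.0, 1.0)
        img = localize.render_talm(locs, bin_nm=10)
        assert img.image.sum() == 1
        assert (img.image > 0).sum() == 1

    def test_histogram_mass_equals_count(self):
        rng = np.random.default_rng(10)
        locs = pd.DataFrame(
            {
                "frame": np.zeros(777, int),
                "x_um": rng.uniform(0, 5, 777),
                "y_um": rng.uniform(0, 5, 777),
            }
        )
        img = localize.render_talm(locs, bin_nm=20)
        assert img.image.sum() == 777

    def test_tube_renders_elongated_structure(self):
        cfg = simkit.AcquisitionConfig(rng_seed=11, frame_count=900)
        locs, _ = simkit.simulate_nanotube_trajectories(1.0, 5.0, 16.0, 10, cfg)
        img = localize.render_talm(locs, bin_nm=10)
        ny, nx = img.image.shape
        assert nx > 10 * ny or nx > 100  # long axis dominates

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            localize.render_talm(single_emitter_locs(1, 1), bin_nm=0)


class TestProfileFwhm:
    def test_gaussian_samples_known_fwhm(self):
        rng = np.random.default_rng(12)
        n = 20000
        locs = pd.DataFrame(
            {
                "frame": np.zeros(n, int),
                "x_um": rng.uniform(0, 10, n),
                "y_um": rng.normal(5.0, 0.019, n),
            }
        )
        res = localize.profile_fwhm(locs, (5.0, 5.0), (1.0, 0.0))
        assert res.fwhm_nm == pytest.approx(2.3548 * 19.0, rel=0.05)

    def test_tube_width_closed_form(self):
        # transverse variance = sigma_loc^2 + (d/(2 sqrt 2))^2
        cfg = simkit.AcquisitionConfig(rng_seed=13, frame_count=900)
        d_nm = 16.0
        locs, _ = simkit.simulate_nanotube_trajectories(1.0, 5.0, d_nm, 20, cfg)
        proj, axis = diffusion.project_onto_axis(locs)
        center = (locs["x_um"].mean(), locs["y_um"].mean())
        res = localize.profile_fwhm(locs, center, tuple(axis))
        expected = 2.3548 * np.hypot(19.0, d_nm / (2 * np.sqrt(2)))
        assert res.fwhm_nm == pytest.approx(expected, rel=0.07)

    def test_deconvolved_width(self):
        r = localize.FwhmResult(fwhm_nm=2.3548 * 25, sigma_nm=25.0,
                                center_nm=0.0, n_locs=100)
        assert r.deconvolved_width_nm(19.0) == pytest.approx(
            np.sqrt(25**2 - 19**2)
        )

    def test_too_few_localizations_rejected(self):
        locs = single_emitter_locs(1.0, 1.0, frames=10)
        with pytest.raises(ValueError, match="localizations"):
            localize.profile_fwhm(locs, (1.0, 1.0), (1.0, 0.0))


class TestThompsonPrecision:
    def test_more_photons_better_precision(self):
        a = localize.thompson_precision(100, 0.128, 0.107, 10)
        b = localize.thompson_precision(1000, 0.128, 0.107, 10)
        assert b < a
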