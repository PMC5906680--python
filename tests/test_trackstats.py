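"""Linking, mobility classification, registration and kymograph checks."""

import numpy as np
import pandas as pd
import pytest

from poretrack import simkit, trackstats

DT = 0.019


def loc_row(frame, x, y, photons=500.0):
    return {"frame": frame, "x_um": x, "y_um": y, "photons": photons,
            "background": 0.0, "channel": 0}


class TestFilterImmobile:
    def test_stationary_emitter_flagged_immobile(self):
        rng = np.random.default_rng(0)
        locs = pd.DataFrame(
            [loc_row(f, 2.0 + rng.normal(0, 0.019), 2.0 + rng.normal(0, 0.019))
             for f in range(100)]
        )
        immob, mobile = trackstats.filter_immobile(locs)
        assert len(immob) > 90 and len(mobile) < 10

    def test_fast_emitter_stays_mobile(self):
        cfg = simkit.AcquisitionConfig(rng_seed=1, frame_count=100, field_size_px=128)
        locs, _ = simkit.simulate_planar_trajectories([(2.5, 1.0)], 0.0, 5, cfg)
        immob, mobile = trackstats.filter_immobile(locs)
        # inter-frame jump ~ sqrt(pi D dt) ~ 435 nm >> eps 57 nm
        assert len(mobile) > 0.9 * len(locs)

    def test_empty_table_two_empty_sets(self):
        empty = pd.DataFrame(columns=["frame", "x_um", "y_um"])
        immob, mobile = trackstats.filter_immobile(empty)
        assert len(immob) == 0 and len(mobile) == 0


class TestLink:
    def test_single_emitter_single_trajectory(self):
        locs = pd.DataFrame([loc_row(f, 1.0, 1.0) for f in range(100)])
        linked = trackstats.link(locs, max_disp_um=0.5)
        assert linked["traj_id"].nunique() == 1
        assert len(linked) == 100

    def test_parallel_emitters_stay_separate(self):
        rows = []
        for f in range(50):
            rows.append(loc_row(f, 1.0 + 0.01 * f, 1.0))
            rows.append(loc_row(f, 1.0 + 0.01 * f, 1.0 + 10 * 0.107))
        linked = trackstats.link(pd.DataFrame(rows), max_disp_um=0.5)
        assert linked["traj_id"].nunique() == 2
        for _, g in linked.groupby("traj_id"):
            assert g["y_um"].nunique() == 1

    def test_gap_closing_bridges_missing_frame(self):
        frames = [f for f in range(30) if f != 15]
        locs = pd.DataFrame([loc_row(f, 1.0, 1.0) for f in frames])
        linked = trackstats.link(locs, max_disp_um=0.5, max_gap=1)
        assert linked["traj_id"].nunique() == 1

    def test_no_gap_closing_when_disallowed(self):
        frames = [f for f in range(30) if f not in (14, 15)]
        locs = pd.DataFrame([loc_row(f, 1.0, 1.0) for f in frames])
        linked = trackstats.link(locs, max_disp_um=0.5, max_gap=1)
        assert linked["traj_id"].nunique() == 2  # 2-frame gap > max_gap

    def test_linking_conserves_detections(self):
        cfg = simkit.AcquisitionConfig(rng_seed=2, frame_count=30, field_size_px=256)
        locs, _ = simkit.simulate_planar_trajectories(
            [(2.5, 0.5), (1.0, 0.5)], 0.2, 60, cfg
        )
        linked = trackstats.link(locs.drop(columns="particle"), max_disp_um=0.8)
        assert len(linked) == len(locs)
        assert (linked["traj_id"] >= 0).all()

    def test_invalid_max_disp(self):
        with pytest.raises(ValueError):
            trackstats.link(pd.DataFrame([loc_row(0, 1, 1)]), max_disp_um=0.0)


class TestClassifyMobility:
    def test_immobile_true_d_zero(self):
        rng = np.random.default_rng(3)
        traj = pd.DataFrame(
            [loc_row(f, 2.0 + rng.normal(0, 0.019), 2.0 + rng.normal(0, 0.019))
             for f in range(30)]
        ).assign(traj_id=0)
        assert trackstats.classify_mobility(traj) == "immobile"

    def test_fast_diffusion_classified_mobile(self):
        cfg = simkit.AcquisitionConfig(rng_seed=4, frame_count=30)
        locs, _ = simkit.simulate_planar_trajectories([(2.5, 1.0)], 0.0, 1, cfg)
        assert trackstats.classify_mobility(locs) == "mobile"

    def test_short_trajectory_unclassified(self):
        traj = pd.DataFrame([loc_row(f, 1.0, 1.0) for f in range(3)]).assign(traj_id=0)
        assert trackstats.classify_mobility(traj) == "unclassified"

    def test_accuracy_on_mixture_exceeds_95_percent(self):
        # sparse field so linked trajectories rarely cross
        cfg = simkit.AcquisitionConfig(rng_seed=5, frame_count=30, field_size_px=512)
        locs, gt = simkit.simulate_planar_trajectories(
            [(2.5, 0.5), (1.0, 0.5)], 0.3, 200, cfg
        )
        linked = trackstats.link(locs.drop(columns="particle"), max_disp_um=0.8)
        # majority-vote mapping of trajectories onto generating particles
        # (link() returns rows frame-sorted, so align on the same ordering)
        linked["particle"] = (
            locs.sort_values("frame", kind="stable")
            .reset_index(drop=True)["particle"]
        )
        cls = trackstats.classify_trajectories(linked)
        truth = gt.particles.set_index("particle")["mobility"]
        correct = total = 0
        for tid, g in linked.groupby("traj_id"):
            p = g["particle"].mode()[0]
            row = cls[cls["traj_id"] == tid]["mobility"].iloc[0]
            if row == "unclassified":
                continue
            total += 1
            correct += row == truth[p]
        assert total > 150
        assert correct / total >= 0.95


class TestEstimateTransform:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(6).uniform(0, 50, (8, 2))
        tf = trackstats.estimate_transform(pts, pts)
        assert tf.rms_residual_um < 1e-12
        assert abs(tf.angle_rad) < 1e-12

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(7).uniform(0, 50, (8, 2))
        tf = trackstats.estimate_transform(pts, pts - [1.0, 0.0])
        assert np.allclose(tf.translation_um, [1.0, 0.0], atol=1e-12)
        assert abs(tf.angle_rad) < 1e-12

    def test_rigid_motion_with_jitter_recovered_to_5nm(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 50, (20, 2))
        th = 0.05
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = (pts - [0.5, 1.5]) @ rot + rng.normal(0, 0.010, (20, 2))
        tf = trackstats.estimate_transform(pts, moved)
        back = tf.apply(moved)
        assert np.sqrt(np.mean(np.sum((back - pts) ** 2, axis=1))) < 0.015
        assert tf.rms_residual_um < 0.015

    def test_apply_inverts_noiseless_motion_exactly(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 20, (10, 2))
        th = -0.3
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ rot.T + [2.0, -1.0]
        tf = trackstats.estimate_transform(pts, moved)
        assert np.allclose(tf.apply(moved), pts, atol=1e-10)

    def test_collinear_beads_flagged(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        tf = trackstats.estimate_transform(pts, pts)
        assert tf.flagged

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            trackstats.estimate_transform(np.zeros((1, 2)), np.zeros((1, 2)))


class TestColocalize:
    def test_identical_tables_all_colocalized(self):
        locs = pd.DataFrame([loc_row(0, x, 1.0) for x in (1.0, 3.0, 5.0)])
        pairs = trackstats.colocalize(locs, locs)
        assert len(pairs) == 3

    def test_offset_200nm_none_at_default_radius(self):
        a = pd.DataFrame([loc_row(0, 1.0, 1.0)])
        b = pd.DataFrame([loc_row(0, 1.2, 1.0)])
        assert len(trackstats.colocalize(a, b)) == 0

    def test_offset_100nm_within_one_pixel_radius(self):
        a = pd.DataFrame([loc_row(0, 1.0, 1.0)])
        b = pd.DataFrame([loc_row(0, 1.1, 1.0)])
        pairs = trackstats.colocalize(a, b)
        assert len(pairs) == 1
        assert pairs["distance_nm"][0] == pytest.approx(100.0)

    def test_mutuality_prevents_double_counting(self):
        a = pd.DataFrame([loc_row(0, 1.00, 1.0), loc_row(0, 1.05, 1.0)])
        b = pd.DataFrame([loc_row(0, 1.02, 1.0)])
        pairs = trackstats.colocalize(a, b)
        assert len(pairs) == 1


class TestKymograph:
    def test_static_emitter_horizontal_streak(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=10, field_size_px=32, frame_count=10, background_photons=0.0
        )
        locs = pd.DataFrame([loc_row(f, 1.7, 1.7) for f in range(10)])
        stack = simkit.render_movie(locs, cfg, shot_noise=False)
        line = np.array([[0.5, 1.7], [3.0, 1.7]])
        kymo = trackstats.kymograph(stack, line, cfg)
        peaks = kymo.argmax(axis=0)
        assert np.ptp(peaks) == 0  # same position every frame

    def test_moving_emitter_sloped_streak(self):
        cfg = simkit.AcquisitionConfig(
            rng_seed=11, field_size_px=32, frame_count=10, background_photons=0.0
        )
        v = 0.2  # µm per frame
        locs = pd.DataFrame([loc_row(f, 0.8 + v * f, 1.7) for f in range(10)])
        stack = simkit.render_movie(locs, cfg, shot_noise=False)
        line = np.array([[0.5, 1.7], [3.2, 1.7]])
        kymo = trackstats.kymograph(stack, line, cfg, sample_um=0.0535)
        peaks = kymo.argmax(axis=0)
        slopes = np.diff(peaks) * 0.0535
        assert np.mean(slopes) == pytest.approx(v, rel=0.1)

    def test_localization_mode_counts_points(self):
        cfg = simkit.AcquisitionConfig(rng_seed=12)
        locs = pd.DataFrame([loc_row(f, 1.0 + 0.05 * f, 2.0) for f in range(5)])
        line = np.array([[0.9, 2.0], [1.5, 2.0]])
        kymo = trackstats.kymograph(locs, line, cfg)
        assert kymo.sum() == 5

    def test_zero_length_line_rejected(self):
        cfg = simkit.AcquisitionConfig(rng_seed=13)
        with pytest.raises(ValueError):
            trackstats.kymograph(np.zeros((2, 8, 8)), np.array([[1, 1], [1, 1]]), cfg)
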