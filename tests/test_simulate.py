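"""Synthetic gaze simulator: geometry, perturbations, faults, closure."""

import numpy as np
import pandas as pd
import pytest

import gaze3d
from gaze3d import (
    IVTParams,
    SimulationConfig,
    angular_distance,
    evaluate_against_ground_truth,
    io,
    ivt,
    make_target_grid,
    simulate_recording,
    simulate_vor_session,
)
from gaze3d.simulate import HeadMotionParams


class TestTargetGrid:
    def test_stated_eccentricities(self):
        targets = {t.id: t for t in make_target_grid(2.0)}
        forward = np.array([0, 0, 1.0])
        assert angular_distance(targets["center"].position, forward) == pytest.approx(
            0.0, abs=1e-9
        )
        assert angular_distance(
            targets["upper_center"].position, forward
        ) == pytest.approx(12.13, abs=1e-6)
        assert angular_distance(
            targets["upper_left"].position, forward
        ) == pytest.approx(18.25, abs=1e-6)

    def test_nine_targets_reading_order(self):
        targets = make_target_grid(1.0)
        assert len(targets) == 9
        assert targets[0].id == "upper_left" and targets[-1].id == "lower_right"

    def test_angle_bounds_checked(self):
        with pytest.raises(ValueError):
            make_target_grid(1.0, edge_angle_deg=85.0)


class TestGridSimulation:
    def test_noise_free_session_has_zero_error(self):
        rec, gt = simulate_recording(
            SimulationConfig(distances=(1.0,), fixation_duration_s=0.5, seed=3)
        )
        results = evaluate_against_ground_truth(rec, gt)
        assert len(results) == 9
        assert max(r.accuracy_cm for r in results) < 1e-9
        assert max(r.accuracy_deg for r in results) < 1e-6

    def test_pure_offset_recovered_exactly(self):
        rec, gt = simulate_recording(
            SimulationConfig(distances=(2.0,), fixation_duration_s=3.0,
                             offset_deg=1.0, seed=5)
        )
        results = evaluate_against_ground_truth(rec, gt)
        for r in results:
            assert r.accuracy_deg == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(distances=(1.0,), fixation_duration_s=0.3,
                               noise_sd_deg=0.5, dropout_rate=0.1, seed=9)
        rec_a, gt_a = simulate_recording(cfg)
        rec_b, gt_b = simulate_recording(cfg)
        pd.testing.assert_frame_equal(rec_a.data, rec_b.data)
        pd.testing.assert_frame_equal(gt_a.per_sample, gt_b.per_sample)

    def test_fault_free_mean_delta(self):
        rec, _ = simulate_recording(
            SimulationConfig(distances=(1.0,), fixation_duration_s=0.5, seed=1)
        )
        deltas = np.diff(rec.relative_timestamps)
        # timestamps carry the 100 ns clock quantization
        assert deltas.mean() == pytest.approx(1000.0 / 30.0, abs=1e-4)

    def test_dropout_marks_samples_invalid(self):
        rec, gt = simulate_recording(
            SimulationConfig(distances=(1.0,), fixation_duration_s=0.5,
                             dropout_rate=0.2, seed=4)
        )
        n_invalid = (~rec.valid).sum()
        assert n_invalid == int(0.2 * len(rec))
        assert np.isnan(rec.origins[~rec.valid]).all()
        assert (gt.per_sample["dropout"].to_numpy() == ~rec.valid).all()

    def test_walking_head_translates_with_grid(self):
        hm = HeadMotionParams(walk_amplitude_m=0.3, walk_frequency_hz=0.5)
        rec, gt = simulate_recording(
            SimulationConfig(setting="walking_grid", distances=(1.0,),
                             fixation_duration_s=1.0, head_motion=hm, seed=6)
        )
        z = rec.origins[:, 2]
        assert z.max() > 0.25 and z.min() < -0.25
        # grid moves rigidly: head-frame error still zero
        results = evaluate_against_ground_truth(rec, gt)
        assert max(r.accuracy_deg for r in results) < 1e-6

    def test_unknown_setting_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(setting="flying")


class TestVORSession:
    cfg = SimulationConfig(setting="stationary_target", session_length_s=4.0,
                           target_distance_m=0.4987, seed=2)

    def test_noise_free_gaze_points_at_sphere_center(self):
        rec, gt = simulate_vor_session(self.cfg)
        center = np.asarray(gt.session["sphere_center"])
        assert np.abs(rec.points - center).max() < 1e-6

    def test_configured_distance_reproduced(self):
        rec, gt = simulate_vor_session(self.cfg)
        res = evaluate_against_ground_truth(rec, gt)[0]
        assert abs(res.mean_distance_cm - 49.87) < 0.5

    def test_yaw_amplitude_matches_config(self):
        rec, gt = simulate_vor_session(self.cfg)
        assert gt.per_sample["head_yaw_deg"].abs().max() == pytest.approx(30.0, abs=0.1)

    def test_grid_entry_point_rejects_wrong_setting(self):
        with pytest.raises(ValueError):
            simulate_vor_session(SimulationConfig(setting="resting_grid"))

    def test_aoi_is_the_sphere(self):
        rec, _ = simulate_vor_session(self.cfg)
        names = set(rec.aoi_names) - {""}
        assert names == {"stationary_target"}


class TestPipelineClosure:
    def test_simulate_write_load_validate_detect(self, tmp_path):
        cfg = SimulationConfig(
            distances=(2.0,), fixation_duration_s=1.0, saccade_duration_ms=166.67,
            offset_deg=1.0, noise_sd_deg=0.4, duplicate_count=2, drop_frame_count=2,
            seed=13,
        )
        rec, gt = simulate_recording(cfg)
        csv, meta = tmp_path / "s.csv", tmp_path / "s.json"
        io.write_recording(rec, csv, meta)
        loaded = io.load_recording(csv, meta)
        cleaned, report = io.validate_timestamps(loaded)
        assert report.n_duplicates == 2
        _, events = ivt(cleaned, IVTParams(30.0, 20.0))
        events = gaze3d.discard_short_fixations(events, gaze3d.DiscardParams(200.0))
        assert len(events) == 9  # one fixation per grid target
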