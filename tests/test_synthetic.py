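"""Tests of the calibration path, eye/camera model, and session generator."""

import numpy as np
import pandas as pd
import pytest

from gazekit.dlc_io import (
    RAW_LANDMARKS,
    DLCFormatError,
    empty_table,
    read_dlc_csv,
    write_dlc_csv,
)
from gazekit.preprocess import filter_low_likelihood
from gazekit.synthetic import (
    CameraModel,
    HeadPose,
    SimulationConfig,
    gaze_direction,
    generate_calibration_path,
    simulate_frame,
    simulate_session,
)

FRONTAL = HeadPose()


class TestCalibrationPath:
    def test_serpentine_structure(self, geom):
        path = generate_calibration_path(geom, n_lines=5)
        y = path["y"].to_numpy()
        assert np.all(np.diff(y) >= 0), "y must be monotonically non-decreasing"
        # exactly n_lines distinct horizontal levels -> 4 vertical increments
        levels = np.unique(np.round(y[np.isin(y, np.unique(y))], 6))
        plateau_levels = np.unique(np.round(np.linspace(50, geom.height_px - 50, 5), 6))
        assert set(plateau_levels) <= set(levels)
        assert np.all(path["x"] >= 0) and np.all(path["x"] <= geom.width_px)

    def test_slowdown_increases_edge_sampling_density(self, geom):
        """With slow ends and a fast middle, the end thirds of a sweep hold
        more samples than the middle third (sampling density ~ 1/speed)."""
        path = generate_calibration_path(geom, n_lines=2, slow_factor=0.4, fast_factor=1.6)
        first_line = path[np.isclose(path["y"], path["y"].iloc[0])]
        x = first_line["x"].to_numpy()
        span = x.max() - x.min()
        third = span / 3
        n_ends = np.sum(x < x.min() + third) + np.sum(x > x.max() - third)
        n_mid = np.sum((x >= x.min() + third) & (x <= x.max() - third))
        assert n_ends / 2 > n_mid

    def test_default_session_lasts_about_one_minute(self, geom):
        path = generate_calibration_path(geom)
        n_frames = len(path)
        assert 0.8 * 1800 <= n_frames <= 1.2 * 1800

    def test_rejects_degenerate_inputs(self, geom):
        with pytest.raises(ValueError):
            generate_calibration_path(geom, n_lines=1)
        with pytest.raises(ValueError):
            generate_calibration_path(geom, margin_px=1300.0)
        with pytest.raises(ValueError):
            generate_calibration_path(geom, slow_factor=0.0)


class TestGazeDirection:
    def test_straight_ahead(self):
        v = gaze_direction((0, 0, 500), (0, 0, 0))
        assert np.allclose(v, [0, 0, -1])

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3) + 5
        assert np.allclose(gaze_direction(a, b), -gaze_direction(b, a))

    def test_unit_norm(self, rng):
        for _ in range(1000):
            a, b = rng.normal(size=3), rng.normal(size=3) * 10 + 1
            assert abs(np.linalg.norm(gaze_direction(a, b)) - 1.0) < 1e-12

    def test_rejects_coincident_points(self):
        with pytest.raises(ValueError):
            gaze_direction((1, 2, 3), (1, 2, 3))


class TestSimulateFrame:
    def _noiseless(self):
        return SimulationConfig(noise_sd_px=0.0, blink_probability=0.0, seed=0)

    def test_frontal_center_target_is_symmetric(self, geom, face, cam, rng):
        """Looking at the screen's horizontal center from a frontal pose, the
        left/right pupil centers project symmetrically about the midline."""
        obs, valid = simulate_frame(
            (geom.width_px / 2, 720.0), FRONTAL, face, cam, geom, self._noiseless(), rng
        )
        assert valid
        left = np.mean([[obs[f"left_pupil_corner_{k}"][0], obs[f"left_pupil_corner_{k}"][1]] for k in range(1, 5)], axis=0)
        right = np.mean([[obs[f"right_pupil_corner_{k}"][0], obs[f"right_pupil_corner_{k}"][1]] for k in range(1, 5)], axis=0)
        midline = cam.principal_point[0]
        assert left[0] - midline == pytest.approx(midline - right[0], abs=1e-6)
        assert left[1] == pytest.approx(right[1], abs=1e-6)

    def test_only_pupils_move_with_gaze(self, geom, face, cam, rng):
        cfg = self._noiseless()
        obs_a, _ = simulate_frame((100.0, 100.0), FRONTAL, face, cam, geom, cfg, rng)
        obs_b, _ = simulate_frame((2400.0, 1300.0), FRONTAL, face, cam, geom, cfg, rng)
        for name in RAW_LANDMARKS:
            a = np.array(obs_a[name][:2])
            b = np.array(obs_b[name][:2])
            if "pupil" in name:
                assert not np.allclose(a, b)
            else:
                assert np.allclose(a, b)

    def test_noise_magnitude_recovered(self, geom, face, cam):
        """Monte-Carlo: with noise_sd_px=1 the per-coordinate SD is ~1 px."""
        cfg = SimulationConfig(noise_sd_px=1.0, blink_probability=0.0, seed=0)
        rng = np.random.default_rng(77)
        xs = np.array(
            [
                simulate_frame((1280.0, 720.0), FRONTAL, face, cam, geom, cfg, rng)[0][
                    "lip_philtrum"
                ][:2]
                for _ in range(10_000)
            ]
        )
        assert xs[:, 0].std() == pytest.approx(1.0, rel=0.1)
        assert xs[:, 1].std() == pytest.approx(1.0, rel=0.1)

    def test_pose_moves_static_landmarks(self, geom, face, cam, rng):
        cfg = self._noiseless()
        target = (1280.0, 720.0)
        obs_a, _ = simulate_frame(target, HeadPose(yaw_deg=-20), face, cam, geom, cfg, rng)
        obs_b, _ = simulate_frame(target, HeadPose(yaw_deg=20), face, cam, geom, cfg, rng)
        assert not np.allclose(obs_a["lip_philtrum"][:2], obs_b["lip_philtrum"][:2])

    def test_identifiability_over_screen_grid(self, geom, face, cam, rng):
        """Zero noise, fixed pose: distinct targets give distinct pupil
        projections over a 10x10 screen grid."""
        cfg = self._noiseless()
        feats = []
        for gx in np.linspace(50, geom.width_px - 50, 10):
            for gy in np.linspace(50, geom.height_px - 50, 10):
                obs, _ = simulate_frame((gx, gy), FRONTAL, face, cam, geom, cfg, rng)
                feats.append(
                    [v for k in sorted(obs) if "pupil" in k for v in obs[k][:2]]
                )
        feats = np.asarray(feats)
        dists = np.linalg.norm(feats[:, None, :] - feats[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() > 1e-6


class TestSimulateSession:
    def test_row_counts_and_alignment(self, geom, face, cam, short_path):
        cfg = SimulationConfig(seed=3)
        landmarks, targets = simulate_session(short_path, face, cam, geom, cfg)
        assert len(landmarks) == len(targets) == 3 * len(short_path)
        assert landmarks.index.equals(targets.index)
        assert list(targets["pose"].unique()) == [0, 1, 2]

    def test_blink_rate_recovered_by_filter(self, geom, face, cam, short_path):
        cfg = SimulationConfig(seed=5, blink_probability=0.1)
        landmarks, _ = simulate_session(short_path, face, cam, geom, cfg)
        _, report = filter_low_likelihood(landmarks, threshold=0.7)
        n = report["n_input"]
        sd = np.sqrt(0.1 * 0.9 / n)
        assert abs(report["fraction_removed"] - 0.1) < 3 * sd

    def test_no_blinks_means_high_likelihoods(self, geom, face, cam, short_path):
        cfg = SimulationConfig(seed=5, blink_probability=0.0)
        landmarks, _ = simulate_session(short_path, face, cam, geom, cfg)
        lik = landmarks.xs("likelihood", axis=1, level="coords")
        assert (lik.to_numpy() >= 0.9).all()

    def test_seed_determinism(self, geom, face, cam, short_path):
        cfg = SimulationConfig(seed=9)
        a = simulate_session(short_path, face, cam, geom, cfg)
        b = simulate_session(short_path, face, cam, geom, cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestDlcCsvRoundTrip:
    def test_round_trip_small_session(self, tmp_path, small_session):
        landmarks, _, _ = small_session
        f = tmp_path / "session.csv"
        write_dlc_csv(landmarks.iloc[:100], f)
        back = read_dlc_csv(f)
        assert np.allclose(back.to_numpy(), landmarks.iloc[:100].to_numpy(), atol=1e-9)
        assert list(back.columns) == list(landmarks.columns)

    def test_column_schema(self, tmp_path, small_session):
        landmarks, _, _ = small_session
        f = tmp_path / "session.csv"
        write_dlc_csv(landmarks, f)
        header = f.read_text().splitlines()[:3]
        assert header[0].startswith("scorer")
        assert header[1].startswith("bodyparts")
        assert header[2].startswith("coords")
        # 13 raw tracked points x (x, y, likelihood) + frame index column
        assert len(header[2].split(",")) == 1 + 3 * 13

    def test_empty_session(self, tmp_path):
        f = tmp_path / "empty.csv"
        write_dlc_csv(empty_table(), f)
        back = read_dlc_csv(f)
        assert len(back) == 0
        assert list(back.columns) == list(empty_table().columns)

    def test_malformed_header_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("a,b,c\n1,2,3\n4,5,6\n")
        with pytest.raises(DLCFormatError):
            read_dlc_csv(f)


def test_invalid_pose_and_config_rejected():
    with pytest.raises(ValueError):
        HeadPose(position_mm=(0.0, 0.0, -10.0))
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd_px=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(normal_likelihood_range=(0.5, 1.0))


def test_camera_projects_principal_axis_to_principal_point():
    cam = CameraModel()
    px, in_front = cam.project(np.array([[0.0, 0.0, 500.0]]))
    assert np.allclose(px[0], cam.principal_point)
    assert in_front.all()
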