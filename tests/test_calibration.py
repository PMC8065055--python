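"""Device calibrations: pivot, US probe, TRUS probe, MR, table shift."""

import numpy as np
import pytest

from navfuse.calibration import (
    PoseReading,
    PoseStream,
    TrusSweep,
    UsCalibrationObservation,
    average_pose,
    calibrate_mr,
    calibrate_pivot,
    calibrate_trus_probe,
    calibrate_us_probe,
    track_table_shift,
)
from navfuse.pointreg import DegenerateFiducialsError, FiducialSet
from navfuse.transforms import (
    FrameMismatchError,
    apply_to_array,
    compose,
    from_rotation_translation,
    invert,
    random_rigid,
    translation,
)
from scipy.spatial.transform import Rotation


def _pivot_poses(tip, pivot, n, rng, sigma=0.0, span_scale=1.0):
    poses = []
    for _ in range(n):
        r = Rotation.from_rotvec(
            span_scale * rng.uniform(-0.8, 0.8, 3)
        ).as_matrix()
        t = pivot - r @ tip + rng.normal(0, sigma, 3)
        poses.append(from_rotation_translation(r, t, source="stylus", target="world"))
    return poses


class TestPivot:
    def test_noiseless_recovery(self, rng):
        tip = np.array([0.0, 5.0, 120.0])
        pivot = np.array([100.0, -50.0, 30.0])
        res = calibrate_pivot(_pivot_poses(tip, pivot, 50, rng))
        assert np.allclose(res.tip_offset_mm, tip, atol=1e-9)
        assert np.allclose(res.pivot_point_mm, pivot, atol=1e-9)
        assert res.rms_mm < 1e-9

    def test_noisy_residual_matches_sigma(self, rng):
        tip = np.array([0.0, 0.0, 150.0])
        pivot = np.array([10.0, 20.0, 30.0])
        res = calibrate_pivot(_pivot_poses(tip, pivot, 1000, rng, sigma=0.2))
        assert res.rms_mm == pytest.approx(0.2, rel=0.2)
        assert np.linalg.norm(res.tip_offset_mm - tip) < 0.2

    def test_pure_translation_rejected(self, rng):
        poses = [
            translation(rng.uniform(-100, 100, 3), source="stylus", target="world")
            for _ in range(20)
        ]
        with pytest.raises(DegenerateFiducialsError, match="span"):
            calibrate_pivot(poses)

    def test_too_few_poses_rejected(self, rng):
        tip, pivot = np.zeros(3), np.ones(3)
        with pytest.raises(DegenerateFiducialsError, match=">="):
            calibrate_pivot(_pivot_poses(tip, pivot, 5, rng))

    def test_stream_input(self, rng):
        tip, pivot = np.array([1.0, 2.0, 100.0]), np.array([5.0, 5.0, 5.0])
        stream = PoseStream(
            readings=[
                PoseReading(time_s=i * 0.1, tool_id="stylus", pose=p)
                for i, p in enumerate(_pivot_poses(tip, pivot, 30, rng))
            ]
        )
        res = calibrate_pivot(stream)
        assert np.allclose(res.tip_offset_mm, tip, atol=1e-9)


def _us_world(seed, n_obs, sigma=0.0, n_tips=7):
    """Synthetic US-calibration world; returns (observations, truth C)."""
    rng = np.random.default_rng(seed)
    c_true = random_rigid(rng, "US", "trans", max_translation_mm=80)
    pose_tank = random_rigid(rng, "tank", "world", max_translation_mm=400)
    tank_tips = rng.uniform(-40, 40, (n_tips, 3))
    labels = [f"c{i}" for i in range(n_tips)]
    tips_world = apply_to_array(pose_tank, tank_tips)
    obs = []
    for _ in range(n_obs):
        pose_probe = random_rigid(rng, "trans", "world", max_translation_mm=400)
        world_to_img = invert(compose(pose_probe, c_true))
        img = apply_to_array(world_to_img, tips_world) + rng.normal(
            0, sigma, (n_tips, 3)
        )
        tank = tank_tips + rng.normal(0, sigma, (n_tips, 3))
        obs.append(
            UsCalibrationObservation(
                image_tips=FiducialSet.from_arrays(labels, img, frame="US"),
                tank_tips=FiducialSet.from_arrays(labels, tank, frame="tank"),
                pose_probe=pose_probe,
                pose_tank=pose_tank,
            )
        )
    return obs, c_true


class TestUsProbe:
    def test_noiseless_exact_recovery(self):
        obs, c_true = _us_world(0, 1)
        cal = calibrate_us_probe(obs)
        assert np.max(np.abs(cal.image_to_tool.matrix - c_true.matrix)) < 1e-9
        assert cal.fre_mm < 1e-9

    def test_more_observations_reduce_error(self):
        test_pts = np.random.default_rng(9).uniform(-50, 50, (20, 3))
        rms = {}
        for n_obs in (1, 5):
            errs = []
            for rep in range(100):
                obs, c_true = _us_world(1000 + rep, n_obs, sigma=0.3)
                cal = calibrate_us_probe(obs)
                d = apply_to_array(cal.image_to_tool, test_pts) - apply_to_array(
                    c_true, test_pts
                )
                errs.append(np.mean(np.sum(d**2, axis=1)))
            rms[n_obs] = np.sqrt(np.mean(errs))
        assert rms[5] < rms[1]

    def test_frame_mismatch_rejected(self):
        obs, _ = _us_world(2, 1)
        bad = UsCalibrationObservation(
            image_tips=obs[0].image_tips,
            tank_tips=FiducialSet.from_arrays(
                obs[0].tank_tips.labels, obs[0].tank_tips.coordinates, frame="boat"
            ),
            pose_probe=obs[0].pose_probe,
            pose_tank=obs[0].pose_tank,
        )
        with pytest.raises(FrameMismatchError):
            calibrate_us_probe([bad])

    def test_invariant_to_global_tracker_motion(self, rng):
        obs, _ = _us_world(3, 3, sigma=0.1)
        cal = calibrate_us_probe(obs)
        g = random_rigid(rng, "world", "world2")
        moved = [
            UsCalibrationObservation(
                image_tips=o.image_tips,
                tank_tips=o.tank_tips,
                pose_probe=compose(g, o.pose_probe),
                pose_tank=compose(g, o.pose_tank),
            )
            for o in obs
        ]
        cal2 = calibrate_us_probe(moved)
        assert np.max(np.abs(cal.image_to_tool.matrix - cal2.image_to_tool.matrix)) < 1e-9


def _trus_sweep(seed, sigma=0.0, n=15, collinear=False):
    rng = np.random.default_rng(seed)
    c_true = random_rigid(rng, "TRUS", "trans", max_translation_mm=60)
    pose_probe = random_rigid(rng, "trans", "world", max_translation_mm=300)
    spacing = (0.4, 0.4)
    if collinear:
        px = np.column_stack([np.arange(n, dtype=float), np.full(n, 3.0)])
    else:
        px = rng.uniform(0, 200, (n, 2))
    img_mm = np.column_stack([px[:, 0] * spacing[0], px[:, 1] * spacing[1], np.zeros(n)])
    world = apply_to_array(compose(pose_probe, c_true), img_mm)
    labels = [f"f{i}" for i in range(n)]
    tips = FiducialSet.from_arrays(
        labels, world + rng.normal(0, sigma, (n, 3)), frame="world"
    )
    sweep = TrusSweep(
        pixel_points=px,
        pixel_spacing_mm=spacing,
        pointer_tips=tips,
        pose_probe=pose_probe,
    )
    return sweep, c_true


class TestTrusProbe:
    def test_noiseless_exact_recovery(self):
        sweep, c_true = _trus_sweep(0)
        cal = calibrate_trus_probe([sweep])
        assert np.max(np.abs(cal.image_to_tool.matrix - c_true.matrix)) < 1e-9
        assert cal.fre_mm < 1e-9
        assert cal.registration.coplanar

    def test_collinear_rejected(self):
        sweep, _ = _trus_sweep(1, collinear=True)
        with pytest.raises(DegenerateFiducialsError):
            calibrate_trus_probe([sweep])

    def test_noisy_fre_matches_independent_solver(self):
        """Mean FRE over replicates agrees with a quaternion-method oracle."""

        def horn_fre(m, f):
            # independent closed-form rigid fit (Horn's quaternion method)
            mc, fc = m - m.mean(0), f - f.mean(0)
            s = mc.T @ fc
            tr = np.trace(s)
            delta = np.array([s[1, 2] - s[2, 1], s[2, 0] - s[0, 2], s[0, 1] - s[1, 0]])
            q = np.zeros((4, 4))
            q[0, 0] = tr
            q[0, 1:] = delta
            q[1:, 0] = delta
            q[1:, 1:] = s + s.T - tr * np.eye(3)
            w, v = np.linalg.eigh(q)
            quat = v[:, -1]  # (w, x, y, z)
            r = Rotation.from_quat(
                [quat[1], quat[2], quat[3], quat[0]]
            ).as_matrix()
            res = (mc @ r.T) - fc
            return np.sqrt(np.mean(np.sum(res**2, axis=1)))

        mine, oracle = [], []
        for rep in range(300):
            sweep, c_true = _trus_sweep(500 + rep, sigma=0.3)
            cal = calibrate_trus_probe([sweep])
            mine.append(cal.fre_mm)
            sx, sy = sweep.pixel_spacing_mm
            m = np.column_stack(
                [sweep.pixel_points[:, 0] * sx, sweep.pixel_points[:, 1] * sy,
                 np.zeros(len(sweep.pixel_points))]
            )
            to_tool = invert(sweep.pose_probe)
            f = apply_to_array(to_tool, sweep.pointer_tips.coordinates)
            oracle.append(horn_fre(m, f))
        assert np.mean(mine) == pytest.approx(np.mean(oracle), rel=0.15)


def _mr_world(seed, sigma=0.0, n_tips=18, n_repeats=5):
    rng = np.random.default_rng(seed)
    m_true = random_rigid(rng, "MR", "ORF_TABLE", max_translation_mm=300)
    tips_mr = rng.uniform(-60, 60, (n_tips, 3))
    labels = [f"cone_{i}" for i in range(n_tips)]
    tips_table = apply_to_array(m_true, tips_mr)
    reps = {
        lab: tips_table[i] + rng.normal(0, sigma, (n_repeats, 3))
        for i, lab in enumerate(labels)
    }
    ref = FiducialSet.from_repeats(reps, frame="ORF_TABLE")
    img = FiducialSet.from_arrays(labels, tips_mr, frame="MR")
    return ref, img, m_true


class TestMrCalibration:
    def test_noiseless_exact(self):
        ref, img, m_true = _mr_world(0)
        cal = calibrate_mr(ref, img)
        assert np.max(np.abs(cal.mr_to_reference.matrix - m_true.matrix)) < 1e-9
        assert cal.reference == "table"

    def test_repeat_averaging_reduces_fre(self):
        fre5, fre1 = [], []
        for rep in range(300):
            ref, img, _ = _mr_world(2000 + rep, sigma=0.3, n_repeats=5)
            fre5.append(calibrate_mr(ref, img).fre_mm)
            ref1, img1, _ = _mr_world(2000 + rep, sigma=0.3, n_repeats=1)
            fre1.append(calibrate_mr(ref1, img1).fre_mm)
        assert np.mean(fre5) < np.mean(fre1)

    def test_two_tips_rejected(self):
        ref, img, _ = _mr_world(1, n_tips=2)
        with pytest.raises(DegenerateFiducialsError):
            calibrate_mr(ref, img)


def _stream(pose, tool, n, sigma, seed, t0=0.0):
    rng = np.random.default_rng(seed)
    readings = []
    for i in range(n):
        t = pose.translation + rng.normal(0, sigma, 3)
        readings.append(
            PoseReading(
                time_s=t0 + 0.1 * i,
                tool_id=tool,
                pose=from_rotation_translation(
                    pose.rotation, t, source=pose.source, target=pose.target
                ),
            )
        )
    return PoseStream(readings=readings)


class TestTableShift:
    def test_identical_streams_give_identity(self, rng):
        pose = random_rigid(rng, "ORF_TABLE", "world")
        s = _stream(pose, "ORF_TABLE", 20, 0.0, 0)
        shift = track_table_shift(s, s, "ORF_TABLE")
        assert np.allclose(shift.matrix, np.eye(4), atol=1e-12)
        assert shift.source == "ORF_TABLE_moved"
        assert shift.target == "ORF_TABLE"

    def test_pure_translation_recovered(self, rng):
        pose = random_rigid(rng, "ORF_TABLE", "world")
        moved = from_rotation_translation(
            pose.rotation,
            pose.translation + np.array([0.0, 0.0, 200.0]),
            source="ORF_TABLE",
            target="world",
        )
        shift = track_table_shift(
            _stream(pose, "ORF_TABLE", 10, 0.0, 0),
            _stream(moved, "ORF_TABLE", 10, 0.0, 1),
            "ORF_TABLE",
        )
        assert np.allclose(shift.rotation, np.eye(3), atol=1e-12)
        # translation expressed in the tool frame has magnitude 200
        assert np.linalg.norm(shift.translation) == pytest.approx(200.0, abs=1e-9)

    def test_jitter_averages_out(self, rng):
        pose = random_rigid(rng, "ORF_TABLE", "world")
        moved = from_rotation_translation(
            pose.rotation,
            pose.translation + np.array([150.0, 0.0, 0.0]),
            source="ORF_TABLE",
            target="world",
        )
        shift = track_table_shift(
            _stream(pose, "ORF_TABLE", 100, 0.3, 10),
            _stream(moved, "ORF_TABLE", 100, 0.3, 11),
            "ORF_TABLE",
        )
        assert np.linalg.norm(shift.translation) == pytest.approx(150.0, abs=0.1)

    def test_missing_tool_rejected(self, rng):
        pose = random_rigid(rng, "ORF_TABLE", "world")
        s = _stream(pose, "ORF_TABLE", 10, 0.0, 0)
        with pytest.raises(ValueError, match="no valid readings"):
            track_table_shift(s, s, "other_tool")


class TestAveragePose:
    def test_chordal_mean_of_jitter(self, rng):
        pose = random_rigid(rng, "tool", "world")
        jittered = []
        for _ in range(500):
            dr = Rotation.from_rotvec(rng.normal(0, 0.001, 3)).as_matrix()
            jittered.append(
                from_rotation_translation(
                    dr @ pose.rotation,
                    pose.translation + rng.normal(0, 0.3, 3),
                    source="tool",
                    target="world",
                )
            )
        mean = average_pose(jittered)
        assert np.max(np.abs(mean.rotation - pose.rotation)) < 1e-3
        assert np.linalg.norm(mean.translation - pose.translation) < 0.1

    def test_mixed_frames_rejected(self, rng):
        with pytest.raises(FrameMismatchError):
            average_pose(
                [random_rigid(rng, "a", "world"), random_rigid(rng, "b", "world")]
            )
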