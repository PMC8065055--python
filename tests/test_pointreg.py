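"""Paired-point registration: exact recovery, FRE statistics, CAD refinement."""

import numpy as np
import pytest

from navfuse.pointreg import (
    DegenerateFiducialsError,
    FiducialSet,
    average_repeats,
    compute_tre,
    refine_fiducials_via_cad,
    register_points,
)
from navfuse.transforms import (
    apply_to_array,
    axis_rotation,
    compose,
    from_rotation_translation,
    identity,
    random_rigid,
    translation,
)


def _set(coords, frame="A", labels=None):
    coords = np.asarray(coords, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(coords))]
    return FiducialSet.from_arrays(labels, coords, frame=frame)


UNIT_POINTS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1]],
    dtype=float,
)


class TestAverageRepeats:
    def test_single_reading_unchanged(self):
        raw = FiducialSet.from_repeats({"a": [[1, 2, 3]]}, frame="A")
        out = average_repeats(raw)
        assert np.allclose(out.coordinates, [[1, 2, 3]])
        assert out.spreads["a"] == 0.0

    def test_two_reading_mean_and_spread(self):
        raw = FiducialSet.from_repeats({"a": [[0, 0, 0], [2, 0, 0]]}, frame="A")
        out = average_repeats(raw)
        assert np.allclose(out.coordinates, [[1, 0, 0]])
        assert out.spreads["a"] == pytest.approx(1.0)

    def test_outlier_is_rejected(self):
        raw = FiducialSet.from_repeats(
            {"a": [[0, 0, 0], [0.1, 0, 0], [-0.1, 0, 0], [0.05, 0, 0], [50, 0, 0]]},
            frame="A",
        )
        out = average_repeats(raw)
        assert abs(out.coordinates[0, 0]) < 0.2  # outlier did not drag the mean

    def test_zero_readings_rejected(self):
        with pytest.raises(ValueError):
            FiducialSet.from_repeats({"a": np.empty((0, 3))}, frame="A")

    def test_spread_matches_sampling_theory(self, rng):
        # n readings of per-axis sigma noise: E[spread] ~ sigma*sqrt(3)*sqrt((n-1)/n)
        sigma, n_read, n_labels = 0.3, 10, 10_000
        truth = rng.uniform(-50, 50, size=(n_labels, 3))
        readings = {
            f"l{i}": truth[i] + rng.normal(0, sigma, size=(n_read, 3))
            for i in range(n_labels)
        }
        out = average_repeats(FiducialSet.from_repeats(readings, frame="A"))
        mean_spread = np.mean(list(out.spreads.values()))
        expect = sigma * np.sqrt(3) * np.sqrt((n_read - 1) / n_read)
        assert mean_spread == pytest.approx(expect, rel=0.02)


class TestRegisterPoints:
    def test_identity_on_equal_sets(self):
        fs = _set(UNIT_POINTS)
        res = register_points(fs, _set(UNIT_POINTS))
        assert np.allclose(res.transform.matrix, np.eye(4), atol=1e-12)
        assert res.fre_mm == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_known_motion(self):
        t = compose(
            translation((1, 2, 3), source="B", target="B"),
            axis_rotation("z", 90, source="A", target="B"),
        )
        moving = _set(UNIT_POINTS, frame="A")
        fixed = _set(apply_to_array(t, UNIT_POINTS), frame="B")
        res = register_points(moving, fixed)
        assert np.allclose(res.transform.matrix, t.matrix, atol=1e-10)
        assert res.fre_mm < 1e-10

    def test_too_few_points(self):
        with pytest.raises(DegenerateFiducialsError):
            register_points(_set(UNIT_POINTS[:2]), _set(UNIT_POINTS[:2] + 1))

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateFiducialsError):
            register_points(_set(pts), _set(pts + 1))

    def test_coplanar_flagged_with_proper_rotation(self, rng):
        pts = np.column_stack([rng.uniform(-20, 20, (8, 2)), np.zeros(8)])
        t = random_rigid(rng, "A", "B")
        res = register_points(
            _set(pts, frame="A"),
            _set(apply_to_array(t, pts) + rng.normal(0, 0.1, pts.shape), frame="B"),
        )
        assert res.coplanar
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_label_pairing_beats_ordering(self, rng):
        t = random_rigid(rng, "A", "B")
        moving = _set(UNIT_POINTS, frame="A")
        perm = rng.permutation(len(UNIT_POINTS))
        fixed = FiducialSet.from_arrays(
            [f"p{i}" for i in perm],
            apply_to_array(t, UNIT_POINTS[perm]),
            frame="B",
        )
        res = register_points(moving, fixed)
        assert res.fre_mm < 1e-10

    def test_equivariance_under_common_motion(self, rng):
        moving = _set(rng.uniform(-30, 30, (7, 3)), frame="A")
        fixed = _set(
            apply_to_array(random_rigid(rng, "A", "B"), moving.coordinates)
            + rng.normal(0, 0.3, (7, 3)),
            frame="B",
        )
        base = register_points(moving, fixed).fre_mm
        g = random_rigid(rng, "B", "B")
        moved_fixed = _set(apply_to_array(g, fixed.coordinates), frame="B")
        assert register_points(moving, moved_fixed).fre_mm == pytest.approx(
            base, abs=1e-9
        )

    def test_optimality_against_perturbations(self, rng):
        moving = _set(rng.uniform(-30, 30, (7, 3)), frame="A")
        fixed = _set(
            moving.coordinates + rng.normal(0, 0.5, (7, 3)), frame="A"
        )
        res = register_points(moving, fixed)
        m, f = moving.coordinates, fixed.coordinates
        for _ in range(50):
            pert = random_rigid(rng, "A", "A", max_translation_mm=0.5)
            small = from_rotation_translation(
                pert.rotation @ res.transform.rotation,
                res.transform.translation + rng.normal(0, 0.2, 3),
                source="A",
                target="A",
            )
            fre = np.sqrt(np.mean(np.linalg.norm(apply_to_array(small, m) - f, axis=1) ** 2))
            assert fre >= res.fre_mm - 1e-12

    def test_fre_is_rms_of_residuals(self, rng):
        moving = _set(rng.uniform(-30, 30, (9, 3)), frame="A")
        fixed = _set(moving.coordinates + rng.normal(0, 0.4, (9, 3)), frame="A")
        res = register_points(moving, fixed)
        assert res.fre_mm == pytest.approx(
            np.sqrt(np.mean(res.per_point_residuals_mm**2)), abs=1e-12
        )

    def test_fitzpatrick_fre_expectation(self):
        # mean FRE^2 ~ (1 - 2/N) * FLE^2 under isotropic localization noise
        rng = np.random.default_rng(1)
        n, reps = 7, 4000
        fle_total = 0.3
        sigma_axis = fle_total / np.sqrt(3)
        base = np.random.default_rng(0).uniform(-40, 40, size=(n, 3))
        fixed = _set(base, frame="A")
        labels = fixed.labels
        fre_sq = np.empty(reps)
        for i in range(reps):
            noisy = base + rng.normal(0, sigma_axis, size=(n, 3))
            res = register_points(
                FiducialSet.from_arrays(labels, noisy, frame="A"), fixed
            )
            fre_sq[i] = res.fre_mm**2
        expect = (1 - 2 / n) * fle_total**2
        assert np.mean(fre_sq) == pytest.approx(expect, rel=0.05)


class TestComputeTre:
    def test_identity_zeroes(self):
        fs = _set(UNIT_POINTS)
        rep = compute_tre(fs, fs, identity("A"))
        assert np.all(rep.distances_mm == 0)
        assert rep.mean_mm == 0.0

    def test_single_displaced_target(self):
        a = _set([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        b = _set([[1, 0, 0], [5, 0, 0], [0, 5, 0]])
        rep = compute_tre(a, b, identity("A"))
        assert rep.distances_mm[0] == pytest.approx(1.0)

    def test_unpaired_label_rejected(self):
        a = _set(UNIT_POINTS[:3])
        b = FiducialSet.from_arrays(["x", "y", "z"], UNIT_POINTS[:3], frame="A")
        with pytest.raises(ValueError, match="unpaired"):
            compute_tre(a, b, identity("A"))

    def test_tre_exceeds_fre_and_vanishes_with_noise(self, rng):
        # calibration replica: 7 fit tips, 70 held-out targets, 100 replicates
        tips = rng.uniform(-40, 40, (7, 3))
        targets = rng.uniform(-40, 40, (70, 3))
        truth = random_rigid(rng, "A", "B")
        fre_means, tre_means = [], []
        for sigma in (0.3,):
            for _ in range(100):
                noisy_tips = apply_to_array(truth, tips) + rng.normal(0, sigma, tips.shape)
                res = register_points(
                    _set(tips, frame="A"), _set(noisy_tips, frame="B")
                )
                rep = compute_tre(
                    _set(targets, frame="A", labels=[f"t{i}" for i in range(70)]),
                    _set(
                        apply_to_array(truth, targets),
                        frame="B",
                        labels=[f"t{i}" for i in range(70)],
                    ),
                    res.transform,
                )
                fre_means.append(res.fre_mm)
                tre_means.append(rep.mean_mm)
        assert np.mean(tre_means) > 0
        # zero noise: everything collapses to machine precision
        res0 = register_points(
            _set(tips, frame="A"), _set(apply_to_array(truth, tips), frame="B")
        )
        rep0 = compute_tre(
            _set(targets, frame="A", labels=[f"t{i}" for i in range(70)]),
            _set(
                apply_to_array(truth, targets),
                frame="B",
                labels=[f"t{i}" for i in range(70)],
            ),
            res0.transform,
        )
        assert rep0.mean_mm < 1e-9


class TestCadRefinement:
    def test_already_aligned(self):
        cad = _set(UNIT_POINTS * 20, frame="tank")
        refined, reg = refine_fiducials_via_cad(cad, cad)
        assert np.allclose(refined.coordinates, cad.coordinates, atol=1e-10)
        assert reg.fre_mm < 1e-10

    def test_noiseless_known_motion(self, rng):
        cad = _set(rng.uniform(-50, 50, (7, 3)), frame="CAD")
        t = random_rigid(rng, "CAD", "tank")
        measured = _set(apply_to_array(t, cad.coordinates), frame="tank")
        refined, _ = refine_fiducials_via_cad(measured, cad)
        assert np.allclose(refined.coordinates, measured.coordinates, atol=1e-10)
        assert refined.frame == "tank"

    def test_refinement_reduces_tip_error(self, rng):
        cad = _set(np.random.default_rng(5).uniform(-50, 50, (7, 3)), frame="CAD")
        t = random_rigid(rng, "CAD", "tank")
        true_tank = apply_to_array(t, cad.coordinates)
        raw_sq, ref_sq = [], []
        for _ in range(1000):
            noisy = _set(true_tank + rng.normal(0, 0.3, (7, 3)), frame="tank")
            refined, _ = refine_fiducials_via_cad(noisy, cad)
            raw_sq.append(np.mean(np.sum((noisy.coordinates - true_tank) ** 2, axis=1)))
            ref_sq.append(np.mean(np.sum((refined.coordinates - true_tank) ** 2, axis=1)))
        assert np.sqrt(np.mean(ref_sq)) < np.sqrt(np.mean(raw_sq))
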