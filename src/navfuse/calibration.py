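"""Device calibrations: stylus pivot, 3D-US probe, TRUS probe, MR, table shift.

Each calibration reduces to paired-point rigid registration
(:mod:`navfuse.pointreg`) on observations re-expressed in the right frame
via tracker poses:

* ``calibrate_pivot`` -- stylus tip offset from poses rotating about a fixed
  physical point (algebraic least squares).
* ``calibrate_us_probe`` -- image-to-tool transform of a tracked 3D-US probe
  from multi-cone phantom images paired with stylus-measured tank tips.
* ``calibrate_trus_probe`` -- image-to-tool transform of a 2D TRUS probe from
  in-plane pointer sweeps (coplanar fiducials, handled explicitly).
* ``calibrate_mr`` -- MR-image-to-reference-tool transform from an 18-cone
  phantom measured with a stylus (5 repeats per tip) and localized in MR.
* ``track_table_shift`` -- the rigid motion of the table reference tool
  between two pose epochs, used to carry a gantry-referenced calibration
  across a table translation.

Pose averaging over an epoch uses the chordal mean for rotations (mean
matrix projected back onto SO(3)), adequate for the sub-degree jitter of an
optical tracker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pointreg import (
    DegenerateFiducialsError,
    FiducialSet,
    RegistrationResult,
    average_repeats,
    register_points,
)
from .transforms import (
    FrameMismatchError,
    RigidTransform,
    compose,
    from_rotation_translation,
    invert,
    retag,
)

__all__ = [
    "PoseReading",
    "PoseStream",
    "ProbeCalibration",
    "MrCalibration",
    "PivotResult",
    "UsCalibrationObservation",
    "TrusSweep",
    "average_pose",
    "calibrate_pivot",
    "calibrate_us_probe",
    "calibrate_trus_probe",
    "calibrate_mr",
    "track_table_shift",
]


@dataclass(frozen=True)
class PoseReading:
    time_s: float
    tool_id: str
    pose: RigidTransform  # tool frame -> tracker frame
    valid: bool = True


@dataclass
class PoseStream:
    """Timestamped tracker readings, possibly interleaving several tools."""

    readings: list[PoseReading]

    def __post_init__(self):
        times = [r.time_s for r in self.readings]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("pose stream times must be non-decreasing")

    def __len__(self):
        return len(self.readings)

    @property
    def tool_ids(self) -> list[str]:
        seen = []
        for r in self.readings:
            if r.tool_id not in seen:
                seen.append(r.tool_id)
        return seen

    def select(self, tool_id: str, valid_only: bool = True) -> list[RigidTransform]:
        return [
            r.pose
            for r in self.readings
            if r.tool_id == tool_id and (r.valid or not valid_only)
        ]


@dataclass
class ProbeCalibration:
    """Spatial calibration of an imaging probe: image mm -> tracking-tool frame."""

    image_to_tool: RigidTransform
    fre_mm: float
    n_images_used: int
    registration: RegistrationResult | None = None


@dataclass
class MrCalibration:
    """MR image mm -> optical reference tool frame.

    ``reference`` records which physical tool anchors the calibration:
    ``"table"`` (reference rides with the table; enables the reduced
    table-shift chain) or ``"gantry"`` (world-fixed reference on the MR
    housing; the full chain with an explicit table link is required).
    """

    mr_to_reference: RigidTransform
    fre_mm: float
    reference: str = "table"
    registration: RegistrationResult | None = None

    @property
    def reference_to_mr(self) -> RigidTransform:
        return invert(self.mr_to_reference)


@dataclass
class PivotResult:
    tip_offset_mm: np.ndarray  # stylus tip in the tool frame
    pivot_point_mm: np.ndarray  # fixed divot point in the tracker frame
    rms_mm: float
    n_poses: int


def average_pose(poses: Sequence[RigidTransform]) -> RigidTransform:
    """Epoch-average pose: mean translation, chordal-mean rotation.

    The mean of the rotation matrices is projected back onto SO(3) via SVD
    (with determinant correction), which minimizes the chordal distance to
    the samples -- an excellent approximation for tightly clustered
    orientations such as static-tool jitter.
    """
    if not poses:
        raise ValueError("cannot average an empty pose list")
    frames = {(p.source, p.target) for p in poses}
    if len(frames) != 1:
        raise FrameMismatchError(f"poses mix frames: {sorted(frames)}")
    t = np.mean([p.translation for p in poses], axis=0)
    m = np.mean([p.rotation for p in poses], axis=0)
    u, _, vt = np.linalg.svd(m)
    r = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
    src, tgt = next(iter(frames))
    return from_rotation_translation(r, t, source=src, target=tgt)


def _orientation_span_deg(rotations: list[np.ndarray]) -> float:
    r0 = rotations[0]
    best = 0.0
    for r in rotations[1:]:
        c = (np.trace(r0.T @ r) - 1.0) / 2.0
        best = max(best, float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))))
    return best


def calibrate_pivot(
    poses: PoseStream | Sequence[RigidTransform],
    tool_id: str | None = None,
    min_poses: int = 10,
    min_span_deg: float = 30.0,
) -> PivotResult:
    """Algebraic least-squares pivot calibration of a stylus.

    With the stylus tip resting in a fixed divot while the tool is rocked
    through a range of orientations, every pose satisfies
    ``R_i p_tip + t_i = p_pivot``.  Stacking gives the linear system
    ``[R_i | -I] (p_tip, p_pivot) = -t_i`` solved in one least-squares shot.

    Requires at least ``min_poses`` valid poses spanning at least
    ``min_span_deg`` of orientation; a pure-translation stream leaves the
    tip direction unobservable and is rejected.
    """
    if isinstance(poses, PoseStream):
        ids = poses.tool_ids
        if tool_id is None:
            if len(ids) != 1:
                raise ValueError(f"stream has tools {ids}; specify tool_id")
            tool_id = ids[0]
        plist = poses.select(tool_id)
    else:
        plist = list(poses)
    n = len(plist)
    if n < min_poses:
        raise DegenerateFiducialsError(f"need >= {min_poses} valid poses, got {n}")
    rot = [p.rotation for p in plist]
    span = _orientation_span_deg(rot)
    if span < min_span_deg:
        raise DegenerateFiducialsError(
            f"orientation span {span:.1f} deg < {min_span_deg} deg; pivot is unobservable"
        )
    a = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, p in enumerate(plist):
        a[3 * i : 3 * i + 3, :3] = p.rotation
        a[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -p.translation
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    tip, pivot = x[:3], x[3:]
    res = a @ x - b
    # per-coordinate RMS: directly comparable to the per-axis tracker sigma
    rms = float(np.sqrt(np.mean(res**2)))
    return PivotResult(tip_offset_mm=tip, pivot_point_mm=pivot, rms_mm=rms, n_poses=n)


@dataclass
class UsCalibrationObservation:
    """One multi-cone image paired with the stylus-measured tank tips.

    ``image_tips`` live in the US image frame, ``tank_tips`` in the tank
    reference tool frame; the two poses place probe tool and tank tool in
    the common tracker frame at acquisition time.
    """

    image_tips: FiducialSet
    tank_tips: FiducialSet
    pose_probe: RigidTransform  # probe tool -> tracker
    pose_tank: RigidTransform  # tank tool -> tracker


def calibrate_us_probe(
    observations: Sequence[UsCalibrationObservation],
) -> ProbeCalibration:
    """Spatial calibration of a tracked 3D-US probe.

    For each observation the tank tips are carried into the probe-tool frame
    via ``invert(pose_probe) . pose_tank``; image/tool tip pairs are pooled
    across observations (the lower-variance estimator compared to averaging
    per-observation transforms) and a single rigid registration image->tool
    is fit, with the FRE computed over the pooled set.
    """
    if not observations:
        raise ValueError("need at least one observation")
    image_frame = observations[0].image_tips.frame
    tool_frame = observations[0].pose_probe.source
    pooled_img, pooled_tool = [], []
    for i, obs in enumerate(observations):
        if obs.pose_tank.source != obs.tank_tips.frame:
            raise FrameMismatchError(
                f"observation {i}: tank pose maps '{obs.pose_tank.source}' but tank tips "
                f"are in '{obs.tank_tips.frame}'"
            )
        if obs.pose_probe.target != obs.pose_tank.target:
            raise FrameMismatchError(
                f"observation {i}: probe and tank poses live in different tracker frames"
            )
        if obs.image_tips.frame != image_frame or obs.pose_probe.source != tool_frame:
            raise FrameMismatchError(f"observation {i}: inconsistent image/tool frames")
        tank_to_tool = compose(invert(obs.pose_probe), obs.pose_tank)
        tips_tool = average_repeats(obs.tank_tips)
        mapped = FiducialSet.from_arrays(
            tips_tool.labels,
            np.array([tank_to_tool.matrix[:3, :3] @ p + tank_to_tool.matrix[:3, 3]
                      for p in tips_tool.coordinates]),
            frame=tool_frame,
        )
        pooled_img.append(average_repeats(obs.image_tips).relabelled(f"{i:02d}/"))
        pooled_tool.append(mapped.relabelled(f"{i:02d}/"))
    moving = FiducialSet(
        points=[p for s in pooled_img for p in s.points], frame=image_frame
    )
    fixed = FiducialSet(
        points=[p for s in pooled_tool for p in s.points], frame=tool_frame
    )
    reg = register_points(moving, fixed)
    return ProbeCalibration(
        image_to_tool=reg.transform,
        fre_mm=reg.fre_mm,
        n_images_used=len(observations),
        registration=reg,
    )


@dataclass
class TrusSweep:
    """Pointer sweep through the 2D TRUS image plane.

    ``pixel_points`` are (N, 2) pixel indices of the pointer tip in the 2D
    image (0-based, at pixel centers); ``pixel_spacing_mm`` converts them to
    image millimetres.  ``pointer_tips`` are the matching calibrated-pointer
    tip positions in the tracker frame; ``pose_probe`` is the (fixed) TRUS
    probe tool pose during the sweep.
    """

    pixel_points: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    pointer_tips: FiducialSet  # tracker frame
    pose_probe: RigidTransform  # probe tool -> tracker
    image_frame: str = "TRUS"


def calibrate_trus_probe(sweeps: Sequence[TrusSweep]) -> ProbeCalibration:
    """Spatial calibration of a 2D TRUS probe from in-plane pointer points.

    Pixel points are lifted to 3-D in the image plane (z = 0, millimetres
    via the pixel spacing); pointer tips are mapped into the probe-tool
    frame; a coplanar-safe rigid registration yields image->tool.  Collinear
    in-plane points are rejected.
    """
    if not sweeps:
        raise ValueError("need at least one sweep")
    image_frame = sweeps[0].image_frame
    tool_frame = sweeps[0].pose_probe.source
    pooled_img, pooled_tool = [], []
    for i, sw in enumerate(sweeps):
        px = np.asarray(sw.pixel_points, dtype=float).reshape(-1, 2)
        if len(px) != len(sw.pointer_tips):
            raise ValueError(f"sweep {i}: pixel and pointer point counts differ")
        sx, sy = sw.pixel_spacing_mm
        lifted = np.column_stack([px[:, 0] * sx, px[:, 1] * sy, np.zeros(len(px))])
        to_tool = invert(sw.pose_probe)
        tips = sw.pointer_tips.coordinates @ to_tool.matrix[:3, :3].T + to_tool.matrix[:3, 3]
        labels = [f"{i:02d}/{lab}" for lab in sw.pointer_tips.labels]
        pooled_img.append(FiducialSet.from_arrays(labels, lifted, frame=image_frame))
        pooled_tool.append(FiducialSet.from_arrays(labels, tips, frame=tool_frame))
    moving = FiducialSet(points=[p for s in pooled_img for p in s.points], frame=image_frame)
    fixed = FiducialSet(points=[p for s in pooled_tool for p in s.points], frame=tool_frame)
    reg = register_points(moving, fixed)
    return ProbeCalibration(
        image_to_tool=reg.transform,
        fre_mm=reg.fre_mm,
        n_images_used=len(sweeps),
        registration=reg,
    )


def calibrate_mr(
    tips_in_reference_frame: FiducialSet,
    tips_in_mr_image: FiducialSet,
    reference: str = "table",
    min_tips: int = 3,
) -> MrCalibration:
    """MR calibration from the 18-cone phantom.

    Stylus repeats (5 per tip in the reference protocol) are averaged with
    outlier rejection first; the registration maps MR image millimetres into
    the optical reference tool frame.
    """
    averaged = average_repeats(tips_in_reference_frame)
    if len(averaged) < min_tips:
        raise DegenerateFiducialsError(
            f"need >= {min_tips} paired tips, got {len(averaged)}"
        )
    reg = register_points(average_repeats(tips_in_mr_image), averaged)
    return MrCalibration(
        mr_to_reference=reg.transform,
        fre_mm=reg.fre_mm,
        reference=reference,
        registration=reg,
    )


def track_table_shift(
    before: PoseStream,
    after: PoseStream,
    table_tool: str,
    moved_frame: str | None = None,
) -> RigidTransform:
    """Rigid motion of the table reference tool between two pose epochs.

    Each epoch is averaged (:func:`average_pose`) and the shift is
    ``invert(mean_before) . mean_after``: it maps coordinates expressed in
    the post-move tool frame (relabelled ``moved_frame``, default
    ``"<tool>_moved"``) into the pre-move tool frame, exactly the link the
    table-shift fusion chain consumes.
    """
    pb = before.select(table_tool)
    pa = after.select(table_tool)
    if not pb or not pa:
        raise ValueError(
            f"tool {table_tool!r} has no valid readings in one of the epochs"
        )
    mean_b = average_pose(pb)
    mean_a = average_pose(pa)
    shift = compose(invert(mean_b), mean_a)
    if moved_frame is None:
        moved_frame = f"{shift.source}_moved"
    return retag(shift, source=moved_frame)
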