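"""Paired-point rigid registration and its error statistics.

Every calibration in a tracked-navigation system reduces to the same
primitive: given the positions of cone-tip fiducials in two coordinate
frames, find the least-squares rigid transform between them and report the
fiducial registration error (FRE).  Held-out points not used for the fit
give the target registration error (TRE), the clinically meaningful number.

Correspondences are given by labels (tips are identified manually in the
images); no automatic matching is performed.  The solver is the standard
SVD method (Arun/Umeyama without scale) with a determinant-sign correction
so that coplanar fiducial sets -- e.g. in-plane TRUS points -- can never
yield a reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import (
    FrameMismatchError,
    Point3D,
    RigidTransform,
    Transform,
    apply_to_array,
    from_rotation_translation,
)

__all__ = [
    "DegenerateFiducialsError",
    "FiducialSet",
    "RegistrationResult",
    "TreReport",
    "average_repeats",
    "register_points",
    "compute_tre",
    "refine_fiducials_via_cad",
]

#: relative singular-value threshold below which a point set counts as
#: collinear (rank < 2) for registration purposes
_COLLINEAR_RTOL = 1e-9


class DegenerateFiducialsError(ValueError):
    """Too few or geometrically degenerate fiducials for a rigid fit."""


@dataclass
class FiducialSet:
    """Ordered, labelled 3-D points sharing one coordinate frame.

    ``repeats`` optionally holds the raw repeated stylus/image readings per
    label (an (n, 3) array each); ``spreads`` holds the per-label 3-D RMS
    about the mean once repeats have been averaged.
    """

    points: list[Point3D]
    frame: str
    repeats: dict[str, np.ndarray] | None = None
    spreads: dict[str, float] | None = None

    def __post_init__(self):
        labels = [p.label for p in self.points]
        if any(lab is None for lab in labels):
            raise ValueError("all fiducials must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise ValueError(f"duplicate fiducial labels: {dupes}")
        for p in self.points:
            if p.frame != self.frame:
                raise FrameMismatchError(
                    f"point {p.label!r} is in frame '{p.frame}', set is in '{self.frame}'"
                )

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) array in the set's frame, in point order."""
        return np.array([p.coordinates for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_arrays(cls, labels, coords, frame: str) -> "FiducialSet":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(labels) != len(coords):
            raise ValueError("labels and coordinates differ in length")
        pts = [Point3D(c, frame=frame, label=str(lab)) for lab, c in zip(labels, coords)]
        return cls(points=pts, frame=frame)

    @classmethod
    def from_repeats(cls, readings: dict[str, np.ndarray], frame: str) -> "FiducialSet":
        """Build a raw set from per-label repeated readings.

        The provisional point per label is the plain mean; call
        :func:`average_repeats` to apply outlier rejection and get spreads.
        """
        pts = []
        reps = {}
        for lab, arr in readings.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            if len(arr) == 0:
                raise ValueError(f"label {lab!r} has zero readings")
            reps[str(lab)] = arr
            pts.append(Point3D(arr.mean(axis=0), frame=frame, label=str(lab)))
        return cls(points=pts, frame=frame, repeats=reps)

    def relabelled(self, prefix: str) -> "FiducialSet":
        pts = [
            Point3D(p.coordinates, frame=self.frame, label=f"{prefix}{p.label}")
            for p in self.points
        ]
        return FiducialSet(points=pts, frame=self.frame)


@dataclass
class RegistrationResult:
    """Rigid fit plus residual statistics.

    ``fre_mm`` is the root-mean-square of the per-point residuals by
    construction.  ``coplanar`` flags fiducial sets of rank 2 (all points in
    one plane), which are legitimate but worth surfacing because their
    out-of-plane accuracy relies entirely on the reflection guard.
    """

    transform: RigidTransform
    fre_mm: float
    per_point_residuals_mm: np.ndarray
    coplanar: bool = False


@dataclass
class TreReport:
    labels: list[str]
    distances_mm: np.ndarray
    mean_mm: float
    sd_mm: float


def average_repeats(raw: FiducialSet) -> FiducialSet:
    """Collapse repeated readings to one point per label with outlier rejection.

    Stylus measurements are repeated (10x for the US tank tips, 5x for the
    MR cones) purely to beat down tracker jitter.  Readings farther than
    3x the median absolute deviation from the per-label median are discarded
    before averaging; the per-label spread (3-D RMS about the kept mean) is
    recorded as a jitter estimate.
    """
    if raw.repeats is None:
        return FiducialSet(
            points=list(raw.points),
            frame=raw.frame,
            spreads={lab: 0.0 for lab in raw.labels},
        )
    pts, spreads, kept = [], {}, {}
    for lab in raw.labels:
        arr = raw.repeats.get(lab)
        if arr is None or len(arr) == 0:
            raise ValueError(f"label {lab!r} has zero readings")
        med = np.median(arr, axis=0)
        d = np.linalg.norm(arr - med, axis=1)
        mad = np.median(d)
        keep = d <= 3.0 * mad if mad > 0 else d <= 0.0
        if not np.any(keep):  # pragma: no cover - at least half are within the MAD
            keep = np.ones(len(arr), dtype=bool)
        sel = arr[keep]
        mean = sel.mean(axis=0)
        pts.append(Point3D(mean, frame=raw.frame, label=lab))
        spreads[lab] = float(np.sqrt(np.mean(np.sum((sel - mean) ** 2, axis=1))))
        kept[lab] = sel
    return FiducialSet(points=pts, frame=raw.frame, repeats=kept, spreads=spreads)


def _paired_coordinates(moving: FiducialSet, fixed: FiducialSet):
    if set(moving.labels) != set(fixed.labels):
        missing = sorted(set(moving.labels) ^ set(fixed.labels))
        raise ValueError(f"label sets differ; unpaired labels: {missing}")
    order = moving.labels
    fixed_by_label = {p.label: p.coordinates for p in fixed.points}
    m = moving.coordinates
    f = np.array([fixed_by_label[lab] for lab in order])
    return order, m, f


def _rank_of(centered: np.ndarray) -> int:
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0:
        return 0
    return int(np.sum(s > _COLLINEAR_RTOL * len(centered) * s[0]))


def register_points(moving: FiducialSet, fixed: FiducialSet) -> RegistrationResult:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``.

    Implements the SVD (Arun) solution of the orthogonal Procrustes problem
    with the determinant-sign correction, so the result is always a proper
    rotation even for coplanar fiducial configurations.  The fit is
    independent of point ordering given the label pairing.

    Raises
    ------
    DegenerateFiducialsError
        For fewer than 3 points or a collinear configuration.
    """
    labels, m, f = _paired_coordinates(moving, fixed)
    n = len(labels)
    if n < 3:
        raise DegenerateFiducialsError(f"need >= 3 fiducials, got {n}")
    mc, fc = m - m.mean(axis=0), f - f.mean(axis=0)
    if _rank_of(mc) < 2 or _rank_of(fc) < 2:
        raise DegenerateFiducialsError("fiducials are collinear; rigid fit is ill-posed")
    coplanar = _rank_of(mc) < 3 or _rank_of(fc) < 3
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = f.mean(axis=0) - r @ m.mean(axis=0)
    transform = from_rotation_translation(r, t, source=moving.frame, target=fixed.frame)
    residuals = np.linalg.norm(apply_to_array(transform, m) - f, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(
        transform=transform,
        fre_mm=fre,
        per_point_residuals_mm=residuals,
        coplanar=coplanar,
    )


def compute_tre(
    targets_moving: FiducialSet, targets_fixed: FiducialSet, t: Transform
) -> TreReport:
    """Target registration error at held-out, label-paired points.

    ``TRE_i = || t . m_i - f_i ||``; the targets must be disjoint from the
    fiducials that produced ``t`` for the number to mean anything.  Reported
    as mean +/- sample standard deviation over targets.
    """
    labels, m, f = _paired_coordinates(targets_moving, targets_fixed)
    d = np.linalg.norm(apply_to_array(t, m) - f, axis=1)
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return TreReport(labels=labels, distances_mm=d, mean_mm=float(np.mean(d)), sd_mm=sd)


def refine_fiducials_via_cad(
    measured_tank: FiducialSet, cad: FiducialSet
) -> tuple[FiducialSet, RegistrationResult]:
    """Replace noisy stylus tip readings by CAD coordinates mapped into the tank.

    The cone tips are known exactly in the phantom's CAD model.  Registering
    CAD -> tank on the noisy measurements and mapping the CAD tips through
    the fit yields tip coordinates whose errors are limited to the rigid
    fit's uncertainty instead of the full per-point stylus jitter.

    Returns the refined set (in the tank frame) and the CAD-fit registration
    (whose FRE quantifies how well the stylus readings match the CAD shape).
    """
    reg = register_points(cad, measured_tank)
    refined = apply_to_array(reg.transform, cad.coordinates)
    out = FiducialSet.from_arrays(cad.labels, refined, frame=measured_tank.frame)
    return out, reg
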