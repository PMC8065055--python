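"""Homogeneous 3-D transform algebra between named coordinate frames.

Every spatial relationship in a tracked-navigation system -- probe
calibrations, tracker poses, image-to-image fusions -- is a 4x4 homogeneous
matrix mapping one named coordinate frame into another.  This module provides
the two transform kinds (rigid and general affine), labelled 3-D points, and
the three primitive operations (compose, invert, apply) with strict frame
bookkeeping: a chain whose frames do not match head-to-tail is rejected
rather than silently multiplied.

Conventions
-----------
* Points are column vectors; transforms act by left multiplication, so a
  chain ``T_B_to_C @ T_A_to_B`` maps A-frame coordinates into C.
* All coordinates are millimetres; all frames are right-handed; anatomical
  volumes use LPS internally (RAS-coded files are converted at I/O).
* Rotations are stored as matrices.  Quaternions (scalar-last, as written in
  pose CSV files) are accepted at construction and must be unit to 1e-6.
* A matrix qualifies as rigid when ``R^T R = I`` and ``det R = +1`` within
  1e-9.  Drift below 1e-6 is repaired by polar re-orthonormalization;
  anything larger is an error, never silently fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "FrameMismatchError",
    "DegenerateTransformError",
    "Point3D",
    "RigidTransform",
    "AffineTransform",
    "Transform",
    "compose",
    "invert",
    "apply",
    "apply_to_array",
    "retag",
    "identity",
    "translation",
    "axis_rotation",
    "from_rotation_translation",
    "from_quaternion",
    "random_rigid",
]

RIGID_TOL = 1e-9
REORTHO_TOL = 1e-6
QUAT_NORM_TOL = 1e-6


class FrameMismatchError(ValueError):
    """Raised when transforms or points are chained across mismatched frames."""


class DegenerateTransformError(ValueError):
    """Raised for matrices that are not valid members of their transform class."""


def _as_matrix(matrix) -> np.ndarray:
    m = np.array(matrix, dtype=float)
    if m.shape != (4, 4):
        raise DegenerateTransformError(f"expected a 4x4 matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise DegenerateTransformError("matrix contains non-finite entries")
    if np.max(np.abs(m[3] - (0.0, 0.0, 0.0, 1.0))) > RIGID_TOL:
        raise DegenerateTransformError(f"last row must be (0,0,0,1), got {m[3]}")
    m[3] = (0.0, 0.0, 0.0, 1.0)
    return m


def _check_frames(source: str, target: str) -> None:
    if not source or not target:
        raise ValueError("frame names must be non-empty strings")


@dataclass(frozen=True)
class Point3D:
    """A labelled point in millimetres, tagged with its coordinate frame."""

    coordinates: np.ndarray
    frame: str
    label: str | None = None

    def __post_init__(self):
        c = np.array(self.coordinates, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError(f"non-finite coordinates for point {self.label!r}: {c}")
        if not self.frame:
            raise ValueError("frame name must be non-empty")
        c.flags.writeable = False
        object.__setattr__(self, "coordinates", c)


@dataclass(frozen=True)
class RigidTransform:
    """A rotation + translation between two named frames.

    ``matrix`` maps homogeneous column vectors in ``source``-frame
    millimetres to ``target``-frame millimetres.
    """

    matrix: np.ndarray
    source: str
    target: str

    def __post_init__(self):
        _check_frames(self.source, self.target)
        m = _as_matrix(self.matrix)
        r = m[:3, :3]
        drift = np.max(np.abs(r.T @ r - np.eye(3)))
        if drift > RIGID_TOL:
            if drift < REORTHO_TOL:
                # polar projection onto SO(3): nearest rotation in Frobenius norm
                u, _, vt = np.linalg.svd(r)
                r = u @ vt
                m[:3, :3] = r
            else:
                raise DegenerateTransformError(
                    f"rotation block is not orthonormal (drift {drift:.3e})"
                )
        if abs(np.linalg.det(m[:3, :3]) - 1.0) > REORTHO_TOL:
            raise DegenerateTransformError(
                "rotation block has determinant != +1 (reflection or degenerate)"
            )
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def quaternion(self) -> np.ndarray:
        """Unit quaternion, scalar-last (x, y, z, w)."""
        return Rotation.from_matrix(self.rotation).as_quat()

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.matrix, np.eye(4)))

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"RigidTransform({self.source!r} -> {self.target!r})"


@dataclass(frozen=True)
class AffineTransform:
    """A general invertible affine map between two named frames."""

    matrix: np.ndarray
    source: str
    target: str

    def __post_init__(self):
        _check_frames(self.source, self.target)
        m = _as_matrix(self.matrix)
        if np.linalg.cond(m[:3, :3]) > 1e12:
            raise DegenerateTransformError("affine 3x3 block is singular or near-singular")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.matrix, np.eye(4)))

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"AffineTransform({self.source!r} -> {self.target!r})"


Transform = Union[RigidTransform, AffineTransform]


def compose(a: Transform, b: Transform) -> Transform:
    """Chain two transforms: the result maps ``b.source`` into ``a.target``.

    Frames must chain head-to-tail (``a.source == b.target``); the product of
    two rigid transforms is rigid, any other combination is affine.
    """
    if a.source != b.target:
        raise FrameMismatchError(
            f"cannot chain '{b.source}->{b.target}' into '{a.source}->{a.target}': "
            f"inner frames '{b.target}' and '{a.source}' differ"
        )
    m = a.matrix @ b.matrix
    cls = (
        RigidTransform
        if isinstance(a, RigidTransform) and isinstance(b, RigidTransform)
        else AffineTransform
    )
    return cls(m, source=b.source, target=a.target)


def invert(t: Transform) -> Transform:
    """Inverse map with source and target frames swapped."""
    if isinstance(t, RigidTransform):
        r = t.rotation.T
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = -r @ t.translation
        return RigidTransform(m, source=t.target, target=t.source)
    try:
        m = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in ctor
        raise DegenerateTransformError("affine transform is singular") from exc
    return AffineTransform(m, source=t.target, target=t.source)


def apply(t: Transform, p: Point3D) -> Point3D:
    """Map a point through a transform; the point must live in ``t.source``."""
    if p.frame != t.source:
        raise FrameMismatchError(
            f"point is in frame '{p.frame}' but transform maps '{t.source}' -> '{t.target}'"
        )
    c = t.matrix[:3, :3] @ p.coordinates + t.matrix[:3, 3]
    return Point3D(c, frame=t.target, label=p.label)


def apply_to_array(t: Transform, coords: np.ndarray) -> np.ndarray:
    """Map an (N, 3) array of source-frame coordinates; no frame check."""
    coords = np.asarray(coords, dtype=float)
    return coords @ t.matrix[:3, :3].T + t.matrix[:3, 3]


def retag(t: Transform, source: str | None = None, target: str | None = None) -> Transform:
    """Relabel the frames of a transform without touching its matrix.

    Needed when a physically identical frame acquires a new name, e.g. the
    table reference tool before ("ORF_TABLE") and after ("ORF_moved") a
    tracked table shift.
    """
    return dataclasses.replace(
        t,
        source=t.source if source is None else source,
        target=t.target if target is None else target,
    )


# ---------------------------------------------------------------------------
# constructors


def identity(frame: str, target: str | None = None) -> RigidTransform:
    return RigidTransform(np.eye(4), source=frame, target=frame if target is None else target)


def translation(offset, source: str, target: str) -> RigidTransform:
    m = np.eye(4)
    m[:3, 3] = np.asarray(offset, dtype=float).reshape(3)
    return RigidTransform(m, source=source, target=target)


def axis_rotation(axis: str, degrees: float, source: str, target: str) -> RigidTransform:
    """Rotation about a principal axis ('x', 'y' or 'z'), in degrees."""
    m = np.eye(4)
    m[:3, :3] = Rotation.from_euler(axis, degrees, degrees=True).as_matrix()
    return RigidTransform(m, source=source, target=target)


def from_rotation_translation(r, t, source: str, target: str) -> RigidTransform:
    m = np.eye(4)
    m[:3, :3] = np.asarray(r, dtype=float)
    m[:3, 3] = np.asarray(t, dtype=float).reshape(3)
    return RigidTransform(m, source=source, target=target)


def from_quaternion(quat_xyzw, t, source: str, target: str) -> RigidTransform:
    """Build a rigid transform from a scalar-last unit quaternion.

    Quaternions off unit norm by more than 1e-6 are rejected (a tracker
    writing such values is broken); smaller drift is normalized.
    """
    q = np.asarray(quat_xyzw, dtype=float).reshape(4)
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > QUAT_NORM_TOL:
        raise DegenerateTransformError(f"quaternion norm {norm:.8f} deviates from 1 by > 1e-6")
    return from_rotation_translation(
        Rotation.from_quat(q / norm).as_matrix(), t, source=source, target=target
    )


def random_rigid(
    rng: np.random.Generator,
    source: str,
    target: str,
    max_translation_mm: float = 100.0,
) -> RigidTransform:
    """A uniformly random rotation with a uniform box translation (test helper)."""
    r = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return from_rotation_translation(r, t, source=source, target=target)
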