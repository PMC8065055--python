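"""Fusion transform chains: assembling calibrations and live poses into
MR <-> US <-> TRUS mappings, including table-shift compensation.

The navigation idea: instead of registering MR to TRUS across modalities,
chain tracked-device calibrations.  With ``C = T_US^trans`` (probe spatial
calibration), reference-tool pose ``T_ref`` and probe pose ``T_probe``
(both tool->tracker), and the MR calibration ``T_ORF^MR``:

    T_US^MR = T_ORF^MR . [invert(T_ref) . T_probe] . T_US^trans

When the table moves between the MR scan and the US acquisition, the
tracked shift ``S = invert(T_table_before) . T_table_after`` (moved-tool
frame -> pre-move tool frame) is inserted; with a gantry-mounted reference
an additional static table link ``T_ORF_TABLE^ORF_MR`` is required, with a
table-mounted reference the chain reduces by dropping that link.

Chains are folded left-to-right with strict frame checking.  Links whose
matrix is *exactly* the identity are treated as pure frame bridges and
skipped, so a chain with a no-op table shift reproduces the shift-free
chain bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk

from .calibration import MrCalibration, ProbeCalibration
from .transforms import (
    FrameMismatchError,
    Point3D,
    RigidTransform,
    Transform,
    apply,
    compose,
    invert,
    retag,
)
from .volume import LabelMask, VolumeImage

__all__ = [
    "ChainSpec",
    "fold_chain",
    "mr_from_us",
    "mr_from_us_with_tableshift",
    "map_points_trus_to_mr",
    "resample_volume",
    "fuse_volumes",
]


def fold_chain(factors: Sequence[Transform]) -> Transform:
    """Compose a left-to-right factor list with frame checking.

    The leftmost factor is the outermost map (matrix product order), i.e.
    ``fold_chain([a, b, c])`` maps ``c.source`` into ``a.target``.  Exact
    identity matrices act as frame bridges (relabel only, no multiply), so
    that algebraically reducible chains reduce exactly.
    """
    if not factors:
        raise ValueError("empty chain")
    result = None
    for f in factors:
        if result is None:
            result = f
            continue
        if result.source != f.target:
            raise FrameMismatchError(
                f"cannot chain '{f.source}->{f.target}' into "
                f"'{result.source}->{result.target}': inner frames differ"
            )
        if f.is_identity:
            result = retag(result, source=f.source)
        elif result.is_identity:
            result = retag(f, target=result.target)
        else:
            result = compose(result, f)
    return result


@dataclass
class ChainSpec:
    """A declared transform chain: stored links and live-pose placeholders.

    Links are either a concrete :class:`Transform` or a tuple
    ``(tool_id, inverted)`` resolved against a pose lookup at evaluation
    time.  Evaluation must yield the declared source -> target mapping.
    """

    links: list[Transform | tuple[str, bool]]
    source: str
    target: str

    def resolve(self, poses: dict[str, RigidTransform] | None = None) -> Transform:
        factors: list[Transform] = []
        for link in self.links:
            if isinstance(link, tuple):
                tool_id, inverted = link
                if poses is None or tool_id not in poses:
                    raise KeyError(f"no live pose supplied for tool {tool_id!r}")
                pose = poses[tool_id]
                factors.append(invert(pose) if inverted else pose)
            else:
                factors.append(link)
        out = fold_chain(factors)
        if out.source != self.source or out.target != self.target:
            raise FrameMismatchError(
                f"chain evaluates to '{out.source}->{out.target}', "
                f"declared '{self.source}->{self.target}'"
            )
        return out


def mr_from_us(
    mr_cal: MrCalibration,
    pose_probe: RigidTransform,
    pose_ref: RigidTransform,
    probe_cal: ProbeCalibration,
) -> RigidTransform:
    """US-image-to-MR-image map with no table motion.

    Chains the MR calibration, the live probe-tool-relative-to-reference
    link ``invert(pose_ref) . pose_probe`` and the probe spatial
    calibration.  Both poses must live in the same tracker frame and
    ``pose_ref`` must be the tool the MR calibration references.
    """
    if pose_probe.target != pose_ref.target:
        raise FrameMismatchError(
            f"probe pose tracker frame '{pose_probe.target}' != reference pose "
            f"tracker frame '{pose_ref.target}'"
        )
    return fold_chain(
        [mr_cal.reference_to_mr, invert(pose_ref), pose_probe, probe_cal.image_to_tool]
    )


def mr_from_us_with_tableshift(
    mr_cal: MrCalibration,
    shift: RigidTransform,
    pose_probe_after: RigidTransform,
    pose_ref_after: RigidTransform,
    probe_cal: ProbeCalibration,
    table_link: RigidTransform | None = None,
) -> RigidTransform:
    """US-image-to-MR-image map across a tracked table shift.

    ``shift`` is the tracked table motion (moved-tool frame -> pre-move tool
    frame, from :func:`navfuse.calibration.track_table_shift`);
    ``pose_ref_after`` is the post-move reading of the table reference tool
    (its frame is the shift's source).  With a gantry-referenced MR
    calibration the static ``table_link`` (table tool -> gantry tool at the
    MR epoch) is required; with a table-referenced calibration it is dropped
    and the chain reduces to the shorter form.  A shift that is exactly the
    identity reproduces the no-shift chain bit for bit.
    """
    if mr_cal.reference == "gantry":
        if table_link is None:
            raise ValueError(
                "gantry-referenced MR calibration requires the static table link"
            )
        head = [mr_cal.reference_to_mr, table_link, shift]
    else:
        if table_link is not None:
            raise ValueError(
                "table-referenced MR calibration must not be given a table link"
            )
        head = [mr_cal.reference_to_mr, shift]
    return fold_chain(
        head + [invert(pose_ref_after), pose_probe_after, probe_cal.image_to_tool]
    )


def map_points_trus_to_mr(
    points: Sequence[Point3D],
    t_us_mr: RigidTransform,
    t_trus_us: Transform,
) -> list[Point3D]:
    """Carry TRUS-image points into MR-image coordinates.

    Composes the intra-modal TRUS->US registration with the tracked US->MR
    chain; labels and ordering are preserved.
    """
    full = compose(t_us_mr, t_trus_us)
    return [apply(full, p) for p in points]


_INTERPOLATORS = {
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def _sitk_affine(t: Transform) -> sitk.AffineTransform:
    out = sitk.AffineTransform(3)
    out.SetMatrix(tuple(t.matrix[:3, :3].flatten()))
    out.SetTranslation(tuple(t.matrix[:3, 3]))
    return out


def resample_volume(
    moving: VolumeImage | LabelMask,
    fixed_grid: VolumeImage | LabelMask,
    t: Transform,
    interpolator: str = "linear",
) -> VolumeImage | LabelMask:
    """Resample ``moving`` onto ``fixed_grid`` through ``t`` (moving->fixed).

    SimpleITK's resampler wants the fixed->moving point map, i.e. the
    inverse of ``t``.  Outside the moving support the output is zero-filled.
    Label masks should use nearest-neighbour interpolation.
    """
    if t.source != moving.frame or t.target != fixed_grid.frame:
        raise FrameMismatchError(
            f"transform maps '{t.source}->{t.target}' but volumes are "
            f"'{moving.frame}' (moving) and '{fixed_grid.frame}' (fixed)"
        )
    tr = _sitk_affine(invert(t))
    out = sitk.Resample(
        moving.to_sitk(),
        fixed_grid.to_sitk(),
        tr,
        _INTERPOLATORS[interpolator],
        0.0,
    )
    if isinstance(moving, LabelMask):
        res = LabelMask.from_sitk(out, frame=fixed_grid.frame)
        res.voxels = res.voxels.astype(bool)
        return res
    return VolumeImage.from_sitk(out, frame=fixed_grid.frame)


def fuse_volumes(
    moving: VolumeImage,
    fixed_grid: VolumeImage,
    t: Transform,
    mode: Literal["overlay", "checkerboard"] = "overlay",
    alpha: float = 0.5,
    tile_voxels: int = 8,
) -> VolumeImage:
    """Resample ``moving`` into the fixed grid and combine for display.

    ``overlay`` alpha-blends (``alpha`` weighting the moving image);
    ``checkerboard`` interleaves cubic tiles of ``tile_voxels`` per side --
    the standard qualitative checks that two registered volumes agree.
    """
    res = resample_volume(moving, fixed_grid, t, interpolator="linear")
    if mode == "overlay":
        fused = alpha * res.voxels + (1.0 - alpha) * fixed_grid.voxels
    elif mode == "checkerboard":
        nx, ny, nz = fixed_grid.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        odd = ((ii // tile_voxels) + (jj // tile_voxels) + (kk // tile_voxels)) % 2 == 1
        fused = np.where(odd, res.voxels, fixed_grid.voxels)
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    out = fixed_grid.with_voxels(fused)
    return out
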