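"""Intra-modal image registration: masked affine alignment by mutual information.

The one image-based registration in the navigation system: the pre-procedure
abdominal 3D-US volume is aligned to the intra-procedure 3D-TRUS volume with
a 12-parameter affine transform maximizing a Mattes-style mutual-information
metric on manually masked (prostate-region) volumes.  Being intra-modal, the
intensity statistics of the two volumes actually correspond -- the reason the
tracker-based workflow replaces the hard MR/TRUS inter-modal registration
with this easy US/US one.

``register_affine`` drives SimpleITK's multi-resolution registration
framework (the same ITK machinery behind 3D Slicer's registration tool) with
a fixed sampling seed for determinism.  ``mutual_information`` is an
independent joint-histogram implementation used for reporting and as a guard:
the returned alignment is never allowed to score a lower MI than the
initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .chain import resample_volume
from .transforms import AffineTransform, Transform, identity, invert
from .volume import LabelMask, VolumeImage

__all__ = [
    "OverlapError",
    "BoxRoi",
    "EllipsoidRoi",
    "RegistrationReport",
    "mask_volume",
    "intensity_entropy",
    "mutual_information",
    "register_affine",
]


class OverlapError(ValueError):
    """The two volumes share no in-mask support under the given transform."""


@dataclass
class BoxRoi:
    """Axis-aligned box in physical millimetres (full edge lengths)."""

    center_mm: np.ndarray
    size_mm: np.ndarray

    def contains(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm, dtype=float)
        h = np.asarray(self.size_mm, dtype=float) / 2.0
        return np.all(np.abs(coords - c) <= h, axis=-1)


@dataclass
class EllipsoidRoi:
    """Axis-aligned ellipsoid in physical millimetres."""

    center_mm: np.ndarray
    semi_axes_mm: np.ndarray

    def contains(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm, dtype=float)
        a = np.asarray(self.semi_axes_mm, dtype=float)
        rel = (coords - c) / a
        return np.sum(rel**2, axis=-1) <= 1.0


def mask_volume(v: VolumeImage, roi: BoxRoi | EllipsoidRoi) -> tuple[VolumeImage, LabelMask]:
    """Zero everything outside the region of interest.

    Emulates the manual masking step that reduces the volumes to the
    prostate region before intra-modal registration.  Raises
    :class:`OverlapError` if the ROI misses the volume entirely.
    """
    inside = roi.contains(v.physical_grid())
    if not inside.any():
        raise OverlapError("ROI does not intersect the volume extent")
    masked = v.with_voxels(np.where(inside, v.voxels, 0.0))
    mask = LabelMask(
        voxels=inside,
        spacing=v.spacing,
        origin=v.origin,
        direction=v.direction,
        frame=v.frame,
    )
    return masked, mask


def _bin_indices(values: np.ndarray, bins: int, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp)
    idx = np.floor((values - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _robust_range(values: np.ndarray, percentiles=(0.5, 99.5)) -> tuple[float, float]:
    lo, hi = np.percentile(values, percentiles)
    return float(lo), float(hi)


def intensity_entropy(v: VolumeImage, bins: int = 32, mask: LabelMask | None = None) -> float:
    """Shannon entropy (nats) of the binned intensity histogram."""
    vals = v.voxels[mask.voxels] if mask is not None else v.voxels.ravel()
    lo, hi = _robust_range(vals)
    idx = _bin_indices(vals, bins, lo, hi)
    p = np.bincount(idx, minlength=bins).astype(float)
    return _entropy(p / p.sum())


def mutual_information(
    fixed: VolumeImage,
    moving: VolumeImage,
    t: Transform | None = None,
    bins: int = 32,
    fixed_mask: LabelMask | None = None,
    moving_mask: LabelMask | None = None,
) -> float:
    """Mutual information (nats) of the joint intensity histogram.

    The moving volume is resampled onto the fixed grid through ``t``
    (moving -> fixed; identity on matching grids skips resampling so that
    ``MI(X, X) == H(X)`` holds exactly); the histogram is accumulated over
    voxels inside both masks and inside the moving volume's support, with
    hard binning over the robust (0.5-99.5 percentile) intensity range of
    each image.  Always >= 0; raises :class:`OverlapError` on empty overlap.
    """
    if bins < 8:
        raise ValueError("use at least 8 histogram bins")
    if t is None:
        t = identity(moving.frame, target=fixed.frame)
    same = fixed.same_grid(moving) and t.is_identity
    if same:
        mov = moving.voxels
        support = np.ones(fixed.shape, dtype=bool)
        mmask = moving_mask.voxels if moving_mask is not None else None
    else:
        mov = resample_volume(moving, fixed, t, interpolator="linear").voxels
        ones = moving.with_voxels(np.ones(moving.shape))
        support = resample_volume(ones, fixed, t, interpolator="linear").voxels > 0.999
        mmask = None
        if moving_mask is not None:
            mmask = (
                resample_volume(moving_mask, fixed, t, interpolator="nearest").voxels
            )
    sel = support
    if fixed_mask is not None:
        sel = sel & fixed_mask.voxels
    if mmask is not None:
        sel = sel & mmask
    if not sel.any():
        raise OverlapError("no overlapping in-mask voxels under the given transform")
    fv, mv = fixed.voxels[sel], mov[sel]
    flo, fhi = _robust_range(fv)
    mlo, mhi = _robust_range(mv)
    fi = _bin_indices(fv, bins, flo, fhi)
    mi_ = _bin_indices(mv, bins, mlo, mhi)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (fi, mi_), 1.0)
    joint /= joint.sum()
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    return max(hx + hy - hxy, 0.0)


@dataclass
class RegistrationReport:
    final_metric: float  # optimizer's own metric (negated MI)
    mi_init: float
    mi_final: float
    iterations: int
    stop_condition: str
    seed: int
    fell_back_to_init: bool


def _sitk_affine_from(t: Transform, center: np.ndarray) -> sitk.AffineTransform:
    out = sitk.AffineTransform(3)
    out.SetCenter(tuple(center))
    # re-center: matrix stays, offset adjusts so the global map is preserved
    a = t.matrix[:3, :3]
    b = t.matrix[:3, 3]
    out.SetMatrix(tuple(a.flatten()))
    out.SetTranslation(tuple(a @ center + b - center))
    return out


def _homogeneous_from_sitk(tr: sitk.Transform) -> np.ndarray:
    tr = sitk.AffineTransform(tr)
    a = np.array(tr.GetMatrix()).reshape(3, 3)
    c = np.array(tr.GetCenter())
    t = np.array(tr.GetTranslation())
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = t + c - a @ c
    return m


def register_affine(
    fixed: VolumeImage,
    moving: VolumeImage,
    fixed_mask: LabelMask | None = None,
    moving_mask: LabelMask | None = None,
    init: Transform | None = None,
    seed: int = 1,
    bins: int = 32,
    sampling_fraction: float = 0.25,
    shrink_factors=(4, 2, 1),
    smoothing_sigmas=(2.0, 1.0, 0.0),
) -> tuple[AffineTransform, RegistrationReport]:
    """Affine registration maximizing Mattes mutual information.

    Multi-resolution (downsampling x4/x2/x1 with matched Gaussian
    smoothing), gradient-descent on the 12 affine parameters centered at the
    fixed-mask centroid, seeded random metric sampling -- deterministic for
    a given seed and inputs.  The returned transform maps moving-frame
    points into the fixed frame (the inverse of ITK's resampling
    convention), tagged with the volumes' frames.

    If the optimizer ends at a pose whose (independently computed) mutual
    information is below the initialization's, the initialization is
    returned instead and flagged: the registration never worsens alignment.
    """
    f_img = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    m_img = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)

    if fixed_mask is not None:
        center = fixed_mask.centroid_mm()
    else:
        center = fixed.index_to_physical((np.array(fixed.shape) - 1) / 2.0)

    init_t = init if init is not None else identity(moving.frame, target=fixed.frame)
    # ITK optimizes the fixed -> moving map used for resampling
    initial = _sitk_affine_from(invert(init_t), center)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(sampling_fraction, seed)
    if fixed_mask is not None:
        reg.SetMetricFixedMask(fixed_mask.to_sitk())
    if moving_mask is not None:
        reg.SetMetricMovingMask(moving_mask.to_sitk())
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=300,
        gradientMagnitudeTolerance=1e-6,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)
    try:
        reg.SetNumberOfWorkUnits(1)  # deterministic metric accumulation
    except AttributeError:  # pragma: no cover - older SimpleITK
        pass

    final = reg.Execute(f_img, m_img)
    m_fixed_to_moving = _homogeneous_from_sitk(final)
    result = AffineTransform(
        np.linalg.inv(m_fixed_to_moving), source=moving.frame, target=fixed.frame
    )

    mi_init = mutual_information(
        fixed, moving, init_t, bins=bins, fixed_mask=fixed_mask, moving_mask=moving_mask
    )
    mi_final = mutual_information(
        fixed, moving, result, bins=bins, fixed_mask=fixed_mask, moving_mask=moving_mask
    )
    fell_back = mi_final < mi_init
    if fell_back:
        result = (
            init_t
            if isinstance(init_t, AffineTransform)
            else AffineTransform(init_t.matrix, source=init_t.source, target=init_t.target)
        )
        mi_final = mi_init
    report = RegistrationReport(
        final_metric=float(reg.GetMetricValue()),
        mi_init=float(mi_init),
        mi_final=float(mi_final),
        iterations=int(reg.GetOptimizerIteration()),
        stop_condition=reg.GetOptimizerStopConditionDescription(),
        seed=seed,
        fell_back_to_init=fell_back,
    )
    return result, report
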