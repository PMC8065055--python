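"""Synthetic stand-ins for the physical study objects.

Everything the tracked-fusion pipeline consumes can be simulated with known
ground truth:

* multi-cone calibration phantoms (7-cone preset for US probe calibration,
  18-cone preset for MR calibration) as labelled tip fiducial sets;
* a tissue-equivalent prostate phantom -- a 4 x 4.5 x 4 cm ellipsoidal
  gland containing three spherical lesions of 5 mm radius -- rendered with
  MR-like (piecewise constant + Gaussian noise) or US-like (multiplicative
  speckle + depth attenuation) appearance, with exact lesion masks;
* optical-tracker pose streams with configurable static jitter
  (0.25-0.35 mm 3-D RMS class);
* whole simulated experiments (:func:`simulate_experiment`) bundling every
  observation the calibration/fusion pipeline needs, plus the
  :class:`ExperimentTruth` it was generated from, for recovery testing.

Noise convention: every ``sigma`` in this module is a per-axis standard
deviation in millimetres; the corresponding 3-D RMS displacement is
``sigma * sqrt(3)``.  The tracker default of 0.3 mm 3-D RMS (middle of the
Polaris 0.25-0.35 mm static-accuracy class) is therefore ``0.3/sqrt(3)``
per axis.

All generators are deterministic under a fixed master seed: the master seed
spawns per-component child seeds, so replicates are independent but
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    PoseReading,
    PoseStream,
    UsCalibrationObservation,
)
from .pointreg import FiducialSet
from .transforms import (
    AffineTransform,
    Point3D,
    RigidTransform,
    Transform,
    apply_to_array,
    compose,
    from_rotation_translation,
    invert,
    random_rigid,
)
from .volume import LabelMask, VolumeImage

__all__ = [
    "TRACKER_SIGMA_AXIS_MM",
    "PhantomSpec",
    "PhantomVolumes",
    "NoiseModel",
    "ExperimentTruth",
    "ExperimentBundle",
    "make_multicone",
    "render_volume",
    "perturb_fiducials",
    "simulate_pose_stream",
    "make_experiment_truth",
    "simulate_experiment",
]

#: per-axis tracker jitter corresponding to 0.3 mm 3-D RMS static accuracy
TRACKER_SIGMA_AXIS_MM = 0.3 / np.sqrt(3.0)


# ---------------------------------------------------------------------------
# multi-cone calibration phantoms


def make_multicone(
    n: int = 7,
    pitch_mm: float = 20.0,
    heights_mm: tuple[float, ...] = (10.0, 18.0, 26.0, 14.0),
    frame: str = "CAD",
    seed: int | None = None,
) -> FiducialSet:
    """Labelled cone-tip fiducials of a multi-cone calibration phantom.

    Tips sit on a square grid of ``pitch_mm`` on the base plate with cone
    heights cycling through ``heights_mm``, giving a non-coplanar cloud.
    ``n=7`` is the US-calibration preset, ``n=18`` the MR preset.  With a
    seed, tips are additionally perturbed by up to 1 mm (deterministically)
    so distinct phantom instances are not congruent.
    """
    if n < 3:
        raise ValueError(f"a calibration phantom needs >= 3 cones, got {n}")
    cols = int(np.ceil(np.sqrt(n)))
    coords = []
    for i in range(n):
        r, c = divmod(i, cols)
        coords.append([c * pitch_mm, r * pitch_mm, heights_mm[i % len(heights_mm)]])
    coords = np.asarray(coords, dtype=float)
    coords -= coords.mean(axis=0)
    if seed is not None:
        rng = np.random.default_rng(seed)
        coords = coords + rng.uniform(-1.0, 1.0, size=coords.shape)
    labels = [f"cone_{i + 1:02d}" for i in range(n)]
    return FiducialSet.from_arrays(labels, coords, frame=frame)


# ---------------------------------------------------------------------------
# prostate phantom rendering


@dataclass
class PhantomSpec:
    """Geometry and appearance of the simulated prostate phantom.

    The default gland semi-axes (20, 22.5, 20) mm give the 4 x 4.5 x 4 cm
    bounding box of the physical phantom; the three default lesions of 5 mm
    radius (the smallest clinically significant tumour size) sit
    non-collinearly inside the gland.
    """

    gland_center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gland_semi_axes_mm: np.ndarray = field(
        default_factory=lambda: np.array([20.0, 22.5, 20.0])
    )
    lesion_centers_mm: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-8.0, 6.0, 2.0], [7.0, -5.0, -6.0], [2.0, 9.0, -9.0]]
        )
    )
    lesion_radius_mm: float = 5.0
    # MR appearance: piecewise-constant means + additive Gaussian noise
    mr_intensities: tuple[float, float, float] = (20.0, 110.0, 180.0)  # bg, gland, lesion
    mr_noise_sigma: float = 3.0
    # US appearance: mean echogenicity x multiplicative speckle, depth attenuation
    us_intensities: tuple[float, float, float] = (12.0, 90.0, 45.0)
    us_speckle_shape: float = 16.0  # gamma shape; speckle variance = 1/shape
    us_attenuation_per_mm: float = 0.008

    def __post_init__(self):
        self.gland_center_mm = np.asarray(self.gland_center_mm, dtype=float).reshape(3)
        self.gland_semi_axes_mm = np.asarray(
            self.gland_semi_axes_mm, dtype=float
        ).reshape(3)
        self.lesion_centers_mm = np.asarray(self.lesion_centers_mm, dtype=float).reshape(
            -1, 3
        )
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        shrunk = self.gland_semi_axes_mm - self.lesion_radius_mm
        if np.any(shrunk <= 0):
            raise ValueError("lesions cannot fit inside the gland")
        rel = (self.lesion_centers_mm - self.gland_center_mm) / shrunk
        if np.any(np.sum(rel**2, axis=1) > 1.0):
            raise ValueError("all lesions must lie fully inside the gland")

    @property
    def lesion_labels(self) -> list[str]:
        return [f"lesion_{i + 1}" for i in range(len(self.lesion_centers_mm))]


@dataclass
class PhantomVolumes:
    """A rendered phantom: image, gland mask, exact per-lesion masks and centers."""

    image: VolumeImage
    gland_mask: LabelMask
    lesion_masks: dict[str, LabelMask]
    lesion_centers: dict[str, Point3D]


def _soft_edge(signed_distance: np.ndarray, width: float) -> np.ndarray:
    """Occupancy in [0, 1] from an approximate signed distance (mm)."""
    return np.clip(0.5 - signed_distance / width, 0.0, 1.0)


def render_volume(
    spec: PhantomSpec,
    modality: str = "mr",
    spacing_mm: float = 1.0,
    margin_mm: float = 12.0,
    seed: int = 0,
    frame: str = "MR",
    world_transform: Transform | None = None,
) -> PhantomVolumes:
    """Rasterize the prostate phantom on a regular grid.

    ``world_transform`` (phantom frame -> volume frame) places the phantom
    in the rendered frame; membership is evaluated analytically at mapped
    voxel centers, so a transformed render is geometrically exact rather
    than an interpolated resampling.  Edges get partial-volume softening of
    one voxel width; lesion and gland masks are exact center-inclusion
    masks.  The grid must resolve the lesions with at least 4 voxels across
    the diameter.
    """
    if modality not in ("mr", "us"):
        raise ValueError(f"modality must be 'mr' or 'us', got {modality!r}")
    if 2.0 * spec.lesion_radius_mm / spacing_mm < 4.0:
        raise ValueError(
            f"spacing {spacing_mm} mm does not resolve {spec.lesion_radius_mm} mm "
            "lesions with >= 4 voxels across"
        )
    half = spec.gland_semi_axes_mm + margin_mm
    grid_center = spec.gland_center_mm
    if world_transform is not None:
        grid_center = apply_to_array(world_transform, grid_center[None, :])[0]
        # axis-aligned grid in the target frame: enough margin for rotation
        half = np.full(3, float(np.max(half)))
    lo = grid_center - half
    n_vox = np.ceil(2 * half / spacing_mm).astype(int) + 1

    vol = VolumeImage(
        voxels=np.zeros(tuple(n_vox)),
        spacing=np.full(3, spacing_mm),
        origin=lo,
        direction=np.eye(3),
        frame=frame,
    )
    coords = vol.physical_grid()  # phantom-frame == volume-frame by default
    if world_transform is not None:
        inv_t = invert(world_transform)
        coords = coords @ inv_t.matrix[:3, :3].T + inv_t.matrix[:3, 3]

    # gland: approximate signed distance of the ellipsoid
    rel = (coords - spec.gland_center_mm) / spec.gland_semi_axes_mm
    rho = np.sqrt(np.sum(rel**2, axis=-1))
    gland_sd = (rho - 1.0) * float(np.mean(spec.gland_semi_axes_mm))
    gland_occ = _soft_edge(gland_sd, spacing_mm)
    gland_mask_arr = rho <= 1.0

    lesion_occ = np.zeros_like(gland_occ)
    lesion_masks: dict[str, LabelMask] = {}
    lesion_centers: dict[str, Point3D] = {}
    for lab, center in zip(spec.lesion_labels, spec.lesion_centers_mm):
        sd = np.linalg.norm(coords - center, axis=-1) - spec.lesion_radius_mm
        if np.all(sd > 0):
            raise ValueError(f"{lab} lies outside the rendered grid")
        lesion_occ = np.maximum(lesion_occ, _soft_edge(sd, spacing_mm))
        lesion_masks[lab] = LabelMask(
            voxels=sd <= 0.0,
            spacing=vol.spacing,
            origin=vol.origin,
            direction=vol.direction,
            frame=frame,
        )
        c = center
        if world_transform is not None:
            c = apply_to_array(world_transform, center[None, :])[0]
        lesion_centers[lab] = Point3D(c, frame=frame, label=lab)

    rng = np.random.default_rng(seed)
    if modality == "mr":
        bg, gl, le = spec.mr_intensities
        img = bg + (gl - bg) * gland_occ + (le - gl) * lesion_occ * gland_occ
        img = img + rng.normal(0.0, spec.mr_noise_sigma, size=img.shape)
    else:
        bg, gl, le = spec.us_intensities
        mean = bg + (gl - bg) * gland_occ + (le - gl) * lesion_occ * gland_occ
        k = spec.us_speckle_shape
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=mean.shape)
        depth = coords[..., 1] - coords[..., 1].min()
        img = mean * speckle * np.exp(-spec.us_attenuation_per_mm * depth)

    vol.voxels = img
    gland = LabelMask(
        voxels=gland_mask_arr,
        spacing=vol.spacing,
        origin=vol.origin,
        direction=vol.direction,
        frame=frame,
    )
    return PhantomVolumes(
        image=vol,
        gland_mask=gland,
        lesion_masks=lesion_masks,
        lesion_centers=lesion_centers,
    )


# ---------------------------------------------------------------------------
# tracker simulation


def perturb_fiducials(
    fs: FiducialSet, sigma_axis_mm: float, rng: np.random.Generator
) -> FiducialSet:
    """Add isotropic per-axis Gaussian localization noise to every point."""
    if sigma_axis_mm < 0:
        raise ValueError("sigma must be >= 0")
    noisy = fs.coordinates + rng.normal(0.0, sigma_axis_mm, size=(len(fs), 3))
    return FiducialSet.from_arrays(fs.labels, noisy, frame=fs.frame)


def _jittered_pose(
    pose: RigidTransform,
    sigma_axis_mm: float,
    sigma_rot_deg: float,
    rng: np.random.Generator,
) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    t = pose.translation + rng.normal(0.0, sigma_axis_mm, size=3)
    r = pose.rotation
    if sigma_rot_deg > 0:
        rotvec = rng.normal(0.0, np.radians(sigma_rot_deg), size=3)
        r = Rotation.from_rotvec(rotvec).as_matrix() @ r
    return from_rotation_translation(r, t, source=pose.source, target=pose.target)


def simulate_pose_stream(
    poses: dict[str, RigidTransform],
    n_readings: int = 100,
    sigma_axis_mm: float = TRACKER_SIGMA_AXIS_MM,
    sigma_rot_deg: float = 0.05,
    seed: int = 0,
    t0_s: float = 0.0,
    dt_s: float = 0.02,
) -> PoseStream:
    """Static tracker readings of one or more tools with Gaussian jitter.

    Each reading perturbs the true pose by isotropic per-axis translational
    jitter and a small rotation-vector jitter; ``sigma = 0`` reproduces the
    truth exactly.  Readings of the tools are interleaved per time step.
    """
    if sigma_axis_mm < 0 or sigma_rot_deg < 0:
        raise ValueError("jitter sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    readings = []
    for i in range(n_readings):
        for tool_id, pose in poses.items():
            readings.append(
                PoseReading(
                    time_s=t0_s + i * dt_s,
                    tool_id=tool_id,
                    pose=_jittered_pose(pose, sigma_axis_mm, sigma_rot_deg, rng),
                    valid=True,
                )
            )
    return PoseStream(readings=readings)


# ---------------------------------------------------------------------------
# whole simulated experiments


@dataclass
class NoiseModel:
    """Per-axis noise sigmas (mm / deg) of every simulated error source."""

    tracker_sigma_mm: float = TRACKER_SIGMA_AXIS_MM
    tracker_sigma_deg: float = 0.05
    stylus_fle_mm: float = TRACKER_SIGMA_AXIS_MM
    us_fle_mm: float = 1.0 / np.sqrt(3.0)  # 1.0 mm 3-D RMS image localization
    mr_fle_mm: float = 0.5 / np.sqrt(3.0)  # 0.5 mm 3-D RMS image localization

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(
            tracker_sigma_mm=self.tracker_sigma_mm * factor,
            tracker_sigma_deg=self.tracker_sigma_deg * factor,
            stylus_fle_mm=self.stylus_fle_mm * factor,
            us_fle_mm=self.us_fle_mm * factor,
            mr_fle_mm=self.mr_fle_mm * factor,
        )

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ExperimentTruth:
    """Ground truth of a simulated calibration/fusion world.

    The simulated phantoms are static in the tracker ("world") frame, as in
    a phantom bench experiment; the MR image frame is anchored to the world
    by the rigid map ``world_to_mr``.  Poses are tool -> world.
    """

    world_to_mr: RigidTransform
    t_us_trans: RigidTransform  # US image -> probe tool (probe calibration truth)
    t_trus_us: AffineTransform  # TRUS image -> US image (intra-modal truth)
    pose_gantry: RigidTransform
    pose_table_before: RigidTransform
    pose_table_after: RigidTransform
    pose_tank: RigidTransform
    pose_probe_us: RigidTransform  # probe pose at the ab-3D-US acquisition
    probe_cal_poses: list[RigidTransform]  # probe poses for the calibration images
    tank_tips_world: FiducialSet
    cad_tips: FiducialSet
    mr_cone_tips_world: FiducialSet
    target_tips_world: FiducialSet  # held-out second phantom, for TRE
    phantom: PhantomSpec
    noise: NoiseModel
    seed: int

    @property
    def t_us_mr_true(self) -> RigidTransform:
        """The true US-image-to-MR-image map implied by the world."""
        return compose(self.world_to_mr, compose(self.pose_probe_us, self.t_us_trans))


@dataclass
class ExperimentBundle:
    """Everything the calibration/fusion pipeline consumes, plus the truth."""

    truth: ExperimentTruth
    us_observations: list[UsCalibrationObservation]
    mr_tips_reference: FiducialSet  # stylus repeats in the table-tool frame
    mr_tips_image: FiducialSet  # cone tips localized in the MR image
    stream_before: PoseStream  # gantry + table tools, MR epoch
    stream_after: PoseStream  # table + probe tools, US epoch
    trus_points: list[Point3D]  # lesion centroids in the TRUS frame
    lesion_points_mr_true: list[Point3D]  # ground-truth lesion centroids, MR frame
    target_tips_us: FiducialSet  # held-out tips in the US image frame
    target_tips_mr: FiducialSet  # held-out tips in the MR image frame
    table_tool: str = "ORF_TABLE"
    gantry_tool: str = "ORF_MR"
    probe_tool: str = "trans"
    volumes: dict[str, PhantomVolumes] | None = None


def _map_set(t: Transform, fs: FiducialSet, frame: str) -> FiducialSet:
    return FiducialSet.from_arrays(
        fs.labels, apply_to_array(t, fs.coordinates), frame=frame
    )


def make_experiment_truth(
    seed: int = 0,
    noise: NoiseModel | None = None,
    n_cal_images: int = 5,
    table_shift_mm: tuple[float, float, float] = (0.0, 0.0, 150.0),
    phantom: PhantomSpec | None = None,
) -> ExperimentTruth:
    """Draw a reproducible ground-truth world for a simulated experiment.

    Tool poses and calibration transforms are random rigid maps at bench
    scale (translations up to ~0.5 m); the table moves by ``table_shift_mm``
    between the MR and US epochs.
    """
    rng = np.random.default_rng(seed)
    noise = NoiseModel() if noise is None else noise
    phantom = PhantomSpec() if phantom is None else phantom

    world_to_mr = random_rigid(rng, source="world", target="MR", max_translation_mm=200)
    t_us_trans = random_rigid(rng, source="US", target="trans", max_translation_mm=80)

    # mild affine for the TRUS->US truth: small rotation, shift, anisotropic scale
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(rng.uniform(-0.05, 0.05, 3)).as_matrix()
    scale = np.diag(1.0 + rng.uniform(-0.03, 0.03, 3))
    m = np.eye(4)
    m[:3, :3] = rot @ scale
    m[:3, 3] = rng.uniform(-10, 10, 3)
    t_trus_us = AffineTransform(m, source="TRUS", target="US")

    pose_gantry = random_rigid(rng, source="ORF_MR", target="world", max_translation_mm=500)
    pose_table_before = random_rigid(
        rng, source="ORF_TABLE", target="world", max_translation_mm=500
    )
    shift_world = np.asarray(table_shift_mm, dtype=float)
    m_after = np.array(pose_table_before.matrix)
    m_after[:3, 3] = m_after[:3, 3] + shift_world
    pose_table_after = RigidTransform(m_after, source="ORF_TABLE", target="world")
    pose_tank = random_rigid(rng, source="tank", target="world", max_translation_mm=500)
    pose_probe_us = random_rigid(rng, source="trans", target="world", max_translation_mm=400)
    probe_cal_poses = [
        random_rigid(rng, source="trans", target="world", max_translation_mm=400)
        for _ in range(n_cal_images)
    ]

    cad_tips = make_multicone(7, frame="CAD", seed=int(rng.integers(2**31)))
    t_cad_world = random_rigid(rng, source="CAD", target="world", max_translation_mm=400)
    tank_tips_world = _map_set(t_cad_world, cad_tips, "world")

    mr_cone_cad = make_multicone(18, frame="CAD18", seed=int(rng.integers(2**31)))
    t_cone_world = random_rigid(rng, source="CAD18", target="world", max_translation_mm=300)
    mr_cone_tips_world = _map_set(t_cone_world, mr_cone_cad, "world")

    # held-out second multi-cone phantom: 7 tips seen in 10 images = 70 targets
    tgt_cad = make_multicone(7, frame="CAD2", seed=int(rng.integers(2**31)))
    t_tgt_world = random_rigid(rng, source="CAD2", target="world", max_translation_mm=400)
    target_tips_world = _map_set(t_tgt_world, tgt_cad, "world")

    return ExperimentTruth(
        world_to_mr=world_to_mr,
        t_us_trans=t_us_trans,
        t_trus_us=t_trus_us,
        pose_gantry=pose_gantry,
        pose_table_before=pose_table_before,
        pose_table_after=pose_table_after,
        pose_tank=pose_tank,
        pose_probe_us=pose_probe_us,
        probe_cal_poses=probe_cal_poses,
        tank_tips_world=tank_tips_world,
        cad_tips=cad_tips,
        mr_cone_tips_world=mr_cone_tips_world,
        target_tips_world=target_tips_world,
        phantom=phantom,
        noise=noise,
        seed=seed,
    )


def _world_to_us(truth: ExperimentTruth) -> Transform:
    return invert(compose(truth.pose_probe_us, truth.t_us_trans))


def simulate_experiment(
    truth: ExperimentTruth,
    seed: int | None = None,
    n_pose_readings: int = 50,
    n_stylus_repeats: int = 10,
    n_mr_repeats: int = 5,
    render_volumes: bool = False,
    volume_spacing_mm: float = 1.0,
) -> ExperimentBundle:
    """Generate every noisy observation of one experiment run.

    With all sigmas zero the bundle reproduces the truth to numerical
    precision through the whole downstream pipeline (the system-closure
    property every other module is tested against).
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    nz = truth.noise

    def child():
        return int(rng.integers(2**31))

    # --- US probe calibration observations --------------------------------
    us_obs = []
    world_to_tank = invert(truth.pose_tank)
    for pose in truth.probe_cal_poses:
        world_to_img = invert(compose(pose, truth.t_us_trans))
        img_tips = _map_set(world_to_img, truth.tank_tips_world, "US")
        img_tips = perturb_fiducials(img_tips, nz.us_fle_mm, rng)
        tank_repeats = {}
        tank_true = _map_set(world_to_tank, truth.tank_tips_world, "tank")
        for lab, c in zip(tank_true.labels, tank_true.coordinates):
            tank_repeats[lab] = c + rng.normal(
                0.0, nz.stylus_fle_mm, size=(n_stylus_repeats, 3)
            )
        tank_tips = FiducialSet.from_repeats(tank_repeats, frame="tank")
        pose_probe = average_pose_of_jitter(pose, nz, n_pose_readings, child())
        pose_tank = average_pose_of_jitter(truth.pose_tank, nz, n_pose_readings, child())
        us_obs.append(
            UsCalibrationObservation(
                image_tips=img_tips,
                tank_tips=tank_tips,
                pose_probe=pose_probe,
                pose_tank=pose_tank,
            )
        )

    # --- MR calibration ----------------------------------------------------
    world_to_table = invert(truth.pose_table_before)
    mr_ref_true = _map_set(world_to_table, truth.mr_cone_tips_world, "ORF_TABLE")
    ref_repeats = {
        lab: c + rng.normal(0.0, nz.stylus_fle_mm, size=(n_mr_repeats, 3))
        for lab, c in zip(mr_ref_true.labels, mr_ref_true.coordinates)
    }
    mr_tips_reference = FiducialSet.from_repeats(ref_repeats, frame="ORF_TABLE")
    mr_tips_image = perturb_fiducials(
        _map_set(truth.world_to_mr, truth.mr_cone_tips_world, "MR"), nz.mr_fle_mm, rng
    )

    # --- pose streams for the two epochs ------------------------------------
    stream_before = simulate_pose_stream(
        {"ORF_MR": truth.pose_gantry, "ORF_TABLE": truth.pose_table_before},
        n_readings=n_pose_readings,
        sigma_axis_mm=nz.tracker_sigma_mm,
        sigma_rot_deg=nz.tracker_sigma_deg,
        seed=child(),
    )
    stream_after = simulate_pose_stream(
        {"ORF_TABLE": truth.pose_table_after, "trans": truth.pose_probe_us},
        n_readings=n_pose_readings,
        sigma_axis_mm=nz.tracker_sigma_mm,
        sigma_rot_deg=nz.tracker_sigma_deg,
        seed=child(),
        t0_s=100.0,
    )

    # --- lesion targets ------------------------------------------------------
    # the prostate phantom sits at a fixed place in the world; by construction
    # its MR-frame lesion coordinates are world coords mapped through the truth
    lesions_world = FiducialSet.from_arrays(
        truth.phantom.lesion_labels, truth.phantom.lesion_centers_mm, frame="world"
    )
    lesions_mr = _map_set(truth.world_to_mr, lesions_world, "MR")
    lesions_us = _map_set(_world_to_us(truth), lesions_world, "US")
    lesions_trus = _map_set(invert(truth.t_trus_us), lesions_us, "TRUS")
    trus_points = list(lesions_trus.points)
    lesion_points_mr_true = list(lesions_mr.points)

    # --- held-out TRE targets ------------------------------------------------
    tgt_us = perturb_fiducials(
        _map_set(_world_to_us(truth), truth.target_tips_world, "US"), nz.us_fle_mm, rng
    )
    tgt_mr = perturb_fiducials(
        _map_set(truth.world_to_mr, truth.target_tips_world, "MR"), nz.mr_fle_mm, rng
    )

    volumes = None
    if render_volumes:
        t_phantom_mr = truth.world_to_mr  # phantom coordinates are world coordinates
        volumes = {
            "mr": render_volume(
                truth.phantom,
                modality="mr",
                spacing_mm=volume_spacing_mm,
                seed=child(),
                frame="MR",
                world_transform=t_phantom_mr,
            ),
            "us": render_volume(
                truth.phantom,
                modality="us",
                spacing_mm=volume_spacing_mm,
                seed=child(),
                frame="US",
                world_transform=_world_to_us(truth),
            ),
        }

    return ExperimentBundle(
        truth=truth,
        us_observations=us_obs,
        mr_tips_reference=mr_tips_reference,
        mr_tips_image=mr_tips_image,
        stream_before=stream_before,
        stream_after=stream_after,
        trus_points=trus_points,
        lesion_points_mr_true=lesion_points_mr_true,
        target_tips_us=tgt_us,
        target_tips_mr=tgt_mr,
        volumes=volumes,
    )


def average_pose_of_jitter(
    pose: RigidTransform, noise: NoiseModel, n_readings: int, seed: int
) -> RigidTransform:
    """The epoch-average of a jittered static pose, as an acquisition would log it."""
    from .calibration import average_pose

    stream = simulate_pose_stream(
        {pose.source: pose},
        n_readings=n_readings,
        sigma_axis_mm=noise.tracker_sigma_mm,
        sigma_rot_deg=noise.tracker_sigma_deg,
        seed=seed,
    )
    return average_pose(stream.select(pose.source))
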