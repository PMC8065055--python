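"""Intra-modal US/US affine registration with mutual information.

Renders two US-like views of the prostate phantom that differ by a small
affine motion (rotation + shift + anisotropic scale) and independent
speckle, masks them to the gland region, and registers them. The recovered
transform is scored at the lesion centroids.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from navfuse.phantom import PhantomSpec, render_volume
from navfuse.register import EllipsoidRoi, mask_volume, register_affine
from navfuse.transforms import AffineTransform, apply_to_array

spec = PhantomSpec()
fixed = render_volume(spec, "us", spacing_mm=1.25, seed=10, frame="US_pre")

m = np.eye(4)
m[:3, :3] = Rotation.from_euler("xyz", [6, -4, 8], degrees=True).as_matrix() \
    @ np.diag([1.02, 0.98, 1.01])
m[:3, 3] = [3.0, -4.0, 2.0]
t_true = AffineTransform(m, source="phantom", target="TRUS")
moving = render_volume(spec, "us", spacing_mm=1.25, seed=11, frame="TRUS",
                       world_transform=t_true)

_, gland_roi = mask_volume(
    fixed.image, EllipsoidRoi(spec.gland_center_mm, spec.gland_semi_axes_mm + 6)
)
t, report = register_affine(fixed.image, moving.image, fixed_mask=gland_roi, seed=1)

centers = spec.lesion_centers_mm
tre = np.linalg.norm(
    apply_to_array(t, apply_to_array(t_true, centers)) - centers, axis=1
)
print(f"mutual information      : {report.mi_init:.3f} -> {report.mi_final:.3f} nats")
print(f"optimizer iterations    : {report.iterations}")
print(f"lesion centroid TRE     : {np.array2string(tre, precision=3)} mm "
      f"(mean {tre.mean():.3f} mm)")
print()
print("MI rises as the gland structures line up; a sub-voxel (< 1.25 mm)")
print("lesion TRE means the affine registration recovered the simulated")
print("probe repositioning despite independent speckle in the two scans.")
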