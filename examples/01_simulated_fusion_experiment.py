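"""End-to-end simulated fusion experiment.

Builds a ground-truth world (probe calibration, MR calibration, tracker
poses, a 150 mm table shift and a prostate phantom), simulates every noisy
observation, reruns the whole calibration + chain pipeline, and scores the
mapped lesion positions against the truth.
"""

import numpy as np

from navfuse.phantom import NoiseModel, make_experiment_truth, simulate_experiment
from navfuse.pipeline import run_fusion_pipeline

truth = make_experiment_truth(seed=1, table_shift_mm=(0.0, 0.0, 150.0))
bundle = simulate_experiment(truth, seed=2)
out = run_fusion_pipeline(bundle)

print(f"US probe calibration FRE : {out.probe_cal.fre_mm:.3f} mm "
      f"({out.probe_cal.n_images_used} pooled images)")
print(f"MR calibration FRE       : {out.mr_cal.fre_mm:.3f} mm (18 cone tips)")
print(f"tracked table shift      : {np.linalg.norm(out.shift.translation):.1f} mm")
print(f"lesion mapping errors    : "
      f"{np.array2string(out.lesion_errors_mm, precision=3)} mm")
print(f"held-out 70-point TRE    : {out.target_tre.mean_mm:.2f} "
      f"+/- {out.target_tre.sd_mm:.2f} mm")
print()
print("The FREs are the residuals of the two point-based calibrations; the")
print("TRE is the error at targets never used for calibration -- the number")
print("that matters for navigating a biopsy needle. With the default 0.3 mm")
print("tracker jitter and 0.5-1 mm image localization noise it lands at")
print("low-millimetre scale.")

# the same world with all noise off closes exactly:
clean = run_fusion_pipeline(
    simulate_experiment(
        make_experiment_truth(seed=1, noise=NoiseModel.zero(),
                              table_shift_mm=(0.0, 0.0, 150.0))
    )
)
print(f"\nzero-noise closure check : max error "
      f"{clean.lesion_errors_mm.max():.2e} mm (machine precision)")
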