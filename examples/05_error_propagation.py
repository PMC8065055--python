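"""Error propagation: quadrature arithmetic and Monte-Carlo verification.

The chain error from MR to TRUS combines the independent link errors in
quadrature. The Monte-Carlo propagation re-simulates the full chain and
confirms the first-order picture: the target error scales linearly with
the noise level.
"""

import numpy as np

from navfuse.errorprop import ErrorBudget, monte_carlo_chain_tre, quadrature_total
from navfuse.phantom import NoiseModel, make_experiment_truth

budget = ErrorBudget(components=[
    ("intra-modal US/US registration", 3.7),
    ("TRUS calibration FRE", 1.18),
])
total = quadrature_total(budget)
print(f"quadrature total: sqrt(3.7^2 + 1.18^2) = {total:.2f} mm (~3.9 mm)")
print("  -> the expected MR-to-TRUS error when the intra-modal registration")
print("     error and the TRUS calibration residual act independently.\n")

truth = make_experiment_truth(seed=5)
for scale, label in ((0.5, "half"), (1.0, "nominal"), (2.0, "double")):
    res = monte_carlo_chain_tre(truth, n_reps=200, seed=9,
                                noise=NoiseModel().scaled(scale))
    print(f"{label:>8} noise: chain TRE {res.mean_mm:.3f} +/- {res.sd_mm:.3f} mm "
          f"(n={res.n_replicates})")
print()
print("Halving or doubling every noise source halves/doubles the mean chain")
print("TRE -- the linear-propagation regime that justifies the quadrature sum.")
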