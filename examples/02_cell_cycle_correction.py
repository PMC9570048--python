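"""Why the cell-cycle control matters.

Simulates two populations with *no* programmed expression shifts, but with
the contrast population proliferating less (lower latent cell-cycle
activity). Because unicellular-origin genes couple positively to that
activity, their raw mean expression differs between the populations even
though nothing was programmed. The intercept contrast at a common slope
removes most of that confound.
"""

import numpy as np

from cellrecap import (
    SimulationConfig,
    cc_signature_genes,
    evolutionary_profile,
    simulate_expression,
)
from cellrecap.datatypes import N_STRATA

config = SimulationConfig(
    n_genes_per_stratum=40,
    n_cells_per_population=200,
    shift_profile=(0.0,) * N_STRATA,          # nothing programmed
    cc_activity_params={"reference": (0.4, 0.4),   # cycling fast
                        "contrast": (-0.4, 0.4)},  # cycling slowly
    seed=7,
)
matrix, strata, _ = simulate_expression(config)

s1 = sorted(strata.stratum_genes(1))
raw_ref = matrix.values.loc[s1, matrix.cells_in("reference")].mean().mean()
raw_con = matrix.values.loc[s1, matrix.cells_in("contrast")].mean().mean()
print(f"stratum-1 raw mean expression: reference {raw_ref:.3f}, "
      f"contrast {raw_con:.3f}")
print(f"raw difference (confounded by proliferation): "
      f"{raw_con - raw_ref:+.3f}")

profile = evolutionary_profile(
    matrix, strata, cc_signature_genes(config), "contrast", "reference",
    normalize=False)
c = profile.contrasts[0]
print(f"intercept contrast at equal slopes:          "
      f"{c.delta_intercept:+.3f}  (95% CI {c.ci[0]:+.3f} .. {c.ci[1]:+.3f})")

print()
print("The raw means differ purely because the populations cycle at")
print("different rates; the common-slope intercept difference, which")
print("extrapolates both populations to zero cell-cycle activity, is an")
print("order of magnitude closer to the true value of 0.")
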