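"""Evolutionary profile of a simulated differentiation contrast.

Generates a synthetic dataset in which the contrast population carries the
default three-phase shift profile (unicellular strata down, strata 3-9 up,
strata 10-17 unchanged), then recovers it: per phylostratum, the mean
expression of the stratum's genes is regressed on the mitotic cell-cycle
signature in each population, and the two regression lines are compared by
their intercept difference at a common slope.
"""

from cellrecap import (
    SimulationConfig,
    cc_signature_genes,
    evolutionary_profile,
    simulate_expression,
)

config = SimulationConfig(n_cells_per_population=300, seed=42)
matrix, strata, truth = simulate_expression(config)
print(f"simulated {matrix.values.shape[0]} genes x "
      f"{matrix.values.shape[1]} cells (two populations)")

profile = evolutionary_profile(
    matrix, strata, cc_signature_genes(config), "contrast", "reference")
frame = profile.to_frame()
print(frame[["stratum", "delta_intercept", "ci_low", "ci_high",
             "call"]].round(3).to_string(index=False))

print()
print("delta_intercept is the contrast-minus-reference expression difference")
print("extrapolated to zero cell-cycle activity; 'down'/'up' means the 95%")
print("CI excludes zero. The programmed three phases (down x2, up x7,")
print("null x8) should be visible in the calls, with the sign flipping at")
print("stratum 3 (Opisthokonta, the unicellular/multicellular divide).")
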