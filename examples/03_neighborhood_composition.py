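"""Interactome neighborhood composition reverses a gene's contrast.

Simulates a coupled dataset: an interactome whose unicellular-origin (UC)
block is denser than the multicellular (MC) blocks, with each gene's
expression shift blended from its node's MC-neighborhood fraction f as
delta = (1-f) * (-0.1) + f * (+0.1). UC genes are then binned by f (cut
points 0.25 / 0.5 / 0.75) and each bin's intercept contrast is estimated.
"""

from cellrecap.pipeline import PipelineConfig, run_network_contrast
from cellrecap.simulate import SimulationConfig

config = PipelineConfig(
    output_dir="scratch/example_network",
    seed=7,
    simulate=SimulationConfig(n_genes_per_stratum=100,
                              n_cells_per_population=200),
)
out = run_network_contrast(config)
print(out["bin_contrasts"].round(3).to_string(index=False))

print()
print("Reading the UC rows top to bottom: as the fraction of MC partners in")
print("a UC protein's one-step neighborhood grows, the gene's contrast")
print("rises monotonically and turns positive above f = 0.75 -- the")
print("neighborhood, not the gene's own age, ends up driving its behavior.")
print(f"artifacts written to {out['outdir']}")
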