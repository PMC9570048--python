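# cellrecap

Cell-cycle-controlled contrasts of gene-age-binned expression in
single-cell transcriptomes — a pipeline for asking whether cell
differentiation recapitulates phylogenesis, and for measuring how a
protein's interactome neighborhood distorts that recapitulation.

## Who this is for

Researchers analyzing single-cell (or bulk) expression matrices together
with phylostratigraphic gene dating: gene-age profiling of differentiation,
reprogramming or oncogenesis contrasts, with explicit control for
proliferative activity, plus interaction-network stratification and
DAG-propagated functional enrichment. All stages run equally on synthetic
data with known ground truth, which is how the package validates itself.

## The statistic

Genes are binned into 17 phylostrata (cellular organisms → Hominidae);
strata 1–2 are unicellular-origin (UC), 3–17 multicellular-origin (MC).
For a gene group and a cell population, the per-cell back-transformed mean
expression *y* of the group is regressed on the per-cell mean *x* of the
mitotic cell-cycle signature (GO:0000278). Two populations are compared by
the one-covariate ANCOVA

    y = a + Δa·g + b·x + ε ,      g = 1 in the contrast population,

so **Δa** — the intercept difference at a common slope — is the expression
difference extrapolated to zero cell-cycle activity, freed from the
confound that earlier, faster-cycling populations overexpress UC genes
simply because those genes couple to the cell cycle. SE, p and CI come
from the standard linear-model covariance with t-distribution quantiles.
The per-stratum vector of Δa values is the *evolutionary profile*; UC and
MC genes binned by the MC fraction of their one-step interactome
neighborhood give the network-composition contrasts; hypergeometric tests
with DAG-propagated category membership and Benjamini–Hochberg FDR give
the functional enrichment.

See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

`examples/01_evolutionary_profile.py` simulates 3890 genes × 600 cells in
which the contrast population carries a three-phase shift profile
(UC strata down by 0.15 log2 units, strata 3–9 up by 0.08, strata 10–17
unchanged) and then recovers it:

```
$ python examples/01_evolutionary_profile.py
simulated 3890 genes x 600 cells (two populations)
 stratum  delta_intercept  ci_low  ci_high call
       1           -0.734  -0.808   -0.660 down
       2           -0.805  -0.876   -0.735 down
       3            0.351   0.283    0.420   up
       4            0.494   0.414    0.574   up
       ...
       9            0.428   0.355    0.502   up
      10           -0.019  -0.097    0.059 null
      ...
```

The calls read as programmed: both UC strata down, strata 3–9 up, the
late strata null — with the sign flipping at stratum 3 (Opisthokonta, the
unicellular/multicellular divide). `delta_intercept` is on the linear
expression scale of the normalized matrix.

`examples/03_neighborhood_composition.py` couples each gene's shift to its
interactome neighborhood (UC base −0.1, MC base +0.1, blended by the
node's MC fraction *f*) and recovers the reversal:

```
           bin  n_genes  delta_intercept    se  ci_low  ci_high  p_value call
 UC_mc_le_0.25       60           -0.465 0.038  -0.539   -0.391    0.000 down
UC_mc_0.25_0.5       31           -0.300 0.053  -0.404   -0.196    0.000 down
UC_mc_0.5_0.75       40            0.044 0.045  -0.044    0.133    0.324 null
  UC_mc_0.75_1       69            0.270 0.037   0.198    0.342    0.000   up
```

UC genes whose proteins sit in a mostly-MC neighborhood (*f* > 0.75)
behave like MC genes — the contrast turns positive. The other examples
demonstrate the cell-cycle correction on a confounded null
(`02_cell_cycle_correction.py`) and planted-signal enrichment
(`04_enrichment.py`).

## Command line

A thin CLI wraps the same pipeline functions, driven by one YAML config
with either input paths or a `simulate:` block:

```sh
cellrecap simulate run.yaml        # write a synthetic dataset
cellrecap profile run.yaml        # evolutionary + slope profiles
cellrecap network run.yaml        # composition bins + contrasts
cellrecap enrich run.yaml         # DAG-propagated enrichment
cellrecap benchmark run.yaml      # ground-truth recovery report
```

Every run writes TSV/GMT artifacts and a manifest (config hash, version,
seed) to its output directory; repeated runs with the same seed are
byte-identical.

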