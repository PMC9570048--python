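"""Synthetic single-cell data with the statistical structure the analysis assumes.

The generator produces, with known ground truth: (i) a genes x cells
expression matrix in which each cell carries a latent cell-cycle activity
(Gaussian on the log2 scale, hence log-normal on the linear scale), each
gene's log2 expression couples to that activity with a phylostratum-dependent
slope (positive for the unicellular strata, declining to negative after
Bilateria), and the contrast population's intercepts are shifted per stratum
with a three-phase profile; (ii) an interactome whose unicellular-origin
block is denser than the multicellular blocks and whose per-node
multicellular-neighborhood fraction can re-blend a gene's programmed shift
(so the neighborhood composition, not the gene's own age, drives its
contrast); (iii) a small single-rooted ontology DAG with optionally planted
stratum-biased annotations.

Every generator is deterministic under a fixed seed; component sub-seeds are
derived from the one configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    N_STRATA,
    OntologyDAG,
    PhylostratumMap,
)
from .network import InteractionNetwork, build_network

#: default stratum -> cell-cycle coupling: positive in the unicellular strata,
#: tapering through the early multicellular strata, negative after Bilateria
DEFAULT_SLOPE_PROFILE: tuple[float, ...] = (
    0.4, 0.4, 0.25, 0.1, -0.05, *([-0.2] * 12),
)

#: default stratum -> contrast-minus-reference intercept shift (log2): the
#: three-phase pattern (down in strata 1-2, up in 3-9, flat in 10-17)
DEFAULT_SHIFT_PROFILE: tuple[float, ...] = (
    -0.15, -0.15, *([0.08] * 7), *([0.0] * 8),
)


@dataclass
class NetworkParams:
    """Stochastic-block-model parameters for the synthetic interactome.

    The UC block is denser relative to its outside connections than the MC
    blocks (``p_within_uc / p_between_ucmc > p_within_mc / p_between_mc``).
    Each UC node additionally draws a mixing propensity t ~ Beta(a, a) that
    trades its within-block edge probability against its UC-MC probability,
    so node-level MC-neighborhood fractions span the whole [0, 1] range and
    populate all four composition bins downstream.
    """

    p_within_uc: float = 0.3
    p_within_mc: float = 0.05
    p_between_ucmc: float = 0.04
    p_between_mc: float = 0.01
    n_mc_blocks: int = 3
    mixing_beta: float = 0.4
    confidence_range: tuple[float, float] = (0.4, 1.0)
    confidence_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_within_uc", "p_within_mc", "p_between_ucmc",
                     "p_between_mc"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        lo, hi = self.confidence_range
        if not 0 < lo < hi <= 1:
            raise ValueError("confidence_range must satisfy 0 < lo < hi <= 1")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    n_genes_per_stratum: int = 50
    n_cells_per_population: int = 200
    populations: tuple[str, ...] = ("reference", "contrast")
    #: population -> (location, scale) of latent cell-cycle activity, log2 scale
    cc_activity_params: dict[str, tuple[float, float]] | None = None
    slope_profile: tuple[float, ...] = DEFAULT_SLOPE_PROFILE
    shift_profile: tuple[float, ...] = DEFAULT_SHIFT_PROFILE
    #: per-population multiplier on the shift profile (reference gets 0)
    population_shift_scales: tuple[float, ...] | None = None
    base_intercept: float = 3.0
    #: per-gene baseline spread (log2), drawn once per gene, shared by all cells
    gene_baseline_sd: float = 1.0
    noise_sd: float = 0.5
    n_cc_genes: int = 40
    cc_gene_intercept: float = 3.0
    #: undated background genes (no shift, no cell-cycle coupling); real
    #: matrices are transcriptome-wide while dating covers a minority of genes,
    #: and quantile normalization presumes that majority-unchanged background
    n_background_genes: int = 3000
    neighborhood_coupling: tuple[float, float] = (-0.1, 0.1)
    network_params: NetworkParams = field(default_factory=NetworkParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_per_stratum < 1 or self.n_cells_per_population < 1:
            raise ValueError("gene and cell counts must be >= 1")
        if self.n_cc_genes < 1:
            raise ValueError("n_cc_genes must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.gene_baseline_sd < 0:
            raise ValueError("gene_baseline_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.populations) < 1:
            raise ValueError("need at least one population")
        for profile, name in ((self.slope_profile, "slope_profile"),
                              (self.shift_profile, "shift_profile")):
            if len(profile) != N_STRATA:
                raise ValueError(
                    f"{name} must have exactly {N_STRATA} entries, "
                    f"got {len(profile)}")
        if self.cc_activity_params is None:
            self.cc_activity_params = {p: (0.0, 0.6) for p in self.populations}
        missing = [p for p in self.populations if p not in self.cc_activity_params]
        if missing:
            raise ValueError(f"cc_activity_params missing populations {missing}")
        if self.population_shift_scales is None:
            self.population_shift_scales = tuple(
                0.0 if i == 0 else 1.0 for i in range(len(self.populations)))
        if len(self.population_shift_scales) != len(self.populations):
            raise ValueError("population_shift_scales must match populations")


@dataclass
class GroundTruth:
    """What the generator programmed, for recovery checks downstream."""

    gene_strata: pd.Series
    gene_shifts: pd.Series            # contrast-vs-reference log2 shift per gene
    cell_activity: pd.Series | None = None
    node_mc_fraction: pd.Series | None = None
    node_block: pd.Series | None = None
    node_mixing: pd.Series | None = None


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, component)))


def make_gene_ids(n_genes_per_stratum: int) -> pd.Series:
    """Deterministic gene ids 'PSss_Gnnn' with their stratum assignment."""
    ids, strata = [], []
    for s in range(1, N_STRATA + 1):
        for i in range(n_genes_per_stratum):
            ids.append(f"PS{s:02d}_G{i:03d}")
            strata.append(s)
    return pd.Series(strata, index=ids, dtype=int)


def simulate_expression(config: SimulationConfig,
                        gene_shifts: pd.Series | None = None
                        ) -> tuple[ExpressionMatrix, PhylostratumMap, GroundTruth]:
    """Generate the expression matrix under the configured generative model.

    For cell j of population P with latent activity ``c_j ~ N(loc_P, scale_P)``
    (log2 scale), gene i of stratum s has

        log2 expr = base_intercept + m_P * delta_i + beta_s * c_j + eps

    with ``eps ~ N(0, noise_sd)``, ``m_P`` the population's shift multiplier
    (0 for the first/reference population) and ``delta_i`` the stratum shift
    unless overridden per gene via ``gene_shifts``. The cell-cycle signature
    genes ('CCG...') track ``c_j`` with unit slope and are disjoint from the
    strata. The matrix is emitted on the linear scale (2**log2, strictly
    positive).
    """
    rng = _rng(config.seed, 0)
    strata = make_gene_ids(config.n_genes_per_stratum)
    shifts = strata.map(
        lambda s: config.shift_profile[s - 1]).astype(float)
    if gene_shifts is not None:
        shifts.update(gene_shifts.astype(float))
    slopes = strata.map(lambda s: config.slope_profile[s - 1]).to_numpy()

    cc_ids = [f"CCG{i:03d}" for i in range(config.n_cc_genes)]
    cell_ids, cell_pops, activity = [], [], []
    for pop in config.populations:
        loc, scale = config.cc_activity_params[pop]
        c = rng.normal(loc, scale, size=config.n_cells_per_population)
        activity.append(c)
        cell_ids.extend(f"{pop}_{j:03d}" for j in range(config.n_cells_per_population))
        cell_pops.extend([pop] * config.n_cells_per_population)
    c_all = np.concatenate(activity)
    labels = pd.Series(cell_pops, index=cell_ids)
    scale_by_pop = dict(zip(config.populations, config.population_shift_scales))
    m = labels.map(scale_by_pop).to_numpy(dtype=float)

    bg_ids = [f"BGG{i:04d}" for i in range(config.n_background_genes)]
    n_total = len(strata) + config.n_cc_genes + config.n_background_genes
    baselines = config.gene_baseline_sd * rng.normal(0.0, 1.0, size=n_total)

    # strata genes: baseline + shift + slope * activity (+ noise below)
    log2_strata = (
        config.base_intercept
        + baselines[:len(strata), None]
        + np.outer(shifts.to_numpy(), m)
        + np.outer(slopes, np.ones_like(c_all)) * c_all
    )
    # cc signature genes: track activity with unit slope
    cc_base = baselines[len(strata):len(strata) + config.n_cc_genes]
    log2_cc = (config.cc_gene_intercept + cc_base[:, None]
               + np.tile(c_all, (config.n_cc_genes, 1)))
    # undated background genes: baseline only (no shift, no coupling)
    bg_base = baselines[len(strata) + config.n_cc_genes:]
    log2_bg = (config.base_intercept + bg_base[:, None]
               + np.zeros((config.n_background_genes, len(c_all))))
    log2 = np.vstack([log2_strata, log2_cc, log2_bg])
    if config.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)
    values = pd.DataFrame(np.exp2(log2),
                          index=[*strata.index, *cc_ids, *bg_ids],
                          columns=cell_ids)
    matrix = ExpressionMatrix(values=values, cell_labels=labels)
    strata_map = PhylostratumMap(strata=strata.copy())
    truth = GroundTruth(
        gene_strata=strata.copy(),
        gene_shifts=shifts,
        cell_activity=pd.Series(c_all, index=cell_ids),
    )
    return matrix, strata_map, truth


def cc_signature_genes(config: SimulationConfig) -> frozenset[str]:
    """The designated cell-cycle signature gene set of a simulated matrix."""
    return frozenset(f"CCG{i:03d}" for i in range(config.n_cc_genes))


def simulate_network(config: SimulationConfig, strata: PhylostratumMap
                     ) -> tuple[pd.DataFrame, InteractionNetwork, GroundTruth]:
    """Generate a confidence-scored interactome over the strata-map genes.

    Returns the raw edge records (protein_a, protein_b, confidence), the
    network filtered at the configured confidence threshold, and ground truth
    holding each node's block, mixing propensity, realized MC-neighborhood
    fraction on the filtered graph, and the neighborhood-blended shift
    ``delta_i = (1 - f_i) * delta_uc_base + f_i * delta_mc_base`` (nodes with
    no dated neighbors keep their stratum shift).
    """
    rng = _rng(config.seed, 1)
    params = config.network_params
    genes = np.asarray(strata.strata.index)
    is_uc = strata.strata.to_numpy() <= strata.uc_max_stratum
    n = len(genes)
    uc_idx = np.flatnonzero(is_uc)
    mc_idx = np.flatnonzero(~is_uc)

    block = np.empty(n, dtype=object)
    block[uc_idx] = "UC_block"
    mc_assign = rng.integers(0, max(params.n_mc_blocks, 1), size=len(mc_idx))
    for b in range(max(params.n_mc_blocks, 1)):
        block[mc_idx[mc_assign == b]] = f"MC_block_{b}"

    mixing = np.zeros(n)
    mixing[uc_idx] = rng.beta(params.mixing_beta, params.mixing_beta,
                              size=len(uc_idx))

    # pairwise edge probabilities, blockwise
    prob = np.zeros((n, n))
    if len(mc_idx):
        same_mc = np.equal.outer(block[mc_idx], block[mc_idx])
        pm = np.where(same_mc, params.p_within_mc, params.p_between_mc)
        prob[np.ix_(mc_idx, mc_idx)] = pm
    if len(uc_idx):
        keep = 1.0 - mixing[uc_idx]
        puu = 2.0 * params.p_within_uc * np.sqrt(np.outer(keep, keep))
        prob[np.ix_(uc_idx, uc_idx)] = puu
        if len(mc_idx):
            pum = np.tile(2.0 * params.p_between_ucmc * mixing[uc_idx],
                          (len(mc_idx), 1)).T
            prob[np.ix_(uc_idx, mc_idx)] = pum
            prob[np.ix_(mc_idx, uc_idx)] = pum.T
    np.clip(prob, 0.0, 1.0, out=prob)

    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(len(iu)) < prob[iu, ju]
    ia, jb = iu[hit], ju[hit]
    lo, hi = params.confidence_range
    conf = rng.uniform(lo, hi, size=len(ia))
    edges = pd.DataFrame({
        "protein_a": genes[ia],
        "protein_b": genes[jb],
        "confidence": conf,
    })
    net = build_network(edges, strata,
                        confidence_threshold=params.confidence_threshold)

    # realized MC fraction on the filtered graph (every node here is dated)
    adj = {g: set(net.graph.neighbors(g)) for g in net.graph.nodes}
    uc_set = set(genes[uc_idx])
    f = np.full(n, np.nan)
    for k, g in enumerate(genes):
        nbrs = adj.get(g, set())
        if nbrs:
            f[k] = sum(1 for x in nbrs if x not in uc_set) / len(nbrs)
    delta_uc, delta_mc = config.neighborhood_coupling
    stratum_shift = strata.strata.map(
        lambda s: config.shift_profile[s - 1]).to_numpy(dtype=float)
    blended = np.where(np.isnan(f), stratum_shift,
                       (1.0 - f) * delta_uc + f * delta_mc)
    truth = GroundTruth(
        gene_strata=strata.strata.copy(),
        gene_shifts=pd.Series(blended, index=genes),
        node_mc_fraction=pd.Series(f, index=genes),
        node_block=pd.Series(block, index=genes),
        node_mixing=pd.Series(mixing, index=genes),
    )
    return edges, net, truth


def simulate_neighborhood_coupled(config: SimulationConfig) -> dict:
    """Full coupled dataset: interactome first, then expression whose per-gene
    shifts are blended by each node's realized MC-neighborhood fraction."""
    strata_map = PhylostratumMap(strata=make_gene_ids(config.n_genes_per_stratum))
    edges, net, net_truth = simulate_network(config, strata_map)
    matrix, strata_map, expr_truth = simulate_expression(
        config, gene_shifts=net_truth.gene_shifts)
    truth = GroundTruth(
        gene_strata=expr_truth.gene_strata,
        gene_shifts=expr_truth.gene_shifts,
        cell_activity=expr_truth.cell_activity,
        node_mc_fraction=net_truth.node_mc_fraction,
        node_block=net_truth.node_block,
        node_mixing=net_truth.node_mixing,
    )
    return {"matrix": matrix, "strata": strata_map, "edges": edges,
            "network": net, "truth": truth}


def simulate_ontology(n_terms: int, depth: int, annotations_per_gene: int,
                      seed: int, genes: list[str] | None = None,
                      planted: dict[str, set[str]] | None = None
                      ) -> OntologyDAG:
    """Random single-rooted is_a DAG with direct gene annotations.

    Terms are layered; each non-root term gets one parent in the layer above
    (plus, occasionally, a second parent elsewhere, creating diamonds).
    ``planted`` maps term id (e.g. 'T0007') -> gene set to annotate there
    directly, which plants an enrichment signal for those genes.
    """
    if depth < 1 or n_terms < depth:
        raise ValueError("need n_terms >= depth >= 1")
    if annotations_per_gene < 0:
        raise ValueError("annotations_per_gene must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    term_ids = [f"T{k:04d}" for k in range(n_terms)]
    graph = nx.DiGraph()
    graph.add_node(term_ids[0], name="root")
    levels: list[list[str]] = [[term_ids[0]]]
    # guarantee the requested depth with a chain, then fill remaining terms
    for d in range(1, depth):
        graph.add_node(term_ids[d], name=f"term_{d}")
        graph.add_edge(term_ids[d], levels[-1][0])
        levels.append([term_ids[d]])
    for k in range(depth, n_terms):
        level = int(rng.integers(1, depth + 1)) if depth > 1 else 1
        level = min(level, len(levels))
        parent = levels[level - 1][int(rng.integers(len(levels[level - 1])))]
        graph.add_node(term_ids[k], name=f"term_{k}")
        graph.add_edge(term_ids[k], parent)
        if level < len(levels):
            levels[level].append(term_ids[k])
        else:
            levels.append([term_ids[k]])
        if depth > 1 and rng.random() < 0.2:
            # diamond: a second parent strictly above this term's level
            upper = [t for lev in levels[:level] for t in lev if t != parent]
            if upper:
                graph.add_edge(term_ids[k],
                               upper[int(rng.integers(len(upper)))])
    annotations: dict[str, set[str]] = {}
    if genes:
        candidates = term_ids[1:] if n_terms > 1 else term_ids
        for g in genes:
            k = min(annotations_per_gene, len(candidates))
            if k:
                chosen = rng.choice(len(candidates), size=k, replace=False)
                annotations[g] = {candidates[int(c)] for c in chosen}
    if planted:
        for term, members in planted.items():
            if term not in graph:
                raise KeyError(f"planted term {term!r} not in the DAG")
            for g in members:
                annotations.setdefault(g, set()).add(term)
    return OntologyDAG(graph=graph,
                       annotations={g: frozenset(t) for g, t in annotations.items()})


def null_config(**overrides) -> SimulationConfig:
    """Convenience: a configuration with no programmed shifts."""
    defaults = dict(shift_profile=(0.0,) * N_STRATA)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def with_overrides(config: SimulationConfig, **overrides) -> SimulationConfig:
    """A copy of ``config`` with the given fields replaced."""
    return replace(config, **overrides)


def make_gene_sets(strata_map: PhylostratumMap) -> GeneSetCollection:
    """Stratum-wise and UC/MC gene sets of a simulated strata map."""
    sets: dict[str, frozenset[str]] = {}
    for s in range(1, N_STRATA + 1):
        genes = strata_map.stratum_genes(s)
        if genes:
            sets[f"stratum_{s:02d}"] = genes
    sets["UC"] = strata_map.uc_genes()
    sets["MC"] = strata_map.mc_genes()
    return GeneSetCollection(sets=sets)
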