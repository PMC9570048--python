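"""DAG-propagated functional enrichment with hypergeometric tails and FDR.

A gene belongs to an ontology category if it is directly annotated to the
category or to any of its descendants in the is_a DAG. Over- and
under-representation of categories in a gene sample is assessed against a
gene universe with exact hypergeometric tail probabilities (upper tail when
observed/expected > 1, lower tail otherwise), corrected across categories by
the Benjamini-Hochberg step-up procedure. Pathway compendia are deduplicated
by uniting entries with identical gene sets before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, OntologyDAG


@dataclass
class EnrichmentResult:
    """One category's observed/expected ratio with its tail p and FDR."""

    category: str
    name: str
    n_observed: int
    n_expected: float
    oe_ratio: float
    direction: str          # 'enriched' | 'underrepresented' | 'none'
    p_value: float
    fdr: float


def propagate_annotations(dag: OntologyDAG) -> dict[str, frozenset[str]]:
    """Term -> genes annotated to the term or any of its descendants.

    Computed for every term by accumulating direct annotations upward along
    the child -> parent edges in topological order, so each edge is visited
    once.
    """
    if not nx.is_directed_acyclic_graph(dag.graph):
        raise ValueError("ontology is_a relation contains a cycle")
    genes_at: dict[str, set[str]] = {t: set() for t in dag.graph.nodes}
    for gene, terms in dag.annotations.items():
        for t in terms:
            genes_at[t].add(gene)
    # children come before parents under child -> parent edge orientation
    for term in nx.topological_sort(dag.graph):
        for parent in dag.graph.successors(term):
            genes_at[parent] |= genes_at[term]
    return {t: frozenset(g) for t, g in genes_at.items()}


def hypergeometric_test(k: int, K: int, n_sample: int, N: int
                        ) -> tuple[float, float, str]:
    """Exact tail probability and O/E ratio for a category overlap.

    ``k`` category genes observed in a sample of ``n_sample`` from a universe
    of ``N`` genes of which ``K`` are in the category. When O/E > 1 the upper
    tail P(X >= k) is reported; when O/E < 1 the lower tail P(X <= k); at
    O/E = 1 exactly, twice the smaller tail capped at 1.
    """
    if not (0 <= k <= min(K, n_sample) and K <= N and n_sample <= N):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n_sample={n_sample}, N={N}")
    expected = n_sample * K / N
    oe = k / expected if expected > 0 else np.nan
    dist = stats.hypergeom(N, K, n_sample)
    if expected == 0:
        return 1.0, oe, "none"
    if oe > 1:
        return float(dist.sf(k - 1)), float(oe), "enriched"
    if oe < 1:
        return float(dist.cdf(k)), float(oe), "underrepresented"
    p = 2 * min(dist.sf(k - 1), dist.cdf(k))
    return float(min(p, 1.0)), float(oe), "none"


def correct_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deduplicate_pathways(collection: GeneSetCollection) -> GeneSetCollection:
    """Unite entries with identical gene sets; names joined with '|'."""
    by_members: dict[frozenset[str], list[str]] = {}
    for name, genes in collection.sets.items():
        by_members.setdefault(genes, []).append(name)
    merged = {"|".join(sorted(names)): genes
              for genes, names in by_members.items()}
    return GeneSetCollection(sets=merged)


def enrich_gene_sample(sample: Iterable[str], universe: Iterable[str],
                       categories: Mapping[str, frozenset[str]] |
                       GeneSetCollection,
                       names: Mapping[str, str] | None = None,
                       alpha: float = 0.05,
                       min_category_size: int = 3) -> pd.DataFrame:
    """Test every category for over/under-representation in the sample.

    Categories are restricted to the universe before testing; those with
    fewer than ``min_category_size`` universe genes are skipped. One BH
    correction spans all tested categories; results are sorted by FDR, ties
    by p-value.
    """
    sample = frozenset(sample)
    universe = frozenset(universe)
    stray = sample - universe
    if stray:
        raise ValueError(
            f"sample genes outside the universe: {sorted(stray)[:5]}")
    if isinstance(categories, GeneSetCollection):
        categories = categories.sets
    names = names or {}
    N, n_sample = len(universe), len(sample)
    rows = []
    for cat, members in categories.items():
        in_universe = frozenset(members) & universe
        K = len(in_universe)
        if K < min_category_size:
            continue
        k = len(in_universe & sample)
        p, oe, direction = hypergeometric_test(k, K, n_sample, N)
        rows.append((cat, names.get(cat, cat), k, n_sample * K / N, oe,
                     direction, p))
    df = pd.DataFrame(rows, columns=["category", "name", "n_observed",
                                     "n_expected", "oe_ratio", "direction",
                                     "p_value"])
    if len(df):
        df["fdr"] = correct_fdr(df["p_value"])
        df["significant"] = df["fdr"] <= alpha
        df = df.sort_values(["fdr", "p_value", "category"],
                            kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df
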