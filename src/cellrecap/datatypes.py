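"""Core in-memory containers shared by every stage of the analysis.

The pipeline contrasts gene-group expression between cell populations while
controlling for cell-cycle activity, so the containers here carry exactly
what those contrasts need: a genes x cells expression matrix with population
labels, a gene -> phylostratum (evolutionary age class) map, named gene-set
collections, and an ontology DAG with gene annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: The 17 phylostrata used for human gene dating, oldest first.
STRATUM_NAMES: tuple[str, ...] = (
    "cellular organisms",
    "Eukaryota",
    "Opisthokonta",
    "Metazoa",
    "Eumetazoa",
    "Bilateria",
    "Chordata",
    "Vertebrata",
    "Euteleostomi",
    "Tetrapoda",
    "Amniota",
    "Mammalia",
    "Theria",
    "Eutheria",
    "Boreoeutheria",
    "Primates",
    "Hominidae",
)

N_STRATA: int = len(STRATUM_NAMES)


@dataclass
class ExpressionMatrix:
    """Non-negative, linear-scale expression values (genes x cells) plus labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with cell ids as columns; linear scale
        (log transforms are applied internally by downstream stages).
    cell_labels
        Series mapping every cell id to its population / stage label.
    """

    values: pd.DataFrame
    cell_labels: pd.Series

    def __post_init__(self) -> None:
        dup_genes = self.values.index[self.values.index.duplicated()]
        if len(dup_genes):
            raise ValueError(f"duplicate gene ids: {sorted(set(dup_genes))}")
        dup_cells = self.values.columns[self.values.columns.duplicated()]
        if len(dup_cells):
            raise ValueError(f"duplicate cell ids: {sorted(set(dup_cells))}")
        vals = self.values.to_numpy()
        if vals.size and (vals < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value (gene {bad!r})")
        missing = [c for c in self.values.columns if c not in self.cell_labels.index]
        if missing:
            raise ValueError(f"cells without a population label: {missing}")
        # keep labels aligned to matrix column order
        self.cell_labels = self.cell_labels.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.cell_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def cells_in(self, population: str) -> pd.Index:
        """Cell ids carrying the given label."""
        mask = self.cell_labels == population
        if not mask.any():
            raise KeyError(f"no cells labeled {population!r}")
        return self.cell_labels.index[mask]


@dataclass
class PhylostratumMap:
    """Gene -> phylostratum (1..17) assignment with the UC/MC partition.

    Unicellular-origin (UC) genes are those from strata ``1..uc_max_stratum``;
    everything later is multicellular-origin (MC). The boundary defaults to 2
    (stratum 3, Opisthokonta, sits on the unicellular/multicellular divide and
    is counted as MC by default) but is configurable.
    """

    strata: pd.Series
    uc_max_stratum: int = 2
    stratum_names: tuple[str, ...] = STRATUM_NAMES

    def __post_init__(self) -> None:
        s = self.strata.astype(int)
        bad = s[(s < 1) | (s > N_STRATA)]
        if len(bad):
            raise ValueError(
                f"strata outside 1..{N_STRATA} for genes {sorted(bad.index[:5])}"
            )
        if not 1 <= self.uc_max_stratum < N_STRATA:
            raise ValueError("uc_max_stratum must lie within 1..16")
        self.strata = s

    def stratum_genes(self, stratum: int) -> frozenset[str]:
        return frozenset(self.strata.index[self.strata == stratum])

    def uc_genes(self) -> frozenset[str]:
        return frozenset(self.strata.index[self.strata <= self.uc_max_stratum])

    def mc_genes(self) -> frozenset[str]:
        return frozenset(self.strata.index[self.strata > self.uc_max_stratum])

    def origin(self, gene: str) -> str:
        """'UC', 'MC' or 'unknown' for an arbitrary gene id."""
        if gene not in self.strata.index:
            return "unknown"
        return "UC" if self.strata[gene] <= self.uc_max_stratum else "MC"


@dataclass
class GeneSetCollection:
    """Named gene sets (signatures, pathways, cluster memberships, bins)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty}")
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_dict(cls, d: dict[str, set[str] | frozenset[str]], *,
                  drop_empty: bool = False) -> "GeneSetCollection":
        if drop_empty:
            empty = [k for k, v in d.items() if not v]
            if empty:
                warnings.warn(f"dropping empty gene sets: {empty}", stacklevel=2)
            d = {k: v for k, v in d.items() if v}
        return cls({k: frozenset(v) for k, v in d.items()})


@dataclass
class OntologyDAG:
    """Ontology terms with is_a edges (child -> parent) and direct annotations.

    ``graph`` nodes are term ids (node attribute ``name`` holds the label);
    an edge ``(child, parent)`` states child is_a parent. ``annotations`` maps
    gene id -> the set of terms the gene is *directly* annotated to; DAG
    propagation to ancestor terms is performed by the enrichment stage.
    """

    graph: nx.DiGraph
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise ValueError(f"ontology is_a relation contains a cycle: {cyc}")
        terms = set(self.graph.nodes)
        for gene, anns in self.annotations.items():
            unknown = set(anns) - terms
            if unknown:
                raise ValueError(
                    f"gene {gene!r} annotated to unknown terms {sorted(unknown)}"
                )
        self.annotations = {g: frozenset(a) for g, a in self.annotations.items()}

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def term_name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def roots(self) -> list[str]:
        """Terms with no parent (out-degree zero under child->parent edges)."""
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]
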