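"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are stored on the linear scale (dense TSV or MatrixMarket
triplet plus row/column name files), phylostrata and cell labels as 2-column
TSV, interaction edges as 3-column TSV, gene sets as GMT, and ontologies as a
minimal OBO subset (id / name / is_a stanzas) with a 2-column annotation TSV.
Every reader validates the invariants of the container it builds; every
writer round-trips through its reader up to 12 significant digits.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    N_STRATA,
    OntologyDAG,
    PhylostratumMap,
)

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_cell_labels(path: str | os.PathLike) -> pd.Series:
    """Read a 2-column TSV (cell_id, label) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"],
                     dtype=str)
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate cell id in labels file: {dup!r}")
    return df.set_index("cell_id")["label"].rename(None).rename_axis(None)


def write_cell_labels(labels: pd.Series, path: str | os.PathLike) -> None:
    labels.rename_axis("cell_id").rename("label").to_csv(
        path, sep="\t", header=False)


def read_expression(path: str | os.PathLike, labels_path: str | os.PathLike,
                    layout: str = "dense") -> ExpressionMatrix:
    """Read an expression matrix in ``dense`` or ``triplet`` layout.

    Dense: TSV, first column gene ids, header row of cell ids. Triplet: a
    MatrixMarket ``.mtx`` file listing nonzero entries, with sibling files
    ``<stem>.genes.tsv`` and ``<stem>.cells.tsv`` naming rows and columns.
    """
    labels = read_cell_labels(labels_path)
    if layout == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif layout == "triplet":
        path = Path(path)
        stem = path.with_suffix("")
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path))
        genes = pd.read_csv(f"{stem}.genes.tsv", header=None, dtype=str)[0]
        cells = pd.read_csv(f"{stem}.cells.tsv", header=None, dtype=str)[0]
        df = pd.DataFrame(mat.toarray(), index=genes.to_list(),
                          columns=cells.to_list())
    else:
        raise ValueError(f"unknown layout {layout!r} (expected dense|triplet)")
    return ExpressionMatrix(values=df.astype(float), cell_labels=labels)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike,
                     labels_path: str | os.PathLike,
                     layout: str = "dense") -> None:
    write_cell_labels(matrix.cell_labels, labels_path)
    if layout == "dense":
        matrix.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    elif layout == "triplet":
        path = Path(path)
        stem = path.with_suffix("")
        sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
        scipy.io.mmwrite(str(path), sparse, precision=12)
        pd.Series(matrix.gene_ids).to_csv(f"{stem}.genes.tsv", index=False,
                                          header=False)
        pd.Series(matrix.cell_ids).to_csv(f"{stem}.cells.tsv", index=False,
                                          header=False)
    else:
        raise ValueError(f"unknown layout {layout!r} (expected dense|triplet)")


# ---------------------------------------------------------------------------
# phylostrata
# ---------------------------------------------------------------------------

def read_phylostrata(path: str | os.PathLike, *,
                     uc_max_stratum: int = 2) -> PhylostratumMap:
    """Read a 2-column TSV (gene_id, stratum in 1..17)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "stratum"], dtype={"gene_id": str})
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id in strata file: {dup!r}")
    strata = df.set_index("gene_id")["stratum"].astype(int)
    out_of_range = strata[(strata < 1) | (strata > N_STRATA)]
    if len(out_of_range):
        gene = out_of_range.index[0]
        raise ValueError(
            f"stratum {out_of_range.iloc[0]} outside 1..{N_STRATA} "
            f"(gene {gene!r})")
    return PhylostratumMap(strata=strata, uc_max_stratum=uc_max_stratum)


def write_phylostrata(strata_map: PhylostratumMap,
                      path: str | os.PathLike) -> None:
    strata_map.strata.rename_axis("gene_id").to_csv(path, sep="\t",
                                                    header=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: per line, name, description, then >= 1 gene ids."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields "
                    "(need name, description and at least one gene)")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# interaction edges
# ---------------------------------------------------------------------------

def read_network_edges(path: str | os.PathLike) -> pd.DataFrame:
    """Read raw edges as a 3-column TSV (protein_a, protein_b, confidence).

    No filtering or deduplication happens here; that is the network stage's
    decision.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["protein_a", "protein_b", "confidence"],
                     dtype={"protein_a": str, "protein_b": str})
    df["confidence"] = df["confidence"].astype(float)
    return df


def write_network_edges(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    edges.to_csv(path, sep="\t", header=False, index=False,
                 float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# ontology (OBO subset) + annotations
# ---------------------------------------------------------------------------

def read_ontology(obo_path: str | os.PathLike,
                  annotations_path: str | os.PathLike | None = None
                  ) -> OntologyDAG:
    """Read an OBO(-subset) ontology and an optional gene->term TSV."""
    multigraph = obonet.read_obo(obo_path)
    # obonet orients edges child -> parent already; collapse the multigraph
    graph = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node, name=data.get("name", node))
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    annotations: dict[str, frozenset[str]] = {}
    if annotations_path is not None:
        df = pd.read_csv(annotations_path, sep="\t", header=None,
                         names=["gene_id", "term_id"], dtype=str)
        for gene, sub in df.groupby("gene_id"):
            annotations[gene] = frozenset(sub["term_id"])
    return OntologyDAG(graph=graph, annotations=annotations)


def write_ontology(dag: OntologyDAG, obo_path: str | os.PathLike,
                   annotations_path: str | os.PathLike | None = None) -> None:
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in dag.graph.nodes:
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.term_name(term)}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {dag.term_name(parent)}\n")
    if annotations_path is not None:
        with open(annotations_path, "w") as fh:
            for gene in sorted(dag.annotations):
                for term in sorted(dag.annotations[gene]):
                    fh.write(f"{gene}\t{term}\n")
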