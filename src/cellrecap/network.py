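"""Confidence-filtered interactome and one-step neighborhood composition.

Edges are kept only above a strict confidence threshold (default > 0.5, the
top half of the score range). For every protein the fraction of
multicellular-origin (MC) partners among its *dated* direct neighbors is
computed; unicellular-origin (UC) genes are then partitioned into four bins
of that MC fraction (cut points 0.25 / 0.5 / 0.75, lowest bin closed at
0.25), and symmetrically MC genes by their UC fraction. Cluster-membership
files (e.g. the UC giant cluster) stratify UC/MC genes into inside/outside
groups for contrast analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, PhylostratumMap

#: composition bin upper edges; lowest bin is [0, 0.25], others half-open
BIN_EDGES: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
BIN_LABELS: tuple[str, ...] = ("le_0.25", "0.25_0.5", "0.5_0.75", "0.75_1")


@dataclass
class InteractionNetwork:
    """Simple undirected graph with per-node origin labels.

    Node attribute ``origin`` is 'UC', 'MC' or 'unknown'; edge attribute
    ``confidence`` lies in (0, 1] and strictly exceeds ``threshold``.
    """

    graph: nx.Graph
    threshold: float

    def origin(self, node: str) -> str:
        return self.graph.nodes[node]["origin"]

    def nodes_with_origin(self, origin: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["origin"] == origin]


def build_network(edges: pd.DataFrame, strata: PhylostratumMap,
                  confidence_threshold: float = 0.5) -> InteractionNetwork:
    """Filter, deduplicate and label raw edge records.

    Edges with confidence strictly greater than the threshold are kept;
    duplicate undirected pairs collapse to their maximum confidence;
    self-loops are dropped. Nodes are labeled UC/MC from the strata map
    (genes absent from it are 'unknown').
    """
    conf = edges["confidence"].to_numpy(dtype=float)
    if len(conf) and ((conf <= 0) | (conf > 1)).any():
        bad = conf[(conf <= 0) | (conf > 1)][0]
        raise ValueError(f"confidence {bad} outside (0, 1]")
    graph = nx.Graph()
    for a, b, c in edges.itertuples(index=False):
        if a == b or c <= confidence_threshold:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], c)
        else:
            graph.add_edge(a, b, confidence=float(c))
    for node in graph.nodes:
        graph.nodes[node]["origin"] = strata.origin(node)
    return InteractionNetwork(graph=graph, threshold=confidence_threshold)


def neighborhood_fractions(net: InteractionNetwork,
                           min_neighbors: int = 3) -> pd.DataFrame:
    """Per node: dated-neighbor counts and MC fraction among dated neighbors.

    ``mc_fraction`` is NaN (undefined) for nodes with fewer than
    ``min_neighbors`` dated neighbors; undated ('unknown') neighbors are
    excluded from the denominator.
    """
    rows = []
    for node in net.graph.nodes:
        nbrs = list(net.graph.neighbors(node))
        origins = [net.origin(x) for x in nbrs]
        n_dated = sum(o != "unknown" for o in origins)
        n_mc = sum(o == "MC" for o in origins)
        f = n_mc / n_dated if n_dated >= min_neighbors else np.nan
        rows.append((node, net.origin(node), len(nbrs), n_dated, f))
    df = pd.DataFrame(rows, columns=["node", "origin", "n_neighbors",
                                     "n_dated", "mc_fraction"])
    df["uc_fraction"] = 1.0 - df["mc_fraction"]
    return df.set_index("node")


def _bin_index(fraction: float) -> int:
    """Bin a fraction at cut points 0.25/0.5/0.75; lowest bin closed at 0.25."""
    for i, edge in enumerate(BIN_EDGES):
        if fraction <= edge:
            return i
    return len(BIN_EDGES) - 1


def bin_by_composition(profile: pd.DataFrame,
                       net: InteractionNetwork) -> GeneSetCollection:
    """Partition UC genes by MC-neighborhood fraction (and MC genes by UC
    fraction) into the four composition bins.

    Returns sets named ``UC_mc_<bin>`` and ``MC_uc_<bin>``; genes whose
    fraction is undefined are left out. Empty bins are dropped with a
    warning.
    """
    sets: dict[str, set[str]] = {
        **{f"UC_mc_{lab}": set() for lab in BIN_LABELS},
        **{f"MC_uc_{lab}": set() for lab in BIN_LABELS},
    }
    for node, row in profile.iterrows():
        if np.isnan(row["mc_fraction"]):
            continue
        if row["origin"] == "UC":
            sets[f"UC_mc_{BIN_LABELS[_bin_index(row['mc_fraction'])]}"].add(node)
        elif row["origin"] == "MC":
            sets[f"MC_uc_{BIN_LABELS[_bin_index(row['uc_fraction'])]}"].add(node)
    if all(not members for members in sets.values()):
        warnings.warn("no node has a defined neighborhood fraction; "
                      "all composition bins are empty", stacklevel=2)
    return GeneSetCollection.from_dict(sets, drop_empty=True)


def cluster_contrast_groups(strata: PhylostratumMap,
                            clusters: GeneSetCollection,
                            cluster_name: str | None = None
                            ) -> GeneSetCollection:
    """The six contrast groups around a giant-cluster membership file.

    UC-all, MC-all, and UC/MC split by membership in the named cluster
    (default: the collection's first set). Empty groups are flagged with a
    warning and dropped.
    """
    if cluster_name is None:
        cluster_name = clusters.names()[0]
    cluster = clusters[cluster_name]
    uc, mc = strata.uc_genes(), strata.mc_genes()
    groups = {
        "UC_all": set(uc),
        "MC_all": set(mc),
        f"UC_in_{cluster_name}": set(uc & cluster),
        f"UC_outside_{cluster_name}": set(uc - cluster),
        f"MC_in_{cluster_name}": set(mc & cluster),
        f"MC_outside_{cluster_name}": set(mc - cluster),
    }
    return GeneSetCollection.from_dict(groups, drop_empty=True)
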