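"""Module detection, module completeness, and per-sample network topology.

The metaweb's co-occurrence layer is partitioned into modules with the
walktrap algorithm (short random walks, agglomerative merging, cut at the
maximum-modularity level).  Each individual sample then induces a timepoint
network — the subgraphs of both layers on the ASVs present in that sample —
for which we track Newman-Girvan modularity, global transitivity and the
co-exclusion proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .io import ConsistencyError
from .metaweb import Metaweb, OccurrenceMatrix


@dataclass
class ModulePartition:
    """Node -> module label map with the partition's modularity Q.

    Labels are contiguous integers starting at 0.
    """

    labels: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def module_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.labels.items():
            out.setdefault(m, []).append(node)
        return {m: sorted(v) for m, v in out.items()}


@dataclass
class TimepointNetwork:
    """Induced subgraphs of both metaweb layers for one sample."""

    sample_id: str
    nodes: list[str]
    cooccurrence_edges: list[tuple[str, str]]
    coexclusion_edges: list[tuple[str, str]]
    metrics: dict[str, float] = field(default_factory=dict)
    null_z: dict[str, float] = field(default_factory=dict)

    def cooccurrence_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.cooccurrence_edges)
        return g

    def coexclusion_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.coexclusion_edges)
        return g


# ---------------------------------------------------------------------------
# igraph helpers (fast path shared with the null models)
# ---------------------------------------------------------------------------

def _igraph_from_edges(n: int, edges: list[tuple[int, int]]) -> ig.Graph:
    return ig.Graph(n=n, edges=edges, directed=False)


def _walktrap_partition(g: ig.Graph, walk_length: int = 4) -> tuple[np.ndarray, float]:
    """Walktrap membership and modularity at the maximum-modularity cut.

    Isolated nodes end up in singleton modules.  Returns (membership, Q);
    Q is nan for an edgeless graph.
    """
    if g.ecount() == 0:
        return np.arange(g.vcount()), float("nan")
    dendro = g.community_walktrap(steps=walk_length)
    clustering = dendro.as_clustering()
    return np.asarray(clustering.membership), float(clustering.modularity)


def _transitivity(g: ig.Graph) -> float:
    """Global transitivity; nan when the graph has no connected triples."""
    return float(g.transitivity_undirected(mode="nan"))


def _avg_local_clustering(g: ig.Graph) -> float:
    vals = g.transitivity_local_undirected(mode="nan")
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _graph_metrics(g_co: ig.Graph, g_ex: ig.Graph, walk_length: int = 4,
                   clustering_mode: str = "transitivity") -> dict[str, float]:
    """The three per-sample metrics on a pair of layer graphs."""
    n_co = g_co.ecount()
    n_ex = g_ex.ecount()
    if g_co.vcount() >= 2 and n_co > 0:
        _, q = _walktrap_partition(g_co, walk_length)
    else:
        q = float("nan")
    if clustering_mode == "average_local":
        cc = _avg_local_clustering(g_co)
    else:
        cc = _transitivity(g_co)
    prop = n_ex / (n_ex + n_co) if (n_ex + n_co) > 0 else float("nan")
    return {"modularity": q, "clustering": cc, "coexclusion_proportion": prop}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def detect_modules(metaweb: Metaweb, walk_length: int = 4, seed: int | None = None) -> ModulePartition:
    """Walktrap modules of the co-occurrence layer.

    Node order is the sorted ASV ids, making the result deterministic.
    ``seed`` is accepted for interface uniformity; walktrap itself is
    deterministic.  Nodes isolated in the co-occurrence layer (only
    co-exclusion edges) become singleton modules.
    """
    nodes = sorted(metaweb.nodes)
    if not nodes:
        return ModulePartition(labels={}, modularity=float("nan"))
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in metaweb.cooccurrence]
    g = _igraph_from_edges(len(nodes), edges)
    membership, q = _walktrap_partition(g, walk_length)
    # relabel to contiguous integers ordered by first appearance
    relabel: dict[int, int] = {}
    labels = {}
    for node, m in zip(nodes, membership):
        if m not in relabel:
            relabel[m] = len(relabel)
        labels[node] = relabel[m]
    return ModulePartition(labels=labels, modularity=q)


def modularity(graph: nx.Graph, partition: dict[str, int]) -> float:
    """Newman-Girvan Q of a given partition; nan for an edgeless graph."""
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ConsistencyError(f"nodes missing from partition: {missing[:5]}")
    if graph.number_of_edges() == 0:
        return float("nan")
    groups: dict[int, set] = {}
    for n in graph.nodes:
        groups.setdefault(partition[n], set()).add(n)
    return float(nx.community.modularity(graph, list(groups.values())))


def clustering_coefficient(graph: nx.Graph, mode: str = "transitivity") -> float:
    """Global transitivity (3 x triangles / triples); nan when no triples.

    ``mode='average_local'`` returns the mean local clustering coefficient
    over nodes of degree >= 2 instead.
    """
    g = ig.Graph.TupleList(graph.edges(), directed=False) if graph.number_of_edges() else ig.Graph(n=graph.number_of_nodes())
    if mode == "average_local":
        return _avg_local_clustering(g)
    return _transitivity(g)


def coexclusion_proportion(tp: TimepointNetwork) -> float:
    """Share of a sample's induced edges that are co-exclusions."""
    n_ex = len(tp.coexclusion_edges)
    n_co = len(tp.cooccurrence_edges)
    if n_ex + n_co == 0:
        return float("nan")
    return n_ex / (n_ex + n_co)


def node_coexclusion_proportion(tp: TimepointNetwork) -> float:
    """Node-based variant: nodes touching >=1 co-exclusion edge over all
    present metaweb nodes."""
    if not tp.nodes:
        return float("nan")
    touched = set()
    for a, b in tp.coexclusion_edges:
        touched.add(a)
        touched.add(b)
    return len(touched) / len(tp.nodes)


def module_completeness(partition: ModulePartition, occ: OccurrenceMatrix) -> pd.DataFrame:
    """Proportion of each module's nodes present in each sample.

    Returns a sample x module DataFrame; columns are module labels.
    """
    members = partition.module_members()
    idx = {a: i for i, a in enumerate(occ.asv_ids)}
    unknown = [n for n in partition.labels if n not in idx]
    if unknown:
        raise ConsistencyError(f"partition nodes absent from occurrence matrix: {unknown[:5]}")
    out = {}
    for m, nodes in sorted(members.items()):
        rows = [idx[n] for n in nodes]
        out[m] = occ.presence[rows, :].mean(axis=0)
    return pd.DataFrame(out, index=occ.sample_ids)


def extract_timepoint_networks(metaweb: Metaweb, occ: OccurrenceMatrix,
                               walk_length: int = 4,
                               fresh_partition: bool = True,
                               partition: Optional[ModulePartition] = None,
                               clustering_mode: str = "transitivity") -> list[TimepointNetwork]:
    """One timepoint network per sample, with its topology metrics.

    Modularity is scored on a fresh walktrap partition of the induced
    co-occurrence subgraph by default; with ``fresh_partition=False`` the
    metaweb partition is inherited and scored instead.  Samples with fewer
    than two present metaweb nodes get nan metrics.
    """
    nodes = sorted(metaweb.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    co_edges = [(index[a], index[b]) for a, b in metaweb.cooccurrence]
    ex_edges = [(index[a], index[b]) for a, b in metaweb.coexclusion]
    asv_row = {a: i for i, a in enumerate(occ.asv_ids)}
    rows = np.array([asv_row.get(n, -1) for n in nodes])
    if partition is None and not fresh_partition:
        partition = detect_modules(metaweb, walk_length)

    results = []
    co_arr = np.asarray(co_edges, dtype=int).reshape(-1, 2)
    ex_arr = np.asarray(ex_edges, dtype=int).reshape(-1, 2)
    for s_col, sample_id in enumerate(occ.sample_ids):
        present_mask = np.zeros(len(nodes), dtype=bool)
        valid = rows >= 0
        present_mask[valid] = occ.presence[rows[valid], s_col]
        present_idx = np.flatnonzero(present_mask)
        local = -np.ones(len(nodes), dtype=int)
        local[present_idx] = np.arange(len(present_idx))
        tp_nodes = [nodes[i] for i in present_idx]

        def induced(arr):
            if arr.size == 0 or present_idx.size == 0:
                return np.empty((0, 2), dtype=int)
            keep = present_mask[arr[:, 0]] & present_mask[arr[:, 1]]
            return np.stack([local[arr[keep, 0]], local[arr[keep, 1]]], axis=1) if keep.any() else np.empty((0, 2), dtype=int)

        co_sub = induced(co_arr)
        ex_sub = induced(ex_arr)
        tp = TimepointNetwork(
            sample_id=sample_id,
            nodes=tp_nodes,
            cooccurrence_edges=[(tp_nodes[i], tp_nodes[j]) for i, j in co_sub],
            coexclusion_edges=[(tp_nodes[i], tp_nodes[j]) for i, j in ex_sub],
        )
        if len(tp_nodes) < 2:
            tp.metrics = {"modularity": float("nan"), "clustering": float("nan"),
                          "coexclusion_proportion": float("nan")}
        else:
            g_co = _igraph_from_edges(len(tp_nodes), [tuple(e) for e in co_sub])
            g_ex = _igraph_from_edges(len(tp_nodes), [tuple(e) for e in ex_sub])
            if fresh_partition or partition is None:
                tp.metrics = _graph_metrics(g_co, g_ex, walk_length, clustering_mode)
            else:
                tp.metrics = _graph_metrics(g_co, g_ex, walk_length, clustering_mode)
                if g_co.ecount() > 0:
                    tp.metrics["modularity"] = modularity(
                        tp.cooccurrence_graph(), {n: partition.labels[n] for n in tp_nodes}
                    )
        tp.metrics["node_coexclusion_proportion"] = node_coexclusion_proportion(tp)
        results.append(tp)
    return results


def topology_table(networks: list[TimepointNetwork]) -> pd.DataFrame:
    rows = []
    for tp in networks:
        row = {"sample_id": tp.sample_id, "n_nodes": len(tp.nodes),
               "n_cooccurrence": len(tp.cooccurrence_edges),
               "n_coexclusion": len(tp.coexclusion_edges)}
        row.update(tp.metrics)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
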