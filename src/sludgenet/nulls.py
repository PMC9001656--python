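"""Stochastic-block-model nulls for timepoint-network metrics.

A plain Bernoulli SBM is fitted once per layer on the metaweb, with blocks
given by the walktrap module partition: the edge probability between blocks
k and l is the observed edge count divided by the number of possible pairs.
Null timepoint networks are then drawn on fresh synthetic nodes, picking the
same number of nodes from each module as observed in the sample, and the
same topology metrics are computed on each draw; z-scores standardise the
observed metric against the resulting null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (ModulePartition, TimepointNetwork, _graph_metrics,
                       _igraph_from_edges, extract_timepoint_networks)
from .metaweb import Metaweb, OccurrenceMatrix

METRICS = ("modularity", "clustering", "coexclusion_proportion")


@dataclass
class BlockModel:
    """Symmetric block-pair edge-probability matrices, one per layer."""

    block_labels: list[int]
    block_sizes: np.ndarray
    p_cooccurrence: np.ndarray
    p_coexclusion: np.ndarray

    def __post_init__(self) -> None:
        for P in (self.p_cooccurrence, self.p_coexclusion):
            if not np.allclose(P, P.T):
                raise ValueError("block probability matrix must be symmetric")
            if P.size and (P.min() < 0 or P.max() > 1):
                raise ValueError("block probabilities must lie in [0, 1]")


def fit_sbm(metaweb: Metaweb, partition: ModulePartition) -> BlockModel:
    """Moment-matching SBM fit: p_kl = observed edges / possible pairs.

    Within-block pairs count n_k (n_k - 1) / 2; a block of size 1 has no
    within pairs and its within-block probability is defined as 0.
    """
    blocks = sorted(set(partition.labels.values()))
    b_index = {b: i for i, b in enumerate(blocks)}
    K = len(blocks)
    sizes = np.zeros(K, dtype=int)
    for node in metaweb.nodes:
        sizes[b_index[partition.labels[node]]] += 1

    def layer_matrix(edges) -> np.ndarray:
        counts = np.zeros((K, K))
        for a, b in edges:
            ka, kb = b_index[partition.labels[a]], b_index[partition.labels[b]]
            counts[ka, kb] += 1
            if ka != kb:
                counts[kb, ka] += 1
        possible = np.outer(sizes, sizes).astype(float)
        np.fill_diagonal(possible, sizes * (sizes - 1) / 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(possible > 0, counts / np.maximum(possible, 1e-300), 0.0)
        return P

    return BlockModel(
        block_labels=blocks,
        block_sizes=sizes,
        p_cooccurrence=layer_matrix(metaweb.cooccurrence),
        p_coexclusion=layer_matrix(metaweb.coexclusion),
    )


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    return _TRIU_CACHE[n]


def _draw_layer_edges(P: np.ndarray, sizes: np.ndarray, offsets: np.ndarray,
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    """Bernoulli-SBM edges via per-block-pair binomial counts."""
    edges: list[tuple[int, int]] = []
    K = len(sizes)
    for k in range(K):
        nk = sizes[k]
        if nk >= 2 and P[k, k] > 0:
            iu, ju = _triu(nk)
            m = len(iu)
            e = rng.binomial(m, P[k, k])
            if e:
                pick = rng.choice(m, size=e, replace=False)
                edges.extend(zip(offsets[k] + iu[pick], offsets[k] + ju[pick]))
        for l in range(k + 1, K):
            nl = sizes[l]
            m = nk * nl
            if m and P[k, l] > 0:
                e = rng.binomial(m, P[k, l])
                if e:
                    pick = rng.choice(m, size=e, replace=False)
                    edges.extend(zip(offsets[k] + pick // nl, offsets[l] + pick % nl))
    return edges


def sample_null_timepoint(block_model: BlockModel, module_counts: dict[int, int],
                          rng: np.random.Generator, walk_length: int = 4,
                          clustering_mode: str = "transitivity") -> dict[str, float]:
    """Draw one synthetic timepoint network and return its metrics.

    ``module_counts`` maps block label -> number of nodes to generate; the
    nodes are fresh (not subsampled from the metaweb).
    """
    labels = block_model.block_labels
    sizes = np.array([module_counts.get(b, 0) for b in labels], dtype=int)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n = int(sizes.sum())
    if n < 2:
        return {m: float("nan") for m in METRICS}
    co = _draw_layer_edges(block_model.p_cooccurrence, sizes, offsets, rng)
    ex = _draw_layer_edges(block_model.p_coexclusion, sizes, offsets, rng)
    g_co = _igraph_from_edges(n, co)
    g_ex = _igraph_from_edges(n, ex)
    return _graph_metrics(g_co, g_ex, walk_length, clustering_mode)


def observed_module_counts(tp: TimepointNetwork, partition: ModulePartition) -> dict[int, int]:
    counts: dict[int, int] = {}
    for node in tp.nodes:
        m = partition.labels[node]
        counts[m] = counts.get(m, 0) + 1
    return counts


def null_distributions(metaweb: Metaweb, partition: ModulePartition,
                       occ: OccurrenceMatrix, n_iter: int = 1000,
                       seed: int = 0, walk_length: int = 4,
                       clustering_mode: str = "transitivity",
                       networks: list[TimepointNetwork] | None = None) -> pd.DataFrame:
    """Per-sample null mean/sd/z for the three topology metrics.

    Undefined draws (e.g. an edgeless null network) are excluded from the
    null mean and sd rather than imputed; a null sd of 0 leaves the z-score
    undefined (nan).
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 for a null sd")
    rng = np.random.default_rng(seed)
    bm = fit_sbm(metaweb, partition)
    if networks is None:
        networks = extract_timepoint_networks(metaweb, occ, walk_length,
                                              clustering_mode=clustering_mode)
    rows = []
    for tp in networks:
        counts = observed_module_counts(tp, partition)
        draws = {m: [] for m in METRICS}
        for _ in range(n_iter):
            vals = sample_null_timepoint(bm, counts, rng, walk_length, clustering_mode)
            for m in METRICS:
                if np.isfinite(vals[m]):
                    draws[m].append(vals[m])
        row = {"sample_id": tp.sample_id}
        for m in METRICS:
            obs = tp.metrics.get(m, float("nan"))
            arr = np.asarray(draws[m])
            mean = float(arr.mean()) if arr.size else float("nan")
            sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
            z = (obs - mean) / sd if np.isfinite(obs) and np.isfinite(sd) and sd > 0 else float("nan")
            tp.null_z[m] = z
            row.update({f"{m}_obs": obs, f"{m}_null_mean": mean,
                        f"{m}_null_sd": sd, f"{m}_z": z})
        row["n_iterations"] = n_iter
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
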