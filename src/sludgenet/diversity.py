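"""Hill-number alpha-diversity and Bray-Curtis beta-diversity.

Hill numbers ^qD are effective species counts: q=0 is richness, q=1 the
exponential of Shannon entropy, q=2 the inverse Simpson concentration.  The
phylogenetic analogue ^qpD follows the branch-segment formulation: each
branch carries the summed relative abundance of its descendant tips, and
diversity is an effective number of equally abundant lineages per unit of
abundance-weighted tree depth (for q=0 this is Faith's PD divided by the
mean depth).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .io import CountMatrix, Phylogeny

HILL_ORDERS = (0.0, 1.0, 2.0)


def hill_number(abundances: np.ndarray, q: float) -> float:
    """Effective number of species of order q.

    ^qD = (sum p_i^q)^(1/(1-q)) for q != 1; the q->1 limit is
    exp(-sum p_i ln p_i).  All-zero input yields nan.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or a.sum() <= 0:
        return float("nan")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    p = a[a > 0] / a.sum()
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def _branch_segments(phylogeny: Phylogeny, tip_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and tip-incidence of every edge with positive length.

    Returns (lengths, incidence) where incidence[b, i] is True when tip i
    descends through branch b.  The root edge is excluded.
    """
    tree = phylogeny.tree
    pos = {label: i for i, label in enumerate(tip_order)}
    lengths = []
    rows = []
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        mask = np.zeros(len(tip_order), dtype=bool)
        for leaf in node.leaf_iter():
            idx = pos.get(leaf.taxon.label)
            if idx is not None:
                mask[idx] = True
        if node.edge.length and mask.any():
            lengths.append(float(node.edge.length))
            rows.append(mask)
    if not rows:
        return np.zeros(0), np.zeros((0, len(tip_order)), dtype=bool)
    return np.asarray(lengths), np.stack(rows)


def phylo_hill_number(abundances: np.ndarray, phylogeny: Phylogeny,
                      tip_order: list[str], q: float = 0.0) -> float:
    """Phylogenetic Hill number ^qpD over branch segments.

    With branch lengths L_b, branch abundances a_b (sum of descendant tip
    relative abundances) and mean depth T = sum L_b a_b:

        ^qpD = [ sum_b (L_b / T) a_b^q ]^(1/(1-q)),   q != 1,

    with the entropy limit at q=1.  For q=0 this reduces to Faith's PD of
    the present taxa divided by T.  A single present taxon returns 1 by
    convention.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size != len(tip_order):
        raise ValueError("abundance vector does not match tip order")
    if a.sum() <= 0:
        return float("nan")
    if (a > 0).sum() == 1:
        return 1.0
    p = a / a.sum()
    lengths, incidence = _branch_segments(phylogeny, tip_order)
    branch_ab = incidence @ p
    keep = branch_ab > 0
    L = lengths[keep]
    ab = branch_ab[keep]
    T = float(L @ ab)
    if T <= 0:
        return float("nan")
    w = L / T
    if q == 1.0:
        return float(np.exp(-np.sum(w * ab * np.log(ab))))
    return float(np.sum(w * ab ** q) ** (1.0 / (1.0 - q)))


def alpha_diversity_table(counts: CountMatrix, phylogeny: Phylogeny | None = None) -> pd.DataFrame:
    """Per-sample ^0D, ^1D, ^2D and (when a tree is given) ^0pD."""
    rows = {}
    for q in HILL_ORDERS:
        rows[f"hill_q{int(q)}"] = [
            hill_number(counts.counts[:, s], q) for s in range(counts.n_samples)
        ]
    if phylogeny is not None:
        phylogeny.check_covers(counts.asv_ids)
        lengths, incidence = _branch_segments(phylogeny, counts.asv_ids)
        vals = []
        for s in range(counts.n_samples):
            a = counts.counts[:, s].astype(float)
            if a.sum() <= 0:
                vals.append(float("nan"))
                continue
            if (a > 0).sum() == 1:
                vals.append(1.0)
                continue
            p = a / a.sum()
            ab = incidence @ p
            keep = ab > 0
            T = float(lengths[keep] @ ab[keep])
            vals.append(float(np.sum(lengths[keep] * (ab[keep] ** 0)) / T) if T > 0 else float("nan"))
        rows["phylo_hill_q0"] = vals
    return pd.DataFrame(rows, index=counts.sample_ids)


def bray_curtis(counts: CountMatrix) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity.

    BC(s, t) = 1 - 2 sum_i min(a_is, a_it) / (sum_i a_is + sum_i a_it);
    a pair of all-zero samples is undefined (nan).
    """
    if counts.n_samples < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    X = counts.counts.T.astype(float)
    tot = X.sum(axis=1)
    n = len(tot)
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(X[i], X[i + 1:]).sum(axis=1)
        denom = tot[i] + tot[i + 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, 1.0 - 2.0 * shared / np.maximum(denom, 1e-300), np.nan)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return pd.DataFrame(d, index=counts.sample_ids, columns=counts.sample_ids)
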