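"""Occurrence filtering and the probabilistic co-occurrence metaweb.

Pairwise association follows the exact hypergeometric model: given two taxa
present in ``n_a`` and ``n_b`` of ``N`` samples, the number of shared samples
under random, independent placement is hypergeometric,

    P(J = j) = C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b).

The probability of co-occurrence is the strict lower tail P(J < j_obs): a
value above the significance level (default 0.95) means the pair shares more
samples than essentially all random placements, i.e. co-occurrence; the
symmetric upper tail P(J > j_obs) above the level flags co-exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import hypergeom

from .io import CountMatrix, ConsistencyError


@dataclass
class OccurrenceMatrix:
    """Binary presence matrix plus per-ASV timepoint occupancy.

    ``presence`` is ASV x sample boolean; ``timepoint_occupancy`` counts the
    timepoints in which the ASV is present in at least one replicate.
    """

    asv_ids: list[str]
    sample_ids: list[str]
    presence: np.ndarray
    timepoint_occupancy: np.ndarray
    timepoints: np.ndarray  # 1-based timepoint index per sample column
    n_timepoints: int

    @property
    def sample_occupancy(self) -> np.ndarray:
        """Number of individual samples each ASV is present in."""
        return self.presence.sum(axis=1)


@dataclass
class PairAssociation:
    asv_a: str
    asv_b: str
    n_a: int
    n_b: int
    j_obs: int
    p_lt: float
    p_gt: float
    classification: str  # cooccurrence | coexclusion | none


@dataclass
class Metaweb:
    """Two undirected edge layers over the filtered ASV set.

    ``cooccurrence`` and ``coexclusion`` map sorted id pairs to the tail
    probability that made them significant.  ``nodes`` holds only ASVs with
    at least one significant edge.  The layers are disjoint by construction.
    """

    nodes: list[str]
    cooccurrence: dict[tuple[str, str], float]
    coexclusion: dict[tuple[str, str], float]
    partition: Optional[object] = None
    pairs: Optional["np.ndarray"] = None  # full test table, see build_metaweb

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degree_in_layer(self, layer: str) -> dict[str, int]:
        edges = self.cooccurrence if layer == "cooccurrence" else self.coexclusion
        deg = {n: 0 for n in self.nodes}
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def occurrence_matrix(counts: CountMatrix, presence_threshold: int = 0) -> OccurrenceMatrix:
    """Derive presence and timepoint occupancy from a count matrix."""
    pres = counts.presence(presence_threshold)
    tps = counts.timepoints
    unique_tps = np.unique(tps)
    # present at a timepoint if present in >=1 of its replicate samples
    per_tp = np.stack([pres[:, tps == t].any(axis=1) for t in unique_tps], axis=1)
    return OccurrenceMatrix(
        asv_ids=list(counts.asv_ids),
        sample_ids=list(counts.sample_ids),
        presence=pres,
        timepoint_occupancy=per_tp.sum(axis=1),
        timepoints=tps,
        n_timepoints=len(unique_tps),
    )


def filter_by_occurrence(counts: CountMatrix, presence_threshold: int = 0) -> CountMatrix:
    """Keep ASVs present in more than one, but not in every, timepoint.

    Occupancy is counted at the timepoint level (present in any replicate).
    The sample set is unchanged.
    """
    if counts.n_timepoints < 2:
        raise ConsistencyError("occurrence filter needs at least 2 timepoints")
    occ = occurrence_matrix(counts, presence_threshold)
    t = occ.timepoint_occupancy
    keep = (t > 1) & (t < occ.n_timepoints)
    kept_ids = [a for a, k in zip(counts.asv_ids, keep) if k]
    return counts.subset_asvs(kept_ids)


def pair_tail_probabilities(n_a: int, n_b: int, j_obs: int, N: int) -> tuple[float, float]:
    """Strict tail probabilities of the hypergeometric co-occurrence model.

    Returns ``(p_lt, p_gt)`` with ``p_lt = P(J < j_obs)`` and
    ``p_gt = P(J > j_obs)`` for J ~ Hypergeometric(N, n_a, n_b).
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError("occupancies must lie in [0, N]")
    lo = max(0, n_a + n_b - N)
    hi = min(n_a, n_b)
    if not lo <= j_obs <= hi:
        raise ValueError(f"j_obs={j_obs} outside feasible range [{lo}, {hi}]")
    rv = hypergeom(N, n_a, n_b)
    p_lt = float(rv.cdf(j_obs - 1)) if j_obs > lo else 0.0
    p_gt = float(rv.sf(j_obs)) if j_obs < hi else 0.0
    return p_lt, p_gt


def classify_pair(p_lt: float, p_gt: float, support_size: int,
                  significance: float = 0.95, strict_tail: bool = True) -> str:
    """Classify one pair given its tail probabilities.

    Pairs whose feasible support is a single point are never significant.
    With ``strict_tail`` (default) the strict tails computed by
    :func:`pair_tail_probabilities` are compared with >=; the alternative
    uses inclusive tails, i.e. requires the strict tail plus the point mass
    to stay below 1 - significance on the opposite side.
    """
    if support_size <= 1:
        return "none"
    if strict_tail:
        if p_lt >= significance:
            return "cooccurrence"
        if p_gt >= significance:
            return "coexclusion"
    else:
        # inclusive reading: P(J <= j_obs) >= significance
        p_point = 1.0 - p_lt - p_gt
        if p_lt + p_point >= significance and p_lt > p_gt:
            return "cooccurrence"
        if p_gt + p_point >= significance and p_gt > p_lt:
            return "coexclusion"
    return "none"


def build_metaweb(occ: OccurrenceMatrix, significance: float = 0.95,
                  strict_tail: bool = True) -> Metaweb:
    """Test every unordered ASV pair and assemble the two-layer metaweb.

    Association is evaluated over individual samples (every replicate is a
    sample), not pooled timepoints.  Nodes without any significant edge are
    excluded from the metaweb node set.
    """
    ids = occ.asv_ids
    n = len(ids)
    if n < 2:
        return Metaweb(nodes=[], cooccurrence={}, coexclusion={})
    B = occ.presence.astype(np.int64)
    N = B.shape[1]
    nocc = B.sum(axis=1)
    J = B @ B.T

    iu, ju = np.triu_indices(n, k=1)
    n_a = nocc[iu]
    n_b = nocc[ju]
    j_obs = J[iu, ju]
    lo = np.maximum(0, n_a + n_b - N)
    hi = np.minimum(n_a, n_b)

    p_lt = hypergeom.cdf(j_obs - 1, N, n_a, n_b)
    p_gt = hypergeom.sf(j_obs, N, n_a, n_b)
    p_lt = np.where(j_obs > lo, p_lt, 0.0)
    p_gt = np.where(j_obs < hi, p_gt, 0.0)
    single_point = hi == lo

    if strict_tail:
        co = (p_lt >= significance) & ~single_point
        ex = (p_gt >= significance) & ~single_point
    else:
        p_point = 1.0 - p_lt - p_gt
        co = (p_lt + p_point >= significance) & (p_lt > p_gt) & ~single_point
        ex = (p_gt + p_point >= significance) & (p_gt > p_lt) & ~single_point
    ex &= ~co  # layers disjoint; lower tail takes precedence (cannot co-fire)

    cooc = {}
    coex = {}
    used = set()
    for k in np.flatnonzero(co):
        a, b = ids[iu[k]], ids[ju[k]]
        key = (a, b) if a < b else (b, a)
        cooc[key] = float(p_lt[k])
        used.update(key)
    for k in np.flatnonzero(ex):
        a, b = ids[iu[k]], ids[ju[k]]
        key = (a, b) if a < b else (b, a)
        coex[key] = float(p_gt[k])
        used.update(key)

    import pandas as pd

    pairs = pd.DataFrame({
        "asv_a": [ids[i] for i in iu],
        "asv_b": [ids[j] for j in ju],
        "n_a": n_a, "n_b": n_b, "j_obs": j_obs,
        "p_lt": p_lt, "p_gt": p_gt,
        "classification": np.where(co, "cooccurrence", np.where(ex, "coexclusion", "none")),
    })
    return Metaweb(nodes=sorted(used), cooccurrence=cooc, coexclusion=coex, pairs=pairs)
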