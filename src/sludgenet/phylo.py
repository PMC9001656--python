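"""Phylogenetic signal and community phylogenetic dispersion.

Habitat filtering is assessed in two steps.  First, phylogenetic signal in
environmental preference: each ASV's environmental optimum is its
abundance-weighted mean of the selected environmental variables, and a
Mantel correlogram relates optimum distances to patristic distances.
Second, per-sample dispersion: abundance-weighted mean pairwise distance
(MPD) and mean nearest-taxon distance (MNTD) are standardised against a
taxa-labels null that shuffles the tip labels of the distance matrix across
the full analysed pool; NRI = -SES(MPD) and NTI = -SES(MNTD), so positive
values indicate phylogenetic clustering and negative values overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConsistencyError, CountMatrix, Phylogeny, SampleMetadata

DEFAULT_OPTIMA_VARIABLES = ("temperature", "bod_in", "tn_in", "tp_in")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ConsistencyError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ConsistencyError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ConsistencyError("distance matrix diagonal must be zero")
        self.values = v

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        pos = {t: i for i, t in enumerate(self.ids)}
        missing = [t for t in ids if t not in pos]
        if missing:
            raise ConsistencyError(f"ids absent from distance matrix: {missing[:5]}")
        idx = np.array([pos[t] for t in ids])
        return DistanceMatrix(ids=list(ids), values=self.values[np.ix_(idx, idx)])


def cophenetic_distances(phylogeny: Phylogeny) -> DistanceMatrix:
    """Patristic (branch-length path) distances between all tip pairs."""
    tree = phylogeny.tree
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(ids=labels, values=d)


def environmental_optima(counts: CountMatrix, meta: SampleMetadata,
                         variables: list[str] | tuple[str, ...] = DEFAULT_OPTIMA_VARIABLES
                         ) -> pd.DataFrame:
    """Abundance-weighted mean of each environmental variable per ASV.

    optimum(i, v) = sum_s a_is E_sv / sum_s a_is.  ASVs with zero total
    abundance get nan.
    """
    table = meta.aligned_to(counts.sample_ids)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ConsistencyError(f"variables absent from metadata: {missing}")
    A = counts.counts.astype(float)
    tot = A.sum(axis=1)
    E = table[list(variables)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        opt = (A @ E) / tot[:, None]
    opt[tot == 0, :] = np.nan
    return pd.DataFrame(opt, index=counts.asv_ids, columns=list(variables))


def optima_distance_matrix(optima: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance on z-scored optima across variables."""
    X = optima.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    d = np.sqrt(np.nansum(diff ** 2, axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(optima.index), values=d)


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

def sturges_classes(values: np.ndarray) -> np.ndarray:
    """Class edges by Sturges' rule over the given pairwise distances."""
    k = int(np.ceil(np.log2(len(values)) + 1))
    return np.linspace(values.min(), values.max(), k + 1)


def mantel_correlogram(trait_dist: DistanceMatrix, phylo_dist: DistanceMatrix,
                       n_permutations: int = 999, seed: int = 0) -> pd.DataFrame:
    """Mantel correlogram of trait distance against phylogenetic distance.

    Phylogenetic distances are binned into Sturges classes; for each class
    the statistic is the (sign-flipped) Pearson correlation between the
    trait-distance vector and the class-membership indicator, so a positive
    value means trait similarity within the class.  Two-sided permutation
    p-values use tip-label shuffles, with progressive Bonferroni correction
    across classes (class i tested at level alpha / i, reported as p * i).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if trait_dist.ids != phylo_dist.ids:
        trait_dist = trait_dist.subset(phylo_dist.ids)
    n = len(phylo_dist.ids)
    iu = np.triu_indices(n, k=1)
    pvec = phylo_dist.values[iu]
    edges = sturges_classes(pvec)
    k = len(edges) - 1
    which = np.clip(np.digitize(pvec, edges[1:-1]), 0, k - 1)

    D = trait_dist.values
    rng = np.random.default_rng(seed)

    def class_stats(tvec: np.ndarray) -> np.ndarray:
        out = np.full(k, np.nan)
        tz = tvec - tvec.mean()
        tsd = tz.std()
        if tsd == 0:
            return out
        for c in range(k):
            ind = (which == c).astype(float)
            if ind.sum() in (0, len(ind)):
                continue
            iz = ind - ind.mean()
            out[c] = -float((tz * iz).mean() / (tsd * iz.std()))
        return out

    r_obs = class_stats(D[iu])
    exceed = np.zeros(k)
    valid = np.zeros(k)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = class_stats(D[np.ix_(perm, perm)][iu])
        ok = np.isfinite(r_perm) & np.isfinite(r_obs)
        exceed[ok] += np.abs(r_perm[ok]) >= np.abs(r_obs[ok])
        valid[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (exceed + 1) / (valid + 1)
    p[~np.isfinite(r_obs)] = np.nan

    rows = []
    for c in range(k):
        n_pairs = int((which == c).sum())
        p_adj = min(1.0, p[c] * (c + 1)) if np.isfinite(p[c]) else np.nan
        rows.append({
            "class_index": c,
            "d_lower": edges[c],
            "d_upper": edges[c + 1],
            "d_center": 0.5 * (edges[c] + edges[c + 1]),
            "n_pairs": n_pairs,
            "r": r_obs[c],
            "p": p[c],
            "p_adj": p_adj,
            "skipped": n_pairs == 0 or not np.isfinite(r_obs[c]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MPD / MNTD and SES dispersion
# ---------------------------------------------------------------------------

def mpd(abundances: np.ndarray, dist: np.ndarray, weighted: bool = True) -> float:
    """Abundance-weighted mean pairwise distance among present taxa."""
    a = np.asarray(abundances, dtype=float)
    present = a > 0
    if present.sum() < 2:
        return float("nan")
    f = a[present]
    if not weighted:
        f = np.ones_like(f)
    f = f / f.sum()
    d = dist[np.ix_(present, present)]
    num = f @ d @ f
    den = 1.0 - float(f @ f)
    return float(num / den)


def mntd(abundances: np.ndarray, dist: np.ndarray, weighted: bool = True) -> float:
    """Abundance-weighted mean distance to the nearest present neighbour."""
    a = np.asarray(abundances, dtype=float)
    present = a > 0
    if present.sum() < 2:
        return float("nan")
    f = a[present]
    if not weighted:
        f = np.ones_like(f)
    f = f / f.sum()
    d = dist[np.ix_(present, present)].copy()
    np.fill_diagonal(d, np.inf)
    return float(f @ d.min(axis=1))


def ses_dispersion(counts: CountMatrix, dist: DistanceMatrix, n_null: int = 999,
                   seed: int = 0, weighted: bool = True,
                   exhaustive: bool = False) -> pd.DataFrame:
    """Per-sample SES of MPD and MNTD under the taxa-labels null.

    The null shuffles the tip labels of the distance matrix across the full
    analysed taxon pool (all ASVs in ``counts``) and recomputes both metrics
    per sample; SES = (obs - null mean) / null sd with the sd taken over the
    ``n_null`` randomisations.  NRI = -SES(MPD), NTI = -SES(MNTD); both are
    nan where the null sd is 0 or a sample has fewer than two taxa.

    With ``exhaustive=True`` the null enumerates every label permutation
    instead of sampling (pools of at most 8 taxa), which makes the SES exact.
    """
    sub = dist.subset(counts.asv_ids)
    D = sub.values
    A = counts.counts.astype(float)
    rng = np.random.default_rng(seed)
    n_taxa = counts.n_asvs
    if exhaustive and n_taxa > 8:
        raise ValueError("exhaustive null is limited to pools of 8 taxa")

    def all_samples(perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mpds = np.empty(counts.n_samples)
        mntds = np.empty(counts.n_samples)
        for s in range(counts.n_samples):
            a = A[:, s]
            present = np.flatnonzero(a > 0)
            if len(present) < 2:
                mpds[s] = mntds[s] = np.nan
                continue
            f = a[present] if weighted else np.ones(len(present))
            f = f / f.sum()
            idx = perm[present]
            d = D[np.ix_(idx, idx)]
            num = f @ d @ f
            mpds[s] = num / (1.0 - f @ f)
            d = d.copy()
            np.fill_diagonal(d, np.inf)
            mntds[s] = f @ d.min(axis=1)
        return mpds, mntds

    identity = np.arange(n_taxa)
    obs_mpd, obs_mntd = all_samples(identity)
    if exhaustive:
        from itertools import permutations as _perms

        perms = [np.array(p) for p in _perms(range(n_taxa))]
    else:
        perms = [rng.permutation(n_taxa) for _ in range(n_null)]
    null_mpd = np.empty((len(perms), counts.n_samples))
    null_mntd = np.empty((len(perms), counts.n_samples))
    for it, perm in enumerate(perms):
        null_mpd[it], null_mntd[it] = all_samples(perm)

    # the exhaustive null is the full permutation population, so its sd has
    # no sampling correction; sampled nulls use the unbiased estimator
    ddof = 0 if exhaustive else 1

    def ses(obs, nulls):
        import warnings

        with warnings.catch_warnings():
            # samples with <2 present taxa yield all-nan null columns
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(nulls, axis=0)
            sd = np.nanstd(nulls, axis=0, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (obs - mean) / sd, np.nan)
        return mean, sd, z

    mpd_mean, mpd_sd, ses_mpd = ses(obs_mpd, null_mpd)
    mntd_mean, mntd_sd, ses_mntd = ses(obs_mntd, null_mntd)
    return pd.DataFrame({
        "mpd_obs": obs_mpd, "mpd_null_mean": mpd_mean, "mpd_null_sd": mpd_sd,
        "ses_mpd": ses_mpd, "nri": -ses_mpd,
        "mntd_obs": obs_mntd, "mntd_null_mean": mntd_mean, "mntd_null_sd": mntd_sd,
        "ses_mntd": ses_mntd, "nti": -ses_mntd,
        "n_null": len(perms),
    }, index=counts.sample_ids)
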