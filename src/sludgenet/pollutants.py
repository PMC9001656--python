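"""Pollutant removal rates and node-abundance correlations.

The removal rate of a pollutant is the percentage reduction between
influent and effluent.  Metaweb-node abundances (per-sample relative
abundances) are rank-correlated with the removal rates of BOD, TN and TP;
p-values are Benjamini-Hochberg corrected across all node x pollutant
tests and nodes with q <= FDR are flagged significant.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConsistencyError, CountMatrix, SampleMetadata, POLLUTANTS

EXACT_PERMUTATION_MAX_N = 8


def removal_rate(influent: float | np.ndarray, effluent: float | np.ndarray) -> float | np.ndarray:
    """Percentage removal, 100 (in - out) / in.

    Negative values (effluent above influent) are retained; non-positive
    influent yields nan.
    """
    influent = np.asarray(influent, dtype=float)
    effluent = np.asarray(effluent, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(influent > 0, 100.0 * (influent - effluent) / influent, np.nan)
    return float(r) if r.ndim == 0 else r


def removal_rate_table(meta: SampleMetadata, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-sample removal rates (%) for BOD, TN and TP."""
    table = meta.table if sample_ids is None else meta.aligned_to(sample_ids)
    out = {}
    for pol in POLLUTANTS:
        out[pol] = removal_rate(table[f"{pol}_in"].to_numpy(), table[f"{pol}_out"].to_numpy())
    return pd.DataFrame(out, index=table.index)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; exact permutation p for small n,
    t approximation otherwise.  Constant input yields (nan, nan)."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    n = len(x)
    rho, p_t = stats.spearmanr(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r, _ = stats.pearsonr(rx, ry[list(perm)])
            count += abs(r) >= obs - 1e-12
            total += 1
        return float(rho), count / total
    return float(rho), float(p_t)


def correlate_nodes(counts: CountMatrix, rates: pd.DataFrame, fdr: float = 0.05,
                    pooled_fdr: bool = True) -> pd.DataFrame:
    """Spearman correlation of each node's relative abundance with each
    pollutant removal rate, BH-corrected.

    ``counts`` should already be restricted to metaweb nodes.  BH is applied
    pooled across pollutants by default; ``pooled_fdr=False`` corrects within
    each pollutant separately.  Requires >= 4 samples with defined rates.
    """
    rel = counts.relative_abundance()
    rows = []
    for pol in rates.columns:
        r = rates.loc[counts.sample_ids, pol].to_numpy(dtype=float)
        ok = np.isfinite(r)
        if ok.sum() < 4:
            raise ConsistencyError(f"fewer than 4 samples with defined {pol} removal rate")
        for i, asv in enumerate(counts.asv_ids):
            rho, p = _spearman(rel[i, ok], r[ok])
            rows.append({"asv_id": asv, "pollutant": pol, "rho": rho, "p": p})
    df = pd.DataFrame(rows)

    df["q"] = np.nan
    df["significant"] = False
    groups = [df.index] if pooled_fdr else [g.index for _, g in df.groupby("pollutant")]
    for idx in groups:
        mask = df.loc[idx, "p"].notna()
        tested = idx[mask]
        if len(tested):
            rej, q, _, _ = multipletests(df.loc[tested, "p"], alpha=fdr, method="fdr_bh")
            df.loc[tested, "q"] = q
            df.loc[tested, "significant"] = rej
    df["sign"] = np.sign(df["rho"]).where(df["significant"], 0.0)
    return df


def correlated_abundance_series(correlations: pd.DataFrame, counts: CountMatrix) -> pd.DataFrame:
    """Per-sample summed relative abundance of significantly correlated nodes.

    Returns one column per (pollutant, direction) pair, e.g. ``tn_positive``:
    the summed relative abundance of nodes whose abundance correlates
    positively (resp. negatively) with that pollutant's removal rate.
    """
    rel = counts.relative_abundance()
    pos = {a: i for i, a in enumerate(counts.asv_ids)}
    out = {}
    for pol, grp in correlations.groupby("pollutant"):
        for direction, sign in (("positive", 1), ("negative", -1)):
            nodes = grp.loc[(grp["significant"]) & (np.sign(grp["rho"]) == sign), "asv_id"]
            idx = [pos[a] for a in nodes if a in pos]
            out[f"{pol}_{direction}"] = rel[idx, :].sum(axis=0) if idx else np.zeros(counts.n_samples)
    return pd.DataFrame(out, index=counts.sample_ids)
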