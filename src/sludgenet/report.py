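"""Run summary and reproducibility manifest.

Aggregates the stage output tables of one run directory into a single
machine-readable JSON summary (metaweb sizes, module sizes, per-sample
metrics, NRI/NTI means and temporal trends) plus a manifest of file hashes.
Every summary number is recomputable from the stage TSVs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class MissingStageError(FileNotFoundError):
    """A stage output required by the summary is absent."""


STAGE_FILES = {
    "metaweb": "edges.tsv",
    "modules": "partition.tsv",
    "timepoints": "topology.tsv",
    "nulls": "nulls.tsv",
    "phylo": "dispersion.tsv",
    "diversity": "alpha.tsv",
}


def _require(run_dir: Path, stage: str) -> Path:
    path = run_dir / STAGE_FILES[stage]
    if not path.exists():
        raise MissingStageError(f"stage '{stage}' output missing: {path.name}")
    return path


def _trend(values: pd.Series, timepoints: pd.Series) -> dict:
    """Spearman correlation of a per-sample series with its timepoint."""
    ok = values.notna() & timepoints.notna()
    if ok.sum() < 3 or values[ok].nunique() < 2:
        return {"rho": None, "p": None}
    rho, p = stats.spearmanr(timepoints[ok], values[ok])
    return {"rho": float(rho), "p": float(p)}


def _mean_sd(values: pd.Series) -> dict:
    v = values.dropna()
    return {"mean": float(v.mean()) if len(v) else None,
            "sd": float(v.std(ddof=1)) if len(v) > 1 else None,
            "n": int(len(v))}


def summarize(run_dir: str | Path) -> dict:
    """Aggregate one run directory into a summary dict (JSON-ready)."""
    run_dir = Path(run_dir)
    edges = pd.read_csv(_require(run_dir, "metaweb"), sep="\t")
    partition = pd.read_csv(_require(run_dir, "modules"), sep="\t")
    topology = pd.read_csv(_require(run_dir, "timepoints"), sep="\t", index_col=0)
    nulls = pd.read_csv(_require(run_dir, "nulls"), sep="\t", index_col=0)
    dispersion = pd.read_csv(_require(run_dir, "phylo"), sep="\t", index_col=0)
    alpha = pd.read_csv(_require(run_dir, "diversity"), sep="\t", index_col=0)

    map_path = run_dir / "map.csv"
    if map_path.exists():
        smap = pd.read_csv(map_path, index_col=0)["timepoint"]
    else:
        smap = pd.Series(np.arange(len(topology)) + 1, index=topology.index)

    module_sizes = partition.groupby("module").size().sort_index()
    summary: dict = {
        "metaweb": {
            "n_nodes": int(pd.unique(edges[["node_a", "node_b"]].to_numpy().ravel()).size),
            "n_cooccurrence_edges": int((edges["layer"] == "cooccurrence").sum()),
            "n_coexclusion_edges": int((edges["layer"] == "coexclusion").sum()),
        },
        "modules": {
            "n_modules": int(module_sizes.size),
            "sizes": {str(k): int(v) for k, v in module_sizes.items()},
        },
        "topology": {
            m: {**_mean_sd(topology[m]),
                "trend_vs_time": _trend(topology[m], smap.reindex(topology.index))}
            for m in ("modularity", "clustering", "coexclusion_proportion")
            if m in topology
        },
        "null_z": {
            c: _mean_sd(nulls[c]) for c in nulls.columns if c.endswith("_z")
        },
        "dispersion": {
            m: {**_mean_sd(dispersion[m]),
                "trend_vs_time": _trend(dispersion[m], smap.reindex(dispersion.index))}
            for m in ("nri", "nti")
        },
        "diversity": {
            c: {**_mean_sd(alpha[c]),
                "trend_vs_time": _trend(alpha[c], smap.reindex(alpha.index))}
            for c in alpha.columns
        },
    }
    log_path = run_dir / "run_log.json"
    if log_path.exists():
        summary["run_log"] = json.loads(log_path.read_text())
    return summary


def write_summary(run_dir: str | Path, out_name: str = "summary.json") -> dict:
    run_dir = Path(run_dir)
    summary = summarize(run_dir)
    (run_dir / out_name).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    write_manifest(run_dir)
    return summary


def write_manifest(run_dir: str | Path, out_name: str = "manifest.txt") -> None:
    run_dir = Path(run_dir)
    lines = []
    for path in sorted(run_dir.iterdir()):
        if path.name == out_name or not path.is_file():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        lines.append(f"{digest}  {path.name}")
    (run_dir / out_name).write_text("\n".join(lines) + "\n")


def append_run_log(run_dir: str | Path, stage: str, seed: int, config: dict,
                   elapsed: float) -> None:
    """Append a stage record (config echo, seed, timing) to the run log."""
    run_dir = Path(run_dir)
    log_path = run_dir / "run_log.json"
    entries = json.loads(log_path.read_text()) if log_path.exists() else []
    entries.append({
        "stage": stage,
        "seed": seed,
        "config": config,
        "elapsed_seconds": round(elapsed, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })
    log_path.write_text(json.dumps(entries, indent=2) + "\n")
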