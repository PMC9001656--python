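"""Core data model and file I/O.

The pipeline operates on three primary inputs: an ASV-by-sample count table
(TSV), per-sample metadata (CSV with timepoint, replicate, temperature and
influent/effluent pollutant concentrations), and a rooted phylogeny with
branch lengths (Newick) whose tips cover the analysed ASVs.  Orientation is
fixed throughout the package: ASVs are rows, samples are columns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConsistencyError(ValueError):
    """Raised when two inputs that must agree (ids, shapes) do not."""


METADATA_COLUMNS = (
    "temperature",
    "bod_in", "bod_out",
    "tn_in", "tn_out",
    "tp_in", "tp_out",
)

POLLUTANTS = ("bod", "tn", "tp")


@dataclass
class CountMatrix:
    """ASV x sample non-negative integer counts with a sample design map.

    Parameters
    ----------
    asv_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_asvs, n_samples)
        Non-negative integers.
    sample_map : dict
        ``sample_id -> (timepoint_index, replicate_index)`` with 1-based
        indices; each (timepoint, replicate) pair occurs once.
    """

    asv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_map: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise FormatError("duplicate ASV ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ConsistencyError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.sample_map]
        if missing:
            raise ConsistencyError(f"samples missing from sample map: {missing}")
        pairs = [self.sample_map[s] for s in self.sample_ids]
        if len(set(pairs)) != len(pairs):
            raise ConsistencyError("duplicate (timepoint, replicate) pair in sample map")

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def timepoints(self) -> np.ndarray:
        """1-based timepoint index per sample (column order)."""
        return np.array([self.sample_map[s][0] for s in self.sample_ids])

    @property
    def n_timepoints(self) -> int:
        return len(set(t for t, _ in self.sample_map.values()))

    def relative_abundance(self) -> np.ndarray:
        """Counts divided by column sums; all-zero columns yield zeros."""
        tot = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(tot > 0, self.counts / np.maximum(tot, 1), 0.0)
        return rel

    def presence(self, threshold: int = 0) -> np.ndarray:
        """Boolean presence matrix: count > threshold."""
        return self.counts > threshold

    def subset_asvs(self, keep_ids: Iterable[str]) -> "CountMatrix":
        keep = set(keep_ids)
        idx = [i for i, a in enumerate(self.asv_ids) if a in keep]
        return CountMatrix(
            asv_ids=[self.asv_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            sample_map=dict(self.sample_map),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.asv_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample environmental and operational measurements.

    Wraps a DataFrame indexed by sample id with columns ``temperature``,
    ``bod_in``/``bod_out``, ``tn_in``/``tn_out``, ``tp_in``/``tp_out`` (mg/L)
    and ``timepoint``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS + ("timepoint",) if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, sample_ids: list[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ConsistencyError(f"metadata missing samples: {missing}")
        return self.table.loc[sample_ids]


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; tips are ASV ids."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError("tree has edges without branch lengths")
            if edge.length < 0:
                raise FormatError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def check_covers(self, asv_ids: Iterable[str]) -> None:
        missing = set(asv_ids) - set(self.tip_labels)
        if missing:
            raise ConsistencyError(f"tree tips do not cover ASVs: {sorted(missing)[:5]}...")

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick() + "\n")


@dataclass
class RunConfig:
    """Knobs shared across pipeline stages.

    significance
        Tail-probability threshold of the pairwise hypergeometric model
        (default 0.95, the probability-of-co-occurrence cutoff).
    walk_length
        Walktrap random-walk length (default 4).
    n_sbm / n_phylo
        Null-model iteration counts for the stochastic-block-model network
        nulls (default 1000) and the taxa-label phylogenetic nulls
        (default 999).
    fdr
        Benjamini-Hochberg false-discovery level for pollutant correlations.
    presence_threshold
        A taxon is present in a sample when count > threshold (default 0).
    strict_tail
        If True (default) an edge requires tail probability >= significance
        computed on the strict tail P(J < j_obs) (resp. P(J > j_obs)).
    """

    significance: float = 0.95
    walk_length: int = 4
    n_sbm: int = 1000
    n_phylo: int = 999
    fdr: float = 0.05
    seed: int = 0
    presence_threshold: int = 0
    strict_tail: bool = True
    fresh_timepoint_partition: bool = True
    clustering_mode: str = "transitivity"  # or "average_local"

    def __post_init__(self) -> None:
        if not 0 < self.significance < 1:
            raise ValueError("significance must lie in (0, 1)")
        if self.n_sbm < 1 or self.n_phylo < 1:
            raise ValueError("iteration counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, sample_map_path: str | Path) -> CountMatrix:
    """Read a TSV count table and its sample-design CSV.

    The TSV has a header row of sample ids and ASV ids in the first column;
    the CSV has columns ``sample_id,timepoint,replicate``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise FormatError("duplicate ASV ids in count table")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in count table")
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer counts in {path}: {exc}") from exc

    mdf = pd.read_csv(sample_map_path)
    required = {"sample_id", "timepoint", "replicate"}
    if not required.issubset(mdf.columns):
        raise FormatError(f"sample map must have columns {sorted(required)}")
    sample_map = {
        str(r.sample_id): (int(r.timepoint), int(r.replicate))
        for r in mdf.itertuples()
    }
    return CountMatrix(
        asv_ids=[str(a) for a in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=counts,
        sample_map=sample_map,
    )


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree.  The terminal semicolon is required;
    quoted labels are allowed and internal labels are ignored."""
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise FormatError("Newick file must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick {path}: {exc}") from exc
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_count_table(cm: CountMatrix, path: str | Path, sample_map_path: str | Path) -> None:
    cm.to_dataframe().to_csv(path, sep="\t", index_label="asv_id")
    rows = [
        {"sample_id": s, "timepoint": cm.sample_map[s][0], "replicate": cm.sample_map[s][1]}
        for s in cm.sample_ids
    ]
    pd.DataFrame(rows).to_csv(sample_map_path, index=False)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="sample_id")


def metaweb_to_graphs(metaweb) -> nx.Graph:
    """Single graph view of a metaweb: edge attribute ``layer`` in
    {cooccurrence, coexclusion}, node attribute ``module`` when available."""
    g = nx.Graph()
    g.add_nodes_from(metaweb.nodes)
    if metaweb.partition is not None:
        nx.set_node_attributes(g, metaweb.partition.labels, "module")
    for (a, b), p in metaweb.cooccurrence.items():
        g.add_edge(a, b, layer="cooccurrence", p_value=float(p))
    for (a, b), p in metaweb.coexclusion.items():
        g.add_edge(a, b, layer="coexclusion", p_value=float(p))
    return g


def write_network(metaweb, graphml_path: str | Path, edgelist_path: str | Path | None = None) -> None:
    """Write a metaweb as GraphML plus a plain TSV edge list."""
    g = metaweb_to_graphs(metaweb)
    nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        rows = [
            {"node_a": a, "node_b": b, "layer": d["layer"], "p_value": d["p_value"]}
            for a, b, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "layer", "p_value"]).to_csv(
            edgelist_path, sep="\t", index=False
        )


def read_network(graphml_path: str | Path):
    """Read a GraphML metaweb written by :func:`write_network`."""
    from .metaweb import Metaweb  # local import to avoid cycle
    from .dynamics import ModulePartition

    g = nx.read_graphml(graphml_path)
    co = {}
    ex = {}
    for a, b, d in g.edges(data=True):
        key = (a, b) if a < b else (b, a)
        if d.get("layer") == "coexclusion":
            ex[key] = float(d.get("p_value", np.nan))
        else:
            co[key] = float(d.get("p_value", np.nan))
    modules = nx.get_node_attributes(g, "module")
    partition = None
    if modules and len(modules) == g.number_of_nodes():
        partition = ModulePartition(labels={n: int(m) for n, m in modules.items()}, modularity=np.nan)
    return Metaweb(nodes=sorted(g.nodes), cooccurrence=co, coexclusion=ex, partition=partition)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
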