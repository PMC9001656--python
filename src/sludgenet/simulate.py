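"""Synthetic activated-sludge time series with planted community structure.

Two scenarios mirror the study designs the pipeline targets:

``seasonal``
    An established plant: two planted modules of ASVs whose abundances track
    a sinusoidal temperature series in antiphase.  Each ASV has a Gaussian
    niche response around a temperature optimum; optima evolve by Brownian
    motion on a simulated Yule tree and module membership follows clades, so
    environmental preference carries phylogenetic signal.

``succession``
    A starting-up plant: three planted modules.  One — a cohesive inoculum
    community with no niche structure — decays geometrically in favour of
    the other two, which are temperature-filtered in antiphase.  The
    strength of environmental filtering (the inverse niche width) increases
    over the sampling period, emulating deterministic community assembly
    taking over from the stochastic start.

Counts are multinomial draws at a fixed sequencing depth per sample, so
column sums equal the depth exactly.  A configurable number of "rare" ASVs
(present in at most one timepoint) and "ubiquitous" ASVs (present in every
timepoint) exercises the downstream occurrence filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import CountMatrix, Phylogeny, SampleMetadata

MODULE_RARE = "rare"
MODULE_UBIQUITOUS = "ubiquitous"


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study scenario.

    Defaults follow the two emulated designs: 22 monthly timepoints with
    triplicate samples and temperature between 18.0 and 27.6 degC for the
    seasonal scenario; 23 timepoints between 11.33 and 23.50 degC for the
    succession scenario.
    """

    scenario: str
    module_sizes: tuple[int, ...]
    n_timepoints: int
    n_replicates: int = 3
    temp_range: tuple[float, float] = (18.0, 27.6)
    niche_sigma: float = 2.5
    niche_sigma_start: float | None = None  # succession: weak early filtering
    filter_ramp_timepoints: int | None = None  # timepoints to reach full filtering
    brownian_rate: float = 4.0
    depth: int = 5000
    decay: float = 0.72  # succession: per-timepoint geometric decay of the inoculum module
    n_rare: int = 8
    n_ubiquitous: int = 8
    ubiquitous_weight: float = 0.6
    inoculum_weight: float = 1.0
    lognormal_noise: float = 0.0
    seasonal_period: float = 12.0

    def __post_init__(self) -> None:
        if self.scenario not in ("seasonal", "succession"):
            raise ValueError("scenario must be 'seasonal' or 'succession'")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.temp_range[1] <= self.temp_range[0]:
            raise ValueError("temperature range must be increasing")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.niche_sigma <= 0:
            raise ValueError("niche width must be positive")
        if not 0 <= self.decay <= 1:
            raise ValueError("decay must lie in [0, 1]")

    @property
    def n_asvs(self) -> int:
        return sum(self.module_sizes) + self.n_rare + self.n_ubiquitous

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @classmethod
    def seasonal(cls, **overrides) -> "ScenarioSpec":
        base = dict(scenario="seasonal", module_sizes=(50, 50), n_timepoints=22,
                    temp_range=(18.0, 27.6), niche_sigma=2.5)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def succession(cls, **overrides) -> "ScenarioSpec":
        base = dict(scenario="succession", module_sizes=(28, 28, 56), n_timepoints=23,
                    temp_range=(11.33, 23.50), niche_sigma=3.3,
                    niche_sigma_start=8.0, filter_ramp_timepoints=8,
                    brownian_rate=10.0, lognormal_noise=0.6)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with total depth 1.

    Lineages split at unit rate; the process stops at ``n_tips`` lineages
    and runs one extra exponential waiting time so terminal branches are
    positive.  All branch lengths are then rescaled so every root-to-tip
    depth equals 1.  Tips are labelled ``ASV0001`` ... in traversal order.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)

    # birth time per node index; root (index 0) splits at t=0 into nodes 1, 2
    birth = [0.0, 0.0, 0.0]
    children: dict[int, list[int]] = {0: [1, 2]}
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        pick = int(rng.integers(k))
        node = active.pop(pick)
        for _ in range(2):
            birth.append(t)
            children.setdefault(node, []).append(len(birth) - 1)
            active.append(len(birth) - 1)
    t_end = t + rng.exponential(1.0 / n_tips)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    dnodes = {0: tree.seed_node}
    tree.seed_node.edge.length = None
    order = sorted(children)  # parents always created before children
    for node in order:
        for ch in children[node]:
            d = dendropy.Node()
            dnodes[node].add_child(d)
            dnodes[ch] = d
    # edge of a node spans its birth to its own split (or to t_end for leaves)
    for idx in range(1, len(birth)):
        end_time = birth[children[idx][0]] if idx in children else t_end
        dnodes[idx].edge.length = (end_time - birth[idx]) / t_end

    counter = 0
    for leaf in tree.leaf_node_iter():
        counter += 1
        leaf.taxon = taxon_namespace.new_taxon(label=f"ASV{counter:04d}")
    return Phylogeny(tree)


def evolve_optima(phylogeny: Phylogeny, brownian_rate: float, seed: int = 0,
                  root_value: float = 0.0) -> pd.Series:
    """Brownian-motion trait values at the tips.

    Each branch adds a Normal(0, rate * length) increment, so the variance
    of a tip value is rate times its root-to-tip depth and closely related
    tips receive similar values.  A rate of 0 returns the root value for
    every tip.
    """
    if brownian_rate < 0:
        raise ValueError("Brownian rate must be non-negative")
    rng = np.random.default_rng(seed)
    tree = phylogeny.tree
    values: dict[int, float] = {id(tree.seed_node): root_value}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = values[id(node.parent_node)]
        step = rng.normal(0.0, np.sqrt(brownian_rate * node.edge.length)) if node.edge.length else 0.0
        values[id(node)] = parent_val + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out)


def _assign_roles(spec: ScenarioSpec, tip_order: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Module/rare/ubiquitous label per tip.

    Rare and ubiquitous taxa are scattered uniformly over tree positions, as
    is the inoculum module (the last one) in the succession scenario — a
    seeding community carries no local niche structure, so its members span
    the whole tree.  The remaining tips, in tree traversal order, form
    contiguous blocks that approximate clades — one per niche-structured
    module.
    """
    n = len(tip_order)
    n_scattered = spec.n_rare + spec.n_ubiquitous
    scattered_module = spec.scenario == "succession"
    clade_sizes = list(spec.module_sizes[:-1] if scattered_module else spec.module_sizes)
    if scattered_module:
        n_scattered += spec.module_sizes[-1]
    special = rng.choice(n, size=n_scattered, replace=False)
    rare = set(special[:spec.n_rare])
    ubiq = set(special[spec.n_rare:spec.n_rare + spec.n_ubiquitous])
    inoculum = set(special[spec.n_rare + spec.n_ubiquitous:])
    roles = {}
    block = 0
    filled = 0
    for i, tip in enumerate(tip_order):
        if i in rare:
            roles[tip] = MODULE_RARE
        elif i in ubiq:
            roles[tip] = MODULE_UBIQUITOUS
        elif i in inoculum:
            roles[tip] = f"M{spec.n_modules}"
        else:
            roles[tip] = f"M{block + 1}"
            filled += 1
            if filled == clade_sizes[block] and block < len(clade_sizes) - 1:
                block += 1
                filled = 0
    return roles


def temperature_series(spec: ScenarioSpec) -> np.ndarray:
    """Sinusoidal monthly temperature spanning the configured range."""
    lo, hi = spec.temp_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    t = np.arange(spec.n_timepoints)
    return mid + amp * np.sin(2.0 * np.pi * t / spec.seasonal_period)


def _niche_sigma_series(spec: ScenarioSpec) -> np.ndarray:
    """Per-timepoint niche width.

    Constant unless a start width is set; with one, the width narrows
    linearly from the start value to ``niche_sigma`` over the first
    ``filter_ramp_timepoints`` timepoints (default: the whole series) and
    stays there — environmental filtering strengthening as the community
    assembles.
    """
    if spec.niche_sigma_start is None:
        return np.full(spec.n_timepoints, spec.niche_sigma)
    ramp = spec.filter_ramp_timepoints or spec.n_timepoints
    s = np.minimum(1.0, np.arange(spec.n_timepoints) / max(ramp - 1, 1))
    return spec.niche_sigma_start + (spec.niche_sigma - spec.niche_sigma_start) * s


def module_temperature_centers(spec: ScenarioSpec) -> dict[str, float | None]:
    """Planted temperature optimum per module.

    Seasonal: the two modules sit at +/- 0.8 of the temperature amplitude
    (warm vs cold, antiphase).  Succession: modules M1/M2 are warm/cold and
    the inoculum module M3 has no temperature preference (None).
    """
    lo, hi = spec.temp_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    centers: dict[str, float | None] = {"M1": mid + 0.8 * amp, "M2": mid - 0.8 * amp}
    if spec.scenario == "succession":
        centers["M3"] = None
    return centers


@dataclass
class SimulationResult:
    counts: CountMatrix
    metadata: SampleMetadata
    truth: dict
    phylogeny: Phylogeny
    optima: pd.Series


def simulate_scenario(spec: ScenarioSpec, phylogeny: Phylogeny, optima: pd.Series,
                      seed: int = 0) -> SimulationResult:
    """Draw counts and metadata for one scenario on a given tree.

    ``optima`` holds the Brownian trait values from :func:`evolve_optima`;
    within each planted module they are recentred on the module's planted
    temperature optimum, so module membership and niche preference align
    while phylogenetic signal at short distances is preserved.
    """
    tips = phylogeny.tip_labels
    if len(tips) != spec.n_asvs:
        raise ValueError(f"tree has {len(tips)} tips but spec requires {spec.n_asvs}")
    rng = np.random.default_rng(seed)
    roles = _assign_roles(spec, tips, rng)
    centers = module_temperature_centers(spec)

    temps = temperature_series(spec)
    sigmas = _niche_sigma_series(spec)

    # per-ASV temperature optimum: module centre + centred Brownian deviation
    opt = np.full(len(tips), np.nan)
    for m, c in centers.items():
        idx = [i for i, t in enumerate(tips) if roles[t] == m]
        if c is None or not idx:
            continue
        dev = optima[[tips[i] for i in idx]].to_numpy()
        opt[idx] = c + dev - dev.mean()

    base = rng.lognormal(mean=0.0, sigma=0.5, size=len(tips))
    rare_tp = rng.integers(spec.n_timepoints, size=len(tips))  # used for rare taxa only

    module_index = {f"M{k + 1}": k for k in range(spec.n_modules)}
    weights = np.zeros((len(tips), spec.n_timepoints))
    for i, tip in enumerate(tips):
        role = roles[tip]
        if role == MODULE_RARE:
            w = np.zeros(spec.n_timepoints)
            w[rare_tp[i]] = base[i]
        elif role == MODULE_UBIQUITOUS:
            w = np.full(spec.n_timepoints, spec.ubiquitous_weight * base[i])
        else:
            if spec.scenario == "succession" and role == "M3":
                # cohesive inoculum: geometric decay, no niche filtering
                w = spec.inoculum_weight * base[i] * spec.decay ** np.arange(spec.n_timepoints)
            else:
                w = base[i] * np.exp(-((temps - opt[i]) ** 2) / (2.0 * sigmas ** 2))
        weights[i] = w

    # metadata: influent concentrations track temperature; removal efficiency
    # is stable for the established plant and rises during start-up
    lo, hi = spec.temp_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    season = (temps - mid) / amp
    s_t = np.linspace(0.0, 1.0, spec.n_timepoints)
    infl = {
        "bod": 320.0 * (1.0 + 0.25 * season),
        "tn": 65.0 * (1.0 + 0.25 * season),
        "tp": 9.0 * (1.0 + 0.10 * season),
    }
    if spec.scenario == "seasonal":
        eff = {"bod": np.full_like(s_t, 0.92), "tn": np.full_like(s_t, 0.72),
               "tp": np.full_like(s_t, 0.65)}
    else:
        eff = {"bod": 0.70 + 0.25 * s_t, "tn": 0.30 + 0.55 * s_t,
               "tp": 0.25 + 0.55 * s_t}

    sample_ids = []
    sample_map = {}
    counts = np.zeros((len(tips), spec.n_timepoints * spec.n_replicates), dtype=np.int64)
    meta_rows = []
    col = 0
    for t in range(spec.n_timepoints):
        p = weights[:, t]
        if spec.lognormal_noise > 0:
            p = p * rng.lognormal(0.0, spec.lognormal_noise, size=len(p))
        for r in range(spec.n_replicates):
            pr = p
            if spec.lognormal_noise > 0:
                pr = p * rng.lognormal(0.0, spec.lognormal_noise, size=len(p))
            pr = pr / pr.sum()
            sid = f"S{t + 1:02d}R{r + 1}"
            sample_ids.append(sid)
            sample_map[sid] = (t + 1, r + 1)
            counts[:, col] = rng.multinomial(spec.depth, pr)
            noise = rng.normal(1.0, 0.02, size=6)
            meta_rows.append({
                "sample_id": sid,
                "timepoint": t + 1,
                "temperature": temps[t],
                "bod_in": infl["bod"][t] * noise[0],
                "bod_out": infl["bod"][t] * (1 - eff["bod"][t]) * noise[1],
                "tn_in": infl["tn"][t] * noise[2],
                "tn_out": infl["tn"][t] * (1 - eff["tn"][t]) * noise[3],
                "tp_in": infl["tp"][t] * noise[4],
                "tp_out": infl["tp"][t] * (1 - eff["tp"][t]) * noise[5],
            })
            col += 1

    cm = CountMatrix(asv_ids=list(tips), sample_ids=sample_ids,
                     counts=counts, sample_map=sample_map)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = {
        "scenario": spec.scenario,
        "module_of": roles,
        "module_names": [f"M{k + 1}" for k in range(spec.n_modules)],
        "temperature": temps.tolist(),
        "centers": {k: v for k, v in centers.items()},
        "optima": {tip: (None if np.isnan(opt[i]) else float(opt[i])) for i, tip in enumerate(tips)},
        "spec": spec.to_dict(),
    }
    return SimulationResult(counts=cm, metadata=meta, truth=truth,
                            phylogeny=phylogeny, optima=optima)


def simulate_dataset(spec: ScenarioSpec, seed: int = 0) -> SimulationResult:
    """Tree + Brownian optima + counts in one call with derived sub-seeds."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_bm, s_counts = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    phylogeny = simulate_tree(spec.n_asvs, s_tree)
    optima = evolve_optima(phylogeny, spec.brownian_rate, s_bm)
    return simulate_scenario(spec, phylogeny, optima, s_counts)
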