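# sludgenet

Community-assembly diagnostics for activated-sludge microbiome time series.

Activated-sludge bioreactors in wastewater treatment plants host dense,
dynamic microbial communities whose composition shifts with season,
operation and start-up history. `sludgenet` is a pipeline for asking, from
an ASV count table sampled over time, *how* such a community is assembled:
whether taxa associate and segregate beyond chance, how the resulting
ecological modules wax and wane, whether assembly is phylogenetically
structured (habitat filtering vs. stochasticity), and which community
members track pollutant removal performance.

It is aimed at microbial ecologists working with 16S amplicon time series
from engineered or natural systems who want the full chain — association
networks, network nulls, dispersion nulls, diversity, and performance
correlations — as one tested, scriptable toolkit.

## What it computes

**Co-occurrence metaweb.** After an occurrence filter (keep ASVs present in
more than one but not every timepoint), every ASV pair is scored with the
exact hypergeometric association model: with occupancies $n_a, n_b$ out of
$N$ samples and $j$ shared samples,

$$P(J=j) = \frac{\binom{n_a}{j}\binom{N-n_a}{n_b-j}}{\binom{N}{n_b}},$$

a pair is a *co-occurrence* when $P(J < j_{obs}) \ge 0.95$ and a
*co-exclusion* when $P(J > j_{obs}) \ge 0.95$. Significant pairs form a
two-layer regional metaweb; walktrap community detection on the
co-occurrence layer yields ecological modules.

**Network dynamics.** Each sample induces a timepoint network (the metaweb
subgraphs on the ASVs present in it). Per sample the pipeline tracks module
completeness (fraction of a module's nodes present), Newman–Girvan
modularity $Q$, global transitivity, and the co-exclusion proportion, each
standardised against a stochastic-block-model null that redraws networks
with the observed per-module node counts.

**Phylogenetic dispersion.** Abundance-weighted MPD and MNTD per sample are
standardised against a taxa-labels null (shuffling the tips of the
patristic distance matrix across the analysed pool):
$\mathrm{NRI} = -\mathrm{SES(MPD)}$, $\mathrm{NTI} = -\mathrm{SES(MNTD)}$,
positive values indicating phylogenetic clustering (habitat filtering).
Phylogenetic signal in environmental preference is tested with Mantel
correlograms between ASV environmental optima (abundance-weighted means of
temperature and influent BOD/TN/TP) and patristic distance.

**Diversity and performance.** Hill numbers $^0D, {}^1D, {}^2D$ and the
phylogenetic Hill number $^0pD$, Bray–Curtis dissimilarities, pollutant
removal rates $100\,(C_{in}-C_{out})/C_{in}$, and BH-FDR-controlled Spearman
screens of node abundance against removal rates.

**Synthetic scenarios.** A generator emulates two study designs on a
simulated phylogeny with Brownian-motion niche optima: a *seasonal*
established plant (two modules tracking temperature in antiphase, 22
monthly timepoints × 3 replicates) and a *succession* start-up plant (a
scattered inoculum module decaying in favour of two niche-structured
modules under strengthening filtering, 23 timepoints × 3 replicates). All
downstream stages are tested against the planted truth.

## Worked example

```python
import numpy as np
from scipy import stats
import sludgenet as sn

res = sn.simulate_dataset(sn.ScenarioSpec.seasonal(), seed=1)
filtered = sn.filter_by_occurrence(res.counts)
occ = sn.occurrence_matrix(filtered)
web = sn.build_metaweb(occ)
part = sn.detect_modules(web)
comp = sn.module_completeness(part, occ)
temps = np.array([res.truth["temperature"][res.counts.sample_map[s][0] - 1]
                  for s in occ.sample_ids])
print(f"retained {filtered.n_asvs} of {res.counts.n_asvs} ASVs after the occurrence filter")
print(f"metaweb: {web.n_nodes} nodes, {len(web.cooccurrence)} co-occurrence / "
      f"{len(web.coexclusion)} co-exclusion edges")
print(f"walktrap found {part.n_modules} modules (Q = {part.modularity:.3f})")
for m, members in sorted(part.module_members().items()):
    rho = stats.spearmanr(comp[m], temps)[0]
    print(f"  module {m}: {len(members)} nodes, completeness vs temperature rho = {rho:+.2f}")
```

prints

```
retained 56 of 116 ASVs after the occurrence filter
metaweb: 56 nodes, 756 co-occurrence / 672 co-exclusion edges
walktrap found 2 modules (Q = 0.500)
  module 0: 28 nodes, completeness vs temperature rho = +0.95
  module 1: 28 nodes, completeness vs temperature rho = -0.95
```

The two recovered modules are exactly the planted warm- and cold-preferring
communities: each module's completeness (share of its members present in a
sample) rises and falls with the temperature sinusoid, in antiphase.

The same analysis is available from the shell, one stage per subcommand,
reading and writing plain TSV/CSV/Newick/GraphML files in a run directory:

```bash
sludgenet --seed 1 --out-dir run simulate --scenario seasonal
sludgenet --seed 1 --out-dir run metaweb
sludgenet --seed 1 --out-dir run modules
sludgenet --seed 1 --out-dir run timepoints
sludgenet --seed 1 --out-dir run nulls
sludgenet --seed 1 --out-dir run phylo
sludgenet --seed 1 --out-dir run diversity
sludgenet --seed 1 --out-dir run correlate
sludgenet --seed 1 --out-dir run report   # summary.json + manifest.txt
```

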