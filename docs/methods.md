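# Methods

This note documents the models and procedures `sludgenet` implements, the
parameters that matter, what the synthetic scenarios do and do not emulate,
and the numerical and design choices made where more than one convention
exists.

## Pairwise association model

Presence is `count > threshold` (default 0), evaluated per individual
sample — every replicate is a sample. Occupancy for the *occurrence filter*
is counted at the timepoint level (present in at least one replicate of the
timepoint): ASVs present in more than one but not in every timepoint are
retained. The association test itself runs over all individual samples
(N = timepoints × replicates), so replicate-level noise informs the model.

For each unordered pair the number of shared samples under independent
random placement is hypergeometric. We report the strict tails
`p_lt = P(J < j_obs)` and `p_gt = P(J > j_obs)`; a pair is a co-occurrence
when `p_lt >= significance` (default 0.95) and a co-exclusion when
`p_gt >= significance`. The two rules cannot fire together at any
significance above 0.5, so the layers are disjoint. Choices worth noting:

- *Strict vs. inclusive tail.* "Probability of co-occurrence ≥ 0.95" is
  read as the strict tail (the chance a random placement shares *fewer*
  samples than observed). An inclusive variant is available via
  `RunConfig.strict_tail = False`.
- *Degenerate support.* Pairs whose feasible overlap range is a single
  point (e.g. one ASV present in every sample) carry no information and are
  classified `none`.
- *No multiple-testing correction* is applied to pair tests; the fixed 0.95
  rule is the model. The measured type-I rate of the rule on independent
  presences (p = 0.5, N = 60) is about 5%, and is asserted to stay ≤ 7% in
  the tests.
- Tail probabilities come from `scipy.stats.hypergeom`, whose log-space
  evaluation is accurate far beyond the N ≈ 200 regime used here; the tests
  pin it against exhaustive enumeration at N = 10 (1e−12) and a 100 000-draw
  permutation oracle at N ≤ 30 (0.01).

Metaweb nodes are the filtered ASVs with at least one significant edge.

## Modules and timepoint networks

Modules are detected on the co-occurrence layer with walktrap (random-walk
length 4, the common default), cutting the merge dendrogram at the
maximum-modularity level. Node order is fixed (sorted ASV ids), making the
partition deterministic. ASVs whose only significant edges are
co-exclusions are isolated in this layer and become singleton modules.

Each sample induces one timepoint network per layer (nodes: present
metaweb ASVs; edges: metaweb edges with both endpoints present). Metrics:

- *Modularity Q*: scored on a fresh walktrap partition of the induced
  co-occurrence subgraph (the per-sample structure is what the time series
  tracks). Scoring the inherited metaweb partition instead is available via
  `RunConfig.fresh_timepoint_partition = False`.
- *Clustering*: global transitivity (3 × triangles / connected triples),
  undefined (NaN) when there are no triples. Mean local clustering is
  available behind `clustering_mode = "average_local"`.
- *Co-exclusion proportion*: co-exclusion edges over all induced edges,
  undefined when the sample induces no edges. Because "proportion of
  co-excluding nodes" is ambiguous, a node-based variant (share of present
  nodes touching a co-exclusion edge) is reported alongside.

Samples with fewer than two present metaweb nodes get NaN metrics
throughout; NaNs propagate explicitly rather than being imputed.

## Stochastic-block-model nulls

A plain (non-degree-corrected) Bernoulli SBM is fitted once per layer on
the metaweb with blocks given by the walktrap modules:
`p_kl = observed edges between k and l / possible pairs`, within-block
pairs counted as n(n−1)/2 and size-1 blocks assigned probability 0. This
moment-matching fit reproduces per-block-pair edge counts in expectation
exactly.

Null timepoint networks are drawn on fresh synthetic nodes, with the
observed sample's per-module node counts, independently per layer (both
layers are needed so the null co-exclusion proportion is defined). Per
sample and metric, `n_sbm` draws (default 1000) give a null mean and sd;
z = (obs − mean)/sd, undefined when sd = 0 or the observation is undefined.
Undefined draws (e.g. edgeless null graphs) are excluded from the null
moments. Self-consistency is asserted in the tests: data generated from the
fitted SBM scores |z| ≤ 3 in ≥ 99% of evaluations.

## Phylogenetic dispersion

Patristic distances are taken from the tree's branch lengths (dendropy's
phylogenetic distance matrix). Environmental optima are abundance-weighted
means of selected metadata variables (default: temperature and influent
BOD/TN/TP) using raw counts as weights; multivariate trait distance is
Euclidean on z-scored optima. The Mantel correlogram bins phylogenetic
distances into Sturges classes; the per-class statistic is the sign-flipped
Pearson correlation between trait distances and class membership (positive
= trait similarity within the class), with two-sided tip-shuffle
permutation p-values and progressive Bonferroni correction (class *i*
reported as min(1, p·i)).

MPD and MNTD are abundance-weighted by per-sample relative abundances. The
taxa-labels null shuffles the labels of the distance matrix across the full
analysed pool — the metaweb node set, per dataset — holding composition
fixed; 999 randomisations by default, SES with the sample sd (ddof 1). An
exhaustive mode enumerates all label permutations for pools of ≤ 8 taxa
and uses the population sd, making the SES exact; the sampled estimator
converges to it. NRI/NTI are invariant to rescaling all branch lengths, and
undefined when the null sd is 0 (e.g. a star phylogeny).

## Diversity

Hill numbers use the entropy limit at q = 1, not a numerical q → 1
approach. The phylogenetic Hill number uses the branch-segment
formulation: branch abundances are summed descendant relative abundances,
the mean depth T̄ is the abundance-weighted total branch length, and
q = 0 reduces to Faith's PD of the present subtree divided by T̄ (a single
present taxon returns 1 by convention). Diversity is computed on raw
counts normalised to relative abundances; no rarefaction (depths are equal
by design in the generator, and real runs should rarefy upstream if depths
vary grossly). Bray–Curtis is computed on counts, undefined for a pair of
all-zero samples.

## Pollutant correlations

Removal rate is `100 (in − out)/in` (%), kept when negative, undefined for
non-positive influent. Node abundances are per-sample relative abundances
(depths may vary in real data). Spearman uses mid-rank ties with the
t-approximation for n > 8 and exact permutation enumeration for n ≤ 8 —
enumerating beyond 8! permutations per node is not worth the cost given the
t-approximation's accuracy at n ≥ 9. Benjamini–Hochberg is applied pooled
across the three pollutants by default (`pooled_fdr = False` corrects per
pollutant); significance is q ≤ 0.05.

## Synthetic scenarios

The generator emulates the *output* of amplicon processing for two study
designs, not reads: a count table over 22/23 monthly timepoints × 3
replicates, per-sample metadata, a tree, and ground-truth module labels.

Common machinery: a Yule tree (unit birth rate, depth normalised to 1);
Brownian niche optima (variance = rate × depth), recentred per module on
the module's planted temperature optimum so membership and niche align
while short-distance phylogenetic signal is preserved; a sinusoidal
monthly temperature series spanning the configured range; Gaussian niche
response `exp(−(T − opt)² / 2σ²)`; lognormal baseline abundances
(sd 0.5); multinomial counts at fixed depth 5000 per sample (column sums
are exact). A few "rare" taxa (one timepoint only) and "ubiquitous" taxa
(every timepoint) exercise the occurrence filter. Influent concentrations
track temperature; effluent is influent × (1 − efficiency).

*Seasonal* (established plant): two clade modules of 50 ASVs at warm/cold
optima (±0.8 of the temperature amplitude), niche width 2.5 °C, Brownian
rate 4. The planted effect is antiphase module dynamics; module-summed
abundances correlate with temperature at |ρ| ≳ 0.9.

*Succession* (start-up plant): three modules — two clades of 28 ASVs in
temperature antiphase, and a 56-ASV *inoculum* module scattered uniformly
across the tree (a seeding community carries no local niche structure)
whose mixing weight decays geometrically (factor 0.72 per timepoint) with
no niche filtering. Environmental filtering strengthens as the community
assembles: the niche width narrows linearly from 8 °C to 3.3 °C over the
first 8 timepoints. Replicate-level lognormal noise (sd 0.6) adds presence
flicker near the detection boundary. Removal efficiencies rise over the
sampling period. This design plants the qualitative start-up pattern the
pipeline is meant to recover: the synchronized inoculum forms a dense early
clique connected to everything (low early modularity, high early
clustering); as it disappears and filtering narrows, networks resolve into
two separated, noise-thinned niche modules (modularity rises, clustering
falls), abundance concentrates on phylogenetically close, niche-matched
taxa (NTI rises), and evenness drops (¹D falls).

What the generator does *not* emulate: sequencing-depth variation,
overdispersion beyond the optional lognormal flag, taxonomic structure,
chimeras, true inoculum composition (the succession scenario is a stylised
stand-in, not a calibration), or covariation of operational parameters
beyond temperature seasonality. Passing tests therefore demonstrate that
the pipeline recovers planted structure of realistic size and noise — not
that any particular real plant behaves this way.

## Problem sizes and determinism

Default analysis sizes follow the study designs (66/69 samples, ~100–130
ASVs before filtering); null models default to 1000 SBM iterations and 999
label randomisations. The test suite uses reduced null counts (59–199)
where only a sign or calibration is asserted, and the full defaults in the
acceptance script. All randomised stages take a seed; the CLI derives
per-stage streams from the master seed, and two runs with the same seed
produce byte-identical stage tables (asserted in the tests).

## Known limitations

- The pair model conditions on occupancies and assumes exchangeable
  samples; strong temporal autocorrelation inflates its significance, which
  is intrinsic to the method rather than a bug.
- Walktrap on the metaweb treats edges as unweighted; tail probabilities
  are not used as weights.
- The Mantel correlogram uses equal-width Sturges classes; very skewed
  distance distributions may leave sparse outer classes (flagged, skipped).
- NRI/NTI undefined values (tiny samples, degenerate distances) are
  reported as NaN and excluded from summaries rather than imputed.
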