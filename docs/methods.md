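# Methods

This note documents the models, defaults and numerical choices behind
`specfp`, and what the synthetic benchmarks do and do not establish.

## Genes-only pathway graphs

KGML documents describe pathway maps as typed entries (gene, compound, map,
group) connected by relations. The parser projects these onto a simple,
undirected, unweighted graph over bare NCBI gene IDs:

* **All relation subtypes become edges.** Activation, inhibition, binding
  etc. all collapse to an undirected edge, because the downstream spectral
  machinery uses unweighted, undirected adjacency only.
* **Group entries** (protein complexes) are replaced by their component
  entries, each inheriting every edge of the group. No intra-complex edges
  are invented.
* **Compound pass-through.** A connection gene—compound—…—compound—gene is
  biologically a gene–gene interaction mediated by metabolites; each
  maximal compound-connected chain is contracted, i.e. all gene entries
  attached to one connected component of compound entries become pairwise
  adjacent. Map and other non-gene/non-compound entries are dropped along
  with their edges (no contraction through map links — a stated choice,
  since reference behavior for maplink inheritance is not fixed).
* **Multi-gene entries** are split into one node per gene, each inheriting
  the entry's edges; self-loops arising from splitting are dropped.
* **Isolated genes are retained.** Gene scores sum over a cluster's vertex
  sets, and silently dropping degree-0 genes would change the profiles.
* Organism prefixes (`hsa:` etc.) are stripped; mixed-organism documents
  are rejected.

Edge lists carry isolated nodes as single-token lines so round-trips are
lossless; for edge lists the pathway ID rides on the file stem.

## Spectral densities

The graph signature is the exact adjacency spectrum (dense symmetric
eigendecomposition — pathway graphs have tens to low hundreds of nodes, so
no approximate spectral methods are needed). Eigenvalues are smoothed with
a Gaussian kernel at the Silverman plug-in bandwidth

    h = 0.9 · min(sd, IQR/1.34) · n^(−1/5),

taking the minimum over the *positive* candidates (the `bw.nrd0`
convention) so an IQR of zero does not produce a degenerate bandwidth; a
fully constant spectrum (e.g. an edgeless graph) falls back to a documented
constant h = 10⁻³ with a warning. Raw eigenvalues are used by default; a
1/√n scaling flag exists for comparisons across very different graph
sizes.

Densities are evaluated on one grid per comparison: 512 points spanning the
pooled eigenvalue range padded by 3× the largest per-graph bandwidth. The
kernel width is clamped from below at half the median grid spacing, since a
kernel much narrower than the grid would lose its mass between grid points.
Before any log-ratio divergence, gridded densities are converted to cell
masses, floored at 10⁻¹² and renormalized, which keeps JS finite on
near-disjoint supports. Divergences are natural-log (nats) by default with
a base flag; the JS *distance* √JS is what enters distance matrices.

## Permutation tests

The two-set statistic is JS(mean density of A, mean density of B); the
k-group statistic is the mean over groups of JS(group mean, grand mean of
all pooled graphs). Both build the null by re-partitioning the pooled
graphs with the original group sizes; the grid is computed once from the
pool and reused in every permutation, since exchangeability requires a
fixed embedding. p-values use the add-one estimator
p = (1 + #{perm ≥ obs})/(B + 1), so p ≥ 1/(B+1) and is never 0. Defaults:
B = 1000 permutations, seed 1. A computed statistic below 10⁻¹⁵ is snapped
to exactly zero (rounding noise from identical mixtures). The k-group
statistic's exact form in other implementations varies; the form here is
validated by its own type-I calibration and power, under balanced and
unbalanced group sizes, rather than by matching any external code
bit-for-bit.

## Clustering and baselines

Graph collections are clustered by complete-linkage agglomerative
clustering (the `hclust` default) on the pairwise JS-distance matrix, cut
at k clusters (default k = 2, matching the two-condition design). The
three connectivity baselines summarize each graph by the distribution of a
node-level metric: degree uses its exact integer pmf on the pooled degree
support; betweenness and closeness are histogrammed on a shared 50-bin
equal-width grid over the pooled range. "Average centrality" is genuinely
ambiguous (per-graph scalar vs node-level distribution); the distributional
reading is the default because a JS distance between scalars is ill-posed,
and a scalar-summary mode (`summary="mean"`, absolute mean differences) is
exposed. Closeness is computed within connected components (the NetworkX
convention, component-size rescaled). Partition agreement uses the
standard permutation-model Adjusted Rand Index.

## Gene distinctiveness and fingerprint

The per-gene profile in cluster k is the empirical distribution of the
gene's degree across the cluster pathways that contain it, on the union of
degree values observed in the clusters compared, with additive smoothing
α = 0.5 per support point (KL is undefined whenever the opposing cluster
assigns zero mass; smoothing makes every profile strictly positive). An
alternative reading — a distribution over all vertices of the cluster —
is internally inconsistent with a per-gene divergence and is not
implemented. D^g[k] is the minimum KL against any other cluster; with two
clusters it is the single directed KL. Genes present in only one cluster
are excluded from the ranking by default; an opt-in "unique" policy
assigns them the maximum finite D^g + 10⁻⁶ and flags them, since treating
presence/absence as comparable evidence to rewiring is a modelling choice.

The driving set D_k takes the top 10 genes by D^g (configurable; ties at
the cutoff are all included and the tie is recorded in the selection-rule
string; ordering ties break by ascending gene ID). The fingerprint is one
row per pathway — Jaccard between D_k and the pathway's gene set — sorted
by KEGG class then descending Jaccard; within each cluster the
maximum-Jaccard pathways (ties included, score > 0) are flagged.
Fingerprint differences are reported per shared pathway (signed and
absolute) and aggregated per KEGG class as the mean of member differences.

## Pipeline gating

The `run` orchestration tests all groups jointly (ANOGVA), then each group
against a designated reference group; clustering and prioritization run
only for pairs with permutation p < α (default 0.05). Pooled pathway IDs
are namespaced `<group>:<pathway_id>` because the same pathway may occur
in both groups. Reruns with the same config and seed produce byte-identical
CSV/JSON artifacts; the run log is excluded from that guarantee because it
records per-stage wall time.

## Synthetic study conditions

The generators define the benchmark conditions:

* **Test calibration/power**: G(n=50, p=0.1) sets of 20 graphs per group
  (10 vs 40 for the unbalanced variant); alternatives G(50, 0.3) for the
  two-set test and Barabási–Albert (m=3) as the deviant third group for
  the k-group test. 200 permutations per test; 200 replicates for type-I,
  100 for power, sized to keep the full suite within minutes on one CPU
  while leaving binomial confidence intervals tight enough to be
  informative.
* **Degree-confounded clustering benchmark**: 10 ring lattices (k = 4)
  vs 10 random 4-regular graphs on 50 nodes. All 20 graphs share the exact
  same degree pmf, so the degree baseline is structurally blind here while
  the spectra differ — the designed separation between spectral and
  first-moment connectivity methods.
* **Planted collections**: 8 pathways per cluster, 30 background genes per
  pathway wired G(30, 0.15), one planted gene present in every pathway
  with exact degree 2 in cluster A and 12 in cluster B (attached to a
  uniform random sample of background genes). Planted/synthetic IDs are
  ≥ 900000, above the real NCBI human gene ID range. The null variant
  plants the same degree in both clusters, making the smoothed profiles
  identical and D^g exactly 0.

These fixtures emulate the *statistical* structure the method exploits —
collections of exchangeable graphs per condition, genes with shifted
wiring — but not real KEGG topology (hub distributions, modularity,
pathway size heterogeneity, shared subgraphs between pathways). Passing
the benchmarks therefore demonstrates correctness and calibration of the
machinery, not biological validity on any particular database snapshot;
results on real enrichment-derived pathway lists will also depend on the
database versions used to build them.

## Known limitations

* Exact dense eigendecomposition is O(n³) per graph; fine for pathways,
  wrong tool for graphs with 10⁴+ nodes.
* The permutation tests assume graphs are exchangeable units within a
  group; systematically paired or overlapping pathways violate this.
* Flat k must be chosen; no automatic model selection is provided.
* The KGML parser implements a stated contract for group/compound handling;
  other parsers make slightly different choices (notably around map links)
  and can produce different gene-gene edge sets from the same document.
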