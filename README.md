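# specfp

Spectral comparison, clustering and KL-divergence fingerprinting of pathway
gene networks.

Two diseases can share a diagnosis-level comorbidity while the biological
pathways underlying each are wired quite differently. `specfp` compares
*collections* of pathway networks — e.g. the KEGG pathways enriched for two
disorders' gene sets — by the shape of their adjacency spectra rather than by
gene-set overlap, and then asks *which genes* and *which pathways* drive the
difference. It is aimed at systems-biology researchers working with KEGG
KGML pathway maps or any collection of undirected gene–gene graphs.

## Method

A pathway is an undirected, unweighted simple graph over NCBI gene IDs
(KGML is parsed genes-only: compounds are contracted through, groups
expanded, map entries dropped). For each graph the full adjacency spectrum
λ₁ ≤ … ≤ λₙ is smoothed with a Gaussian kernel at the Silverman bandwidth
into a spectral density on a grid shared across the comparison.

* **Two-set test** (Takahashi-style): statistic JS(μ̂_A, μ̂_B), the
  Jensen–Shannon divergence between the mean spectral densities of two
  graph sets; the null is built by permuting the pooled graphs, and
  p = (1 + #{perm ≥ obs}) / (B + 1).
* **k-group test** (ANOGVA): mean over groups of JS(group mean, grand
  mean), same permutation scheme.
* **Clustering**: complete-linkage agglomerative clustering of the pairwise
  JS-distance matrix (√JS between per-graph densities), scored against
  known labels by the Adjusted Rand Index and compared with degree /
  betweenness / closeness baselines.
* **Gene prioritization**: for gene *g*, p_k is the distribution of its
  degree across the pathways of cluster *k* containing it (additively
  smoothed). Then

      KL_g[k,l] = Σ_x p_k(x) log(p_k(x)/p_l(x)),   D^g[k] = min_{l≠k} KL_g[k,l]

  and the driving set D_k collects the highest-D^g genes of cluster k.
* **Fingerprint**: each pathway S_k is ranked by the Jaccard similarity
  J(D_k, S_k) = |D_k ∩ S_k| / |D_k ∪ S_k|, sorted by KEGG class — pathways
  rich in driving genes are the ones pulling the clusters apart.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Build a synthetic two-cluster pathway collection in which gene `990001` is
wired with degree 2 in every cluster-A pathway and degree 12 in every
cluster-B pathway, then run the full chain:

```python
from specfp import (PlantedCollectionSpec, build_planted_collection,
                    gene_scores, takahashi_test, top_driving_genes, fingerprint)

a, b, truth = build_planted_collection(PlantedCollectionSpec(seed=1))
res = takahashi_test(a, b, n_permutations=1000, seed=1)
print(f"JS divergence = {res.statistic:.4f}, p = {res.p_value:.4g}")

scores = gene_scores({"A": a, "B": b})
for s in sorted(scores, key=lambda s: -s.distinctiveness)[:3]:
    print(f"gene {s.gene}  cluster {s.cluster}  D^g = {s.distinctiveness:.3f}")

driving = {l: top_driving_genes(scores, l, top_n=10) for l in ("A", "B")}
rows = fingerprint({"A": a, "B": b}, driving)
best = max((r for r in rows if r.cluster == "A"), key=lambda r: r.jaccard)
print(f"top pathway in A: {best.pathway_id}  Jaccard = {best.jaccard:.3f}")
```

This prints:

```
JS divergence = 0.0034, p = 0.002997
gene 990001  cluster A  D^g = 2.518
gene 990001  cluster B  D^g = 2.518
gene 900025  cluster A  D^g = 0.754
top pathway in A: synA-000  Jaccard = 0.323
```

The two clusters are significantly different (p ≈ 0.003); the planted gene
`990001` tops the distinctiveness ranking in both directions by a wide
margin (its degree profile is a point mass at 2 in A and at 12 in B, so
KL is large both ways), and the fingerprint ranks its host pathways first.

The same pipeline runs from the shell:

```sh
specfp simulate --model erdos_renyi --p 0.1 --out-dir groups/sparse
specfp simulate --model erdos_renyi --p 0.4 --seed 2 --out-dir groups/dense
specfp run --group sparse=groups/sparse --group dense=groups/dense --out-dir run1
```

`run1/` then contains the ANOGVA and pairwise test JSON, and — for every
pair whose permutation p-value clears the 0.05 gate — cluster labels, gene
scores, driving-gene sets and the fingerprint CSV. Non-significant pairs
are skipped with a note, mirroring the design of clustering only groups
that differ detectably.

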