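"""Gene distinctiveness and the pathway network fingerprint.

After a pooled pathway collection has been split into clusters, each gene is
scored by how differently it is wired in one cluster versus another.  The
gene's profile in a cluster is the empirical distribution of its degree
across the cluster's pathways that contain it; profiles are compared by KL
divergence on the union of observed degree values (with additive smoothing,
since a degree seen in one cluster may be unseen in the other):

    KL_g[k, l] = sum_x p_k(x) log(p_k(x) / p_l(x))

A gene's distinctiveness in cluster k is the minimum divergence against any
other cluster, D^g[k] = min_{l != k} KL_g[k, l]: a gene is only as
distinctive as its closest rival cluster allows.  The genes with the highest
D^g form the driving set D_k, and every pathway S_k in the cluster is ranked
by the Jaccard similarity J(D_k, S_k) = |D_k & S_k| / |D_k | S_k| — the
pathway "fingerprint".  Pathways rich in driving genes score high and are
the ones pulling the clusters apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import GeneGraph, GraphSet
from .spectral import kl_divergence

__all__ = [
    "DegreeProfile",
    "GeneScore",
    "DrivingGeneSet",
    "FingerprintRow",
    "GeneAbsentError",
    "gene_degrees",
    "gene_degree_profile",
    "gene_kl",
    "distinctiveness",
    "gene_scores",
    "top_driving_genes",
    "pathway_jaccard",
    "fingerprint",
    "fingerprint_frame",
    "fingerprint_difference",
]

#: Additive pseudocount per support point for degree-profile smoothing.
SMOOTHING_ALPHA = 0.5


class GeneAbsentError(KeyError):
    """Raised when a gene appears in no pathway of the queried cluster."""


@dataclass
class DegreeProfile:
    gene: str
    cluster: str
    support: np.ndarray
    probabilities: np.ndarray
    n_pathways: int

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.support) != len(self.probabilities):
            raise ValueError("support/probability length mismatch")
        if np.any(self.support < 0):
            raise ValueError("degree support must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class GeneScore:
    gene: str
    cluster: str
    kl_values: dict = field(default_factory=dict)
    distinctiveness: float = 0.0
    unique_to_cluster: bool = False

    def __post_init__(self) -> None:
        if self.kl_values and not self.unique_to_cluster:
            if abs(self.distinctiveness - min(self.kl_values.values())) > 1e-12:
                raise ValueError("distinctiveness must equal min of kl_values")
        if self.distinctiveness < 0:
            raise ValueError("distinctiveness must be non-negative")


@dataclass
class DrivingGeneSet:
    cluster: str
    genes: frozenset
    selection_rule: str


@dataclass
class FingerprintRow:
    pathway_id: str
    cluster: str
    kegg_class: str
    jaccard: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.jaccard <= 1.0:
            raise ValueError("jaccard must be in [0, 1]")


def gene_degrees(gene: str, cluster: GraphSet) -> list[int]:
    """Degree of ``gene`` in each cluster pathway containing it."""
    degs = [g.degree(gene) for g in cluster if gene in g]
    if not degs:
        raise GeneAbsentError(f"gene {gene!r} absent from cluster {cluster.label!r}")
    return degs


def gene_degree_profile(
    gene: str,
    cluster: GraphSet,
    support,
    alpha: float = SMOOTHING_ALPHA,
) -> DegreeProfile:
    """Smoothed pmf of the gene's degree across the cluster's pathways.

    ``support`` is the shared list of degree values over the clusters being
    compared; additive smoothing (``alpha`` pseudocount per support point)
    guarantees strictly positive probabilities so KL is finite.
    """
    degs = gene_degrees(gene, cluster)
    support = np.asarray(sorted(set(int(s) for s in support)), dtype=int)
    missing = set(degs) - set(support.tolist())
    if missing:
        raise ValueError(f"support is missing observed degrees {sorted(missing)}")
    counts = np.array([degs.count(int(s)) for s in support], dtype=float)
    probs = (counts + alpha) / (counts.sum() + alpha * len(support))
    return DegreeProfile(gene, cluster.label, support, probs, n_pathways=len(degs))


def gene_kl(
    gene: str,
    cluster_k: GraphSet,
    cluster_l: GraphSet,
    alpha: float = SMOOTHING_ALPHA,
) -> float:
    """Directed divergence KL_g[k, l] of the gene's degree profiles.

    The support is the union of degree values observed for the gene in the
    two clusters; note KL_g[k, l] != KL_g[l, k] in general.
    """
    support = sorted(set(gene_degrees(gene, cluster_k)) | set(gene_degrees(gene, cluster_l)))
    pk = gene_degree_profile(gene, cluster_k, support, alpha)
    pl = gene_degree_profile(gene, cluster_l, support, alpha)
    return kl_divergence(pk.probabilities, pl.probabilities)


def distinctiveness(
    gene: str, clusters: dict[str, GraphSet], home: str, alpha: float = SMOOTHING_ALPHA
) -> GeneScore:
    """D^g[k]: the gene's minimum KL divergence against any other cluster."""
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    if home not in clusters:
        raise KeyError(f"unknown cluster {home!r}")
    kls = {}
    for label, other in clusters.items():
        if label == home:
            continue
        try:
            kls[label] = gene_kl(gene, clusters[home], other, alpha)
        except GeneAbsentError:
            continue
    if not kls:
        raise GeneAbsentError(
            f"gene {gene!r} appears in no cluster other than {home!r}"
        )
    return GeneScore(gene, home, kls, min(kls.values()))


def gene_scores(
    clusters: dict[str, GraphSet],
    alpha: float = SMOOTHING_ALPHA,
    absent_policy: str = "exclude",
) -> list[GeneScore]:
    """Score every gene of every cluster by distinctiveness.

    Genes present in only one cluster have no defined divergence; by default
    they are excluded from the ranking.  ``absent_policy="unique"`` instead
    assigns them the maximum finite D^g observed plus a small increment and
    flags them ``unique_to_cluster`` — treating "wired differently" and
    "present at all" as comparable evidence is a modelling choice, hence
    opt-in.
    """
    if absent_policy not in {"exclude", "unique"}:
        raise ValueError("absent_policy must be 'exclude' or 'unique'")
    scores: list[GeneScore] = []
    uniques: list[tuple[str, str]] = []
    for label, cluster in clusters.items():
        for gene in sorted(cluster.genes(), key=_gene_key):
            try:
                scores.append(distinctiveness(gene, clusters, label, alpha))
            except GeneAbsentError:
                uniques.append((gene, label))
    if absent_policy == "unique" and uniques:
        ceiling = max((s.distinctiveness for s in scores), default=0.0) + 1e-6
        for gene, label in uniques:
            scores.append(
                GeneScore(gene, label, {}, ceiling, unique_to_cluster=True)
            )
    return scores


def _gene_key(gene: str):
    return (0, int(gene)) if str(gene).isdigit() else (1, str(gene))


def top_driving_genes(
    scores: list[GeneScore], cluster: str, top_n: int = 10
) -> DrivingGeneSet:
    """The driving set D_k: the ``top_n`` highest-D^g genes of a cluster.

    Ties are broken by ascending gene ID for ordering, and every gene tied
    with the score at the cutoff is included (so the set may exceed top_n).
    """
    pool = sorted(
        (s for s in scores if s.cluster == cluster),
        key=lambda s: (-s.distinctiveness, _gene_key(s.gene)),
    )
    if not pool:
        raise ValueError(f"no scores for cluster {cluster!r}")
    rule = f"top_n={top_n}"
    if len(pool) <= top_n:
        if len(pool) < top_n:
            warnings.warn(
                f"cluster {cluster!r} has only {len(pool)} scored genes (< {top_n})"
            )
        chosen = pool
    else:
        cutoff = pool[top_n - 1].distinctiveness
        chosen = [s for s in pool if s.distinctiveness >= cutoff]
        if len(chosen) > top_n:
            rule += f"+ties({len(chosen)})"
    return DrivingGeneSet(cluster, frozenset(s.gene for s in chosen), rule)


def pathway_jaccard(driving: DrivingGeneSet, pathway: GeneGraph) -> float:
    """Jaccard similarity between the driving-gene set and a pathway's genes."""
    a, b = set(driving.genes), set(pathway.nodes)
    union = a | b
    if not union:
        warnings.warn("both gene sets empty; Jaccard defined as 0")
        return 0.0
    return len(a & b) / len(union)


def fingerprint(
    clusters: dict[str, GraphSet],
    driving_sets: dict[str, DrivingGeneSet],
    metadata: dict[str, str] | None = None,
) -> list[FingerprintRow]:
    """Per-pathway Jaccard fingerprint, sorted by KEGG class then score.

    ``metadata`` maps pathway_id -> kegg_class and overrides per-graph
    classes; pathways with no class anywhere get "unknown".  Within each
    cluster the maximum-Jaccard pathways (ties included, score > 0) are
    flagged — these are the figures' bolded pathways.
    """
    rows: list[FingerprintRow] = []
    for label, cluster in clusters.items():
        driving = driving_sets[label]
        cluster_rows = []
        for g in cluster:
            kc = (metadata or {}).get(g.pathway_id) or g.kegg_class or "unknown"
            cluster_rows.append(
                FingerprintRow(g.pathway_id, label, kc, pathway_jaccard(driving, g))
            )
        best = max((r.jaccard for r in cluster_rows), default=0.0)
        for r in cluster_rows:
            r.flagged = best > 0 and r.jaccard == best
        rows.extend(cluster_rows)
    rows.sort(key=lambda r: (r.kegg_class, -r.jaccard, r.pathway_id))
    return rows


def fingerprint_frame(rows: list[FingerprintRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "cluster": r.cluster,
                "kegg_class": r.kegg_class,
                "jaccard": r.jaccard,
                "flagged": r.flagged,
            }
            for r in rows
        ]
    )


def fingerprint_difference(
    fp_a: list[FingerprintRow], fp_b: list[FingerprintRow]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed and absolute Jaccard differences between two fingerprints.

    Returns (per-pathway table, per-KEGG-class aggregate), both sorted by
    absolute difference; the class aggregate is the mean of its members'
    signed differences.  Matching is on pathway_id.
    """
    a = {r.pathway_id: r for r in fp_a}
    b = {r.pathway_id: r for r in fp_b}
    shared = sorted(set(a) & set(b))
    if not shared:
        warnings.warn("fingerprints share no pathways")
        empty = pd.DataFrame(
            columns=["pathway_id", "kegg_class", "jaccard_a", "jaccard_b", "difference", "abs_difference"]
        )
        return empty, pd.DataFrame(columns=["kegg_class", "difference", "abs_difference"])
    rows = []
    for pid in shared:
        d = a[pid].jaccard - b[pid].jaccard
        rows.append(
            {
                "pathway_id": pid,
                "kegg_class": a[pid].kegg_class,
                "jaccard_a": a[pid].jaccard,
                "jaccard_b": b[pid].jaccard,
                "difference": d,
                "abs_difference": abs(d),
            }
        )
    by_pathway = (
        pd.DataFrame(rows)
        .sort_values(["abs_difference", "pathway_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    by_class = (
        by_pathway.groupby("kegg_class", as_index=False)["difference"]
        .mean()
        .assign(abs_difference=lambda df: df["difference"].abs())
        .sort_values(["abs_difference", "kegg_class"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return by_pathway, by_class
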