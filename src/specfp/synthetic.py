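"""Synthetic inputs: random-graph sets, planted collections, KGML fixtures.

Three generators cover the pipeline's test surface:

* :func:`sample_graph_set` draws graph collections from named random-graph
  models (Erdős–Rényi, k-regular, Watts–Strogatz, Barabási–Albert, ring
  lattice) — the null and alternative worlds of the permutation tests.
* :func:`build_planted_collection` builds a two-cluster pathway collection
  in which designated genes are wired with a different degree in each
  cluster, the ground truth for distinctiveness recovery.
* :func:`synth_kgml` emits a miniature KGML document together with the
  exactly expected genes-only graph, exercising compound pass-through, group
  expansion and multi-gene entries.

Synthetic gene IDs live at or above 900000, a range no real NCBI human gene
ID occupies, so fixture output can never be mistaken for biology.  All
generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from lxml import etree

from .graphs import GeneGraph, GraphSet, parse_kgml

__all__ = [
    "ModelSpec",
    "PlantedCollectionSpec",
    "sample_graph_set",
    "build_planted_collection",
    "synth_kgml",
    "MODELS",
]

GENE_ID_BASE = 900000
PLANTED_ID_BASE = 990000

MODELS = ("erdos_renyi", "k_regular", "watts_strogatz", "barabasi_albert", "ring_lattice")


@dataclass
class ModelSpec:
    """A named random-graph model plus its parameters and replication count."""

    model: str
    n: int
    n_graphs: int = 1
    p: float | None = None      # edge probability (erdos_renyi)
    k: int | None = None        # degree (k_regular) / ring neighbors (ws, lattice)
    m: int | None = None        # attachment edges (barabasi_albert)
    rewire: float | None = None  # rewiring probability (watts_strogatz)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n < 1 or self.n_graphs < 1:
            raise ValueError("n and n_graphs must be positive")


def _node_map(n: int) -> dict:
    return {i: str(GENE_ID_BASE + i) for i in range(n)}


def _draw(spec: ModelSpec, seed: int) -> nx.Graph:
    if spec.model == "erdos_renyi":
        if spec.p is None:
            raise ValueError("erdos_renyi requires p")
        g = nx.gnp_random_graph(spec.n, spec.p, seed=seed)
    elif spec.model == "k_regular":
        if spec.k is None:
            raise ValueError("k_regular requires k")
        if (spec.n * spec.k) % 2 != 0 or spec.k >= spec.n:
            raise ValueError(f"no {spec.k}-regular graph on {spec.n} nodes")
        g = nx.random_regular_graph(spec.k, spec.n, seed=seed)
    elif spec.model == "watts_strogatz":
        if spec.k is None or spec.rewire is None:
            raise ValueError("watts_strogatz requires k and rewire")
        g = nx.watts_strogatz_graph(spec.n, spec.k, spec.rewire, seed=seed)
    elif spec.model == "barabasi_albert":
        if spec.m is None:
            raise ValueError("barabasi_albert requires m")
        g = nx.barabasi_albert_graph(spec.n, spec.m, seed=seed)
    else:  # ring_lattice: Watts-Strogatz with zero rewiring, deterministic
        if spec.k is None:
            raise ValueError("ring_lattice requires k")
        g = nx.watts_strogatz_graph(spec.n, spec.k, 0.0)
    return nx.relabel_nodes(g, _node_map(spec.n))


def sample_graph_set(spec: ModelSpec, label: str | None = None) -> GraphSet:
    """Draw ``spec.n_graphs`` independent graphs; reproducible under seed."""
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s) for s in ss.generate_state(spec.n_graphs) >> 1]
    label = label or spec.model
    graphs = [
        GeneGraph(f"{label}-{i:03d}", _draw(spec, child_seeds[i]))
        for i in range(spec.n_graphs)
    ]
    return GraphSet(label, graphs)


@dataclass
class PlantedCollectionSpec:
    """Two-cluster collection with genes planted at cluster-specific degrees."""

    n_pathways: int = 8          # pathways per cluster
    n: int = 30                  # background genes per pathway
    background_p: float = 0.15   # Erdős–Rényi edge probability of the background
    planted_genes: tuple = (str(PLANTED_ID_BASE + 1),)
    degree_a: int = 2            # planted-gene degree in every cluster-A pathway
    degree_b: int = 12           # planted-gene degree in every cluster-B pathway
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.n < 2:
            raise ValueError("need >= 1 pathway and >= 2 background genes")
        for d in (self.degree_a, self.degree_b):
            if not 1 <= d <= self.n:
                raise ValueError(f"planted degree {d} infeasible for n={self.n}")
        if not 0 <= self.background_p <= 1:
            raise ValueError("background_p must be a probability")


def _planted_pathway(
    pid: str, spec: PlantedCollectionSpec, degree: int, seed: int
) -> GeneGraph:
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(spec.n, spec.background_p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, _node_map(spec.n))
    background = sorted(g.nodes)
    for gene in spec.planted_genes:
        targets = rng.choice(background, size=degree, replace=False)
        g.add_node(str(gene))
        for t in targets:
            g.add_edge(str(gene), t)
    return GeneGraph(pid, g)


def build_planted_collection(
    spec: PlantedCollectionSpec,
) -> tuple[GraphSet, GraphSet, dict]:
    """Build clusters A and B plus a truth record of the planted structure.

    Every pathway shares the same background gene universe; each planted
    gene appears in every pathway, attached to a uniform random sample of
    background genes of the cluster's target size, so its degree profile is
    a point mass at ``degree_a`` in A and ``degree_b`` in B while background
    genes keep statistically identical wiring in both clusters.
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s) for s in ss.generate_state(2 * spec.n_pathways) >> 1]
    a_graphs = [
        _planted_pathway(f"synA-{i:03d}", spec, spec.degree_a, seeds[i])
        for i in range(spec.n_pathways)
    ]
    b_graphs = [
        _planted_pathway(f"synB-{i:03d}", spec, spec.degree_b, seeds[spec.n_pathways + i])
        for i in range(spec.n_pathways)
    ]
    set_a, set_b = GraphSet("clusterA", a_graphs), GraphSet("clusterB", b_graphs)
    truth = {
        "planted_genes": [str(g) for g in spec.planted_genes],
        "degree_a": spec.degree_a,
        "degree_b": spec.degree_b,
        "host_pathways": {
            str(g): [gr.pathway_id for gr in a_graphs + b_graphs]
            for g in spec.planted_genes
        },
        "seed": spec.seed,
    }
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# KGML fixture generator
# ---------------------------------------------------------------------------


def synth_kgml(
    n_genes: int,
    n_compound_bridges: int = 0,
    n_groups: int = 0,
    multi_gene_entries: int = 0,
    seed: int = 1,
    pathway_id: str = "hsa99999",
    organism: str = "hsa",
) -> tuple[str, GeneGraph]:
    """A miniature KGML document plus its exactly expected genes-only graph.

    The base layout is a path over ``n_genes`` single-gene entries.  Each
    compound bridge adds two fresh genes joined through a compound entry
    (expected: one direct gene-gene edge).  Each group adds a two-gene group
    entry related to the first path gene (expected: both components edged to
    it).  Each multi-gene entry lists two genes in one entry related to the
    first path gene (expected: both genes edged to it).  Entry IDs and
    document order are shuffled with ``seed`` so parsing must be
    order-independent.
    """
    if min(n_genes, n_compound_bridges, n_groups, multi_gene_entries) < 0:
        raise ValueError("counts must be non-negative")
    if (n_groups or multi_gene_entries) and n_genes < 1:
        raise ValueError("groups and multi-gene entries need at least one path gene")

    rng = np.random.default_rng(seed)
    entries: list[dict] = []      # {"type","names"| "components"}
    relations: list[tuple[int, int]] = []  # indices into entries
    exp_nodes: set[str] = set()
    exp_edges: set[frozenset] = set()

    def add_entry(**kw) -> int:
        entries.append(kw)
        return len(entries) - 1

    path_genes = [str(GENE_ID_BASE + 1 + i) for i in range(n_genes)]
    path_idx = [add_entry(type="gene", names=[g]) for g in path_genes]
    exp_nodes.update(path_genes)
    for i in range(n_genes - 1):
        relations.append((path_idx[i], path_idx[i + 1]))
        exp_edges.add(frozenset((path_genes[i], path_genes[i + 1])))

    for j in range(n_compound_bridges):
        ga, gb = str(910000 + 2 * j + 1), str(910000 + 2 * j + 2)
        ia = add_entry(type="gene", names=[ga])
        ib = add_entry(type="gene", names=[gb])
        ic = add_entry(type="compound", names=[f"C{j:05d}"])
        relations.append((ia, ic))
        relations.append((ic, ib))
        exp_nodes.update((ga, gb))
        exp_edges.add(frozenset((ga, gb)))

    for j in range(n_groups):
        ga, gb = str(920000 + 2 * j + 1), str(920000 + 2 * j + 2)
        ia = add_entry(type="gene", names=[ga])
        ib = add_entry(type="gene", names=[gb])
        ig = add_entry(type="group", components=[ia, ib])
        relations.append((ig, path_idx[0]))
        exp_nodes.update((ga, gb))
        exp_edges.add(frozenset((ga, path_genes[0])))
        exp_edges.add(frozenset((gb, path_genes[0])))

    for j in range(multi_gene_entries):
        ga, gb = str(930000 + 2 * j + 1), str(930000 + 2 * j + 2)
        im = add_entry(type="gene", names=[ga, gb])
        relations.append((im, path_idx[0]))
        exp_nodes.update((ga, gb))
        exp_edges.add(frozenset((ga, path_genes[0])))
        exp_edges.add(frozenset((gb, path_genes[0])))

    # shuffle KGML entry ids and document order
    ids = rng.permutation(np.arange(1, len(entries) + 1)).tolist() if entries else []
    order = rng.permutation(len(entries)).tolist() if entries else []

    root = etree.Element(
        "pathway", name=f"path:{pathway_id}", org=organism, title="synthetic fixture"
    )
    for pos in order:
        e = entries[pos]
        if e["type"] == "group":
            el = etree.SubElement(root, "entry", id=str(ids[pos]), name="undefined", type="group")
            for c in e["components"]:
                etree.SubElement(el, "component", id=str(ids[c]))
        elif e["type"] == "compound":
            etree.SubElement(
                root, "entry", id=str(ids[pos]), name=f"cpd:{e['names'][0]}", type="compound"
            )
        else:
            name = " ".join(f"{organism}:{g}" for g in e["names"])
            etree.SubElement(root, "entry", id=str(ids[pos]), name=name, type="gene")
    for a, b in relations:
        etree.SubElement(
            root, "relation", entry1=str(ids[a]), entry2=str(ids[b]), type="PPrel"
        )

    doc = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    expected = GeneGraph.from_edges(
        pathway_id, exp_nodes, [tuple(e) for e in exp_edges], title="synthetic fixture"
    )
    return doc.decode(), expected


def _parse_self_check(*args, **kwargs):  # pragma: no cover - debugging helper
    doc, expected = synth_kgml(*args, **kwargs)
    got = parse_kgml(doc)
    return got.nodes == expected.nodes and got.edges == expected.edges
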