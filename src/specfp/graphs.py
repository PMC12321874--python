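"""Genes-only pathway networks.

A pathway is represented as an undirected, unweighted, simple graph whose
nodes are bare NCBI gene identifiers (organism prefix stripped).  Graphs are
built either from KGML (KEGG Markup Language) documents or from plain
edge-list / GraphML files.  KGML construction removes every compound, map and
group entry: groups are expanded into their component entries, and gene
connections that run through chains of compounds are contracted into direct
gene-gene edges so that connectivity carried by metabolites survives the
genes-only projection.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from lxml import etree

__all__ = [
    "GeneGraph",
    "GraphSet",
    "parse_kgml",
    "load_graph",
    "load_graph_set",
    "write_graph",
    "write_metadata",
]

#: KGML entry types that never survive into a genes-only graph.
_DROPPED_ENTRY_TYPES = frozenset(
    {"map", "ortholog", "enzyme", "brite", "other", "reaction"}
)


@dataclass
class GeneGraph:
    """One pathway as a simple undirected graph over NCBI gene IDs."""

    pathway_id: str
    graph: nx.Graph
    title: str = ""
    kegg_class: str = ""

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        bad = [n for n in g.nodes if not str(n).isdigit()]
        if bad:
            raise ValueError(f"node labels must be bare numeric gene IDs, got {bad[:3]}")

    @classmethod
    def from_edges(
        cls,
        pathway_id: str,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        title: str = "",
        kegg_class: str = "",
    ) -> "GeneGraph":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        g.add_edges_from((str(u), str(v)) for u, v in edges if str(u) != str(v))
        return cls(pathway_id, g, title=title, kegg_class=kegg_class)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class GraphSet:
    """A labeled, ordered collection of pathway graphs.

    Pathway IDs must be unique within the set; the set must be non-empty.
    """

    label: str
    graphs: list[GeneGraph] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.graphs:
            raise ValueError(f"GraphSet {self.label!r} is empty")
        ids = [g.pathway_id for g in self.graphs]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate pathway IDs in {self.label!r}: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, i):
        return self.graphs[i]

    @property
    def pathway_ids(self) -> list[str]:
        return [g.pathway_id for g in self.graphs]

    def genes(self) -> frozenset:
        """Union of gene IDs over all pathways in the set."""
        out: set = set()
        for g in self.graphs:
            out |= g.nodes
        return frozenset(out)


# ---------------------------------------------------------------------------
# KGML parsing
# ---------------------------------------------------------------------------


def _split_gene_names(name: str) -> tuple[list[str], set[str]]:
    """Split a KGML entry name attribute into bare gene IDs and prefixes."""
    genes, prefixes = [], set()
    for token in name.split():
        if ":" in token:
            prefix, gid = token.split(":", 1)
            prefixes.add(prefix)
        else:
            gid = token
        if gid:
            genes.append(gid)
    return genes, prefixes


def parse_kgml(source) -> GeneGraph:
    """Parse a KGML document into a genes-only :class:`GeneGraph`.

    ``source`` may be a path, an open file object, or a bytes/str XML
    document.  All relation subtypes produce an edge (direction and sign are
    discarded), group entries are expanded into their components, and gene
    connections running through compound-only chains are contracted into
    direct gene-gene edges.  Multi-gene entries become one node per gene,
    each inheriting every edge of the entry.  Self-loops are dropped; genes
    left with no edges are retained.
    """
    if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("<"):
        tree = etree.parse(str(source))
        root = tree.getroot()
    else:
        data = source.read() if hasattr(source, "read") else source
        if isinstance(data, str):
            data = data.encode()
        root = etree.fromstring(data)

    pathway_id = (root.get("name") or "").split(":")[-1]
    title = root.get("title") or ""

    entry_type: dict[str, str] = {}
    entry_genes: dict[str, list[str]] = {}
    entry_components: dict[str, list[str]] = {}
    prefixes: set[str] = set()

    for e in root.findall("entry"):
        eid = e.get("id")
        etype = e.get("type") or "other"
        entry_type[eid] = etype
        if etype == "gene":
            genes, pfx = _split_gene_names(e.get("name") or "")
            entry_genes[eid] = genes
            prefixes |= pfx
        elif etype == "group":
            entry_components[eid] = [c.get("id") for c in e.findall("component")]

    if len(prefixes) > 1:
        raise ValueError(f"mixed organism prefixes in KGML: {sorted(prefixes)}")

    # entry-level undirected edges from relations
    rel_edges: set[frozenset] = set()
    for r in root.findall("relation"):
        a, b = r.get("entry1"), r.get("entry2")
        if a in entry_type and b in entry_type and a != b:
            rel_edges.add(frozenset((a, b)))

    # expand groups: each component inherits every edge of the group
    adj: dict[str, set[str]] = {eid: set() for eid in entry_type}
    for edge in rel_edges:
        u, v = tuple(edge)
        adj[u].add(v)
        adj[v].add(u)
    for gid, comps in entry_components.items():
        comps = [c for c in comps if c in entry_type and entry_type[c] != "group"]
        for c in comps:
            for nb in adj[gid]:
                if nb != c:
                    adj[c].add(nb)
                    adj[nb].add(c)
        for nb in list(adj[gid]):
            adj[nb].discard(gid)
        adj[gid] = set()

    def is_gene(eid: str) -> bool:
        return entry_type.get(eid) == "gene"

    def is_compound(eid: str) -> bool:
        return entry_type.get(eid) == "compound"

    # contract gene—compound—...—compound—gene chains: genes attached to the
    # same connected component of compound entries become directly adjacent
    compound_ids = [eid for eid in entry_type if is_compound(eid)]
    seen: set[str] = set()
    gene_gene: set[frozenset] = set()
    for start in compound_ids:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            c = stack.pop()
            if c in comp:
                continue
            comp.add(c)
            stack.extend(nb for nb in adj[c] if is_compound(nb) and nb not in comp)
        seen |= comp
        attached = sorted({nb for c in comp for nb in adj[c] if is_gene(nb)})
        for i, u in enumerate(attached):
            for v in attached[i + 1 :]:
                gene_gene.add(frozenset((u, v)))

    for edge in rel_edges:
        u, v = tuple(edge)
        if is_gene(u) and is_gene(v) and v in adj[u]:
            gene_gene.add(frozenset((u, v)))
    # group expansion may have created gene-gene adjacencies absent from rel_edges
    for u in adj:
        if not is_gene(u):
            continue
        for v in adj[u]:
            if is_gene(v):
                gene_gene.add(frozenset((u, v)))

    g = nx.Graph()
    for eid, genes in entry_genes.items():
        g.add_nodes_from(genes)
    for edge in gene_gene:
        u, v = tuple(edge)
        for gu in entry_genes.get(u, ()):
            for gv in entry_genes.get(v, ()):
                if gu != gv:
                    g.add_edge(gu, gv)

    if g.number_of_nodes() == 0:
        warnings.warn(f"KGML {pathway_id or '<unnamed>'} contains no gene entries")
    return GeneGraph(pathway_id, g, title=title)


# ---------------------------------------------------------------------------
# Plain-graph I/O
# ---------------------------------------------------------------------------


def _read_edge_list(path: Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if lineno == 0 and any(not t.isdigit() for t in tokens):
                continue  # header row
            if len(tokens) == 1:
                g.add_node(tokens[0])
            elif len(tokens) >= 2:
                if tokens[0] != tokens[1]:
                    g.add_edge(tokens[0], tokens[1])
                else:
                    g.add_node(tokens[0])
    return g


def load_graph(path, pathway_id: str | None = None) -> GeneGraph:
    """Load a single pathway graph from KGML, edge list, or GraphML."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xml", ".kgml"}:
        return parse_kgml(path)
    if suffix == ".graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in raw.nodes)
        g.add_edges_from((str(u), str(v)) for u, v in raw.edges if str(u) != str(v))
        pid = raw.graph.get("pathway_id") or pathway_id or path.stem
        return GeneGraph(
            pid,
            g,
            title=raw.graph.get("title", ""),
            kegg_class=raw.graph.get("kegg_class", ""),
        )
    g = _read_edge_list(path)
    return GeneGraph(pathway_id or path.stem, g)


def load_graph_set(
    paths: Sequence,
    label: str,
    metadata_table: Mapping[str, Mapping] | "object" = None,
) -> GraphSet:
    """Load a labeled collection of pathway graphs.

    ``metadata_table`` optionally maps pathway_id to a mapping with ``title``
    and/or ``kegg_class`` keys (a pandas DataFrame indexed by pathway_id also
    works via ``.loc``).  Pathways missing from the table keep an empty
    kegg_class, with a warning.
    """
    meta = _coerce_metadata(metadata_table)
    graphs = []
    for p in paths:
        g = load_graph(p)
        if meta is not None:
            row = meta.get(g.pathway_id)
            if row is None:
                warnings.warn(f"no metadata for pathway {g.pathway_id!r}")
            else:
                g.title = row.get("title", g.title) or g.title
                g.kegg_class = row.get("kegg_class", g.kegg_class) or g.kegg_class
        graphs.append(g)
    return GraphSet(label, graphs)


def _coerce_metadata(table) -> dict | None:
    if table is None:
        return None
    if isinstance(table, (str, Path)):
        out = {}
        with open(table, newline="") as fh:
            for row in csv.DictReader(fh):
                out[row["pathway_id"]] = row
        return out
    if hasattr(table, "iterrows"):  # DataFrame with pathway_id column or index
        out = {}
        for _, row in table.iterrows():
            key = row.get("pathway_id", row.name)
            out[str(key)] = dict(row)
        return out
    return dict(table)


def write_graph(graph: GeneGraph, path, fmt: str = "edge_list") -> Path:
    """Serialize a pathway graph.

    ``edge_list`` writes one tab-separated edge per line; isolated nodes are
    written as single-token lines so the node set round-trips exactly.  For
    edge lists the pathway identity is carried by the file stem, so name the
    file after the pathway ID if it must survive a round trip.  ``graphml``
    stores pathway_id/title/kegg_class as graph attributes.
    """
    path = Path(path)
    if fmt == "edge_list":
        with open(path, "w") as fh:
            for u, v in sorted((sorted(e) for e in graph.graph.edges)):
                fh.write(f"{u}\t{v}\n")
            for n in sorted(nx.isolates(graph.graph)):
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        g = graph.graph.copy()
        g.graph["pathway_id"] = graph.pathway_id
        g.graph["title"] = graph.title
        g.graph["kegg_class"] = graph.kegg_class
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'edge_list' or 'graphml'")
    return path


def write_metadata(graphs: Iterable[GeneGraph], path) -> Path:
    """Write pathway metadata (pathway_id, title, kegg_class) as CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pathway_id", "title", "kegg_class"])
        for g in graphs:
            w.writerow([g.pathway_id, g.title, g.kegg_class])
    return path
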