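"""Ontology parsing, gene annotation, and the layered network wiring diagram.

The visible network mirrors a Gene Ontology-style hierarchy: each retained
term becomes a small neural module wired to (i) the genes annotated to it
and (ii) the modules of its retained children. This module turns an OBO
file plus annotation tables into that wiring diagram (`OntologyLayout`),
pruning terms with neither annotated genes nor surviving children and
re-attaching orphaned children to their nearest retained ancestors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

OMICS_CHANNELS = ("mutation", "amplification", "deletion")
ALL_CHANNELS = OMICS_CHANNELS + ("expression",)


class OntologyError(ValueError):
    """Structural problem with the ontology (cycle, missing/ambiguous root)."""


@dataclass
class OntologyGraph:
    """A rooted DAG of terms linked by child -> parent ``is_a`` edges."""

    terms: set[str]
    edges: set[tuple[str, str]]  # (child, parent)
    root: str

    def parents_of(self, term: str) -> list[str]:
        return sorted(p for c, p in self.edges if c == term)

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle through edge {cyc[0][:2]}")
        roots = [t for t in self.terms if g.out_degree(t) == 0]
        if len(roots) != 1 or roots[0] != self.root:
            raise OntologyError(
                f"expected a single root {self.root!r}, found sinks {sorted(roots)}"
            )
        for t in self.terms:
            if t != self.root and not nx.has_path(g, t, self.root):
                raise OntologyError(f"term {t!r} has no is_a path to the root")


@dataclass
class TermAnnotation:
    """Per-channel term -> gene-set maps restricted to a declared gene universe."""

    channels: dict[str, dict[str, set[str]]]
    universes: dict[str, list[str]]
    dropped_genes: dict[str, int] = field(default_factory=dict)
    dropped_terms: dict[str, int] = field(default_factory=dict)

    def genes(self, channel: str, term: str) -> set[str]:
        return self.channels.get(channel, {}).get(term, set())


def parse_obo(path: str, root: str | None = None) -> OntologyGraph:
    """Parse an OBO file keeping only ``is_a`` edges between non-obsolete terms.

    If `root` is given, the graph is restricted to terms from which the root
    is reachable; otherwise the unique sink of the full graph is the root.
    """
    try:
        multi = obonet.read_obo(path)
    except OSError:
        raise
    g = nx.DiGraph()
    for term, data in multi.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            continue
        g.add_node(term)
    for child, parent, key in multi.edges(keys=True):
        if key != "is_a":
            continue
        if child in g and parent in g:
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle through edge {cyc[0][:2]}")
    if root is None:
        sinks = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(sinks) != 1:
            raise OntologyError(
                f"expected exactly one root term, found {len(sinks)}: {sorted(sinks)[:5]}"
            )
        root = sinks[0]
    elif root not in g:
        raise OntologyError(f"requested root {root!r} not present in the ontology")
    keep = {t for t in g.nodes if t == root or nx.has_path(g, t, root)}
    edges = {(c, p) for c, p in g.edges if c in keep and p in keep}
    graph = OntologyGraph(terms=keep, edges=edges, root=root)
    graph.validate()
    return graph


def load_annotations(
    paths: dict[str, str],
    universes: dict[str, list[str]],
    graph: OntologyGraph | None = None,
    unknown_term: str = "warn",
) -> TermAnnotation:
    """Load term -> gene annotation files, one per omics channel.

    Each file is either GMT (term, description, genes...) or a two-column
    TSV (term, gene). Genes outside the channel's declared universe are
    dropped and counted; terms absent from `graph` are warned about and
    dropped (or raise, with ``unknown_term='error'``).
    """
    channels: dict[str, dict[str, set[str]]] = {}
    dropped_genes: dict[str, int] = {}
    dropped_terms: dict[str, int] = {}
    for channel, path in paths.items():
        universe = set(universes[channel])
        term_map: dict[str, set[str]] = {}
        n_gene_drop = n_term_drop = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) >= 3:  # GMT: term, description, genes...
                    term, genes = fields[0], fields[2:]
                else:  # two-column TSV
                    term, genes = fields[0], fields[1:]
                if graph is not None and term not in graph.terms:
                    if unknown_term == "error":
                        raise KeyError(f"annotation term {term!r} not in ontology")
                    n_term_drop += 1
                    continue
                bucket = term_map.setdefault(term, set())
                for gene in genes:
                    if gene in universe:
                        bucket.add(gene)
                    else:
                        n_gene_drop += 1
        channels[channel] = term_map
        dropped_genes[channel] = n_gene_drop
        dropped_terms[channel] = n_term_drop
        if n_gene_drop or n_term_drop:
            logger.warning(
                "channel %s: dropped %d out-of-universe gene entries, "
                "%d unknown-term lines", channel, n_gene_drop, n_term_drop,
            )
    return TermAnnotation(channels=channels, universes=dict(universes),
                          dropped_genes=dropped_genes, dropped_terms=dropped_terms)


@dataclass
class OntologyLayout:
    """The pruned, layered wiring diagram the model is built from.

    `order` lists retained terms children-strictly-before-parents.
    `children[t]` are the retained terms wired into module `t` (nearest
    retained descendants in the original DAG). `gene_index[channel][t]`
    holds the column indices of module `t`'s input genes in that channel's
    gene dictionary (`gene_dict[channel]`, gene -> column).
    """

    order: list[str]
    root: str
    children: dict[str, list[str]]
    gene_index: dict[str, dict[str, list[int]]]
    gene_dict: dict[str, dict[str, int]]
    depth: dict[str, int]

    @property
    def terms(self) -> set[str]:
        return set(self.order)

    def leaves(self) -> list[str]:
        return [t for t in self.order if not self.children[t]]

    def term_genes(self, channel: str, term: str) -> list[str]:
        rev = {i: g for g, i in self.gene_dict[channel].items()}
        return [rev[i] for i in self.gene_index[channel][term]]

    def as_graph(self) -> OntologyGraph:
        edges = {(c, p) for p, cs in self.children.items() for c in cs}
        return OntologyGraph(terms=self.terms, edges=edges, root=self.root)

    # -- serialization --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "order": self.order,
            "root": self.root,
            "children": self.children,
            "gene_index": self.gene_index,
            "gene_dict": self.gene_dict,
            "depth": self.depth,
        })

    @classmethod
    def from_json(cls, text: str) -> "OntologyLayout":
        d = json.loads(text)
        return cls(order=d["order"], root=d["root"], children=d["children"],
                   gene_index=d["gene_index"], gene_dict=d["gene_dict"],
                   depth=d["depth"])


def build_layout(
    graph: OntologyGraph,
    ann: TermAnnotation,
    min_genes: int = 1,
    propagate: bool = False,
) -> OntologyLayout:
    """Prune the ontology and lay out the retained terms for model building.

    Retention rule: a term is kept iff the union of its mutation /
    amplification / deletion genes has at least `min_genes` members, or it
    has at least one retained child. Children of pruned terms are re-attached
    to their nearest retained ancestors. With `propagate`, each term's gene
    sets are unioned over all its descendants first (true-path rule).
    """
    graph.validate()
    g = nx.DiGraph()
    g.add_nodes_from(graph.terms)
    g.add_edges_from(graph.edges)

    direct: dict[str, dict[str, set[str]]] = {
        ch: {t: set(ann.genes(ch, t)) for t in graph.terms} for ch in ALL_CHANNELS
    }
    topo = list(nx.topological_sort(g))  # children before parents
    genes_of = direct
    if propagate:
        genes_of = {ch: {t: set(direct[ch][t]) for t in graph.terms}
                    for ch in ALL_CHANNELS}
        for t in topo:
            for parent in g.successors(t):
                for ch in ALL_CHANNELS:
                    genes_of[ch][parent] |= genes_of[ch][t]

    retained: set[str] = set()
    has_retained_desc: dict[str, bool] = {}
    for t in topo:
        omics_union = set().union(*(genes_of[ch][t] for ch in OMICS_CHANNELS))
        has_retained_desc[t] = any(
            c in retained or has_retained_desc[c] for c in g.predecessors(t)
        )
        if len(omics_union) >= min_genes or has_retained_desc[t]:
            retained.add(t)
    if graph.root not in retained:
        raise OntologyError("empty model: the root term was pruned "
                            "(no annotated genes anywhere)")

    # nearest retained ancestors of each retained term
    children: dict[str, list[str]] = {t: [] for t in retained}
    for t in retained:
        if t == graph.root:
            continue
        anc: set[str] = set()
        stack = list(g.successors(t))
        seen: set[str] = set()
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            if u in retained:
                anc.add(u)
            else:
                stack.extend(g.successors(u))
        for p in anc:
            children[p].append(t)
    for p in children:
        children[p] = sorted(children[p])

    depth: dict[str, int] = {}
    for t in topo:
        if t not in retained:
            continue
        kids = children[t]
        depth[t] = 0 if not kids else 1 + max(depth[c] for c in kids)
    order = sorted(retained, key=lambda t: (depth[t], t))

    gene_dict: dict[str, dict[str, int]] = {}
    gene_index: dict[str, dict[str, list[int]]] = {}
    for ch in ALL_CHANNELS:
        used = sorted(set().union(*(genes_of[ch][t] for t in retained))
                      if retained else set())
        gene_dict[ch] = {gname: i for i, gname in enumerate(used)}
        gene_index[ch] = {
            t: sorted(gene_dict[ch][gname] for gname in genes_of[ch][t])
            for t in retained
        }
    return OntologyLayout(order=order, root=graph.root, children=children,
                          gene_index=gene_index, gene_dict=gene_dict, depth=depth)
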