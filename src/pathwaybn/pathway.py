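"""Pathway graphs, search constraints, and compound attachment.

The seed (initially mapped) pathway, the constraint set fed to structure
search, and the final metabolic network (relation graph plus compounds) all
live here.  A pathway graph is a directed gene-level graph; edges flagged
``required`` come from the initial reference mapping and are pinned during
search, while the ``allowed`` whitelist comes from the relation
knowledgebase — everything outside it is excluded from search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .knowledgebase import GeneKOMap, PathwayMap, RelationKnowledgebase, allowed_gene_edges

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class PathwayGraph:
    """Directed gene-level graph with a subset of edges pinned as required."""

    nodes: set[str]
    edges: set[Edge]
    required: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.edges = set(self.edges)
        self.required = set(self.required)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge {u}->{v} not allowed")
            self.nodes.update((u, v))
        if not self.required <= self.edges:
            raise ValueError("required edges must be a subset of edges")

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(set(self.nodes), set(self.edges), set(self.required))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def parents(self, node: str) -> list[str]:
        return sorted(u for (u, v) in self.edges if v == node)

    def to_tsv(self) -> str:
        lines = ["source\ttarget\trequired"]
        for u, v in sorted(self.edges):
            lines.append(f"{u}\t{v}\t{int((u, v) in self.required)}")
        for n in sorted(self.nodes):
            if not any(n in e for e in self.edges):
                lines.append(f"{n}\t\t0")  # isolated node
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PathwayGraph":
        nodes, edges, required = set(), set(), set()
        for raw in text.strip().splitlines()[1:]:
            u, v, req = (raw.split("\t") + ["", "0"])[:3]
            if v:
                edges.add((u, v))
                if req.strip() == "1":
                    required.add((u, v))
            elif u:
                nodes.add(u)
        return cls(nodes, edges, required)


@dataclass
class ConstraintSet:
    """Required edges (pinned) plus the allowed-edge whitelist for search."""

    required_edges: set[Edge]
    allowed_edges: set[Edge]

    def __post_init__(self) -> None:
        for u, v in self.allowed_edges | self.required_edges:
            if u == v:
                raise ValueError(f"self-pair {u}->{v} in constraints")
        if not self.required_edges <= self.allowed_edges:
            raise ValueError("required edges must be contained in allowed edges")


@dataclass
class MetabolicNetwork:
    """A relation graph decorated with the compounds its edges carry."""

    graph: PathwayGraph
    edge_compounds: dict[Edge, frozenset[str]]

    def __post_init__(self) -> None:
        stray = set(self.edge_compounds) - self.graph.edges
        if stray:
            raise ValueError(f"compound annotations on non-edges: {sorted(stray)}")

    def to_tsv(self) -> str:
        lines = ["source\ttarget\trequired\tcompounds"]
        for u, v in sorted(self.graph.edges):
            comps = ",".join(sorted(self.edge_compounds.get((u, v), frozenset())))
            lines.append(f"{u}\t{v}\t{int((u, v) in self.graph.required)}\t{comps}")
        return "\n".join(lines) + "\n"


def _break_cycles(edges: set[Edge]) -> tuple[set[Edge], set[Edge]]:
    """Remove edges until acyclic; deterministic (lexicographically smallest
    edge of each detected cycle goes first).  Returns (kept, demoted)."""
    g = nx.DiGraph()
    g.add_edges_from(sorted(edges))
    demoted: set[Edge] = set()
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        drop = min((u, v) for u, v, _ in cycle)
        g.remove_edge(*drop)
        demoted.add(drop)
    return edges - demoted, demoted


def initial_map(reference: PathwayMap, komap: GeneKOMap) -> PathwayGraph:
    """Project a reference map onto an organism's genes: the seed pathway.

    A gene is mapped when its KO set intersects an enzyme entry of the map;
    every reference relation whose endpoints are both mapped expands (by
    cartesian product over genes sharing the endpoint KOs) to required gene
    edges.  If the expansion contains directed cycles — common in metabolic
    maps but illegal for a Bayesian network — edges are deterministically
    demoted until the seed is a DAG (they stay in the knowledgebase-derived
    whitelist, so search may re-orient them).
    """
    ko_to_genes = komap.ko_to_genes()
    mapped: set[str] = set()
    for entry in reference.enzyme_entries():
        for ko in entry.ko_ids:
            mapped.update(ko_to_genes.get(ko, ()))
    edges: set[Edge] = set()
    for rec in reference.records:
        for ku, kd in rec.ko_pairs():
            for gu in ko_to_genes.get(ku, ()):
                for gd in ko_to_genes.get(kd, ()):
                    if gu != gd and gu in mapped and gd in mapped:
                        edges.add((gu, gd))
    kept, demoted = _break_cycles(edges)
    if demoted:
        logger.info("initial map: demoted %d cycle-forming edges: %s",
                    len(demoted), sorted(demoted))
    return PathwayGraph(mapped, kept, required=set(kept))


def build_constraints(initial: PathwayGraph, kb: RelationKnowledgebase,
                      komap: GeneKOMap, candidates: set[str]) -> ConstraintSet:
    """Assemble search constraints for a candidate gene pool.

    Required edges are the seed pathway's; the whitelist is every
    knowledgebase-supported gene pair over the candidates, plus the required
    edges themselves (a seed edge always remains legal even if its record is
    absent from the knowledgebase).
    """
    if not initial.nodes <= candidates:
        raise ValueError("candidate pool must contain every seed-pathway gene")
    allowed = allowed_gene_edges(kb, komap, set(candidates))
    return ConstraintSet(set(initial.required), allowed | set(initial.required))


def attach_compounds(graph: PathwayGraph, kb: RelationKnowledgebase,
                     komap: GeneKOMap) -> MetabolicNetwork:
    """Decorate each predicted edge with the compounds of its supporting records.

    For an edge (g_u, g_d) every knowledgebase record supporting any ordered
    KO pair of the endpoints contributes its compounds; edges backed only by
    compound-free records map to the empty set.
    """
    edge_compounds: dict[Edge, frozenset[str]] = {}
    for (gu, gd) in graph.edges:
        comps: set[str] = set()
        for ku in komap[gu]:
            for kd in komap[gd]:
                for rec in kb.records_for_pair(ku, kd):
                    comps.update(rec.compounds)
        edge_compounds[(gu, gd)] = frozenset(comps)
    return MetabolicNetwork(graph.copy(), edge_compounds)
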