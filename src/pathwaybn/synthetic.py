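"""Self-contained synthetic benchmarks for the whole reconstruction pipeline.

A benchmark bundle holds a ground-truth DAG, expression data sampled from its
linear-Gaussian model, a gene→KO table, and KGML documents: a *reference map*
encoding a partial seed of the truth (emulating the incomplete initial
homology mapping) and a *knowledgebase map* encoding a noisy superset of the
truth (true edges plus decoys), so every pipeline stage can be exercised and
scored against a known answer without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from xml.sax.saxutils import quoteattr

import numpy as np

from .expression import ExpressionMatrix
from .knowledgebase import GeneKOMap
from .pathway import Edge, PathwayGraph


def generate_truth_dag(n_nodes: int, edge_density: float, rng_seed: int) -> PathwayGraph:
    """Random DAG: draw a topological order, include each forward pair i.i.d.

    ``edge_density`` is the inclusion probability for each of the
    n(n−1)/2 order-respecting pairs; acyclicity holds by construction.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    order = [genes[i] for i in rng.permutation(n_nodes)]
    edges: set[Edge] = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_density:
                edges.add((order[i], order[j]))
    return PathwayGraph(set(genes), edges)


def simulate_expression(truth: PathwayGraph, M: int,
                        coef_range: tuple[float, float] = (0.8, 0.8),
                        noise_sd: float = 1.0, rng_seed: int = 0,
                        random_sign: bool = True) -> ExpressionMatrix:
    """Ancestral sampling from the truth DAG's linear-Gaussian model.

    Roots are N(0, noise_sd²); a child is the coefficient-weighted sum of its
    parents plus N(0, noise_sd²) noise.  Edge coefficients have magnitude
    drawn uniformly from ``coef_range`` with (by default) a random sign, so
    the default (0.8, 0.8) gives coefficients of ±0.8.
    """
    if M < 2:
        raise ValueError("need M ≥ 2 conditions")
    if not truth.is_acyclic():
        raise ValueError("truth graph must be acyclic")
    import networkx as nx
    rng = np.random.default_rng(rng_seed)
    order = list(nx.topological_sort(truth.to_networkx()))
    lo, hi = coef_range
    coefs: dict[Edge, float] = {}
    for e in sorted(truth.edges):
        mag = rng.uniform(lo, hi)
        sign = rng.choice([-1.0, 1.0]) if random_sign else 1.0
        coefs[e] = sign * mag
    rows: dict[str, np.ndarray] = {}
    for node in order:
        eps = rng.normal(0.0, noise_sd, size=M)
        val = eps.copy()
        for (u, v), c in coefs.items():
            if v == node:
                val += c * rows[u]
        rows[node] = val
    genes = sorted(truth.nodes)
    values = np.vstack([rows[g] for g in genes])
    conds = [f"c{i:03d}" for i in range(M)]
    return ExpressionMatrix(genes, conds, values, np.zeros((len(genes), M), dtype=bool))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def corrupt_knowledgebase(truth: PathwayGraph, decoy_fraction: float,
                          drop_fraction: float, rng_seed: int) -> set[Edge]:
    """A noisy whitelist: true edges minus a dropped subset, plus decoys.

    Decoys are random non-true ordered pairs; their count and the dropped
    count are round(fraction · |true edges|).
    """
    if not 0.0 <= decoy_fraction or not 0.0 <= drop_fraction <= 1.0:
        raise ValueError("fractions must be non-negative (drop ≤ 1)")
    rng = np.random.default_rng(rng_seed)
    true_edges = sorted(truth.edges)
    n_drop = _round_half_up(drop_fraction * len(true_edges))
    n_decoy = _round_half_up(decoy_fraction * len(true_edges))
    genes = sorted(truth.nodes)
    non_true = [(u, v) for u in genes for v in genes
                if u != v and (u, v) not in truth.edges]
    if n_decoy > len(non_true):
        raise ValueError(f"cannot draw {n_decoy} decoys from {len(non_true)} non-true pairs")
    kept = set(true_edges)
    if n_drop:
        dropped = rng.choice(len(true_edges), size=n_drop, replace=False)
        kept -= {true_edges[i] for i in dropped}
    decoys = {non_true[i] for i in rng.choice(len(non_true), size=n_decoy, replace=False)}
    return kept | decoys


def sequential_gene_ko_map(genes: list[str], kos_per_gene: int = 1) -> GeneKOMap:
    """Assign each gene its own KO number(s), K00001 upward."""
    entries: dict[str, frozenset[str]] = {}
    counter = 1
    for g in sorted(genes):
        kos = frozenset(f"K{counter + i:05d}" for i in range(kos_per_gene))
        counter += kos_per_gene
        entries[g] = kos
    return GeneKOMap(entries)


def gene_ko_table(komap: GeneKOMap) -> str:
    """Two-column TSV rendering of a gene→KO map."""
    lines = []
    for g in sorted(komap.entries):
        for ko in sorted(komap.entries[g]):
            lines.append(f"{g}\t{ko}")
    return "\n".join(lines) + "\n"


def emit_kgml_fixture(truth: PathwayGraph, komap: GeneKOMap, map_id: str,
                      edges: set[Edge] | None = None,
                      compounds: dict[Edge, str] | None = None) -> str:
    """Write a KGML document whose relations encode the truth's edges.

    One enzyme entry is emitted per gene (carrying all its KO ids) and one
    ECrel relation per edge; an optional compound id per edge is emitted as a
    compound entry plus a relation subtype.  Parsing the output recovers the
    edge set exactly.
    """
    missing = sorted(truth.nodes - komap.genes)
    if missing:
        raise KeyError(f"truth nodes absent from gene→KO map: {missing}")
    use_edges = sorted(truth.edges if edges is None else edges)
    compounds = compounds or {}
    genes = sorted(truth.nodes)
    entry_id = {g: str(i + 1) for i, g in enumerate(genes)}
    next_id = len(genes) + 1
    lines = ["<?xml version=\"1.0\"?>",
             f"<pathway name={quoteattr(map_id)} org=\"ko\" number=\"00000\">"]
    for g in genes:
        names = " ".join(f"ko:{k}" for k in sorted(komap[g]))
        lines.append(f'  <entry id="{entry_id[g]}" name="{names}" type="ortholog"/>')
    comp_entry: dict[str, str] = {}
    for e in use_edges:
        cid = compounds.get(e)
        if cid and cid not in comp_entry:
            comp_entry[cid] = str(next_id)
            next_id += 1
            lines.append(f'  <entry id="{comp_entry[cid]}" name="cpd:{cid}" type="compound"/>')
    for (u, v) in use_edges:
        cid = compounds.get((u, v))
        sub = (f'\n    <subtype name="compound" value="{comp_entry[cid]}"/>\n  '
               if cid else "")
        lines.append(f'  <relation entry1="{entry_id[u]}" entry2="{entry_id[v]}" '
                     f'type="ECrel">{sub}</relation>')
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


@dataclass
class BenchmarkBundle:
    """Everything one desk-scale experiment needs, derived from one seed."""

    truth: PathwayGraph
    data: ExpressionMatrix
    komap: GeneKOMap
    kgml_docs: list[str]            # [reference (seed) map, knowledgebase map]
    komap_table: str
    seed_edges: set[Edge]           # truth edges on the reference map
    allowed_edges: set[Edge]        # knowledgebase-map edges (noisy superset)
    kb_noise: tuple[float, float]   # (decoy_fraction, dropped_fraction)
    seed: int


def make_bundle(n_nodes: int = 8, M: int = 1000, edge_density: float = 0.35,
                coef_range: tuple[float, float] = (0.8, 0.8), noise_sd: float = 1.0,
                decoy_fraction: float = 0.5, drop_fraction: float = 0.0,
                seed_edge_fraction: float = 0.5, seed: int = 0) -> BenchmarkBundle:
    """Generate a complete seeded benchmark bundle.

    The reference map carries a random ``seed_edge_fraction`` of the truth's
    edges (the incomplete initial mapping); the knowledgebase map carries the
    corrupted whitelist (truth ∪ decoys, minus drops) plus the seed edges so
    required ⊆ allowed always holds.
    """
    ss = np.random.SeedSequence(seed)
    s_dag, s_expr, s_kb, s_seed = (int(c.generate_state(1)[0] % (2**31))
                                   for c in ss.spawn(4))
    truth = generate_truth_dag(n_nodes, edge_density, s_dag)
    if not truth.edges:  # degenerate draw: force one edge so the bundle is non-trivial
        genes = sorted(truth.nodes)
        truth.edges.add((genes[0], genes[1]))
    data = simulate_expression(truth, M, coef_range, noise_sd, s_expr)
    komap = sequential_gene_ko_map(sorted(truth.nodes))
    allowed = corrupt_knowledgebase(truth, decoy_fraction, drop_fraction, s_kb)
    rng = np.random.default_rng(s_seed)
    true_edges = sorted(truth.edges)
    n_seed = _round_half_up(seed_edge_fraction * len(true_edges))
    seed_edges = ({true_edges[i] for i in
                   rng.choice(len(true_edges), size=n_seed, replace=False)}
                  if n_seed else set())
    allowed |= seed_edges
    ref_kgml = emit_kgml_fixture(truth, komap, "synthetic_reference", edges=seed_edges)
    # one compound per true edge so compound attachment has something to find
    edge_compounds = {e: f"C{i + 1:05d}" for i, e in enumerate(sorted(truth.edges))}
    kb_kgml = emit_kgml_fixture(truth, komap, "synthetic_knowledgebase", edges=allowed,
                                compounds=edge_compounds)
    return BenchmarkBundle(truth, data, komap, [ref_kgml, kb_kgml],
                           gene_ko_table(komap), seed_edges, allowed,
                           (decoy_fraction, drop_fraction), seed)
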