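"""Desk-scale benchmark experiments exercising the whole method.

These are the package's standing experiments: greedy-search optimality
against the exhaustive oracle, the benefit of knowledge constraints over
unconstrained inference, cross-validated cluster-number recovery, and KGML
round-trip fidelity.  Every experiment is seeded and self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import evaluate_edges
from .expression import ExpressionMatrix, select_num_clusters
from .knowledgebase import build_knowledgebase, parse_kgml
from .pathway import ConstraintSet, PathwayGraph
from .structure import exhaustive_search, greedy_search
from .synthetic import emit_kgml_fixture, generate_truth_dag, make_bundle, \
    sequential_gene_ko_map


def _all_pairs(genes):
    return {(u, v) for u in genes for v in genes if u != v}


def random_instance(seed: int, n_genes: int = 4, M: int = 500) -> ExpressionMatrix:
    """A random expression instance: iid standard-normal rows."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    X = rng.normal(size=(n_genes, M))
    return ExpressionMatrix(genes, [f"c{j:03d}" for j in range(M)], X,
                            np.zeros((n_genes, M), dtype=bool))


def oracle_match_rate(n_instances: int = 100, seed: int = 0,
                      n_genes: int = 4, M: int = 500) -> tuple[int, int]:
    """How often unconstrained greedy search from the empty graph attains the
    exhaustive-search optimum score on random instances."""
    ss = np.random.SeedSequence(seed)
    matches = 0
    for child in ss.spawn(n_instances):
        data = random_instance(int(child.generate_state(1)[0] % (2**31)), n_genes, M)
        genes = data.gene_ids
        cons = ConstraintSet(set(), _all_pairs(genes))
        _, rep, _ = greedy_search(PathwayGraph(set(genes), set()), data, cons)
        _, best = exhaustive_search(genes, data, cons)
        matches += abs(rep.total - best.total) < 1e-9
    return matches, n_instances


@dataclass
class ConstraintBenefit:
    precision_wins: int          # constrained precision strictly > unconstrained
    recall_at_least_seed: int    # constrained recall >= initial-map recall
    n: int
    constrained_precision: list[float]
    unconstrained_precision: list[float]
    constrained_recall: list[float]
    seed_recall: list[float]


def constraint_benefit(n_replicates: int = 50, seed: int = 0, n_nodes: int = 8,
                       M: int = 1000, decoy_fraction: float = 0.5) -> ConstraintBenefit:
    """Constrained vs unconstrained structure learning on synthetic bundles.

    Constrained: start from the seed pathway with the noisy knowledgebase
    whitelist (truth ∪ decoys) and the seed edges required.  Unconstrained:
    start from the empty graph with every ordered pair allowed.  Both are
    scored against the true network.
    """
    ss = np.random.SeedSequence(seed)
    out = ConstraintBenefit(0, 0, n_replicates, [], [], [], [])
    for child in ss.spawn(n_replicates):
        b = make_bundle(n_nodes=n_nodes, M=M, decoy_fraction=decoy_fraction,
                        drop_fraction=0.0,
                        seed=int(child.generate_state(1)[0] % (2**31)))
        genes = sorted(b.truth.nodes)
        cons = ConstraintSet(set(b.seed_edges), set(b.allowed_edges))
        start = PathwayGraph(set(genes), set(b.seed_edges), set(b.seed_edges))
        g_con, _, _ = greedy_search(start, b.data, cons)
        g_unc, _, _ = greedy_search(PathwayGraph(set(genes), set()), b.data,
                                    ConstraintSet(set(), _all_pairs(genes)))
        r_con = evaluate_edges(g_con.edges, b.truth.edges)
        r_unc = evaluate_edges(g_unc.edges, b.truth.edges)
        r_seed = (evaluate_edges(b.seed_edges, b.truth.edges)
                  if b.seed_edges else None)
        out.precision_wins += r_con.precision > r_unc.precision
        out.recall_at_least_seed += r_con.recall >= (r_seed.recall if r_seed else 0.0)
        out.constrained_precision.append(r_con.precision)
        out.unconstrained_precision.append(r_unc.precision)
        out.constrained_recall.append(r_con.recall)
        out.seed_recall.append(r_seed.recall if r_seed else 0.0)
    return out


def separated_mixture(seed: int, n_components: int = 3, per_component: int = 30,
                      dims: int = 5, separation: float = 6.0) -> ExpressionMatrix:
    """Gene rows from well-separated unit-variance Gaussians (pairwise mean
    distance = ``separation`` standard deviations)."""
    rng = np.random.default_rng(seed)
    means = np.zeros((n_components, dims))
    for c in range(n_components):
        means[c, c % dims] = separation / np.sqrt(2)
    X = np.vstack([rng.normal(means[c], 1.0, size=(per_component, dims))
                   for c in range(n_components)])
    genes = [f"g{i:03d}" for i in range(n_components * per_component)]
    return ExpressionMatrix(genes, [f"c{j}" for j in range(dims)], X,
                            np.zeros_like(X, dtype=bool))


def cluster_recovery_rate(n_draws: int = 20, seed: int = 0, k_true: int = 3,
                          k_max: int = 6, folds: int = 5) -> tuple[int, int]:
    """How often cross-validation recovers the generating component count."""
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_draws):
        s = int(child.generate_state(1)[0] % (2**31))
        mat = separated_mixture(s, n_components=k_true)
        hits += select_num_clusters(mat, 1, k_max, folds=folds, seed=s) == k_true
    return hits, n_draws


def kgml_roundtrip_rate(n_fixtures: int = 20, seed: int = 0,
                        n_nodes: int = 8) -> tuple[int, int]:
    """How often emit → parse → index recovers the generating KO edge set."""
    ss = np.random.SeedSequence(seed)
    exact = 0
    for i, child in enumerate(ss.spawn(n_fixtures)):
        s = int(child.generate_state(1)[0] % (2**31))
        truth = generate_truth_dag(n_nodes, 0.4, s)
        komap = sequential_gene_ko_map(sorted(truth.nodes))
        kb = build_knowledgebase([parse_kgml(emit_kgml_fixture(truth, komap, f"m{i}"))])
        expected = {(next(iter(komap[u])), next(iter(komap[v])))
                    for u, v in truth.edges}
        exact += set(kb.ko_pair_index) == expected
    return exact, n_fixtures
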