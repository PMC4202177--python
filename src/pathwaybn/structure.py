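"""BIC scoring of linear-Gaussian Bayesian networks and constrained greedy
structure search.

Each gene's expression is modelled as Gaussian around a linear function of
its parents' expression.  A graph G over genes is scored with the Bayesian
Information Criterion,

    Score(G : D) = l(theta_hat_G : D) - (log M / 2) * Dim(G),

where l is the maximised log-likelihood of the data D, M is the number of
conditions, and Dim(G) counts the free parameters: per node, one coefficient
per parent plus an intercept and a variance (|parents| + 2).  The score
decomposes over node families, so local add/remove/reverse moves are scored
by recomputing only the affected families.  Search is greedy hill climbing
restricted to a whitelist of knowledgebase-supported edges, with seed edges
pinned; an exhaustive enumerator over tiny gene sets serves as an oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import numpy as np

from .expression import ExpressionMatrix
from .pathway import ConstraintSet, Edge, PathwayGraph

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-6
IMPROVEMENT_TOL = 1e-9


@dataclass
class GaussianNodeModel:
    """Maximum-likelihood linear-Gaussian model of one node given its parents."""

    node: str
    parents: list[str]
    intercept: float
    coefficients: np.ndarray
    variance: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.parents):
            raise ValueError("one coefficient per parent required")
        if self.variance < VARIANCE_FLOOR - 1e-15:
            raise ValueError("variance below floor")


@dataclass
class ScoreReport:
    total: float
    per_node: dict[str, float]
    dim: int
    loglik: float
    M: int

    def to_dict(self) -> dict:
        return {"total": self.total, "loglik": self.loglik, "dim": self.dim,
                "M": self.M, "per_node": dict(sorted(self.per_node.items()))}


class MoveKind(Enum):
    ADD = "add"
    REMOVE = "remove"
    REVERSE = "reverse"


@dataclass(frozen=True, order=True)
class Move:
    kind: MoveKind = field(compare=False)
    edge: Edge

    # deterministic ordering: add < remove < reverse, then lexicographic edge
    def sort_key(self) -> tuple:
        order = {MoveKind.ADD: 0, MoveKind.REMOVE: 1, MoveKind.REVERSE: 2}
        return (order[self.kind], self.edge)


def fit_node(node: str, parents: list[str], data: ExpressionMatrix) -> GaussianNodeModel:
    """OLS of a node's row on its parents' rows, ML residual variance.

    The variance divides by M (maximum-likelihood, not the unbiased M-p-1)
    and is floored at 1e-6.  Rank-deficient designs (collinear parents) fall
    back to the pseudo-inverse solution.
    """
    y = data.row(node)
    M = data.M
    if M <= len(parents) + 1:
        raise ValueError(f"need M > |parents|+1 conditions (M={M}, parents={len(parents)})")
    if not parents:
        mean = float(y.mean())
        var = max(float(y.var()), VARIANCE_FLOOR)
        return GaussianNodeModel(node, [], mean, np.empty(0), var)
    X = np.column_stack([np.ones(M)] + [data.row(p) for p in parents])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.debug("rank-deficient design for node %s (parents %s)", node, parents)
    resid = y - X @ beta
    var = max(float(resid @ resid) / M, VARIANCE_FLOOR)
    return GaussianNodeModel(node, list(parents), float(beta[0]), beta[1:], var)


def _gaussian_loglik(y: np.ndarray, pred: np.ndarray, var: float) -> float:
    M = len(y)
    rss = float(np.sum((y - pred) ** 2))
    return -0.5 * M * math.log(2 * math.pi * var) - rss / (2 * var)


def family_score(node: str, parents: list[str], data: ExpressionMatrix) -> float:
    """BIC contribution of one family: loglik − (log M / 2)(|parents| + 2)."""
    model = fit_node(node, parents, data)
    y = data.row(node)
    if parents:
        X = np.column_stack([np.ones(data.M)] + [data.row(p) for p in parents])
        pred = X @ np.concatenate([[model.intercept], model.coefficients])
    else:
        pred = np.full(data.M, model.intercept)
    ll = _gaussian_loglik(y, pred, model.variance)
    penalty = (math.log(data.M) / 2.0) * (len(parents) + 2)
    return ll - penalty


def _family_loglik(node: str, parents: list[str], data: ExpressionMatrix) -> float:
    return family_score(node, parents, data) + (math.log(data.M) / 2.0) * (len(parents) + 2)


def bic_score(graph: PathwayGraph, data: ExpressionMatrix) -> ScoreReport:
    """Decomposable BIC of a DAG: the sum of its family scores."""
    import networkx as nx
    g = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cycle = [f"{u}->{v}" for u, v, _ in nx.find_cycle(g, orientation="original")]
        raise ValueError(f"graph contains a cycle: {' '.join(cycle)}")
    missing = sorted(graph.nodes - set(data.gene_ids))
    if missing:
        raise KeyError(f"graph nodes absent from expression data: {missing}")
    per_node, total, dim, loglik = {}, 0.0, 0, 0.0
    for node in sorted(graph.nodes):
        parents = graph.parents(node)
        fs = family_score(node, parents, data)
        per_node[node] = fs
        total += fs
        dim += len(parents) + 2
        loglik += fs + (math.log(data.M) / 2.0) * (len(parents) + 2)
    return ScoreReport(total, per_node, dim, loglik, data.M)


class _AdjacencyView:
    """Mutable adjacency with reachability queries for fast acyclicity checks."""

    def __init__(self, nodes: set[str], edges: set[Edge]):
        self.succ: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v in edges:
            self.succ[u].add(v)

    def reachable(self, src: str, dst: str, skip_edge: Edge | None = None) -> bool:
        stack, seen = [src], {src}
        while stack:
            cur = stack.pop()
            if cur == dst:
                return True
            for nxt in self.succ[cur]:
                if skip_edge is not None and (cur, nxt) == skip_edge:
                    continue
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def add(self, u: str, v: str) -> None:
        self.succ[u].add(v)

    def remove(self, u: str, v: str) -> None:
        self.succ[u].discard(v)


def _check_consistent(graph: PathwayGraph, constraints: ConstraintSet) -> None:
    if not constraints.required_edges <= graph.edges:
        raise ValueError("graph is missing required edges")
    if not graph.edges <= constraints.allowed_edges:
        raise ValueError("graph contains edges outside the allowed whitelist")
    if not graph.is_acyclic():
        raise ValueError("graph is cyclic")


def legal_moves(graph: PathwayGraph, constraints: ConstraintSet) -> list[Move]:
    """All moves legal under the knowledge constraints and acyclicity.

    Adds draw only from the whitelist; removes and reversals never touch a
    required edge; a reversal additionally needs the reversed direction to be
    whitelisted; every move must leave the graph acyclic.
    """
    _check_consistent(graph, constraints)
    adj = _AdjacencyView(graph.nodes, graph.edges)
    moves: list[Move] = []
    for (u, v) in sorted(constraints.allowed_edges - graph.edges):
        if u in graph.nodes and v in graph.nodes and not adj.reachable(v, u):
            moves.append(Move(MoveKind.ADD, (u, v)))
    for (u, v) in sorted(graph.edges - constraints.required_edges):
        moves.append(Move(MoveKind.REMOVE, (u, v)))
        if (v, u) in constraints.allowed_edges and not adj.reachable(u, v, skip_edge=(u, v)):
            moves.append(Move(MoveKind.REVERSE, (u, v)))
    return sorted(moves, key=Move.sort_key)


@dataclass
class TraceStep:
    move: Move
    score: float


def greedy_search(initial: PathwayGraph, data: ExpressionMatrix,
                  constraints: ConstraintSet, max_iters: int = 10_000,
                  ) -> tuple[PathwayGraph, ScoreReport, list[TraceStep]]:
    """Greedy hill climbing: apply the best legal move until none improves.

    At every iteration all legal add/remove/reverse moves are scored by their
    family-score delta (exact, by decomposability); the highest-delta move is
    applied if it improves the total by more than 1e-9, with deterministic
    tie-breaking (add < remove < reverse, then lexicographic edge).  The
    required ⊆ edges ⊆ allowed and acyclicity invariants are re-checked at
    every accepted state.
    """
    _check_consistent(initial, constraints)
    current = initial.copy()
    parents: dict[str, set[str]] = {n: set() for n in current.nodes}
    for u, v in current.edges:
        parents[v].add(u)

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def fam(node: str, pset: set[str]) -> float:
        key = (node, tuple(sorted(pset)))
        if key not in cache:
            cache[key] = family_score(node, sorted(pset), data)
        return cache[key]

    score = sum(fam(n, parents[n]) for n in current.nodes)
    trace: list[TraceStep] = []
    for _ in range(max_iters):
        best: tuple[float, tuple, Move] | None = None
        for move in legal_moves(current, constraints):
            u, v = move.edge
            if move.kind is MoveKind.ADD:
                delta = fam(v, parents[v] | {u}) - fam(v, parents[v])
            elif move.kind is MoveKind.REMOVE:
                delta = fam(v, parents[v] - {u}) - fam(v, parents[v])
            else:  # reverse u->v  =>  v->u
                delta = (fam(v, parents[v] - {u}) - fam(v, parents[v])
                         + fam(u, parents[u] | {v}) - fam(u, parents[u]))
            key = (-delta, move.sort_key())
            if best is None or key < (best[0], best[1]):
                best = (-delta, move.sort_key(), move)
        if best is None or -best[0] <= IMPROVEMENT_TOL:
            break
        move = best[2]
        u, v = move.edge
        if move.kind is MoveKind.ADD:
            current.edges.add((u, v))
            parents[v].add(u)
        elif move.kind is MoveKind.REMOVE:
            current.edges.remove((u, v))
            parents[v].discard(u)
        else:
            current.edges.remove((u, v))
            current.edges.add((v, u))
            parents[v].discard(u)
            parents[u].add(v)
        score += -best[0]
        _check_consistent(current, constraints)
        trace.append(TraceStep(move, score))
    report = bic_score(current, data)
    return current, report, trace


def exhaustive_search(genes: list[str], data: ExpressionMatrix,
                      constraints: ConstraintSet,
                      ) -> tuple[PathwayGraph, ScoreReport]:
    """Score every constraint-respecting DAG over ≤5 genes; return the best.

    Ties break toward fewer edges, then the lexicographically smallest edge
    list.  Intended as a ground-truth oracle for the greedy search on tiny
    instances; refuses more than five genes.
    """
    if len(genes) > 5:
        raise ValueError("exhaustive search is limited to 5 genes")
    gene_set = set(genes)
    required = sorted(e for e in constraints.required_edges
                      if e[0] in gene_set and e[1] in gene_set)
    optional = sorted(e for e in constraints.allowed_edges - set(required)
                      if e[0] in gene_set and e[1] in gene_set)

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def fam(node: str, pset: tuple[str, ...]) -> float:
        key = (node, pset)
        if key not in cache:
            cache[key] = family_score(node, list(pset), data)
        return cache[key]

    best: tuple[float, int, tuple, set[Edge]] | None = None
    n_opt = len(optional)
    for mask in range(1 << n_opt):
        edges = set(required)
        edges.update(optional[i] for i in range(n_opt) if mask >> i & 1)
        if _has_cycle(gene_set, edges):
            continue
        parents: dict[str, list[str]] = {g: [] for g in genes}
        for u, v in edges:
            parents[v].append(u)
        total = sum(fam(g, tuple(sorted(parents[g]))) for g in genes)
        key = (-total, len(edges), tuple(sorted(edges)))
        if best is None or key < (best[0], best[1], best[2]):
            best = (-total, len(edges), tuple(sorted(edges)), edges)
    assert best is not None  # the empty/required-only graph is always evaluated
    graph = PathwayGraph(gene_set, best[3], required=set(required))
    return graph, bic_score(graph, data)


def _has_cycle(nodes: set[str], edges: set[Edge]) -> bool:
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in edges:
        succ[u].append(v)
        indeg[v] += 1
    stack = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while stack:
        n = stack.pop()
        seen += 1
        for m in succ[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                stack.append(m)
    return seen != len(nodes)


def count_dags(n: int) -> int:
    """Number of labelled DAGs on n nodes (for oracle sanity checks)."""
    # Robinson's recurrence
    a = [1]
    for m in range(1, n + 1):
        total = 0
        for k in range(1, m + 1):
            total += (-1) ** (k + 1) * math.comb(m, k) * (2 ** (k * (m - k))) * a[m - k]
        a.append(total)
    return a[n]


def trace_to_tsv(trace: list[TraceStep]) -> str:
    lines = ["step\tkind\tsource\ttarget\tscore"]
    for i, step in enumerate(trace, 1):
        u, v = step.move.edge
        lines.append(f"{i}\t{step.move.kind.value}\t{u}\t{v}\t{step.score:.6f}")
    return "\n".join(lines) + "\n"
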