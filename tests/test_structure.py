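"""BIC scoring, legal moves, greedy search, and the exhaustive oracle."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import pathwaybn as pb
from pathwaybn.pathway import ConstraintSet, PathwayGraph
from pathwaybn.structure import (Move, MoveKind, bic_score, count_dags,
                                 exhaustive_search, family_score, fit_node,
                                 greedy_search, legal_moves)
from conftest import make_matrix


def all_pairs(genes):
    return {(u, v) for u in genes for v in genes if u != v}


class TestFitNode:
    def test_no_parents_closed_form(self, random_matrix):
        model = fit_node("g0", [], random_matrix)
        y = random_matrix.row("g0")
        assert model.intercept == pytest.approx(y.mean())
        assert model.variance == pytest.approx(y.var())  # ML (divide by M)

    def test_exact_linear_child(self):
        x = np.linspace(-2, 2, 50)
        mat = make_matrix(np.vstack([x, 2 * x + 1]))
        model = fit_node("g1", ["g0"], mat)
        assert model.coefficients[0] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.variance == pytest.approx(1e-6)  # floored

    def test_two_parent_fit_matches_normal_equations(self):
        """Oracle: solve X'X beta = X'y directly."""
        rng = np.random.default_rng(5)
        P = rng.normal(size=(2, 200))
        y = 0.7 * P[0] - 1.2 * P[1] + 0.3 + rng.normal(0, 0.5, 200)
        mat = make_matrix(np.vstack([P, y]))
        model = fit_node("g2", ["g0", "g1"], mat)
        X = np.column_stack([np.ones(200), P[0], P[1]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_collinear_parents_do_not_crash(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        mat = make_matrix(np.vstack([x, x, rng.normal(size=60)]))
        score = family_score("g2", ["g0", "g1"], mat)
        assert np.isfinite(score)


class TestFamilyScore:
    def test_matches_direct_density_summation(self):
        """Oracle: sum scipy log-densities under the ML marginal model."""
        rng = np.random.default_rng(1)
        y = rng.normal(size=100)
        mat = make_matrix(y[None, :])
        expected = norm.logpdf(y, loc=y.mean(), scale=np.sqrt(y.var())).sum() \
            - (math.log(100) / 2) * 2
        assert family_score("g0", [], mat) == pytest.approx(expected, abs=1e-9)

    def test_extra_parent_changes_penalty_by_half_log_m(self):
        rng = np.random.default_rng(2)
        mat = make_matrix(rng.normal(size=(2, 300)))
        s0 = family_score("g0", [], mat)
        s1 = family_score("g0", ["g1"], mat)
        # decompose: loglik difference is >= 0, penalty difference exactly log(M)/2
        ll0 = s0 + (math.log(300) / 2) * 2
        ll1 = s1 + (math.log(300) / 2) * 3
        assert ll1 >= ll0 - 1e-9
        assert (s1 - s0) == pytest.approx((ll1 - ll0) - math.log(300) / 2, abs=1e-9)


class TestBicScore:
    def test_empty_graph_decomposition(self, random_matrix):
        genes = random_matrix.gene_ids
        g = PathwayGraph(set(genes), set())
        rep = bic_score(g, random_matrix)
        assert rep.dim == 2 * len(genes)
        expected = sum(family_score(n, [], random_matrix) for n in genes)
        assert rep.total == pytest.approx(expected, abs=1e-9)
        assert rep.total == pytest.approx(rep.loglik - (math.log(rep.M) / 2) * rep.dim,
                                          abs=1e-9)

    def test_neighbour_differs_only_in_affected_family(self, random_matrix):
        genes = random_matrix.gene_ids[:4]
        g = PathwayGraph(set(genes), {(genes[0], genes[1])})
        g2 = PathwayGraph(set(genes), {(genes[0], genes[1]), (genes[2], genes[1])})
        full_delta = bic_score(g2, random_matrix).total - bic_score(g, random_matrix).total
        fam_delta = (family_score(genes[1], sorted([genes[0], genes[2]]), random_matrix)
                     - family_score(genes[1], [genes[0]], random_matrix))
        assert full_delta == pytest.approx(fam_delta, abs=1e-9)

    def test_invariant_to_gene_ordering(self, random_matrix):
        genes = random_matrix.gene_ids
        g = PathwayGraph(set(genes), {(genes[0], genes[1]), (genes[2], genes[3])})
        shuffled = random_matrix.subset(list(reversed(genes)))
        assert bic_score(g, random_matrix).total == pytest.approx(
            bic_score(g, shuffled).total, abs=1e-9)

    def test_cycle_is_an_error_naming_it(self, random_matrix):
        genes = random_matrix.gene_ids[:2]
        g = PathwayGraph(set(genes), set())
        g.edges |= {(genes[0], genes[1]), (genes[1], genes[0])}
        with pytest.raises(ValueError, match="cycle"):
            bic_score(g, random_matrix)


class TestLegalMoves:
    def test_fully_pinned_graph_has_no_moves(self, random_matrix):
        g = PathwayGraph({"g0", "g1"}, {("g0", "g1")}, {("g0", "g1")})
        cons = ConstraintSet({("g0", "g1")}, {("g0", "g1")})
        assert legal_moves(g, cons) == []

    def test_empty_graph_all_adds(self):
        genes = ["g0", "g1", "g2"]
        g = PathwayGraph(set(genes), set())
        cons = ConstraintSet(set(), all_pairs(genes))
        moves = legal_moves(g, cons)
        assert len(moves) == 6
        assert all(m.kind is MoveKind.ADD for m in moves)

    def test_chain_move_enumeration(self):
        """Hand enumeration on chain A->B->C with everything allowed:
        adds {A->C} (C->A closes a cycle), removes and reversals of both
        chain edges — five moves in total."""
        genes = ["A", "B", "C"]
        g = PathwayGraph(set(genes), {("A", "B"), ("B", "C")})
        cons = ConstraintSet(set(), all_pairs(genes))
        moves = {(m.kind.value, m.edge) for m in legal_moves(g, cons)}
        assert moves == {("add", ("A", "C")),
                         ("remove", ("A", "B")), ("remove", ("B", "C")),
                         ("reverse", ("A", "B")), ("reverse", ("B", "C"))}

    def test_reversal_needs_reverse_direction_allowed(self):
        g = PathwayGraph({"A", "B"}, {("A", "B")})
        cons = ConstraintSet(set(), {("A", "B")})
        moves = {(m.kind.value, m.edge) for m in legal_moves(g, cons)}
        assert moves == {("remove", ("A", "B"))}

    def test_inconsistent_graph_errors(self):
        g = PathwayGraph({"A", "B"}, {("A", "B")})
        cons = ConstraintSet(set(), {("B", "A")})
        with pytest.raises(ValueError):
            legal_moves(g, cons)


class TestGreedySearch:
    def test_no_legal_moves_returns_initial(self, random_matrix):
        g = PathwayGraph({"g0", "g1"}, {("g0", "g1")}, {("g0", "g1")})
        cons = ConstraintSet({("g0", "g1")}, {("g0", "g1")})
        out, _, trace = greedy_search(g, random_matrix, cons)
        assert out.edges == g.edges and trace == []

    def test_trace_scores_strictly_increase(self):
        truth = pb.generate_truth_dag(5, 0.5, 3)
        data = pb.simulate_expression(truth, 300, rng_seed=4)
        genes = sorted(truth.nodes)
        cons = ConstraintSet(set(), all_pairs(genes))
        _, _, trace = greedy_search(PathwayGraph(set(genes), set()), data, cons)
        scores = [t.score for t in trace]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_constraints_respected_throughout(self):
        b = pb.make_bundle(n_nodes=6, M=300, seed=8)
        cons = ConstraintSet(set(b.seed_edges), set(b.allowed_edges))
        start = PathwayGraph(set(b.truth.nodes), set(b.seed_edges), set(b.seed_edges))
        out, _, trace = greedy_search(start, b.data, cons)
        assert cons.required_edges <= out.edges <= cons.allowed_edges
        assert out.is_acyclic()
        # replay the trace, checking every intermediate state
        g = start.copy()
        for step in trace:
            u, v = step.move.edge
            if step.move.kind is MoveKind.ADD:
                g.edges.add((u, v))
            elif step.move.kind is MoveKind.REMOVE:
                g.edges.remove((u, v))
            else:
                g.edges.remove((u, v))
                g.edges.add((v, u))
            assert cons.required_edges <= g.edges <= cons.allowed_edges
            assert g.is_acyclic()
        assert g.edges == out.edges

    def test_matches_exhaustive_on_small_random_data(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            mat = make_matrix(rng.normal(size=(4, 200)))
            genes = mat.gene_ids
            cons = ConstraintSet(set(), all_pairs(genes))
            _, rep, _ = greedy_search(PathwayGraph(set(genes), set()), mat, cons)
            _, best = exhaustive_search(genes, mat, cons)
            hits += abs(rep.total - best.total) < 1e-9
        assert hits == 10


class TestExhaustiveSearch:
    def test_two_gene_enumeration(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.normal(size=(2, 100)))
        genes = mat.gene_ids
        cons = ConstraintSet(set(), all_pairs(genes))
        g, rep = exhaustive_search(genes, mat, cons)
        candidates = [set(), {(genes[0], genes[1])}, {(genes[1], genes[0])}]
        scores = [bic_score(PathwayGraph(set(genes), e), mat).total for e in candidates]
        assert rep.total == pytest.approx(max(scores), abs=1e-9)

    def test_required_edge_forced_into_result(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(size=(3, 100)))
        genes = mat.gene_ids
        req = {(genes[0], genes[1])}
        cons = ConstraintSet(req, all_pairs(genes))
        g, _ = exhaustive_search(genes, mat, cons)
        assert req <= g.edges

    def test_dag_counts(self):
        assert count_dags(3) == 25 and count_dags(4) == 543

    def test_enumerates_exactly_25_dags_on_3_genes(self):
        from pathwaybn.structure import _has_cycle
        genes = ["a", "b", "c"]
        pairs = sorted(all_pairs(genes))
        n_dags = sum(not _has_cycle(set(genes),
                                    {pairs[i] for i in range(6) if mask >> i & 1})
                     for mask in range(64))
        assert n_dags == 25

    def test_refuses_more_than_five_genes(self, random_matrix):
        genes = random_matrix.gene_ids  # six genes
        with pytest.raises(ValueError):
            exhaustive_search(genes, random_matrix, ConstraintSet(set(), set()))


def test_markov_equivalent_dags_score_equally():
    """A chain and its reversal encode the same independencies: equal BIC."""
    rng = np.random.default_rng(9)
    x = rng.normal(size=400)
    y = 0.8 * x + rng.normal(size=400)
    mat = make_matrix(np.vstack([x, y]))
    fwd = bic_score(PathwayGraph({"g0", "g1"}, {("g0", "g1")}), mat).total
    bwd = bic_score(PathwayGraph({"g0", "g1"}, {("g1", "g0")}), mat).total
    assert fwd == pytest.approx(bwd, abs=1e-8)
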