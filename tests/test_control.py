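import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from splicecontrol.control import (
    ControlProblem,
    clique_centrality,
    enumerate_optimal_sets,
    generic_rank,
    hopcroft_karp,
    matching_path_cover,
    min_driver_set,
    sample_configurations,
)


def random_problem(rng, n_nodes=8, n_inputs=3, n_targets=3, p_edge=0.25):
    nodes = [f"v{i}" for i in range(n_nodes)]
    edges = [
        (a, b)
        for a in nodes
        for b in nodes
        if a != b and rng.random() < p_edge
    ]
    inputs = list(rng.choice(nodes, size=n_inputs, replace=False))
    rest = [v for v in nodes if v not in inputs]
    targets = list(rng.choice(rest, size=min(n_targets, len(rest)), replace=False))
    return ControlProblem(nodes=nodes, edges=edges, targets=targets, inputs=inputs)


def exact_rank(problem, drivers):
    """Symbolic-oracle rank: exact rational arithmetic on a random instantiation."""
    import sympy

    if not drivers:
        return 0
    rng = np.random.default_rng(123)
    idx = {v: i for i, v in enumerate(problem.nodes)}
    n = problem.n
    A = sympy.zeros(n, n)
    for s, t in problem.edges:
        A[idx[t], idx[s]] = Fraction(int(rng.integers(1, 97)), 97)
    B = sympy.zeros(n, len(drivers))
    for j, d in enumerate(sorted(set(drivers))):
        B[idx[d], j] = 1
    rows = [idx[t] for t in problem.targets]
    blocks = []
    M = B
    for _ in range(n):
        blocks.append(M[rows, :])
        M = A @ M
    ctrb = sympy.Matrix.hstack(*blocks)
    return ctrb.rank()


class TestGenericRank:
    def test_empty_driver_set_rank_zero(self):
        p = ControlProblem(nodes=["a", "b"], edges=[("a", "b")],
                           targets=["b"], inputs=["a"])
        assert generic_rank(p, []) == 0

    def test_targets_inside_drivers_identity_block(self):
        nodes = ["t1", "t2", "x"]
        p = ControlProblem(nodes=nodes, edges=[], targets=["t1", "t2"],
                           inputs=["t1", "t2", "x"])
        assert generic_rank(p, ["t1", "t2"]) == 2

    def test_chain_transfers_rank(self):
        p = ControlProblem(nodes=["u", "v", "t"], edges=[("u", "v"), ("v", "t")],
                           targets=["t"], inputs=["u"])
        assert generic_rank(p, ["u"]) == 1

    def test_monotone_in_driver_set(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            p = random_problem(rng)
            subset = [u for u in p.inputs if rng.random() < 0.5]
            superset = sorted(set(subset) | {p.inputs[0]})
            assert generic_rank(p, subset) <= generic_rank(p, superset)

    def test_agrees_with_exact_rational_oracle(self):
        # all subsets of U on small random digraphs vs exact symbolic rank
        rng = np.random.default_rng(1)
        for _ in range(6):
            p = random_problem(rng, n_nodes=6, n_inputs=3, n_targets=2, p_edge=0.3)
            for r in range(len(p.inputs) + 1):
                for K in itertools.combinations(p.inputs, r):
                    assert generic_rank(p, list(K), draws=3) == exact_rank(p, list(K))


def brute_force_max_matching(left, right, edges):
    best = 0
    edge_list = list(edges)
    for r in range(len(edge_list), 0, -1):
        for combo in itertools.combinations(edge_list, r):
            ls = [a for a, _ in combo]
            rs = [b for _, b in combo]
            if len(set(ls)) == r and len(set(rs)) == r:
                return r
    return best


class TestHopcroftKarp:
    def test_no_edges_empty_matching(self):
        assert hopcroft_karp(["a"], ["x"], []) == {}

    def test_complete_bipartite_perfect_matching(self):
        m = hopcroft_karp(list("abc"), list("xyz"),
                          [(l, r) for l in "abc" for r in "xyz"])
        assert len(m) == 3
        assert len(set(m.values())) == 3

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            left = [f"l{i}" for i in range(5)]
            right = [f"r{i}" for i in range(5)]
            edges = [(a, b) for a in left for b in right if rng.random() < 0.35]
            m = hopcroft_karp(left, right, edges)
            assert set(m.items()) <= set(edges)
            assert len(m) == brute_force_max_matching(left, right, edges)


class TestMinDriverSet:
    def test_single_edge_driver(self):
        p = ControlProblem(nodes=["u", "t"], edges=[("u", "t")],
                           targets=["t"], inputs=["u"])
        sol = min_driver_set(p)
        assert sol.drivers == ["u"] and sol.feasible and sol.minimal_certified

    def test_two_disjoint_chains_need_two_drivers(self):
        p = ControlProblem(
            nodes=["u1", "u2", "t1", "t2"],
            edges=[("u1", "t1"), ("u2", "t2")],
            targets=["t1", "t2"], inputs=["u1", "u2"],
        )
        sol = min_driver_set(p)
        assert sorted(sol.drivers) == ["u1", "u2"]
        # subset-lattice brute force: no singleton works
        for u in ("u1", "u2"):
            assert generic_rank(p, [u]) < 2

    def test_unreachable_target_reported(self):
        p = ControlProblem(nodes=["u", "t", "z"], edges=[("u", "t")],
                           targets=["t", "z"], inputs=["u"])
        sol = min_driver_set(p)
        assert sol.infeasible_targets == ["z"]
        assert not sol.feasible

    def test_returned_set_minimal_by_exhaustive_certificate(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(25):
            p = random_problem(rng, n_nodes=8, n_inputs=4, n_targets=3)
            sol = min_driver_set(p)
            if not sol.feasible:
                continue
            checked += 1
            m = len(sol.drivers)
            assert generic_rank(p, sol.drivers) == p.n_targets
            if m > 1:
                for K in itertools.combinations(p.inputs, m - 1):
                    assert generic_rank(p, list(K)) < p.n_targets
        assert checked >= 5

    def test_matching_cover_feasible_and_paths_end_at_targets(self):
        rng = np.random.default_rng(4)
        p = random_problem(rng, n_nodes=10, n_inputs=4, n_targets=3, p_edge=0.3)
        if p.unreachable_targets():
            pytest.skip("drawn instance lacks reachability")
        drivers, paths = matching_path_cover(p)
        assert generic_rank(p, drivers) == p.n_targets
        for t, path in paths.items():
            assert path[-1] == t


class TestSampling:
    def test_unique_optimum_all_frequencies_one(self):
        p = ControlProblem(
            nodes=["u1", "u2", "t1", "t2"],
            edges=[("u1", "t1"), ("u2", "t2")],
            targets=["t1", "t2"], inputs=["u1", "u2"],
        )
        f = sample_configurations(p, 2, mode="enumerate")
        assert f.to_dict() == {"u1": 1.0, "u2": 1.0}

    def test_symmetric_drivers_split_half(self):
        p = ControlProblem(
            nodes=["u1", "u2", "t"],
            edges=[("u1", "t"), ("u2", "t")],
            targets=["t"], inputs=["u1", "u2"],
        )
        f_enum = sample_configurations(p, 1, mode="enumerate")
        assert f_enum.to_dict() == {"u1": 0.5, "u2": 0.5}
        f_walk = sample_configurations(p, 1, mode="walk", steps=4000,
                                       burn=400, thin=4, seed=5)
        assert abs(f_walk["u1"] - 0.5) < 0.05

    def test_walk_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(6)
        compared = 0
        for _ in range(12):
            p = random_problem(rng, n_nodes=7, n_inputs=4, n_targets=2)
            sol = min_driver_set(p)
            if not sol.feasible:
                continue
            m = len(sol.drivers)
            if m == len(p.inputs):
                continue
            opt = enumerate_optimal_sets(p, m)
            if not 1 <= len(opt) <= 100:
                continue
            f_enum = sample_configurations(p, m, mode="enumerate")
            f_walk = sample_configurations(p, m, mode="walk", steps=10_000,
                                           burn=1000, thin=10, seed=7)
            assert np.max(np.abs(f_enum - f_walk)) < 0.05
            compared += 1
        assert compared >= 3

    def test_bad_step_budget_rejected(self):
        p = ControlProblem(nodes=["u", "t"], edges=[("u", "t")],
                           targets=["t"], inputs=["u"])
        with pytest.raises(ValueError, match="steps"):
            sample_configurations(p, 1, mode="walk", steps=10, burn=10)


class TestCliqueCentrality:
    def test_triangle_scores_two(self):
        scores = clique_centrality(nx.complete_graph(3))
        assert scores.tolist() == [2.0, 2.0, 2.0]

    def test_k4_scores_six(self):
        scores = clique_centrality(nx.complete_graph(4))
        assert set(scores) == {6.0}

    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        scores = clique_centrality(g)
        assert scores["c"] == 0.0 and scores["a"] == 1.0

    def test_matches_exhaustive_clique_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(1 << 30)))
            scores = clique_centrality(g)
            # oracle: test all vertex subsets for maximal-clique-ness
            nodes = list(g.nodes)
            expected = {v: 0 for v in nodes}
            for r in range(2, 9):
                for sub in itertools.combinations(nodes, r):
                    if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                        is_maximal = not any(
                            all(g.has_edge(w, u) for u in sub)
                            for w in nodes if w not in sub
                        )
                        if is_maximal:
                            for v in sub:
                                expected[v] += math.factorial(r - 1)
            assert scores.to_dict() == {v: float(c) for v, c in expected.items()}
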