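"""Constrained target control of the inferred regulatory network.

The called network defines the structure of a linear system dx/dt = Ax + Bu,
y = Cx: A carries a free parameter on every inferred edge, B injects inputs
at a candidate driver subset K of the allowed TF set U, and C reads out the
AS target set O.  K steers O when the output controllability matrix
[CB, CAB, ..., CA^(N-1)B] reaches full row rank N_o; structurally this holds
for almost every parameter assignment, so feasibility is certified by
instantiating A with random values and taking the best rank over a few
draws.  A branch-and-bound search returns a minimum-cardinality feasible K,
and sampling over the family of alternative optimal driver sets yields a
per-TF control frequency; TFs with frequency > 0.5 are called key TFs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ControlProblem:
    """Directed network with target set O (AS events) and allowed inputs U (TFs)."""

    nodes: list[str]
    edges: list[tuple[str, str]]  # (source, target)
    targets: list[str]  # O
    inputs: list[str]  # U

    def __post_init__(self) -> None:
        self.nodes = [str(v) for v in self.nodes]
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for s, t in self.edges:
            if s not in node_set or t not in node_set:
                raise ValueError(f"edge ({s}, {t}) references unknown node")
        if not self.targets:
            raise ValueError("target set O is empty")
        if not self.inputs:
            raise ValueError("input set U is empty")
        for group, name in ((self.targets, "target"), (self.inputs, "input")):
            for v in group:
                if v not in node_set:
                    raise ValueError(f"{name} {v} not in node set")
        self.targets = sorted(set(self.targets))
        self.inputs = sorted(set(self.inputs))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def unreachable_targets(self) -> list[str]:
        """Targets no input can reach (hence uncontrollable from U)."""
        g = self.digraph()
        reach: set[str] = set()
        for u in self.inputs:
            reach |= nx.descendants(g, u) | {u}
        return [t for t in self.targets if t not in reach]

    @classmethod
    def from_network(cls, network, targets: list[str], inputs: list[str]) -> "ControlProblem":
        """Build from a LayeredNetwork using its called edges."""
        called = network.called_edges()
        nodes = sorted(
            set(called["source"]) | set(called["target"]) | set(targets) | set(inputs)
        )
        edges = list(zip(called["source"].astype(str), called["target"].astype(str)))
        return cls(nodes=nodes, edges=edges, targets=list(targets), inputs=list(inputs))


@dataclass
class ControlSolution:
    """Minimal driver set, certificate rank, paths and per-TF frequencies."""

    drivers: list[str]
    rank: int
    n_targets: int
    minimal_certified: bool
    paths: dict[str, list[str]] = field(default_factory=dict)
    frequencies: pd.Series | None = None
    key_tfs: list[str] = field(default_factory=list)
    infeasible_targets: list[str] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return self.rank == self.n_targets


def _adjacency_pattern(problem: ControlProblem) -> np.ndarray:
    idx = {v: i for i, v in enumerate(problem.nodes)}
    A = np.zeros((problem.n, problem.n), dtype=bool)
    for s, t in problem.edges:
        A[idx[t], idx[s]] = True
    return A


def generic_rank(
    problem: ControlProblem,
    drivers: list[str] | tuple[str, ...],
    draws: int = 3,
    seed: int = 0,
) -> int:
    """Generic rank of [CB, CAB, ..., CA^(N-1)B] for driver set K.

    Each draw instantiates the nonzero pattern of A with independent values
    uniform on +/-[0.2, 1.8], normalized by (1 + spectral norm) so powers
    stay bounded; the rank is read off the singular values at tolerance
    1e-9 * sigma_max and the maximum over draws is returned (structural rank
    holds for almost every assignment).
    """
    drivers = sorted(set(drivers))
    unknown = [d for d in drivers if d not in problem.nodes]
    if unknown:
        raise ValueError(f"drivers not in node set: {unknown}")
    if not drivers:
        return 0
    idx = {v: i for i, v in enumerate(problem.nodes)}
    pattern = _adjacency_pattern(problem)
    n = problem.n
    B = np.zeros((n, len(drivers)))
    for j, d in enumerate(drivers):
        B[idx[d], j] = 1.0
    target_rows = [idx[t] for t in problem.targets]

    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(max(1, draws)):
        vals = rng.uniform(0.2, 1.8, size=pattern.shape) * rng.choice(
            [-1.0, 1.0], size=pattern.shape
        )
        A = np.where(pattern, vals, 0.0)
        if pattern.any():
            A = A / (1.0 + np.linalg.norm(A, 2))
        blocks = []
        M = B
        for _ in range(n):
            blocks.append(M[target_rows, :])
            M = A @ M
        ctrb = np.hstack(blocks)
        sv = np.linalg.svd(ctrb, compute_uv=False)
        if sv.size and sv[0] > 0:
            best = max(best, int(np.sum(sv > 1e-9 * sv[0])))
        if best == problem.n_targets:
            break
    return best


def hopcroft_karp(
    left: list[str], right: list[str], edges: list[tuple[str, str]]
) -> dict[str, str]:
    """Maximum bipartite matching (left -> right) via Hopcroft–Karp."""
    g = nx.Graph()
    g.add_nodes_from((("L", v) for v in left), bipartite=0)
    g.add_nodes_from((("R", v) for v in right), bipartite=1)
    g.add_edges_from((("L", a), ("R", b)) for a, b in edges)
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=[("L", v) for v in left])
    return {a[1]: b[1] for a, b in matching.items() if a[0] == "L"}


def matching_path_cover(problem: ControlProblem) -> tuple[list[str], dict[str, list[str]]]:
    """Feasible driver set and vertex-disjoint control paths via iterated matching.

    Starting from the targets, each round matches the current frontier to
    unused in-neighbours with a maximum matching; matched predecessors extend
    the control paths backwards until they reach U or cannot extend.  The
    returned driver set is augmented greedily (by generic-rank gain) until it
    certifies rank N_o, or the full input set is reached.
    """
    g = problem.digraph()
    in_u = set(problem.inputs)
    paths: dict[str, list[str]] = {t: [t] for t in problem.targets}
    active = {t: t for t in problem.targets}  # current head per target
    used = set(problem.targets)
    drivers: set[str] = set()

    while active:
        # heads already in U become drivers for their chain
        done = [t for t, head in active.items() if head in in_u]
        for t in done:
            drivers.add(active.pop(t))
        if not active:
            break
        frontier = sorted(set(active.values()))
        preds = sorted(
            {p for h in frontier for p in g.predecessors(h)} - used
        )
        edges = [(p, h) for h in frontier for p in g.predecessors(h) if p not in used]
        if not preds or not edges:
            active.clear()  # stuck chains: no in-neighbours left
            break
        match = hopcroft_karp(preds, frontier, edges)
        head_to_pred = {h: p for p, h in match.items()}
        progressed = False
        for t in list(active):
            head = active[t]
            p = head_to_pred.get(head)
            if p is None:
                del active[t]  # chain cannot extend
                continue
            paths[t] = [p] + paths[t]
            active[t] = p
            used.add(p)
            progressed = True
        if not progressed:
            break

    # greedy augmentation with the rank oracle until feasible
    current = sorted(drivers & in_u)
    rank = generic_rank(problem, current) if current else 0
    remaining = [u for u in problem.inputs if u not in current]
    while rank < problem.n_targets and remaining:
        gains = []
        for u in remaining:
            r = generic_rank(problem, current + [u])
            gains.append((r, u))
        best_rank, best_u = max(gains, key=lambda x: (x[0], x[1]))
        if best_rank <= rank:
            # no single input helps; add them all (monotonicity caps at U)
            current = sorted(set(current) | set(remaining))
            rank = generic_rank(problem, current)
            break
        current.append(best_u)
        remaining.remove(best_u)
        rank = best_rank
    return sorted(current), paths


def min_driver_set(
    problem: ControlProblem,
    exact: bool = True,
    draws: int = 3,
    seed: int = 0,
    max_subsets: int = 2_000_000,
) -> ControlSolution:
    """Minimum-cardinality driver set K within U certified by the rank condition.

    The matching construction supplies a feasible upper bound; exact mode
    then enumerates subsets of U in increasing size (skipping subsets that
    cannot even reach every target), so the first feasible subset found is
    provably minimum.
    """
    infeasible = problem.unreachable_targets()
    if infeasible:
        return ControlSolution(
            drivers=[], rank=0, n_targets=problem.n_targets,
            minimal_certified=False, infeasible_targets=infeasible,
        )
    if len(problem.inputs) > 25 and exact:
        raise ValueError("exact mode supports at most 25 inputs")

    feasible_k0, paths = matching_path_cover(problem)
    rank0 = generic_rank(problem, feasible_k0, draws=draws, seed=seed)
    if rank0 < problem.n_targets:
        # even the full input set fails the rank condition
        full_rank = generic_rank(problem, problem.inputs, draws=draws, seed=seed)
        if full_rank < problem.n_targets:
            return ControlSolution(
                drivers=sorted(problem.inputs), rank=full_rank,
                n_targets=problem.n_targets, minimal_certified=False, paths=paths,
            )
        feasible_k0 = sorted(problem.inputs)

    ub = len(feasible_k0)
    if not exact:
        return ControlSolution(
            drivers=feasible_k0, rank=problem.n_targets,
            n_targets=problem.n_targets, minimal_certified=False, paths=paths,
        )

    g = problem.digraph()
    reach_sets = {
        u: (nx.descendants(g, u) | {u}) & set(problem.targets) for u in problem.inputs
    }
    targets = set(problem.targets)
    tested = 0
    for m in range(1, ub + 1):
        for K in itertools.combinations(problem.inputs, m):
            tested += 1
            if tested > max_subsets:
                raise RuntimeError("subset budget exceeded; use exact=False")
            cover = set()
            for u in K:
                cover |= reach_sets[u]
            if cover != targets:
                continue
            if generic_rank(problem, list(K), draws=draws, seed=seed) == problem.n_targets:
                return ControlSolution(
                    drivers=list(K), rank=problem.n_targets,
                    n_targets=problem.n_targets, minimal_certified=True,
                    paths=_driver_paths(problem, list(K)),
                )
    # should not happen: feasible_k0 itself is enumerated at m = ub
    return ControlSolution(
        drivers=feasible_k0, rank=problem.n_targets,
        n_targets=problem.n_targets, minimal_certified=True, paths=paths,
    )


def _driver_paths(problem: ControlProblem, drivers: list[str]) -> dict[str, list[str]]:
    """Shortest control path from the driver set to each target (reporting aid)."""
    g = problem.digraph()
    paths: dict[str, list[str]] = {}
    for t in problem.targets:
        best = None
        for d in drivers:
            try:
                p = nx.shortest_path(g, d, t)
            except nx.NetworkXNoPath:
                continue
            if best is None or len(p) < len(best):
                best = p
        if best is not None:
            paths[t] = best
    return paths


def _is_feasible(problem, K, m_cache, draws, seed) -> bool:
    key = frozenset(K)
    if key not in m_cache:
        m_cache[key] = (
            generic_rank(problem, sorted(K), draws=draws, seed=seed) == problem.n_targets
        )
    return m_cache[key]


def enumerate_optimal_sets(
    problem: ControlProblem, size: int, draws: int = 3, seed: int = 0
) -> list[frozenset[str]]:
    """All feasible driver subsets of U of the given (minimum) cardinality."""
    cache: dict[frozenset, bool] = {}
    return [
        frozenset(K)
        for K in itertools.combinations(problem.inputs, size)
        if _is_feasible(problem, K, cache, draws, seed)
    ]


def sample_configurations(
    problem: ControlProblem,
    size: int,
    mode: str = "enumerate",
    steps: int = 10_000,
    burn: int = 1000,
    thin: int = 10,
    seed: int = 0,
    draws: int = 3,
) -> pd.Series:
    """Per-TF frequency across alternative optimal driver configurations.

    ``enumerate`` lists every feasible size-``size`` subset of U and reports
    exact membership fractions.  ``walk`` runs a Markov chain over the same
    family: a uniformly chosen single-element swap is proposed each step and
    accepted iff the swapped set still certifies the rank condition (a
    symmetric proposal, so the stationary distribution is uniform over the
    connected feasible family); configurations are recorded every ``thin``
    steps after ``burn``.
    """
    if mode not in {"enumerate", "walk"}:
        raise ValueError("mode must be 'enumerate' or 'walk'")
    inputs = problem.inputs
    if mode == "enumerate":
        sets = enumerate_optimal_sets(problem, size, draws=draws, seed=seed)
        if not sets:
            raise ValueError(f"no feasible driver set of size {size}")
        counts = {u: sum(u in K for K in sets) / len(sets) for u in inputs}
        return pd.Series(counts, name="frequency").sort_index()

    if steps <= burn:
        raise ValueError("steps must exceed burn")
    rng = np.random.default_rng(seed)
    cache: dict[frozenset, bool] = {}
    # start from some feasible set
    current = None
    for K in itertools.combinations(inputs, size):
        if _is_feasible(problem, K, cache, draws, seed):
            current = set(K)
            break
    if current is None:
        raise ValueError(f"no feasible driver set of size {size}")
    counts = {u: 0 for u in inputs}
    recorded = 0
    outside = [u for u in inputs if u not in current]
    for step in range(steps):
        # lazy chain (stay w.p. 1/2) to guarantee aperiodicity
        if outside and rng.random() < 0.5:
            drop = rng.choice(sorted(current))
            add = rng.choice(sorted(outside))
            proposal = (current - {drop}) | {add}
            if _is_feasible(problem, proposal, cache, draws, seed):
                current = proposal
                outside = [u for u in inputs if u not in current]
        if step >= burn and (step - burn) % thin == 0:
            for u in current:
                counts[u] += 1
            recorded += 1
    freq = {u: counts[u] / recorded for u in inputs}
    return pd.Series(freq, name="frequency").sort_index()


def key_tfs(frequencies: pd.Series, threshold: float = 0.5) -> list[str]:
    """TFs whose control frequency exceeds the threshold (default 0.5)."""
    return sorted(frequencies.index[frequencies > threshold].tolist())


def clique_centrality(graph: nx.Graph | nx.DiGraph) -> pd.Series:
    """Maximal-clique centrality: sum of (|C|-1)! over maximal cliques containing v.

    Computed on the undirected projection; only cliques of size >= 2 count,
    so isolated nodes score 0.  Used to preselect hub TFs as constraint sets.
    """
    und = graph.to_undirected() if graph.is_directed() else graph
    scores = {v: 0 for v in und.nodes}
    for clique in nx.find_cliques(und):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return pd.Series(scores, name="mcc", dtype=float).sort_index()


def solve_control(
    problem: ControlProblem,
    mode: str = "enumerate",
    steps: int = 10_000,
    burn: int = 1000,
    thin: int = 10,
    seed: int = 0,
    exact: bool = True,
) -> ControlSolution:
    """Convenience wrapper: minimum driver set plus configuration frequencies."""
    sol = min_driver_set(problem, exact=exact, seed=seed)
    if sol.infeasible_targets or not sol.feasible:
        return sol
    freqs = sample_configurations(
        problem, size=len(sol.drivers), mode=mode, steps=steps,
        burn=burn, thin=thin, seed=seed,
    )
    sol.frequencies = freqs
    sol.key_tfs = key_tfs(freqs)
    return sol
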