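"""Trait-network learning: hill-climbing search over DAGs with Gaussian BIC.

The phenotypic network over traits is a linear-Gaussian Bayesian network
scored by the decomposable BIC

    score(dag) = sum_nodes [ loglik(node | parents at MLE) ] - (d/2) ln n

where d counts the free parameters (per node: one coefficient per parent,
an intercept and a residual variance).  Higher is better.  Greedy hill
climbing over single-edge additions, deletions and reversals finds a
local optimum; nonparametric bootstrap over rows yields arc strength
(fraction of resampled networks containing the arc in either direction)
and direction (fraction of those with a given orientation), and arcs are
kept when strength >= 80% and direction > 50%.  The contribution of each
retained edge is the change in the network score when the edge is removed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitGraph",
    "EdgeSupport",
    "ScoreReport",
    "local_bic",
    "bic_score",
    "hill_climb",
    "bootstrap_edges",
    "select_edges",
    "edge_delta_bic",
]

BOOTSTRAP_BUDGET = 5e8  # B * n cells before a workload warning


@dataclass(frozen=True)
class TraitGraph:
    """A DAG over traits: ``edges`` are ordered (parent, child) pairs."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(sorted(set(map(tuple, self.edges)))))
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop {p}->{c}")
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge {p}->{c} references unknown node")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        if self._find_cycle() is not None:
            raise ValueError(f"graph contains a cycle: {self._find_cycle()}")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == node))

    def _find_cycle(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        try:
            return nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None

    def with_edge(self, edge: tuple[str, str]) -> "TraitGraph":
        return TraitGraph(self.nodes, self.edges + (edge,))

    def without_edge(self, edge: tuple[str, str]) -> "TraitGraph":
        return TraitGraph(self.nodes, tuple(e for e in self.edges if e != tuple(edge)))


@dataclass
class EdgeSupport:
    """Bootstrap arc support: one row per ordered (parent, child) pair."""

    table: pd.DataFrame  # parent, child, strength (%), direction (%)
    n_bootstrap: int


@dataclass
class ScoreReport:
    score: float
    delta_bic: pd.DataFrame = field(default_factory=pd.DataFrame)  # parent, child, delta_bic


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def local_bic(data: pd.DataFrame, node: str, parents: tuple[str, ...]) -> float:
    """BIC contribution of one node given its parents (higher is better)."""
    y = data[node].to_numpy(float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [data[p].to_numpy(float) for p in parents])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular parent design for node {node!r} (collinear traits)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        s2 = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    d = len(parents) + 2  # coefficients + intercept + variance
    return loglik - 0.5 * d * np.log(n)


def bic_score(data: pd.DataFrame, dag: TraitGraph) -> float:
    """Decomposable Gaussian network score: sum of local BICs."""
    missing = [v for v in dag.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"dag nodes missing from data: {missing}")
    if data[list(dag.nodes)].isna().any().any():
        raise ValueError("network data must be complete")
    return sum(local_bic(data, v, dag.parents(v)) for v in dag.nodes)


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def _creates_cycle(adj: dict[str, set[str]], parent: str, child: str) -> bool:
    # adding parent->child cycles iff child already reaches parent
    stack, seen = [child], set()
    while stack:
        v = stack.pop()
        if v == parent:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj[v])
    return False


def _random_dag(nodes: tuple[str, ...], rng: np.random.Generator) -> TraitGraph:
    order = list(nodes)
    rng.shuffle(order)
    edges = [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(i + 1, len(order))
        if rng.random() < 0.5
    ]
    return TraitGraph(nodes, tuple(edges))


def hill_climb(
    data: pd.DataFrame,
    nodes: list[str] | None = None,
    restarts: int = 10,
    seed: int = 0,
    local_score=None,
    tie_break_order: list[str] | None = None,
) -> TraitGraph:
    """Greedy DAG search over add/delete/reverse moves.

    Each step applies the single best score-improving move (acyclicity
    enforced on every candidate) and stops at a local optimum.  Restart 0
    starts from the empty graph, later restarts from random DAGs; the best
    final score wins, ties broken by the lexicographically smallest edge
    set.  Deterministic for a given seed.

    ``tie_break_order`` sets the node priority used when candidate moves
    have exactly equal gain (default: lexicographic).  Gaussian BIC is
    score-equivalent, so the orientation of an isolated arc is an exact
    tie; the bootstrap permutes this order per replicate so the equivalence
    class is sampled rather than always resolved the same way.
    """
    nodes_t = tuple(nodes) if nodes is not None else tuple(data.columns)
    n = len(data)
    if n <= len(nodes_t) + 1:
        raise ValueError("need more rows than traits + 1 to learn a network")
    score_local = local_score or (lambda v, pa: local_bic(data, v, pa))
    prio = {v: i for i, v in enumerate(tie_break_order or sorted(nodes_t))}
    if set(prio) != set(nodes_t):
        raise ValueError("tie_break_order must be a permutation of the nodes")
    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def ls(v: str, pa: tuple[str, ...]) -> float:
        key = (v, pa)
        if key not in cache:
            cache[key] = score_local(v, pa)
        return cache[key]

    rng = np.random.Generator(np.random.PCG64(seed))
    best_graph: TraitGraph | None = None
    best_score = -np.inf

    for rs in range(max(1, restarts)):
        g = TraitGraph(nodes_t) if rs == 0 else _random_dag(nodes_t, rng)
        edges = set(g.edges)
        parents = {v: set(g.parents(v)) for v in nodes_t}
        score = sum(ls(v, tuple(sorted(parents[v]))) for v in nodes_t)
        while True:
            adj = {v: {c for p, c in edges if p == v} for v in nodes_t}
            candidates: list[tuple[float, tuple[str, str, str]]] = []
            for u, v in itertools.permutations(nodes_t, 2):
                if (u, v) not in edges:
                    if not _creates_cycle(adj, u, v):
                        gain = (ls(v, tuple(sorted(parents[v] | {u})))
                                - ls(v, tuple(sorted(parents[v]))))
                        candidates.append((gain, ("add", u, v)))
                else:
                    gain = (ls(v, tuple(sorted(parents[v] - {u})))
                            - ls(v, tuple(sorted(parents[v]))))
                    candidates.append((gain, ("del", u, v)))
                    # reversal: delete u->v then add v->u
                    adj2 = {k: set(s) for k, s in adj.items()}
                    adj2[u].discard(v)
                    if not _creates_cycle(adj2, v, u):
                        gain_rev = (
                            gain
                            + ls(u, tuple(sorted(parents[u] | {v})))
                            - ls(u, tuple(sorted(parents[u])))
                        )
                        candidates.append((gain_rev, ("rev", u, v)))
            improving = [(g, m) for g, m in candidates if g > 1e-10]
            if not improving:
                break
            best_gain = max(g for g, _ in improving)
            best_move = min(
                (m for g, m in improving if g >= best_gain - 1e-12),
                key=lambda m: (m[0], prio[m[1]], prio[m[2]]),
            )
            kind, u, v = best_move
            if kind == "add":
                edges.add((u, v))
                parents[v].add(u)
            elif kind == "del":
                edges.discard((u, v))
                parents[v].discard(u)
            else:
                edges.discard((u, v))
                parents[v].discard(u)
                edges.add((v, u))
                parents[u].add(v)
            score += best_gain

        final = TraitGraph(nodes_t, tuple(edges))
        final_score = sum(ls(v, final.parents(v)) for v in nodes_t)
        if final_score > best_score + 1e-12 or (
            abs(final_score - best_score) <= 1e-12
            and (best_graph is None or final.edges < best_graph.edges)
        ):
            best_graph, best_score = final, final_score
    assert best_graph is not None
    return best_graph


def bootstrap_edges(
    data: pd.DataFrame,
    B: int = 50_000,
    seed: int = 0,
    nodes: list[str] | None = None,
    restarts: int = 1,
) -> EdgeSupport:
    """Arc strength and direction from B nonparametric row resamples.

    Strength of an ordered pair (u, v) is the percentage of bootstrap
    networks containing the arc in either direction; direction is the
    percentage of those networks orienting it u -> v.  Rows are put in a
    canonical sorted order before resampling, so the tallies depend only
    on the data values and the seed, not on input row order.  Each
    replicate draws a fresh node priority for exact-tie breaking so that
    score-equivalent orientations are sampled evenly.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap sample")
    nodes_t = tuple(nodes) if nodes is not None else tuple(data.columns)
    n = len(data)
    if B * n > BOOTSTRAP_BUDGET:
        logger.warning("bootstrap workload B*n = %g exceeds budget %g", B * n,
                       BOOTSTRAP_BUDGET)
    rng = np.random.Generator(np.random.PCG64(seed))
    arr = (data[list(nodes_t)]
           .sort_values(list(nodes_t), kind="mergesort")
           .reset_index(drop=True))
    present: dict[frozenset, int] = {}
    oriented: dict[tuple[str, str], int] = {}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = arr.iloc[idx].reset_index(drop=True)
        order = list(rng.permutation(nodes_t))
        g = hill_climb(sub, nodes=list(nodes_t), restarts=restarts,
                       seed=int(rng.integers(0, 2**31)),
                       tie_break_order=order)
        for u, v in g.edges:
            present[frozenset((u, v))] = present.get(frozenset((u, v)), 0) + 1
            oriented[(u, v)] = oriented.get((u, v), 0) + 1
    rows = []
    for u, v in itertools.permutations(nodes_t, 2):
        np_ = present.get(frozenset((u, v)), 0)
        no = oriented.get((u, v), 0)
        rows.append({
            "parent": u, "child": v,
            "strength": 100.0 * np_ / B,
            "direction": 100.0 * no / np_ if np_ else 0.0,
        })
    return EdgeSupport(table=pd.DataFrame(rows), n_bootstrap=B)


def select_edges(
    support: EdgeSupport, min_strength: float = 80.0, min_direction: float = 50.0
) -> TraitGraph:
    """Keep arcs with strength >= min_strength and direction strictly >
    min_direction; the selected arc set must be acyclic."""
    tab = support.table
    keep = tab[(tab["strength"] >= min_strength) & (tab["direction"] > min_direction)]
    nodes = tuple(sorted(set(tab["parent"]) | set(tab["child"])))
    edges = tuple(sorted((r.parent, r.child) for r in keep.itertuples()))
    return TraitGraph(nodes, edges)  # raises listing the cycle if cyclic


def edge_delta_bic(data: pd.DataFrame, dag: TraitGraph) -> ScoreReport:
    """Per-edge score change on removal: delta = score(dag) - score(dag \\ e).

    Positive delta means the network score worsens when the edge is
    dropped (the edge contributes); by decomposability only the child's
    local score changes.
    """
    total = bic_score(data, dag)
    rows = []
    for e in dag.edges:
        delta = total - bic_score(data, dag.without_edge(e))
        rows.append({"parent": e[0], "child": e[1], "delta_bic": delta})
    return ScoreReport(score=total, delta_bic=pd.DataFrame(rows))
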