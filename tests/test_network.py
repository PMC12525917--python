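"""Hill-climbing structure search, BIC scoring and bootstrap arc support."""

import itertools

import numpy as np
import pandas as pd
import pytest

from semgwas import (
    TraitGraph, bic_score, bootstrap_edges, edge_delta_bic, hill_climb,
    select_edges,
)
from semgwas.network import EdgeSupport


def all_dags(nodes):
    """Every labeled DAG on the given nodes (543 for 4 nodes)."""
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.append((u, v))
            elif s == 2:
                edges.append((v, u))
        try:
            yield TraitGraph(tuple(nodes), tuple(edges))
        except ValueError:
            continue


def exhaustive_best(data, nodes):
    best, best_score = None, -np.inf
    for g in all_dags(nodes):
        s = bic_score(data, g)
        if s > best_score:
            best, best_score = g, s
    return best, best_score


@pytest.fixture
def chain_data():
    rng = np.random.Generator(np.random.PCG64(21))
    n = 500
    y1 = rng.standard_normal(n)
    y2 = 0.9 * y1 + 0.3 * rng.standard_normal(n)
    y3 = -0.8 * y2 + 0.3 * rng.standard_normal(n)
    y4 = 0.7 * y3 + 0.3 * rng.standard_normal(n)
    return pd.DataFrame({"NP": y1, "NG": y2, "HGW": y3, "PT": y4})


class TestGraph:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            TraitGraph(("a", "b"), (("a", "b"), ("b", "a")))

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            TraitGraph(("a",), (("a", "a"),))


class TestScore:
    def test_empty_graph_closed_form(self, rng):
        n = 200
        data = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        g = TraitGraph(("a", "b", "c"))
        expect = 0.0
        for c in "abc":
            s2 = np.var(data[c].to_numpy())  # MLE variance
            expect += -0.5 * n * (np.log(2 * np.pi * s2) + 1.0) - np.log(n)
        assert bic_score(data, g) == pytest.approx(expect, rel=1e-12)

    def test_decomposability_random_dags(self, rng):
        from semgwas.network import local_bic

        data = pd.DataFrame(rng.standard_normal((100, 4)),
                            columns=["w", "x", "y", "z"])
        dags = list(all_dags(("w", "x", "y", "z")))
        for i in rng.choice(len(dags), size=50, replace=False):
            g = dags[i]
            total = sum(local_bic(data, v, g.parents(v)) for v in g.nodes)
            assert bic_score(data, g) == pytest.approx(total, rel=1e-12)

    def test_strong_edge_beats_penalty(self, rng):
        n = 200
        y1 = rng.standard_normal(n)
        data = pd.DataFrame({"a": y1, "b": 2 * y1 + 1e-3 * rng.standard_normal(n)})
        nodes = ("a", "b")
        assert (bic_score(data, TraitGraph(nodes, (("a", "b"),)))
                > bic_score(data, TraitGraph(nodes)))

    def test_collinear_parents_error(self, rng):
        y = rng.standard_normal(50)
        data = pd.DataFrame({"a": y, "b": 2 * y, "c": rng.standard_normal(50)})
        g = TraitGraph(("a", "b", "c"), (("a", "c"), ("b", "c")))
        with pytest.raises(ValueError, match="'c'"):
            bic_score(data, g)


class TestHillClimb:
    def test_independent_noise_gives_empty_graph(self, rng):
        data = pd.DataFrame(rng.standard_normal((500, 4)),
                            columns=["a", "b", "c", "d"])
        g = hill_climb(data, restarts=10, seed=0)
        assert g.edges == ()
        best, _ = exhaustive_best(data, ("a", "b", "c", "d"))
        assert best.edges == ()

    def test_chain_recovery_matches_exhaustive_optimum(self, chain_data):
        g = hill_climb(chain_data, restarts=10, seed=0)
        _, best_score = exhaustive_best(chain_data, tuple(chain_data.columns))
        assert bic_score(chain_data, g) == pytest.approx(best_score, rel=1e-12)
        skeleton = {frozenset(e) for e in g.edges}
        assert skeleton == {frozenset(("NP", "NG")), frozenset(("NG", "HGW")),
                            frozenset(("HGW", "PT"))}

    def test_two_node_single_edge(self, rng):
        y1 = rng.standard_normal(300)
        data = pd.DataFrame({"a": y1, "b": y1 + 0.3 * rng.standard_normal(300)})
        g = hill_climb(data, restarts=5, seed=0)
        assert len(g.edges) == 1
        _, best_score = exhaustive_best(data, ("a", "b"))
        assert bic_score(data, g) == pytest.approx(best_score, rel=1e-12)

    def test_score_never_below_empty(self, rng):
        for s in range(10):
            data = pd.DataFrame(
                np.random.Generator(np.random.PCG64(s)).standard_normal((60, 4)),
                columns=["a", "b", "c", "d"])
            g = hill_climb(data, restarts=3, seed=s)
            assert (bic_score(data, g)
                    >= bic_score(data, TraitGraph(tuple(data.columns))) - 1e-9)


class TestBootstrap:
    def test_forced_edge_full_strength(self, rng):
        y1 = rng.standard_normal(100)
        data = pd.DataFrame({"a": y1, "b": 2.0 * y1})
        # noiseless relation: every resample contains the arc
        support = bootstrap_edges(data, B=200, seed=0)
        row = support.table.set_index(["parent", "child"])
        assert row.loc[("a", "b"), "strength"] == 100.0
        assert row.loc[("b", "a"), "strength"] == 100.0

    def test_determinism(self, chain_data):
        s1 = bootstrap_edges(chain_data, B=30, seed=5)
        s2 = bootstrap_edges(chain_data, B=30, seed=5)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_row_order_invariance(self, chain_data):
        s1 = bootstrap_edges(chain_data, B=30, seed=5)
        shuffled = chain_data.sample(frac=1.0, random_state=3)
        s2 = bootstrap_edges(shuffled, B=30, seed=5)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_markov_equivalent_direction_near_half(self, rng):
        y1 = rng.standard_normal(200)
        data = pd.DataFrame({"a": y1, "b": y1 + 0.5 * rng.standard_normal(200)})
        support = bootstrap_edges(data, B=2000, seed=1)
        row = support.table.set_index(["parent", "child"])
        assert row.loc[("a", "b"), "direction"] == pytest.approx(50.0, abs=5.0)


class TestSelect:
    def _support(self, rows):
        return EdgeSupport(table=pd.DataFrame(rows), n_bootstrap=1000)

    def test_threshold_rules(self):
        support = self._support([
            {"parent": "a", "child": "b", "strength": 99.98, "direction": 100.0},
            {"parent": "b", "child": "c", "strength": 79.9, "direction": 100.0},
            {"parent": "c", "child": "d", "strength": 100.0, "direction": 50.0},
        ])
        g = select_edges(support)
        assert g.edges == (("a", "b"),)

    def test_cycle_after_selection_errors(self):
        support = self._support([
            {"parent": "a", "child": "b", "strength": 100.0, "direction": 60.0},
            {"parent": "b", "child": "a", "strength": 100.0, "direction": 60.0},
        ])
        with pytest.raises(ValueError, match="cycle"):
            select_edges(support)


class TestDeltaBIC:
    def test_pure_penalty_edge(self, rng):
        n = 100
        data = pd.DataFrame({"a": rng.standard_normal(n),
                             "b": rng.standard_normal(n)})
        # center, then orthogonalize, so the MLE coefficient is exactly 0
        data["a"] -= data["a"].mean()
        data["b"] -= data["b"].mean()
        data["b"] -= (data["b"] @ data["a"]) / (data["a"] @ data["a"]) * data["a"]
        g = TraitGraph(("a", "b"), (("a", "b"),))
        rep = edge_delta_bic(data, g)
        delta = rep.delta_bic["delta_bic"].iloc[0]
        assert delta == pytest.approx(-0.5 * np.log(n), rel=1e-9)

    def test_true_edges_positive(self, chain_data):
        g = TraitGraph(("NP", "NG", "HGW", "PT"),
                       (("NP", "NG"), ("NG", "HGW"), ("HGW", "PT")))
        rep = edge_delta_bic(chain_data, g)
        assert (rep.delta_bic["delta_bic"] > 0).all()

    def test_only_child_local_score_changes(self, chain_data):
        from semgwas.network import local_bic

        g = TraitGraph(("NP", "NG", "HGW", "PT"),
                       (("NP", "NG"), ("NG", "HGW")))
        rep = edge_delta_bic(chain_data, g)
        row = rep.delta_bic.set_index(["parent", "child"])
        expect = (local_bic(chain_data, "NG", ("NP",))
                  - local_bic(chain_data, "NG", ()))
        assert row.loc[("NP", "NG"), "delta_bic"] == pytest.approx(expect, rel=1e-12)
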