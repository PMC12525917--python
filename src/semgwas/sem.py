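"""Structural-coefficient estimation for a recursive trait system.

Given the selected trait DAG, each child trait is regressed on its parent
traits with the genomic covariance structure respected: the model for a
child k with parent set pa(k) is

    y_k = 1 mu + sum_{l in pa(k)} lambda_{kl} y_l + g_k + e_k,
    g_k ~ N(0, G sg2_k),  e_k ~ N(0, I se2_k)

with (sg2_k, se2_k) fixed at the multi-trait GBLUP posterior means
(two-stage estimation).  Because the system is fully recursive (a DAG),
equation-by-equation generalized least squares is a consistent estimator
of the structural coefficients lambda — the expected change in the child
per unit change in the parent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import TraitGraph

__all__ = ["StructuralMatrix", "topological_order", "estimate_lambdas"]


@dataclass
class StructuralMatrix:
    """Lambda[child, parent] holds the structural coefficient of each edge."""

    traits: list[str]
    Lambda: np.ndarray  # t x t, nonzero only at DAG edges
    table: pd.DataFrame  # parent, child, lambda

    def __post_init__(self) -> None:
        t = len(self.traits)
        L = np.asarray(self.Lambda, float)
        if L.shape != (t, t):
            raise ValueError("Lambda must be t x t")
        if np.any(np.diag(L) != 0):
            raise ValueError("Lambda must have a zero diagonal")
        # acyclicity <=> nilpotency for a DAG coefficient matrix
        if np.abs(np.linalg.matrix_power(L, t)).max() > 1e-10:
            raise ValueError("Lambda is not nilpotent: the trait system is not recursive")
        self.Lambda = L


def topological_order(dag: TraitGraph) -> list[str]:
    """Parents before children; ties broken lexicographically."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(sorted(dag.nodes))
    g.add_edges_from(dag.edges)
    return list(nx.lexicographical_topological_sort(g))


def estimate_lambdas(
    y_star: pd.DataFrame,
    dag: TraitGraph,
    G: np.ndarray | None,
    var_g: dict[str, float] | None = None,
    var_e: dict[str, float] | None = None,
) -> StructuralMatrix:
    """Equation-wise GLS estimates of the edge coefficients.

    ``var_g``/``var_e`` give per-trait genetic and residual variances
    (posterior means from the multi-trait fit).  Passing ``G=None`` (or an
    all-zero genetic variance) reduces each equation to ordinary least
    squares.
    """
    traits = topological_order(dag)
    n = len(y_star)
    t = len(traits)
    Lam = np.zeros((t, t))
    rows = []
    tindex = {tr: i for i, tr in enumerate(traits)}

    for child in traits:
        pa = dag.parents(child)
        if not pa:
            continue
        y = y_star[child].to_numpy(float)
        X = np.column_stack([np.ones(n)] + [y_star[p].to_numpy(float) for p in pa])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear parents for trait {child!r}")
        sg = (var_g or {}).get(child, 0.0)
        se = (var_e or {}).get(child, 1.0)
        if G is None or sg == 0.0:
            V = np.eye(n) * se
        else:
            Gm = np.asarray(G, float)
            V = sg * Gm + se * np.eye(n)
            if np.linalg.eigvalsh(V).min() <= 0:
                warnings.warn("singular trait covariance; adding 1e-6 jitter",
                              stacklevel=2)
                V = V + 1e-6 * np.eye(n)
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, y)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        for j, p in enumerate(pa):
            lam = float(beta[1 + j])
            Lam[tindex[child], tindex[p]] = lam
            rows.append({"parent": p, "child": child, "lambda": lam})

    table = pd.DataFrame(rows, columns=["parent", "child", "lambda"])
    return StructuralMatrix(traits=traits, Lambda=Lam, table=table)
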