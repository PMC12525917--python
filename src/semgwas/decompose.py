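"""Decomposition of SNP effects into direct, indirect and total components.

In a recursive trait system with structural matrix Lambda (Lambda[child,
parent] = lambda of the edge), a SNP's direct effect on an upstream trait
propagates to downstream traits along every directed path, scaled by the
product of the edge coefficients on the path:

    indirect(path l -> ... -> k) = (prod of lambdas along path) * direct_l
    total_k = direct_k + sum over all paths into k

Equivalently, the vector of total effects solves
(I - Lambda) total = direct, so total = (I - Lambda)^{-1} direct.  Both
routes are computed and asserted equal; the path form is what gets
reported because it names each mediating chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import TraitGraph
from .sem import StructuralMatrix

__all__ = ["EffectDecomposition", "enumerate_paths", "path_coefficient",
           "decompose_effects"]


@dataclass
class EffectDecomposition:
    """Long table: one row per SNP x trait x component.

    ``component`` is ``direct``, ``indirect:<path>`` (path written
    parent->...->trait) or ``total``; total = direct + sum(indirect)
    exactly.
    """

    traits: list[str]
    table: pd.DataFrame  # snp, trait, component, value


def enumerate_paths(dag: TraitGraph, target: str) -> list[tuple[str, ...]]:
    """All simple directed paths from any ancestor into ``target``.

    Deterministic order: lexicographic by the path's node string.  A
    target with no ancestors yields the empty list.
    """
    import networkx as nx

    if target not in dag.nodes:
        raise ValueError(f"unknown target trait {target!r}")
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    paths = []
    for src in dag.nodes:
        if src == target:
            continue
        for p in nx.all_simple_paths(g, src, target):
            paths.append(tuple(p))
    return sorted(paths, key=lambda p: "->".join(p))


def path_coefficient(path: tuple[str, ...], Lam: StructuralMatrix) -> float:
    """Product of the edge lambdas along a directed path."""
    idx = {tr: i for i, tr in enumerate(Lam.traits)}
    out = 1.0
    for parent, child in zip(path[:-1], path[1:]):
        lam = Lam.Lambda[idx[child], idx[parent]]
        if lam == 0.0:
            raise ValueError(f"edge {parent}->{child} has no structural coefficient")
        out *= lam
    return out


def decompose_effects(
    direct: pd.DataFrame, dag: TraitGraph, Lam: StructuralMatrix
) -> EffectDecomposition:
    """Split each SNP's per-trait direct effects into indirect and total.

    ``direct`` is wide-format: one row per SNP (index = SNP id), one
    column per trait, holding the scan's per-trait effects.  The path-sum
    totals are cross-checked against the (I - Lambda)^{-1} solve.
    """
    traits = Lam.traits
    missing = [t for t in traits if t not in direct.columns]
    if missing:
        raise ValueError(f"direct effects missing for traits: {missing}")
    for p, c in dag.edges:
        idx = {tr: i for i, tr in enumerate(traits)}
        if Lam.Lambda[idx[c], idx[p]] == 0.0:
            raise ValueError(f"Lambda has no coefficient for DAG edge {p}->{c}")
    t = len(traits)
    D = direct[traits].to_numpy(float)           # (n_snp, t)
    I_minus = np.eye(t) - Lam.Lambda
    total_inv = np.linalg.solve(I_minus, D.T).T   # per SNP: (I-Lam)^-1 d

    paths_by_trait = {tr: enumerate_paths(dag, tr) for tr in traits}
    tidx = {tr: i for i, tr in enumerate(traits)}

    rows = []
    total_path = np.array(D, copy=True)
    for tr in traits:
        k = tidx[tr]
        for path in paths_by_trait[tr]:
            coef = path_coefficient(path, Lam)
            contrib = coef * D[:, tidx[path[0]]]
            total_path[:, k] += contrib
            label = "indirect:" + "->".join(path[:-1]) + f"->{tr}"
            rows.append((tr, label, contrib))
    if not np.allclose(total_path, total_inv, rtol=0, atol=1e-10 * max(1.0, np.abs(D).max())):
        raise AssertionError("path-sum totals disagree with the (I - Lambda)^-1 solve")

    snps = direct.index.to_numpy()
    frames = []
    for tr in traits:
        k = tidx[tr]
        frames.append(pd.DataFrame({"snp": snps, "trait": tr,
                                    "component": "direct", "value": D[:, k]}))
    for tr, label, contrib in rows:
        frames.append(pd.DataFrame({"snp": snps, "trait": tr,
                                    "component": label, "value": contrib}))
    for tr in traits:
        k = tidx[tr]
        frames.append(pd.DataFrame({"snp": snps, "trait": tr,
                                    "component": "total", "value": total_path[:, k]}))
    table = pd.concat(frames, ignore_index=True)
    return EffectDecomposition(traits=list(traits), table=table)
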