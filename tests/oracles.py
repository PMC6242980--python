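"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions with plain Python loops
and sets, deliberately sharing no code path with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from sfcnlink import Graph, ScoreMatrix
from sfcnlink.evaluation import EdgeSplit


def oracle_pair_score(g: Graph, name: str, x: int, y: int, lp_epsilon: float = 0.001):
    """Set-based per-pair formula for every index."""
    nx_, ny_ = set(g.neighbors(x)), set(g.neighbors(y))
    common = nx_ & ny_
    kx, ky = len(nx_), len(ny_)
    if name == "cn":
        return len(common)
    if name == "salton":
        return len(common) / math.sqrt(kx * ky) if kx * ky else 0.0
    if name == "ra":
        return sum(1.0 / len(g.neighbors(z)) for z in common)
    if name == "hpi":
        return len(common) / min(kx, ky) if min(kx, ky) else 0.0
    if name == "hdi":
        return len(common) / max(kx, ky) if max(kx, ky) else 0.0
    if name == "lhn":
        return len(common) / (kx * ky) if kx * ky else 0.0
    if name == "lnbra":
        if not common:
            return 0.0
        eta = g.n_nodes * (g.n_nodes - 1) / (2 * g.n_edges) - 1
        total = 0.0
        for z in common:
            nbrs = sorted(g.neighbors(z))
            kz = len(nbrs)
            conn = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
            disc = kz * (kz - 1) // 2 - conn
            total += math.log2(eta * (conn + 1) / (disc + 1)) / kz
        return total
    if name == "lp":
        # count walks by explicit enumeration over intermediate nodes
        nodes = range(1, g.n_nodes + 1)
        w2 = sum(1 for i in nodes if g.has_edge(x, i) and g.has_edge(i, y))
        w3 = sum(
            1
            for i in nodes
            for j in nodes
            if g.has_edge(x, i) and g.has_edge(i, j) and g.has_edge(j, y)
        )
        return w2 + lp_epsilon * w3
    raise ValueError(name)


def oracle_induced_edge_count(g: Graph, z: int) -> int:
    """Edge count of the subgraph induced by Γ(z)."""
    nbrs = sorted(g.neighbors(z))
    return sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))


def oracle_fcn(g: Graph, c2: ScoreMatrix, x: int, y: int):
    """Naive per-node application of the three classification rules.

    Returns (type1, type2, type3, c1, c2, c3) with type3 net of 1/2.
    """
    t1, t2, t3 = set(), set(), set()
    c1 = c2_sum = c3 = 0.0
    for i in range(1, g.n_nodes + 1):
        if i in (x, y):
            continue
        r_xi = 1.0 if g.has_edge(x, i) else 0.0
        r_iy = 1.0 if g.has_edge(i, y) else 0.0
        s_xi = c2[x, i]
        s_iy = c2[i, y]
        if r_xi * s_iy != 0:
            t1.add(i)
        if s_xi * r_iy != 0:
            t2.add(i)
        if s_xi * s_iy != 0:
            t3.add(i)
        c1 += r_xi * s_iy
        c2_sum += s_xi * r_iy
        c3 += s_xi * s_iy
    return t1, t2, t3 - t1 - t2, c1, c2_sum, c3


def oracle_auc_exact(scores: ScoreMatrix, split: EdgeSplit, g_full: Graph) -> float:
    """Double loop over every (probe, nonexistent) comparison."""
    pos = [scores[x, y] for x, y in sorted(split.probe_edges)]
    neg = [
        scores[i, j]
        for i, j in itertools.combinations(range(1, g_full.n_nodes + 1), 2)
        if not g_full.has_edge(i, j)
    ]
    higher = tied = 0
    for p in pos:
        for q in neg:
            if p > q:
                higher += 1
            elif p == q:
                tied += 1
    return (higher + 0.5 * tied) / (len(pos) * len(neg))


def oracle_precision(scores: ScoreMatrix, split: EdgeSplit, g_full: Graph, L: int) -> float:
    """Full sort of all non-training pairs, then count probe hits in top L."""
    candidates = [
        (i, j)
        for i, j in itertools.combinations(range(1, g_full.n_nodes + 1), 2)
        if (i, j) not in split.training_edges
    ]
    ranked = sorted(candidates, key=lambda p: (-scores[p[0], p[1]], p[0], p[1]))
    return sum(1 for p in ranked[:L] if p in split.probe_edges) / L


def random_graph(rng: np.random.Generator, n_max: int = 30, p: float | None = None) -> Graph:
    """Seeded ER graph on 5..n_max nodes, built without networkx."""
    n = int(rng.integers(5, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.1, 0.4))
    edges = [
        (i, j)
        for i, j in itertools.combinations(range(1, n + 1), 2)
        if rng.random() < p
    ]
    return Graph(n, edges)
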