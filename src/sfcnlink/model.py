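"""Future-common-neighbor scoring model.

A future common neighbor of a target pair (x, y) is a node that is not
yet a common neighbor but is predicted to become one: type 1 is already
linked to x and is similar to y, type 2 is already linked to y and is
similar to x, and type 3 is linked to neither but similar to both.
Similarity along the missing link(s) is measured by a pluggable base
index C2; the pair itself is scored directly by a second base index C1.
The combined score is

    s(x, y) = alpha * s_C1(x, y)
            + beta * (Γx·S_y + S_x·Γy + S_x·S_y)

where Γx, Γy are the 0/1 connection rows of x and y, and S_x, S_y the
C2-score rows, all with positions x and y forced to 0 so the pair never
contributes to itself.  The three dot products are the type-1, type-2
and type-3 contributions.

The score is implemented literally: a node that already is a common
neighbor still contributes whichever products are nonzero.  An optional
strict mode instead zeroes the C2 entries of current common neighbors,
so only genuinely prospective neighbors contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .graph import Graph
from .indexes import IndexSpec, ScoreMatrix, score_matrix


@dataclass(frozen=True)
class SFCNConfig:
    """Model configuration: base indexes C1/C2 and the weights alpha/beta.

    ``alpha`` weights the direct C1 score of the pair (the current
    common-neighbor term); ``beta`` weights the summed future-common-
    neighbor contributions.  Defaults alpha=9, beta=1.
    """

    c1: IndexSpec
    c2: IndexSpec
    alpha: float = 9.0
    beta: float = 1.0
    strict_fcn: bool = False

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")

    @property
    def label(self) -> str:
        return f"SFCN-{self.c1.label}-{self.c2.label}"


@dataclass(frozen=True)
class PairVectors:
    """The four per-pair vectors: connection rows and C2-score rows.

    Entry ``i-1`` refers to node ``i``; positions x−1 and y−1 are zero
    in all four vectors.  Arrays may hold exact rationals (object
    dtype) or floats.
    """

    x: int
    y: int
    gamma_x: np.ndarray
    gamma_y: np.ndarray
    s_x: np.ndarray
    s_y: np.ndarray


@dataclass(frozen=True)
class FCNReport:
    """Identified future common neighbors of one pair and their contributions.

    The three node sets are pairwise disjoint (type 3 is reported net of
    types 1 and 2) and never contain x or y.  The contributions are the
    three raw dot products Γx·S_y, S_x·Γy and S_x·S_y — a node may
    contribute to more than one of them.
    """

    type1: frozenset[int]
    type2: frozenset[int]
    type3: frozenset[int]
    contribution1: Any
    contribution2: Any
    contribution3: Any

    @property
    def total_future_contribution(self):
        return self.contribution1 + self.contribution2 + self.contribution3

    def to_dict(self, g: Graph | None = None) -> dict:
        def _labels(nodes):
            ordered = sorted(nodes)
            if g is not None:
                return [g.node_label(i) for i in ordered]
            return list(ordered)

        return {
            "type1": _labels(self.type1),
            "type2": _labels(self.type2),
            "type3": _labels(self.type3),
            "contribution1": float(self.contribution1),
            "contribution2": float(self.contribution2),
            "contribution3": float(self.contribution3),
            "total_future_contribution": float(self.total_future_contribution),
        }


def build_pair_vectors(
    g: Graph, c2_matrix: ScoreMatrix, x: int, y: int, strict: bool = False
) -> PairVectors:
    """Extract the four vectors for pair (x, y) from g and a C2 matrix.

    ``strict`` additionally zeroes the C2 entries of current common
    neighbors of (x, y), restricting contributions to nodes that are
    not yet common neighbors.
    """
    if x == y:
        raise ValueError("pair must consist of two distinct nodes")
    g._check_node(x)
    g._check_node(y)
    if c2_matrix.n != g.n_nodes:
        raise ValueError("C2 matrix size does not match graph")
    A = g.adjacency()
    gamma_x = A[x - 1].copy()
    gamma_y = A[y - 1].copy()
    s_x = c2_matrix.values[x - 1].copy()
    s_y = c2_matrix.values[y - 1].copy()
    for idx in (x - 1, y - 1):
        gamma_x[idx] = 0.0
        gamma_y[idx] = 0.0
        s_x[idx] = 0.0
        s_y[idx] = 0.0
    if strict:
        current = (gamma_x * gamma_y) != 0
        s_x[current] = 0.0
        s_y[current] = 0.0
    return PairVectors(x, y, gamma_x, gamma_y, s_x, s_y)


def identify_fcn(v: PairVectors) -> FCNReport:
    """Classify future common neighbors from the pair vectors.

    type 1: linked to x, C2-similar to y  (γx[i]·S_y[i] ≠ 0);
    type 2: C2-similar to x, linked to y  (S_x[i]·γy[i] ≠ 0);
    type 3: C2-similar to both and in neither of the first two sets.
    Works on float or exact-rational vectors; contributions keep the
    input arithmetic.
    """
    p1 = v.gamma_x * v.s_y
    p2 = v.s_x * v.gamma_y
    p3 = v.s_x * v.s_y
    t1 = frozenset(int(i) + 1 for i in np.flatnonzero(p1 != 0))
    t2 = frozenset(int(i) + 1 for i in np.flatnonzero(p2 != 0))
    t3 = frozenset(int(i) + 1 for i in np.flatnonzero(p3 != 0)) - t1 - t2
    return FCNReport(t1, t2, t3, p1.sum(), p2.sum(), p3.sum())


def sfcn_score(
    g: Graph,
    c1_matrix: ScoreMatrix,
    c2_matrix: ScoreMatrix,
    x: int,
    y: int,
    cfg: SFCNConfig,
) -> float:
    """Score one pair: alpha·C1[x,y] + beta·(future-contribution sum)."""
    v = build_pair_vectors(g, c2_matrix, x, y, strict=cfg.strict_fcn)
    report = identify_fcn(v)
    return cfg.alpha * c1_matrix[x, y] + cfg.beta * float(report.total_future_contribution)


def future_contribution_matrix(
    g: Graph, c2_matrix: ScoreMatrix, strict: bool = False
) -> ScoreMatrix:
    """All-pairs matrix of the summed future-common-neighbor contributions.

    For the literal score, entry (x, y) is (A·S + S·A + S·S)[x, y] with
    A the adjacency and S the C2 matrix; the zero diagonals of A and S
    make the per-pair zeroing of positions x and y automatic.  Strict
    mode subtracts the terms routed through current common neighbors.
    """
    A = g.adjacency()
    S = c2_matrix.values
    F = A @ S + S @ A + S @ S
    if strict:
        E = A * S  # C2 scores restricted to existing links
        F = F - A @ E - E @ A - E @ E
    return ScoreMatrix(F)


def sfcn_components(g: Graph, cfg: SFCNConfig) -> tuple[ScoreMatrix, ScoreMatrix]:
    """C1 matrix and future-contribution matrix for ``g`` under ``cfg``."""
    c1m = score_matrix(g, cfg.c1)
    c2m = score_matrix(g, cfg.c2)
    return c1m, future_contribution_matrix(g, c2m, strict=cfg.strict_fcn)


def sfcn_score_matrix(g: Graph, cfg: SFCNConfig) -> ScoreMatrix:
    """All-pairs model scores: alpha·C1 + beta·(future contributions)."""
    c1m, fm = sfcn_components(g, cfg)
    return ScoreMatrix(cfg.alpha * c1m.values + cfg.beta * fm.values)
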