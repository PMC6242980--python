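"""Eight local similarity indexes for link prediction.

Each index scores an unordered node pair (x, y) from the neighborhood
structure of the scored graph: common neighbors (CN), the degree-
normalised variants Salton, HPI, HDI and LHN, resource allocation (RA),
the local-naive-Bayes-weighted RA (LNBRA), and the local path index
(LP, length-2 plus epsilon-weighted length-3 walks).  Every index is
available both per pair and as a symmetric all-pairs score matrix; the
two routes agree entrywise by contract.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import Graph, _canonical

INDEX_NAMES = ("cn", "salton", "ra", "hpi", "hdi", "lhn", "lnbra", "lp")


@dataclass(frozen=True)
class IndexSpec:
    """A named base index.

    ``lp_epsilon`` is the LP index's weight on length-3 walks (the LP
    index's own adjustable parameter; it is unrelated to the model
    weights alpha/beta).  It is only consulted when ``name == "lp"``.
    """

    name: str
    lp_epsilon: float = 0.001

    def __post_init__(self):
        object.__setattr__(self, "name", str(self.name).lower())
        if self.name not in INDEX_NAMES:
            raise ValueError(
                f"unknown index {self.name!r}; valid names: {', '.join(INDEX_NAMES)}"
            )
        if self.name == "lp" and not self.lp_epsilon > 0:
            raise ValueError("lp_epsilon must be > 0")

    @property
    def label(self) -> str:
        return self.name.upper()


class ScoreMatrix:
    """Symmetric all-pairs similarity scores with zero diagonal.

    Indexed with 1-based node ids: ``m[x, y]``.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("score matrix must be square")
        values = values.copy()
        np.fill_diagonal(values, 0.0)
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, pair) -> float:
        x, y = pair
        if not (1 <= x <= self.n and 1 <= y <= self.n):
            raise ValueError(f"pair ({x},{y}) outside 1..{self.n}")
        return float(self.values[x - 1, y - 1])

    def to_long_frame(self, g: Graph) -> pd.DataFrame:
        """Upper-triangle scores as (node_label_1, node_label_2, score)."""
        if g.n_nodes != self.n:
            raise ValueError("graph size does not match score matrix")
        iu, ju = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "node_label_1": [g.labels[i] for i in iu],
                "node_label_2": [g.labels[j] for j in ju],
                "score": self.values[iu, ju],
            }
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, g: Graph) -> "ScoreMatrix":
        values = np.zeros((g.n_nodes, g.n_nodes))
        for a, b, s in frame.itertuples(index=False):
            i, j = g.node_id(a) - 1, g.node_id(b) - 1
            values[i, j] = s
            values[j, i] = s
        return cls(values)


# -- per-pair scores ---------------------------------------------------


def _common(g: Graph, x: int, y: int) -> frozenset[int]:
    if x == y:
        raise ValueError("pair must consist of two distinct nodes")
    return g.neighbors(x) & g.neighbors(y)


def score_cn(g: Graph, x: int, y: int) -> int:
    """Common-neighbor count |Γx ∩ Γy|."""
    return len(_common(g, x, y))


def score_salton(g: Graph, x: int, y: int) -> float:
    """|Γx ∩ Γy| / sqrt(kx·ky); 0 when either degree is 0."""
    cn = len(_common(g, x, y))
    kk = g.degree(x) * g.degree(y)
    return cn / math.sqrt(kk) if kk else 0.0


def score_ra(g: Graph, x: int, y: int) -> float:
    """Resource allocation: Σ_{z∈Γx∩Γy} 1/k_z."""
    return sum(1.0 / g.degree(z) for z in _common(g, x, y))


def score_hpi(g: Graph, x: int, y: int) -> float:
    """Hub promoted: |Γx ∩ Γy| / min(kx, ky); 0 when min degree is 0."""
    cn = len(_common(g, x, y))
    kmin = min(g.degree(x), g.degree(y))
    return cn / kmin if kmin else 0.0


def score_hdi(g: Graph, x: int, y: int) -> float:
    """Hub depressed: |Γx ∩ Γy| / max(kx, ky); 0 when max degree is 0."""
    cn = len(_common(g, x, y))
    kmax = max(g.degree(x), g.degree(y))
    return cn / kmax if kmax else 0.0


def score_lhn(g: Graph, x: int, y: int) -> float:
    """Leicht–Holme–Newman: |Γx ∩ Γy| / (kx·ky); 0 when either degree is 0."""
    cn = len(_common(g, x, y))
    kk = g.degree(x) * g.degree(y)
    return cn / kk if kk else 0.0


def _lnbra_eta(g: Graph) -> float:
    # prior odds of a nonexistent vs existing link in the scored graph
    if g.n_edges == 0:
        raise ValueError("LNBRA needs at least one edge in the scored graph")
    eta = g.n_nodes * (g.n_nodes - 1) / (2.0 * g.n_edges) - 1.0
    if eta <= 0:
        raise ValueError("LNBRA undefined: graph has no room for nonexistent links")
    return eta


def score_lnbra(g: Graph, x: int, y: int) -> float:
    """Local-naive-Bayes RA: Σ_{z} (1/k_z)·(log2 η + log2 R_z).

    R_z = (N_Δz + 1)/(N_∇z + 1) where N_Δz / N_∇z count connected /
    disconnected node pairs among Γ(z).  May be negative.  An empty
    common-neighbor set scores 0 without consulting η.
    """
    common = _common(g, x, y)
    if not common:
        return 0.0
    eta = _lnbra_eta(g)
    total = 0.0
    for z in common:
        nbrs = sorted(g.neighbors(z))
        kz = len(nbrs)
        n_conn = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if _canonical(a, b) in g.edges
        )
        n_disc = kz * (kz - 1) // 2 - n_conn
        r_z = (n_conn + 1) / (n_disc + 1)
        # log2(eta) + log2(r_z) taken as one log of the product: same
        # quantity, but the combined form cancels exactly when eta·R_z = 1
        total += math.log2(eta * r_z) / kz
    return total


def score_lp(g: Graph, x: int, y: int, epsilon: float = 0.001) -> float:
    """Local path: (A²)_{x,y} + ε·(A³)_{x,y}.

    ε ≥ 0 is accepted here (ε = 0 reduces LP to CN); a negative ε errors.
    """
    if epsilon < 0:
        raise ValueError("lp epsilon must be nonnegative")
    if x == y:
        raise ValueError("pair must consist of two distinct nodes")
    g._check_node(x)
    g._check_node(y)
    A = g.adjacency()
    walks2 = float(A[x - 1] @ A[:, y - 1])
    walks3 = float(A[x - 1] @ A @ A[:, y - 1])
    return walks2 + epsilon * walks3


_PAIR_FUNCS = {
    "cn": score_cn,
    "salton": score_salton,
    "ra": score_ra,
    "hpi": score_hpi,
    "hdi": score_hdi,
    "lhn": score_lhn,
    "lnbra": score_lnbra,
}


def score_pair(g: Graph, x: int, y: int, spec: IndexSpec) -> float:
    """Score one pair with the index named in ``spec``."""
    if spec.name == "lp":
        return score_lp(g, x, y, spec.lp_epsilon)
    return float(_PAIR_FUNCS[spec.name](g, x, y))


# -- all-pairs matrices ------------------------------------------------


def _safe_div(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    return np.divide(num, denom, out=np.zeros_like(num, dtype=float), where=denom > 0)


def score_matrix(g: Graph, spec: IndexSpec) -> ScoreMatrix:
    """All-pairs matrix of the chosen index (symmetric, zero diagonal)."""
    A = g.adjacency()
    k = A.sum(axis=0)
    cn = A @ A
    np.fill_diagonal(cn, 0.0)
    name = spec.name
    if name == "cn":
        S = cn
    elif name == "salton":
        S = _safe_div(cn, np.sqrt(np.outer(k, k)))
    elif name == "ra":
        inv_k = _safe_div(np.ones_like(k), k)
        S = (A * inv_k) @ A
    elif name == "hpi":
        S = _safe_div(cn, np.minimum.outer(k, k))
    elif name == "hdi":
        S = _safe_div(cn, np.maximum.outer(k, k))
    elif name == "lhn":
        S = _safe_div(cn, np.outer(k, k))
    elif name == "lp":
        A2 = A @ A
        S = A2 + spec.lp_epsilon * (A2 @ A)
    elif name == "lnbra":
        if g.n_edges == 0:
            S = np.zeros_like(A)
        else:
            eta = _lnbra_eta(g)
            n_tri = np.diag(A @ A @ A) / 2.0  # edges among Γ(z) = N_Δz
            n_pairs = k * (k - 1) / 2.0
            r = (n_tri + 1.0) / (n_pairs - n_tri + 1.0)
            w = _safe_div(np.log2(eta * r), k)  # combined log, see score_lnbra
            S = (A * w) @ A
    else:  # pragma: no cover - IndexSpec validates
        raise ValueError(f"unknown index {name!r}")
    return ScoreMatrix(S)
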