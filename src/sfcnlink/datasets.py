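"""Built-in fixtures and seeded synthetic graph generators.

The worked-example fixture ships the four printed pair vectors of the
10-node demonstration network (target pair (1, 3), C1 = LHN, C2 = RA)
as exact rationals, so the type-1/2/3 contributions 1/6, 1/5 and 1/15
are reproduced without floating error.  The toy graph is the 5-node
graph used across the module examples.  Random-graph generators
(Erdős–Rényi, Barabási–Albert, planted partition) wrap networkx and
are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np

from .graph import Graph
from .model import PairVectors

TOY_EDGES = ((1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (4, 5))


def toy_graph() -> Graph:
    """The 5-node example graph with edges 1-2, 1-3, 2-3, 2-4, 3-4, 4-5."""
    return Graph(5, TOY_EDGES)


@dataclass(frozen=True)
class Example1Fixture:
    """Printed pair vectors of the 10-node worked example.

    Target pair (1, 3); connection rows gamma_x/gamma_y and RA-score
    rows s_x/s_y as exact fractions, with positions 1 and 3 zeroed.
    """

    n_nodes: int
    x: int
    y: int
    c1_name: str
    c2_name: str
    gamma_x: tuple
    gamma_y: tuple
    s_x: tuple
    s_y: tuple

    def pair_vectors(self) -> PairVectors:
        def _obj(values):
            return np.array([Fraction(v) for v in values], dtype=object)

        return PairVectors(
            self.x,
            self.y,
            _obj(self.gamma_x),
            _obj(self.gamma_y),
            _obj(self.s_x),
            _obj(self.s_y),
        )


def example1_vectors() -> Example1Fixture:
    """The four printed vectors of the worked example, as exact rationals."""
    F = Fraction
    return Example1Fixture(
        n_nodes=10,
        x=1,
        y=3,
        c1_name="lhn",
        c2_name="ra",
        gamma_x=(0, 1, 0, 1, 0, 0, 0, 0, 0, 0),
        gamma_y=(0, 1, 0, 0, 1, 0, 0, 0, 0, 0),
        s_x=(0, 0, 0, 0, F(1, 5), 0, F(1, 5), F(1, 5), 0, F(1, 5)),
        s_y=(0, 0, 0, F(1, 6), 0, F(1, 6), 0, F(1, 6), F(1, 6), F(1, 6)),
    )


# -- synthetic graph generators ---------------------------------------


@dataclass(frozen=True)
class SyntheticGraphSpec:
    """Named random-graph model with its parameters and a seed."""

    model: str  # "erdos_renyi" | "barabasi_albert" | "planted_partition"
    n: int
    seed: int = 0
    p: float | None = None
    m: int | None = None
    communities: int | None = None
    p_in: float | None = None
    p_out: float | None = None


def from_networkx(G: nx.Graph) -> Graph:
    """Relabel an arbitrary networkx graph to contiguous 1-based ids."""
    nodes = sorted(G.nodes())
    index = {v: i + 1 for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in G.edges() if u != v]
    return Graph(len(nodes), edges, labels=[str(v) for v in nodes])


def erdos_renyi(n: int, p: float, seed: int = 0) -> Graph:
    """G(n, p) random graph."""
    if n < 1 or not 0 <= p <= 1:
        raise ValueError("need n >= 1 and 0 <= p <= 1")
    return from_networkx(nx.gnp_random_graph(n, p, seed=seed))


def gnm_random(n: int, m: int, seed: int = 0) -> Graph:
    """Uniform random graph with exactly n nodes and m edges."""
    if n < 1 or not 0 <= m <= n * (n - 1) // 2:
        raise ValueError("need n >= 1 and 0 <= m <= n(n-1)/2")
    return from_networkx(nx.gnm_random_graph(n, m, seed=seed))


def barabasi_albert(n: int, m: int, seed: int = 0) -> Graph:
    """Preferential-attachment graph: each new node brings m edges."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    return from_networkx(nx.barabasi_albert_graph(n, m, seed=seed))


def planted_partition(
    n: int, communities: int, p_in: float, p_out: float, seed: int = 0
) -> Graph:
    """Planted-partition graph: ``communities`` equal groups, edge
    probability p_in within a group and p_out across groups."""
    if communities < 1 or n % communities != 0:
        raise ValueError("n must be a positive multiple of communities")
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise ValueError("p_in and p_out must lie in [0,1]")
    G = nx.planted_partition_graph(communities, n // communities, p_in, p_out, seed=seed)
    return from_networkx(G)


def generate(spec: SyntheticGraphSpec) -> Graph:
    """Build the graph described by ``spec`` (deterministic per seed)."""
    if spec.model == "erdos_renyi":
        if spec.p is None:
            raise ValueError("erdos_renyi needs p")
        return erdos_renyi(spec.n, spec.p, spec.seed)
    if spec.model == "barabasi_albert":
        if spec.m is None:
            raise ValueError("barabasi_albert needs m")
        return barabasi_albert(spec.n, spec.m, spec.seed)
    if spec.model == "planted_partition":
        if spec.communities is None or spec.p_in is None or spec.p_out is None:
            raise ValueError("planted_partition needs communities, p_in, p_out")
        return planted_partition(spec.n, spec.communities, spec.p_in, spec.p_out, spec.seed)
    raise ValueError(f"unknown graph model {spec.model!r}")
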