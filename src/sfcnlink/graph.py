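"""Undirected simple-graph container, edge-list I/O and descriptive statistics.

The graph model is deliberately minimal: an undirected simple graph
(no self-loops, no parallel edges) over contiguous 1-based node ids,
with the original external labels preserved in a label map.  All
similarity indexes and the future-common-neighbor model operate on
this container; heavier graph algorithms (shortest paths, clustering,
assortativity) are delegated to networkx.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


def _canonical(x: int, y: int) -> Edge:
    return (x, y) if x < y else (y, x)


class Graph:
    """Undirected simple graph over node ids ``1..n_nodes``.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; ids are ``1..n_nodes``.
    edges : iterable of (int, int)
        Unordered node-id pairs.  Self-loops and endpoints outside
        ``1..n_nodes`` raise ``ValueError``; duplicates collapse.
    labels : sequence of str, optional
        External labels, position ``i`` labelling node ``i+1``.
        Defaults to the string form of the ids.
    """

    __slots__ = ("n_nodes", "edges", "labels", "_label_to_id", "_adj", "_A")

    def __init__(self, n_nodes: int, edges: Iterable[Edge], labels=None):
        n_nodes = int(n_nodes)
        if n_nodes < 1:
            raise ValueError("graph needs at least one node")
        canon: set[Edge] = set()
        for x, y in edges:
            x, y = int(x), int(y)
            if x == y:
                raise ValueError(f"self-loop at node {x}")
            if not (1 <= x <= n_nodes and 1 <= y <= n_nodes):
                raise ValueError(f"edge ({x},{y}) outside 1..{n_nodes}")
            canon.add(_canonical(x, y))
        self.n_nodes = n_nodes
        self.edges: frozenset[Edge] = frozenset(canon)
        if labels is None:
            labels = tuple(str(i) for i in range(1, n_nodes + 1))
        labels = tuple(str(l) for l in labels)
        if len(labels) != n_nodes:
            raise ValueError("labels length must equal n_nodes")
        if len(set(labels)) != n_nodes:
            raise ValueError("labels must be unique")
        self.labels = labels
        self._label_to_id = {lab: i + 1 for i, lab in enumerate(labels)}
        adj: dict[int, set[int]] = {i: set() for i in range(1, n_nodes + 1)}
        for x, y in self.edges:
            adj[x].add(y)
            adj[y].add(x)
        self._adj = {i: frozenset(s) for i, s in adj.items()}
        self._A: np.ndarray | None = None

    # -- basic queries -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def label_map(self) -> dict[str, int]:
        """External label -> internal 1-based id."""
        return dict(self._label_to_id)

    def node_label(self, x: int) -> str:
        self._check_node(x)
        return self.labels[x - 1]

    def node_id(self, label: str) -> int:
        return self._label_to_id[str(label)]

    def _check_node(self, x: int) -> None:
        if not (1 <= x <= self.n_nodes):
            raise ValueError(f"node id {x} outside 1..{self.n_nodes}")

    def neighbors(self, x: int) -> frozenset[int]:
        """Set Γ_x of nodes adjacent to ``x`` (never contains ``x``)."""
        self._check_node(x)
        return self._adj[x]

    def degree(self, x: int) -> int:
        return len(self.neighbors(x))

    def degrees(self) -> np.ndarray:
        """Degree sequence as an array indexed by node id − 1."""
        return np.array([len(self._adj[i]) for i in range(1, self.n_nodes + 1)])

    def has_edge(self, x: int, y: int) -> bool:
        return _canonical(int(x), int(y)) in self.edges

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (row ``i`` is node ``i+1``)."""
        if self._A is None:
            A = np.zeros((self.n_nodes, self.n_nodes))
            for x, y in self.edges:
                A[x - 1, y - 1] = 1.0
                A[y - 1, x - 1] = 1.0
            self._A = A
        return self._A

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(1, self.n_nodes + 1))
        G.add_edges_from(self.edges)
        return G

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and self.edges == other.edges
            and self.labels == other.labels
        )

    def __hash__(self) -> int:
        return hash((self.n_nodes, self.edges, self.labels))

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# -- edge-list I/O -----------------------------------------------------


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    elif hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def read_edge_list(source, delimiter: str | None = None) -> Graph:
    """Read a two-column edge list into a :class:`Graph`.

    Lines starting with ``#`` and blank lines are ignored.  Fields are
    split on ``delimiter`` (default: commas if the line contains one,
    else any whitespace); only the first two fields are used.  Labels
    are mapped to ids ``1..n`` in order of first appearance.  Duplicate
    edges and self-loops are dropped with a logged warning count.
    """
    labels: dict[str, int] = {}
    edge_ids: set[Edge] = set()
    n_self = n_dup = 0
    seen_any = False
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        seen_any = True
        if delimiter is None:
            fields = line.split(",") if "," in line else line.split()
        else:
            fields = line.split(delimiter)
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 fields, got {len(fields)}")
        a, b = fields[0], fields[1]
        for lab in (a, b):
            if lab not in labels:
                labels[lab] = len(labels) + 1
        i, j = labels[a], labels[b]
        if i == j:
            n_self += 1
            continue
        e = _canonical(i, j)
        if e in edge_ids:
            n_dup += 1
        else:
            edge_ids.add(e)
    if not seen_any:
        raise ValueError("empty edge list: no data lines found")
    if n_self or n_dup:
        logger.warning(
            "dropped %d self-loop(s) and %d duplicate edge(s) while reading", n_self, n_dup
        )
    ordered = sorted(labels, key=labels.get)
    return Graph(len(labels), edge_ids, labels=ordered)


def write_edge_list(g: Graph, target, delimiter: str = " ") -> None:
    """Write ``g`` as a two-column edge list of external labels."""

    def _write(fh: IO[str]) -> None:
        for x, y in sorted(g.edges):
            fh.write(f"{g.labels[x - 1]}{delimiter}{g.labels[y - 1]}\n")

    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


# -- descriptive statistics -------------------------------------------


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive network statistics.

    ``degree_heterogeneity`` is <k²>/<k>² (1 for regular graphs);
    ``clustering_coefficient`` is the mean local clustering with
    degree-0/1 nodes contributing 0; ``assortativity`` is the Pearson
    correlation of endpoint degrees over edges; the average shortest
    distance is taken over reachable distinct pairs only.
    """

    n_nodes: int
    n_links: int
    avg_shortest_distance: float
    avg_degree: float
    degree_heterogeneity: float
    clustering_coefficient: float
    assortativity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_nodes": self.n_nodes,
                    "n_links": self.n_links,
                    "avg_shortest_distance": self.avg_shortest_distance,
                    "avg_degree": self.avg_degree,
                    "degree_heterogeneity": self.degree_heterogeneity,
                    "clustering_coefficient": self.clustering_coefficient,
                    "assortativity": self.assortativity,
                }
            ]
        )


def network_stats(g: Graph) -> NetworkStats:
    """Compute :class:`NetworkStats` for ``g`` (requires ≥ 2 nodes)."""
    if g.n_nodes < 2:
        raise ValueError("network statistics need at least 2 nodes")
    n, m = g.n_nodes, g.n_edges
    avg_degree = 2.0 * m / n
    if m == 0:
        return NetworkStats(n, 0, math.nan, 0.0, math.nan, 0.0, math.nan)
    k = g.degrees().astype(float)
    heterogeneity = float(np.mean(k**2) / np.mean(k) ** 2)
    G = g.to_networkx()
    clustering = float(sum(nx.clustering(G).values()) / n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero degree variance -> nan
        try:
            assortativity = float(nx.degree_assortativity_coefficient(G))
        except (ZeroDivisionError, ValueError):
            assortativity = math.nan
    if not math.isfinite(assortativity):
        assortativity = math.nan
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        total += sum(dists.values())
        count += len(dists) - 1
    if count < n * (n - 1):
        logger.warning(
            "graph is disconnected; average distance taken over reachable pairs only"
        )
    avg_distance = total / count if count else math.nan
    return NetworkStats(n, m, avg_distance, avg_degree, heterogeneity, clustering, assortativity)


def nonexistent_pairs(g: Graph) -> Iterator[Edge]:
    """Yield every unordered node pair absent from ``g`` (the set U−E)."""
    for pair in itertools.combinations(range(1, g.n_nodes + 1), 2):
        if pair not in g.edges:
            yield pair
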