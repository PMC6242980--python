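"""Train/probe evaluation protocol for link prediction.

Observed edges are split at random into a training set E^T and a probe
set E^P; every score matrix is rebuilt on the training graph only.
AUC is the probability that a probe link outscores a nonexistent link
(pairs absent from the full graph), ties counted 0.5 — computed either
exactly from midranks or by seeded Monte-Carlo comparisons.  Precision
at L is the fraction of probe links among the top-L ranked non-training
pairs.  Replicated experiments, the alpha/beta grid sweep (with an
inner sub-split of the training set, so probe information never leaks
into parameter selection) and the training-ratio robustness sweep are
built on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph import Edge, Graph
from .indexes import IndexSpec, ScoreMatrix, score_matrix
from .model import SFCNConfig, future_contribution_matrix, sfcn_score_matrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)
DEFAULT_BETA_GRID = (0.0, 0.4, 0.8, 1.2, 1.6, 2.0)

MethodSpec = IndexSpec | SFCNConfig | Callable


@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint partition of observed edges into training and probe sets."""

    training_edges: frozenset[Edge]
    probe_edges: frozenset[Edge]
    ratio: float
    seed: int


@dataclass(frozen=True)
class AUCCounters:
    """Raw comparison counts behind a sampled AUC estimate."""

    n: int
    n_higher: int
    n_tied: int

    @property
    def auc(self) -> float:
        return (self.n_higher + 0.5 * self.n_tied) / self.n


def split_edges(g: Graph, ratio: float, seed: int) -> EdgeSplit:
    """Sample a probe set of ⌈(1−ratio)·|E|⌉ edges uniformly without replacement.

    |E^T| = round(ratio·|E|); deterministic given (g, ratio, seed).
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    m = g.n_edges
    if m < 2:
        raise ValueError("need at least 2 edges to split")
    n_train = int(round(ratio * m))
    n_probe = m - n_train
    if n_probe < 1 or n_train < 1:
        raise ValueError(f"ratio {ratio} leaves an empty training or probe set")
    edges_sorted = sorted(g.edges)
    rng = np.random.default_rng(seed)
    probe_idx = rng.choice(m, size=n_probe, replace=False)
    probe = frozenset(edges_sorted[i] for i in probe_idx)
    return EdgeSplit(frozenset(g.edges) - probe, probe, ratio, seed)


def training_graph(g: Graph, split: EdgeSplit) -> Graph:
    """Graph over the same nodes containing the training edges only."""
    return Graph(g.n_nodes, split.training_edges, labels=g.labels)


def _positive_negative_scores(
    scores: ScoreMatrix, split: EdgeSplit, g_full: Graph
) -> tuple[np.ndarray, np.ndarray]:
    if scores.n != g_full.n_nodes:
        raise ValueError("score matrix size does not match graph")
    probe = sorted(split.probe_edges)
    if not probe:
        raise ValueError("empty probe set")
    pos = np.array([scores.values[x - 1, y - 1] for x, y in probe])
    iu, ju = np.triu_indices(g_full.n_nodes, k=1)
    A_full = g_full.adjacency()
    missing = A_full[iu, ju] == 0
    neg = scores.values[iu, ju][missing]
    if neg.size == 0:
        raise ValueError("no nonexistent links: graph is complete")
    return pos, neg


def auc(
    scores: ScoreMatrix,
    split: EdgeSplit,
    g_full: Graph,
    mode: str = "exact",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> float:
    """AUC of probe links vs nonexistent links, ties counted 0.5.

    ``mode="exact"`` compares every probe/nonexistent pair via midranks;
    ``mode="sampled"`` draws ``n_samples`` seeded random comparisons.
    """
    pos, neg = _positive_negative_scores(scores, split, g_full)
    if mode == "exact":
        ranks = rankdata(np.concatenate([pos, neg]))
        n_pos, n_neg = pos.size, neg.size
        return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    if mode == "sampled":
        return sampled_auc_counters(scores, split, g_full, n_samples, seed).auc
    raise ValueError(f"unknown AUC mode {mode!r}")


def sampled_auc_counters(
    scores: ScoreMatrix,
    split: EdgeSplit,
    g_full: Graph,
    n_samples: int = 100_000,
    seed: int | None = None,
) -> AUCCounters:
    """Monte-Carlo AUC comparison counters (n, n', n'')."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    pos, neg = _positive_negative_scores(scores, split, g_full)
    rng = np.random.default_rng(seed)
    s1 = pos[rng.integers(0, pos.size, n_samples)]
    s2 = neg[rng.integers(0, neg.size, n_samples)]
    return AUCCounters(n_samples, int(np.sum(s1 > s2)), int(np.sum(s1 == s2)))


def precision_at_L(
    scores: ScoreMatrix, split: EdgeSplit, g_full: Graph, L: int
) -> float:
    """Fraction of probe links among the top-L ranked non-training pairs.

    Candidates are all pairs outside E^T; ties are broken by ascending
    lexicographic node-id pair so the ranking is deterministic.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    if scores.n != g_full.n_nodes:
        raise ValueError("score matrix size does not match graph")
    n = g_full.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    in_training = np.zeros((n, n), dtype=bool)
    for x, y in split.training_edges:
        in_training[x - 1, y - 1] = True
        in_training[y - 1, x - 1] = True
    keep = ~in_training[iu, ju]
    cand_i, cand_j = iu[keep], ju[keep]
    cand_scores = scores.values[cand_i, cand_j]
    if cand_scores.size < L:
        raise ValueError(f"only {cand_scores.size} candidate pairs but L={L}")
    order = np.lexsort((cand_j, cand_i, -cand_scores))[:L]
    probe = split.probe_edges
    hits = sum(1 for i, j in zip(cand_i[order], cand_j[order]) if (i + 1, j + 1) in probe)
    return hits / L


# -- replicated experiments --------------------------------------------


def method_label(method: MethodSpec) -> str:
    if isinstance(method, (IndexSpec, SFCNConfig)):
        return method.label
    return getattr(method, "label", getattr(method, "__name__", repr(method)))


def build_scores(g_train: Graph, method: MethodSpec, split: EdgeSplit | None = None) -> ScoreMatrix:
    """Score matrix on the training graph for an index, a model config,
    or an injected callable ``(g_train, split) -> ScoreMatrix``."""
    if isinstance(method, IndexSpec):
        return score_matrix(g_train, method)
    if isinstance(method, SFCNConfig):
        return sfcn_score_matrix(g_train, method)
    if callable(method):
        return method(g_train, split)
    raise TypeError(f"cannot build scores from {method!r}")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replicate and averaged AUC / precision@L for one method."""

    method: str
    ratio: float
    L: int
    base_seed: int
    auc_values: tuple[float, ...]
    precision_values: tuple[float, ...]

    @property
    def n_replicates(self) -> int:
        return len(self.auc_values)

    @property
    def seeds(self) -> tuple[int, ...]:
        return tuple(self.base_seed + r for r in range(self.n_replicates))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision_values))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-replicate table (method, ratio, replicate, auc, precision)."""
        return pd.DataFrame(
            {
                "method": self.method,
                "ratio": self.ratio,
                "replicate": np.arange(self.n_replicates),
                "seed": self.seeds,
                "auc": self.auc_values,
                "precision": self.precision_values,
            }
        )

    def summary_row(self) -> dict:
        return {
            "method": self.method,
            "ratio": self.ratio,
            "L": self.L,
            "n_replicates": self.n_replicates,
            "mean_auc": self.mean_auc,
            "mean_precision": self.mean_precision,
        }


def run_experiment(
    g: Graph,
    method: MethodSpec,
    ratio: float = 0.9,
    L: int = 100,
    n_replicates: int = 100,
    base_seed: int = 0,
    auc_mode: str = "exact",
    auc_samples: int = 100_000,
) -> ExperimentResult:
    """Replicated split → rebuild scores on E^T → AUC and precision@L.

    Replicate r uses split seed ``base_seed + r``; fully reproducible.
    """
    aucs, precisions = [], []
    for r in range(n_replicates):
        split = split_edges(g, ratio, base_seed + r)
        g_train = training_graph(g, split)
        scores = build_scores(g_train, method, split)
        aucs.append(
            auc(scores, split, g, mode=auc_mode, n_samples=auc_samples, seed=base_seed + r)
        )
        precisions.append(precision_at_L(scores, split, g, L))
    return ExperimentResult(
        method_label(method), ratio, L, base_seed, tuple(aucs), tuple(precisions)
    )


@dataclass(frozen=True)
class SweepResult:
    """Mean-AUC grid over (alpha, beta) with the maximising cell."""

    grid: pd.DataFrame  # index: alpha values, columns: beta values
    best_alpha: float
    best_beta: float
    c1: str
    c2: str
    outer_ratio: float
    inner_ratio: float
    n_replicates: int
    seed: int


def parameter_sweep(
    g: Graph,
    c1: IndexSpec,
    c2: IndexSpec,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    outer_ratio: float = 0.9,
    inner_ratio: float | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    strict_fcn: bool = False,
) -> SweepResult:
    """Learn (alpha, beta) on an inner sub-split of the training set.

    E is first split at ``outer_ratio``; within E^T only, replicated
    inner splits (E^T1 / E^P1) are scored from E^T1 for every grid
    combination, using U−E^T as the negative class.  Returns the grid
    of mean AUC and the maximising (alpha*, beta*), ties resolved to
    the first cell in row-major grid order.
    """
    alpha_grid = tuple(float(a) for a in alpha_grid)
    beta_grid = tuple(float(b) for b in beta_grid)
    if not alpha_grid or not beta_grid:
        raise ValueError("grids must be nonempty")
    if inner_ratio is None:
        inner_ratio = outer_ratio
    outer = split_edges(g, outer_ratio, seed)
    g_inner = training_graph(g, outer)  # the "observed" graph for the inner runs
    grid = np.zeros((len(alpha_grid), len(beta_grid)))
    for r in range(n_replicates):
        inner = split_edges(g_inner, inner_ratio, seed + 1 + r)
        g_t1 = training_graph(g_inner, inner)
        c1m = score_matrix(g_t1, c1)
        c2m = score_matrix(g_t1, c2)
        fm = future_contribution_matrix(g_t1, c2m, strict=strict_fcn)
        for i, a in enumerate(alpha_grid):
            for j, b in enumerate(beta_grid):
                combined = ScoreMatrix(a * c1m.values + b * fm.values)
                grid[i, j] += auc(combined, inner, g_inner, mode="exact")
    grid /= n_replicates
    best_flat = int(np.argmax(grid))
    bi, bj = divmod(best_flat, len(beta_grid))
    frame = pd.DataFrame(grid, index=list(alpha_grid), columns=list(beta_grid))
    frame.index.name = "alpha"
    frame.columns.name = "beta"
    return SweepResult(
        frame,
        alpha_grid[bi],
        beta_grid[bj],
        c1.label,
        c2.label,
        outer_ratio,
        inner_ratio,
        n_replicates,
        seed,
    )


def ratio_sweep(
    g: Graph,
    methods: Sequence[MethodSpec],
    ratios: Sequence[float],
    L: int = 100,
    n_replicates: int = 100,
    seed: int = 0,
    auc_mode: str = "exact",
) -> pd.DataFrame:
    """Mean AUC per (method, ratio): methods as rows, ratios as columns.

    All methods share the same splits at a given ratio (paired design).
    """
    ratios = tuple(float(r) for r in ratios)
    for r in ratios:
        if not 0 < r < 1:
            raise ValueError(f"ratio {r} outside (0,1)")
    table = {}
    for method in methods:
        row = {}
        for ratio in ratios:
            result = run_experiment(
                g,
                method,
                ratio=ratio,
                L=L,
                n_replicates=n_replicates,
                base_seed=seed,
                auc_mode=auc_mode,
            )
            row[ratio] = result.mean_auc
        table[method_label(method)] = row
    frame = pd.DataFrame.from_dict(table, orient="index")
    frame.index.name = "method"
    frame.columns.name = "ratio"
    return frame
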