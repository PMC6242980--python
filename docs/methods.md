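# Methods

## Model

For a target pair (x, y) in an undirected simple graph, four length-|V|
vectors are formed: the connection rows Γx (entries r_{x,i}) and Γy
(entries r_{i,y}), and the similarity rows S_x and S_y holding the
scores of a base index C2 between x (resp. y) and every node. Positions
x and y are forced to 0 in all four vectors, so the pair can never
contribute to its own score. The model score is

    s(x,y) = α·s_C1(x,y) + β·(Γx·S_yᵀ + S_x·Γyᵀ + S_x·S_yᵀ),

a weighted sum of a direct similarity term (any base index C1) and the
accumulated contributions of three classes of prospective common
neighbor: nodes already linked to x and C2-similar to y (the Γx·S_y
term), the mirror class linked to y and similar to x (S_x·Γy), and
nodes similar to both but linked to neither (S_x·S_y).

Two behaviours deserve explicit statement:

- **Literal accumulation (default).** The dot products are taken as
  written: a node that already is a common neighbor of (x, y) still
  contributes whichever products are nonzero, because its similarity
  entries are not zeroed. The classification report keeps the three
  node sets disjoint (type 3 is reported net of types 1 and 2), but the
  three contribution numbers are the raw dot products — one node may
  appear in more than one summand.
- **Strict mode** (`strict_fcn=True`) zeroes the C2 entries of current
  common neighbors before the products are taken, so only genuinely
  prospective neighbors contribute. The literal form is the default
  because it is the form the arithmetic of the shipped worked example
  satisfies; the worked example itself contains no current common
  neighbor with nonzero similarity entries, so it cannot discriminate
  between the two, and both are provided.

The rule orientation (type 1 = linked to **x**, contribution Γx·S_yᵀ)
follows the worked example's arithmetic, which uniquely pins it down:
node 4, linked to node 1, contributes s^RA_{4,3} = 1/6 through the
first product.

All-pairs scoring is three matrix products: with A the adjacency matrix
and S the C2 matrix (both symmetric, zero diagonal), the future term is
A·S + S·A + S·S, and the zero diagonals make the per-pair zeroing of
positions x, y automatic. Strict mode subtracts the terms routed
through current common neighbors using the elementwise product E = A∘S:
A·E + E·A + E·E. Cost is three dense n×n multiplications; for the
network sizes this package targets (≤ a few thousand nodes) this is
seconds.

## Base indexes

With Γ_z the neighbor set and k_z the degree:

| index  | score for (x, y) |
|--------|------------------|
| CN     | \|Γx ∩ Γy\| |
| Salton | \|Γx ∩ Γy\| / √(k_x k_y) |
| RA     | Σ_{z∈Γx∩Γy} 1/k_z |
| HPI    | \|Γx ∩ Γy\| / min(k_x, k_y) |
| HDI    | \|Γx ∩ Γy\| / max(k_x, k_y) |
| LHN    | \|Γx ∩ Γy\| / (k_x k_y) |
| LNBRA  | Σ_{z∈Γx∩Γy} (1/k_z)(log₂η + log₂R_z) |
| LP     | (A²)_{x,y} + ε·(A³)_{x,y} |

For LNBRA, η = |V|(|V|−1)/(2|E|) − 1 is the prior odds of a nonexistent
versus existing link in the scored graph (the training graph during
evaluation), and R_z = (N_Δz+1)/(N_∇z+1) compares the connected and
disconnected node pairs among Γ(z); the score can be negative. The two
base-2 logs are evaluated as the single log of the product η·R_z —
mathematically identical, but the combined form cancels exactly when
η·R_z = 1 instead of leaving ~1e−16 residue.

Degenerate denominators (an endpoint of degree 0 in Salton, HPI, HDI,
LHN) yield score 0 rather than an error: the numerator is necessarily 0
there, and total matrices keep the evaluation pipeline simple. LNBRA
returns 0 for a pair with no common neighbors without consulting η, so
an edgeless graph scores an all-zero matrix like every other index;
η ≤ 0 (a graph with no room for nonexistent links) errors whenever a
score actually needs it. The LP weight ε defaults to 0.001 and must be
positive in an `IndexSpec`; the scoring functions additionally accept
ε = 0, where LP reduces exactly to CN. Scores between already-connected
nodes are computed like any other pair; ranking for prediction later
restricts to non-training pairs.

## Evaluation protocol

`split_edges` partitions the observed edges into a training set E^T of
round(ratio·|E|) edges and a probe set E^P (uniform sampling without
replacement, `numpy.random.default_rng(seed)`); no connectivity of the
training graph is guaranteed. Every score matrix is rebuilt on the
training graph only — a test pins the contract that probe edges never
reach a scorer.

**AUC** compares probe links against nonexistent links U−E (pairs
absent from the *full* graph), counting ties 0.5. The exact mode
evaluates all |E^P|·|U−E| comparisons via midranks
(`scipy.stats.rankdata`), which is the analytic limit of the sampled
definition; a sampled mode draws n seeded comparisons and reports the
(n, n′, n″) counters. Exact mode is the default: it is deterministic,
invariant under strictly monotone score transforms, and removes the
unreported choice of n.

**Precision@L** ranks all pairs outside E^T (probe plus nonexistent) by
descending score, ties broken by ascending lexicographic node-id pair
for determinism, and reports the fraction of probe links in the top L
(default L = 100).

`run_experiment` repeats split → rebuild → measure over n replicates
(default 100) with split seeds base_seed, base_seed+1, …, so runs are
bit-reproducible. `parameter_sweep` learns (α, β) without touching the
probe set: the outer split at ratio 0.9 is held fixed, and replicated
inner splits of E^T (sub-training/sub-probe, inner ratio defaulting to
the outer ratio — the natural choice absent other guidance) score every
grid combination, with U−E^T as the negative class. The default grid is
α ∈ {0, 3, 6, 9, 12, 15} × β ∈ {0, 0.4, 0.8, 1.2, 1.6, 2}. Within the
β = 0 column all α > 0 cells coincide (exact AUC is scale-invariant)
and equal the pure-C1 evaluation; the (0, 0) cell scores everything 0
and lands at AUC 0.5 by the tie rule. Ties in the grid argmax resolve
to the first cell in row-major order. `ratio_sweep` reuses the same
split seeds for every method at a given ratio (a paired design), which
reduces between-method variance.

## Synthetic data

The generators wrap networkx with integer seeds (deterministic across
runs and platforms): Erdős–Rényi G(n, p) and G(n, m), Barabási–Albert
preferential attachment, and planted-partition graphs. The
planted-partition benchmark used by the tests and the acceptance script
— 150 nodes in 3 equal communities, p_in = 0.15, p_out = 0.01, training
ratio 0.9, 20 replicates — is a deliberately scaled-down stand-in for
full-scale evaluation on real networks (hundreds to thousands of nodes,
100 replicates): it produces the common-neighbor signal that
similarity-based predictors rely on, at a size where the whole pipeline
runs in seconds. What it emulates is community-driven link formation;
what it does not emulate is the heavy-tailed degree structure, high
clustering and degree-degree correlations of real biological and social
networks, so passing these tests demonstrates correctness of the
machinery and the expected qualitative ordering (the future-neighbor
model ≥ its base index; more training data helps), not the quantitative
accuracy figures reachable on real data. The full-scale pipeline is the
same code path via `sfcnlink evaluate` / `sfcnlink sweep` on any edge
list.

The worked-example fixture is shipped as the four printed pair vectors
(exact `fractions.Fraction` entries), not as a reconstructed graph: the
underlying 10-node topology is not uniquely recoverable from the
vectors alone, and the vectors are exactly what the contribution
arithmetic consumes. Rationals keep the three contributions 1/6, 1/5,
1/15 exact rather than floating-approximate.

## Numerical and design choices

- Node ids are contiguous and 1-based internally, matching the vector
  indexing convention above; external labels round-trip through the
  edge-list reader/writer (first-appearance order).
- Degree heterogeneity is ⟨k²⟩/⟨k⟩² (1 for regular graphs); average
  shortest distance on a disconnected graph averages over reachable
  pairs with a logged warning; local clustering of degree-0/1 nodes is
  0; assortativity of a degree-regular graph is reported as NaN (zero
  variance).
- Dense float64 matrices throughout; per-pair and matrix routes are
  held to entrywise agreement within 1e−10 by tests.
- Score ties in AUC use exact floating equality — ties in practice are
  structural zeros or identical rational scores, which compare exactly.

## Known limitations

- Dense matrices cap practical size around 10⁴ nodes on ordinary
  memory; a sparse backend would be the natural extension.
- No support for directed, weighted, bipartite or temporal graphs.
- The model is single-step: it scores links one evolution step ahead
  and does not iterate future-neighbor reasoning over longer horizons.
- Training-graph disconnection at low training ratios is tolerated, not
  repaired; indexes simply see fewer paths.
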