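"""Train/probe splitting, AUC, precision@L, experiments and sweeps."""

import numpy as np
import pytest

import sfcnlink as sl
from sfcnlink import (
    Graph,
    IndexSpec,
    ScoreMatrix,
    SFCNConfig,
    auc,
    parameter_sweep,
    planted_partition,
    precision_at_L,
    ratio_sweep,
    run_experiment,
    sampled_auc_counters,
    score_matrix,
    split_edges,
    training_graph,
)
from oracles import oracle_auc_exact, oracle_precision, random_graph

CN = IndexSpec("cn")


def perfect_oracle(split):
    """Injected scorer: 1 on probe edges, 0 elsewhere."""

    def scorer(g_train, s):
        n = g_train.n_nodes
        values = np.zeros((n, n))
        for x, y in split.probe_edges:
            values[x - 1, y - 1] = values[y - 1, x - 1] = 1.0
        return ScoreMatrix(values)

    scorer.label = "perfect"
    return scorer


class TestSplitEdges:
    def test_sizes(self, toy):
        s = split_edges(toy, 0.5, seed=0)
        assert len(s.training_edges) == 3 and len(s.probe_edges) == 3

    def test_partition_is_exact(self, rng):
        g = random_graph(rng)
        s = split_edges(g, 0.9, seed=3)
        assert s.training_edges | s.probe_edges == g.edges
        assert not (s.training_edges & s.probe_edges)
        assert len(s.training_edges) == round(0.9 * g.n_edges)

    def test_deterministic(self, toy):
        assert split_edges(toy, 0.5, 7) == split_edges(toy, 0.5, 7)
        assert split_edges(toy, 0.5, 7) != split_edges(toy, 0.5, 8)

    def test_bad_ratios_rejected(self, toy):
        for ratio in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                split_edges(toy, ratio, 0)
        with pytest.raises(ValueError, match="empty"):
            split_edges(toy, 0.999, 0)  # round(0.999*6)=6 -> empty probe

    def test_probe_sampling_is_uniform(self):
        """Each edge lands in the probe set with frequency ~ 1 - ratio.

        The per-edge binomial band is widened to 4 sigma because 100
        edges are checked simultaneously (Bonferroni); the average
        frequency over all edges is pinned much more tightly.
        """
        g = sl.gnm_random(40, 100, seed=5)
        counts = {e: 0 for e in g.edges}
        n_splits = 1000
        for s in range(n_splits):
            for e in split_edges(g, 0.9, seed=s).probe_edges:
                counts[e] += 1
        freqs = np.array(list(counts.values())) / n_splits
        sigma = np.sqrt(0.1 * 0.9 / n_splits)
        assert np.all(np.abs(freqs - 0.1) < 4 * sigma)
        assert np.mean(freqs) == pytest.approx(0.1)  # 10 of 100 per split

    def test_training_graph_contains_only_training_edges(self, rng):
        g = random_graph(rng)
        s = split_edges(g, 0.8, seed=1)
        tg = training_graph(g, s)
        assert tg.edges == s.training_edges
        assert tg.labels == g.labels


class TestAUC:
    def test_perfect_predictor_scores_one(self, toy):
        s = split_edges(toy, 0.5, seed=0)
        scores = perfect_oracle(s)(toy, s)
        assert auc(scores, s, toy) == 1.0

    def test_constant_scores_give_half(self, toy):
        s = split_edges(toy, 0.5, seed=0)
        scores = ScoreMatrix(np.ones((5, 5)))
        assert auc(scores, s, toy) == 0.5

    def test_exact_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            g = random_graph(rng, n_max=20)
            if g.n_edges < 4:
                continue
            s = split_edges(g, 0.8, seed=11)
            scores = score_matrix(training_graph(g, s), CN)
            assert auc(scores, s, g) == pytest.approx(
                oracle_auc_exact(scores, s, g), abs=1e-12
            )

    def test_sampled_agrees_with_exact(self, rng):
        g = random_graph(rng, n_max=25, p=0.25)
        s = split_edges(g, 0.8, seed=2)
        scores = score_matrix(training_graph(g, s), CN)
        exact = auc(scores, s, g)
        n = 100_000
        sampled = auc(scores, s, g, mode="sampled", n_samples=n, seed=5)
        assert abs(sampled - exact) < 3 * np.sqrt(0.25 / n)

    def test_sampled_counters_consistent(self, toy):
        s = split_edges(toy, 0.5, seed=0)
        scores = score_matrix(training_graph(toy, s), CN)
        c = sampled_auc_counters(scores, s, toy, n_samples=1000, seed=1)
        assert c.n_higher + c.n_tied <= c.n
        assert c.auc == (c.n_higher + 0.5 * c.n_tied) / c.n

    def test_monotone_transform_invariance(self, rng):
        g = random_graph(rng)
        s = split_edges(g, 0.8, seed=4)
        scores = score_matrix(training_graph(g, s), CN)
        base = auc(scores, s, g)
        transformed = ScoreMatrix(np.arctan(3.0 * scores.values + 7.0) - np.arctan(7.0))
        assert auc(transformed, s, g) == pytest.approx(base, abs=1e-12)

    def test_negated_scores_complement(self, rng):
        g = random_graph(rng)
        s = split_edges(g, 0.8, seed=4)
        n = g.n_nodes
        vals = np.random.default_rng(0).normal(size=(n, n))
        vals = vals + vals.T  # continuous: ties have probability ~0
        scores = ScoreMatrix(vals)
        neg = ScoreMatrix(-vals)
        assert auc(scores, s, g) + auc(neg, s, g) == pytest.approx(1.0)

    def test_complete_graph_rejected(self):
        g = Graph(3, [(1, 2), (2, 3), (1, 3)])
        s = split_edges(g, 0.67, seed=0)
        with pytest.raises(ValueError, match="complete"):
            auc(score_matrix(training_graph(g, s), CN), s, g)


class TestPrecision:
    def test_perfect_scores_top_ranked(self, rng):
        g = random_graph(rng, n_max=20)
        s = split_edges(g, 0.8, seed=3)
        scores = perfect_oracle(s)(g, s)
        m = len(s.probe_edges)
        L = m + 5
        assert precision_at_L(scores, s, g, L) == pytest.approx(m / L)

    def test_matches_sort_and_count_oracle(self, rng):
        g = random_graph(rng, n_max=30, p=0.25)
        s = split_edges(g, 0.8, seed=9)
        scores = score_matrix(training_graph(g, s), CN)
        assert precision_at_L(scores, s, g, 20) == oracle_precision(scores, s, g, 20)

    def test_all_zero_scores_deterministic(self, toy):
        s = split_edges(toy, 0.5, seed=0)
        zeros = ScoreMatrix(np.zeros((5, 5)))
        values = {precision_at_L(zeros, s, toy, 5) for _ in range(3)}
        assert len(values) == 1

    def test_too_large_L_rejected(self, toy):
        s = split_edges(toy, 0.5, seed=0)
        scores = ScoreMatrix(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="candidate"):
            precision_at_L(scores, s, toy, 100)


class TestRunExperiment:
    def test_perfect_oracle_reaches_auc_one(self, rng):
        g = random_graph(rng, n_max=20)

        def method(g_train, split):
            return perfect_oracle(split)(g_train, split)

        method.label = "perfect"
        result = run_experiment(g, method, ratio=0.8, L=3, n_replicates=3, base_seed=0)
        assert result.mean_auc == 1.0

    def test_single_replicate_equals_manual_composition(self, rng):
        g = random_graph(rng, n_max=25, p=0.3)
        result = run_experiment(g, CN, ratio=0.8, L=10, n_replicates=1, base_seed=42)
        s = split_edges(g, 0.8, seed=42)
        scores = score_matrix(training_graph(g, s), CN)
        assert result.auc_values[0] == auc(scores, s, g)
        assert result.precision_values[0] == precision_at_L(scores, s, g, 10)

    def test_scores_built_on_training_graph_only(self, rng):
        g = random_graph(rng)
        received = []

        def recorder(g_train, split):
            received.append((g_train.edges, split.training_edges))
            return score_matrix(g_train, CN)

        recorder.label = "recorder"
        run_experiment(g, recorder, ratio=0.8, L=2, n_replicates=3, base_seed=0)
        for edges, training in received:
            assert edges == training  # probe edges never reach the scorer

    def test_cn_beats_chance_on_community_structure(self):
        g = planted_partition(200, 4, 0.15, 0.01, seed=7)
        result = run_experiment(g, CN, ratio=0.9, L=20, n_replicates=20, base_seed=0)
        assert result.mean_auc > 0.5
        assert result.mean_auc == pytest.approx(np.mean(result.auc_values))

    def test_reproducible_end_to_end(self, rng):
        g = random_graph(rng)
        a = run_experiment(g, CN, ratio=0.8, L=3, n_replicates=4, base_seed=5)
        b = run_experiment(g, CN, ratio=0.8, L=3, n_replicates=4, base_seed=5)
        assert a == b

    def test_result_frame_shape(self, rng):
        g = random_graph(rng)
        result = run_experiment(g, CN, ratio=0.8, L=3, n_replicates=4, base_seed=5)
        frame = result.to_frame()
        assert list(frame.columns) == ["method", "ratio", "replicate", "seed", "auc", "precision"]
        assert len(frame) == 4
        assert np.all((frame["auc"] >= 0) & (frame["auc"] <= 1))


@pytest.fixture(scope="module")
def sweep_result():
    g = planted_partition(60, 3, 0.3, 0.05, seed=2)
    return parameter_sweep(g, CN, IndexSpec("ra"), n_replicates=3, seed=1, outer_ratio=0.9)


class TestParameterSweep:

    def test_default_grid_is_6x6(self, sweep_result):
        assert sweep_result.grid.shape == (6, 6)
        assert list(sweep_result.grid.index) == [0, 3, 6, 9, 12, 15]
        assert list(sweep_result.grid.columns) == [0.0, 0.4, 0.8, 1.2, 1.6, 2.0]

    def test_entries_are_probabilities(self, sweep_result):
        assert np.all((sweep_result.grid.values >= 0) & (sweep_result.grid.values <= 1))

    def test_beta_zero_column_constant_over_positive_alpha(self, sweep_result):
        """For beta=0 the score is alpha*C1: exact AUC is invariant to the
        positive scaling, so all alpha>0 cells agree (pure-C1 evaluation)."""
        col = sweep_result.grid[0.0]
        positive = col.loc[col.index > 0]
        assert positive.nunique() == 1

    def test_best_cell_maximises_grid(self, sweep_result):
        r = sweep_result
        assert r.grid.loc[r.best_alpha, r.best_beta] == r.grid.values.max()

    def test_empty_grid_rejected(self, rng):
        g = random_graph(rng)
        with pytest.raises(ValueError):
            parameter_sweep(g, CN, CN, alpha_grid=(), n_replicates=1)


class TestRatioSweep:
    def test_single_cell_reduces_to_run_experiment(self, rng):
        g = random_graph(rng, n_max=25, p=0.3)
        table = ratio_sweep(g, [CN], [0.8], L=5, n_replicates=3, seed=4)
        direct = run_experiment(g, CN, ratio=0.8, L=5, n_replicates=3, base_seed=4)
        assert table.loc["CN", 0.8] == pytest.approx(direct.mean_auc)

    def test_table_layout(self, rng):
        g = random_graph(rng, n_max=25, p=0.3)
        methods = [CN, SFCNConfig(CN, IndexSpec("ra"))]
        table = ratio_sweep(g, methods, [0.6, 0.8], L=5, n_replicates=2, seed=0)
        assert list(table.index) == ["CN", "SFCN-CN-RA"]
        assert list(table.columns) == [0.6, 0.8]

    def test_more_training_data_helps_cn(self):
        g = planted_partition(150, 3, 0.15, 0.01, seed=3)
        table = ratio_sweep(g, [CN], [0.45, 0.9], L=20, n_replicates=20, seed=0)
        assert table.loc["CN", 0.9] >= table.loc["CN", 0.45] - 0.02

    def test_bad_ratio_rejected(self, rng):
        g = random_graph(rng)
        with pytest.raises(ValueError):
            ratio_sweep(g, [CN], [1.2], n_replicates=1)
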