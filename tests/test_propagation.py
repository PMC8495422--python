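"""Random-walk propagation, polarity scoring, bootstrap, and aggregation."""

import numpy as np
import pytest
from scipy import sparse

import lexprop as lp


def _graph_from_dense(W, names=None):
    n = W.shape[0]
    names = names or [f"n{i}" for i in range(n)]
    g = lp.LexicalGraph(nodes=names, weights=sparse.csr_matrix(W),
                        config=lp.GraphConfig())
    return lp.to_transition_matrix(g)


class TestPropagate:
    def test_single_node_self_loop(self):
        P = _graph_from_dense(np.array([[1.0]]))
        d = lp.propagate(P, ["n0"])
        assert d.mass.tolist() == [1.0]

    def test_matches_direct_linear_solve(self):
        # 3-node chain; fixed point has closed form
        # p = (1-beta) * s (I - beta P)^-1.
        W = np.array([[0, 1.0, 0], [1.0, 0, 0.5], [0, 0.5, 0]])
        P = _graph_from_dense(W)
        beta = 0.9
        cfg = lp.WalkConfig(beta=beta, tol=1e-12, max_iter=10000)
        got = lp.propagate(P, ["n0"], cfg).mass
        s = np.array([1.0, 0, 0])
        expected = (1 - beta) * s @ np.linalg.inv(np.eye(3) - beta * P.P.toarray())
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_all_seeds_on_vertex_transitive_graph_uniform(self):
        # 4-cycle: every node equivalent -> uniform stationary mass.
        W = np.zeros((4, 4))
        for i in range(4):
            W[i, (i + 1) % 4] = W[i, (i - 1) % 4] = 1.0
        P = _graph_from_dense(W)
        d = lp.propagate(P, [f"n{i}" for i in range(4)])
        np.testing.assert_allclose(d.mass, 0.25, atol=1e-6)

    def test_nonconvergence_error_reports_residual(self, toy_graph):
        cfg = lp.WalkConfig(tol=1e-15, max_iter=3)
        with pytest.raises(RuntimeError, match="residual"):
            lp.propagate(toy_graph, [toy_graph.nodes[0]], cfg)

    def test_missing_seed_errors(self, toy_graph):
        with pytest.raises(ValueError, match="zzz"):
            lp.propagate(toy_graph, ["zzz"])


class TestMonteCarloPropagate:
    def test_two_node_cycle_reachability(self):
        W = np.array([[0, 1.0], [1.0, 0]])
        P = _graph_from_dense(W)
        cfg = lp.WalkConfig(mc_n_walks=50, mc_walk_length=30, rng_seed=0)
        d = lp.monte_carlo_propagate(P, ["n0"], cfg)
        assert d.mass.sum() == pytest.approx(1.0)
        assert (d.mass > 0).all()

    def test_same_seed_identical_output(self, toy_graph):
        cfg = lp.WalkConfig(mc_n_walks=20, mc_walk_length=50, rng_seed=9)
        d1 = lp.monte_carlo_propagate(toy_graph, [toy_graph.nodes[0]], cfg)
        d2 = lp.monte_carlo_propagate(toy_graph, [toy_graph.nodes[0]], cfg)
        np.testing.assert_array_equal(d1.mass, d2.mass)

    def test_converges_to_deterministic_fixed_point(self, toy_graph):
        # moderate sampling here; the full-scale agreement check lives in
        # the acceptance suite.
        seeds = [toy_graph.nodes[0], toy_graph.nodes[5]]
        cfg = lp.WalkConfig(mc_n_walks=2000, mc_walk_length=500, rng_seed=1)
        mc = lp.monte_carlo_propagate(toy_graph, seeds, cfg)
        ex = lp.propagate(toy_graph, seeds, cfg)
        tv = 0.5 * np.abs(mc.mass - ex.mass).sum()
        assert tv < 0.05


class TestPolarityScore:
    @pytest.mark.parametrize(
        "c,a,expected",
        [(0.64, 0.16, 0.8), (0.3, 0.3, 0.5), (0.2, 0.0, 1.0), (0.0, 0.7, 0.0)],
    )
    def test_examples(self, c, a, expected):
        assert lp.polarity_score(c, a) == pytest.approx(expected)

    def test_zero_total_is_neutral(self):
        assert lp.polarity_score(0.0, 0.0) == 0.5

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            lp.polarity_score(-0.1, 0.2)


class TestScoreDimension:
    def _seeds(self, high, low):
        return lp.SeedSet("CONC", high_pole=list(high), low_pole=list(low))

    def test_degenerate_bootstrap_equals_single_full_run(self, toy_graph):
        seeds = self._seeds(toy_graph.nodes[:2], toy_graph.nodes[2:4])
        cfg = lp.WalkConfig(n_subsets=1, subset_fraction=1.0, rng_seed=0)
        table = lp.score_dimension(toy_graph, seeds, cfg)
        c = lp.propagate(toy_graph, seeds.high_pole, cfg).mass
        a = lp.propagate(toy_graph, seeds.low_pole, cfg).mass
        expected = c / (c + a)
        got = np.array([table.scores[w] for w in toy_graph.nodes])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_scores_within_unit_interval(self, toy_graph):
        seeds = self._seeds(toy_graph.nodes[:3], toy_graph.nodes[3:6])
        table = lp.score_dimension(toy_graph, seeds, lp.WalkConfig(n_subsets=5))
        assert all(0.0 <= s <= 1.0 for s in table.scores.values())

    def test_two_cluster_graph_sides_score_correctly(self, two_cluster_graph):
        seeds = self._seeds(["h0", "h1"], ["l0", "l1"])
        table = lp.score_dimension(two_cluster_graph, seeds,
                                   lp.WalkConfig(n_subsets=1, subset_fraction=1.0))
        assert table.scores["h2"] > 0.5 and table.scores["h3"] > 0.5
        assert table.scores["l2"] < 0.5 and table.scores["l3"] < 0.5

    def test_pole_swap_antisymmetry(self, two_cluster_graph):
        seeds = self._seeds(["h0", "h1"], ["l0", "l1"])
        cfg = lp.WalkConfig(n_subsets=1, subset_fraction=1.0, tol=1e-10)
        t1 = lp.score_dimension(two_cluster_graph, seeds, cfg)
        t2 = lp.score_dimension(two_cluster_graph, seeds.swapped(), cfg)
        for w in t1.scores:
            assert t1.scores[w] + t2.scores[w] == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_node_relabeling(self, two_cluster_graph):
        # permute node order; scores per (renamed) word must be unchanged
        perm = [5, 2, 7, 0, 3, 6, 1, 4]
        P = two_cluster_graph.P.toarray()[np.ix_(perm, perm)]
        nodes = [two_cluster_graph.nodes[i] for i in perm]
        g = lp.LexicalGraph(nodes=nodes, weights=sparse.csr_matrix(P),
                            config=lp.GraphConfig())
        P2 = lp.to_transition_matrix(g)
        seeds = self._seeds(["h0", "h1"], ["l0", "l1"])
        cfg = lp.WalkConfig(n_subsets=1, subset_fraction=1.0, tol=1e-12)
        t1 = lp.score_dimension(two_cluster_graph, seeds, cfg)
        t2 = lp.score_dimension(P2, seeds, cfg)
        for w in t1.scores:
            assert t1.scores[w] == pytest.approx(t2.scores[w], abs=1e-9)

    def test_empty_pole_after_intersection_names_missing(self, toy_graph):
        seeds = self._seeds(["nope1", "nope2"], toy_graph.nodes[:2])
        with pytest.raises(ValueError, match="nope1"):
            lp.score_dimension(toy_graph, seeds)


class TestAggregation:
    def _table(self, scores, label="g", dim="CONC"):
        return lp.WordScoreTable(dimension=dim, label=label, scores=scores)

    def test_corpus_score_examples(self):
        t = self._table({"a": 0.2, "b": 0.4, "c": 0.9})
        assert lp.corpus_score(t, {"a", "b", "c"}) == pytest.approx(0.5)
        t2 = self._table({"a": 0.7, "b": 0.7})
        assert lp.corpus_score(t2, {"a", "b"}) == pytest.approx(0.7)

    def test_corpus_score_matches_independent_mean(self):
        rng = np.random.default_rng(0)
        scores = {f"w{i}": float(s) for i, s in enumerate(rng.random(100))}
        t = self._table(scores)
        got = lp.corpus_score(t, set(scores))
        assert got == pytest.approx(sum(scores.values()) / 100)
        lo, hi = min(scores.values()), max(scores.values())
        assert lo <= got <= hi

    def test_corpus_score_reports_missing(self):
        t = self._table({"a": 0.5})
        score, missing = lp.corpus_score(t, {"a", "b", "c"}, return_missing=True)
        assert score == 0.5 and missing == 2

    def test_corpus_score_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            lp.corpus_score(self._table({"a": 0.5}), {"x"})

    def test_word_mean_across_groups(self):
        tables = [
            self._table({"egg": s}, label=f"g{i}") for i, s in enumerate([0.4, 0.4, 0.4])
        ]
        assert lp.word_mean_across_groups(tables, "egg") == pytest.approx(0.4)

    def test_word_mean_missing_group_errors(self):
        tables = [self._table({"egg": 0.5}, "g1"), self._table({"ham": 0.5}, "g2")]
        with pytest.raises(ValueError, match="g2"):
            lp.word_mean_across_groups(tables, "egg")

    def test_score_table_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            self._table({"a": 1.5})

    def test_score_table_tsv_round_trip(self, tmp_path):
        t = self._table({"a": 0.25, "b": 0.75}, label="G1", dim="IMAG")
        p = tmp_path / "t.tsv"
        t.to_tsv(p, header_comment="config=abc")
        back = lp.WordScoreTable.from_tsv(p)
        assert back.dimension == "IMAG" and back.label == "G1"
        assert back.scores == pytest.approx(t.scores)
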