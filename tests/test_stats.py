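"""Comparison statistics: correlations, distances, clustering, regression,
and the static mean-of-norms baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lexprop as lp


def _brute_spearman(x, y):
    """Independent rank-formula oracle with average ranks."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1, 2, 3, 4, 5]
        assert lp.spearman(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert lp.spearman(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, _ = lp.spearman(x, y)
        assert rho == pytest.approx(_brute_spearman(x, y))
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.random(15)
            b = rng.integers(0, 5, 15).astype(float)  # ties included
            assert lp.spearman(a, b)[0] == pytest.approx(_brute_spearman(a, b), abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            lp.spearman([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=15, unique=True))
    def test_invariant_under_monotone_transform(self, x):
        rng = np.random.default_rng(0)
        y = list(rng.random(len(x)))
        if len(set(y)) < 2:
            return
        base, _ = lp.spearman(x, y)
        fx = [np.exp(v / 50.0) for v in x]  # strictly increasing transform
        gy = [3 * v + 1 for v in y]
        if len(set(fx)) < len(fx):  # exp collapsed near-equal floats: ranks changed
            return
        assert lp.spearman(fx, gy)[0] == pytest.approx(base, abs=1e-12)


class TestGroupDistances:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=list(lp.DIMENSIONS))

    def test_identical_vectors_zero(self):
        df = self._frame([[0.5] * 5, [0.5] * 5])
        d = lp.group_distances(df)
        assert d.euclidean.iloc[0, 1] == 0.0 and d.manhattan.iloc[0, 1] == 0.0

    def test_closed_form_345(self):
        df = self._frame([[0, 0, 0, 0, 0], [3, 4, 0, 0, 0]])
        d = lp.group_distances(df)
        assert d.euclidean.iloc[0, 1] == pytest.approx(5.0)
        assert d.manhattan.iloc[0, 1] == pytest.approx(7.0)

    def test_matches_direct_loop_and_metric_axioms(self):
        rng = np.random.default_rng(3)
        X = rng.random((5, 5))
        df = self._frame(X.tolist())
        d = lp.group_distances(df)
        for i in range(5):
            assert d.euclidean.iloc[i, i] == 0
            for j in range(5):
                eu = np.sqrt(((X[i] - X[j]) ** 2).sum())
                ma = np.abs(X[i] - X[j]).sum()
                assert d.euclidean.iloc[i, j] == pytest.approx(eu)
                assert d.manhattan.iloc[i, j] == pytest.approx(ma)
                for k in range(5):
                    assert d.euclidean.iloc[i, j] <= d.euclidean.iloc[i, k] + d.euclidean.iloc[k, j] + 1e-12
                    assert d.manhattan.iloc[i, j] <= d.manhattan.iloc[i, k] + d.manhattan.iloc[k, j] + 1e-12

    def test_missing_dimension_errors(self):
        df = self._frame([[0.1] * 5, [0.2] * 5])
        df.iloc[0, 2] = np.nan
        with pytest.raises(ValueError, match="g0"):
            lp.group_distances(df)


class TestDimensionCorrelations:
    def test_self_and_identical_columns(self):
        rng = np.random.default_rng(1)
        v = rng.random(30)
        df = pd.DataFrame({"A": v, "B": v, "C": rng.random(30)})
        corr, pval = lp.dimension_correlations(df)
        assert corr.loc["A", "A"] == 1.0
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_recovers_planted_correlation(self):
        rng = np.random.default_rng(4)
        n = 500
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=n)
        df = pd.DataFrame({"X": x, "Y": y})
        corr, _ = lp.dimension_correlations(df, method="pearson")
        assert corr.loc["X", "Y"] == pytest.approx(0.8, abs=0.1)

    def test_too_few_words_errors(self):
        with pytest.raises(ValueError):
            lp.dimension_correlations(pd.DataFrame({"A": [1, 2], "B": [2, 1]}))


class TestClusterDimensions:
    def test_identical_dimensions_merge_first_at_zero(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.2], [0.1, 0.2, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dendro = lp.cluster_dimensions(corr)
        merges = dendro.merge_list()
        assert merges[0]["members"] == ["A", "B"]
        assert merges[0]["height"] == pytest.approx(0.0)

    def test_merge_order_matches_manual_agglomeration(self):
        # complete linkage on d = 1 - r, stepped through by hand:
        # d(A,B)=0.1 merges first; then d({A,B},C)=max(0.5,0.6)=0.6 vs
        # d(C,D)=0.3 -> C,D merge; final height max over cross pairs = 0.9.
        r = np.array([
            [1.0, 0.9, 0.5, 0.2],
            [0.9, 1.0, 0.4, 0.1],
            [0.5, 0.4, 1.0, 0.7],
            [0.2, 0.1, 0.7, 1.0],
        ])
        corr = pd.DataFrame(r, index=list("ABCD"), columns=list("ABCD"))
        merges = lp.cluster_dimensions(corr).merge_list()
        assert merges[0]["members"] == ["A", "B"]
        assert merges[0]["height"] == pytest.approx(0.1)
        assert merges[1]["members"] == ["C", "D"]
        assert merges[1]["height"] == pytest.approx(0.3)
        assert merges[2]["members"] == ["A", "B", "C", "D"]
        assert merges[2]["height"] == pytest.approx(0.9)

    def test_heights_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(-1, 1, (5, 5))
        r = np.corrcoef(A)
        corr = pd.DataFrame(r, index=list(lp.DIMENSIONS), columns=list(lp.DIMENSIONS))
        dendro = lp.cluster_dimensions(corr)
        heights = [m["height"] for m in dendro.merge_list()]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        assert all(0.0 <= h <= 2.0 for h in heights)

    def test_newick_leaves_are_dimension_labels(self):
        rng = np.random.default_rng(7)
        r = np.corrcoef(rng.uniform(-1, 1, (5, 8)))
        corr = pd.DataFrame(r, index=list(lp.DIMENSIONS), columns=list(lp.DIMENSIONS))
        nwk = lp.cluster_dimensions(corr).to_newick()
        for dim in lp.DIMENSIONS:
            assert dim in nwk
        assert nwk.endswith(";")

    def test_heatmap_png_written(self, tmp_path):
        pytest.importorskip("matplotlib")
        rng = np.random.default_rng(8)
        r = np.corrcoef(rng.uniform(-1, 1, (5, 8)))
        corr = pd.DataFrame(r, index=list(lp.DIMENSIONS), columns=list(lp.DIMENSIONS))
        out = tmp_path / "heat.png"
        lp.stats.plot_correlation_heatmap(corr, str(out))
        assert out.stat().st_size > 0

    def test_asymmetric_input_errors(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            lp.cluster_dimensions(bad)


class TestBayesianRegression:
    def test_noiseless_slope_recovered(self):
        x = np.linspace(0, 1, 50)
        X = pd.DataFrame({"x": x})
        y = pd.Series(2.0 * x, name="y")
        summary = lp.bayesian_regression(X, y)
        slope = summary.coefficient("x")
        assert slope.mean == pytest.approx(2.0, abs=0.01)
        assert slope.ci_low <= slope.mean <= slope.ci_high

    def test_gibbs_agrees_with_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.random(200)
        y = 0.8 * x + rng.normal(0, 0.1, 200)
        X = pd.DataFrame({"x": x})
        ys = pd.Series(y, name="y")
        conj = lp.bayesian_regression(X, ys).coefficient("x")
        gibbs = lp.bayesian_regression(X, ys, method="gibbs", n_samples=8000,
                                       rng_seed=1).coefficient("x")
        assert gibbs.mean == pytest.approx(conj.mean, abs=0.02)
        assert gibbs.ci_low == pytest.approx(conj.ci_low, abs=0.03)
        assert gibbs.ci_high == pytest.approx(conj.ci_high, abs=0.03)

    def test_singular_design_errors(self):
        x = np.ones(20)
        X = pd.DataFrame({"x": x})  # collinear with intercept
        y = pd.Series(np.arange(20.0))
        with pytest.raises(ValueError, match="singular"):
            lp.bayesian_regression(X, y)

    def test_too_few_observations_errors(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            lp.bayesian_regression(X, pd.Series([1.0, 2.0]))

    def test_regress_levels_on_word_tables(self):
        rng = np.random.default_rng(9)
        words = [f"w{i}" for i in range(50)]
        lower = lp.WordScoreTable("CONC", "A1", dict(zip(words, rng.random(50))))
        noise = rng.normal(0, 0.02, 50)
        hi_scores = np.clip(np.array([lower.scores[w] for w in words]) * 0.8 + 0.1 + noise, 0, 1)
        higher = lp.WordScoreTable("CONC", "A2", dict(zip(words, hi_scores)))
        summary = lp.regress_levels([lower], higher)
        coef = summary.coefficient("A1")
        assert coef.mean == pytest.approx(0.8, abs=0.1)
        assert summary.n_obs == 50


class TestStaticBaseline:
    def test_uniform_ratings_give_that_rating(self, conc_norms):
        sc = lp.build_subcorpus(["apple table apple"], "x")
        norms = lp.NormsTable("CONC", {"apple": 3.0, "table": 3.0}, 1, 5)
        for fw in (False, True):
            res = lp.static_lpp_score(sc, norms, frequency_weighted=fw)
            assert res.score == pytest.approx(3.0)

    def test_weighted_vs_unweighted_arithmetic(self):
        sc = lp.SubCorpus("x", [["a"] * 3 + ["b"]])
        norms = lp.NormsTable("CONC", {"a": 5.0, "b": 1.0}, 1, 5)
        assert lp.static_lpp_score(sc, norms).score == pytest.approx(3.0)
        assert lp.static_lpp_score(sc, norms, frequency_weighted=True).score == pytest.approx(4.0)

    def test_matches_spreadsheet_recomputation(self, conc_norms):
        docs = ["the apple fell from the tree", "hope is a thing", "justice and truth",
                "a dog and a cat in the house"]
        sc = lp.build_subcorpus(docs, "fx")
        res = lp.static_lpp_score(sc, conc_norms, content_only=True)
        covered = sorted(
            w for w in sc.counts
            if w in conc_norms.entries and w not in lp.corpus.FUNCTION_WORDS
        )
        expected = np.mean([conc_norms.entries[w] for w in covered])
        assert res.score == pytest.approx(float(expected))
        assert res.n_covered == len(covered)
        assert 0 < res.coverage <= 1

    def test_unweighted_frequency_invariance_contrast(self):
        sc1 = lp.SubCorpus("x", [["a", "b"]])
        sc2 = lp.SubCorpus("x", [["a", "b"], ["a", "a", "a"]])
        norms = lp.NormsTable("CONC", {"a": 5.0, "b": 1.0}, 1, 5)
        assert (lp.static_lpp_score(sc1, norms).score
                == lp.static_lpp_score(sc2, norms).score)
        assert (lp.static_lpp_score(sc1, norms, frequency_weighted=True).score
                != lp.static_lpp_score(sc2, norms, frequency_weighted=True).score)

    def test_no_coverage_errors(self):
        sc = lp.SubCorpus("x", [["zzz"]])
        norms = lp.NormsTable("CONC", {"a": 3.0}, 1, 5)
        with pytest.raises(ValueError):
            lp.static_lpp_score(sc, norms)
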