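import numpy as np
import pandas as pd
import pytest

from dispmix.io_geno import SnpMeta
from dispmix.migadmi_model import (
    AdmixtureEvent,
    AdmixtureGraph,
    BalanceMatrix,
    FitConfig,
    Window,
    build_windows,
    compare_hypotheses,
    fit_windows,
    objective,
    parse_hypothesis,
    rms_distance,
    variance_decomposition,
)
from dispmix.simulate import simulate_admixture, two_source_admixture_design


def _meta(positions, chrom="1"):
    return SnpMeta(
        [f"s{i}" for i in range(len(positions))],
        np.array([chrom] * len(positions), dtype=object),
        np.array(positions),
    )


class TestBuildWindows:
    def test_enumeration_over_five_megabases(self):
        # SNPs spanning [0, 5e6): dense enough that no window is dropped
        pos = np.append(np.arange(1, 5_000_000, 100_000), 4_999_999)
        wins = build_windows(_meta(pos), 3_000_000, 1_000_000, min_snps=10)
        assert [(w.start, w.end) for w in wins] == [
            (0, 3_000_000),
            (1_000_000, 4_000_000),
            (2_000_000, 5_000_000),
        ]

    def test_sparse_window_dropped(self):
        # nine SNPs only in [0, 3e6) -> below the 10-SNP floor
        pos = np.linspace(1, 2_999_999, 9, dtype=int)
        wins = build_windows(_meta(pos), 3_000_000, 1_000_000, min_snps=10)
        assert wins == []
        wins = build_windows(_meta(pos), 3_000_000, 1_000_000, min_snps=9)
        assert len(wins) == 1 and wins[0].n_snps == 9

    def test_step_equals_window_tiles_without_overlap(self):
        pos = np.append(np.arange(1, 6_000_000, 50_000), 5_999_999)
        wins = build_windows(_meta(pos), 3_000_000, 3_000_000, min_snps=1)
        assert [(w.start, w.end) for w in wins] == [(0, 3_000_000), (3_000_000, 6_000_000)]
        assert not set(wins[0].snp_index) & set(wins[1].snp_index)

    def test_empty_meta(self):
        assert build_windows(SnpMeta([], np.array([], dtype=object), np.array([], dtype=int))) == []


class TestRmsDistance:
    def test_identical_rows_zero(self):
        X = np.ones((2, 4))
        assert rms_distance(X, 0, 1, Window("1", 0, 10, np.arange(4))) == 0.0

    def test_closed_form(self):
        X = np.array([[3.0, 4.0], [0.0, 0.0]])
        d = rms_distance(X, 0, 1, Window("1", 0, 10, np.array([0, 1])))
        assert abs(d - np.sqrt(12.5)) < 1e-12

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((3, 50))
        win = Window("1", 0, 1, np.arange(17, 41))
        naive = np.sqrt(sum((X[0, i] - X[2, i]) ** 2 for i in win.snp_index) / win.n_snps)
        assert abs(rms_distance(X, 0, 2, win) - naive) < 1e-12

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="empty"):
            rms_distance(np.ones((2, 3)), 0, 1, Window("1", 0, 1, np.array([], dtype=int)))


class TestGraphCovariance:
    def test_star_tree_distance_is_branch_sum(self):
        g = AdmixtureGraph("(a:1.5,b:0.7);")
        V, D = g.covariance(np.array([1.5, 0.7]))
        assert abs(D[0, 1] - 2.2) < 1e-12
        assert V[0, 1] == 0.0

    def test_difference_variance_definition(self):
        g = AdmixtureGraph("(a:1.0,b:1.0);")
        V, D = g.covariance(np.array([1.0, 1.0]))
        # V diag 1, off-diagonal 0 -> D = 2; direct arithmetic
        assert D[0, 1] == V[0, 0] + V[1, 1] - 2 * V[0, 1]

    def test_degenerate_mixture_duplicates_source(self):
        g = AdmixtureGraph("(a:1.0,b:1.0);", [AdmixtureEvent("y", ["a", "b"])])
        # w=(1,0), alpha=1, t_y=0
        V, D = g.covariance(np.array([1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0]))
        ia, iy = g.pop_ids.index("a"), g.pop_ids.index("y")
        np.testing.assert_allclose(V[iy], V[ia], atol=1e-12)
        assert D[ia, iy] == 0.0

    def test_linearity_in_variance_parameters(self):
        graph, truth = two_source_admixture_design()
        V1, D1 = graph.covariance(truth)
        scaled = truth.copy()
        nb = graph.n_branches
        scaled[:nb] *= 2.5
        names = graph.param_names()
        scaled[names.index("y.t_own")] *= 2.5
        V2, D2 = graph.covariance(scaled)
        np.testing.assert_allclose(V2, 2.5 * V1, rtol=1e-10)
        np.testing.assert_allclose(D2, 2.5 * D1, rtol=1e-10, atol=1e-12)

    def test_psd_by_construction(self):
        graph, truth = two_source_admixture_design()
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = truth.copy()
            p[: graph.n_branches] = rng.exponential(1.0, graph.n_branches)
            names = graph.param_names()
            w1 = rng.uniform(0, 1)
            p[names.index("y.w[s1]")] = w1
            p[names.index("y.w[s2]")] = 1 - w1
            p[names.index("y.t_own")] = rng.exponential(0.2)
            p[names.index("y.alpha[s1]")] = rng.uniform()
            p[names.index("y.alpha[s2]")] = rng.uniform()
            V, _ = graph.covariance(p)
            assert np.linalg.eigvalsh(V).min() >= -1e-10

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle|not defined"):
            AdmixtureGraph("(a:1,b:1);", [AdmixtureEvent("y", ["a", "z"])])
        with pytest.raises(ValueError, match="own source"):
            AdmixtureEvent("y", ["y", "a"])


class TestObjective:
    def test_lambda_one_removes_penalty(self):
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=60, seed=2)
        win = build_windows(meta, min_snps=1)[0]
        f1 = objective(truth, X, win, graph, lam=1.0)
        f9 = objective(truth, X, win, graph, lam=0.9)
        penalty = (0.9 - 1.0) * (np.log(0.7) + np.log(0.3))
        assert abs((f9 - f1) - penalty) < 1e-12

    def test_two_population_closed_form(self):
        g = AdmixtureGraph("(a:0.5,b:0.5);")
        X = BalanceMatrix(["a", "b"], ["s0"], np.array([[1.0], [0.0]]))
        win = Window("1", 0, 10, np.array([0]))
        # d_w = 1, choose branches so D = 1 = d_w^2 -> logpdf = -.5 log(2 pi) - .5
        val = objective(np.array([0.5, 0.5]), X, win, g, lam=1.0)
        assert abs(val - (-0.5 * np.log(2 * np.pi) - 0.5)) < 1e-12

    def test_single_snp_window_matches_per_snp_likelihood(self):
        # with one SNP per window the RMS distance is |x_j - x_k|, so the
        # windowed objective must equal the per-SNP pairwise Gaussian
        # log-likelihood with unit SNP scale
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=12, seed=9)
        _, D = graph.covariance(truth)
        gidx = {p: graph.pop_ids.index(p) for p in X.pop_ids}
        P = len(X.pop_ids)
        for i in range(12):
            win = Window("1", 0, 1, np.array([i]))
            windowed = objective(truth, X, win, graph, lam=1.0)
            persnp = 0.0
            for j in range(P - 1):
                for k in range(j + 1, P):
                    diff = X.X[j, i] - X.X[k, i]
                    djk = D[gidx[X.pop_ids[j]], gidx[X.pop_ids[k]]]
                    persnp += -0.5 * np.log(2 * np.pi * djk) - diff**2 / (2 * djk)
            assert abs(windowed - persnp) < 1e-10

    def test_zero_variance_with_positive_distance_rejected(self):
        g = AdmixtureGraph("(a:0.5,b:0.5);")
        X = BalanceMatrix(["a", "b"], ["s0"], np.array([[1.0], [0.0]]))
        win = Window("1", 0, 10, np.array([0]))
        assert objective(np.array([0.0, 0.0]), X, win, g, lam=1.0) == -np.inf

    def test_per_pair_optimum_at_moment_match(self):
        # concavity in each D_jk: the per-pair term peaks at D_jk = d_w^2
        d = 1.3
        def term(D):
            return -0.5 * np.log(2 * np.pi * D) - d * d / (2 * D)
        opt = term(d * d)
        for D in (0.5 * d * d, 0.9 * d * d, 1.1 * d * d, 3 * d * d):
            assert term(D) < opt


class TestDecomposition:
    def test_symmetric_split(self):
        g = AdmixtureGraph("(a:1.0,b:1.0);", [AdmixtureEvent("y", ["a", "b"])])
        # equal independent sources, alpha=1, t_y=0
        d = g.decompose(np.array([1.0, 1.0, 0.5, 0.5, 0.0, 1.0, 1.0]))
        assert abs(d["y"]["a"] - 0.5) < 1e-12
        assert abs(d["y"]["b"] - 0.5) < 1e-12
        assert d["y"]["__own__"] == 0.0

    def test_own_variance_half(self):
        g = AdmixtureGraph("(a:1.0,b:1.0);", [AdmixtureEvent("y", ["a", "b"])])
        # w=(1,0), t_y equals source-1 variance -> (1/2, 0, 1/2)
        d = g.decompose(np.array([1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 1.0]))
        assert abs(d["y"]["a"] - 0.5) < 1e-12
        assert d["y"]["b"] == 0.0
        assert abs(d["y"]["__own__"] - 0.5) < 1e-12

    def test_shares_sum_to_one_on_random_params(self):
        graph, truth = two_source_admixture_design()
        names = graph.param_names()
        rng = np.random.default_rng(2)
        for _ in range(25):
            p = truth.copy()
            p[: graph.n_branches] = rng.exponential(0.8, graph.n_branches)
            w1 = rng.uniform(0.01, 0.99)
            p[names.index("y.w[s1]")] = w1
            p[names.index("y.w[s2]")] = 1 - w1
            p[names.index("y.t_own")] = rng.exponential(0.3)
            p[names.index("y.alpha[s1]")] = rng.uniform()
            p[names.index("y.alpha[s2]")] = rng.uniform()
            shares = graph.decompose(p)["y"]
            vals = np.array(list(shares.values()))
            assert (vals >= -1e-12).all() and (vals <= 1 + 1e-12).all()
            assert abs(vals.sum() - 1.0) < 1e-6


class TestFitWindows:
    def test_weight_recovery_two_sources(self):
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=500, seed=5)
        windows = build_windows(meta)
        fits = fit_windows(X, windows, graph, FitConfig(seed=2))
        iw = graph.param_names().index("y.w[s1]")
        med = float(np.median([f.params[iw] for f in fits]))
        assert 0.6 <= med <= 0.8

    def test_three_source_degenerate_weight_concentrates(self):
        newick = "((s1:0.3,r1:0.3):1.5,(s2:0.3,r2:0.3):1.5,(s3:0.3,r3:0.3):1.5);"
        graph = AdmixtureGraph(newick, [AdmixtureEvent("y", ["s1", "s2", "s3"])])
        names = graph.param_names()
        truth = graph.default_params().copy()
        truth[names.index("y.w[s1]")] = 1.0
        truth[names.index("y.w[s2]")] = 0.0
        truth[names.index("y.w[s3]")] = 0.0
        truth[names.index("y.t_own")] = 0.1
        for s in ("s1", "s2", "s3"):
            truth[names.index(f"y.alpha[{s}]")] = 1.0
        X, meta, _ = simulate_admixture(graph, truth, n_snps=200, seed=6)
        windows = build_windows(meta, min_snps=5)[:4]
        fits = fit_windows(X, windows, graph, FitConfig(seed=3))
        w1 = np.median([f.params[names.index("y.w[s1]")] for f in fits])
        assert w1 > 0.5

    def test_deterministic_given_seed(self):
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=120, seed=4)
        windows = build_windows(meta, min_snps=5)[:2]
        a = fit_windows(X, windows, graph, FitConfig(seed=7))
        b = fit_windows(X, windows, graph, FitConfig(seed=7))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.params, fb.params)

    def test_window_shares_sum_to_one(self):
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=150, seed=8)
        windows = build_windows(meta, min_snps=5)[:3]
        fits = fit_windows(X, windows, graph, FitConfig(seed=1))
        for f in fits:
            total = sum(f.decomposition["y"].values())
            assert abs(total - 1.0) < 1e-6


class TestCompareHypotheses:
    def _fits(self, graph, X, windows, seed=1):
        return fit_windows(X, windows, graph, FitConfig(seed=seed))

    def test_single_hypothesis_table(self):
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=120, seed=1)
        windows = build_windows(meta, min_snps=5)[:2]
        table = compare_hypotheses({"h1": (graph, self._fits(graph, X, windows))})
        assert len(table) == 1 and table.loc[0, "hypothesis"] == "h1"

    def test_equal_k_ranks_by_objective(self):
        graph, truth = two_source_admixture_design()
        X, meta, _ = simulate_admixture(graph, truth, n_snps=120, seed=1)
        windows = build_windows(meta, min_snps=5)[:2]
        fits = self._fits(graph, X, windows)
        worse = [
            type(f)(f.window, f.params, f.param_names, f.objective - 5.0, f.decomposition, f.converged)
            for f in fits
        ]
        table = compare_hypotheses({"good": (graph, fits), "bad": (graph, worse)})
        assert list(table["hypothesis"]) == ["good", "bad"]
        assert np.allclose(table["L"], -table["total_objective"])


def test_parse_hypothesis_round_trip():
    text = """# two cherries and a mixture
((s1:0.3,r1:0.3):1.5,(s2:0.3,r2:0.3):1.5);
y <- s1, s2
"""
    g = parse_hypothesis(text)
    assert g.pop_ids == ["s1", "r1", "s2", "r2", "y"]
    assert g.events[0].sources == ["s1", "s2"]


def test_aggregate_decomposition_weighted_by_snp_count():
    graph, truth = two_source_admixture_design()
    X, meta, _ = simulate_admixture(graph, truth, n_snps=150, seed=3)
    windows = build_windows(meta, min_snps=5)[:3]
    fits = fit_windows(X, windows, graph, FitConfig(seed=1))
    agg = variance_decomposition(fits, graph)
    row = agg.loc["y"]
    assert abs(row.sum() - 1.0) < 1e-6
    manual = sum(f.window.n_snps * f.decomposition["y"]["s1"] for f in fits) / sum(
        f.window.n_snps for f in fits
    )
    assert abs(row["s1"] - manual) < 1e-12
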