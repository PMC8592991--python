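"""TMM, dispersion, exact NB test, BH and the promoter-set classification."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import kstest

from fitcage import diffexp as de


def nb_counts(rng, mu, phi, size):
    if phi <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestTMM:
    def test_identical_columns(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(de.tmm_factors(counts), [1.0, 1.0])

    def test_pure_depth_difference(self, rng):
        """Doubling sequencing depth is absorbed by the library size, not
        the TMM factor."""
        mu = rng.lognormal(3, 1, 500)
        a = rng.poisson(mu)
        counts = pd.DataFrame({"a": a, "b": a * 2})
        np.testing.assert_allclose(de.tmm_factors(counts), [1.0, 1.0], atol=0.02)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 200, size=(300, 5)).astype(float))
        f = de.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_edger_oracle(self, rng, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors."""
        mu = rng.lognormal(3, 1, 300)
        counts = pd.DataFrame(
            {f"s{j}": rng.poisson(mu * f) for j, f in enumerate([1.0, 2.0, 0.7, 1.3])}
        )
        ours = de.tmm_factors(counts).to_numpy()
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t", index=False)
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.delim('{path}'));"
            "cat(calcNormFactors(DGEList(counts=x))$samples$norm.factors)"
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", "-e", script],
            capture_output=True, text=True, check=True,
        )
        theirs = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=0.01)

    def test_degenerate_sample_errors(self):
        counts = pd.DataFrame({"a": [5, 0, 9], "b": [0, 7, 0]})
        with pytest.raises(ValueError, match="shares no expressed promoter"):
            de.tmm_factors(counts)


class TestDispersion:
    def test_poisson_data_near_zero(self, rng):
        counts = pd.DataFrame(rng.poisson(200, size=(500, 8)).astype(float))
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        phi = de.estimate_dispersion(de.CountMatrix(counts), groups)
        assert phi < 0.05

    def test_recovers_planted_dispersion(self, rng):
        mu = rng.lognormal(5, 0.5, 500)
        counts = pd.DataFrame(
            {j: nb_counts(rng, mu, 0.4, 500).astype(float) for j in range(8)}
        )
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        phi = de.estimate_dispersion(de.CountMatrix(counts), groups)
        assert 0.25 < phi < 0.6

    def test_single_promoter_smoke(self, rng):
        counts = pd.DataFrame([[50.0, 60.0, 40.0, 55.0]], columns=list("abcd"))
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        phi = de.estimate_dispersion(de.CountMatrix(counts, counts.sum() * 0 + 100.0), groups)
        assert np.isfinite(phi) and phi >= 0


def binomial_split_oracle(a, b, n_a, n_b):
    """Two-sided exact binomial split test: mass of splits no more probable
    than the observed one under Binomial(a+b, n_a/(n_a+n_b))."""
    t = int(a + b)
    x = np.arange(t + 1)
    p = n_a / (n_a + n_b)
    logpmf = (
        gammaln(t + 1) - gammaln(x + 1) - gammaln(t - x + 1)
        + x * np.log(p) + (t - x) * np.log1p(-p)
    )
    return float(np.exp(logsumexp(logpmf[logpmf <= logpmf[int(a)] + 1e-10])))


class TestExactTest:
    def make_matrix(self, rng, n=300, mu=500, phi=0.0, n_a=4, n_b=4):
        cols = {f"a{i}": nb_counts(rng, mu, phi, n) for i in range(n_a)}
        cols.update({f"b{i}": nb_counts(rng, mu, phi, n) for i in range(n_b)})
        counts = pd.DataFrame(cols).astype(float)
        lib = pd.Series(float(mu * n), index=counts.columns)
        return de.CountMatrix(counts, lib)

    def test_null_pvalues_approximately_uniform(self, rng):
        matrix = self.make_matrix(rng, n=2000, mu=1000)
        res = de.nb_exact_test(matrix, [f"a{i}" for i in range(4)],
                               [f"b{i}" for i in range(4)], phi=0.0)
        assert kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_group_swap_symmetry(self, rng):
        matrix = self.make_matrix(rng, n=50)
        ga, gb = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
        ab = de.nb_exact_test(matrix, ga, gb, phi=0.1)
        ba = de.nb_exact_test(matrix, gb, ga, phi=0.1)
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"], rtol=1e-9)
        np.testing.assert_allclose(ab["logfc"], -ba["logfc"], atol=1e-9)

    def test_poisson_limit_matches_binomial_oracle(self, rng):
        matrix = self.make_matrix(rng, n=40, mu=80, n_a=3, n_b=5)
        res = de.nb_exact_test(matrix, [f"a{i}" for i in range(3)],
                               [f"b{i}" for i in range(5)], phi=0.0)
        counts = matrix.counts
        for pid in counts.index[:20]:
            a = counts.loc[pid, [f"a{i}" for i in range(3)]].sum()
            b = counts.loc[pid, [f"b{i}" for i in range(5)]].sum()
            assert res.loc[pid, "pvalue"] == pytest.approx(
                binomial_split_oracle(a, b, 3, 5), rel=1e-6
            )

    def test_empty_group_errors(self, rng):
        matrix = self.make_matrix(rng, n=10)
        with pytest.raises(ValueError, match="non-empty"):
            de.nb_exact_test(matrix, [], ["b0"], phi=0.1)


class TestBH:
    def test_hand_computation(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_and_bounds(self, rng):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)
        p = rng.uniform(size=100)
        fdr = de.bh_adjust(p)
        assert np.all(fdr >= p - 1e-12) and np.all(fdr <= 1.0)

    def test_stepup_oracle(self, rng):
        """Matches a direct implementation of the step-up procedure."""
        p = rng.uniform(size=37)
        order = np.argsort(p)
        m = p.size
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(de.bh_adjust(p), expect)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


def de_frame(rows):
    """rows: promoter -> (logfc, fdr)"""
    return pd.DataFrame(
        {"logfc": [v[0] for v in rows.values()], "fdr": [v[1] for v in rows.values()]},
        index=list(rows),
    )


STATES = {"up": (1.5, 0.01), "down": (-1.5, 0.01), "flat": (0.3, 0.8)}


def truth_table_frames():
    """One promoter per (state1, state2) combination, for both contrasts."""
    combos = list(itertools.product(STATES, STATES))
    first = de_frame({f"p_{a}_{b}": STATES[a] for a, b in combos})
    second = de_frame({f"p_{a}_{b}": STATES[b] for a, b in combos})
    return first, second


class TestClassification:
    def test_reversible_truth_table(self):
        first, second = truth_table_frames()
        up, down = de.classify_reversible(first, second, fdr=0.05)
        # brute-force oracle over all 9 combinations
        expect_up = {p for p in first.index
                     if first.loc[p, "fdr"] < 0.05 and first.loc[p, "logfc"] > 0
                     and second.loc[p, "fdr"] < 0.05 and second.loc[p, "logfc"] < 0}
        expect_down = {p for p in first.index
                       if first.loc[p, "fdr"] < 0.05 and first.loc[p, "logfc"] < 0
                       and second.loc[p, "fdr"] < 0.05 and second.loc[p, "logfc"] > 0}
        assert up == expect_up == {"p_up_down"}
        assert down == expect_down == {"p_down_up"}

    def test_hypometabolic_truth_table(self):
        first, second = truth_table_frames()
        up, down = de.classify_hypometabolic(first, second, fdr=0.05)
        assert up == {"p_up_up"}
        assert down == {"p_down_down"}

    def test_mismatched_universe_errors(self):
        a = de_frame({"p1": (1, 0.01)})
        b = de_frame({"p2": (1, 0.01)})
        with pytest.raises(ValueError, match="universe"):
            de.classify_reversible(a, b)

    def test_torpor_specific_intersection(self, rng):
        universe = [f"p{i}" for i in range(100)]
        rev = (set(rng.choice(universe, 30, replace=False)),
               set(rng.choice(universe, 10, replace=False)))
        hyp = (set(rng.choice(universe, 30, replace=False)),
               set(rng.choice(universe, 10, replace=False)))
        up, down = de.torpor_specific(rev, hyp)
        assert up == {p for p in universe if p in rev[0] and p in hyp[0]}
        assert down == {p for p in universe if p in rev[1] and p in hyp[1]}
        assert up <= rev[0] and up <= hyp[0]
        assert de.torpor_specific((set(), {"x"}), ({"x"}, set())) == (set(), set())

    def test_deprivation_specific_sign_split_and_overlap(self):
        table = de_frame({"a": (2.0, 0.01), "b": (-2.0, 0.01), "c": (1.0, 0.5)})
        res = de.deprivation_specific(table, torpor_sets=({"a", "z"}, {"q"}))
        assert res["up"] == {"a"} and res["down"] == {"b"}
        assert res["overlap_torpor_up"] == {"a"}
        assert res["overlap_torpor_down"] == set()
        empty = de.deprivation_specific(de_frame({}))
        assert empty["up"] == set() and empty["down"] == set()


class TestRankingAndMDS:
    def test_rank_by_total_fc(self):
        d1 = de_frame({"a": (1.0, 0.01), "b": (-3.0, 0.01)})
        d2 = de_frame({"a": (0.5, 0.01), "b": (1.0, 0.01)})
        table = de.rank_by_total_fc({"a", "b"}, d1, d2)
        assert table["promoter"].tolist() == ["b", "a"]
        assert table["total_fc"].tolist() == [4.0, 1.5]
        single = de.rank_by_total_fc({"a"}, d1, d2)
        assert single["promoter"].tolist() == ["a"]

    def test_identical_samples_have_zero_distance(self, rng):
        col = rng.poisson(100, 200).astype(float)
        counts = pd.DataFrame({"a": col, "b": col, "c": rng.poisson(100, 200)})
        coords = de.mds_embed(de.CountMatrix(counts))
        assert np.linalg.norm(coords.loc["a"] - coords.loc["b"]) == pytest.approx(0, abs=1e-8)

    def test_three_point_metric_preserved(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(400, 3)).astype(float),
                              columns=list("abc"))
        matrix = de.CountMatrix(counts)
        coords = de.mds_embed(matrix, top=100).to_numpy()
        # recompute the leading-logFC distances and compare to the embedding
        lib = matrix.effective_lib.to_numpy()
        logcpm = np.log2((counts.to_numpy() + 0.5) / (lib + 1.0) * 1e6)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            diff2 = np.sort((logcpm[:, i] - logcpm[:, j]) ** 2)[-100:]
            d = np.sqrt(diff2.mean())
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(d, rel=1e-6)
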