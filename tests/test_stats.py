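"""Unit and property tests for the elementary statistics primitives."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from irlncpair.stats import (
    ConstantInputError,
    bh_adjust,
    midranks,
    moderated_t_table,
    pearson,
    rank_test,
    spearman,
)


def _pearson_oracle(x, y):
    """Definitional product-moment formula plus t transform."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    r = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * spstats.t.sf(abs(t), df=n - 2)
    return r, p


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 3.5, 9.0])
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        r_o, p_o = _pearson_oracle(x, y)
        res = pearson(x, y)
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, rel=1e-10)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 40))
            y = rng.normal(size=x.size)
            res = pearson(x, y)
            ref = spstats.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)
        assert pearson(3.0 * x + 7.0, y).r == pytest.approx(pearson(x, y).r)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_gives_one(self):
        x = np.array([1.0, 2.0, 7.0, 9.0, 30.0])
        assert spearman(x, np.exp(x / 10)).r == pytest.approx(1.0)

    def test_equals_rank_transformed_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, size=30).astype(float)
        y = rng.normal(size=30)
        res = spearman(x, y)
        oracle = pearson(midranks(x), midranks(y))
        assert res.r == pytest.approx(oracle.r, abs=1e-12)
        assert res.p == pytest.approx(oracle.p, rel=1e-10)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x = rng.integers(0, 5, size=25).astype(float)
            y = rng.integers(0, 5, size=25).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman(x, y)
            ref = spstats.spearmanr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def _exact_enumeration_oracle(a, b):
    """Two-sided exact Mann-Whitney p by brute force over rank subsets."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestRankTest:
    def test_symmetric_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = rank_test(a, a + 0.0001)  # near-identical, no exact ties
        assert res.statistic == pytest.approx(len(a) ** 2 / 2, abs=2)

    def test_small_sample_exact_value(self):
        res = rank_test([1.0, 2.0], [3.0, 4.0])
        assert res.p == pytest.approx(2 / 6)
        assert res.direction == -1

    def test_strong_separation(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=50)
        res = rank_test(b + 10, b)
        assert res.p < 1e-6
        assert res.direction == 1

    def test_exhaustive_exact_path_vs_enumeration(self):
        """Exact path equals full enumeration for all n1+n2 <= 8 (no ties)."""
        rng = np.random.default_rng(5)
        for n1 in range(1, 5):
            for n2 in range(1, 5):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
                res = rank_test(a, b, exact_threshold=10)
                u_o, p_o = _exact_enumeration_oracle(a, b)
                assert res.statistic == pytest.approx(u_o)
                assert res.p == pytest.approx(p_o)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0.3, 1, 35)
            res = rank_test(a, b)
            ref = spstats.mannwhitneyu(a, b, alternative="two-sided")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestModeratedT:
    @staticmethod
    def _toy(n_null=200, n_shift=10, shift=2.0, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        genes = n_null + n_shift
        mat = rng.normal(6.0, 0.5, size=(genes, 2 * n_per))
        mat[n_null:, :n_per] += shift
        cols = [f"T{i}" for i in range(n_per)] + [f"N{i}" for i in range(n_per)]
        expr = pd.DataFrame(mat, index=[f"G{i}" for i in range(genes)], columns=cols)
        groups = pd.Series(["tumor"] * n_per + ["normal"] * n_per, index=cols)
        return expr, groups

    def test_zero_prior_df_recovers_ordinary_t(self):
        expr, groups = self._toy()
        tab = moderated_t_table(expr, groups, prior_df=0.0)
        tumor = expr.iloc[:, :10].to_numpy()
        normal = expr.iloc[:, 10:].to_numpy()
        ref_t, ref_p = spstats.ttest_ind(tumor, normal, axis=1, equal_var=True)[:2]
        np.testing.assert_allclose(tab["t"].to_numpy(), ref_t, rtol=1e-10)
        np.testing.assert_allclose(tab["p"].to_numpy(), ref_p, rtol=1e-8)

    def test_identical_groups_give_null_result(self):
        expr, groups = self._toy(n_shift=0, n_null=20)
        expr.iloc[0, :10] = expr.iloc[0, 10:].to_numpy()
        tab = moderated_t_table(expr, groups)
        assert tab.iloc[0]["logFC"] == pytest.approx(0.0)
        assert tab.iloc[0]["p"] > 0.99

    def test_shifted_genes_rank_first(self):
        expr, groups = self._toy(seed=3)
        tab = moderated_t_table(expr, groups)
        top10 = set(tab.nsmallest(10, "p").index)
        planted = {f"G{i}" for i in range(200, 210)}
        assert top10 == planted

    def test_posterior_variance_between_gene_and_prior(self):
        """s2_post lies strictly between s2_gene and s0^2 for finite d0."""
        from irlncpair.stats import _fit_variance_prior

        expr, groups = self._toy(seed=4)
        tumor = expr.iloc[:, :10]
        normal = expr.iloc[:, 10:]
        ss = tumor.sub(tumor.mean(axis=1), axis=0).pow(2).sum(axis=1) + normal.sub(
            normal.mean(axis=1), axis=0
        ).pow(2).sum(axis=1)
        s2 = (ss / 18).to_numpy()
        d0, s0 = _fit_variance_prior(s2, 18)
        assert np.isfinite(d0) and d0 > 0
        post = (d0 * s0 + 18 * s2) / (d0 + 18)
        lo = np.minimum(s2, s0)
        hi = np.maximum(s2, s0)
        mask = np.abs(s2 - s0) > 1e-12
        assert np.all(post[mask] > lo[mask]) and np.all(post[mask] < hi[mask])

    def test_infinite_prior_collapses_to_common_variance(self):
        expr, groups = self._toy(seed=5)
        tab_inf = moderated_t_table(expr, groups, prior_df=np.inf)
        # with a common variance, |t| must be proportional to |logFC|
        ratio = (tab_inf["t"] / tab_inf["logFC"]).to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_matches_limma_on_fixture(self, tmp_path):
        """Cross-check prior fit and moderated p against the Bioconductor
        reference implementation on a small fixture (skipped if Rscript or
        limma is unavailable)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        expr, groups = self._toy(n_null=80, n_shift=5, seed=6)
        f_expr = tmp_path / "expr.tsv"
        expr.to_csv(f_expr, sep="\t")
        script = tmp_path / "limma_ref.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(1, c(rep(1,10), rep(0,10)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(logFC=fit$coefficients[,2], t=fit$t[,2],
                              p=fit$p.value[,2])
            write.table(format(out, digits=12), args[2], sep="\t", quote=FALSE)
            """
        )
        out = tmp_path / "limma_out.tsv"
        proc = subprocess.run(
            ["Rscript", str(script), str(f_expr), str(out)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(out, sep="\t")
        tab = moderated_t_table(expr, groups)
        np.testing.assert_allclose(tab["logFC"], ref["logFC"], rtol=1e-6)
        np.testing.assert_allclose(tab["t"], ref["t"], rtol=1e-4)
        np.testing.assert_allclose(tab["p"], ref["p"], rtol=1e-3)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_bounds_dominance_and_order_preserving(self, p):
        adj = bh_adjust(p)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)
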