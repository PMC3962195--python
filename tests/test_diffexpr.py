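import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netgba.diffexpr import (
    ExpressionMatrix,
    fit_f_dist,
    moderated_t,
    quantile_normalize,
    squeeze_var,
    trigamma_inverse,
)

from oracles import pooled_t


def make_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def two_group_meta(n1, n2, tissue="T1"):
    rows = [(f"case_{i}", "case", tissue) for i in range(n1)]
    rows += [(f"ctrl_{i}", "control", tissue) for i in range(n2)]
    return pd.DataFrame(rows, columns=["sample_id", "group", "tissue"])


def null_matrix(rng, n_genes, n1, n2, sigma=1.0):
    x = rng.normal(0.0, sigma, size=(n_genes, n1 + n2))
    samples = [f"case_{i}" for i in range(n1)] + [f"ctrl_{i}" for i in range(n2)]
    return make_matrix(x, samples=samples)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_2x2_order_statistic_means(self):
        m = make_matrix([[1.0, 3.0], [2.0, 4.0]])
        out = quantile_normalize(m).values.to_numpy()
        # sorted columns [1,2] and [3,4]; row means of order stats = [2, 3]
        np.testing.assert_allclose(np.sort(out, axis=0), [[2.0, 2.0], [3.0, 3.0]])

    def test_all_columns_share_one_distribution(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(8, 2, size=(100, 6)))
        out = quantile_normalize(m).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        assert np.max(np.abs(sorted_cols - sorted_cols[:, [0]])) == 0.0

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(50, 4))
        out = quantile_normalize(make_matrix(x)).values.to_numpy()
        for j in range(4):
            assert np.array_equal(np.argsort(x[:, j]), np.argsort(out[:, j]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(make_matrix([[1.0], [2.0]]))


class TestModeratedT:
    def test_prior_df_zero_equals_pooled_t(self):
        rng = np.random.default_rng(10)
        m = null_matrix(rng, 100, 5, 5)
        de = moderated_t(m, two_group_meta(5, 5), "T1", prior_df=0)
        x = m.values.to_numpy()
        for i, gene in enumerate(m.genes):
            expected = pooled_t(x[i, :5], x[i, 5:])
            assert abs(de["t_mod"].iloc[i] - expected) < 1e-10

    def test_prior_df_inf_full_shrinkage(self):
        rng = np.random.default_rng(11)
        m = null_matrix(rng, 200, 5, 5)
        de = moderated_t(m, two_group_meta(5, 5), "T1", prior_df=math.inf)
        s02 = de.attrs["s02"]
        t = de["logFC"] / (math.sqrt(s02) * math.sqrt(1 / 5 + 1 / 5))
        np.testing.assert_allclose(de["t_mod"], t, atol=1e-12)

    def test_null_type_i_error_within_binomial_band(self):
        rng = np.random.default_rng(12)
        m = null_matrix(rng, 500, 5, 5)
        de = moderated_t(m, two_group_meta(5, 5), "T1")
        n_sig = int((de["p"] < 0.05).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 500, 0.05)
        assert lo <= n_sig <= hi

    def test_null_pvalues_uniform_ks(self):
        rng = np.random.default_rng(13)
        m = null_matrix(rng, 500, 5, 5)
        de = moderated_t(m, two_group_meta(5, 5), "T1")
        d = stats.kstest(de["p"], "uniform").statistic
        assert d < 1.63 / math.sqrt(500)  # 1% critical value

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(14)
        m = null_matrix(rng, 50, 4, 4)
        meta = two_group_meta(4, 4)
        de1 = moderated_t(m, meta, "T1")
        perm = rng.permutation(m.values.shape[1])
        m2 = ExpressionMatrix(m.values.iloc[:, perm])
        de2 = moderated_t(m2, meta, "T1")
        np.testing.assert_allclose(de1["t_mod"], de2["t_mod"], atol=1e-12)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(15)
        m = null_matrix(rng, 10, 1, 5)
        with pytest.raises(ValueError, match="per group"):
            moderated_t(m, two_group_meta(1, 5), "T1")

    def test_diagnosis_pools_tissues(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(30, 8))
        samples = [f"s{i}" for i in range(8)]
        m = make_matrix(x, samples=samples)
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["case", "case", "control", "control"] * 2,
                "tissue": ["T1"] * 4 + ["T2"] * 4,
            }
        )
        de = moderated_t(m, meta, "diagnosis")
        assert de.attrs["n_case"] == 4 and de.attrs["n_control"] == 4
        de_t1 = moderated_t(m, meta, "T1")
        assert de_t1.attrs["n_case"] == 2


class TestHyperparameterEstimation:
    def test_recovers_generating_values(self):
        # hierarchical model: sigma2_g ~ s0^2 * d0 / chi2(d0); s2 ~ sigma2 * chi2(d)/d
        rng = np.random.default_rng(20)
        d0, s02, d, n = 4.0, 0.05, 8, 5000
        sigma2 = s02 * d0 / rng.chisquare(d0, size=n)
        s2 = sigma2 * rng.chisquare(d, size=n) / d
        d0_hat, s02_hat = fit_f_dist(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.25
        assert abs(s02_hat - s02) / s02 < 0.25

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.1, 1.0, 5.0, 37.0):
            x = float(polygamma(1, y))
            assert abs(trigamma_inverse(x) - y) / y < 1e-6

    def test_squeeze_var_limits(self):
        s2 = np.array([0.5, 2.0])
        np.testing.assert_allclose(squeeze_var(s2, 4, math.inf, 1.0), [1.0, 1.0])
        np.testing.assert_allclose(squeeze_var(s2, 4, 0.0, 1.0), s2)


LIMMA_SCRIPT = textwrap.dedent(
    """
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{expr}", row.names = 1))
    group <- factor(rep(c("case", "control"), each = {nrep}), levels = c("control", "case"))
    design <- model.matrix(~group)
    fit <- eBayes(lmFit(x, design))
    out <- data.frame(gene = rownames(x), t = fit$t[, 2], d0 = fit$df.prior, s02 = fit$s2.prior)
    write.table(out, "{out}", sep = "\\t", row.names = FALSE, quote = FALSE)
    """
)


class TestLimmaCrossCheck:
    def test_t_matches_reference_within_1e6(self, tmp_path):
        """Moderated t agrees with the Bioconductor reference on a shared fixture."""
        rng = np.random.default_rng(30)
        n1 = n2 = 5
        n_genes = 200
        # heterogeneous gene variances so the estimated prior df is finite
        sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, size=n_genes)
        x = rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(n_genes, n1 + n2))
        x[:10, :n1] += 1.0  # a few real effects
        samples = [f"case_{i}" for i in range(n1)] + [f"ctrl_{i}" for i in range(n2)]
        m = make_matrix(x, samples=samples)
        expr_path = tmp_path / "expr.tsv"
        m.values.to_csv(expr_path, sep="\t", index_label="gene")
        out_path = tmp_path / "limma.tsv"
        script = LIMMA_SCRIPT.format(expr=expr_path, nrep=n1, out=out_path)
        r_file = tmp_path / "check.R"
        r_file.write_text(script)
        subprocess.run(["Rscript", str(r_file)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t", index_col=0)

        de = moderated_t(m, two_group_meta(n1, n2), "T1")
        assert abs(de.attrs["d0"] - ref["d0"].iloc[0]) < 1e-4
        assert abs(de.attrs["s02"] - ref["s02"].iloc[0]) < 1e-8
        np.testing.assert_allclose(de["t_mod"], ref["t"], atol=1e-6)
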