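"""Normalization closed forms, QC boundaries, HVG/ADO/dropout estimators."""

import numpy as np
import pandas as pd
import pytest

from targetseq.expression import (
    ExpressionMatrix,
    ado_from_het_sites,
    cell_cycle_scores,
    detection_threshold,
    dropout_frequency,
    group_correlations,
    highly_variable_genes,
    ks_compare,
    library_bias,
    normalize_3p,
    qc_filter,
    regress_out,
    rpkm_normalize,
)
from targetseq.panel import ConfigurationError
from targetseq.simulate import SimConfig, simulate_expression


def em_from(values: np.ndarray | list, genes=None, cells=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cells), "log2")


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"c1": [100]}, index=["G1"])
        lengths = pd.Series({"G1": 1000})
        em = rpkm_normalize(counts, lengths, mapped_totals=pd.Series({"c1": 1_000_000}))
        # 100 / (1 kb * 1 M reads) = 100 -> log2 = 6.644
        assert em.values.loc["G1", "c1"] == pytest.approx(np.log2(100), abs=1e-9)
        assert em.values.loc["G1", "c1"] == pytest.approx(6.644, abs=1e-3)

    def test_sub_one_rpkm_is_non_detected(self):
        counts = pd.DataFrame({"c1": [99]}, index=["G1"])
        lengths = pd.Series({"G1": 100_000})
        em = rpkm_normalize(counts, lengths, mapped_totals=pd.Series({"c1": 1_000_000}))
        assert em.values.loc["G1", "c1"] == 0.0  # RPKM 0.99 -> 0

    def test_zero_count_zero(self):
        counts = pd.DataFrame({"c1": [0, 10]}, index=["G1", "G2"])
        em = rpkm_normalize(counts, pd.Series({"G1": 1000, "G2": 1000}))
        assert em.values.loc["G1", "c1"] == 0.0

    def test_zero_total_cell_flagged_excluded(self):
        counts = pd.DataFrame({"c1": [10], "dead": [0]}, index=["G1"])
        em = rpkm_normalize(counts, pd.Series({"G1": 1000}))
        assert em.excluded_cells == ["dead"]
        assert "dead" not in em.values.columns

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"c1": [10]}, index=["G1"])
        with pytest.raises(ConfigurationError, match="length"):
            rpkm_normalize(counts, pd.Series({"other": 500}))


class TestNormalize3p:
    def test_identity_when_libsize_equals_target(self):
        counts = pd.DataFrame({"c1": [10, 30]}, index=["G1", "G2"])
        em = normalize_3p(counts, target=40.0)
        assert em.values.loc["G1", "c1"] == pytest.approx(np.log2(10))

    def test_printed_target_constant(self):
        counts = pd.DataFrame({"c1": [10, 4990]}, index=["G1", "G2"])
        em = normalize_3p(counts, target=68_412.0)
        # 10 / 5000 * 68412 = 136.824 -> log2 = 7.096
        assert em.values.loc["G1", "c1"] == pytest.approx(np.log2(136.824), abs=1e-9)
        assert em.values.loc["G1", "c1"] == pytest.approx(7.096, abs=1e-3)

    def test_pre_threshold_sums_equal_target(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(3, size=(200, 30)))
        counts.iloc[0] += 100  # unequal libsizes
        totals = counts.sum(axis=0)
        target = float(totals.mean())
        norm = counts.div(totals, axis=1) * target
        assert np.allclose(norm.sum(axis=0), target)
        # and the module's matrix equals that, post threshold+log
        em = normalize_3p(counts)
        arr = detection_threshold(norm).to_numpy()
        expect = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1)), 0.0)
        assert np.allclose(em.values.to_numpy(), expect)

    def test_all_zero_gene_stays_zero(self):
        counts = pd.DataFrame({"c1": [0, 5], "c2": [0, 7]}, index=["G1", "G2"])
        em = normalize_3p(counts)
        assert (em.values.loc["G1"] == 0).all()

    def test_threshold_idempotent(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.uniform(0, 3, size=(50, 5)))
        once = detection_threshold(vals)
        twice = detection_threshold(once)
        pd.testing.assert_frame_equal(once, twice)


class TestQCFilter:
    def test_full_length_hspc_boundary(self):
        metrics = pd.DataFrame(
            {"pct_exonic": [60, 50], "pct_mapped": [70, 70],
             "n_genes_detected": [1501, 1500]},
            index=["pass_cell", "boundary_cell"],
        )
        res = qc_filter(metrics, "full_length", {"min_genes": 1500})
        assert bool(res.loc["pass_cell", "pass"])
        # strict inequalities: exonic 50 and genes 1500 both fail
        assert not res.loc["boundary_cell", "pass"]
        assert "pct_exonic" in res.loc["boundary_cell", "reasons"]
        assert "n_genes_detected" in res.loc["boundary_cell", "reasons"]

    def test_three_prime_boundary_libsize(self):
        metrics = pd.DataFrame(
            {"total_reads": [2000], "pct_mito": [5], "pct_ercc": [10],
             "n_genes_detected": [600]},
            index=["c"],
        )
        res = qc_filter(metrics, "three_prime")
        assert not res.loc["c", "pass"]  # library size must be > 2000, strictly

    def test_three_prime_pass(self):
        metrics = pd.DataFrame(
            {"total_reads": [3000], "pct_mito": [9.9], "pct_ercc": [10],
             "n_genes_detected": [600]},
            index=["c"],
        )
        assert bool(qc_filter(metrics, "three_prime").loc["c", "pass"])

    def test_missing_metric_fails_with_reason(self):
        metrics = pd.DataFrame({"total_reads": [3000]}, index=["c"])
        res = qc_filter(metrics, "three_prime")
        assert not res.loc["c", "pass"]
        assert "metric_missing:pct_mito" in res.loc["c", "reasons"]


class TestDropoutAndBias:
    def test_fully_detected_gene_zero_dropout(self):
        em = em_from([[2, 3, 4], [0, 0, 0]], genes=["A", "B"])
        freq = dropout_frequency(em, ["A", "B"])
        assert freq["A"] == 0.0 and freq["B"] == 1.0

    def test_simulated_dropout_recovered(self):
        cfg = SimConfig(seed=31, n_cells=500, n_genes=200, dropout_prob=0.3)
        cm, truth = simulate_expression(cfg, ["A"] * 500)
        em = normalize_3p(cm)
        # restrict to genes expressed enough that zeros mean dropout
        strong = cm.index[(cm > 0).mean(axis=1) > 0.6]
        freq = dropout_frequency(em, list(strong))
        assert abs(freq.mean() - 0.3) < 0.05

    def test_library_bias_hand_value(self):
        rpkm = pd.DataFrame({"c1": [10.0] + [1.0] * 9})  # one cell, 10 genes
        # top-10% mean = 10, all-gene mean = 1.9 -> 5.263
        assert library_bias(rpkm).iloc[0] == pytest.approx(10 / 1.9, abs=1e-9)

    def test_equal_genes_unit_bias(self):
        rpkm = pd.DataFrame(np.full((20, 2), 7.0))
        assert np.allclose(library_bias(rpkm), 1.0)

    def test_bias_monotone_in_max(self):
        base = pd.DataFrame(np.arange(1.0, 21.0).reshape(20, 1))
        hi = base.copy()
        hi.iloc[-1] = 200.0
        assert library_bias(hi).iloc[0] > library_bias(base).iloc[0]


class TestHVG:
    def test_spikes_recovered_null_quiet(self):
        n_spike = 50
        spikes = list(range(0, 500, 10))
        cfg = SimConfig(seed=41, n_cells=500, n_genes=2000)
        cm, truth = simulate_expression(cfg, ["A"] * 500, hvg_genes=spikes)
        em = normalize_3p(cm)
        fit = highly_variable_genes(em)
        eligible = [g for g in truth.hvg_genes if fit.loc[g, "log2_mean"] >= 0]
        recall = fit.loc[eligible, "selected"].mean()
        assert recall >= 0.95
        null_genes = fit.index.difference(truth.hvg_genes)
        # null genes should hug the trend: selection near chance, far below spikes
        assert fit.loc[null_genes, "selected"].mean() < 0.6

    def test_low_mean_gene_never_selected(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 3, size=(100, 50))
        vals[0] = np.where(rng.random(50) < 0.5, 0.0, np.log2(1.5))  # mean < 1
        em = em_from(vals)
        fit = highly_variable_genes(em)
        assert fit.loc["G0", "log2_mean"] < 0
        assert not fit.loc["G0", "selected"]

    def test_constant_matrix_empty_selection(self):
        em = em_from(np.full((60, 10), 3.0))
        fit = highly_variable_genes(em)
        assert not fit["selected"].any()


class TestADO:
    def test_af_window_boundaries(self):
        counts = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3"],
            "variant": ["s1"] * 3,
            "n_ref": [50, 96, 10],
            "n_alt": [50, 4, 0],
        })
        est = ado_from_het_sites(counts, min_coverage=10)
        # af 0.5 biallelic; af 0.04 monoallelic; af 0 monoallelic
        assert est.loc["s1", "n_informative_cells"] == 3
        assert est.loc["s1", "n_monoallelic"] == 2

    def test_low_coverage_cells_excluded(self):
        counts = pd.DataFrame({
            "cell_id": ["c1", "c2"], "variant": ["s1"] * 2,
            "n_ref": [4, 50], "n_alt": [5, 50],
        })
        est = ado_from_het_sites(counts, min_coverage=10)
        assert est.loc["s1", "n_informative_cells"] == 1

    def test_simulated_ado_recovered(self):
        rng = np.random.default_rng(51)
        n, depth, ado = 500, 100, 0.1
        lost = rng.random(n) < ado
        af = np.where(lost, np.where(rng.random(n) < 0.5, 0.0, 1.0), 0.5)
        n_alt = rng.binomial(depth, af)
        counts = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            "variant": ["site"] * n,
            "n_ref": depth - n_alt,
            "n_alt": n_alt,
        })
        est = ado_from_het_sites(counts)
        assert abs(est.loc["site", "ado_rate"] - ado) < 0.03


class TestCellCycleAndRegression:
    def test_score_is_mean_of_present_members(self):
        em = em_from([[4, 0], [2, 2], [1, 1]], genes=["S1", "S2", "X"])
        with pytest.warns(UserWarning, match="absent"):
            scores = cell_cycle_scores(em, ["S1", "GONE"], ["S2"])
        assert scores.loc["c0", "s_score"] == 4.0
        assert scores.loc["c1", "g2m_score"] == 2.0

    def test_scores_ignore_genes_outside_sets(self):
        a = em_from([[4, 3], [2, 2], [9, 9]], genes=["S1", "S2", "X"])
        b = em_from([[4, 3], [2, 2], [0, 5]], genes=["S1", "S2", "X"])
        pd.testing.assert_frame_equal(
            cell_cycle_scores(a, ["S1"], ["S2"]), cell_cycle_scores(b, ["S1"], ["S2"]))

    def test_orthogonal_covariate_leaves_gene_unchanged(self):
        n = 40
        gene = np.tile([1.0, 2.0], n // 2)
        cov = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to gene
        em = em_from(gene.reshape(1, n))
        out = regress_out(em, pd.DataFrame({"s": cov}, index=em.cells))
        assert np.allclose(out.values.to_numpy()[0], gene, atol=1e-10)

    def test_pure_covariate_gene_flattened(self):
        rng = np.random.default_rng(7)
        score = rng.normal(size=100)
        em = em_from((2 * score).reshape(1, 100))
        out = regress_out(em, pd.DataFrame({"s": score}, index=em.cells))
        assert out.values.to_numpy().std() < 1e-10
        assert out.values.to_numpy().mean() == pytest.approx(2 * score.mean())

    def test_effect_size_recovered(self):
        rng = np.random.default_rng(8)
        n = 500
        score = rng.normal(size=n)
        gene = 1.5 * score + rng.normal(scale=0.5, size=n)
        X = np.column_stack([np.ones(n), score])
        beta = np.linalg.lstsq(X, gene, rcond=None)[0]
        assert abs(beta[1] - 1.5) < 0.1
        em = em_from(gene.reshape(1, n))
        out = regress_out(em, pd.DataFrame({"s": score}, index=em.cells))
        resid_corr = np.corrcoef(out.values.to_numpy()[0], score)[0, 1]
        assert abs(resid_corr) < 1e-8

    def test_collinear_covariates_named(self):
        em = em_from(np.random.default_rng(0).normal(size=(3, 10)))
        cov = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)},
                           index=em.cells)
        with pytest.raises(ConfigurationError, match="collinear"):
            regress_out(em, cov)


class TestGroupCorrelations:
    def test_identical_cells_correlate_perfectly(self):
        rng = np.random.default_rng(9)
        col = rng.uniform(1, 5, size=100)
        em = em_from(np.column_stack([col] * 6))
        groups = pd.Series(["g"] * 6, index=em.cells)
        corr = group_correlations(em, groups)
        assert np.allclose(corr["g"], 1.0)

    def test_independent_cells_center_near_zero(self):
        # iid noise with no shared per-gene structure: correlations ~ 0
        rng = np.random.default_rng(10)
        em = em_from(rng.uniform(1, 5, size=(2000, 20)))
        groups = pd.Series(["g"] * 20, index=em.cells)
        corr = group_correlations(em, groups)["g"]
        assert abs(np.mean(corr)) < 0.05

    def test_gene_filter_applied_globally(self):
        vals = np.ones((10, 6))
        vals[0] = [1, 0, 0, 0, 0, 0]  # expressed in 1 cell -> filtered
        em = em_from(vals)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=em.cells)
        rng = np.random.default_rng(3)
        em.values.iloc[1:] = rng.uniform(1, 2, size=(9, 6))
        corr = group_correlations(em, groups, min_cells_expr=5)
        assert set(corr) == {"a", "b"}

    def test_ks_self_comparison_zero(self):
        x = np.random.default_rng(4).normal(size=200)
        stat, p = ks_compare(x, x)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_too_small_group_rejected(self):
        em = em_from(np.ones((10, 3)))
        groups = pd.Series(["a", "a", "b"], index=em.cells)
        with pytest.raises(ConfigurationError, match="fewer than 2"):
            group_correlations(em, groups)
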