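"""Correlation estimators, co-expressed subsets, BH adjustment, promoter ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cneduo.coexpression import (
    bh_adjust,
    cis_trans_table,
    coexpressed_subset,
    correlate,
    promoter_ratio,
)
from cneduo.io_formats import ExpressionMatrix
from cneduo.synthetic import ELEMENT_FEATURE, SimulationConfig, simulate_expression_matrix


def matrix_of(rows: dict) -> ExpressionMatrix:
    n = len(next(iter(rows.values())))
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
    )


class TestSubset:
    def test_both_above_threshold(self):
        m = matrix_of({"a": [2, 0, 3], "b": [1, 5, 0]})
        assert coexpressed_subset(m, "a", "b", 1.0) == ["s0"]

    def test_zero_threshold_keeps_all(self):
        m = matrix_of({"a": [2, 0, 3], "b": [1, 5, 0]})
        assert coexpressed_subset(m, "a", "b", 0.0) == ["s0", "s1", "s2"]

    def test_unknown_feature_is_error(self):
        m = matrix_of({"a": [1, 2, 3]})
        with pytest.raises(KeyError):
            coexpressed_subset(m, "a", "zz", 1.0)

    def test_simulated_zeroed_samples_excluded(self):
        cfg = SimulationConfig(seed=21, n_samples=100, zero_fraction=0.3)
        m, ledger = simulate_expression_matrix(cfg)
        subset = coexpressed_subset(m, ELEMENT_FEATURE, "HOXC11", threshold=1.0)
        assert set(subset).isdisjoint(ledger.zeroed_samples)
        # bookkeeping: subset = samples where both features pass the threshold
        va, vb = m.feature(ELEMENT_FEATURE), m.feature("HOXC11")
        expected = [s for s in m.sample_ids if va[s] >= 1.0 and vb[s] >= 1.0]
        assert subset == expected


class TestCorrelate:
    def test_proportional_features_have_r_one(self):
        a = [1.0, 2, 4, 8, 16, 32, 64, 128, 256, 512]
        m = matrix_of({"a": a, "b": [2 * x for x in a]})
        res = correlate(m, "a", "b")
        # the log2(TPM+1) transform keeps a doubled feature almost perfectly linear
        assert res.r == pytest.approx(1.0, abs=1e-3)
        assert correlate(m, "a", "b", method="spearman").r == pytest.approx(1.0)

    def test_monotone_decreasing_spearman_is_minus_one(self):
        a = [1.0, 2, 3, 4, 5]
        m = matrix_of({"a": a, "b": [max(a) - x for x in a]})
        res = correlate(m, "a", "b", method="spearman")
        assert res.r == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        m = matrix_of({"a": rng.lognormal(size=30), "b": rng.lognormal(size=30)})
        r1 = correlate(m, "a", "b")
        r2 = correlate(m, "b", "a")
        assert r1.r == pytest.approx(r2.r) and r1.p == pytest.approx(r2.p)

    def test_scale_invariance_of_log_pearson_after_log(self):
        """Pearson is invariant to positive affine maps on the log scale."""
        rng = np.random.default_rng(1)
        x = np.log2(rng.lognormal(2, 1, 50) + 1)
        y = 0.6 * x + rng.normal(0, 0.3, 50)
        r1, _ = stats.pearsonr(x, y)
        r2, _ = stats.pearsonr(3.0 * x + 5.0, y)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_flagged_not_crashed(self):
        m = matrix_of({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        res = correlate(m, "a", "b")
        assert math.isnan(res.r) and res.undefined_reason == "zero variance"

    def test_too_few_samples_is_error(self):
        m = matrix_of({"a": [1.0, 2], "b": [2.0, 1]})
        with pytest.raises(ValueError, match="at least 3"):
            correlate(m, "a", "b")

    @pytest.mark.parametrize("rho,lo,hi", [(0.9, 0.7, 1.0), (-0.9, -1.0, -0.7)])
    def test_strong_planted_coupling_recovered(self, rho, lo, hi):
        cfg = SimulationConfig(seed=22, n_samples=200, couplings={"G": rho},
                               zero_fraction=0.0)
        m, _ = simulate_expression_matrix(cfg)
        res = correlate(m, ELEMENT_FEATURE, "G")
        assert lo <= res.r <= hi


class TestTableAndBH:
    def test_single_gene_q_equals_p(self):
        cfg = SimulationConfig(seed=23, n_samples=60, couplings={"G": 0.5})
        m, _ = simulate_expression_matrix(cfg)
        table = cis_trans_table(m, ELEMENT_FEATURE, ["G"])
        assert table.loc[0, "q"] == pytest.approx(table.loc[0, "p"])

    def test_bh_monotone_and_bounded(self):
        ps = [0.001, 0.02, 0.5, 0.04, 0.9]
        qs = bh_adjust(ps)
        assert all(0 <= q <= 1 for q in qs)
        order = np.argsort(ps)
        assert all(qs[order[i]] <= qs[order[i + 1]] + 1e-12 for i in range(len(ps) - 1))

    def test_planted_coupling_signs_recovered(self):
        cfg = SimulationConfig(seed=24, n_samples=200)
        m, ledger = simulate_expression_matrix(cfg)
        table = cis_trans_table(m, ELEMENT_FEATURE, sorted(ledger.couplings))
        for _, row in table.iterrows():
            assert np.sign(row["r"]) == np.sign(ledger.couplings[row["gene"]])
        # rows sorted by r descending
        rs = table["r"].to_numpy()
        assert all(rs[i] >= rs[i + 1] for i in range(len(rs) - 1))

    def test_empty_gene_list_is_error(self):
        m = matrix_of({"a": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="empty gene list"):
            cis_trans_table(m, "a", [])

    def test_null_couplings_control_false_discoveries(self):
        """With 20 null genes, BH keeps the q<0.05 discovery fraction near nominal."""
        discoveries = 0
        total = 0
        for seed in range(40):
            cfg = SimulationConfig(
                seed=seed, n_samples=60, zero_fraction=0.0,
                couplings={f"g{i}": 0.0 for i in range(20)},
            )
            m, _ = simulate_expression_matrix(cfg)
            table = cis_trans_table(m, ELEMENT_FEATURE, [f"g{i}" for i in range(20)])
            discoveries += int((table["q"] < 0.05).sum())
            total += len(table)
        assert discoveries / total <= 0.05


class TestPromoterRatio:
    def test_equal_usage_gives_zero_and_p_one(self):
        m = matrix_of({"nc": [4.0, 8, 2], "cod": [4.0, 8, 2]})
        ratios, summary = promoter_ratio(m, "nc", "cod")
        assert all(r == 0 for r in ratios)
        assert summary["sign_test_p"] == 1.0

    def test_fourfold_usage_is_two_on_log2_scale(self):
        m = matrix_of({"nc": [400.0, 800, 1200], "cod": [100.0, 200, 300]})
        ratios, summary = promoter_ratio(m, "nc", "cod")
        assert summary["median_log2_ratio"] == pytest.approx(2.0, abs=0.01)

    def test_planted_threefold_recovered(self):
        cfg = SimulationConfig(seed=25, n_samples=200)
        m, _ = simulate_expression_matrix(cfg)
        _, summary = promoter_ratio(m, "ncHOXD11", "HOXD11")
        assert summary["median_log2_ratio"] == pytest.approx(math.log2(3), abs=0.2)
        assert summary["sign_test_p"] < 1e-6


class TestNullCalibration:
    def test_null_pvalues_approximately_uniform(self):
        """Pearson-on-log p-values under zero coupling pass a KS uniformity check."""
        ps = []
        for seed in range(300):
            cfg = SimulationConfig(seed=seed, n_samples=50, zero_fraction=0.0,
                                   couplings={"G": 0.0})
            m, _ = simulate_expression_matrix(cfg)
            ps.append(correlate(m, ELEMENT_FEATURE, "G").p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_moderate_coupling_sign_recovery_rate(self):
        hits = 0
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_samples=100, zero_fraction=0.0,
                                   couplings={"G": 0.3})
            m, _ = simulate_expression_matrix(cfg)
            hits += correlate(m, ELEMENT_FEATURE, "G").r > 0
        assert hits / 50 >= 0.9
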