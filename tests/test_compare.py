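import math

import numpy as np
import pytest
from scipy import stats

from iolopt import (PairedMatrix, bonferroni, cochran_q_test, compare_methods,
                    correct_cohort_li, correct_method_s, actual_correction,
                    durbin_conover_posthoc, friedman_test, mcnemar_test,
                    rm_anova, shapiro_wilk_gate, simulate_cohort,
                    SyntheticConfig)


class TestShapiroGate:
    def test_returns_valid_w_and_flag(self):
        gate = shapiro_wilk_gate(np.arange(1.0, 51.0))
        assert 0 < gate.w <= 1
        assert gate.normal == (gate.p >= 0.05)

    def test_skewed_sample_fails_gate(self):
        rng = np.random.default_rng(11)
        gate = shapiro_wilk_gate(rng.exponential(1.0, 100))
        assert not gate.normal

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk_gate([3.0] * 10)


class TestFriedman:
    def test_consistent_ranking_oracle(self):
        # 3 subjects, each ranking the columns 1 < 2 < 3:
        # rank sums (3, 6, 9) give Q = 6; chi2_2 survival is exp(-Q/2)
        m = PairedMatrix(np.array([[1.0, 2, 3], [10, 20, 30], [0.1, 0.2, 0.3]]))
        res = friedman_test(m)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == (2,)
        assert res.p_value == pytest.approx(math.exp(-3.0), abs=1e-6)

    def test_identical_columns_null(self):
        m = PairedMatrix(np.tile(np.arange(5.0)[:, None], (1, 3)))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_k2_dominant_column_reaches_maximum(self):
        # with k = 2 and column 2 always larger, Q = n (the enumeration
        # maximum over all +/-1 rank patterns at this n)
        n = 6
        m = PairedMatrix(np.column_stack([np.zeros(n), np.ones(n)]))
        assert friedman_test(m).statistic == pytest.approx(n)

    def test_matches_reference_implementation_with_ties(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(size=(12, 4)), 1)  # rounding forces ties
        res = friedman_test(PairedMatrix(x))
        ref_stat, ref_p = stats.friedmanchisquare(*x.T)
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    def test_subject_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 3))
        res = friedman_test(PairedMatrix(x))
        perm = friedman_test(PairedMatrix(x[rng.permutation(10)]))
        assert res.statistic == pytest.approx(perm.statistic)


class TestRmAnova:
    def test_identical_columns_null(self):
        m = PairedMatrix(np.tile(np.arange(4.0)[:, None], (1, 3)))
        res = rm_anova(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_error_variance_flagged_infinite(self):
        res = rm_anova(PairedMatrix(np.array([[1.0, 2.0], [3.0, 4.0]])))
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0
        assert "infinite" in res.note

    def test_subject_shift_absorbed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 3))
        shifted = x.copy()
        shifted[4] += 7.5
        assert rm_anova(PairedMatrix(x)).statistic == pytest.approx(
            rm_anova(PairedMatrix(shifted)).statistic)

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(21)
        x = rng.normal(size=(15, 3)) + np.array([0.0, 0.2, 0.5])
        res = rm_anova(PairedMatrix(x))
        long = pd.DataFrame({
            "y": x.ravel(),
            "cond": np.tile(np.arange(3), 15),
            "subj": np.repeat(np.arange(15), 3),
        })
        ref = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]))
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]))


class TestCochranQ:
    def test_hand_totals_oracle(self):
        m = PairedMatrix(np.array([[1, 1, 0], [1, 0, 0], [1, 1, 0], [1, 0, 0]],
                                  dtype=float))
        res = cochran_q_test(m)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == (2,)
        assert res.p_value == pytest.approx(math.exp(-3.0), abs=1e-6)

    def test_identical_columns_null(self):
        m = PairedMatrix(np.tile(np.array([1.0, 0, 1, 0])[:, None], (1, 3)))
        assert cochran_q_test(m).statistic == 0.0

    def test_every_row_constant_is_degenerate(self):
        m = PairedMatrix(np.ones((4, 3)))
        res = cochran_q_test(m)
        assert (res.statistic, res.p_value) == (0.0, 1.0)
        assert res.note is not None

    def test_k2_reduces_to_uncorrected_mcnemar(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = (rng.random((20, 2)) < 0.5).astype(float)
            q = cochran_q_test(PairedMatrix(x))
            mc = mcnemar_test(x[:, 0], x[:, 1])
            if q.note is None:
                assert q.statistic == pytest.approx(mc.statistic)

    def test_matches_reference_implementation(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(17)
        x = (rng.random((25, 3)) < [0.4, 0.55, 0.7]).astype(float)
        res = cochran_q_test(PairedMatrix(x))
        ref = sm_ct.cochrans_q(x, return_object=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            cochran_q_test(PairedMatrix(np.array([[0.0, 0.5], [1.0, 1.0]])))


class TestMcNemar:
    def test_chi2_oracle(self):
        x = np.array([1, 1, 1, 0, 1, 0] + [1] * 4, dtype=float)
        y = np.array([0, 0, 0, 1, 1, 0] + [1] * 4, dtype=float)
        res = mcnemar_test(x, y)  # b = 3, c = 1
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(1.0, 1)), abs=1e-6)

    def test_exact_binomial_oracle(self):
        # brute-force two-sided binomial: 2 * P(X <= 1 | n = 4, p = 1/2)
        x = np.array([1, 1, 1, 0, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        res = mcnemar_test(x, y, method="exact")
        expected = 2 * sum(math.comb(4, i) for i in (0, 1)) / 2 ** 4
        assert res.p_value == pytest.approx(expected)  # 0.625

    def test_balanced_discordance_is_null(self):
        x = np.array([1, 0, 1, 0], dtype=float)
        y = np.array([0, 1, 1, 0], dtype=float)
        res = mcnemar_test(x, y)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_no_discordance(self):
        x = np.array([1.0, 0.0])
        assert mcnemar_test(x, x).p_value == 1.0

    def test_matches_reference_implementation(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(31)
        x = (rng.random(60) < 0.5).astype(float)
        y = (rng.random(60) < 0.7).astype(float)
        table = [[np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                 [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))]]
        ref_chi2 = sm_ct.mcnemar(table, exact=False, correction=False)
        res = mcnemar_test(x, y)
        assert res.statistic == pytest.approx(ref_chi2.statistic)
        assert res.p_value == pytest.approx(ref_chi2.pvalue)
        ref_exact = sm_ct.mcnemar(table, exact=True)
        assert mcnemar_test(x, y, method="exact").p_value == pytest.approx(
            ref_exact.pvalue)


class TestDurbinConover:
    def test_hand_oracle_near_consistent_rankings(self):
        # 4 subjects, three of them ranking (1,2,3), one ranking (2,1,3):
        # R = (5, 7, 12), A = 4*14 = 56, B = (25+49+144)/4 = 54.5,
        # denom = sqrt(2*4*1.5/6) = sqrt(2), df = 6
        m = PairedMatrix(np.array([
            [1.0, 2, 3], [1, 2, 3], [1, 2, 3], [2, 1, 3],
        ]))
        pairs = durbin_conover_posthoc(m)
        t13 = next(p for p in pairs if p.pair == ("cond0", "cond2"))
        assert t13.statistic == pytest.approx(-7 / math.sqrt(2))
        assert t13.df == 6
        expected_p = 2 * stats.t.sf(7 / math.sqrt(2), 6)
        assert t13.p_raw == pytest.approx(float(expected_p))
        assert t13.p_adjusted == pytest.approx(min(1.0, 3 * float(expected_p)))
        # the extreme pair carries the largest |t|
        assert abs(t13.statistic) == max(abs(p.statistic) for p in pairs)

    def test_equal_rank_sums_give_null_pair(self):
        m = PairedMatrix(np.array([[1.0, 2, 3], [3, 2, 1], [1, 2, 3], [3, 2, 1]]))
        pairs = durbin_conover_posthoc(m)
        p02 = next(p for p in pairs if p.pair == ("cond0", "cond2"))
        assert p02.statistic == pytest.approx(0.0)
        assert p02.p_raw == 1.0

    def test_all_tied_rows_give_all_null(self):
        m = PairedMatrix(np.ones((4, 3)))
        assert all(p.p_raw == 1.0 for p in durbin_conover_posthoc(m))

    def test_perfectly_consistent_rankings_are_maximally_separated(self):
        m = PairedMatrix(np.array([[1.0, 2, 3], [1, 2, 3], [1, 2, 3]]))
        pairs = durbin_conover_posthoc(m)
        assert all(p.p_raw == 0.0 for p in pairs)

    def test_antisymmetry_and_exchangeability(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(8, 3))
        base = {p.pair: p.statistic for p in durbin_conover_posthoc(PairedMatrix(x))}
        swapped = PairedMatrix(x[:, [1, 0, 2]])
        sw = {p.pair: p.statistic for p in durbin_conover_posthoc(swapped)}
        assert sw[("cond0", "cond1")] == pytest.approx(-base[("cond0", "cond1")])
        assert abs(sw[("cond1", "cond2")]) == pytest.approx(abs(base[("cond0", "cond2")]))


class TestBonferroni:
    def test_caps_at_one_and_preserves_order(self):
        raw = [0.01, 0.2, 0.5]
        adj = [bonferroni(p, 3) for p in raw]
        assert adj == pytest.approx([0.03, 0.6, 1.0])
        assert sorted(adj) == adj


class TestCompareMethods:
    def test_identical_sets_yield_null_omnibus_without_posthoc(self, linear_cohort):
        _, li = correct_cohort_li(linear_cohort)
        comp = compare_methods({"a": li, "b": li, "c": li})
        assert comp.mae.p_value == 1.0
        assert comp.mae.posthoc == ()
        for res in comp.rates.values():
            assert res.p_value == 1.0

    def test_linear_generator_yields_equivalent_columns(self):
        cfg = SyntheticConfig(n_eyes=80, seed=5)
        cohort, formula = simulate_cohort(cfg)
        res, li = correct_cohort_li(cohort)
        actual = actual_correction(cohort, formula.evaluate(res.x_opt))
        assert np.max(np.abs(li.ape_d - actual.ape_d)) < 1e-12
        comp = compare_methods({"method_li": li, "actual": actual})
        assert comp.mae.p_value == 1.0

    def test_nonlinear_generator_separates_method_s(self):
        """Strong curvature at extreme axial lengths makes the uniform-shift
        correction deviate from recomputed actual values; the omnibus test
        detects it at n = 200."""
        cfg = SyntheticConfig(n_eyes=200, seed=2, curvature_d_per_unit2=3.0)
        cohort, formula = simulate_cohort(cfg)
        res, li = correct_cohort_li(cohort)
        comp = compare_methods({
            "method_s": correct_method_s(cohort),
            "method_li": li,
            "actual": actual_correction(cohort, formula.evaluate(res.x_opt)),
        })
        assert comp.mae.p_value < 0.05
        assert comp.mae.posthoc  # post hoc ran because the omnibus fired

    def test_misaligned_sets_rejected(self, linear_cohort):
        _, li = correct_cohort_li(linear_cohort)
        short = correct_method_s(linear_cohort.with_cases(linear_cohort.cases[:4]))
        with pytest.raises(ValueError, match="misaligned"):
            compare_methods({"a": li, "b": short})
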