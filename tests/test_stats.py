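"""Figure-level statistics against hand calculations and library oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from freechoice import stats as fst


class TestPairedT:
    def test_identical_conditions(self):
        res = fst.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        res = fst.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_matches_scipy_oracle(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        res = fst.paired_t(a, b)
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(fst.StatsError):
            fst.paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestWilcoxon:
    def test_all_positive_differences_exact(self):
        res = fst.wilcoxon_signed_rank([2, 4, 6, 8, 10, 12], [1, 2, 3, 4, 5, 6.0])
        assert res.T == 0.0
        assert res.exact
        assert res.p == pytest.approx(2 / 64)

    def test_antisymmetric_differences_split_rank_sum(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = fst.wilcoxon_signed_rank(a, np.zeros(6))
        total = 6 * 7 / 2
        assert res.T == pytest.approx(total / 2)

    def test_matches_scipy_exact_oracle(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(15)
        res = fst.wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="exact")
        assert res.T == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_n20(self, rng):
        for _ in range(20):
            a = rng.standard_normal(22)
            b = rng.standard_normal(22)
            exact = fst.wilcoxon_signed_rank(a, b)
            approx = fst.wilcoxon_signed_rank(a, b, exact_max_n=0)
            assert exact.exact and not approx.exact
            assert abs(exact.p - approx.p) < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(fst.StatsError):
            fst.wilcoxon_signed_rank(np.ones(6), np.ones(6))
        with pytest.raises(fst.StatsError):
            fst.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 1.0], [0.0, 0.0, 0.0, 0.0, 1.0])


class TestRmAnova2x2:
    def test_pure_additive_shift_has_no_interaction(self, rng):
        base = rng.standard_normal(10)
        res = fst.rm_anova_2x2(base, base + 2.0, base + 1.0, base + 3.0)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-20)

    def test_equals_squared_paired_t_on_double_differences(self, rng):
        for _ in range(50):
            cells = rng.standard_normal((4, 12))
            res = fst.rm_anova_2x2(*cells)
            dd = (cells[1] - cells[0]) - (cells[3] - cells[2])
            t = fst.paired_t(dd, np.zeros_like(dd))
            assert res.F_interaction == pytest.approx(t.t**2, rel=1e-10)
            assert res.p == pytest.approx(t.p, rel=1e-10)

    def test_matches_pingouin_oracle(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 14
        cells = rng.standard_normal((4, n)) + np.array([[0.0], [0.5], [0.2], [1.2]])
        res = fst.rm_anova_2x2(*cells)
        rows = []
        for (f1, f2), vals in zip(
            [("a", "lo"), ("a", "hi"), ("b", "lo"), ("b", "hi")], cells
        ):
            for subj, v in enumerate(vals):
                rows.append({"subject": subj, "f1": f1, "f2": f2, "y": v})
        table = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["f1", "f2"], subject="subject"
        )
        ref = table.set_index("Source").loc["f1 * f2"]
        assert res.F_interaction == pytest.approx(ref["F"], rel=1e-6)
        assert res.p == pytest.approx(ref["p_unc"], rel=1e-6)
        mains = table.set_index("Source")
        assert res.F_factor1 == pytest.approx(mains.loc["f1", "F"], rel=1e-6)
        assert res.F_factor2 == pytest.approx(mains.loc["f2", "F"], rel=1e-6)

    def test_interaction_power_at_configured_effect(self):
        """Power > 0.8 for a 1-sd double-difference effect with n = 12."""
        rng = np.random.default_rng(77)
        n = 12
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            cells = rng.standard_normal((4, n))
            cells[3] += 2.0  # interaction: only the (hi, hi) cell shifts
            hits += fst.rm_anova_2x2(*cells).p < 0.05
        assert hits / n_sims > 0.8

    def test_too_few_subjects(self):
        with pytest.raises(fst.StatsError):
            fst.rm_anova_2x2([1.0], [2.0], [3.0], [4.0])


class TestKs:
    def test_identical_samples(self):
        res = fst.ks_two_sample([1, 2, 3.0], [1, 2, 3.0])
        assert res.D == 0.0

    def test_fully_separated(self):
        res = fst.ks_two_sample([0.0, 1.0], [5.0, 6.0])
        assert res.D == 1.0

    def test_hand_traced_ecdf(self):
        res = fst.ks_two_sample([1.0, 2.0], [1.5])
        assert res.D == pytest.approx(0.5)

    def test_matches_scipy_asymptotic_oracle(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(60) + 0.3
        res = fst.ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y, method="asymp")
        assert res.D == pytest.approx(ref.statistic)
        # scipy applies a small-sample continuity adjustment to the asymptotic
        # p; the plain limiting distribution agrees to ~15% at these n
        assert res.p == pytest.approx(ref.pvalue, rel=0.15)


class TestPearsonWald:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert fst.pearson_wald(x, 2 * x + 1).r == pytest.approx(1.0)
        assert fst.pearson_wald(x, -x).r == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        res = fst.pearson_wald(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_constant_input_degenerate(self):
        with pytest.raises(fst.StatsError):
            fst.pearson_wald(np.ones(5), np.arange(5.0))


class TestFisherRz:
    def test_equal_correlations(self):
        assert fst.fisher_rz_compare(0.4, 30, 0.4, 30).z == 0.0

    def test_hand_computed_example(self):
        res = fst.fisher_rz_compare(0.5, 28, 0.0, 28)
        assert res.z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 25), rel=1e-12)
        assert res.z == pytest.approx(1.942, abs=5e-4)

    def test_sign_antisymmetry(self):
        a = fst.fisher_rz_compare(0.6, 20, 0.1, 25)
        b = fst.fisher_rz_compare(0.1, 25, 0.6, 20)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_unit_correlation_rejected(self):
        with pytest.raises(fst.StatsError):
            fst.fisher_rz_compare(1.0, 10, 0.0, 10)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 3, 0.03), (0.6, 2, 1.0), (0.2, 1, 0.2)]
    )
    def test_adjustment(self, p, m, expected):
        assert fst.bonferroni(p, m) == pytest.approx(expected)

    def test_vector_input(self):
        out = fst.bonferroni([0.01, 0.5], 4)
        assert np.allclose(out, [0.04, 1.0])

    def test_invalid_inputs(self):
        with pytest.raises(fst.StatsError):
            fst.bonferroni(1.5, 2)
        with pytest.raises(fst.StatsError):
            fst.bonferroni(0.5, 0)
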