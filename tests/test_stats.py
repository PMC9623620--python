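"""Exact intervals, agreement, paired tests, correlation, design statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import ftpi_dta as fd
from ftpi_dta.stats import ConfusionTable, SampleSizeSpec
from conftest import clopper_pearson_bisection_oracle, mcnemar_enumeration_oracle


class TestClopperPearson:
    def test_boundaries_exact(self):
        assert fd.clopper_pearson(0, 10)[0] == 0.0
        assert fd.clopper_pearson(10, 10)[1] == 1.0

    def test_table_like_interval(self):
        lo, hi = fd.clopper_pearson(69, 76)
        assert lo == pytest.approx(0.819, abs=1e-3)
        assert hi == pytest.approx(0.962, abs=1e-3)

    def test_symmetry_at_half(self):
        lo, hi = fd.clopper_pearson(5, 10)
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    def test_contains_point_estimate(self):
        for k, n in [(0, 5), (3, 7), (7, 7), (40, 120)]:
            lo, hi = fd.clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_matches_bisection_oracle_exhaustively(self):
        for n in range(1, 26):
            for k in range(n + 1):
                lo, hi = fd.clopper_pearson(k, n)
                olo, ohi = clopper_pearson_bisection_oracle(k, n)
                assert lo == pytest.approx(olo, abs=1e-9)
                assert hi == pytest.approx(ohi, abs=1e-9)

    def test_matches_statsmodels_beta_interval(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(0, 10), (3, 10), (69, 76), (120, 245)]:
            lo, hi = fd.clopper_pearson(k, n)
            slo, shi = statsmodels.proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_exact_coverage_at_least_nominal(self):
        """The defining property: true coverage >= 95% for every p."""
        n = 40
        intervals = [fd.clopper_pearson(k, n) for k in range(n + 1)]
        for p in np.arange(0.1, 0.95, 0.1):
            cover = sum(
                sps.binom.pmf(k, n, p)
                for k, (lo, hi) in enumerate(intervals)
                if lo <= p <= hi
            )
            assert cover >= 0.95 - 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fd.clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            fd.clopper_pearson(5, 3)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert fd.cohen_kappa(ConfusionTable(50, 0, 0, 50)) == 1.0

    def test_chance_level(self):
        assert fd.cohen_kappa(ConfusionTable(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # p_o = 0.8, p_e = 0.7*0.7 + 0.3*0.3 = 0.58 -> kappa = 0.22/0.42
        assert fd.cohen_kappa(ConfusionTable(60, 10, 10, 20)) == pytest.approx(0.22 / 0.42)

    @given(st.tuples(*[st.integers(0, 40)] * 4).filter(lambda t: sum(t) > 0))
    def test_rater_swap_invariance(self, cells):
        t = ConfusionTable(*cells)
        try:
            k1 = fd.cohen_kappa(t)
        except ValueError:
            return  # degenerate p_e = 1 case
        assert fd.cohen_kappa(t.transpose()) == pytest.approx(k1, abs=1e-12)

    def test_matches_sklearn_oracle(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 2, 50)
            b = np.where(rng.random(50) < 0.7, a, rng.integers(0, 2, 50))
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            table = ConfusionTable.from_calls(b == 1, a == 1)
            assert fd.cohen_kappa(table) == pytest.approx(
                sk.cohen_kappa_score(a, b), abs=1e-12
            )

    def test_degenerate_unanimous_agreement(self):
        # both raters always positive (or always negative): kappa = 1
        assert fd.cohen_kappa(ConfusionTable(5, 0, 0, 0)) == 1.0
        assert fd.cohen_kappa(ConfusionTable(0, 0, 0, 5)) == 1.0


class TestMcNemar:
    def test_symmetric_counts_give_one(self):
        assert fd.mcnemar(7, 7) == 1.0

    def test_closed_form_tail(self):
        assert fd.mcnemar(0, 8) == pytest.approx(2 * 0.5**8, abs=1e-15)

    def test_matches_enumeration_oracle(self):
        for b in range(0, 13):
            for c in range(0, 13 - b):
                assert fd.mcnemar(b, c) == pytest.approx(
                    mcnemar_enumeration_oracle(b, c), abs=1e-12
                )

    def test_matches_statsmodels_exact(self):
        contingency = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(1, 5), (3, 9), (0, 8), (10, 4)]:
            table = [[5, b], [c, 5]]
            res = contingency.mcnemar(table, exact=True)
            assert fd.mcnemar(b, c) == pytest.approx(res.pvalue, abs=1e-12)

    @given(st.integers(0, 30), st.integers(0, 30))
    def test_symmetry(self, b, c):
        assert fd.mcnemar(b, c) == fd.mcnemar(c, b)

    def test_no_discordance(self):
        assert fd.mcnemar(0, 0) == 1.0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = fd.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = fd.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 6)
        y = 0.4 * x + rng.normal(0, 1, 6)
        r, _ = fd.pearson_r(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_complete_case_pairing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, np.nan]
        r, _ = fd.pearson_r(x, y)
        r_manual, _ = fd.pearson_r([1, 2, 4], [1.1, 2.2, 4.1])
        assert r == pytest.approx(r_manual)

    def test_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            fd.pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="pairs"):
            fd.pearson_r([1, 2], [3, 4])


class TestRankSum:
    def test_identical_groups(self):
        assert fd.rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        assert fd.rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1.5, 1, 80)
        assert fd.rank_sum_test(a, b) < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fd.rank_sum_test([], [1.0])


class TestSampleSize:
    def test_planning_pair(self):
        spec = SampleSizeSpec(expected_p=0.80, precision=0.10, conf=0.95, prevalence=0.25)
        per_class = fd.sample_size_se_sp(spec)
        assert per_class == 62
        assert fd.total_sample_size(per_class, spec.prevalence) == 248

    def test_worst_case_proportion(self):
        assert fd.sample_size_se_sp(SampleSizeSpec(expected_p=0.5)) == 97

    def test_trivial_cases(self):
        assert fd.sample_size_se_sp(SampleSizeSpec(expected_p=0.5, precision=0.999)) == 1
        assert fd.total_sample_size(62, 0.5) == 124
        assert fd.total_sample_size(1, 0.33) == 4

    @given(st.floats(0.05, 0.5), st.floats(0.05, 0.5))
    def test_monotone_in_precision(self, d1, d2):
        lo, hi = sorted((d1, d2))
        n_hi = fd.sample_size_se_sp(SampleSizeSpec(precision=lo))
        n_lo = fd.sample_size_se_sp(SampleSizeSpec(precision=hi))
        assert n_hi >= n_lo

    @given(st.floats(0.05, 0.95))
    def test_maximized_at_half(self, p):
        n_p = fd.sample_size_se_sp(SampleSizeSpec(expected_p=p))
        n_half = fd.sample_size_se_sp(SampleSizeSpec(expected_p=0.5))
        assert n_half >= n_p


class TestIntraAssayCV:
    def _table(self, groups):
        import pandas as pd

        rows = [
            {"sample_id": sid, "value": v} for sid, vals in groups.items() for v in vals
        ]
        return pd.DataFrame(rows)

    def test_constant_replicates(self):
        summary = fd.intra_assay_cv(self._table({"S1": [10, 10, 10]}))
        assert summary.cv_mean == 0.0

    def test_two_point_cv(self):
        summary = fd.intra_assay_cv(self._table({"S1": [9, 11]}))
        assert summary.cv_mean == pytest.approx(np.sqrt(2) / 10, abs=1e-12)

    def test_mean_cv_mirrors_reporting_style(self):
        # five samples with CVs 4.8..8.2% -> mean 6.2%
        groups = {}
        for i, cv in enumerate([0.048, 0.055, 0.060, 0.065, 0.082]):
            groups[f"S{i}"] = [100 * (1 - cv / np.sqrt(2)), 100 * (1 + cv / np.sqrt(2))]
        summary = fd.intra_assay_cv(self._table(groups))
        assert summary.cv_mean == pytest.approx(0.062, abs=1e-3)
        assert summary.cv_min == pytest.approx(0.048, abs=1e-3)
        assert summary.cv_max == pytest.approx(0.082, abs=1e-3)

    def test_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fd.intra_assay_cv(self._table({"S1": [10]}))
        with pytest.raises(ValueError, match="non-positive"):
            fd.intra_assay_cv(self._table({"S1": [0, 0]}))
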