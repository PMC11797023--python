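"""Exact tests, t-tests, weight ANOVA, and execution-assay analysis.

Exact binomial and Fisher p-values are checked against brute-force
enumeration oracles coded here from the definitions (point-probability
two-sided ordering), independent of scipy.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from sbdrive.core_tables import ExecutionRecord, ParameterError
from sbdrive.stats_tests import (
    anova_weight,
    binomial_test_vs_half,
    execution_assay_analysis,
    fisher_exact_2x2,
    proportion_ci,
    t_test,
)


def binom_pvalue_oracle(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0 = 0.5 by full enumeration."""
    pmf = [comb(n, i) * 0.5**n for i in range(n + 1)]
    observed = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= observed * (1 + 1e-12)))


def fisher_pvalue_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the margins."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def hyper(x: int) -> float:
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    observed = hyper(a)
    return min(
        1.0,
        sum(hyper(x) for x in range(lo, hi + 1) if hyper(x) <= observed * (1 + 1e-12)),
    )


class TestBinomial:
    def test_null_mode_p_is_one(self):
        assert binomial_test_vs_half(5, 10).p_value == pytest.approx(1.0)

    def test_extreme_count_closed_form(self):
        assert binomial_test_vs_half(0, 10).p_value == pytest.approx(2 * 0.5**10)

    def test_frozen_enumeration_value(self):
        # oracle: sum of binomial(12, 0.5) point masses <= P(X = 2)
        assert binom_pvalue_oracle(2, 12) == pytest.approx(0.038574, abs=1e-6)
        assert binomial_test_vs_half(2, 12).p_value == pytest.approx(0.038574, abs=1e-6)

    @pytest.mark.parametrize("k,n", [(0, 1), (3, 7), (8, 20), (10, 20), (17, 19)])
    def test_matches_oracle(self, k, n):
        assert binomial_test_vs_half(k, n).p_value == pytest.approx(
            binom_pvalue_oracle(k, n)
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            binomial_test_vs_half(5, 4)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        # C(10,5) = 252 tables; only the two diagonal ones are as extreme
        assert fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_frozen_enumeration_value(self):
        assert fisher_pvalue_oracle(3, 1, 1, 3) == pytest.approx(0.485714, abs=1e-6)
        assert fisher_exact_2x2([[3, 1], [1, 3]]).p_value == pytest.approx(
            0.485714, abs=1e-6
        )

    @pytest.mark.parametrize(
        "table", [(2, 7, 8, 2), (0, 5, 5, 0), (1, 0, 0, 9), (4, 4, 3, 6)]
    )
    def test_matches_oracle(self, table):
        a, b, c, d = table
        assert fisher_exact_2x2([[a, b], [c, d]]).p_value == pytest.approx(
            fisher_pvalue_oracle(a, b, c, d)
        )

    def test_transposition_invariance(self):
        p1 = fisher_exact_2x2([[2, 7], [8, 2]]).p_value
        p2 = fisher_exact_2x2([[2, 8], [7, 2]]).p_value
        p3 = fisher_exact_2x2([[8, 2], [2, 7]]).p_value
        assert p1 == pytest.approx(p2) == pytest.approx(p3)

    def test_negative_cell_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestTTest:
    def test_identical_groups_no_signal(self):
        res = t_test([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_student_closed_form(self):
        # pooled-variance computation by hand: t = -3, df = 4
        res = t_test([1, 2, 3], [4, 5, 6], variant="student")
        assert res.statistic == pytest.approx(-3.6742, abs=1e-3)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.0213, abs=2e-3)

    def test_welch_df_between_bounds(self):
        res = t_test([1.0, 2.0, 3.0, 4.0], [10.0, 30.0], variant="welch")
        # Satterthwaite df must lie between min(n)-1 and n1+n2-2
        assert 1.0 <= res.df <= 4.0

    def test_tiny_group_rejected(self):
        with pytest.raises(ParameterError):
            t_test([1.0], [2.0, 3.0])

    def test_type_i_error_calibrated(self):
        """No true difference at n = 50 per group: rejection rate ~ 5%."""
        rng = np.random.default_rng(7)
        rejections = sum(
            t_test(rng.normal(size=50), rng.normal(size=50)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


def sequential_anova_oracle(df: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Type-I (sequential) F statistics via explicit least-squares projections."""
    y = df["weight_mg"].to_numpy(dtype=float)

    def design(terms: list[str]) -> np.ndarray:
        cols = [np.ones(len(df))]
        if "colony" in terms:
            cols += [
                (df["colony_id"] == c).to_numpy(float)
                for c in sorted(df["colony_id"].unique())[1:]
            ]
        if "geno" in terms:
            cols += [
                (df["genotype"] == g).to_numpy(float)
                for g in sorted(df["genotype"].unique())[1:]
            ]
        if "inter" in terms:
            for c in sorted(df["colony_id"].unique())[1:]:
                for g in sorted(df["genotype"].unique())[1:]:
                    cols.append(
                        ((df["colony_id"] == c) & (df["genotype"] == g)).to_numpy(float)
                    )
        return np.column_stack(cols)

    def rss(X: np.ndarray) -> tuple[float, int]:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rank = np.linalg.matrix_rank(X)
        return float(resid @ resid), rank

    rss0, rk0 = rss(design([]))
    rss1, rk1 = rss(design(["colony"]))
    rss2, rk2 = rss(design(["colony", "geno"]))
    rss3, rk3 = rss(design(["colony", "geno", "inter"]))
    df_resid = len(df) - rk3
    mse = rss3 / df_resid
    return {
        "colony": ((rss0 - rss1) / (rk1 - rk0) / mse, rk1 - rk0),
        "haplotype": ((rss1 - rss2) / (rk2 - rk1) / mse, rk2 - rk1),
        "interaction": ((rss2 - rss3) / (rk3 - rk2) / mse, rk3 - rk2),
    }


class TestAnova:
    def _synthetic(self, colony_effects, hap_effect, n_per_cell=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for c, eff in enumerate(colony_effects):
            for g, shift in (("SB", hap_effect), ("Sb", 0.0)):
                for _ in range(n_per_cell):
                    rows.append(
                        {
                            "colony_id": f"c{c}",
                            "genotype": g,
                            "weight_mg": 6.5 + eff + shift + rng.normal(0, 0.3),
                        }
                    )
        return pd.DataFrame(rows)

    def test_equal_weights_degenerate(self):
        df = self._synthetic([0, 0], 0.0)
        df["weight_mg"] = 6.5
        res = anova_weight(df, colony_filter=None)
        assert res["colony"].statistic == 0.0
        assert res["haplotype"].p_value == 1.0

    def test_matches_least_squares_oracle(self):
        df = self._synthetic([0.0, 0.4, -0.3, 0.8], 0.9, seed=3)
        res = anova_weight(df, colony_filter=None)
        oracle = sequential_anova_oracle(df)
        for term in ("colony", "haplotype", "interaction"):
            f_o, df_o = oracle[term]
            assert res[term].statistic == pytest.approx(f_o, rel=1e-6)
            assert res[term].df[0] == df_o

    def test_colony_only_effect_keeps_haplotype_null(self):
        """Colony effects but no haplotype effect: haplotype term should be
        non-significant in the clear majority of simulations."""
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            df = self._synthetic([0.0, 0.6, -0.6], 0.0, n_per_cell=5, seed=seed)
            res = anova_weight(df, colony_filter=None)
            rejections += res["haplotype"].p_value < 0.05
        assert rejections / n_sims < 0.1

    def test_default_filter_drops_single_haplotype_colonies(self):
        df = self._synthetic([0.0, 0.2, -0.2], 0.5, seed=1)
        df = df[(df["colony_id"] != "c0") | (df["genotype"] == "SB")]
        res = anova_weight(df)
        assert res["colony"].df[0] == 1  # c0 excluded, 2 colonies remain

    def test_too_few_colonies_rejected(self):
        df = self._synthetic([0.0], 0.5)
        with pytest.raises(ParameterError):
            anova_weight(df, colony_filter=None)


class TestProportionCI:
    def test_zero_successes_lower_bound_zero(self):
        ci = proportion_ci(0, 10)
        assert ci.ci_low == 0.0
        assert ci.p_hat == 0.0

    def test_wilson_closed_form(self):
        # Wilson score interval for 14/26 at 95%
        ci = proportion_ci(14, 26)
        assert ci.ci_low == pytest.approx(0.355, abs=5e-3)
        assert ci.ci_high == pytest.approx(0.712, abs=5e-3)

    def test_wilson_symmetric_at_half(self):
        ci = proportion_ci(5, 10)
        assert ci.ci_low + ci.ci_high == pytest.approx(1.0)

    def test_interval_contains_point(self):
        for k, n in [(1, 50), (25, 50), (49, 50)]:
            for method in ("wilson", "clopper_pearson", "bootstrap"):
                ci = proportion_ci(k, n, method=method)
                assert ci.ci_low <= ci.p_hat <= ci.ci_high

    def test_wilson_coverage_calibrated(self):
        """Empirical 95% coverage within [0.93, 0.97] at p in {0.1, 0.5}."""
        rng = np.random.default_rng(11)
        from statsmodels.stats.proportion import proportion_confint

        for p in (0.1, 0.5):
            ks = rng.binomial(100, p, size=10_000)
            lo, hi = proportion_confint(ks, 100, alpha=0.05, method="wilson")
            coverage = np.mean((lo <= p) & (p <= hi))
            assert 0.93 <= coverage <= 0.97


def _exec(form, genotype, executed, i):
    return ExecutionRecord(
        male_id=f"{form}{i}",
        colony_id="c1",
        social_form=form,
        ploidy_genotype=genotype,
        executed=executed,
    )


class TestExecutionAssay:
    def _records(self, rng, p_mono=0.01, p_poly=0.4, n=100):
        recs = []
        for i in range(n):
            recs.append(_exec("monogyne", "SB", rng.random() < p_mono, i))
            geno = ["SB", "Sb", "SB/Sb", "Sb/Sb"][i % 4]
            recs.append(_exec("polygyne", geno, rng.random() < p_poly, n + i))
        return recs

    def test_form_contrast_detects_difference(self):
        """Monogyne 1% vs polygyne 40% execution at n = 100 each:
        the form contrast is significant in >= 95% of 200 simulations."""
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(200):
            report = execution_assay_analysis(self._records(rng))
            hits += report.contrasts["form"].p_value < 0.001
        assert hits / 200 >= 0.95

    def test_all_zero_executions_uninformative(self):
        recs = [
            _exec("monogyne", "SB", False, 1),
            _exec("polygyne", "Sb", False, 2),
            _exec("polygyne", "SB/Sb", False, 3),
            _exec("polygyne", "Sb/Sb", False, 4),
        ]
        report = execution_assay_analysis(recs)
        assert all(r.p_value == 1.0 for r in report.contrasts.values())

    def test_empty_group_skips_contrast_only(self):
        recs = [
            _exec("polygyne", "SB", True, 1),
            _exec("polygyne", "Sb", False, 2),
            _exec("polygyne", "Sb", True, 3),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            report = execution_assay_analysis(recs)
        assert "form" in report.skipped
        assert "haplotype_among_haploids" in report.contrasts
        assert report.proportions["polygyne_haploid"].n == 3
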