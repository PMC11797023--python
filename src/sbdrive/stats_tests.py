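"""The study's statistical test battery on classified data.

Exact binomial tests of haplotype counts against the Mendelian 50:50
expectation, Fisher's exact 2×2 comparisons (two-sided by point-probability
ordering), t-tests of weight differences, a sequential two-way ANOVA of
weight on colony and haplotype, and execution-assay proportions with
Wilson-score confidence intervals.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.proportion import proportion_confint

from .core_tables import ExecutionRecord, ParameterError

__all__ = [
    "TestResult",
    "ProportionCI",
    "ExecutionAssayReport",
    "binomial_test_vs_half",
    "fisher_exact_2x2",
    "t_test",
    "anova_weight",
    "proportion_ci",
    "execution_assay_analysis",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    alternative: str = "two_sided"
    inputs_digest: str = ""


@dataclass(frozen=True)
class ProportionCI:
    successes: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    method: str = "wilson"


def binomial_test_vs_half(k: int, n: int) -> TestResult:
    """Exact two-sided binomial test of k successes in n against p = 0.5.

    Two-sided by summing all outcome probabilities not exceeding that of
    the observed count; under the symmetric null this is the usual doubled
    tail (capped at 1).
    """
    if not (0 <= k <= n) or n < 1:
        raise ParameterError(f"invalid binomial data k={k}, n={n}")
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return TestResult(
        test_name="binomial_vs_half",
        statistic=float(k),
        p_value=float(res.pvalue),
        df=None,
        inputs_digest=f"k={k},n={n}",
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test of independence for a 2×2 count table.

    Two-sided p-value sums hypergeometric probabilities (margins fixed) of
    all tables whose point probability does not exceed the observed one.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ParameterError(f"table must be 2x2, got shape {arr.shape}")
    if (arr < 0).any():
        raise ParameterError("table cells must be non-negative")
    if arr.sum() == 0:
        raise ParameterError("table has no observations")
    odds, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return TestResult(
        test_name="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        df=None,
        inputs_digest=f"table={arr.astype(int).tolist()}",
    )


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
) -> TestResult:
    """Two-sided t-test of a mean difference (Welch default, Student optional)."""
    if variant not in ("welch", "student"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("A", a), ("B", b)):
        if g.size < 2:
            raise ParameterError(f"group {name} needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        # both groups constant and equal: no evidence of a difference
        return TestResult(
            test_name=f"t_{variant}", statistic=0.0, p_value=1.0,
            df=float(a.size + b.size - 2), inputs_digest=f"nA={a.size},nB={b.size}",
        )
    if variant == "student":
        t, p = stats.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = float(
            (va + vb) ** 2
            / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        )
    return TestResult(
        test_name=f"t_{variant}",
        statistic=float(t),
        p_value=float(p),
        df=df,
        inputs_digest=f"nA={a.size},nB={b.size}",
    )


def default_colony_filter(df: pd.DataFrame) -> pd.Series:
    """Keep colonies with >= 2 haploid males including both haplotypes."""
    ok = (
        df.groupby("colony_id")["genotype"]
        .agg(lambda g: len(g) >= 2 and g.nunique() == 2)
    )
    return df["colony_id"].map(ok)


def anova_weight(
    data: pd.DataFrame,
    colony_filter=default_colony_filter,
) -> dict[str, TestResult]:
    """Sequential two-way ANOVA of weight on colony and supergene haplotype.

    ``data`` needs columns ``weight_mg``, ``colony_id``, ``genotype``
    (haploid SB/Sb). Type-I sums of squares with colony entered first, then
    haplotype, then their interaction. ``colony_filter`` selects which
    colonies enter the model (default: colonies holding >= 2 haploid males
    of both haplotypes); the realized dfs are in the returned results.
    """
    required = {"weight_mg", "colony_id", "genotype"}
    if not required <= set(data.columns):
        raise ParameterError(f"data needs columns {sorted(required)}")
    df = data.loc[colony_filter(data)].copy() if colony_filter else data.copy()
    if df["colony_id"].nunique() < 2:
        raise ParameterError("ANOVA needs >= 2 colonies after filtering")
    if df["genotype"].nunique() < 2:
        raise ParameterError("ANOVA needs both haplotypes after filtering")
    total_ss = float(((df["weight_mg"] - df["weight_mg"].mean()) ** 2).sum())
    if total_ss == 0:
        zero = dict(statistic=0.0, p_value=1.0)
        return {
            "colony": TestResult("anova_colony", df=(df["colony_id"].nunique() - 1, 0), **zero),
            "haplotype": TestResult("anova_haplotype", df=(1, 0), **zero),
            "interaction": TestResult("anova_interaction", df=(0, 0), **zero),
        }
    model = ols("weight_mg ~ C(colony_id) + C(genotype) + C(colony_id):C(genotype)", df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unbalanced designs emit benign warnings
        table = anova_lm(model, typ=1)
    resid_df = float(table.loc["Residual", "df"])

    def _row(label: str, name: str) -> TestResult:
        row = table.loc[label]
        f = float(row["F"]) if np.isfinite(row["F"]) else 0.0
        p = float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else 1.0
        return TestResult(
            test_name=name,
            statistic=f,
            p_value=p,
            df=(float(row["df"]), resid_df),
            inputs_digest=f"n={len(df)},colonies={df['colony_id'].nunique()}",
        )

    return {
        "colony": _row("C(colony_id)", "anova_colony"),
        "haplotype": _row("C(genotype)", "anova_haplotype"),
        "interaction": _row("C(colony_id):C(genotype)", "anova_interaction"),
    }


def proportion_ci(
    successes: int, n: int, method: str = "wilson", ci_level: float = 0.95
) -> ProportionCI:
    """Binomial proportion with a 95% CI (Wilson score by default)."""
    if n < 1 or not (0 <= successes <= n):
        raise ParameterError(f"invalid proportion data k={successes}, n={n}")
    if method not in ("wilson", "clopper_pearson", "bootstrap"):
        raise ParameterError(f"unknown CI method {method!r}")
    alpha = 1.0 - ci_level
    if method == "bootstrap":
        rng = np.random.default_rng(0)
        boot = rng.binomial(n, successes / n, size=5000) / n
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    else:
        sm_method = "wilson" if method == "wilson" else "beta"
        lo, hi = proportion_confint(successes, n, alpha=alpha, method=sm_method)
    return ProportionCI(
        successes=successes,
        n=n,
        p_hat=successes / n,
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
    )


@dataclass
class ExecutionAssayReport:
    """Execution proportions per group plus the four planned contrasts."""

    proportions: dict[str, ProportionCI]
    contrasts: dict[str, TestResult]
    skipped: list[str]


def _counts(records: list[ExecutionRecord]) -> tuple[int, int]:
    return sum(r.executed for r in records), len(records)


def execution_assay_analysis(
    records: Sequence[ExecutionRecord],
    ci_method: str = "wilson",
) -> ExecutionAssayReport:
    """Analyse an execution-assay outcome table.

    Reports per-group execution proportions with CIs and Fisher's exact
    tests for the planned contrasts: monogyne vs polygyne; haploid vs
    diploid within polygyne; SB vs Sb among polygyne haploids; SB/Sb vs
    Sb/Sb among polygyne diploids. A contrast with an empty group is
    skipped with a warning rather than failing the run.
    """
    recs = list(records)
    groups: dict[str, list[ExecutionRecord]] = {
        "monogyne": [r for r in recs if r.social_form == "monogyne"],
        "polygyne": [r for r in recs if r.social_form == "polygyne"],
    }
    poly = groups["polygyne"]
    groups["polygyne_haploid"] = [r for r in poly if r.is_haploid]
    groups["polygyne_diploid"] = [r for r in poly if not r.is_haploid]
    for g in ("SB", "Sb", "SB/Sb", "Sb/Sb", "SB/SB"):
        groups[f"polygyne_{g}"] = [r for r in poly if r.ploidy_genotype == g]

    proportions = {
        name: proportion_ci(*_counts(members), method=ci_method)
        for name, members in groups.items()
        if members
    }

    planned = {
        "form": ("monogyne", "polygyne"),
        "ploidy_within_polygyne": ("polygyne_haploid", "polygyne_diploid"),
        "haplotype_among_haploids": ("polygyne_SB", "polygyne_Sb"),
        "genotype_among_diploids": ("polygyne_SB/Sb", "polygyne_Sb/Sb"),
    }
    contrasts: dict[str, TestResult] = {}
    skipped: list[str] = []
    for name, (ga, gb) in planned.items():
        if not groups.get(ga) or not groups.get(gb):
            skipped.append(name)
            warnings.warn(f"execution contrast {name!r} skipped: empty group")
            continue
        ka, na = _counts(groups[ga])
        kb, nb = _counts(groups[gb])
        contrasts[name] = fisher_exact_2x2([[ka, na - ka], [kb, nb - kb]])
    return ExecutionAssayReport(
        proportions=proportions, contrasts=contrasts, skipped=skipped
    )
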