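"""Pooled vs colony-weighted estimation of frequencies and weights."""

from __future__ import annotations

import numpy as np
import pytest

from sbdrive.core_tables import ParameterError, Stage
from sbdrive.frequency_resampling import (
    colony_resampled_frequency,
    colony_resampled_weight,
    pooled_frequency,
    resampled_weight_difference,
)
from sbdrive.ploidy_classifier import PloidyCall


def hap_call(male_id, colony, genotype, weight=6.0, stage=Stage.ADULT):
    return PloidyCall(
        male_id=male_id,
        colony_id=colony,
        stage=stage,
        weight_mg=weight,
        ploidy="haploid",
        supergene_genotype=genotype,
        n_heterozygous_loci=0,
        confirmed_by_microsats=True,
    )


def colony_calls(spec: dict[str, tuple[int, int]], stage=Stage.ADULT):
    """spec: colony -> (n_SB, n_Sb)."""
    calls = []
    for colony, (n_sb_big, n_sb_small) in spec.items():
        for i in range(n_sb_big):
            calls.append(hap_call(f"{colony}:SB{i}", colony, "SB", stage=stage))
        for i in range(n_sb_small):
            calls.append(hap_call(f"{colony}:Sb{i}", colony, "Sb", stage=stage))
    return calls


class TestPooledFrequency:
    def test_simple_proportion(self):
        calls = colony_calls({"A": (3, 1)})
        est = pooled_frequency(calls, "SB", Stage.ADULT, seed=1)
        assert est.point == pytest.approx(0.75)
        assert est.n_units == 4

    def test_degenerate_all_one_haplotype(self):
        calls = colony_calls({"A": (0, 5)})
        est = pooled_frequency(calls, "SB", Stage.ADULT, seed=1)
        assert est.point == 0.0
        assert (est.ci_low, est.ci_high) == (0.0, 0.0)

    def test_no_haploids_rejected(self):
        with pytest.raises(ParameterError):
            pooled_frequency([], "SB", Stage.ADULT)

    def test_ci_brackets_point_and_seed_reproducible(self):
        calls = colony_calls({"A": (30, 10), "B": (5, 25)})
        a = pooled_frequency(calls, "SB", Stage.ADULT, seed=9)
        b = pooled_frequency(calls, "SB", Stage.ADULT, seed=9)
        assert a.ci_low <= a.point <= a.ci_high
        assert (a.point, a.ci_low, a.ci_high) == (b.point, b.ci_low, b.ci_high)


class TestColonyResampledFrequency:
    def test_all_sb_colonies_give_one(self):
        calls = colony_calls({"A": (3, 0), "B": (7, 0)})
        est = colony_resampled_frequency(calls, "SB", Stage.ADULT, seed=0)
        assert est.point == 1.0
        assert np.all(est.replicates == 1.0)

    def test_equal_colony_weight_contract(self):
        """100 SB males in one colony vs a single Sb male in another: every
        replicate draws one male from each, so the colony-weighted value is
        exactly 0.5 while the pooled estimate sits near 0.99."""
        calls = colony_calls({"A": (100, 0), "B": (0, 1)})
        est = colony_resampled_frequency(calls, "SB", Stage.ADULT, seed=3)
        assert np.all(est.replicates == 0.5)
        assert est.point == pytest.approx(0.5)
        pooled = pooled_frequency(calls, "SB", Stage.ADULT, seed=3)
        assert pooled.point == pytest.approx(100 / 101)

    def test_expectation_is_mean_of_colony_frequencies(self):
        """Known per-colony SB fractions: the estimator targets their
        unweighted mean, not the male-weighted pooled value."""
        spec = {"A": (8, 2), "B": (1, 9), "C": (5, 5), "D": (2, 18)}
        f_c = np.array([0.8, 0.1, 0.5, 0.1])
        calls = colony_calls(spec)
        est = colony_resampled_frequency(
            calls, "SB", Stage.ADULT, n_reps=2000, seed=5
        )
        # SE of the replicate mean: one Bernoulli(f_c) draw per colony per rep
        mc_se = np.sqrt(np.sum(f_c * (1 - f_c)) / len(f_c) ** 2 / 2000)
        assert abs(est.point - f_c.mean()) < 3 * mc_se

    def test_duplicating_a_colony_moves_pooled_not_resampled(self):
        """Equal-colony-weight property on a fixed dataset: duplicating all
        males of one colony leaves every replicate distribution unchanged
        (same eligible colonies, same within-colony frequencies)."""
        base = {"A": (9, 1), "B": (2, 8), "C": (4, 4)}
        dup = {"A": (18, 2), "B": (2, 8), "C": (4, 4)}
        est = colony_resampled_frequency(
            colony_calls(base), "SB", Stage.ADULT, n_reps=4000, seed=21
        )
        est_dup = colony_resampled_frequency(
            colony_calls(dup), "SB", Stage.ADULT, n_reps=4000, seed=22
        )
        # both points estimate mean(f_c) with SE < 0.005 at 4000 reps
        assert abs(est.point - est_dup.point) < 0.02
        pooled = pooled_frequency(colony_calls(base), "SB", Stage.ADULT, seed=1)
        pooled_dup = pooled_frequency(colony_calls(dup), "SB", Stage.ADULT, seed=1)
        assert abs(pooled.point - pooled_dup.point) > 0.02

    def test_sb_and_sb_small_are_complementary(self):
        calls = colony_calls({"A": (8, 2), "B": (1, 9), "C": (5, 5)})
        for fn, kwargs in (
            (pooled_frequency, {}),
            (colony_resampled_frequency, {}),
        ):
            big = fn(calls, "SB", Stage.ADULT, seed=2, **kwargs)
            small = fn(calls, "Sb", Stage.ADULT, seed=2, **kwargs)
            assert big.point + small.point == pytest.approx(1.0)

    def test_single_colony_rejected(self):
        with pytest.raises(ParameterError, match="colonies"):
            colony_resampled_frequency(colony_calls({"A": (3, 3)}), "SB", Stage.ADULT)

    def test_percentile_ci_always_available(self):
        calls = colony_calls({"A": (8, 2), "B": (1, 9), "C": (5, 5)})
        est = colony_resampled_frequency(calls, "SB", Stage.ADULT, seed=2)
        lo, hi = est.percentile_ci
        assert lo <= est.point <= hi

    def test_identical_seed_identical_stream(self):
        calls = colony_calls({"A": (8, 2), "B": (1, 9)})
        a = colony_resampled_frequency(calls, "SB", Stage.ADULT, seed=13)
        b = colony_resampled_frequency(calls, "SB", Stage.ADULT, seed=13)
        assert np.array_equal(a.replicates, b.replicates)


class TestColonyResampledWeight:
    def _weight_calls(self, colony_weights: dict[str, list[float]], genotype="SB"):
        return [
            hap_call(f"{c}:{i}", c, genotype, weight=w)
            for c, ws in colony_weights.items()
            for i, w in enumerate(ws)
        ]

    def test_constant_weights_zero_width(self):
        calls = self._weight_calls({"A": [6.5, 6.5], "B": [6.5]})
        est = colony_resampled_weight(calls, "SB", seed=1)
        assert est.point == pytest.approx(6.5)
        assert est.ci_low == est.ci_high == pytest.approx(6.5)

    def test_two_constant_colonies_average(self):
        calls = self._weight_calls({"A": [6.0, 6.0, 6.0], "B": [8.0]})
        est = colony_resampled_weight(calls, "SB", seed=1)
        assert np.all(est.replicates == 7.0)

    def test_eligibility_is_per_haplotype(self):
        calls = self._weight_calls({"A": [6.0], "B": [6.2]}, "Sb") + self._weight_calls(
            {"C": [7.0]}, "SB"
        )
        est = colony_resampled_weight(calls, "Sb", seed=1)
        assert est.n_units == 2
        with pytest.raises(ParameterError, match="SB"):
            colony_resampled_weight(calls, "SB", seed=1)


class TestWeightDifference:
    def test_identical_streams_fraction_half(self):
        rng = np.random.default_rng(0)
        a = rng.normal(7, 0.1, size=5000)
        b = rng.normal(7, 0.1, size=5000)
        res = resampled_weight_difference(a, b)
        assert abs(res.fraction_nonpositive - 0.5) < 0.03

    def test_fully_separated_reports_floor(self):
        a = np.full(500, 7.0)
        b = np.full(500, 6.0)
        res = resampled_weight_difference(a, b)
        assert res.fraction_nonpositive == 0.0
        assert res.p_value == pytest.approx(1 / 500)
        assert res.p_is_upper_bound

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            resampled_weight_difference(np.ones(10), np.ones(9))

    def test_simulated_gap_detected(self):
        """1.0 mg true gap with 0.5 mg residual SD across 10 colonies:
        the replicate-overlap fraction stays below 0.01."""
        rng = np.random.default_rng(42)
        heavy = {f"c{i}": list(7.0 + rng.normal(0, 0.5, 5)) for i in range(10)}
        light = {f"c{i}": list(6.0 + rng.normal(0, 0.5, 5)) for i in range(10)}
        calls = [
            hap_call(f"H{c}:{i}", c, "SB", weight=w)
            for c, ws in heavy.items()
            for i, w in enumerate(ws)
        ] + [
            hap_call(f"L{c}:{i}", c, "Sb", weight=w)
            for c, ws in light.items()
            for i, w in enumerate(ws)
        ]
        est_heavy = colony_resampled_weight(calls, "SB", n_reps=500, seed=1)
        est_light = colony_resampled_weight(calls, "Sb", n_reps=500, seed=2)
        res = resampled_weight_difference(est_heavy, est_light)
        assert res.p_value <= 0.01
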