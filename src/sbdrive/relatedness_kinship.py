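"""Nestmate relatedness of haploid males and effective queen number.

Pairwise relatedness between two haploid multilocus genotypes is the
identity-in-state moment estimator

    r = sum_l (s_l - h_l) / sum_l (1 - h_l)

where ``s_l`` indicates allele identity at locus ``l`` and
``h_l = sum_a p_{l,a}^2`` is the expected identity of two random alleles in
a reference (base) population. Brothers (sons of one singly-mated queen)
have pedigree relatedness 0.5 under male haploidy, and unrelated pairs have
expectation 0, so the population mean over nestmate pairs measures how many
queens effectively contribute a colony's males: with n_e equally
contributing unrelated queens the expectation is 0.5 / n_e, inverted by
:func:`effective_queen_number`.

Population relatedness averages colony values equally (one value per
colony), with a percentile bootstrap over colonies for the CI, mirroring
the colony-equalizing logic of the frequency estimators.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core_tables import AlleleFreqTable, ParameterError, Stage
from .ploidy_classifier import PloidyCall

__all__ = [
    "RelatednessResult",
    "EffectiveQueenEstimate",
    "pairwise_relatedness",
    "colony_and_population_relatedness",
    "bootstrap_difference_test",
    "effective_queen_number",
    "haploid_genotypes_by_colony",
]

HaploidGenotype = Mapping[str, str]  # locus -> single allele label


@dataclass
class RelatednessResult:
    """Relatedness at colony or population scope.

    ``r`` may be negative (pairs sharing fewer alleles than two random
    reference genomes). The population value is the unweighted mean of
    colony values; its CI is a percentile bootstrap over colonies.
    """

    scope: str  # "colony" | "population"
    stage: str
    r: float
    n_pairs: int
    n_colonies: int = 1
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int = 0
    colony_values: dict[str, float] | None = None


@dataclass(frozen=True)
class EffectiveQueenEstimate:
    """Number of equally contributing, unrelated queens explaining observed r.

    Assumes nestmate queens are unrelated to each other and their mates are
    unrelated, so nestmate relatedness is sibling relatedness diluted by the
    number of contributing matrilines: n_e = sibling_r / r.
    """

    n_e: float
    r_input: float
    sibling_r: float = 0.5


def _locus_terms(
    g1: HaploidGenotype, g2: HaploidGenotype, ref: AlleleFreqTable
) -> tuple[float, float]:
    if set(g1) != set(g2):
        raise ParameterError("genotypes cover different locus sets")
    numer = 0.0
    denom = 0.0
    for locus in g1:
        h = ref.expected_homozygosity(locus)
        s = 1.0 if g1[locus] == g2[locus] else 0.0
        numer += s - h
        denom += 1.0 - h
    return numer, denom


def pairwise_relatedness(
    g1: HaploidGenotype, g2: HaploidGenotype, ref: AlleleFreqTable
) -> float:
    """Moment-estimator relatedness between two haploid genotypes.

    Symmetric in its arguments; equals 1 iff the genotypes are identical
    (provided some locus is informative, i.e. h_l < 1).
    """
    numer, denom = _locus_terms(g1, g2, ref)
    if denom <= 0:
        raise ParameterError(
            "all loci have expected identity 1; relatedness undefined"
        )
    return numer / denom


def haploid_genotypes_by_colony(
    calls: Sequence[PloidyCall],
    records_genotypes: Mapping[str, Mapping[str, tuple[str, str]]],
    stage: Stage | str | None = None,
) -> dict[str, list[HaploidGenotype]]:
    """Collect single-allele genotypes of confirmed haploids per colony.

    ``records_genotypes`` maps male_id to the observed two-label genotype;
    haploid observations have equal labels, collapsed here to one allele.
    """
    stage_val = Stage(stage).value if stage is not None else None
    out: dict[str, list[HaploidGenotype]] = {}
    for c in calls:
        if not c.is_haploid or (stage_val is not None and c.stage.value != stage_val):
            continue
        pairs = records_genotypes[c.male_id]
        out.setdefault(c.colony_id, []).append(
            {locus: pair[0] for locus, pair in pairs.items()}
        )
    return out


def _colony_mean_r(
    genotypes: Sequence[HaploidGenotype], ref: AlleleFreqTable
) -> tuple[float, int]:
    """Mean pairwise relatedness over all within-colony pairs.

    The denominator of the estimator is constant across pairs, so the
    colony mean reduces to (mean pair match count − Σh) / Σ(1−h); the match
    counts are accumulated per locus from allele tallies.
    """
    n = len(genotypes)
    n_pairs = n * (n - 1) // 2
    if n_pairs == 0:
        raise ParameterError("colony needs >= 2 haploid genotypes")
    loci = list(genotypes[0])
    h = np.array([ref.expected_homozygosity(locus) for locus in loci])
    denom = float(np.sum(1.0 - h))
    if denom <= 0:
        raise ParameterError("all loci uninformative; relatedness undefined")
    total_matches = 0.0
    for locus in loci:
        tally: dict[str, int] = {}
        for g in genotypes:
            tally[g[locus]] = tally.get(g[locus], 0) + 1
        total_matches += sum(k * (k - 1) / 2 for k in tally.values())
    mean_matches = total_matches / n_pairs
    r = (mean_matches - float(h.sum())) / denom
    return r, n_pairs


def colony_and_population_relatedness(
    genotypes_by_colony: Mapping[str, Sequence[HaploidGenotype]],
    ref: AlleleFreqTable,
    stage: Stage | str = Stage.ADULT,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> RelatednessResult:
    """Per-colony mean relatedness and its colony-equal population average.

    Colonies with fewer than two haploid males contribute no pairs and are
    excluded. The CI resamples colony values with replacement ``n_boot``
    times and takes percentile bounds.
    """
    colony_values: dict[str, float] = {}
    total_pairs = 0
    for colony, genos in genotypes_by_colony.items():
        if len(genos) < 2:
            continue
        r, n_pairs = _colony_mean_r(list(genos), ref)
        colony_values[colony] = r
        total_pairs += n_pairs
    if not colony_values:
        raise ParameterError("no colony with >= 2 haploid males of this stage")
    values = np.array(list(colony_values.values()))
    rng = np.random.default_rng(seed)
    boot = values[rng.integers(0, len(values), size=(n_boot, len(values)))].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return RelatednessResult(
        scope="population",
        stage=Stage(stage).value,
        r=float(values.mean()),
        n_pairs=total_pairs,
        n_colonies=len(values),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        colony_values=colony_values,
    )


def bootstrap_difference_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_iter: int = 5000,
    seed: int = 0,
) -> float:
    """Two-sided bootstrap test for a difference in group means.

    Resamples each group's (single-colony) values with replacement
    ``n_iter`` times; p = 2·min(frac(diff ≤ 0), frac(diff ≥ 0)), clipped to
    [2/n_iter, 1].
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    mean_a = a[rng.integers(0, a.size, size=(n_iter, a.size))].mean(axis=1)
    mean_b = b[rng.integers(0, b.size, size=(n_iter, b.size))].mean(axis=1)
    diff = mean_a - mean_b
    p = 2.0 * min(float(np.mean(diff <= 0)), float(np.mean(diff >= 0)))
    return float(np.clip(p, 2.0 / n_iter, 1.0))


def effective_queen_number(r: float, sibling_r: float = 0.5) -> EffectiveQueenEstimate:
    """Effective queen number from nestmate haploid relatedness.

    With unrelated, equally contributing queens whose mates are also
    unrelated, nestmate male relatedness is sibling_r / n_e; solving for
    n_e gives sibling_r / r. Brothers under male haploidy have
    sibling_r = 0.5.
    """
    if not (0 < r <= 1):
        raise ParameterError(f"relatedness must be in (0, 1], got {r}")
    if not (0 < sibling_r <= 1):
        raise ParameterError(f"sibling relatedness must be in (0, 1], got {sibling_r}")
    return EffectiveQueenEstimate(n_e=sibling_r / r, r_input=r, sibling_r=sibling_r)
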