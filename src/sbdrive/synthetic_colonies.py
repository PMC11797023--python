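"""Forward simulator of the polygyne fire-ant breeding system.

Generates male tables with known ground truth that reproduce the statistical
structure the downstream analysis assumes:

* every reproductive queen in a polygyne colony is an SB/Sb heterozygote;
* fertile (haploid) males develop from unfertilized eggs and carry one of
  the queen's two supergene haplotypes, with a tunable transmission
  distortion ``distortion_delta`` = P(haploid egg carries Sb);
* sterile diploid males arise from matched matings under single-locus
  complementary sex determination, and dominate the male pool (80–95%);
* colonies differ enormously in haploid male production (many produce none,
  a few produce most), modelled by a zero-inflated negative binomial;
* male weight = genotype-group mean + a colony random effect + residual
  noise, with haploid Sb males lighter than haploid SB males and diploids
  heavier still;
* the weight-threshold sampling design: every male below the threshold is
  kept, heavier males are capped per weight bin.

Microsatellite genotypes are drawn through an explicit pedigree (queens and
mates drawn from reference allele frequencies, sons inheriting maternal —
and for diploids also paternal — alleles), so nestmate haploid relatedness
has the pedigree expectation 0.5 / (number of queens).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .core_tables import (
    BAND_SB,
    BAND_Sb,
    DEFAULT_PANEL,
    AlleleFreqTable,
    ExecutionRecord,
    MaleRecord,
    ParameterError,
    Stage,
)

__all__ = [
    "QueenNumberModel",
    "MaleCountModel",
    "WeightModel",
    "SamplingDesign",
    "SimParams",
    "default_allele_freqs",
    "default_execution_probs",
    "simulate_population",
    "simulate_gp9_assay",
    "apply_sampling_design",
    "simulate_execution_assay",
    "execution_group",
]

# Allele-frequency profile for one amply polymorphic microsatellite locus.
# Expected homozygosity sum(p^2) = 0.2698, so a 4-locus panel gives a
# false-haploid probability of 0.2698^4 ≈ 0.0053 — the ~0.5% regime the
# marker panel was chosen to achieve.
_LOCUS_PROFILE = (0.45, 0.20, 0.12, 0.08, 0.06, 0.04, 0.03, 0.02)


def default_allele_freqs(panel: Sequence[str] = DEFAULT_PANEL) -> AlleleFreqTable:
    """Reference allele frequencies for the default 4-locus panel."""
    loci = {
        locus: {f"{locus}_{i + 1:02d}": p for i, p in enumerate(_LOCUS_PROFILE)}
        for locus in panel
    }
    table = AlleleFreqTable(loci)
    table.validate()
    return table


@dataclass(frozen=True)
class QueenNumberModel:
    """Queens per colony: 1 + Poisson(mean - 1), so every colony has >= 1.

    With ``fixed=True`` every colony gets exactly ``round(mean)`` queens
    (useful for pedigree-expectation checks, where nestmate relatedness is
    0.5 / q only when q does not vary between colonies).
    """

    mean: float = 3.0
    fixed: bool = False

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean < 1:
            raise ParameterError(f"queen number mean must be >= 1, got {self.mean}")
        if self.fixed:
            return np.full(n, int(round(self.mean)), dtype=int)
        return 1 + rng.poisson(self.mean - 1.0, size=n)


@dataclass(frozen=True)
class MaleCountModel:
    """Haploid males per colony: zero-inflated negative binomial.

    ``zero_prob`` is the probability a colony produces no haploid males at
    all; producing colonies draw from NB with the given mean and dispersion
    (small dispersion = heavy right tail, letting a couple of colonies hold
    a large share of all haploid males).
    """

    zero_prob: float = 0.375
    mean: float = 17.0
    dispersion: float = 0.6

    @property
    def overall_mean(self) -> float:
        return (1.0 - self.zero_prob) * self.mean

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean <= 0:
            raise ParameterError(f"male count mean must be positive, got {self.mean}")
        if not (0 <= self.zero_prob <= 1):
            raise ParameterError(f"zero_prob must be in [0,1], got {self.zero_prob}")
        if self.dispersion <= 0:
            raise ParameterError(f"dispersion must be positive, got {self.dispersion}")
        # numpy's negative_binomial(n, p): mean = n (1-p)/p
        k = self.dispersion
        p = k / (k + self.mean)
        counts = rng.negative_binomial(k, p, size=n)
        counts[rng.random(n) < self.zero_prob] = 0
        return counts


@dataclass(frozen=True)
class WeightModel:
    """Group weight means/SDs in mg, plus colony-effect and residual SDs.

    Haploid group means default to the observed adult averages (Sb lighter
    than SB); the diploid mean sits above the sampling threshold so that the
    retained diploid sample is weight-truncated, as in the study design.
    """

    haploid_sb_mean: float = 6.12
    haploid_SB_mean: float = 7.07
    diploid_mean: float = 9.0
    colony_sd: float = 0.5
    residual_sd: float = 0.7
    diploid_residual_sd: float = 1.0

    def validate(self) -> None:
        if min(self.haploid_sb_mean, self.haploid_SB_mean, self.diploid_mean) <= 0:
            raise ParameterError("weight means must be positive")
        if min(self.colony_sd, self.residual_sd, self.diploid_residual_sd) < 0:
            raise ParameterError("weight SDs must be non-negative")


@dataclass(frozen=True)
class SamplingDesign:
    """Weight-threshold sampling: keep everything light, cap heavy bins.

    All males with weight < ``threshold_mg`` are retained. Between the
    threshold and ``upper_limit_mg``, at most ``per_bin_cap`` males are kept
    (uniformly at random) per half-open bin of ``bin_width_mg``. Males at or
    above the upper limit are dropped.
    """

    threshold_mg: float = 8.0
    bin_width_mg: float = 0.25
    per_bin_cap: int = 20
    upper_limit_mg: float = 10.0

    def validate(self) -> None:
        if self.bin_width_mg <= 0:
            raise ParameterError(f"bin width must be positive, got {self.bin_width_mg}")
        if self.per_bin_cap < 0:
            raise ParameterError(f"per-bin cap must be >= 0, got {self.per_bin_cap}")
        if self.upper_limit_mg < self.threshold_mg:
            raise ParameterError("upper limit below threshold")


def default_execution_probs() -> dict[str, float]:
    """Per-group execution probabilities for the assay simulator.

    Monogyne workers execute virtually no males; polygyne workers execute
    over half of haploids, diploid SB/Sb males rarely and diploid Sb/Sb
    males at an intermediate-high rate.
    """
    return {
        "monogyne": 0.02,
        "polygyne:SB": 0.50,
        "polygyne:Sb": 0.57,
        "polygyne:SB/SB": 0.20,
        "polygyne:SB/Sb": 0.144,
        "polygyne:Sb/Sb": 0.469,
    }


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the synthetic breeding-system generator.

    ``distortion_delta`` is the probability a haploid egg of an SB/Sb queen
    carries Sb (0.5 = Mendelian). The default 0.78 matches the corrected Sb
    frequency observed among adult haploid males in the study population.
    ``diploid_male_target_fraction`` sets the expected share of diploids
    among all males (the study region sits at 80–95%).
    """

    n_colonies: int = 40
    queens_per_colony: QueenNumberModel = field(default_factory=QueenNumberModel)
    males_per_colony: MaleCountModel = field(default_factory=MaleCountModel)
    distortion_delta: float = 0.78
    matched_mating_rate: float = 0.5
    diploid_male_target_fraction: float = 0.85
    father_pool_sb_freq: float | None = None  # None -> use distortion_delta
    pupa_fraction: float = 0.19
    weight_model: WeightModel = field(default_factory=WeightModel)
    allele_freqs: AlleleFreqTable | None = None  # None -> default_allele_freqs()
    sampling_design: SamplingDesign = field(default_factory=SamplingDesign)
    execution_probs: Mapping[str, float] = field(default_factory=default_execution_probs)
    panel: tuple[str, ...] = DEFAULT_PANEL
    seed: int = 0

    def validate(self) -> None:
        if self.n_colonies < 1:
            raise ParameterError(f"n_colonies must be >= 1, got {self.n_colonies}")
        for name in (
            "distortion_delta",
            "matched_mating_rate",
            "diploid_male_target_fraction",
            "pupa_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.father_pool_sb_freq is not None and not (0 <= self.father_pool_sb_freq <= 1):
            raise ParameterError("father_pool_sb_freq must be in [0, 1]")
        if self.diploid_male_target_fraction >= 1:
            raise ParameterError("diploid_male_target_fraction must be < 1")
        self.weight_model.validate()
        self.sampling_design.validate()
        for p in self.execution_probs.values():
            if not (0 <= p <= 1):
                raise ParameterError("execution probabilities must be in [0, 1]")

    def resolved_allele_freqs(self) -> AlleleFreqTable:
        return self.allele_freqs or default_allele_freqs(self.panel)


def simulate_gp9_assay(genotype: str) -> frozenset[int]:
    """Band pattern of the length-diagnostic Gp-9 PCR for a supergene genotype.

    The B (SB) allele amplifies a 517 bp product, the b (Sb) allele a 423 bp
    product; heterozygotes show both, while haploids and diploid homozygotes
    are indistinguishable single-band patterns.
    """
    mapping = {
        "SB": frozenset({BAND_SB}),
        "Sb": frozenset({BAND_Sb}),
        "SB/SB": frozenset({BAND_SB}),
        "Sb/Sb": frozenset({BAND_Sb}),
        "SB/Sb": frozenset({BAND_SB, BAND_Sb}),
    }
    try:
        return mapping[genotype]
    except KeyError:
        raise ParameterError(f"unknown supergene genotype {genotype!r}") from None


def _draw_allele(rng: np.random.Generator, alleles: list[str], probs: np.ndarray) -> str:
    return alleles[rng.choice(len(alleles), p=probs)]


class _LocusSampler:
    """Pre-tabulated allele sampler for one locus."""

    def __init__(self, freqs: Mapping[str, float]):
        self.alleles = list(freqs)
        self.probs = np.asarray(list(freqs.values()), dtype=float)
        self.probs = self.probs / self.probs.sum()

    def draw(self, rng: np.random.Generator, size: int) -> list[str]:
        idx = rng.choice(len(self.alleles), size=size, p=self.probs)
        return [self.alleles[i] for i in idx]


def simulate_population(params: SimParams) -> list[MaleRecord]:
    """Simulate the full (pre-sampling) male pool of a polygyne population.

    Returns one :class:`MaleRecord` per male with ``truth_ploidy`` and
    ``truth_genotype`` filled. Apply :func:`apply_sampling_design` afterwards
    to emulate the weight-threshold collection protocol.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    freqs = params.resolved_allele_freqs()
    freqs.validate()
    samplers = {locus: _LocusSampler(freqs.loci[locus]) for locus in params.panel}
    wm = params.weight_model
    father_sb = (
        params.distortion_delta
        if params.father_pool_sb_freq is None
        else params.father_pool_sb_freq
    )

    n_queens = params.queens_per_colony.sample(rng, params.n_colonies)
    n_haploid = params.males_per_colony.sample(rng, params.n_colonies)
    # Expected diploids per matched queen chosen so the population-level
    # diploid fraction matches the target in expectation.
    f = params.diploid_male_target_fraction
    mu_hap = params.males_per_colony.overall_mean
    expected_matched = params.matched_mating_rate * params.queens_per_colony.mean
    if f > 0 and expected_matched <= 0:
        raise ParameterError(
            "diploid males requested but matched_mating_rate * queens is zero"
        )
    lam_dip = (f / (1.0 - f)) * mu_hap / expected_matched if f > 0 else 0.0

    records: list[MaleRecord] = []
    for c in range(params.n_colonies):
        colony_id = f"C{c + 1:03d}"
        q = int(n_queens[c])
        # queen genotypes: two reference alleles per locus; one mate each
        queen_geno = {
            locus: np.array(samplers[locus].draw(rng, 2 * q)).reshape(q, 2)
            for locus in params.panel
        }
        mate_geno = {locus: samplers[locus].draw(rng, q) for locus in params.panel}
        matched = rng.random(q) < params.matched_mating_rate
        colony_effect = rng.normal(0.0, wm.colony_sd)

        # --- haploid (fertile, impaternate) males ---
        n_h = int(n_haploid[c])
        mothers = rng.integers(0, q, size=n_h)
        is_sb = rng.random(n_h) < params.distortion_delta
        for j in range(n_h):
            genotype = "Sb" if is_sb[j] else "SB"
            geno = {}
            for locus in params.panel:
                allele = queen_geno[locus][mothers[j], rng.integers(0, 2)]
                geno[locus] = (str(allele), str(allele))
            mean = wm.haploid_sb_mean if is_sb[j] else wm.haploid_SB_mean
            weight = mean + colony_effect + rng.normal(0.0, wm.residual_sd)
            stage = Stage.PUPA if rng.random() < params.pupa_fraction else Stage.ADULT
            records.append(
                MaleRecord(
                    male_id=f"{colony_id}:h{j + 1:04d}",
                    colony_id=colony_id,
                    stage=stage,
                    weight_mg=max(weight, 0.1),
                    gp9_bands=simulate_gp9_assay(genotype),
                    microsat_genotype=geno,
                    truth_ploidy="haploid",
                    truth_genotype=genotype,
                )
            )

        # --- diploid males from matched matings ---
        matched_idx = np.flatnonzero(matched)
        if matched_idx.size and lam_dip > 0:
            n_d = int(rng.poisson(lam_dip * matched_idx.size))
            dip_mothers = matched_idx[rng.integers(0, matched_idx.size, size=n_d)]
            for j in range(n_d):
                m = int(dip_mothers[j])
                maternal_sb = rng.random() < 0.5
                paternal_sb = rng.random() < father_sb
                pair = sorted(
                    ["Sb" if maternal_sb else "SB", "Sb" if paternal_sb else "SB"]
                )
                genotype = "/".join(pair)  # SB/SB, SB/Sb, or Sb/Sb
                geno = {}
                for locus in params.panel:
                    ma = str(queen_geno[locus][m, rng.integers(0, 2)])
                    pa = str(mate_geno[locus][m])
                    geno[locus] = tuple(sorted((ma, pa)))
                weight = wm.diploid_mean + colony_effect + rng.normal(
                    0.0, wm.diploid_residual_sd
                )
                stage = (
                    Stage.PUPA if rng.random() < params.pupa_fraction else Stage.ADULT
                )
                records.append(
                    MaleRecord(
                        male_id=f"{colony_id}:d{j + 1:04d}",
                        colony_id=colony_id,
                        stage=stage,
                        weight_mg=max(weight, 0.1),
                        gp9_bands=simulate_gp9_assay(genotype),
                        microsat_genotype=geno,
                        truth_ploidy="diploid",
                        truth_genotype=genotype,
                    )
                )
    return records


def apply_sampling_design(
    males: Sequence[MaleRecord],
    design: SamplingDesign | None = None,
    seed: int | np.random.Generator = 0,
) -> list[MaleRecord]:
    """Apply the weight-threshold collection protocol to a male pool.

    Input order is preserved among retained males; the per-bin subsample is
    drawn uniformly at random with the given seed.
    """
    design = design or SamplingDesign()
    design.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([m.weight_mg for m in males])
    keep = np.zeros(len(males), dtype=bool)
    keep[weights < design.threshold_mg] = True
    n_bins = math.ceil(
        round((design.upper_limit_mg - design.threshold_mg) / design.bin_width_mg, 9)
    )
    for k in range(n_bins):
        lo = design.threshold_mg + k * design.bin_width_mg
        hi = min(lo + design.bin_width_mg, design.upper_limit_mg)
        in_bin = np.flatnonzero((weights >= lo) & (weights < hi))
        if in_bin.size <= design.per_bin_cap:
            keep[in_bin] = True
        else:
            chosen = rng.choice(in_bin, size=design.per_bin_cap, replace=False)
            keep[chosen] = True
    return [m for m, k in zip(males, keep) if k]


def execution_group(social_form: str, genotype: str) -> str:
    """Group key used to look up execution probabilities."""
    return "monogyne" if social_form == "monogyne" else f"polygyne:{genotype}"


def simulate_execution_assay(
    males: Sequence[MaleRecord],
    execution_probs: Mapping[str, float],
    seed: int = 0,
    social_form: str = "polygyne",
) -> list[ExecutionRecord]:
    """Bernoulli execution outcomes for a cohort of assayed males.

    Each male's execution probability is looked up by its group key
    (``monogyne`` for monogyne cohorts, ``polygyne:<genotype>`` otherwise);
    executed males get a discovery hour uniform on 1..12.
    """
    rng = np.random.default_rng(seed)
    out = []
    for m in males:
        genotype = m.truth_genotype
        if genotype is None:
            raise ParameterError(
                f"{m.male_id}: execution simulation needs truth_genotype"
            )
        key = execution_group(social_form, genotype)
        if key not in execution_probs:
            raise ParameterError(f"no execution probability configured for {key!r}")
        executed = bool(rng.random() < execution_probs[key])
        out.append(
            ExecutionRecord(
                male_id=m.male_id,
                colony_id=m.colony_id,
                social_form=social_form,
                ploidy_genotype=genotype,
                executed=executed,
                hour_observed=int(rng.integers(1, 13)) if executed else None,
            )
        )
    return out


def simulate_monogyne_cohort(n: int, seed: int = 0) -> list[MaleRecord]:
    """Synthetic monogyne control males (all haploid SB) for the assay."""
    rng = np.random.default_rng(seed)
    freqs = default_allele_freqs()
    samplers = {locus: _LocusSampler(freqs.loci[locus]) for locus in DEFAULT_PANEL}
    out = []
    for i in range(n):
        geno = {
            locus: (a := samplers[locus].draw(rng, 1)[0], a)
            for locus in DEFAULT_PANEL
        }
        out.append(
            MaleRecord(
                male_id=f"M:{i + 1:04d}",
                colony_id=f"M{(i % 5) + 1:02d}",
                stage=Stage.ADULT,
                weight_mg=max(7.0 + rng.normal(0, 0.7), 0.1),
                gp9_bands=simulate_gp9_assay("SB"),
                microsat_genotype=geno,
                truth_ploidy="haploid",
                truth_genotype="SB",
            )
        )
    return out


def with_seed(params: SimParams, seed: int) -> SimParams:
    return replace(params, seed=seed)
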