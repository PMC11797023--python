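"""Haplotype-frequency and weight estimation, pooled and colony-weighted.

Two estimators are provided for the frequency of a supergene haplotype
among confirmed haploid males:

* **pooled**: the raw proportion over all males, with a percentile
  bootstrap CI obtained by resampling individuals with replacement;
* **colony-resampled**: the social-structure correction. Each replicate
  draws one haploid male per male-containing colony uniformly at random and
  takes the proportion across colonies; 500 replicate values are averaged.
  This weights colonies equally instead of individual males, removing the
  dominance of the few colonies that produce most of the haploid males, and
  its expectation is the unweighted mean of the per-colony frequencies.

The same one-male-per-colony scheme is reused for mean weights per
haplotype, with one-tailed 95% limits (5th and 95th percentiles of the
replicate means reported separately).

Two confidence intervals are attached to colony-resampled estimates: the
percentile interval of the replicate values and a normal interval on the
replicate mean (mean ± z·SD/√n_reps). With ~25 male-containing colonies a
single replicate proportion moves in steps of ~0.04, so the percentile
interval is wide by construction; the mean interval quantifies the
averaging precision and is the default ``ci_low``/``ci_high``.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_tables import ParameterError, Stage
from .ploidy_classifier import PloidyCall

__all__ = [
    "FrequencyEstimate",
    "WeightDifferenceResult",
    "pooled_frequency",
    "colony_resampled_frequency",
    "colony_resampled_weight",
    "resampled_weight_difference",
]


@dataclass
class FrequencyEstimate:
    """Point estimate with CI for a haplotype frequency or a mean weight."""

    stage: str
    haplotype: str
    point: float
    ci_low: float
    ci_high: float
    method: str  # "pooled_bootstrap" | "colony_resampled"
    n_replicates: int
    n_units: int  # males (pooled) or colonies (resampled)
    seed: int
    percentile_ci: tuple[float, float] | None = None
    replicates: np.ndarray | None = field(default=None, repr=False)


def _filter_haploids(
    calls: Sequence[PloidyCall], stage: Stage | str | None
) -> list[PloidyCall]:
    stage_val = Stage(stage).value if stage is not None else None
    return [
        c
        for c in calls
        if c.is_haploid and (stage_val is None or c.stage.value == stage_val)
    ]


def pooled_frequency(
    calls: Sequence[PloidyCall],
    haplotype: str = "SB",
    stage: Stage | str | None = None,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> FrequencyEstimate:
    """Raw haplotype proportion with an individual-level bootstrap CI.

    Resampling n individuals with replacement makes each bootstrap count a
    Binomial(n, p̂) draw; the CI is the percentile interval of the
    bootstrapped proportions over ``n_boot`` replicates.
    """
    if haplotype not in ("SB", "Sb"):
        raise ParameterError(f"haplotype must be SB or Sb, got {haplotype!r}")
    haploids = _filter_haploids(calls, stage)
    n = len(haploids)
    if n == 0:
        raise ParameterError("pooled_frequency needs at least one haploid call")
    k = sum(1 for c in haploids if c.supergene_genotype == haplotype)
    p_hat = k / n
    rng = np.random.default_rng(seed)
    boot = rng.binomial(n, p_hat, size=n_boot) / n
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return FrequencyEstimate(
        stage=Stage(stage).value if stage is not None else "all",
        haplotype=haplotype,
        point=p_hat,
        ci_low=float(lo),
        ci_high=float(hi),
        method="pooled_bootstrap",
        n_replicates=n_boot,
        n_units=n,
        seed=seed,
        replicates=boot,
    )


def _one_per_colony_replicates(
    values_by_colony: list[np.ndarray], n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate means of one uniformly drawn value per colony."""
    n_col = len(values_by_colony)
    drawn = np.empty((n_reps, n_col))
    for j, vals in enumerate(values_by_colony):
        idx = rng.integers(0, len(vals), size=n_reps)
        drawn[:, j] = vals[idx]
    return drawn.mean(axis=1)


def _mean_ci(values: np.ndarray, ci_level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + ci_level / 2)
    m = values.mean()
    half = z * values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
    return float(m - half), float(m + half)


def colony_resampled_frequency(
    calls: Sequence[PloidyCall],
    haplotype: str = "SB",
    stage: Stage | str | None = None,
    n_reps: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
    ci_method: str = "mean",
) -> FrequencyEstimate:
    """Colony-weighted haplotype frequency by one-male-per-colony resampling.

    Eligible colonies are those containing at least one haploid male of the
    requested stage; each of the ``n_reps`` independent replicates draws one
    such male per eligible colony and records the proportion carrying
    ``haplotype``. The point estimate is the replicate mean. ``ci_method``
    selects which interval populates ``ci_low``/``ci_high``: ``"mean"``
    (normal interval on the replicate mean, the default) or
    ``"percentile"`` (2.5th/97.5th percentiles of replicate values); the
    percentile interval is always available in ``percentile_ci``.
    """
    if haplotype not in ("SB", "Sb"):
        raise ParameterError(f"haplotype must be SB or Sb, got {haplotype!r}")
    if ci_method not in ("mean", "percentile"):
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    haploids = _filter_haploids(calls, stage)
    by_colony: dict[str, list[int]] = {}
    for c in haploids:
        by_colony.setdefault(c.colony_id, []).append(
            1 if c.supergene_genotype == haplotype else 0
        )
    if len(by_colony) < 2:
        raise ParameterError(
            f"colony resampling needs >= 2 eligible colonies, got {len(by_colony)}"
        )
    rng = np.random.default_rng(seed)
    reps = _one_per_colony_replicates(
        [np.asarray(v, dtype=float) for v in by_colony.values()], n_reps, rng
    )
    alpha = 1.0 - ci_level
    pct = tuple(float(q) for q in np.quantile(reps, [alpha / 2, 1 - alpha / 2]))
    mean_lo, mean_hi = _mean_ci(reps, ci_level)
    lo, hi = (mean_lo, mean_hi) if ci_method == "mean" else pct
    return FrequencyEstimate(
        stage=Stage(stage).value if stage is not None else "all",
        haplotype=haplotype,
        point=float(reps.mean()),
        ci_low=lo,
        ci_high=hi,
        method="colony_resampled",
        n_replicates=n_reps,
        n_units=len(by_colony),
        seed=seed,
        percentile_ci=pct,
        replicates=reps,
    )


def colony_resampled_weight(
    calls: Sequence[PloidyCall],
    haplotype: str,
    stage: Stage | str = Stage.ADULT,
    n_reps: int = 500,
    seed: int = 0,
) -> FrequencyEstimate:
    """Colony-weighted mean weight (mg) for one haplotype.

    Same one-male-per-colony scheme as the frequency estimator, restricted
    to haploid males of the requested haplotype; eligibility is therefore
    per haplotype and the SB and Sb streams may use different colony sets.
    ``ci_low``/``ci_high`` hold the one-tailed 95% limits: the 5th and 95th
    percentiles of the replicate means, reported separately.
    """
    if haplotype not in ("SB", "Sb"):
        raise ParameterError(f"haplotype must be SB or Sb, got {haplotype!r}")
    haploids = [
        c for c in _filter_haploids(calls, stage) if c.supergene_genotype == haplotype
    ]
    by_colony: dict[str, list[float]] = {}
    for c in haploids:
        by_colony.setdefault(c.colony_id, []).append(c.weight_mg)
    if len(by_colony) < 2:
        raise ParameterError(
            f"weight resampling needs >= 2 colonies with {haplotype} haploids, "
            f"got {len(by_colony)}"
        )
    rng = np.random.default_rng(seed)
    reps = _one_per_colony_replicates(
        [np.asarray(v, dtype=float) for v in by_colony.values()], n_reps, rng
    )
    lo, hi = (float(q) for q in np.quantile(reps, [0.05, 0.95]))
    return FrequencyEstimate(
        stage=Stage(stage).value,
        haplotype=haplotype,
        point=float(reps.mean()),
        ci_low=lo,
        ci_high=hi,
        method="colony_resampled",
        n_replicates=n_reps,
        n_units=len(by_colony),
        seed=seed,
        percentile_ci=(lo, hi),
        replicates=reps,
    )


@dataclass(frozen=True)
class WeightDifferenceResult:
    """Replicate-level comparison of two resampled weight streams.

    ``fraction_nonpositive`` is the share of replicate pairs in which the
    heavier group's mean did not exceed the lighter group's. When zero, the
    comparison is reported as P < 1/n_reps (``p_is_upper_bound``).
    """

    fraction_nonpositive: float
    n_reps: int
    p_value: float
    p_is_upper_bound: bool
    limits_nonoverlapping: bool


def resampled_weight_difference(
    reps_heavier: np.ndarray | FrequencyEstimate,
    reps_lighter: np.ndarray | FrequencyEstimate,
) -> WeightDifferenceResult:
    """Compare paired replicate streams (e.g. SB vs Sb mean weights)."""
    est_a = reps_heavier if isinstance(reps_heavier, FrequencyEstimate) else None
    est_b = reps_lighter if isinstance(reps_lighter, FrequencyEstimate) else None
    a = est_a.replicates if est_a is not None else np.asarray(reps_heavier, dtype=float)
    b = est_b.replicates if est_b is not None else np.asarray(reps_lighter, dtype=float)
    if a is None or b is None:
        raise ParameterError("estimates must carry their replicate values")
    if len(a) != len(b):
        raise ParameterError(
            f"replicate counts differ: {len(a)} vs {len(b)}"
        )
    n = len(a)
    if n == 0:
        raise ParameterError("empty replicate streams")
    frac = float(np.mean(a - b <= 0))
    nonoverlap = False
    if est_a is not None and est_b is not None:
        nonoverlap = est_a.ci_low > est_b.ci_high
    return WeightDifferenceResult(
        fraction_nonpositive=frac,
        n_reps=n,
        p_value=max(frac, 1.0 / n),
        p_is_upper_bound=frac == 0.0,
        limits_nonoverlapping=nonoverlap,
    )
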