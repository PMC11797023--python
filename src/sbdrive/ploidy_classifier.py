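"""Ploidy and supergene-genotype inference for sampled males.

A male with both Gp-9 products (517 and 423 bp) is unambiguously a diploid
SB/Sb heterozygote. A single-band male may be either a haploid hemizygote or
a diploid homozygote; the two are separated by the multilocus microsatellite
genotype: any heterozygous locus proves diploidy, while homozygosity at the
whole panel is taken as haploidy. The residual risk of that call — a true
diploid homozygous by chance at every panel locus — is the product over loci
of the Hardy–Weinberg expected homozygosity, ~0.5% for the default 4-locus
panel.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .core_tables import (
    BAND_SB,
    BAND_Sb,
    DEFAULT_PANEL,
    AlleleFreqTable,
    MaleRecord,
    ParameterError,
    Stage,
    TableValidationError,
)

__all__ = [
    "PloidyCall",
    "ClassificationSummary",
    "classify_male",
    "false_haploid_probability",
    "classify_table",
]


@dataclass(frozen=True)
class PloidyCall:
    """Inferred ploidy and supergene genotype for one male.

    Colony, stage and weight are carried over from the input record so the
    calls alone are sufficient input for frequency and weight estimation.
    """

    male_id: str
    colony_id: str
    stage: Stage
    weight_mg: float
    ploidy: str  # "haploid" | "diploid" | "unresolved"
    supergene_genotype: str | None
    n_heterozygous_loci: int
    confirmed_by_microsats: bool
    false_haploid_prob: float | None = None

    @property
    def is_haploid(self) -> bool:
        return self.ploidy == "haploid"


def false_haploid_probability(
    freqs: AlleleFreqTable,
    panel: Sequence[str] = DEFAULT_PANEL,
    fis: float = 0.0,
) -> float:
    """Probability a random diploid is homozygous at every panel locus.

    Under Hardy–Weinberg with independent loci this is
    ``prod_l sum_a p_{l,a}^2``; a nonzero inbreeding coefficient ``fis``
    inflates per-locus homozygosity to ``F + (1-F) sum_a p^2``.
    """
    if not panel:
        raise ParameterError("empty locus panel: misclassification probability undefined")
    if not (0 <= fis < 1):
        raise ParameterError(f"fis must be in [0, 1), got {fis}")
    prob = 1.0
    for locus in panel:
        h = freqs.expected_homozygosity(locus)
        prob *= fis + (1.0 - fis) * h
    return prob


def classify_male(
    record: MaleRecord,
    freqs: AlleleFreqTable | None = None,
    panel: Sequence[str] = DEFAULT_PANEL,
    fis: float = 0.0,
) -> PloidyCall:
    """Classify one male from its Gp-9 band pattern and microsatellites.

    Two bands force a diploid SB/Sb call regardless of the microsatellites.
    For single-band males, at least one heterozygous microsatellite locus
    proves diploidy (homozygous at Gp-9, so SB/SB or Sb/Sb according to the
    band); an all-homozygous panel yields a haploid call with the attached
    false-haploid probability. Records with any missing microsatellite call
    (and a single band) are left unresolved.
    """
    if not record.gp9_bands:
        raise TableValidationError(f"{record.male_id}: empty Gp-9 band set")
    observed = {
        locus: pair
        for locus, pair in record.microsat_genotype.items()
        if locus in set(panel)
    }
    n_het = sum(1 for a, b in observed.values() if a != b and "?" not in (a, b))

    common = dict(
        male_id=record.male_id,
        colony_id=record.colony_id,
        stage=record.stage,
        weight_mg=record.weight_mg,
        n_heterozygous_loci=n_het,
    )

    if record.gp9_bands == frozenset({BAND_SB, BAND_Sb}):
        return PloidyCall(
            ploidy="diploid",
            supergene_genotype="SB/Sb",
            confirmed_by_microsats=False,
            **common,
        )

    band = next(iter(record.gp9_bands))
    haplotype = "SB" if band == BAND_SB else "Sb"

    if record.has_missing_genotype:
        return PloidyCall(
            ploidy="unresolved",
            supergene_genotype=None,
            confirmed_by_microsats=False,
            **common,
        )
    if n_het >= 1:
        return PloidyCall(
            ploidy="diploid",
            supergene_genotype=f"{haplotype}/{haplotype}",
            confirmed_by_microsats=True,
            **common,
        )
    return PloidyCall(
        ploidy="haploid",
        supergene_genotype=haplotype,
        confirmed_by_microsats=True,
        false_haploid_prob=(
            false_haploid_probability(freqs, panel, fis) if freqs is not None else None
        ),
        **common,
    )


@dataclass
class ClassificationSummary:
    """Per-record calls plus the reconciling count summary.

    ``counts`` has one row per stage with the accounting the analysis
    reports: total genotyped, two-band diploids, single-band males sent to
    microsatellite screening, and how those resolved.
    """

    calls: list[PloidyCall]
    counts: pd.DataFrame
    errors: list[Exception]

    def haploid_calls(self, stage: Stage | None = None) -> list[PloidyCall]:
        return [
            c
            for c in self.calls
            if c.is_haploid and (stage is None or c.stage == stage)
        ]


def classify_table(
    records: Sequence[MaleRecord],
    freqs: AlleleFreqTable | None = None,
    panel: Sequence[str] = DEFAULT_PANEL,
    fis: float = 0.0,
) -> ClassificationSummary:
    """Classify every record; collect (not raise) per-record errors.

    The count summary satisfies, per stage:
    confirmed_haploid + single_band_diploid + unresolved = single_band.
    """
    calls: list[PloidyCall] = []
    errors: list[Exception] = []
    for rec in records:
        try:
            calls.append(classify_male(rec, freqs, panel, fis))
        except (TableValidationError, ParameterError) as exc:
            errors.append(exc)

    rows = []
    for stage in Stage:
        sub = [c for c in calls if c.stage == stage]
        # two-band males are the diploid SB/Sb calls not confirmed by microsats
        def _is_two_band(c: PloidyCall) -> bool:
            return c.ploidy == "diploid" and not c.confirmed_by_microsats

        two_band = [c for c in sub if _is_two_band(c)]
        single_band = [c for c in sub if not _is_two_band(c)]
        rows.append(
            {
                "stage": stage.value,
                "n_genotyped": len(sub),
                "n_two_band": len(two_band),
                "n_single_band": len(single_band),
                "n_confirmed_haploid": sum(1 for c in single_band if c.is_haploid),
                "n_single_band_diploid": sum(
                    1 for c in single_band if c.ploidy == "diploid"
                ),
                "n_unresolved": sum(1 for c in single_band if c.ploidy == "unresolved"),
            }
        )
    counts = pd.DataFrame(rows)
    return ClassificationSummary(calls=calls, counts=counts, errors=errors)
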