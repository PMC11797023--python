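"""Shared fixtures: record factories and small simulated populations."""

from __future__ import annotations

import pytest

from sbdrive.core_tables import DEFAULT_PANEL, AlleleFreqTable, MaleRecord, Stage
from sbdrive.synthetic_colonies import (
    MaleCountModel,
    QueenNumberModel,
    SimParams,
    default_allele_freqs,
    simulate_gp9_assay,
)


@pytest.fixture(scope="session")
def ref_freqs() -> AlleleFreqTable:
    return default_allele_freqs()


@pytest.fixture
def make_male():
    """Factory for a valid MaleRecord with overridable fields.

    ``genotype`` may be given as a dict locus -> "a/b" string; by default
    every locus is homozygous-appearing (one label), matching a haploid.
    """

    def _make(
        male_id: str = "m1",
        colony_id: str = "c1",
        stage: str = "adult",
        weight_mg: float = 6.0,
        supergene: str = "Sb",
        genotype: dict[str, str] | None = None,
        **kwargs,
    ) -> MaleRecord:
        geno = {locus: (f"{locus}_01", f"{locus}_01") for locus in DEFAULT_PANEL}
        if genotype:
            for locus, val in genotype.items():
                parts = val.split("/")
                if len(parts) == 1:
                    parts = parts * 2
                geno[locus] = tuple(sorted(parts))
        rec = MaleRecord(
            male_id=male_id,
            colony_id=colony_id,
            stage=Stage(stage),
            weight_mg=weight_mg,
            gp9_bands=simulate_gp9_assay(supergene),
            microsat_genotype=geno,
            **kwargs,
        )
        rec.validate()
        return rec

    return _make


def light_params(**overrides) -> SimParams:
    """Small, haploid-only simulation parameters for fast repeated runs."""
    defaults = dict(
        n_colonies=15,
        queens_per_colony=QueenNumberModel(mean=2.0),
        males_per_colony=MaleCountModel(zero_prob=0.2, mean=8.0, dispersion=1.5),
        diploid_male_target_fraction=0.0,
        pupa_fraction=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture
def small_sim_params() -> SimParams:
    return light_params()
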