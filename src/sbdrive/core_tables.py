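"""Domain types, delimited-file I/O, configuration, and validation.

The central object is the :class:`MaleRecord`: one sampled male ant with its
colony of origin, life stage, fresh weight, the band pattern of the
length-diagnostic Gp-9 PCR assay (517 bp product for the B/SB allele, 423 bp
for the b/Sb allele), and a multilocus microsatellite genotype used to
resolve ploidy. Records are read from and written to plain delimited text
(tab-separated by default), and every field is validated on the way in:
malformed input raises a typed error rather than being silently coerced.
"""

from __future__ import annotations

import enum
import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "BAND_SB",
    "BAND_Sb",
    "DEFAULT_PANEL",
    "MISSING_ALLELE",
    "Stage",
    "MaleRecord",
    "AlleleFreqTable",
    "ExecutionRecord",
    "RunConfig",
    "SbdriveError",
    "SchemaError",
    "RowError",
    "TableValidationError",
    "ParameterError",
    "read_male_table",
    "write_male_table",
    "read_allele_freqs",
    "write_allele_freqs",
    "read_execution_table",
    "write_execution_table",
    "write_report",
]

#: PCR product length (bp) diagnostic for the B allele of Gp-9 (SB haplotype).
BAND_SB = 517
#: PCR product length (bp) diagnostic for the b allele of Gp-9 (Sb haplotype).
BAND_Sb = 423

VALID_BANDS = frozenset({BAND_SB, BAND_Sb})

#: Default microsatellite panel used for ploidy confirmation.
DEFAULT_PANEL = ("Sol42_f", "Sol49", "C536", "cassidy")

#: Reserved label for a failed/missing microsatellite call.
MISSING_ALLELE = "?"

HAPLOID_GENOTYPES = ("SB", "Sb")
DIPLOID_GENOTYPES = ("SB/SB", "SB/Sb", "Sb/Sb")
SUPERGENE_GENOTYPES = HAPLOID_GENOTYPES + DIPLOID_GENOTYPES


class SbdriveError(Exception):
    """Base class for all package errors."""


class SchemaError(SbdriveError):
    """A table is structurally wrong (missing/unknown column, bad header)."""


class RowError(SbdriveError):
    """A single row failed validation; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class TableValidationError(SbdriveError):
    """A parsed table violates a domain invariant."""


class ParameterError(SbdriveError):
    """An operation received an invalid parameter or degenerate input."""


class Stage(str, enum.Enum):
    ADULT = "adult"
    PUPA = "pupa"

    @classmethod
    def parse(cls, value: str) -> "Stage":
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise TableValidationError(
                f"stage must be one of {[s.value for s in cls]}, got {value!r}"
            ) from None


@dataclass(frozen=True)
class MaleRecord:
    """One sampled male: identity, phenotype, and marker genotypes.

    ``microsat_genotype`` maps locus name to an unordered pair of allele
    labels; equal labels record a single-allele observation, which may be
    either a diploid homozygote or a haploid hemizygote — that distinction
    is an inference made downstream, not an input. ``truth_*`` fields are
    present only on simulator output.
    """

    male_id: str
    colony_id: str
    stage: Stage
    weight_mg: float
    gp9_bands: frozenset[int]
    microsat_genotype: Mapping[str, tuple[str, str]]
    truth_ploidy: str | None = None
    truth_genotype: str | None = None

    def validate(self, panel: Sequence[str] = DEFAULT_PANEL) -> None:
        if not self.gp9_bands:
            raise TableValidationError(f"{self.male_id}: empty Gp-9 band set")
        if not set(self.gp9_bands) <= VALID_BANDS:
            bad = sorted(set(self.gp9_bands) - VALID_BANDS)
            raise TableValidationError(
                f"{self.male_id}: invalid Gp-9 band(s) {bad}; expected subset of "
                f"{sorted(VALID_BANDS)}"
            )
        if not (self.weight_mg > 0):
            raise TableValidationError(
                f"{self.male_id}: weight must be positive, got {self.weight_mg}"
            )
        if not isinstance(self.stage, Stage):
            raise TableValidationError(f"{self.male_id}: bad stage {self.stage!r}")
        if set(self.microsat_genotype) != set(panel):
            raise TableValidationError(
                f"{self.male_id}: genotype loci {sorted(self.microsat_genotype)} "
                f"do not match panel {sorted(panel)}"
            )
        for locus, pair in self.microsat_genotype.items():
            if len(pair) != 2:
                raise TableValidationError(
                    f"{self.male_id}: locus {locus} needs exactly two allele labels"
                )
        if self.truth_ploidy is not None and self.truth_ploidy not in ("haploid", "diploid"):
            raise TableValidationError(
                f"{self.male_id}: bad truth_ploidy {self.truth_ploidy!r}"
            )
        if self.truth_genotype is not None and self.truth_genotype not in SUPERGENE_GENOTYPES:
            raise TableValidationError(
                f"{self.male_id}: bad truth_genotype {self.truth_genotype!r}"
            )

    @property
    def has_missing_genotype(self) -> bool:
        return any(
            MISSING_ALLELE in pair for pair in self.microsat_genotype.values()
        )


@dataclass(frozen=True)
class AlleleFreqTable:
    """Per-locus allele frequencies of a reference (base) population.

    Used both for the false-haploid misclassification probability (expected
    homozygosity under Hardy–Weinberg) and as the reference for pairwise
    relatedness.
    """

    loci: Mapping[str, Mapping[str, float]]

    def validate(self, tol: float = 1e-6) -> None:
        if not self.loci:
            raise TableValidationError("allele frequency table has no loci")
        for locus, freqs in self.loci.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > tol:
                raise TableValidationError(
                    f"locus {locus}: allele frequencies sum to {total:.6g}, not 1"
                )
            if any(f < 0 for f in freqs.values()):
                raise TableValidationError(f"locus {locus}: negative frequency")
            if sum(1 for f in freqs.values() if f > 0) < 2:
                raise TableValidationError(
                    f"locus {locus}: needs at least 2 alleles with positive frequency"
                )

    def expected_homozygosity(self, locus: str) -> float:
        """Probability two random reference alleles at ``locus`` are identical."""
        try:
            freqs = self.loci[locus]
        except KeyError:
            raise ParameterError(f"locus {locus!r} absent from frequency table") from None
        return float(sum(p * p for p in freqs.values()))

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, float]]) -> "AlleleFreqTable":
        loci = {}
        for locus, cnt in counts.items():
            total = float(sum(cnt.values()))
            if total <= 0:
                raise TableValidationError(f"locus {locus}: non-positive total count")
            loci[locus] = {a: c / total for a, c in cnt.items()}
        table = cls(loci)
        table.validate()
        return table


@dataclass(frozen=True)
class ExecutionRecord:
    """Outcome of one male-execution trial (worker aggression assay)."""

    male_id: str
    colony_id: str
    social_form: str  # "monogyne" | "polygyne"
    ploidy_genotype: str  # SB, Sb, SB/SB, SB/Sb, Sb/Sb
    executed: bool
    hour_observed: int | None = None

    def validate(self) -> None:
        if self.social_form not in ("monogyne", "polygyne"):
            raise TableValidationError(
                f"{self.male_id}: bad social_form {self.social_form!r}"
            )
        if self.ploidy_genotype not in SUPERGENE_GENOTYPES:
            raise TableValidationError(
                f"{self.male_id}: bad ploidy_genotype {self.ploidy_genotype!r}"
            )
        if self.hour_observed is not None and not (0 <= self.hour_observed <= 12):
            raise TableValidationError(
                f"{self.male_id}: hour_observed {self.hour_observed} outside [0, 12]"
            )

    @property
    def is_haploid(self) -> bool:
        return self.ploidy_genotype in HAPLOID_GENOTYPES


@dataclass
class RunConfig:
    """Resolved run configuration with all pipeline defaults.

    Replicate-count defaults: 500 for one-male-per-colony resampling, 5000
    for proportion bootstraps and bootstrap difference tests. The sampling
    design defaults encode the study design: every male below 8.0 mg is
    kept, then at most 20 males per 0.25 mg bin up to 10.0 mg.
    """

    panel: tuple[str, ...] = DEFAULT_PANEL
    sep: str = "\t"
    n_resample_reps: int = 500
    n_bootstrap: int = 5000
    ci_level: float = 0.95
    seed: int = 0
    weight_threshold_mg: float = 8.0
    bin_width_mg: float = 0.25
    per_bin_cap: int = 20
    upper_limit_mg: float = 10.0
    fis: float = 0.0
    column_map: dict[str, str] = field(default_factory=dict)
    male_table: str | None = None
    allele_freq_table: str | None = None
    execution_table: str | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        errors = self.problems()
        if errors:
            raise TableValidationError("; ".join(errors))

    def problems(self) -> list[str]:
        errs = []
        if self.n_resample_reps < 1:
            errs.append(f"n_resample_reps must be >= 1, got {self.n_resample_reps}")
        if self.n_bootstrap < 1:
            errs.append(f"n_bootstrap must be >= 1, got {self.n_bootstrap}")
        if not (0 < self.ci_level < 1):
            errs.append(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.bin_width_mg <= 0:
            errs.append(f"bin_width_mg must be positive, got {self.bin_width_mg}")
        if self.per_bin_cap < 0:
            errs.append(f"per_bin_cap must be >= 0, got {self.per_bin_cap}")
        if not (0 <= self.fis < 1):
            errs.append(f"fis must be in [0, 1), got {self.fis}")
        if len(self.panel) == 0:
            errs.append("panel must name at least one locus")
        if self.sep not in ("\t", ","):
            errs.append(f"sep must be tab or comma, got {self.sep!r}")
        return errs

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise SchemaError(f"unknown configuration key(s): {', '.join(unknown)}")
        kwargs = dict(mapping)
        if "panel" in kwargs:
            kwargs["panel"] = tuple(kwargs["panel"])  # type: ignore[arg-type]
        cfg = cls(**kwargs)  # type: ignore[arg-type]
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Delimited-file readers / writers
# ---------------------------------------------------------------------------

_BASE_MALE_COLUMNS = ("male_id", "colony_id", "stage", "weight_mg", "gp9_bands")
_TRUTH_COLUMNS = ("truth_ploidy", "truth_genotype")


def _parse_bands(value: object, row: int) -> frozenset[int]:
    parts = [p for p in str(value).replace(",", "/").split("/") if p.strip()]
    if not parts:
        raise RowError(row, "empty Gp-9 band value")
    bands = set()
    for p in parts:
        try:
            band = int(float(p))
        except ValueError:
            raise RowError(row, f"unparseable Gp-9 band {p!r}") from None
        if band not in VALID_BANDS:
            raise RowError(
                row, f"band {band} not a valid Gp-9 product length {sorted(VALID_BANDS)}"
            )
        bands.add(band)
    return frozenset(bands)


def _parse_genotype(value: object, locus: str, row: int) -> tuple[str, str]:
    parts = [p.strip() for p in str(value).split("/")]
    if len(parts) == 1:
        parts = parts * 2  # single label = hemizygous/homozygous observation
    if len(parts) != 2 or not all(parts):
        raise RowError(row, f"locus {locus}: bad genotype value {value!r}")
    a, b = sorted(parts)
    return (a, b)


def read_male_table(path: str | Path, config: RunConfig | None = None) -> list[MaleRecord]:
    """Read and validate a delimited male table.

    Expects a header with ``male_id, colony_id, stage, weight_mg, gp9_bands``
    plus one column per panel locus (genotypes as ``a/b``, a bare label for a
    single-allele observation, ``?`` for a missing call). Column names can be
    remapped through ``config.column_map`` (file column -> canonical name).
    Row order is preserved.
    """
    config = config or RunConfig()
    df = pd.read_csv(path, sep=config.sep, dtype=str)
    if config.column_map:
        df = df.rename(columns=config.column_map)
    missing = [c for c in _BASE_MALE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"male table missing column(s): {', '.join(missing)}")
    missing_loci = [l for l in config.panel if l not in df.columns]
    if missing_loci:
        raise SchemaError(f"male table missing locus column(s): {', '.join(missing_loci)}")
    extra = set(df.columns) - set(_BASE_MALE_COLUMNS) - set(config.panel) - set(_TRUTH_COLUMNS)
    if extra:
        raise SchemaError(f"male table has unknown column(s): {', '.join(sorted(extra))}")

    records: list[MaleRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        data = dict(zip(df.columns, row))
        try:
            weight = float(data["weight_mg"])
        except (TypeError, ValueError):
            raise RowError(i, f"unparseable weight {data['weight_mg']!r}") from None
        bands = _parse_bands(data["gp9_bands"], i)
        genotype = {
            locus: _parse_genotype(data[locus], locus, i) for locus in config.panel
        }
        truth_ploidy = data.get("truth_ploidy")
        truth_genotype = data.get("truth_genotype")
        rec = MaleRecord(
            male_id=str(data["male_id"]),
            colony_id=str(data["colony_id"]),
            stage=Stage.parse(data["stage"]),
            weight_mg=weight,
            gp9_bands=bands,
            microsat_genotype=genotype,
            truth_ploidy=None if pd.isna(truth_ploidy) else truth_ploidy,
            truth_genotype=None if pd.isna(truth_genotype) else truth_genotype,
        )
        try:
            rec.validate(config.panel)
        except TableValidationError as exc:
            raise RowError(i, str(exc)) from None
        records.append(rec)
    return records


def males_to_frame(records: Iterable[MaleRecord], panel: Sequence[str] = DEFAULT_PANEL) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "male_id": rec.male_id,
            "colony_id": rec.colony_id,
            "stage": rec.stage.value,
            "weight_mg": rec.weight_mg,
            "gp9_bands": "/".join(str(b) for b in sorted(rec.gp9_bands, reverse=True)),
        }
        for locus in panel:
            a, b = rec.microsat_genotype[locus]
            row[locus] = f"{a}/{b}"
        if rec.truth_ploidy is not None:
            row["truth_ploidy"] = rec.truth_ploidy
            row["truth_genotype"] = rec.truth_genotype
        rows.append(row)
    return pd.DataFrame(rows)


def write_male_table(
    records: Sequence[MaleRecord], path: str | Path, config: RunConfig | None = None
) -> None:
    """Write records as a delimited table readable by :func:`read_male_table`."""
    config = config or RunConfig()
    males_to_frame(records, config.panel).to_csv(path, sep=config.sep, index=False)


def read_allele_freqs(path: str | Path, sep: str = "\t") -> AlleleFreqTable:
    """Read a long-format allele table (``locus, allele, frequency|count``).

    A ``count`` column is normalised to frequencies per locus; a
    ``frequency`` column is validated to sum to 1 per locus (tolerance 1e-6).
    """
    df = pd.read_csv(path, sep=sep, dtype={"locus": str, "allele": str})
    if "locus" not in df.columns or "allele" not in df.columns:
        raise SchemaError("allele table needs 'locus' and 'allele' columns")
    if "frequency" in df.columns:
        loci: dict[str, dict[str, float]] = {}
        for locus, grp in df.groupby("locus", sort=False):
            loci[str(locus)] = dict(zip(grp["allele"], grp["frequency"].astype(float)))
        table = AlleleFreqTable(loci)
        table.validate(tol=1e-6)
        return table
    if "count" in df.columns:
        counts: dict[str, dict[str, float]] = {}
        for locus, grp in df.groupby("locus", sort=False):
            counts[str(locus)] = dict(zip(grp["allele"], grp["count"].astype(float)))
        return AlleleFreqTable.from_counts(counts)
    raise SchemaError("allele table needs a 'frequency' or 'count' column")


def write_allele_freqs(table: AlleleFreqTable, path: str | Path, sep: str = "\t") -> None:
    rows = [
        {"locus": locus, "allele": allele, "frequency": freq}
        for locus, freqs in table.loci.items()
        for allele, freq in freqs.items()
    ]
    pd.DataFrame(rows, columns=["locus", "allele", "frequency"]).to_csv(
        path, sep=sep, index=False
    )


_EXECUTION_COLUMNS = ("male_id", "colony_id", "social_form", "ploidy_genotype", "executed")


def read_execution_table(path: str | Path, sep: str = "\t") -> list[ExecutionRecord]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _EXECUTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"execution table missing column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        executed = str(row["executed"]).strip().lower()
        if executed not in ("true", "false", "1", "0"):
            raise RowError(int(i), f"bad executed value {row['executed']!r}")
        hour = row.get("hour_observed")
        hour_val = None if hour is None or pd.isna(hour) or hour == "" else int(float(hour))
        rec = ExecutionRecord(
            male_id=str(row["male_id"]),
            colony_id=str(row["colony_id"]),
            social_form=str(row["social_form"]),
            ploidy_genotype=str(row["ploidy_genotype"]),
            executed=executed in ("true", "1"),
            hour_observed=hour_val,
        )
        try:
            rec.validate()
        except TableValidationError as exc:
            raise RowError(int(i), str(exc)) from None
        records.append(rec)
    return records


def write_execution_table(
    records: Sequence[ExecutionRecord], path: str | Path, sep: str = "\t"
) -> None:
    rows = [
        {
            "male_id": r.male_id,
            "colony_id": r.colony_id,
            "social_form": r.social_form,
            "ploidy_genotype": r.ploidy_genotype,
            "executed": str(r.executed).lower(),
            "hour_observed": "" if r.hour_observed is None else r.hour_observed,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_EXECUTION_COLUMNS + ("hour_observed",)).to_csv(
        path, sep=sep, index=False
    )


def write_report(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    sep: str = "\t",
    title: str = "sbdrive results",
) -> dict[str, Path]:
    """Write each named result table as TSV plus one human-readable summary.

    Output is deterministic given the inputs: section order follows the
    mapping order and floats are rendered with a fixed format.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    text = io.StringIO()
    text.write(f"# {title}\n")
    for name, df in results.items():
        table_path = out_dir / f"{name}.tsv"
        df.to_csv(table_path, sep=sep, index=False, float_format="%.6g")
        paths[name] = table_path
        text.write(f"\n## {name}\n")
        text.write(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        text.write("\n")
    summary_path = out_dir / "report.txt"
    summary_path.write_text(text.getvalue())
    paths["report"] = summary_path
    return paths


def _replace(rec: MaleRecord, **kwargs) -> MaleRecord:
    return replace(rec, **kwargs)
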