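"""End-to-end orchestration: simulate → classify → estimate → test → report.

The pipeline either simulates a polygyne population or reads an existing
male table, classifies ploidy, estimates haplotype frequencies (pooled and
colony-resampled), compares weights, computes nestmate relatedness and
effective queen number, runs the test battery, and writes a consolidated
report. All randomness derives from one master seed: each stage gets a
sub-seed hashed from the stage name, so adding a stage never perturbs the
streams of earlier ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_tables as ct
from . import frequency_resampling as fr
from . import relatedness_kinship as rk
from . import stats_tests as st
from . import synthetic_colonies as sc
from .core_tables import RunConfig, SchemaError, Stage, TableValidationError
from .ploidy_classifier import (
    ClassificationSummary,
    classify_table,
    false_haploid_probability,
)

__all__ = ["PipelineRun", "stage_seed", "validate_config", "run_pipeline"]

_STAGES = ("simulate", "sampling", "execution", "frequencies", "weights", "relatedness")


def stage_seed(master_seed: int, stage_name: str) -> int:
    """Deterministic sub-seed for a named stage (always below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage_name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, collecting all problems at once."""
    text = Path(path).read_text()
    try:
        mapping = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise SchemaError(f"unparseable configuration: {exc}") from None
    if not isinstance(mapping, dict):
        raise SchemaError("configuration must be a mapping")
    cfg = RunConfig.from_mapping(mapping)  # raises SchemaError on unknown keys
    problems = cfg.problems()
    if problems:
        raise TableValidationError("; ".join(problems))
    return cfg


@dataclass
class PipelineRun:
    """Paths and seeds of one completed pipeline run."""

    config: RunConfig
    outputs: dict[str, Path]
    seeds: dict[str, int]
    log_path: Path
    classification: ClassificationSummary
    frequencies: pd.DataFrame
    weights: pd.DataFrame
    relatedness: pd.DataFrame
    tests: pd.DataFrame


def _frequency_block(calls, config: RunConfig, seed: int) -> pd.DataFrame:
    """Stage × haplotype × method frequency table with CIs."""
    rows = []
    for stage in Stage:
        for hap in ("SB", "Sb"):
            try:
                pooled = fr.pooled_frequency(
                    calls, hap, stage, n_boot=config.n_bootstrap,
                    ci_level=config.ci_level, seed=seed,
                )
                rows.append(_est_row(pooled, "uncorrected"))
            except ct.ParameterError:
                pass
            try:
                resampled = fr.colony_resampled_frequency(
                    calls, hap, stage, n_reps=config.n_resample_reps,
                    ci_level=config.ci_level, seed=seed,
                )
                rows.append(_est_row(resampled, "resampled"))
            except ct.ParameterError:
                pass
    return pd.DataFrame(rows)


def _est_row(est: fr.FrequencyEstimate, label: str) -> dict:
    return {
        "stage": est.stage,
        "haplotype": est.haplotype,
        "method": label,
        "point": est.point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_replicates": est.n_replicates,
        "n_units": est.n_units,
    }


def run_pipeline(
    config: RunConfig,
    sim_params: sc.SimParams | None = None,
    out_dir: str | Path | None = None,
) -> PipelineRun:
    """Run every analysis stage and write the consolidated report.

    Input mode is simulation (default, using ``sim_params``) or an existing
    male table named in ``config.male_table``. Stages whose preconditions a
    given dataset cannot meet (e.g. too few pupal colonies for resampling)
    are recorded in the log and skipped rather than aborting the run.
    """
    config.validate()
    out_dir = Path(out_dir or config.out_dir or "sbdrive_out")
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {name: stage_seed(config.seed, name) for name in _STAGES}
    log_lines = [f"seed: {config.seed}", f"stage_seeds: {json.dumps(seeds)}"]
    outputs: dict[str, Path] = {}

    execution_records: list[ct.ExecutionRecord] = []
    if config.male_table:
        males = ct.read_male_table(config.male_table, config)
        if config.allele_freq_table:
            freqs = ct.read_allele_freqs(config.allele_freq_table, sep=config.sep)
        else:
            freqs = sc.default_allele_freqs(config.panel)
            log_lines.append("allele frequencies: package default (no table given)")
        if config.execution_table:
            execution_records = ct.read_execution_table(
                config.execution_table, sep=config.sep
            )
        log_lines.append(f"input: {config.male_table} ({len(males)} males)")
    else:
        if sim_params is None:
            sim_params = sc.SimParams(
                panel=config.panel,
                sampling_design=sc.SamplingDesign(
                    threshold_mg=config.weight_threshold_mg,
                    bin_width_mg=config.bin_width_mg,
                    per_bin_cap=config.per_bin_cap,
                    upper_limit_mg=config.upper_limit_mg,
                ),
            )
        sim_params = replace(sim_params, seed=seeds["simulate"])
        pool = sc.simulate_population(sim_params)
        males = sc.apply_sampling_design(
            pool, sim_params.sampling_design, seed=seeds["sampling"]
        )
        freqs = sim_params.resolved_allele_freqs()
        # execution cohort: small/medium sampled polygyne males plus a
        # monogyne control cohort
        cohort = [m for m in males if m.weight_mg < 8.5][:150]
        execution_records = sc.simulate_execution_assay(
            cohort, sim_params.execution_probs, seed=seeds["execution"]
        )
        mono = sc.simulate_monogyne_cohort(60, seed=seeds["execution"] + 1)
        execution_records += sc.simulate_execution_assay(
            mono, sim_params.execution_probs, seed=seeds["execution"] + 2,
            social_form="monogyne",
        )
        ct.write_male_table(males, out_dir / "males.tsv", config)
        ct.write_allele_freqs(freqs, out_dir / "allele_freqs.tsv", sep=config.sep)
        ct.write_execution_table(
            execution_records, out_dir / "execution.tsv", sep=config.sep
        )
        outputs["males"] = out_dir / "males.tsv"
        outputs["allele_freqs"] = out_dir / "allele_freqs.tsv"
        outputs["execution"] = out_dir / "execution.tsv"
        log_lines.append(
            f"simulated {len(pool)} males in {sim_params.n_colonies} colonies; "
            f"{len(males)} retained by the sampling design"
        )

    # --- classification ---
    summary = classify_table(males, freqs, config.panel, config.fis)
    calls = summary.calls
    log_lines.append("classification counts:\n" + summary.counts.to_string(index=False))
    log_lines.append(
        f"false-haploid probability (panel, HWE): "
        f"{false_haploid_probability(freqs, config.panel, config.fis):.6f}"
    )
    if summary.errors:
        log_lines.append(f"classification errors: {len(summary.errors)}")

    # --- frequencies ---
    freq_df = _frequency_block(calls, config, seeds["frequencies"])

    # --- weights ---
    weight_rows = []
    tests_rows = []
    adult_haploids = [c for c in calls if c.is_haploid and c.stage == Stage.ADULT]
    sb_w = [c.weight_mg for c in adult_haploids if c.supergene_genotype == "Sb"]
    SB_w = [c.weight_mg for c in adult_haploids if c.supergene_genotype == "SB"]
    dip_w = [
        c.weight_mg
        for c in calls
        if c.ploidy == "diploid" and c.stage == Stage.ADULT
    ]
    for hap, w in (("Sb", sb_w), ("SB", SB_w)):
        if w:
            weight_rows.append(
                {"group": f"haploid_{hap}", "mean_mg": float(np.mean(w)), "n": len(w),
                 "method": "uncorrected"}
            )
    if dip_w:
        weight_rows.append(
            {"group": "diploid", "mean_mg": float(np.mean(dip_w)), "n": len(dip_w),
             "method": "uncorrected"}
        )
    try:
        est_SB = fr.colony_resampled_weight(
            calls, "SB", Stage.ADULT, config.n_resample_reps, seeds["weights"]
        )
        est_sb = fr.colony_resampled_weight(
            calls, "Sb", Stage.ADULT, config.n_resample_reps, seeds["weights"]
        )
        for est in (est_sb, est_SB):
            weight_rows.append(
                {"group": f"haploid_{est.haplotype}", "mean_mg": est.point,
                 "n": est.n_units, "method": "resampled",
                 "limit_low": est.ci_low, "limit_high": est.ci_high}
            )
        diff = fr.resampled_weight_difference(est_SB, est_sb)
        tests_rows.append(
            {"test": "resampled_weight_SB_gt_Sb",
             "statistic": diff.fraction_nonpositive,
             "p_value": diff.p_value,
             "note": "P upper bound" if diff.p_is_upper_bound else ""}
        )
    except ct.ParameterError as exc:
        log_lines.append(f"weight resampling skipped: {exc}")
    if len(sb_w) >= 2 and len(SB_w) >= 2:
        t = st.t_test(SB_w, sb_w)
        tests_rows.append({"test": "t_weight_SB_vs_Sb", "statistic": t.statistic,
                           "p_value": t.p_value, "note": f"df={t.df:.1f}"})
    hap_w = sb_w + SB_w
    if len(hap_w) >= 2 and len(dip_w) >= 2:
        t = st.t_test(dip_w, hap_w)
        tests_rows.append({"test": "t_weight_diploid_vs_haploid",
                           "statistic": t.statistic, "p_value": t.p_value,
                           "note": f"df={t.df:.1f}"})
    try:
        adult_df = pd.DataFrame(
            {"weight_mg": [c.weight_mg for c in adult_haploids],
             "colony_id": [c.colony_id for c in adult_haploids],
             "genotype": [c.supergene_genotype for c in adult_haploids]}
        )
        for term, res in st.anova_weight(adult_df).items():
            tests_rows.append(
                {"test": f"anova_{term}", "statistic": res.statistic,
                 "p_value": res.p_value, "note": f"df={res.df}"}
            )
    except ct.ParameterError as exc:
        log_lines.append(f"ANOVA skipped: {exc}")

    # --- binomial vs 0.5 and adult-vs-pupa Fisher ---
    stage_counts = {}
    for stage in Stage:
        hap = [c for c in calls if c.is_haploid and c.stage == stage]
        k = sum(1 for c in hap if c.supergene_genotype == "SB")
        stage_counts[stage] = (k, len(hap))
        if hap:
            res = st.binomial_test_vs_half(k, len(hap))
            tests_rows.append(
                {"test": f"binomial_vs_half_{stage.value}", "statistic": res.statistic,
                 "p_value": res.p_value, "note": res.inputs_digest}
            )
    (ka, na), (kp, np_) = stage_counts[Stage.ADULT], stage_counts[Stage.PUPA]
    if na and np_:
        res = st.fisher_exact_2x2([[ka, na - ka], [kp, np_ - kp]])
        tests_rows.append(
            {"test": "fisher_adult_vs_pupa", "statistic": res.statistic,
             "p_value": res.p_value, "note": res.inputs_digest}
        )

    # --- relatedness & effective queen number ---
    genotypes = {m.male_id: m.microsat_genotype for m in males}
    rel_rows = []
    rel_results: dict[Stage, rk.RelatednessResult] = {}
    for stage in Stage:
        try:
            by_colony = rk.haploid_genotypes_by_colony(calls, genotypes, stage)
            res = rk.colony_and_population_relatedness(
                by_colony, freqs, stage, n_boot=config.n_bootstrap,
                ci_level=config.ci_level, seed=seeds["relatedness"],
            )
            rel_results[stage] = res
            row = {"stage": stage.value, "r": res.r, "ci_low": res.ci_low,
                   "ci_high": res.ci_high, "n_colonies": res.n_colonies,
                   "n_pairs": res.n_pairs}
            if res.r > 0:
                row["effective_queens"] = rk.effective_queen_number(res.r).n_e
            rel_rows.append(row)
        except ct.ParameterError as exc:
            log_lines.append(f"relatedness ({stage.value}) skipped: {exc}")
    if len(rel_results) == 2:
        p = rk.bootstrap_difference_test(
            list(rel_results[Stage.ADULT].colony_values.values()),
            list(rel_results[Stage.PUPA].colony_values.values()),
            n_iter=config.n_bootstrap,
            seed=seeds["relatedness"],
        )
        tests_rows.append(
            {"test": "bootstrap_r_adult_vs_pupa", "statistic": float("nan"),
             "p_value": p, "note": f"iters={config.n_bootstrap}"}
        )

    # --- execution assay ---
    exec_rows = []
    if execution_records:
        report = st.execution_assay_analysis(execution_records)
        for name, prop in report.proportions.items():
            exec_rows.append(
                {"group": name, "executed": prop.successes, "n": prop.n,
                 "proportion": prop.p_hat, "ci_low": prop.ci_low,
                 "ci_high": prop.ci_high}
            )
        for name, res in report.contrasts.items():
            tests_rows.append(
                {"test": f"execution_{name}", "statistic": res.statistic,
                 "p_value": res.p_value, "note": res.inputs_digest}
            )
        if report.skipped:
            log_lines.append(f"execution contrasts skipped: {report.skipped}")

    freq_df = freq_df if not freq_df.empty else pd.DataFrame(
        columns=["stage", "haplotype", "method", "point", "ci_low", "ci_high"]
    )
    weights_df = pd.DataFrame(weight_rows)
    rel_df = pd.DataFrame(rel_rows)
    tests_df = pd.DataFrame(tests_rows)
    report_tables = {
        "classification_counts": summary.counts,
        "haplotype_frequencies": freq_df,
        "weights": weights_df,
        "relatedness": rel_df,
        "test_battery": tests_df,
    }
    if exec_rows:
        report_tables["execution_proportions"] = pd.DataFrame(exec_rows)
    outputs.update(ct.write_report(report_tables, out_dir, sep=config.sep))

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return PipelineRun(
        config=config,
        outputs=outputs,
        seeds=seeds,
        log_path=log_path,
        classification=summary,
        frequencies=freq_df,
        weights=weights_df,
        relatedness=rel_df,
        tests=tests_df,
    )
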