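"""End-to-end orchestration: QC -> instrument selection -> linear MR -> GRS ->
non-linear MR -> observational analyses, with every stage's table written out.

All stage tables are TSV with a fixed float format so that a fixed-seed run is
byte-identical across invocations; the run log records the seed, derived
sub-seeds and every exclusion decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cohort import Cohort
from .genetics import (GenotypeCounts, build_grs, genotype_distribution_table)
from .io import load_run_config, read_cohort, write_cohort
from .linear import all_linear_estimates, compute_summary_associations, estimates_frame
from .nonlinear import nonlinear_mr
from .observational import adjusted_exposure_regression, describe_and_test, quintile_comparison
from .simulate import CovariateSpec, SimulationConfig, SNPSpec, simulate_cohort
from .validate import build_instrument_report, instrument_report_frame, select_instruments

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one data source."""

    seed: int = 0
    out_dir: Path = Path("telomr_run")
    simulation: Optional[SimulationConfig] = None
    phenotype_path: Optional[Path] = None
    genotype_path: Optional[Path] = None
    candidate_snps: Optional[list[str]] = None
    model: str = "over-dominant"
    adjust_covariates: list[str] = field(default_factory=list)
    screen_covariates: list[str] = field(default_factory=list)
    maf_min: float = 0.05
    hwe_alpha: float = 0.05
    exposure_alpha: float = 0.05
    screen_alpha: float = 0.05
    k_strata: int = 5
    n_boot: int = 1000

    def __post_init__(self) -> None:
        has_files = self.phenotype_path is not None and self.genotype_path is not None
        if (self.simulation is None) == (not has_files):
            raise ValueError("provide exactly one of: a simulation block, or "
                             "phenotype + genotype paths")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        sim = None
        if "simulation" in cfg:
            s = dict(cfg["simulation"])
            snps = tuple(SNPSpec(**d) for d in s.pop("snps"))
            covs = tuple(CovariateSpec(**d) for d in s.pop("covariates", []))
            sim = SimulationConfig(snps=snps, covariates=covs,
                                   seed=cfg.get("seed", 0), **s)
        inp = cfg.get("input", {})
        return cls(
            seed=cfg.get("seed", 0),
            out_dir=Path(cfg.get("out_dir", "telomr_run")),
            simulation=sim,
            phenotype_path=Path(inp["phenotypes"]) if inp else None,
            genotype_path=Path(inp["genotypes"]) if inp else None,
            candidate_snps=cfg.get("candidates"),
            model=cfg.get("model", "over-dominant"),
            adjust_covariates=list(cfg.get("adjust_covariates", [])),
            screen_covariates=list(cfg.get("screen_covariates", [])),
            k_strata=int(cfg.get("k_strata", 5)),
            n_boot=int(cfg.get("n_boot", 1000)),
            **cfg.get("thresholds", {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(load_run_config(path))


@dataclass
class PipelineResult:
    cohort: Cohort
    reports: list
    selected: list[str]
    linear_estimates: Optional[list] = None
    nonlinear: Optional[object] = None
    tables: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FMT)
    return path


def load_or_simulate(config: RunConfig) -> Cohort:
    if config.simulation is not None:
        return simulate_cohort(config.simulation)
    return read_cohort(config.phenotype_path, config.genotype_path,
                       required_snps=config.candidate_snps)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole workflow and write one TSV per stage.

    When no candidate survives instrument selection, the MR stages are skipped
    with a structured log message and the partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}", f"model: {config.model}"]

    cohort = load_or_simulate(config)
    log.append(f"cohort: {cohort.n_cases} cases / {cohort.n_controls} controls")
    if config.simulation is not None:
        write_cohort(cohort, out / "cohort")
    candidates = config.candidate_snps or cohort.snp_ids

    # --- stage 1: genotype QC + instrument selection -------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts_cases = {s: GenotypeCounts.from_genotypes(cohort.cases().genotype(s))
                        for s in candidates}
        counts_controls = {s: GenotypeCounts.from_genotypes(cohort.controls().genotype(s))
                           for s in candidates}
        qc = genotype_distribution_table(candidates, counts_cases, counts_controls)
        reports = [
            build_instrument_report(cohort, s, model=config.model,
                                    screen_covariates=config.screen_covariates)
            for s in candidates
        ]
    reports = select_instruments(reports, maf_min=config.maf_min,
                                 hwe_alpha=config.hwe_alpha,
                                 exposure_alpha=config.exposure_alpha,
                                 screen_alpha=config.screen_alpha)
    tables = {"genotype_distribution": _write(qc, out / "genotype_distribution.tsv"),
              "instruments": _write(instrument_report_frame(reports),
                                    out / "instruments.tsv")}
    for r in reports:
        if not r.selected:
            log.append(f"excluded {r.snp_id}: {r.exclusion_reason}")
    selected = [r.snp_id for r in reports if r.selected]
    log.append(f"selected instruments: {', '.join(selected) or '(none)'}")

    result = PipelineResult(cohort, reports, selected, tables=tables, log=log)

    # --- stage 2: observational analyses (always run) ------------------------
    tables["table1"] = _write(describe_and_test(cohort), out / "table1.tsv")
    obs = adjusted_exposure_regression(cohort, covariates=config.adjust_covariates)
    tables["observational_or"] = _write(
        pd.DataFrame([{"odds_ratio": obs.odds_ratio, "ci_low": obs.ci95[0],
                       "ci_high": obs.ci95[1], "p_value": obs.p_value,
                       "n_used": obs.n_used,
                       "adjusted_for": ",".join(obs.adjusted_for)}]),
        out / "observational_or.tsv")
    tables["quintiles"] = _write(quintile_comparison(cohort), out / "quintiles.tsv")

    if not selected:
        log.append("MR stages skipped: zero instruments selected")
        _write_log(out, log, tables)
        return result

    # --- stage 3: linear MR ---------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = compute_summary_associations(
            cohort, selected, model=config.model,
            outcome_covariates=config.adjust_covariates,
        )
        mbe_seed = (config.seed + 1) % 2**31
        log.append(f"mbe bootstrap sub-seed: {mbe_seed}")
        estimates = all_linear_estimates(summary, n_boot=config.n_boot, seed=mbe_seed)
    tables["summary_associations"] = _write(summary.to_frame(),
                                            out / "summary_associations.tsv")
    tables["mr_linear"] = _write(estimates_frame(estimates), out / "mr_linear.tsv")
    result.linear_estimates = estimates

    # --- stage 4: non-linear MR ------------------------------------------------
    grs = build_grs(cohort.genotypes, {s: {1} for s in selected})
    try:
        nl = nonlinear_mr(cohort, grs, k=config.k_strata,
                          covariates=config.adjust_covariates)
    except ValueError as exc:
        log.append(f"non-linear MR skipped: {exc}")
        _write_log(out, log, tables)
        return result
    tables["strata"] = _write(nl.strata_frame(), out / "strata.tsv")
    tables["nonlinear_tests"] = _write(nl.tests_frame(), out / "nonlinear_tests.tsv")
    curves = pd.concat([c.to_frame() for c in nl.curves.values()], ignore_index=True)
    tables["curves"] = _write(curves, out / "curves.tsv")
    result.nonlinear = nl

    _write_log(out, log, tables)
    return result


def _write_log(out: Path, log: list[str], tables: dict[str, Path]) -> None:
    lines = list(log) + [f"table {name}: {path.name}" for name, path in sorted(tables.items())]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
    tables["log"] = out / "run_log.txt"
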