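"""End-to-end orchestration and the command-line interface.

A single YAML config drives a run: synthetic generation (or a discharge
table on disk), cohort preparation, risk adjustment, variation statistics,
multilevel modelling and profiling, with optional variants (largest
hospitals only; coding-intensity recalibration).  Outputs are delimited
text plus a JSON manifest; reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    apply_hospital_filter,
    coding_intensity_covariate,
    cohort_from_flags,
    subset_largest,
)
from .errors import ConfigurationError
from .glmm import cluster_metrics, model_sequence, table2_frame
from .profiling import caterpillar_data, compare_model_variants, flag_hospitals, shrunken_residuals
from .riskadjust import (
    adjusted_incidence,
    c_statistic_from_fit,
    coefficient_table,
    fit_logistic,
    hospital_summaries,
    screen_comorbidities,
)
from .synthetic import GeneratorConfig, generate_discharges, generate_hospitals
from .variation import mean_centred_log_incidence, variation_report

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; defaults mirror the study
    constants (min 30 eligible cases, 2,000 bootstrap reps, alpha 0.05)."""

    output_dir: str = "psivar_out"
    seed: int = 0
    synthetic: dict | None = None
    discharges_path: str | None = None
    hospitals_path: str | None = None
    psi_name: str = "psi"
    is_quasi_sentinel: bool = False
    min_cases: int = 30
    bootstrap_reps: int = 2000
    alpha: float = 0.05
    or_threshold: float = 2.0
    glmm_method: str = "laplace"
    n_quad: int = 9
    zero_policy: str = "error"
    largest_only: bool = False
    largest_min_beds: int = 450
    coding_intensity: bool = False
    coding_threshold: int | str = "median"
    write_discharges: bool = False

    def __post_init__(self):
        if self.synthetic is None and self.discharges_path is None:
            raise ConfigurationError(
                "config needs either a 'synthetic' section or 'discharges_path'"
            )
        if self.min_cases < 1 or self.bootstrap_reps < 1:
            raise ConfigurationError("min_cases and bootstrap_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_canonical_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        gen = GeneratorConfig(**{**config.synthetic, "seed": config.seed})
        hospitals = generate_hospitals(gen)
        discharges = generate_discharges(hospitals, gen)
        comorbidities = gen.comorbidity_names
        psi = gen.psi_name
    else:
        discharges = pd.read_csv(config.discharges_path)
        hospitals = (
            pd.read_csv(config.hospitals_path)
            if config.hospitals_path
            else None
        )
        psi = config.psi_name
        reserved = {"hospital_id", "age", "sex", "n_secondary_dx"}
        comorbidities = [
            c for c in discharges.columns
            if c not in reserved and not c.startswith(("eligible_", "event_"))
        ]
    return discharges, hospitals, comorbidities, psi


def _write(df: pd.DataFrame, path: Path, files: dict) -> None:
    df.to_csv(path, index=False)
    files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _analyse_cohort(
    cohort: Cohort,
    comorbidities: list[str],
    config: RunConfig,
    outdir: Path,
    files: dict,
    tag: str = "",
) -> pd.DataFrame:
    """Full pipeline on one prepared cohort; returns the flagged estimates."""
    suffix = f"_{tag}" if tag else ""
    psi = cohort.psi_name

    if cohort.is_quasi_sentinel:
        covariates: list[str] = []
        selected: list[str] = []
    else:
        candidates = [
            c for c in comorbidities
            if c in cohort.records.columns and cohort.records[c].nunique() > 1
        ]
        selected = (
            screen_comorbidities(cohort, candidates, config.or_threshold)
            if candidates
            else []
        )
        covariates = ["age", "sex"] + selected
        if config.coding_intensity and tag == "coding":
            covariates = covariates + ["high_coding"]

    fit = fit_logistic(cohort, covariates)
    cstat = c_statistic_from_fit(fit, cohort, covariates)
    _write(
        coefficient_table(fit, config.alpha).reset_index(names="term"),
        outdir / f"coefficients_{psi}{suffix}.csv", files,
    )

    summaries = hospital_summaries(fit, cohort, covariates)
    summaries = adjusted_incidence(summaries, cohort.is_quasi_sentinel)
    if cohort.hospitals is not None:
        summaries = summaries.merge(
            cohort.hospitals.reset_index()[
                [c for c in ("hospital_id", "beds", "teaching")
                 if c in cohort.hospitals.reset_index().columns]
            ],
            on="hospital_id", how="left",
        )
    _write(summaries, outdir / f"hospital_summaries_{psi}{suffix}.csv", files)

    report = variation_report(
        summaries,
        quasi_sentinel=cohort.is_quasi_sentinel,
        reps=config.bootstrap_reps,
        alpha=config.alpha,
        seed=config.seed,
        zero_policy=config.zero_policy,
    )
    table1 = report.to_frame()
    table1.insert(0, "psi", psi)
    table1["c_statistic"] = cstat
    _write(table1, outdir / f"variation_{psi}{suffix}.csv", files)
    _write(
        mean_centred_log_incidence(summaries, cohort.is_quasi_sentinel),
        outdir / f"figure1_{psi}{suffix}.csv", files,
    )

    fits = model_sequence(
        cohort, selected + (["high_coding"] if "high_coding" in covariates else []),
        method=config.glmm_method, n_quad=config.n_quad,
    )
    _write(
        table2_frame(fits, config.alpha).reset_index(names="row"),
        outdir / f"table2_{psi}{suffix}.csv", files,
    )

    final = fits[-1]
    estimates = shrunken_residuals(final, cohort)
    flag_report, estimates = flag_hospitals(
        estimates, alpha=config.alpha, psi_name=psi
    )
    cat = caterpillar_data(estimates, alpha=config.alpha)
    _write(cat, outdir / f"caterpillar_{psi}{suffix}.csv", files)
    path = outdir / f"flags_{psi}{suffix}.json"
    path.write_text(json.dumps(flag_report.to_dict(), indent=2, sort_keys=True))
    files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return estimates


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    discharges, hospitals, comorbidities, psi = _load_inputs(config)
    if config.write_discharges:
        _write(discharges, outdir / f"discharges_{psi}.csv", files)
        if hospitals is not None:
            _write(hospitals, outdir / f"hospitals_{psi}.csv", files)

    cohort = cohort_from_flags(
        discharges, psi, hospital_attrs=hospitals,
        is_quasi_sentinel=config.is_quasi_sentinel,
    )
    cohort = apply_hospital_filter(cohort, config.min_cases)
    if cohort.exclusions:
        excl = pd.DataFrame(
            cohort.exclusions, columns=["hospital_id", "n_eligible", "reason"]
        )
        _write(excl, outdir / f"exclusions_{psi}.csv", files)

    estimates = _analyse_cohort(cohort, comorbidities, config, outdir, files)

    if config.largest_only:
        big = subset_largest(cohort, min_beds=config.largest_min_beds)
        big = apply_hospital_filter(big, config.min_cases)
        est_big = _analyse_cohort(
            big, comorbidities, config, outdir, files, tag="largest"
        )
    if config.coding_intensity:
        coded, thr = coding_intensity_covariate(cohort, config.coding_threshold)
        est_coding = _analyse_cohort(
            coded, comorbidities, config, outdir, files, tag="coding"
        )
        comparison = compare_model_variants(estimates, est_coding)
        comparison["coding_threshold"] = thr
        path = outdir / f"coding_comparison_{psi}.json"
        path.write_text(json.dumps(comparison, indent=2, sort_keys=True))
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "config": yaml.safe_load(config.to_canonical_yaml()),
        "files": dict(sorted(files.items())),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


# ----------------------------------------------------------------- CLI


@click.group()
@click.version_option(__version__)
def cli():
    """Hospital safety-indicator variation and profiling pipeline."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


def _config_from(path, seed, output_dir):
    config = RunConfig.from_yaml(path)
    if seed is not None:
        config.seed = seed
    if output_dir is not None:
        config.output_dir = output_dir
    return config


_config_opt = click.option(
    "--config", "config_path", required=True,
    type=click.Path(exists=True, dir_okay=False),
)
_seed_opt = click.option("--seed", type=int, default=None)
_out_opt = click.option("--out", "output_dir", type=click.Path(), default=None)


@cli.command("simulate")
@_config_opt
@_seed_opt
@_out_opt
def simulate_cmd(config_path, seed, output_dir):
    """Generate synthetic discharge and hospital tables."""
    config = _config_from(config_path, seed, output_dir)
    if config.synthetic is None:
        raise click.UsageError("config has no 'synthetic' section")
    gen = GeneratorConfig(**{**config.synthetic, "seed": config.seed})
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    hospitals = generate_hospitals(gen)
    discharges = generate_discharges(hospitals, gen)
    hospitals.to_csv(outdir / f"hospitals_{gen.psi_name}.csv", index=False)
    discharges.to_csv(outdir / f"discharges_{gen.psi_name}.csv", index=False)
    click.echo(
        f"wrote {len(discharges)} discharges across {len(hospitals)} hospitals"
    )


@cli.command("run-all")
@_config_opt
@_seed_opt
@_out_opt
def run_all_cmd(config_path, seed, output_dir):
    """Full pipeline: prepare, adjust, variation, glmm, profile."""
    config = _config_from(config_path, seed, output_dir)
    manifest = run_analysis(config)
    click.echo(json.dumps({"config_sha256": manifest["config_sha256"],
                           "n_files": len(manifest["files"])}))


def _partial_command(name, help_text, **overrides):
    @cli.command(name, help=help_text)
    @_config_opt
    @_seed_opt
    @_out_opt
    def _cmd(config_path, seed, output_dir):
        config = _config_from(config_path, seed, output_dir)
        for k, v in overrides.items():
            setattr(config, k, v)
        run_analysis(config)
        click.echo(f"{name}: done")

    _cmd.__name__ = f"{name.replace('-', '_')}_cmd"
    return _cmd


# stage verbs reuse the pipeline; variants are toggled via config flags
prepare_cmd = _partial_command(
    "prepare", "Build and filter the analysis cohort (runs the pipeline)."
)
adjust_cmd = _partial_command(
    "adjust", "Patient-level risk adjustment and hospital summaries."
)
variation_cmd = _partial_command(
    "variation", "RV ratios and systematic-variation statistic."
)
glmm_cmd = _partial_command("glmm", "Random-intercept logistic model sequence.")
profile_cmd = _partial_command(
    "profile", "Shrunken residuals, flags and caterpillar data."
)


if __name__ == "__main__":  # pragma: no cover
    cli()
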