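"""End-to-end orchestration: survey -> model -> scenarios -> reports.

One :class:`RunConfig` drives a reproducible run: a survey CSV *or* a
synthetic-survey configuration (exactly one), an intake table, a scenario
configuration, and optionally an external coefficient file that bypasses
fitting.  Outputs are plain files in the output directory plus a manifest
recording the seed, package version and SHA-256 of every input, so that
identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from . import __version__
from .composition import load_baseline_intakes, read_group_intake_table
from .regression import (
    COVARIATE_TERMS,
    DEFAULT_TERMS,
    backward_stepwise_aic,
    covariate_means,
    evaluate_scenarios,
    load_demo_model,
    TGModel,
)
from .reporting import scenario_table, write_nutrient_diff, nutrient_diff
from .scenarios import scenario_library
from .survey import GeneratorConfig, generate_population, read_survey_csv

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs of one reproducible pipeline run."""

    out_dir: Union[str, Path] = "dietsim_out"
    seed: int = 0
    intake_table: Union[str, Path, None] = None      # default: packaged fixture
    allow_missing_as_zero: bool = False
    survey_csv: Union[str, Path, None] = None
    synth: GeneratorConfig | None = None
    scenario_config: Union[str, Path, dict, None] = None
    scenario_ids: tuple[str, ...] = ()               # () = whole library
    coefficients_csv: Union[str, Path, None] = None  # skip fitting if given
    stepwise: bool = True
    terms: tuple[str, ...] = DEFAULT_TERMS
    smearing: bool = False
    write_diffs: bool = True
    extra_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.survey_csv is not None and self.synth is not None:
            raise ValueError("supply exactly one of survey_csv / synth config")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dietsim",
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        **config.extra_manifest,
    }

    # -- inputs ------------------------------------------------------------
    baseline = _stage("intake_table")(_load_intakes)(config, manifest)
    records = _stage("survey")(_load_survey)(config, manifest, out)

    # -- triglyceride model -------------------------------------------------
    model = _stage("fit")(_get_model)(config, manifest, records)
    (out / "model_report.json").write_text(
        json.dumps(model.report(), indent=2) + "\n", encoding="utf-8"
    )

    # -- scenarios -----------------------------------------------------------
    specs = _stage("scenarios")(scenario_library)(config.scenario_config)
    if config.scenario_ids:
        by_id = {s.id: s for s in specs}
        missing = [i for i in config.scenario_ids if i not in by_id]
        if missing:
            raise PipelineError(f"stage 'scenarios': unknown scenario ids {missing}")
        specs = [by_id[i] for i in config.scenario_ids]
    covs = {}
    if records is not None:
        wanted = [t for t in model.terms if t in COVARIATE_TERMS]
        if wanted:
            covs = covariate_means(records, wanted)
    results = _stage("predict")(evaluate_scenarios)(
        model, baseline, specs, covariates=covs, smearing=config.smearing
    )

    # -- reports -------------------------------------------------------------
    scenario_table(results, out / "scenario_results.csv", fmt="csv")
    scenario_table(results, out / "scenario_results.json", fmt="json")
    if config.write_diffs:
        diff_dir = out / "nutrient_diffs"
        diff_dir.mkdir(exist_ok=True)
        base_total = baseline.aggregate_total()
        for r in results:
            write_nutrient_diff(
                nutrient_diff(base_total, r.modelled_total),
                diff_dir / f"{r.scenario_id}.csv",
            )
    manifest["n_scenarios"] = len(results)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("pipeline complete: %s (%d scenarios)", out, len(results))
    return out


def _load_intakes(config: RunConfig, manifest: dict):
    if config.intake_table is None:
        manifest["inputs"]["intake_table"] = "packaged baseline fixture"
        return load_baseline_intakes()
    p = Path(config.intake_table)
    manifest["inputs"]["intake_table"] = {"path": str(p), "sha256": _sha256(p)}
    return read_group_intake_table(
        p, allow_missing_as_zero=config.allow_missing_as_zero
    )


def _load_survey(config: RunConfig, manifest: dict, out: Path):
    if config.survey_csv is not None:
        p = Path(config.survey_csv)
        manifest["inputs"]["survey"] = {"path": str(p), "sha256": _sha256(p)}
        return read_survey_csv(p)
    if config.synth is not None:
        synth = config.synth
        synth.seed = config.seed
        records = generate_population(synth)
        manifest["inputs"]["survey"] = {
            "synthetic": True, "n": synth.n, "seed": synth.seed,
            "sigma": synth.sigma, "intake_cv": synth.intake_cv,
        }
        return records
    manifest["inputs"]["survey"] = None
    return None


def _get_model(config: RunConfig, manifest: dict, records) -> TGModel:
    if config.coefficients_csv is not None:
        p = Path(config.coefficients_csv)
        manifest["inputs"]["coefficients"] = {"path": str(p), "sha256": _sha256(p)}
        return TGModel.from_coefficients_csv(p)
    if records is None:
        manifest["inputs"]["coefficients"] = "packaged demo coefficients"
        return load_demo_model()
    if config.stepwise:
        return backward_stepwise_aic(records, config.terms)
    from .regression import fit_ols_log_tg

    return fit_ols_log_tg(records, config.terms)
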