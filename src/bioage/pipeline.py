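"""End-to-end orchestration: simulate/ingest -> eligibility -> selection ->
model fits -> predictions -> evaluation, with a reproducible run manifest.

Identical config + seed yields byte-identical artifacts: all floats are
serialised at full precision (repr), display rounding happens only in the
rendered report tables, and the manifest records no wall-clock state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    FOLLOWUP_CAP_DAYS,
    CohortTable,
    ParameterMatrix,
    apply_exclusions,
    read_parameter_table,
    truncate_followup,
    write_parameter_table,
)
from .kdm import KlemeraDoubal
from .pca import PCABioAge
from .roc import AGE_EDGES, STRATA, _stratum_mask, incidence_rate, stratified_evaluation
from .selection import select_parameters
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "bioage_run"
    seed: int = 0
    input_path: str | None = None  # if None, simulate
    simulate: GeneratorConfig | None = None
    age_threshold: float = 0.2
    collinearity_threshold: float = 0.9
    eigenvalue_cutoff: float = 1.0
    followup_cap_days: float = FOLLOWUP_CAP_DAYS
    sex_mode: str = "union"  # union | intersection | male | female
    age_edges: tuple[float, float, float] = AGE_EDGES

    def validate(self) -> None:
        if not (0 < self.age_threshold <= 1):
            raise ValueError("age_threshold must lie in (0, 1]")
        if not (0 < self.collinearity_threshold <= 1):
            raise ValueError("collinearity_threshold must lie in (0, 1]")
        if self.eigenvalue_cutoff <= 0:
            raise ValueError("eigenvalue_cutoff must be positive")
        if self.followup_cap_days <= 0:
            raise ValueError("followup_cap_days must be positive")
        if self.sex_mode not in ("intersection", "union", "male", "female"):
            raise ValueError(f"unknown sex_mode {self.sex_mode!r}")
        edges = self.age_edges
        if not (len(edges) == 3 and edges[0] < edges[1] < edges[2]):
            raise ValueError("age_edges must be three strictly increasing values")
        if self.input_path is None and self.simulate is None:
            raise ValueError("either input_path or a simulation config is required")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.simulate = GeneratorConfig(**sim)
        if cfg.age_edges is not None:
            cfg.age_edges = tuple(cfg.age_edges)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_edges"] = list(self.age_edges)
        return d


@dataclass
class RunResult:
    config: RunConfig
    manifest: dict
    cohort: CohortTable
    ages: pd.DataFrame
    selection: dict
    evaluation: dict
    tables: dict = field(default_factory=dict)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _distribution_table(ages: pd.DataFrame, edges) -> dict:
    """Mean/SD/min/max of CA and the three biological ages, overall and per
    CA category."""
    out = {}
    ca = ages["ca"].to_numpy(dtype=float)
    for stratum in STRATA:
        mask = _stratum_mask(ca, stratum, edges)
        if mask.sum() == 0:
            out[stratum] = None
            continue
        sub = ages.loc[mask]
        out[stratum] = {
            pred: {
                "mean": float(sub[pred].mean()),
                "sd": float(sub[pred].std(ddof=1)) if mask.sum() > 1 else 0.0,
                "min": float(sub[pred].min()),
                "max": float(sub[pred].max()),
            }
            for pred in ("ca", "ba", "ba_e", "ba_ec")
        }
    return out


def _death_table(cohort: CohortTable, edges) -> dict:
    """Death counts and crude incidence, overall and per CA category."""
    ca = cohort.ca_years.to_numpy(dtype=float)
    out = {}
    for stratum in STRATA:
        mask = _stratum_mask(ca, stratum, edges)
        sub = cohort.frame.loc[mask]
        n = len(sub)
        deaths = int((sub["status"] == "all_cause_death").sum())
        cv = int((sub["death_cause"] == "cardiovascular").sum())
        mean_fu = float(sub["followup_days"].mean()) if n else 0.0
        out[stratum] = {
            "n": n,
            "all_cause_deaths": deaths,
            "cardiovascular_deaths": cv,
            "non_cardiovascular_deaths": deaths - cv,
            "mean_followup_days": mean_fu,
            "rate_per_100py": incidence_rate(deaths, n, mean_fu) if n and mean_fu > 0 else None,
        }
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write per-stage artifacts under
    ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_written: dict[str, str] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("input")
        if config.input_path is not None:
            cohort, params = read_parameter_table(config.input_path)
        else:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            cohort, params, truth = generate_cohort(sim)
            truth.true_biological_age.to_csv(out / "latent_truth.csv")
            stages_written["latent_truth"] = "latent_truth.csv"
        n_input = cohort.n

        _stage("exclusions")
        cohort, params, excl_report = apply_exclusions(cohort, params)
        _stage("truncation")
        cohort = truncate_followup(cohort, config.followup_cap_days)
        params = params.drop_constant_columns()
        write_parameter_table(cohort, params, out / "cohort.csv")
        stages_written["cohort"] = "cohort.csv"

        _stage("selection")
        report = select_parameters(
            params, cohort, config.age_threshold, config.collinearity_threshold
        )
        columns = report.selected(config.sex_mode)
        if not columns:
            raise RuntimeError(
                f"selection ({config.sex_mode}) retained no parameters; "
                "lower the age threshold or inspect the selection report"
            )
        _json_dump(report.to_dict(), out / "selection.json")
        stages_written["selection"] = "selection.json"

        _stage("fit_pca")
        pca_res = PCABioAge(params, cohort, columns, config.eigenvalue_cutoff).fit()
        pca_res.to_json(out / "model_pca.json")
        stages_written["model_pca"] = "model_pca.json"

        _stage("fit_kdm")
        kdm_res = KlemeraDoubal(params, cohort, columns).fit()
        kdm_res.to_json(out / "model_kdm.json")
        stages_written["model_kdm"] = "model_kdm.json"

        _stage("predict")
        ca = cohort.ca_years
        ages = pd.DataFrame(
            {
                "ca": ca,
                "ba": pca_res.predict(params, ca),
                "ba_e": kdm_res.predict_ba_e(params),
                "ba_ec": kdm_res.predict_ba_ec(params, ca),
            }
        )
        ages.to_csv(out / "ages.csv")
        stages_written["ages"] = "ages.csv"

        _stage("evaluate")
        outcomes = pd.DataFrame(
            {
                "all_cause_death": cohort.is_dead.astype(int),
                "cardiovascular_death": cohort.is_cv_death.astype(int),
            }
        )
        comparison = stratified_evaluation(ages, outcomes, edges=config.age_edges)

        table2 = _death_table(cohort, config.age_edges)
        table3 = _distribution_table(ages, config.age_edges)
        table4 = comparison.to_dict()
        _json_dump(table2, out / "table2_deaths.json")
        _json_dump(table3, out / "table3_distributions.json")
        _json_dump(table4, out / "table4_auc.json")
        comparison.frame().to_csv(out / "table4_auc.tsv", sep="\t", index=False)
        stages_written.update(
            {
                "table2": "table2_deaths.json",
                "table3": "table3_distributions.json",
                "table4": "table4_auc.json",
            }
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {_current_stage(stages_written)}: {exc}") from exc

    # out_dir is location, not configuration: identical runs into different
    # directories must produce identical manifests.
    config_dict = config.to_dict()
    config_dict.pop("out_dir")
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_input": n_input,
        "n_analyzed": cohort.n,
        "exclusions": excl_report,
        "n_selected_parameters": len(columns),
        "artifacts": {
            name: {"path": rel, "sha256": _sha256(out / rel)} for name, rel in stages_written.items()
        },
    }
    _json_dump(manifest, out / "manifest.json")
    return RunResult(
        config=config,
        manifest=manifest,
        cohort=cohort,
        ages=ages,
        selection=report.to_dict(),
        evaluation=table4,
        tables={"table2": table2, "table3": table3, "table4": table4},
    )


def _current_stage(stages_written: dict) -> str:
    order = ["input", "cohort", "selection", "model_pca", "model_kdm", "ages", "table4"]
    done = set(stages_written)
    for name in order:
        if name not in done:
            return name
    return "finalize"
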