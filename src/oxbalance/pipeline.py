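"""Configuration-driven orchestration: simulate -> score -> analyze ->
mediate -> render tables, with a machine-readable run manifest.

A single global seed fans out deterministically to per-stage child seeds so
stages can be re-run in isolation; every output records the seed used.
Stage failures abort the run with the failing stage named and a ``FAILED``
marker left in the output directory alongside any partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import biomarker_associations
from .components import default_components, load_components
from .mediation import mediation_suite
from .scoring import categorize_quartiles, score_cohort
from .simulate import SimulationConfig, generate_cohort
from .survival import (
    ModelSpec,
    baseline_table,
    fit_cox,
    leave_one_out,
    results_to_frame,
    subscore_analysis,
)

log = logging.getLogger("oxbalance")

KNOWN_ANALYSES = (
    "baseline",
    "cox",
    "complications",
    "biomarkers",
    "subscores",
    "leave_one_out",
    "mediation",
)
SUBSITE_OUTCOMES = ("crc", "proximal", "distal", "rectal")
COMPLICATION_OUTCOMES = ("metastasis", "obstruction", "abdominal_pain")
SEX_SUBGROUPS = (
    (None, "overall"),
    ("sex == 'male'", "male"),
    ("sex == 'female'", "female"),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """What to run, on which input, where to write."""

    outdir: str | Path = "oxbalance_run"
    seed: int = 0
    input_path: str | Path | None = None  # cohort CSV; None -> simulate
    simulation: SimulationConfig | None = None
    components_path: str | Path | None = None
    analyses: tuple[str, ...] = KNOWN_ANALYSES
    mediation_sims: int = 500

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise PipelineError(f"unknown analyses requested: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            **{k: v for k, v in raw.items() if k != "analyses"},
            analyses=tuple(raw.get("analyses", KNOWN_ANALYSES)),
        )
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "input_path": str(self.input_path) if self.input_path else None,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "components_path": str(self.components_path)
            if self.components_path
            else None,
            "analyses": list(self.analyses),
            "mediation_sims": self.mediation_sims,
        }


def _child_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, children)
    }


def _config_hash(config: RunConfig) -> str:
    payload = config.to_dict()
    payload.pop("outdir", None)  # where results land is not part of the run
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, na_rep="")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in dependency order; returns the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage_seeds = _child_seeds(config.seed, ("simulate", "mediation"))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "stages": {},
        "row_counts": {},
    }
    stage = "setup"
    try:
        specs = (
            load_components(config.components_path)
            if config.components_path
            else default_components()
        )

        stage = "cohort"
        if config.input_path is not None:
            cohort = pd.read_csv(config.input_path)
            log.info("loaded cohort: %d rows from %s", len(cohort), config.input_path)
        else:
            sim = config.simulation or SimulationConfig()
            sim = replace(sim, seed=stage_seeds["simulate"])
            simulated = generate_cohort(sim, specs)
            simulated.write(outdir / "cohort.csv")
            cohort = simulated.cohort
            (outdir / "simulation_config.json").write_text(
                json.dumps(sim.to_dict(), indent=2)
            )
            log.info("simulated cohort: %d rows", len(cohort))
        manifest["row_counts"]["cohort"] = int(len(cohort))
        manifest["stages"]["cohort"] = "ok"

        stage = "score"
        scored = categorize_quartiles(score_cohort(cohort, specs))
        _write_csv(scored.data, outdir / "scored.csv")
        (outdir / "exclusions.json").write_text(json.dumps(scored.exclusions, indent=2))
        manifest["row_counts"]["scored"] = int(len(scored.data))
        manifest["quartile_edges"] = list(scored.quartile_edges)
        manifest["stages"]["score"] = "ok"
        log.info(
            "scored cohort: %d retained, %d excluded",
            scored.exclusions["n_retained"],
            scored.exclusions["n_excluded"],
        )

        if "baseline" in config.analyses:
            stage = "baseline"
            _write_csv(baseline_table(scored), outdir / "table_baseline.csv")
            manifest["stages"]["baseline"] = "ok"

        if "cox" in config.analyses:
            stage = "cox"
            results = []
            for outcome in SUBSITE_OUTCOMES:
                for subgroup, label in SEX_SUBGROUPS:
                    for model_id in (1, 2, 3):
                        for form in ("continuous", "quartile"):
                            spec = ModelSpec(
                                model_id=model_id,
                                exposure_form=form,
                                outcome=outcome,
                                subgroup=subgroup,
                                subgroup_label=label,
                            )
                            results.extend(fit_cox(scored, spec))
            _write_csv(results_to_frame(results), outdir / "table_cox.csv")
            manifest["stages"]["cox"] = "ok"

        if "complications" in config.analyses:
            stage = "complications"
            cases = scored.data[scored.data["crc"] == 1]
            results = []
            for outcome in COMPLICATION_OUTCOMES:
                for model_id in (1, 2, 3):
                    spec = ModelSpec(
                        model_id=model_id, outcome=outcome, subgroup_label="crc cases"
                    )
                    results.extend(fit_cox(cases, spec))
            _write_csv(results_to_frame(results), outdir / "table_complications.csv")
            manifest["stages"]["complications"] = "ok"

        if "biomarkers" in config.analyses:
            stage = "biomarkers"
            _write_csv(biomarker_associations(scored), outdir / "table_biomarkers.csv")
            manifest["stages"]["biomarkers"] = "ok"

        if "subscores" in config.analyses:
            stage = "subscores"
            rows = []
            for subgroup, label in SEX_SUBGROUPS:
                for model_id in (1, 2, 3):
                    spec = ModelSpec(
                        model_id=model_id, subgroup=subgroup, subgroup_label=label
                    )
                    for sub, res in subscore_analysis(scored, spec).items():
                        rows.append(res)
            frame = results_to_frame(rows)
            _write_csv(frame, outdir / "table_subscores.csv")
            manifest["stages"]["subscores"] = "ok"

        if "leave_one_out" in config.analyses:
            stage = "leave_one_out"
            _write_csv(leave_one_out(scored), outdir / "table_leave_one_out.csv")
            manifest["stages"]["leave_one_out"] = "ok"

        if "mediation" in config.analyses:
            stage = "mediation"
            results = mediation_suite(
                scored, n_sims=config.mediation_sims, seed=stage_seeds["mediation"]
            )
            payload = {}
            lines = []
            for mediator, res in results.items():
                payload[mediator] = {
                    "ie": res.ie,
                    "de": res.de,
                    "total": res.total,
                    "prop_mediated_pct": res.prop_mediated_pct,
                    "sign_flipped": res.sign_flipped,
                    "ci": res.ci,
                    "significant_ie": res.significant_ie,
                    "path_a": res.path_a,
                    "path_b": res.path_b,
                    "n_used": res.n_used,
                    "n_sims": res.n_sims,
                    "seed": res.seed,
                    "status": res.status,
                }
                lines.extend(res.summary_lines() + [""])
            (outdir / "mediation.json").write_text(json.dumps(payload, indent=2))
            (outdir / "mediation_summary.txt").write_text("\n".join(lines))
            manifest["stages"]["mediation"] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        failed_marker.write_text(f"stage {stage!r} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
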