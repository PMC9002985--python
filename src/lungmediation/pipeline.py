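"""One-command orchestration: simulate -> fit -> effects -> bootstrap ->
sensitivity -> report.

The pipeline is configured by a YAML/JSON mapping with exactly one cohort
source (``input`` path or ``generate`` block), a mandatory ``seed``, and
optional model/bootstrap/sensitivity blocks. Each configured line and
bronchodilator state produces a parallel set of artifacts; a run manifest
records the configuration hash, seed and package version so any bundle can
be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapConfig, BootstrapSummary, bootstrap_effects, percentile_ci
from .coefficients import CONTRASTS, ModelSpec, PathCoefficients
from .cohort import CohortTable, SchemaConfig, read_cohort, summarize_cohort, write_cohort
from .effects import classify_mediation, decompose_effects
from .model import fit_multigroup_model
from .sensitivity import (DEFAULT_BETA_GRID, SensitivityScenario, grid_frame,
                          run_grid, scenario_from_paths)
from .synthetic import GeneratorParams, default_generator_params, generate_cohort

logger = logging.getLogger(__name__)

INDIRECT_PATHWAYS = ("nie_via_m1", "nie_via_m2", "nie_via_m1_m2")
PATHWAY_LABELS = {
    "nde": "direct",
    "nie_via_m1": "via offspring overweight",
    "nie_via_m2": "via offspring height",
    "nie_via_m1_m2": "via offspring overweight and height",
    "total": "total",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    input_path: str | None = None
    schema_path: str | None = None
    generate: dict | None = None
    lines: tuple = ("paternal",)
    bronchodilator_states: tuple = ("pre",)
    outcome_set: str = "fev1_fvc_pair"
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    sensitivity: dict | None = None
    min_group_n: int = 50

    def validate(self) -> "PipelineConfig":
        if (self.input_path is None) == (self.generate is None):
            raise PipelineError(
                "exactly one of 'input' and 'generate' must be configured")
        if self.seed is None:
            raise PipelineError("a seed is mandatory")
        return self

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "seed" not in payload:
            raise PipelineError("a seed is mandatory")
        boot = BootstrapConfig(**payload.pop("bootstrap", {}))
        if "seed" not in payload.get("_bootstrap_seed_override", {}):
            boot.seed = int(payload["seed"])
        return cls(
            seed=int(payload["seed"]),
            output_dir=payload.get("output_dir", "lungmediation_out"),
            input_path=payload.get("input"),
            schema_path=payload.get("schema"),
            generate=payload.get("generate"),
            lines=tuple(payload.get("lines", ("paternal",))),
            bronchodilator_states=tuple(payload.get("bronchodilator", ("pre",))),
            outcome_set=payload.get("outcome_set", "fev1_fvc_pair"),
            bootstrap=boot,
            sensitivity=payload.get("sensitivity"),
        ).validate()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path).read()
        payload = yaml.safe_load(text)
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "output_dir": self.output_dir,
            "input": self.input_path, "schema": self.schema_path,
            "generate": self.generate, "lines": list(self.lines),
            "bronchodilator": list(self.bronchodilator_states),
            "outcome_set": self.outcome_set,
            "bootstrap": {"b": self.bootstrap.b, "seed": self.bootstrap.seed,
                          "levels": list(self.bootstrap.levels),
                          "min_success": self.bootstrap.min_success},
            "sensitivity": self.sensitivity,
        }


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def indirect_effects_frame(summary: BootstrapSummary) -> pd.DataFrame:
    """Indirect-effects report: contrast x pathway x group x outcome rows."""
    tab = summary.table
    sel = tab[tab.effect.isin(INDIRECT_PATHWAYS) & (tab.group != "delta")].copy()
    sel["pathway"] = sel.effect.map(PATHWAY_LABELS)
    cols = ["contrast", "pathway", "group", "outcome",
            "estimate", "lower", "upper", "significant"]
    return sel[cols].reset_index(drop=True)


def direct_effects_frame(summary: BootstrapSummary, coefs_by_group: dict,
                         levels=(2.5, 97.5)) -> pd.DataFrame:
    """Direct-effects report: exposure NDE rows plus mediator-path rows.

    Exposure rows carry bootstrap intervals from the effects summary;
    mediator-path rows (latent-overweight -> height / outcomes,
    height -> outcomes, exposure -> mediators) get intervals from the
    retained per-resample coefficient draws when available.
    """
    rows = []
    tab = summary.table
    for contrast in CONTRASTS:
        for group, cf in coefs_by_group.items():
            for outcome in cf.outcomes:
                hit = tab[(tab.contrast == contrast) & (tab.group == group) &
                          (tab.outcome == outcome) & (tab.effect == "nde")]
                r = hit.iloc[0]
                rows.append({"predictor": f"exposure_{contrast}", "target": outcome,
                             "group": group, "estimate": r.estimate,
                             "lower": r.lower, "upper": r.upper,
                             "significant": r.significant})

    def path_entries(cf: PathCoefficients):
        entries = [("exposure_before_puberty_vs_never", "latent_overweight", cf.a[1]),
                   ("exposure_at30_vs_never", "latent_overweight", cf.a[2]),
                   ("exposure_before_puberty_vs_never", "height_cm", cf.h[1]),
                   ("exposure_at30_vs_never", "height_cm", cf.h[2]),
                   ("latent_overweight", "height_cm", cf.d)]
        for k, outcome in enumerate(cf.outcomes):
            entries.append(("latent_overweight", outcome, cf.b1[k]))
            entries.append(("height_cm", outcome, cf.b2[k]))
        return entries

    for group, cf in coefs_by_group.items():
        draws = summary.coefficient_draws.get(group)
        ref_vecs = None
        if draws is not None and len(draws):
            ref_vecs = [PathCoefficients.from_vector(v, cf.outcomes)
                        for v in draws]
        entries = path_entries(cf)
        for i, (predictor, target, value) in enumerate(entries):
            lower = upper = np.nan
            significant = None
            if ref_vecs is not None:
                vals = np.array([path_entries(rv)[i][2] for rv in ref_vecs])
                lower, upper = percentile_ci(vals, levels)
                significant = bool(lower > 0 or upper < 0)
            rows.append({"predictor": predictor, "target": target, "group": group,
                         "estimate": float(value), "lower": lower, "upper": upper,
                         "significant": significant})
    return pd.DataFrame(rows)


def mediation_summary_text(summary: BootstrapSummary) -> str:
    """Plain-text mediation classification per contrast/outcome/pathway."""
    lines = []
    tab = summary.table
    for contrast in CONTRASTS:
        for outcome in sorted(tab.outcome.unique()):
            for group in ("son", "daughter"):
                nde = tab[(tab.contrast == contrast) & (tab.group == group) &
                          (tab.outcome == outcome) & (tab.effect == "nde")].iloc[0]
                for pathway in INDIRECT_PATHWAYS:
                    nie = tab[(tab.contrast == contrast) & (tab.group == group) &
                              (tab.outcome == outcome) &
                              (tab.effect == pathway)].iloc[0]
                    cls = classify_mediation(
                        bool(nde.significant), bool(nie.significant),
                        bool(np.sign(nde.estimate) == np.sign(nie.estimate)))
                    lines.append(
                        f"{contrast} | {outcome} | {group} | "
                        f"{PATHWAY_LABELS[pathway]}: {cls}")
    return "\n".join(lines) + "\n"


def write_report(outputs: dict, out_dir: Path) -> dict:
    """Write per-stage report files; returns a name->path mapping."""
    written = {}
    for label, payload in outputs.items():
        summary: BootstrapSummary = payload["bootstrap"]
        coefs = payload["coefficients"]
        ind = indirect_effects_frame(summary)
        direct = direct_effects_frame(summary, coefs, summary.levels)
        paths = {
            f"indirect_effects_{label}": out_dir / f"indirect_effects_{label}.csv",
            f"direct_effects_{label}": out_dir / f"direct_effects_{label}.csv",
            f"bootstrap_{label}": out_dir / f"bootstrap_{label}.csv",
            f"mediation_{label}": out_dir / f"mediation_{label}.txt",
            f"effects_{label}": out_dir / f"effects_{label}.json",
        }
        ind.to_csv(paths[f"indirect_effects_{label}"], index=False)
        direct.to_csv(paths[f"direct_effects_{label}"], index=False)
        summary.table.to_csv(paths[f"bootstrap_{label}"], index=False)
        paths[f"mediation_{label}"].write_text(mediation_summary_text(summary))
        unrounded = [decompose_effects(cf, contrast, group, outcome).as_dict()
                     for group, cf in coefs.items()
                     for contrast in CONTRASTS for outcome in cf.outcomes]
        paths[f"effects_{label}"].write_text(json.dumps(unrounded, indent=1))
        written.update({k: str(v) for k, v in paths.items()})
    return written


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _load_cohort(config: PipelineConfig, out_dir: Path) -> CohortTable:
    if config.input_path is not None:
        schema = SchemaConfig.from_file(config.schema_path) \
            if config.schema_path else None
        return read_cohort(config.input_path, schema)
    gen = dict(config.generate)
    n_parents = int(gen.pop("n_parents", 500))
    line = gen.pop("line", config.lines[0])
    if "params" in gen:
        params = GeneratorParams.from_dict(gen["params"])
    else:
        params = default_generator_params(line)
    table, oracle = generate_cohort(params, n_parents, config.seed)
    write_cohort(table, out_dir / "cohort.csv")
    pd.DataFrame({"offspring_id": oracle.offspring_id,
                  "m1_star": oracle.m1_star}).to_csv(
        out_dir / "oracle.csv", index=False)
    (out_dir / "generator_params.json").write_text(
        json.dumps(params.to_dict(), indent=1))
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the artifact manifest.

    Any stage failure aborts with the stage name while keeping the
    artifacts already written.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "artifacts": {},
        "stages_completed": [],
    }

    def fail(stage, exc):
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    try:
        table = _load_cohort(config, out_dir)
    except Exception as exc:
        fail("load", exc)
    manifest["stages_completed"].append("load")

    outputs = {}
    fitted_sons_paternal = None
    for line in config.lines:
        try:
            summary_tab = summarize_cohort(table, line)
            summary_tab.df.to_csv(out_dir / f"descriptives_{line}.csv", index=False)
        except Exception as exc:
            fail(f"descriptives:{line}", exc)
        for state in config.bronchodilator_states:
            label = f"{line}_{state}"
            spec = ModelSpec(line=line, outcome_set=config.outcome_set,
                             bronchodilator=state)
            try:
                fits = fit_multigroup_model(table, spec)
                for g, fr in fits.items():
                    if fr.n_obs < config.min_group_n:
                        logger.warning("group %s (%s): only %d records",
                                       g, label, fr.n_obs)
                (out_dir / f"fit_{label}.json").write_text(json.dumps(
                    {g: fr.to_dict() for g, fr in fits.items()}, indent=1))
            except Exception as exc:
                fail(f"fit:{label}", exc)
            try:
                boot = bootstrap_effects(table, spec, config.bootstrap,
                                         keep_coefficients=True)
            except Exception as exc:
                fail(f"bootstrap:{label}", exc)
            outputs[label] = {
                "bootstrap": boot,
                "coefficients": {g: fr.coefficients for g, fr in fits.items()},
            }
            if line == "paternal" and state == "pre":
                fitted_sons_paternal = fits["son"].coefficients
            manifest["stages_completed"].append(f"model:{label}")

    try:
        manifest["artifacts"].update(write_report(outputs, out_dir))
    except Exception as exc:
        fail("report", exc)
    manifest["stages_completed"].append("report")

    if config.sensitivity and config.sensitivity.get("enabled", True):
        try:
            sens_cfg = {k: v for k, v in config.sensitivity.items()
                        if k not in ("enabled", "beta_grid", "confounder_counts")}
            if fitted_sons_paternal is not None:
                cf = fitted_sons_paternal
                prev = float(
                    (table.for_line("paternal").df.parent_exposure
                     == "before_puberty").mean())
                k = 0  # first configured outcome
                base = scenario_from_paths(
                    nde_ml=float(cf.c[k, 1]), nie_path_a=float(cf.h[1]),
                    nie_path_b=float(cf.b2[k]),
                    exposure_prevalence=min(max(prev, 0.01), 0.99),
                    seed=config.seed, **sens_cfg)
            else:
                base = SensitivityScenario(seed=config.seed, **sens_cfg).validate()
            grid = config.sensitivity.get("beta_grid", DEFAULT_BETA_GRID)
            counts = config.sensitivity.get("confounder_counts", (1, 2))
            results = run_grid(base, grid, counts)
            frame = grid_frame(results)
            frame.to_csv(out_dir / "sensitivity.csv", index=False)
            (out_dir / "sensitivity.json").write_text(json.dumps(
                [r.to_dict() for r in results], indent=1))
            manifest["artifacts"]["sensitivity"] = str(out_dir / "sensitivity.csv")
        except Exception as exc:
            fail("sensitivity", exc)
        manifest["stages_completed"].append("sensitivity")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["artifacts"]["manifest"] = str(out_dir / "manifest.json")
    return manifest
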