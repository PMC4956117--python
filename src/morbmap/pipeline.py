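"""One-call orchestration: ingest or simulate -> describe -> design -> fit -> summarise.

Driven by a single YAML/JSON config (see ``validate_config`` for the
schema).  Every run writes a reproducibility manifest — config echo,
SHA-256 of every output file, exclusion counts, acceptance rates — that is
byte-identical across reruns with the same config and seed (timings go to
the log file, not the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import descriptives, ingest, synthetic
from .design import build_design
from .graphs import egypt_governorate_names, egypt_governorates, read_edge_list
from .mcmc import ModelSpec, run_mcmc, save_chains
from .summary import write_results

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("morbmap")

_SOURCE_KEYS = {
    "kind", "path", "column_map", "profile", "n_children",
    "spatial_var", "unstructured_var",
}
_TOP_KEYS = {"seed", "out_dir", "source", "recode", "formula", "smooth_terms", "graph", "model"}
_RECODE_KEYS = {"bmi_threshold", "maternal_age_threshold", "collapse_wealth"}
_MODEL_KEYS = {
    "n_iterations", "burn_in", "thinning", "beta_prior_precision",
    "ig_a", "ig_b", "include_spatial", "include_unstructured", "initial_variance",
}


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every field problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    """Normalised pipeline configuration (output of :func:`validate_config`)."""

    seed: int
    out_dir: Path
    source: dict
    recode: dict = field(default_factory=dict)
    formula: list[str] | None = None
    smooth_terms: list[str] = field(default_factory=list)
    graph: str = "egypt"
    model: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "source": dict(self.source),
            "recode": dict(self.recode),
            "formula": list(self.formula) if self.formula else None,
            "smooth_terms": list(self.smooth_terms),
            "graph": self.graph,
            "model": dict(self.model),
        }


def validate_config(config, seed_override: int | None = None) -> RunConfig:
    """Normalise and validate a config mapping or YAML/JSON file path.

    Fills documented defaults, rejects unknown keys by name, and reports
    every problem at once in :class:`ConfigError`.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigError(["config must be a mapping"])
    errors: list[str] = []
    unknown = set(config) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level key(s): {sorted(unknown)}")

    seed = seed_override if seed_override is not None else config.get("seed")
    if seed is None:
        errors.append("seed is mandatory (every stochastic stage uses it)")
    elif not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {type(seed).__name__}")

    if "out_dir" not in config:
        errors.append("out_dir is mandatory")

    source = config.get("source")
    if not isinstance(source, dict):
        errors.append("source must be a mapping with a 'kind' key")
        source = {}
    else:
        unknown = set(source) - _SOURCE_KEYS
        if unknown:
            errors.append(f"unknown source key(s): {sorted(unknown)}")
        kind = source.get("kind")
        if kind not in ("synthetic", "csv", "sav"):
            errors.append(f"source.kind must be 'synthetic', 'csv' or 'sav', got {kind!r}")
        if kind == "synthetic" and "path" in source:
            errors.append("source: give either a synthetic spec or a file path, not both")
        if kind in ("csv", "sav"):
            if "path" not in source:
                errors.append(f"source.kind={kind!r} requires source.path")
            for key in ("profile", "n_children", "spatial_var", "unstructured_var"):
                if key in source:
                    errors.append(f"source.{key} only applies to synthetic sources")
        if kind == "synthetic":
            profile = source.setdefault("profile", "edhs_like")
            if profile not in ("edhs_like", "two_binary"):
                errors.append(f"unknown synthetic profile {profile!r}")
            n = source.setdefault("n_children", 10872 if profile == "edhs_like" else 4000)
            if not isinstance(n, int) or n <= 0:
                errors.append("source.n_children must be a positive integer")

    recode = dict(config.get("recode") or {})
    unknown = set(recode) - _RECODE_KEYS
    if unknown:
        errors.append(f"unknown recode key(s): {sorted(unknown)}")

    model = dict(config.get("model") or {})
    unknown = set(model) - _MODEL_KEYS
    if unknown:
        errors.append(f"unknown model key(s): {sorted(unknown)}")
    for key in ("n_iterations", "burn_in"):
        if key in model and (not isinstance(model[key], int) or model[key] < 0):
            errors.append(f"model.{key} must be a non-negative integer")
    if "thinning" in model and (not isinstance(model["thinning"], int) or model["thinning"] < 1):
        errors.append("model.thinning must be an integer >= 1")

    formula = config.get("formula")
    if formula is not None and (
        not isinstance(formula, list) or not all(isinstance(t, str) for t in formula)
    ):
        errors.append("formula must be a list of covariate names")
    smooth = config.get("smooth_terms") or []
    if not isinstance(smooth, list):
        errors.append("smooth_terms must be a list of covariate names")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        seed=seed,
        out_dir=Path(config["out_dir"]),
        source=source,
        recode=recode,
        formula=list(formula) if formula else None,
        smooth_terms=list(smooth),
        graph=config.get("graph", "egypt"),
        model=model,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_graph(spec: str):
    if spec == "egypt":
        return egypt_governorates()
    return read_edge_list(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    A stage failure propagates with the stage named; outputs land under
    ``config.out_dir`` (data/, descriptives/, chains/, results/,
    manifest.json, run.log).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}
    t0 = time.time()

    def _stage(name):
        logger.info("stage %s starting (t=%.1fs)", name, time.time() - t0)

    try:
        graph = _load_graph(config.graph)

        _stage("data")
        if config.source["kind"] == "synthetic":
            profile = config.source["profile"]
            n = config.source["n_children"]
            if profile == "edhs_like":
                truth = synthetic.edhs_like_truth(config.seed, n_children=n)
            else:
                truth = synthetic.two_binary_truth(
                    config.seed,
                    n_children=n,
                    spatial_var=config.source.get("spatial_var", 0.3),
                    unstructured_var=config.source.get("unstructured_var", 0.1),
                    graph=graph,
                )
            truth.graph = graph
            survey = synthetic.generate_survey(truth)
            records = survey.records
            data_dir = out / "data"
            synthetic.write_survey(survey, data_dir / "survey.csv")
            manifest["stages"]["data"] = {
                "kind": "synthetic", "profile": profile, "n_records": len(records),
            }
            formula = config.formula or [c.name for c in truth.covariates]
        else:
            column_map = config.source.get("column_map")
            if isinstance(column_map, str):
                column_map = yaml.safe_load(Path(column_map).read_text())
            records, report = ingest.read_survey(
                config.source["path"],
                dialect=config.source["kind"],
                column_map=column_map,
                graph=graph,
            )
            options = ingest.RecodeOptions(**config.recode)
            records = ingest.recode_covariates(records, options)
            (out / "data").mkdir(exist_ok=True)
            report.to_json(out / "data" / "validation_report.json")
            manifest["stages"]["data"] = {
                "kind": config.source["kind"],
                "rows_read": report.rows_read,
                "rows_flagged": report.rows_flagged,
                "recode": options.manifest(),
            }
            formula = config.formula or [
                t for t in (
                    "child_age_group", "sex", "maternal_age_group", "bmi_group",
                    "residence", "household_size", "antenatal_visits",
                    "place_of_delivery", "working_status", "wealth_quintile",
                    "mother_education",
                )
                if t in records.columns
            ]
        logger.info("data stage: %d records", len(records))

        _stage("descriptives")
        factors = [t for t in formula if not pd.api.types.is_float_dtype(records[t])]
        desc_paths = descriptives.write_descriptive_tables(
            records, factors, out / "descriptives"
        )
        manifest["stages"]["descriptives"] = {"factors": factors}

        _stage("design")
        model_rows = records.dropna(subset=list(formula) + list(config.smooth_terms))
        n_dropped = len(records) - len(model_rows)
        if n_dropped:
            logger.info("complete-case filter dropped %d rows", n_dropped)
        design = build_design(
            model_rows, formula=formula, graph=graph, smooth_terms=config.smooth_terms
        )
        manifest["stages"]["design"] = design.manifest()
        manifest["stages"]["design"]["complete_case_dropped"] = n_dropped

        _stage("mcmc")
        spec = ModelSpec(seed=config.seed, **config.model)
        samples = run_mcmc(design, model_rows["category"].to_numpy(), spec)
        save_chains(samples, out / "chains")
        manifest["stages"]["mcmc"] = {
            "spec": spec.to_dict(),
            "n_draws": samples.n_draws,
            "acceptance": {k: round(v, 4) for k, v in samples.acceptance.items()},
            "acceptance_warnings": samples.diagnostics["acceptance_warnings"],
        }

        _stage("summaries")
        lookup = egypt_governorate_names() if config.graph == "egypt" else None
        paths = write_results(samples, out / "results", name_lookup=lookup)
        manifest["stages"]["summaries"] = {"n_categories": len(paths["or"])}

        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                manifest["files"][str(p.relative_to(out))] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete in %.1fs", time.time() - t0)
        return manifest
    except Exception as err:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        logger.error("pipeline failed after stage '%s': %s", stage, err)
        raise RuntimeError(f"pipeline failed in or after stage '{stage}': {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()
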