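"""YAML run configuration, run manifests, and deterministic test fixtures."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .cohort import OutcomeGenerator, sample_center_effects, simulate_cohort
from .engine import ANALYSES, DetectionSummary, ExperimentGrid, desk_grid, \
    run_experiment
from .scales import get_scale
from .templates import StudyTemplate, get_template

__all__ = ["ConfigError", "RunConfig", "load_config", "make_fixtures",
           "write_manifest"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


_GRID_KEYS = {"H", "n_grid", "n_reps", "sd", "scenarios", "analyses",
              "master_seed", "alpha", "rule", "se_source"}
_TOP_KEYS = {"template", "scale", "baseline_probs", "grid", "preset"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    template: StudyTemplate
    grid: ExperimentGrid
    template_name: str
    preset: str = "full"

    @property
    def config_hash(self) -> str:
        payload = {
            "template": self.template_name,
            "scale": self.template.scale.name,
            "baseline_probs":
                list(map(float, self.template.generator.baseline_probs))
                if self.template.generator.baseline_probs is not None
                else None,
            "grid": asdict(self.grid),
            "preset": self.preset,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Minimal config::

        template: impact        # impact | practise | custom
        preset: desk            # optional: desk | full
        grid:                   # optional overrides of ExperimentGrid
          n_reps: 100
          master_seed: 7

    A ``custom`` template additionally needs ``scale`` (a built-in scale
    name) and ``baseline_probs`` (category probabilities, worst to best).
    Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    name = raw.get("template")
    if name is None:
        raise ConfigError("config must name a template "
                          "(impact | practise | custom)")
    preset = raw.get("preset", "full")
    if preset not in ("desk", "full"):
        raise ConfigError("preset must be 'desk' or 'full'")
    if name == "custom":
        if "scale" not in raw or "baseline_probs" not in raw:
            raise ConfigError("custom template needs 'scale' and "
                              "'baseline_probs'")
        scale = get_scale(str(raw["scale"]))
        try:
            gen = OutcomeGenerator(mode="configured", scale=scale,
                                   baseline_probs=np.asarray(
                                       raw["baseline_probs"], dtype=float))
        except ValueError as err:
            raise ConfigError(str(err)) from err
        base = get_template("impact")  # covariate model as noise filler
        template = StudyTemplate(name="custom", scale=scale,
                                 cov_model=base.cov_model, generator=gen,
                                 analysis_covariates=())
    elif name in ("impact", "practise"):
        if "scale" in raw or "baseline_probs" in raw:
            raise ConfigError("scale/baseline_probs only apply to "
                              "template: custom")
        template = get_template(name)
    else:
        raise ConfigError(f"unknown template {name!r}")
    grid = desk_grid() if preset == "desk" else ExperimentGrid()
    overrides = raw.get("grid", {})
    if overrides:
        if not isinstance(overrides, dict):
            raise ConfigError("'grid' must be a mapping")
        _check_keys(overrides, _GRID_KEYS, "grid")
        for key in ("n_grid", "scenarios", "analyses"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        try:
            grid = replace(grid, **overrides)
        except (ValueError, TypeError) as err:
            raise ConfigError(str(err)) from err
    return RunConfig(template=template, grid=grid, template_name=name,
                     preset=preset)


def write_manifest(config: RunConfig, outdir: Path) -> Path:
    """Record what produced the outputs: config hash, seed, versions."""
    import ordprofile

    manifest = {
        "package": "ordprofile",
        "version": ordprofile.__version__,
        "numpy": np.__version__,
        "template": config.template_name,
        "preset": config.preset,
        "master_seed": config.grid.master_seed,
        "config_hash": config.config_hash,
        "grid": asdict(config.grid),
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def make_fixtures(seed: int = 0, outdir=".") -> dict[str, Path]:
    """Write a tiny deterministic cohort CSV and a toy detection summary.

    The cohort (4 hospitals x 30 patients, TBI template) exercises the
    full patient-table round trip; the toy summary (8 hospitals, 3
    replicates, 2 grid cells) round-trips through the ``analyze``
    subcommand.  Identical seeds give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = get_template("impact")
    effects = sample_center_effects(4, 0.35, "A",
                                    np.random.SeedSequence(seed,
                                                           spawn_key=(0,)))
    cohort = simulate_cohort(template.generator, template.cov_model,
                             4, 30, effects,
                             np.random.SeedSequence(seed, spawn_key=(1,)))
    cohort_path = outdir / "fixture_cohort.csv"
    cohort.data.round(6).to_csv(cohort_path, index=False,
                                float_format="%.6f")
    grid = ExperimentGrid(H=8, n_grid=(25, 50), n_reps=3,
                          scenarios=("A",), analyses=ANALYSES,
                          master_seed=seed)
    summary = run_experiment(template, grid)
    summary_path = outdir / "fixture_summary.csv"
    summary.table.round(6).to_csv(summary_path, index=False,
                                  float_format="%.6f")
    return {"cohort": cohort_path, "summary": summary_path}
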