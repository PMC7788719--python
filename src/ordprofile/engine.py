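"""Monte-Carlo engine: scenario A/B experiments over a patients-per-hospital grid.

One replicate simulates a single cohort and feeds the *same* patients to
all three analyses (full ordinal scale, favorable/unfavorable dichotomy,
mortality dichotomy), so between-analysis comparisons share the
Monte-Carlo noise of the cohort draw.  Every replicate is reproducible in
isolation: randomness for (scenario, grid cell, replicate, stage) comes
from a dedicated ``numpy`` seed substream derived from the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import sample_center_effects, simulate_cohort
from .fitting import DesignSpec, FitError, fit_binary_logistic, \
    fit_proportional_odds
from .outliers import flag_outliers
from .scales import dichotomize
from .templates import StudyTemplate

__all__ = ["ExperimentGrid", "DetectionSummary", "desk_grid",
           "run_replicate", "run_experiment", "ANALYSES"]

ANALYSES = ("ordinal", "favorable", "mortality")
_SCENARIO_CODE = {"A": 0, "B": 1}
_STAGE_EFFECTS, _STAGE_COHORT = 0, 1


@dataclass(frozen=True)
class ExperimentGrid:
    """Configuration of a full Monte-Carlo experiment."""

    H: int = 250
    n_grid: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 175, 200)
    n_reps: int = 500
    sd: float = 0.35
    scenarios: tuple[str, ...] = ("A", "B")
    analyses: tuple[str, ...] = ANALYSES
    master_seed: int = 20210106
    alpha: float = 0.05
    rule: str = "wald_vs_mean"
    se_source: str = "marginal"

    def __post_init__(self):
        if self.H < 2:
            raise ValueError("H must be >= 2")
        n = np.asarray(self.n_grid)
        if n.size == 0 or (n <= 0).any() or (np.diff(n) <= 0).any():
            raise ValueError("n_grid must be strictly increasing positive "
                             "integers")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        bad = set(self.scenarios) - {"A", "B"}
        if bad or not self.scenarios:
            raise ValueError(f"invalid scenarios {sorted(bad)}")
        bad = set(self.analyses) - set(ANALYSES)
        if bad or not self.analyses:
            raise ValueError(f"invalid analyses {sorted(bad)}")


def desk_grid(**overrides) -> ExperimentGrid:
    """Scaled-down preset for desk checks and continuous testing."""
    base = ExperimentGrid(H=50, n_grid=(25, 50, 100, 150, 200), n_reps=100)
    return replace(base, **overrides) if overrides else base


@dataclass
class DetectionSummary:
    """Tidy per-replicate detection counts plus the grid that produced them."""

    table: pd.DataFrame
    grid: ExperimentGrid

    def mean_table(self, scenario: str | None = None) -> pd.DataFrame:
        """Mean flagged fraction and Monte-Carlo SE per (scenario,
        analysis, n_per_hospital)."""
        t = self.table
        if scenario is not None:
            t = t[t["scenario"] == scenario]
        g = t.groupby(["scenario", "analysis", "n_per_hospital"],
                      as_index=False)
        out = g.agg(
            flagged_fraction=("flagged_fraction", "mean"),
            sd=("flagged_fraction", "std"),
            n_reps=("flagged_fraction", "size"),
            mean_non_estimable=("n_non_estimable", "mean"),
            n_failed=("failed", "sum"),
        )
        out["mc_se"] = out["sd"].fillna(0.0) / np.sqrt(out["n_reps"])
        return out.drop(columns="sd")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: ExperimentGrid | None = None
                 ) -> "DetectionSummary":
        return cls(pd.read_csv(path), grid or ExperimentGrid())


def _rep_seed(master_seed: int, scenario: str, cell_index: int,
              rep: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        master_seed,
        spawn_key=(_SCENARIO_CODE[scenario], cell_index, rep, stage))


def run_replicate(template: StudyTemplate, grid: ExperimentGrid,
                  scenario: str, cell_index: int, rep: int) -> list[dict]:
    """One Monte-Carlo replicate of one grid cell.

    Returns one record per analysis with the flagged count, the number of
    non-estimable hospitals, and a failure marker (a fit that errors out
    is recorded, never silently dropped).
    """
    n_per_hospital = grid.n_grid[cell_index]
    effects = sample_center_effects(
        grid.H, grid.sd if scenario == "A" else 0.0, scenario,
        _rep_seed(grid.master_seed, scenario, cell_index, rep,
                  _STAGE_EFFECTS))
    cohort = simulate_cohort(
        template.generator, template.cov_model, grid.H, n_per_hospital,
        effects,
        _rep_seed(grid.master_seed, scenario, cell_index, rep,
                  _STAGE_COHORT))
    design = DesignSpec(covariates=template.analysis_covariates)
    y_ord = cohort.outcomes()
    records = []
    for analysis in grid.analyses:
        rec = {
            "scenario": scenario,
            "analysis": analysis,
            "n_per_hospital": n_per_hospital,
            "rep": rep,
            "n_hospitals": grid.H,
            "n_flagged": 0,
            "n_non_estimable": 0,
            "flagged_fraction": np.nan,
            "failed": False,
        }
        df = cohort.data.copy()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if analysis == "ordinal":
                    fit = fit_proportional_odds(
                        df, design,
                        n_categories=template.scale.n_categories)
                else:
                    df["outcome"] = dichotomize(y_ord, template.scale,
                                                analysis)
                    fit = fit_binary_logistic(df, design)
            det = flag_outliers(fit, rule=grid.rule, alpha=grid.alpha,
                                se_source=grid.se_source)
            rec.update(n_flagged=det.n_flagged,
                       n_non_estimable=det.n_non_estimable,
                       flagged_fraction=det.flagged_fraction)
        except (FitError, ValueError, np.linalg.LinAlgError):
            rec["failed"] = True
        records.append(rec)
    return records


def run_experiment(template: StudyTemplate, grid: ExperimentGrid,
                   n_jobs: int = 1, progress: bool = False
                   ) -> DetectionSummary:
    """Run all scenarios, grid cells and replicates of an experiment.

    ``n_jobs != 1`` parallelizes over replicates with joblib; the seed
    substream design makes the result identical to the serial run.
    """
    tasks = [(scenario, ci, rep)
             for scenario in grid.scenarios
             for ci in range(len(grid.n_grid))
             for rep in range(grid.n_reps)]
    if n_jobs == 1:
        chunks = []
        last_cell = None
        for scenario, ci, rep in tasks:
            if progress and (scenario, ci) != last_cell:
                last_cell = (scenario, ci)
                print(f"[ordprofile] scenario {scenario}, "
                      f"n/hospital {grid.n_grid[ci]}", flush=True)
            chunks.append(run_replicate(template, grid, scenario, ci, rep))
    else:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(template, grid, scenario, ci, rep)
            for scenario, ci, rep in tasks)
    records = [rec for chunk in chunks for rec in chunk]
    table = pd.DataFrame.from_records(records)
    n_failed = int(table["failed"].sum())
    if n_failed:
        warnings.warn(f"{n_failed} model fits failed and are excluded from "
                      "mean detection rates", stacklevel=2)
    return DetectionSummary(table, grid)
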