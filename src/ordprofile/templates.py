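"""Built-in study templates emulating the TBI and stroke source cohorts.

Each template bundles a covariate model, an outcome generator configured
to the published marginal outcome distribution, the outcome scale, and
the covariates the analysis models adjust for.

``impact``
    Traumatic brain injury cohort: age (median 30, IQR 21-45), 78% male,
    80% with both pupils reactive, 6-level Glasgow Coma Scale motor score,
    outcomes on the collapsed 4-point GOS with 32% in the bottom merged
    category and 52% favorable.

``practise``
    Acute stroke cohort: age (median 73, IQR 62-80), 54% male, 18% atrial
    fibrillation, 17% diabetes, 20% prior ischemic stroke, NIHSS with
    mean 8, outcomes on the collapsed 6-point mRS with 21% in the bottom
    merged category and 56% favorable.

Only the bottom-category and favorable fractions of the outcome
distributions are published; the interior splits are fixed template
choices (see docs/methods.md).  Covariates default to zero effect on
outcome, so the configured marginals hold exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    BernoulliSpec,
    CategoricalSpec,
    CovariateModel,
    GammaIntSpec,
    LogNormalSpec,
    OutcomeGenerator,
)
from .scales import GOS4, MRS6, OutcomeScale

__all__ = ["StudyTemplate", "impact_template", "practise_template",
           "get_template", "TEMPLATE_NAMES"]

# GCS motor score frequencies from the TBI cohort's published table
# (counts 1490, 1166, 1244, 2208, 2593, 291; renormalised — the printed
# counts cover 8992 of 9578 patients).
_MOTOR_COUNTS = np.array([1490, 1166, 1244, 2208, 2593, 291], dtype=float)
_MOTOR_LABELS = (
    "none", "extension", "abnormal_flexion", "withdrawal",
    "localizes", "obeys",
)

#: 4-point GOS baseline, worst to best; bottom = 0.32, favorable = 0.52.
IMPACT_OUTCOME_PROBS = (0.32, 0.16, 0.22, 0.30)

#: 6-point mRS baseline, worst to best; bottom = 0.21, favorable = 0.56.
PRACTISE_OUTCOME_PROBS = (0.21, 0.12, 0.11, 0.14, 0.22, 0.20)


@dataclass(frozen=True)
class StudyTemplate:
    """A named simulation setting: generator + covariates + analysis design."""

    name: str
    scale: OutcomeScale
    cov_model: CovariateModel
    generator: OutcomeGenerator
    analysis_covariates: tuple[str, ...]
    #: number of centers in the real study (metadata only; simulations
    #: use the configured hospital count)
    real_centers: int = 0


def impact_template() -> StudyTemplate:
    cov_model = CovariateModel((
        LogNormalSpec("age", median=30.0, iqr=(21.0, 45.0),
                      low=14.0, high=95.0),
        CategoricalSpec("sex", ("female", "male"), (0.22, 0.78)),
        CategoricalSpec("pupils", ("not_reactive", "both_reactive"),
                        (0.20, 0.80)),
        CategoricalSpec("motor", _MOTOR_LABELS,
                        tuple(_MOTOR_COUNTS / _MOTOR_COUNTS.sum())),
    ))
    gen = OutcomeGenerator(mode="configured", scale=GOS4,
                           baseline_probs=np.array(IMPACT_OUTCOME_PROBS))
    return StudyTemplate(
        name="impact",
        scale=GOS4,
        cov_model=cov_model,
        generator=gen,
        analysis_covariates=("age", "pupils", "motor"),
        real_centers=265,
    )


def practise_template() -> StudyTemplate:
    cov_model = CovariateModel((
        LogNormalSpec("age", median=73.0, iqr=(62.0, 80.0),
                      low=18.0, high=102.0),
        CategoricalSpec("sex", ("female", "male"), (0.46, 0.54)),
        BernoulliSpec("af", 0.18),
        BernoulliSpec("dm", 0.17),
        BernoulliSpec("prior_stroke", 0.20),
        GammaIntSpec("nihss", mean=8.0, sd=6.0, max_value=42),
    ))
    gen = OutcomeGenerator(mode="configured", scale=MRS6,
                           baseline_probs=np.array(PRACTISE_OUTCOME_PROBS))
    return StudyTemplate(
        name="practise",
        scale=MRS6,
        cov_model=cov_model,
        generator=gen,
        analysis_covariates=("age", "nihss", "prior_stroke", "af", "dm"),
        real_centers=12,
    )


_TEMPLATES = {"impact": impact_template, "practise": practise_template}
TEMPLATE_NAMES = tuple(_TEMPLATES)


def get_template(name: str) -> StudyTemplate:
    try:
        return _TEMPLATES[name]()
    except KeyError:
        raise KeyError(
            f"unknown template {name!r}; available: {TEMPLATE_NAMES}"
        ) from None
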