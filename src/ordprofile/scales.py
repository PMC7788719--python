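"""Ordinal clinical outcome scales and their dichotomizations.

Outcome categories are stored worst-to-best and indexed 1-based, so a
positive shift on the cumulative logits means better outcomes.  Two scales
ship built in:

``gos4``
    Glasgow Outcome Scale (traumatic brain injury) with death and
    vegetative state merged, leaving 4 levels.
``mrs6``
    modified Rankin Scale (stroke) with death (mRS 6) and severe
    disability (mRS 5) merged, leaving 6 levels.

Each scale carries two cut points: a *favorable* cut (good recovery /
functional independence versus the rest) and a *mortality* cut separating
the bottom merged category (death plus the worst disability state) from
everyone else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OutcomeScale",
    "GOS5",
    "MRS7",
    "GOS4",
    "MRS6",
    "BUILTIN_SCALES",
    "get_scale",
    "collapse_scale",
    "dichotomize",
]


@dataclass(frozen=True)
class OutcomeScale:
    """An ordered clinical outcome scale with its dichotomization cuts.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"gos4"``.
    categories : tuple of str
        Labels ordered worst to best.
    favorable_cut : int
        1-based category index ``c`` such that outcomes with index >= ``c``
        count as favorable.
    mortality_cut : int
        1-based index; outcomes with index > ``mortality_cut`` count as
        alive / not severely disabled (the "event" is the bottom merged
        category).  Always 1 for the built-in scales.
    """

    name: str
    categories: tuple[str, ...]
    favorable_cut: int
    mortality_cut: int = 1

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("an outcome scale needs at least 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category labels must be unique")
        if not 1 <= self.mortality_cut < self.n_categories:
            raise ValueError("mortality_cut out of range")
        if not 1 <= self.favorable_cut <= self.n_categories:
            raise ValueError("favorable_cut out of range")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def validate_outcomes(self, outcomes: np.ndarray) -> np.ndarray:
        y = np.asarray(outcomes)
        if y.size and (y.min() < 1 or y.max() > self.n_categories):
            raise ValueError(
                f"outcome indices must lie in 1..{self.n_categories}"
            )
        return y.astype(np.int64)


#: 5-point Glasgow Outcome Scale, worst to best.
GOS5 = OutcomeScale(
    "gos5",
    ("death", "vegetative_state", "severe_disability",
     "moderate_disability", "good_recovery"),
    favorable_cut=4,
)

#: 7-point modified Rankin Scale, worst to best (mRS 6 = death, 0 = none).
MRS7 = OutcomeScale(
    "mrs7",
    ("mrs6_death", "mrs5", "mrs4", "mrs3", "mrs2", "mrs1", "mrs0"),
    favorable_cut=5,
)


def collapse_scale(
    raw_scale: OutcomeScale,
    merge_worst: tuple[str, str],
    name: str | None = None,
    merged_label: str | None = None,
) -> OutcomeScale:
    """Merge the two worst categories of ``raw_scale`` into one.

    The merge is restricted to the two worst, adjacent categories (the
    ethically motivated pooling of death with the worst disability state);
    anything else raises ``ValueError``.
    """
    if raw_scale.n_categories < 3:
        raise ValueError("cannot collapse a scale with fewer than 3 categories")
    worst_pair = raw_scale.categories[:2]
    if tuple(merge_worst) != worst_pair:
        raise ValueError(
            f"merge_worst must be the two worst categories {worst_pair}, "
            f"got {tuple(merge_worst)}"
        )
    label = merged_label or "_or_".join(merge_worst)
    cats = (label,) + raw_scale.categories[2:]
    return OutcomeScale(
        name or raw_scale.name + "_collapsed",
        cats,
        favorable_cut=raw_scale.favorable_cut - 1,
        mortality_cut=1,
    )


#: Collapsed 4-point GOS (death/vegetative merged).
GOS4 = collapse_scale(GOS5, ("death", "vegetative_state"), name="gos4")

#: Collapsed 6-point mRS (death / mRS 5 merged).
MRS6 = collapse_scale(MRS7, ("mrs6_death", "mrs5"), name="mrs6")

BUILTIN_SCALES: dict[str, OutcomeScale] = {
    "gos4": GOS4,
    "mrs6": MRS6,
    "gos5": GOS5,
    "mrs7": MRS7,
}


def get_scale(name: str) -> OutcomeScale:
    try:
        return BUILTIN_SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; built-ins: {sorted(BUILTIN_SCALES)}"
        ) from None


def dichotomize(outcomes, scale: OutcomeScale, cut: str) -> np.ndarray:
    """Dichotomize ordinal outcomes at one of the scale's cut points.

    ``cut="favorable"`` returns 1 where the category index is at or above
    the favorable cut.  ``cut="mortality"`` returns 1 where the patient is
    *not* in the bottom merged category, i.e. the event (death or worst
    disability) is coded 0.  Both codings keep "1 = better outcome" so the
    sign of a center effect means the same thing in every analysis.
    """
    y = scale.validate_outcomes(outcomes)
    if cut == "favorable":
        return (y >= scale.favorable_cut).astype(np.int64)
    if cut == "mortality":
        return (y > scale.mortality_cut).astype(np.int64)
    raise ValueError("cut must be 'favorable' or 'mortality'")
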