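"""Equal-power sample-size translation of detection-rate curves.

The simulation engine produces, per analysis type, a detection-rate curve:
mean fraction of hospitals flagged versus patients per hospital.  This
module converts pairs of curves into the headline quantity: by how much
can the per-hospital sample size shrink when the ordinal analysis replaces
a dichotomized one, at the same power to detect outlying hospitals?

Raw Monte-Carlo curves can dip non-monotonically, so each curve is first
smoothed by isotonic regression (least-squares nondecreasing fit) and then
inverted by piecewise-linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

__all__ = ["PowerCurve", "EfficiencyResult", "required_n",
           "efficiency_gain", "summarize_efficiency"]


@dataclass
class PowerCurve:
    """Detection rate versus patients per hospital for one analysis."""

    analysis: str
    n: np.ndarray
    fraction: np.ndarray
    mc_se: np.ndarray | None = None
    smoothed: np.ndarray = field(init=False)

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.n.ndim != 1 or self.n.size == 0:
            raise ValueError("curve needs at least one point")
        if np.any(np.diff(self.n) <= 0):
            raise ValueError("n values must be strictly increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        self.smoothed = isotonic_regression(self.fraction).x


def required_n(curve: PowerCurve, target: float) -> float | None:
    """Smallest patients-per-hospital at which the curve reaches ``target``.

    Piecewise-linear interpolation on the isotonic-smoothed curve.
    Returns ``None`` when the target exceeds the curve's maximum.  A
    target at or below the curve's first point returns the smallest
    evaluated n (the curve gives no information below its grid).
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("target power must lie in [0, 1]")
    f = curve.smoothed
    if target > f[-1]:
        return None
    idx = int(np.argmax(f >= target))  # first index reaching the target
    if idx == 0:
        return float(curve.n[0])
    f0, f1 = f[idx - 1], f[idx]
    n0, n1 = curve.n[idx - 1], curve.n[idx]
    return float(n0 + (target - f0) / (f1 - f0) * (n1 - n0))


def efficiency_gain(n_comp: float, n_ref: float) -> float:
    """Fractional sample-size reduction ``1 - n_comp / n_ref``."""
    if n_comp <= 0 or n_ref <= 0:
        raise ValueError("sample sizes must be positive")
    return 1.0 - n_comp / n_ref


@dataclass
class EfficiencyResult:
    """Equal-power comparisons between a reference and a comparator curve."""

    comparisons: pd.DataFrame
    max_reduction: dict

    def to_frame(self) -> pd.DataFrame:
        return self.comparisons


def _curves_from_summary(mean_table: pd.DataFrame) -> dict[str, PowerCurve]:
    curves = {}
    for analysis, grp in mean_table.groupby("analysis"):
        grp = grp.sort_values("n_per_hospital")
        curves[analysis] = PowerCurve(
            analysis,
            grp["n_per_hospital"].to_numpy(),
            grp["flagged_fraction"].to_numpy(),
            grp["mc_se"].to_numpy() if "mc_se" in grp else None,
        )
    return curves


def summarize_efficiency(summary, targets=None,
                         comparator: str = "ordinal",
                         references=("favorable", "mortality")
                         ) -> EfficiencyResult:
    """Equal-power sample-size reductions of ``comparator`` vs references.

    ``summary`` is a :class:`~ordprofile.engine.DetectionSummary` (or its
    scenario-A mean table).  By default the target power levels are the
    reference curve's own achieved (smoothed) detection fractions at each
    grid point, so every reference grid point yields one comparison; the
    per-pair maximum reduction over those targets is the "up to X%"
    figure.  Explicit ``targets`` override that.
    """
    from .engine import DetectionSummary

    if isinstance(summary, DetectionSummary):
        table = summary.mean_table(scenario="A")
    else:
        table = summary
    curves = _curves_from_summary(table)
    if comparator not in curves:
        raise ValueError(f"no {comparator!r} curve in the summary")
    comp = curves[comparator]
    rows = []
    max_reduction: dict = {}
    for ref_name in references:
        if ref_name not in curves:
            continue
        ref = curves[ref_name]
        if targets is None:
            pair_targets = [(float(t), float(nr))
                            for nr, t in zip(ref.n, ref.smoothed)]
        else:
            pair_targets = [(float(t), required_n(ref, float(t)))
                            for t in targets]
        best = None
        for t, n_ref in pair_targets:
            n_comp = required_n(comp, t)
            defined = n_comp is not None and n_ref is not None and t > 0
            red = efficiency_gain(n_comp, n_ref) if defined else np.nan
            rows.append({
                "reference": ref_name, "comparator": comparator,
                "target_power": t,
                "n_ref": n_ref if n_ref is not None else np.nan,
                "n_comp": n_comp if n_comp is not None else np.nan,
                "reduction": red,
            })
            if defined and (best is None or red > best):
                best = red
        max_reduction[ref_name] = best
    return EfficiencyResult(pd.DataFrame(rows), max_reduction)
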