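"""Synthetic patient cohorts: covariates, ordinal outcomes, center effects.

The generator follows the cumulative-logit ("proportional odds")
convention used throughout the package: with categories indexed 1..K from
worst to best, the model works on logit P(Y >= k) for k = 2..K.  A
hospital's center effect ``beta_h`` shifts *every* cumulative logit by the
same amount, so a positive effect raises the chance of every good outcome
simultaneously (an exact stochastic ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, softmax

from .scales import OutcomeScale

__all__ = [
    "CategoricalSpec",
    "BernoulliSpec",
    "LogNormalSpec",
    "GammaIntSpec",
    "CovariateModel",
    "OutcomeGenerator",
    "CenterEffectVector",
    "PatientCohort",
    "sample_covariates",
    "sample_center_effects",
    "shift_cumulative_logits",
    "outcome_probabilities",
    "simulate_cohort",
    "fit_generator",
]

_NORMAL_IQR_HALFWIDTH = 0.6744897501960817  # 75th percentile of N(0,1)


# ---------------------------------------------------------------------------
# covariate marginal specs


@dataclass(frozen=True)
class CategoricalSpec:
    """Categorical covariate with fixed label probabilities."""

    name: str
    labels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if len(self.labels) != p.size or p.size < 2:
            raise ValueError(f"{self.name}: labels/probs mismatch")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: probabilities must sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> pd.Series:
        idx = rng.choice(len(self.labels), size=n, p=np.asarray(self.probs))
        return pd.Series(np.asarray(self.labels, dtype=object)[idx],
                         name=self.name)


@dataclass(frozen=True)
class BernoulliSpec:
    """Binary 0/1 covariate (e.g. comorbidity present)."""

    name: str
    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.name}: p outside [0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> pd.Series:
        return pd.Series((rng.random(n) < self.p).astype(np.int64),
                         name=self.name)


@dataclass(frozen=True)
class LogNormalSpec:
    """Positive continuous covariate calibrated to a printed median and IQR.

    The log-scale sigma is chosen so the ratio q75/q25 matches the target
    IQR ratio; the median is matched exactly.  Values are clipped to
    ``[low, high]``.
    """

    name: str
    median: float
    iqr: tuple[float, float]
    low: float = 0.0
    high: float = np.inf

    def __post_init__(self):
        q25, q75 = self.iqr
        if not 0 < q25 < self.median < q75:
            raise ValueError(f"{self.name}: need q25 < median < q75, all > 0")

    @property
    def sigma(self) -> float:
        q25, q75 = self.iqr
        return float(np.log(q75 / q25) / (2 * _NORMAL_IQR_HALFWIDTH))

    def sample(self, rng: np.random.Generator, n: int) -> pd.Series:
        x = np.exp(np.log(self.median) + self.sigma * rng.standard_normal(n))
        return pd.Series(np.clip(x, self.low, self.high), name=self.name)


@dataclass(frozen=True)
class GammaIntSpec:
    """Non-negative integer score (e.g. NIHSS) from a rounded gamma."""

    name: str
    mean: float
    sd: float
    max_value: int

    def __post_init__(self):
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError(f"{self.name}: mean and sd must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> pd.Series:
        shape = (self.mean / self.sd) ** 2
        scale = self.sd**2 / self.mean
        x = np.rint(rng.gamma(shape, scale, size=n))
        return pd.Series(np.clip(x, 0, self.max_value).astype(np.int64),
                         name=self.name)


@dataclass(frozen=True)
class CovariateModel:
    """Ordered collection of covariate marginal specs."""

    specs: tuple

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def sample(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        if n == 0:
            return pd.DataFrame({s.name: pd.Series(dtype=object)
                                 for s in self.specs})
        return pd.DataFrame({s.name: s.sample(rng, n) for s in self.specs})


def sample_covariates(model: CovariateModel, n: int,
                      seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` covariate rows; reproducible given the seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return model.sample(rng, n)


# ---------------------------------------------------------------------------
# outcome generator


def _encode_design(df: pd.DataFrame, columns: Sequence[str],
                   categories: dict[str, tuple] | None = None):
    """Dummy-encode categorical columns (drop first level), pass numerics.

    Returns (matrix, column names, categories map) so a fitted generator can
    re-apply the identical encoding at prediction time.
    """
    mats, names = [], []
    cats_out: dict[str, tuple] = {}
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            if categories is not None and col in categories:
                levels = categories[col]
            else:
                levels = tuple(sorted(s.dropna().unique()))
            cats_out[col] = tuple(levels)
            for lv in levels[1:]:
                mats.append((s.to_numpy() == lv).astype(float))
                names.append(f"{col}[{lv}]")
        else:
            cats_out[col] = ()
            mats.append(s.to_numpy(dtype=float))
            names.append(col)
    X = np.column_stack(mats) if mats else np.empty((len(df), 0))
    return X, names, cats_out


@dataclass
class OutcomeGenerator:
    """Probability model for the ordinal outcome given covariates.

    Two modes:

    ``configured``
        Baseline category probabilities (worst to best) define thresholds
        on the cumulative-logit scale; optional covariate coefficients
        ``gamma`` shift every cumulative logit (proportional odds).  The
        default gamma = 0 makes covariates pure noise, so the printed
        marginal outcome distribution is reproduced exactly in expectation.
    ``fitted``
        Multinomial-logit coefficients (reference category = worst)
        estimated from patient-level data by :func:`fit_generator`.
    """

    mode: str
    scale: OutcomeScale
    baseline_probs: np.ndarray | None = None
    gamma: dict[str, float] = field(default_factory=dict)
    # fitted mode
    coef: np.ndarray | None = None          # (p+1, K-1) incl. intercept row
    feature_columns: tuple[str, ...] = ()
    feature_categories: dict = field(default_factory=dict)
    design_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in ("configured", "fitted"):
            raise ValueError("mode must be 'configured' or 'fitted'")
        if self.mode == "configured":
            p = np.asarray(self.baseline_probs, dtype=float)
            if p.ndim != 1 or p.size != self.scale.n_categories:
                raise ValueError("baseline_probs length must match the scale")
            if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-10:
                raise ValueError("baseline_probs must be positive, sum to 1")
            self.baseline_probs = p / p.sum()

    @property
    def n_categories(self) -> int:
        return self.scale.n_categories

    def _base_probs(self, covariates: pd.DataFrame | None,
                    n: int) -> np.ndarray:
        K = self.n_categories
        if self.mode == "configured":
            P = np.tile(self.baseline_probs, (n, 1))
            if self.gamma:
                if covariates is None:
                    raise ValueError("gamma set but no covariates supplied")
                eta = np.zeros(n)
                for name, g in self.gamma.items():
                    eta += g * covariates[name].to_numpy(dtype=float)
                P = shift_cumulative_logits(P, eta)
            return P
        # fitted: multinomial logit vs reference (worst) category
        if covariates is None:
            raise ValueError("fitted generator needs covariates")
        X, _, _ = _encode_design(covariates, self.feature_columns,
                                 self.feature_categories)
        Z = np.column_stack([np.ones(len(X)), X])
        eta = Z @ self.coef                       # (n, K-1)
        full = np.column_stack([np.zeros(n), eta])
        return softmax(full, axis=1)

    def category_probs(self, covariates: pd.DataFrame | None,
                       beta: np.ndarray | float = 0.0) -> np.ndarray:
        """Per-row category probabilities after the center-effect shift."""
        if covariates is not None:
            n = len(covariates)
        else:
            b = np.atleast_1d(np.asarray(beta, dtype=float))
            n = b.size
        P = self._base_probs(covariates, n)
        out = shift_cumulative_logits(P, beta)
        if covariates is None and np.ndim(beta) == 0:
            return np.asarray(out)[0]
        return out


def shift_cumulative_logits(probs: np.ndarray,
                            beta: np.ndarray | float) -> np.ndarray:
    """Apply an additive shift on every cumulative logit of ``probs``.

    ``probs`` is (n, K) or (K,), categories worst to best.  For k >= 2,
    logit P(Y >= k) gains ``beta``; the category probabilities are the
    differences of the shifted survivor function.  beta = 0 returns the
    input unchanged (up to floating point identity).
    """
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("center effect must be finite")
    if np.all(beta == 0.0):
        out = P.copy()
        return out if np.asarray(probs).ndim > 1 else out[0]
    shift = beta[:, None] if beta.ndim == 1 else beta
    # survivor function Q_k = P(Y >= k), k = 2..K
    Q = np.cumsum(P[:, ::-1], axis=1)[:, ::-1][:, 1:]
    Q = np.clip(Q, 1e-15, 1 - 1e-15)
    Qs = expit(logit(Q) + shift)
    Qfull = np.concatenate([np.ones((len(P), 1)), Qs,
                            np.zeros((len(P), 1))], axis=1)
    out = Qfull[:, :-1] - Qfull[:, 1:]
    out = np.clip(out, 0.0, 1.0)
    out /= out.sum(axis=1, keepdims=True)
    return out if np.asarray(probs).ndim > 1 else out[0]


def outcome_probabilities(gen: OutcomeGenerator,
                          covariates: pd.DataFrame | None,
                          beta_h: float) -> np.ndarray:
    """Category probabilities for one profile (or table) at effect ``beta_h``."""
    return gen.category_probs(covariates, beta_h)


# ---------------------------------------------------------------------------
# center effects and cohorts


@dataclass(frozen=True)
class CenterEffectVector:
    """True per-hospital effects on the cumulative-logit scale."""

    beta: np.ndarray
    sd: float
    scenario: str

    def __post_init__(self):
        if self.scenario not in ("A", "B"):
            raise ValueError("scenario must be 'A' or 'B'")

    @property
    def n_hospitals(self) -> int:
        return len(self.beta)


def sample_center_effects(H: int, sd: float, scenario: str,
                          seed: int | np.random.Generator
                          ) -> CenterEffectVector:
    """Draw true center effects: i.i.d. N(0, sd) in scenario A, zeros in B."""
    if H < 2:
        raise ValueError("need at least 2 hospitals")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if scenario == "B":
        return CenterEffectVector(np.zeros(H), 0.0, "B")
    if scenario != "A":
        raise ValueError("scenario must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    return CenterEffectVector(rng.normal(0.0, sd, size=H), sd, "A")


@dataclass
class PatientCohort:
    """Realized patient table: hospital id, covariates, ordinal outcome."""

    data: pd.DataFrame
    scale: OutcomeScale
    covariate_names: tuple[str, ...]

    def __post_init__(self):
        required = {"hospital_id", "outcome"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        self.scale.validate_outcomes(self.data["outcome"].to_numpy())

    @property
    def n_hospitals(self) -> int:
        return self.data["hospital_id"].nunique()

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def outcomes(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=np.int64)

    def to_csv(self, path) -> None:
        cols = ["hospital_id", *self.covariate_names, "outcome"]
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scale: OutcomeScale) -> "PatientCohort":
        df = pd.read_csv(path)
        covs = tuple(c for c in df.columns
                     if c not in ("hospital_id", "outcome"))
        return cls(df, scale, covs)


def simulate_cohort(gen: OutcomeGenerator,
                    cov_model: CovariateModel | None,
                    H: int,
                    n_per_hospital: int,
                    effects: CenterEffectVector,
                    seed: int | np.random.Generator,
                    max_patients: int = 5_000_000) -> PatientCohort:
    """Simulate a full cohort of ``H`` equal-sized hospitals.

    Each patient's ordinal outcome is drawn from the generator's category
    probabilities after shifting all cumulative logits by their hospital's
    true effect.
    """
    if effects.n_hospitals != H:
        raise ValueError("effects length must equal H")
    n_total = H * n_per_hospital
    if n_total > max_patients:
        raise ValueError(f"cohort of {n_total} exceeds limit {max_patients}")
    rng = np.random.default_rng(seed)
    hospital_id = np.repeat(np.arange(1, H + 1), n_per_hospital)
    cov = (cov_model.sample(rng, n_total) if cov_model is not None
           else None)
    beta_per_patient = effects.beta[hospital_id - 1]
    P = gen.category_probs(cov, beta_per_patient) if cov is not None else \
        gen.category_probs(None, beta_per_patient)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_total)
    y = (u[:, None] >= cum).sum(axis=1) + 1
    df = pd.DataFrame({"hospital_id": hospital_id})
    names: tuple[str, ...] = ()
    if cov is not None:
        for c in cov.columns:
            df[c] = cov[c].to_numpy()
        names = tuple(cov.columns)
    df["outcome"] = y.astype(np.int64)
    return PatientCohort(df, gen.scale, names)


def fit_generator(data: pd.DataFrame, scale: OutcomeScale,
                  covariates: Sequence[str]) -> OutcomeGenerator:
    """Fit a multinomial-logit outcome generator to a patient-level table.

    Maximum-likelihood multinomial logistic regression of the outcome
    category (reference = worst category) on the given covariates;
    categorical covariates are dummy-encoded.  Every category must be
    observed at least once.
    """
    import statsmodels.api as sm

    y = scale.validate_outcomes(data["outcome"].to_numpy())
    counts = np.bincount(y, minlength=scale.n_categories + 1)[1:]
    if (counts == 0).any():
        empty = [scale.categories[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"outcome categories with zero observations: {empty}")
    X, names, cats = _encode_design(data, covariates)
    Z = np.column_stack([np.ones(len(data)), X])
    model = sm.MNLogit(y - 1, Z)
    res = model.fit(method="newton", maxiter=200, disp=False)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            "multinomial generator fit did not converge "
            "(possible separation in the covariates)")
    return OutcomeGenerator(
        mode="fitted",
        scale=scale,
        coef=np.asarray(res.params),         # (p+1, K-1)
        feature_columns=tuple(covariates),
        feature_categories=cats,
        design_names=tuple(names),
    )
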