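"""Fixed-effect analysis models for hospital profiling.

Two maximum-likelihood fitters, written as direct Newton solvers so that
thousands of Monte-Carlo fits stay cheap:

* :func:`fit_binary_logistic` — ordinary logistic regression of a
  dichotomized outcome on case-mix covariates plus hospital as a
  categorical variable;
* :func:`fit_proportional_odds` — cumulative-logit regression of the full
  ordinal outcome with a common (proportional-odds) coefficient per
  covariate and hospital.

Both use the "higher = better" orientation: the ordinal model is
``logit P(Y >= k) = alpha_k + x'gamma + b_hospital`` for k = 2..K, and the
binary model codes 1 for the better half of the dichotomy, so a positive
hospital coefficient always means better outcomes.

Hospitals are reference-coded internally (first estimable hospital as
baseline).  Estimates are then re-expressed as deviations from the mean
center effect with delta-method standard errors from the full coefficient
covariance; the reference-coded (marginal) standard errors are kept as
well, because the conventional profiling workflow reads its confidence
intervals off those (see outliers module).

A hospital whose outcomes are completely one-sided (all the same binary
value; all in the worst or all in the best ordinal category) has no finite
coefficient (separation).  Such hospitals are dropped from the fit and
reported as ``non_estimable``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import PatientCohort

__all__ = ["DesignSpec", "FitResult", "FitError",
           "fit_binary_logistic", "fit_proportional_odds"]


class FitError(RuntimeError):
    """Raised when a model fit fails irrecoverably."""


@dataclass(frozen=True)
class DesignSpec:
    """Analysis design: adjustment covariates and hospital coding."""

    covariates: tuple[str, ...] = ()
    coding: str = "reference"
    reference: object = None  # hospital id; default = first estimable

    def __post_init__(self):
        if self.coding != "reference":
            raise ValueError("only reference coding is implemented")


@dataclass
class FitResult:
    """Per-hospital center-effect estimates from one model fit.

    ``center_effects`` are deviations from the mean effect over the
    estimable hospitals (log-odds units; they sum to zero).  ``se`` are
    the delta-method standard errors of those deviations; ``se_marginal``
    are the reference-coded coefficient standard errors (the reference
    hospital is assigned the median of the others).  Non-estimable
    hospitals carry NaN everywhere.
    """

    model: str
    hospital_ids: np.ndarray
    center_effects: np.ndarray
    se: np.ndarray
    se_marginal: np.ndarray
    covariate_coefs: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    non_estimable: tuple
    reference: object
    thresholds: np.ndarray | None = None
    intercept: float | None = None
    cov_deviation: np.ndarray | None = None

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)

    @property
    def estimable(self) -> np.ndarray:
        return ~np.isin(self.hospital_ids, list(self.non_estimable))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hospital_id": self.hospital_ids,
            "center_effect": self.center_effects,
            "se": self.se,
            "se_marginal": self.se_marginal,
            "estimable": self.estimable,
        })


# ---------------------------------------------------------------------------
# design matrices


def _covariate_design(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list]:
    """Numeric columns centered; categoricals dummy-coded dropping the
    first observed level.  Constant columns are dropped (they would make
    the information matrix singular)."""
    cols, names = [], []
    for c in covariates:
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            for lv in levels[1:]:
                v = (s.to_numpy() == lv).astype(float)
                if v.std() > 0:
                    cols.append(v)
                    names.append(f"{c}[{lv}]")
        else:
            v = s.to_numpy(dtype=float)
            if v.std() > 0:
                cols.append(v - v.mean())
                names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _hospital_dummies(hospital_id: np.ndarray, hospitals: np.ndarray,
                      reference) -> tuple[np.ndarray, list]:
    keep = [h for h in hospitals if h != reference]
    X = np.empty((len(hospital_id), len(keep)))
    for j, h in enumerate(keep):
        X[:, j] = hospital_id == h
    return X, keep


# ---------------------------------------------------------------------------
# generic Newton maximizer with step-halving


def _newton_maximize(psi0, fgh, gtol=1e-8, maxiter=100):
    psi = np.asarray(psi0, dtype=float).copy()
    ll, g, H = fgh(psi, hess=True)
    if not np.isfinite(ll):
        raise FitError("log-likelihood not finite at the starting values")
    it = 0
    converged = False
    for it in range(1, maxiter + 1):
        if np.max(np.abs(g)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular information matrix: {err}") from err
        direction = -step  # H is negative definite at a maximum
        t = 1.0
        for _ in range(50):
            ll_new = fgh(psi + t * direction, hess=False)[0]
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                break
            t *= 0.5
        else:
            # no improving step: treat current point as the optimum
            break
        psi = psi + t * direction
        ll, g, H = fgh(psi, hess=True)
    if np.max(np.abs(g)) < gtol:
        converged = True
    return psi, ll, H, converged, it


# ---------------------------------------------------------------------------
# binary logistic


def _binary_fgh(X, y):
    def fgh(psi, hess=True):
        eta = X @ psi
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        mu = expit(eta)
        g = X.T @ (y - mu)
        if not hess:
            return ll, g, None
        w = mu * (1.0 - mu)
        H = -(X * w[:, None]).T @ X
        return ll, g, H
    return fgh


def _po_fgh(X, y, K, cat_idx):
    """Cumulative-logit log-likelihood, gradient and Hessian.

    Parameter vector: (alpha_2..alpha_K, beta).  alpha_k is the intercept
    of logit P(Y >= k); validity (decreasing alphas) is enforced by the
    likelihood itself going to -inf when category probabilities turn
    non-positive, which the line search then rejects.
    """
    n, p = X.shape

    def fgh(psi, hess=True):
        alpha = psi[:K - 1]
        beta = psi[K - 1:]
        eta = X @ beta if p else np.zeros(n)
        A = np.empty(K + 2)
        A[0] = np.nan
        A[1] = np.inf
        A[2:K + 1] = alpha
        A[K + 1] = -np.inf
        a_lin = A[y] + eta
        b_lin = A[y + 1] + eta
        sa = expit(a_lin)
        sb = expit(b_lin)
        pr = sa - sb
        if np.any(pr <= 0):
            return -np.inf, None, None
        ll = float(np.sum(np.log(pr)))
        da = sa * (1.0 - sa)
        db = sb * (1.0 - sb)
        la = da / pr
        lb = -db / pr
        g_eta = la + lb
        bc_a = np.bincount(y, weights=la, minlength=K + 2)
        bc_b = np.bincount(y + 1, weights=lb, minlength=K + 2)
        g_alpha = (bc_a + bc_b)[2:K + 1]
        g = np.concatenate([g_alpha, X.T @ g_eta if p else []])
        if not hess:
            return ll, g, None
        ca = da * (1.0 - 2.0 * sa)
        cb = db * (1.0 - 2.0 * sb)
        laa = ca / pr - la * la
        lbb = -cb / pr - (db / pr) ** 2
        lab = da * db / (pr * pr)
        h_eta = laa + 2.0 * lab + lbb
        m = K - 1 + p
        H = np.zeros((m, m))
        # threshold block
        d_aa = np.bincount(y, weights=laa, minlength=K + 2)
        d_bb = np.bincount(y + 1, weights=lbb, minlength=K + 2)
        diag = (d_aa + d_bb)[2:K + 1]
        off = np.bincount(y, weights=lab, minlength=K + 2)[2:K]
        ia = np.arange(K - 1)
        H[ia, ia] = diag
        if K > 2:
            H[ia[:-1], ia[:-1] + 1] = off
            H[ia[:-1] + 1, ia[:-1]] = off
        if p:
            w_a = laa + lab
            w_b = lbb + lab
            for k in range(2, K + 1):
                row = np.zeros(p)
                idx_a = cat_idx[k]
                idx_b = cat_idx[k - 1]
                if idx_a.size:
                    row += w_a[idx_a] @ X[idx_a]
                if idx_b.size:
                    row += w_b[idx_b] @ X[idx_b]
                H[k - 2, K - 1:] = row
                H[K - 1:, k - 2] = row
            H[K - 1:, K - 1:] = (X * h_eta[:, None]).T @ X
        return ll, g, H
    return fgh


# ---------------------------------------------------------------------------
# shared assembly


def _as_table(data) -> pd.DataFrame:
    if isinstance(data, PatientCohort):
        return data.data
    return data


def _deviation_transform(hospitals, est_hosp, coefs, cov, reference):
    """Reference-coded hospital coefficients -> deviations from the mean.

    ``coefs``/``cov`` cover the non-reference estimable hospitals in
    order.  Returns (deviation, se_dev, se_marginal, cov_dev) over the
    estimable set."""
    m = len(est_hosp)
    b = np.zeros(m)
    S = np.zeros((m, m))
    nonref = [i for i, h in enumerate(est_hosp) if h != reference]
    b[nonref] = coefs
    S[np.ix_(nonref, nonref)] = cov
    d = b - b.mean()
    rm = S.mean(axis=1, keepdims=True)
    cm = S.mean(axis=0, keepdims=True)
    Sd = S - rm - cm + S.mean()
    se_dev = np.sqrt(np.clip(np.diag(Sd), 0.0, None))
    se_marg = np.sqrt(np.clip(np.diag(S), 0.0, None))
    if m > 1:
        ref_pos = [i for i, h in enumerate(est_hosp) if h == reference]
        if ref_pos:
            others = np.delete(se_marg, ref_pos[0])
            se_marg[ref_pos[0]] = np.median(others) if others.size else np.nan
    return d, se_dev, se_marg, Sd


def _prepare(df, y, design, one_sided_mask):
    """Split hospitals into estimable / non-estimable, pick reference."""
    hospitals = np.array(sorted(df["hospital_id"].unique()))
    hid = df["hospital_id"].to_numpy()
    non_est = []
    for h in hospitals:
        if one_sided_mask(y[hid == h]):
            non_est.append(h)
    est_hosp = np.array([h for h in hospitals if h not in set(non_est)])
    if est_hosp.size == 0:
        raise FitError("no estimable hospitals (all outcomes one-sided)")
    reference = design.reference
    if reference is None or reference not in est_hosp:
        reference = est_hosp[0]
    keep = ~np.isin(hid, non_est)
    return hospitals, est_hosp, non_est, reference, keep


def _finalize(model, hospitals, est_hosp, non_est, reference, d, se_dev,
              se_marg, Sd, cov_names, cov_coefs, ll, converged, it,
              thresholds=None, intercept=None):
    H = len(hospitals)
    full = {name: np.full(H, np.nan) for name in ("d", "se", "sm")}
    pos = {h: i for i, h in enumerate(hospitals)}
    for j, h in enumerate(est_hosp):
        i = pos[h]
        full["d"][i] = d[j]
        full["se"][i] = se_dev[j]
        full["sm"][i] = se_marg[j]
    return FitResult(
        model=model,
        hospital_ids=hospitals,
        center_effects=full["d"],
        se=full["se"],
        se_marginal=full["sm"],
        covariate_coefs=dict(zip(cov_names, cov_coefs)),
        loglik=ll,
        converged=converged,
        n_iter=it,
        non_estimable=tuple(non_est),
        reference=reference,
        thresholds=thresholds,
        intercept=intercept,
        cov_deviation=Sd,
    )


# ---------------------------------------------------------------------------
# public fitters


def fit_binary_logistic(data, design: DesignSpec = DesignSpec(),
                        outcome: str = "outcome") -> FitResult:
    """Fit a fixed-effect logistic regression with hospital as categorical.

    ``data`` is a :class:`PatientCohort` or DataFrame whose ``outcome``
    column is binary 0/1 (1 = better half of the dichotomy).
    """
    df = _as_table(data)
    y = df[outcome].to_numpy()
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("binary outcome must be coded 0/1")
    if vals.size < 2:
        raise FitError("outcome is constant; model not identifiable")
    hospitals, est_hosp, non_est, reference, keep = _prepare(
        df, y, design, lambda v: v.min() == v.max())
    dfk = df.loc[keep]
    yk = y[keep].astype(float)
    Xc, cov_names = _covariate_design(dfk, design.covariates)
    Xh, hosp_order = _hospital_dummies(dfk["hospital_id"].to_numpy(),
                                       est_hosp, reference)
    X = np.column_stack([np.ones(len(dfk)), Xc, Xh])
    psi0 = np.zeros(X.shape[1])
    psi0[0] = logit(yk.mean())
    psi, ll, Hmat, converged, it = _newton_maximize(psi0, _binary_fgh(X, yk))
    cov_all = np.linalg.inv(-Hmat)
    q = 1 + len(cov_names)
    hosp_coefs = psi[q:]
    hosp_cov = cov_all[q:, q:]
    d, se_dev, se_marg, Sd = _deviation_transform(
        hospitals, est_hosp, hosp_coefs, hosp_cov, reference)
    return _finalize("binary", hospitals, est_hosp, non_est, reference,
                     d, se_dev, se_marg, Sd, cov_names, psi[1:q],
                     ll, converged, it, intercept=float(psi[0]))


def fit_proportional_odds(data, design: DesignSpec = DesignSpec(),
                          n_categories: int | None = None,
                          outcome: str = "outcome") -> FitResult:
    """Fit a proportional-odds (cumulative logit) fixed-effect model.

    The outcome column holds 1-based category indices, worst to best.
    Globally unobserved categories are merged into their neighbours with a
    warning (the thresholds bounding an empty category are not separately
    identifiable).  For K = 2 the model coincides with binary logistic
    regression on the indicator of the top category.
    """
    df = _as_table(data)
    y = df[outcome].to_numpy(dtype=np.int64)
    if n_categories is None:
        n_categories = int(y.max())
    if y.min() < 1 or y.max() > n_categories:
        raise ValueError("outcome indices out of range")
    observed = np.unique(y)
    if observed.size < 2:
        raise FitError("outcome is constant; model not identifiable")
    if observed.size < n_categories:
        warnings.warn(
            f"{n_categories - observed.size} outcome categories unobserved; "
            "merging into adjacent observed categories", stacklevel=2)
        y = np.searchsorted(observed, y) + 1
    K = int(observed.size) if observed.size < n_categories else n_categories
    hospitals, est_hosp, non_est, reference, keep = _prepare(
        df, y, design,
        lambda v: (v == 1).all() or (v == K).all())
    dfk = df.loc[keep]
    yk = y[keep]
    Xc, cov_names = _covariate_design(dfk, design.covariates)
    Xh, _ = _hospital_dummies(dfk["hospital_id"].to_numpy(),
                              est_hosp, reference)
    X = np.column_stack([Xc, Xh]) if Xc.size or Xh.size else \
        np.empty((len(dfk), 0))
    # intercept-only cumulative logits as starting thresholds
    cum = np.array([(yk >= k).mean() for k in range(2, K + 1)])
    alpha0 = logit(np.clip(cum, 1e-6, 1 - 1e-6))
    psi0 = np.concatenate([alpha0, np.zeros(X.shape[1])])
    cat_idx = {k: np.flatnonzero(yk == k) for k in range(1, K + 1)}
    psi, ll, Hmat, converged, it = _newton_maximize(
        psi0, _po_fgh(X, yk, K, cat_idx))
    cov_all = np.linalg.inv(-Hmat)
    q = K - 1 + len(cov_names)
    hosp_coefs = psi[q:]
    hosp_cov = cov_all[q:, q:]
    d, se_dev, se_marg, Sd = _deviation_transform(
        hospitals, est_hosp, hosp_coefs, hosp_cov, reference)
    return _finalize("ordinal", hospitals, est_hosp, non_est, reference,
                     d, se_dev, se_marg, Sd, cov_names,
                     psi[K - 1:q], ll, converged, it,
                     thresholds=psi[:K - 1].copy())
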