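"""Transition-matrix estimation from longitudinal CGI-S panels.

Three estimators of the weekly 4x4 severity transition matrix from
patient-level panels of weekly CGI-S scores:

* a proportional-odds (ordered logit) model — the base estimator: the
  dependent variable is the current severity state and the independent
  variables are indicators of the previous week's state (Normal is the
  reference), so each origin state yields one row of the matrix;
* empirical counting of observed consecutive transitions (complete pairs),
  with binomial standard errors per cell;
* last-observation-carried-forward (LOCF) imputation as a preprocessing
  variant — missing post-baseline visits are filled from the most recent
  observed post-baseline visit; baseline observations are never carried
  forward into the treatment phase.

Panels are pandas DataFrames with columns ``patient_id, arm, week, cgis``
(``cgis`` nullable integer, NA = missing visit). CGI-S scores are mapped to
the four severity bands before any estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .config import TransitionMatrix
from .states import N_STATES, cgis_to_state

__all__ = [
    "PANEL_COLUMNS",
    "OrderedLogitFit",
    "EstimationError",
    "locf_impute",
    "transition_pairs",
    "empirical_transition_matrix",
    "fit_ordered_logit",
    "logit_to_matrix",
    "proportional_odds_matrix",
    "read_panel",
    "write_panel",
]

PANEL_COLUMNS = ["patient_id", "arm", "week", "cgis"]


class EstimationError(ValueError):
    """The panel does not support the requested estimator."""


class FitWarning(UserWarning):
    """Non-fatal fitting issue (separation, ridge refit)."""


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise EstimationError(f"panel is missing columns {missing}")
    return panel


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a panel CSV (columns patient_id, arm, week, cgis; empty = missing)."""
    panel = pd.read_csv(path, dtype={"patient_id": str, "arm": str})
    panel["cgis"] = panel["cgis"].astype("Int64")
    return _check_panel(panel)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    _check_panel(panel)[PANEL_COLUMNS].to_csv(path, index=False)


def locf_impute(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill missing post-baseline visits by carrying the last post-baseline
    observation forward; baseline (week 0) values are never carried forward.

    Observed values are never altered. Post-baseline weeks preceding the
    first post-baseline observation stay missing.
    """
    panel = _check_panel(panel).sort_values(["patient_id", "week"]).copy()
    post = panel[panel["week"] > 0]
    filled = post.groupby("patient_id")["cgis"].ffill()
    panel.loc[filled.index, "cgis"] = filled
    return panel


def transition_pairs(panel: pd.DataFrame, include_baseline: bool = True) -> np.ndarray:
    """Counts of observed consecutive state transitions, shape (4, 4).

    Pools all consecutive observed week pairs per patient (weeks must be
    adjacent integers). ``include_baseline`` controls whether the baseline ->
    week-1 pair contributes.
    """
    panel = _check_panel(panel).sort_values(["patient_id", "week"])
    counts = np.zeros((N_STATES, N_STATES), dtype=float)
    for _, grp in panel.groupby("patient_id", sort=False):
        weeks = grp["week"].to_numpy()
        cgis = grp["cgis"].to_numpy(dtype=float, na_value=np.nan)
        for a in range(len(grp) - 1):
            if weeks[a + 1] != weeks[a] + 1:
                continue
            if not include_baseline and weeks[a] == 0:
                continue
            if np.isnan(cgis[a]) or np.isnan(cgis[a + 1]):
                continue
            counts[cgis_to_state(int(cgis[a])), cgis_to_state(int(cgis[a + 1]))] += 1
    return counts


def empirical_transition_matrix(panel: pd.DataFrame, include_baseline: bool = True) -> TransitionMatrix:
    """Transition matrix from observed transition frequencies.

    Cell (i, j) is the fraction of observed pairs leaving state i that land
    in state j; standard errors are binomial, sqrt(p(1-p)/n_i). Origin states
    with no observed pairs yield NaN rows (the caller must supply a
    fallback).
    """
    counts = transition_pairs(panel, include_baseline=include_baseline)
    n = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts / np.where(n > 0, n, 1), np.nan)
        se = np.where(n > 0, np.sqrt(p * (1 - p) / np.where(n > 0, n, 1)), np.nan)
    if np.any(n == 0):
        empty = [i for i in range(N_STATES) if n[i, 0] == 0]
        warnings.warn(f"no observed transitions out of state indices {empty}", FitWarning, stacklevel=2)
    return TransitionMatrix(p=p, se=np.nan_to_num(se, nan=0.0), raw=p.copy())


# ---------------------------------------------------------------------------
# proportional-odds ordered logit
# ---------------------------------------------------------------------------


@dataclass
class OrderedLogitFit:
    """Fitted proportional-odds model for weekly severity transitions.

    ``beta`` are the coefficients of the previous-state indicators (Mild,
    Moderate, Severe; Normal is the reference); ``theta`` the three strictly
    increasing cutpoints on the logit scale. ``cov`` is the covariance of
    (beta_1..3, theta_1..3) from the inverse observed-information matrix.
    """

    beta: np.ndarray
    theta: np.ndarray
    loglike: float
    converged: bool
    cov: np.ndarray
    n_pairs: int
    ridge: float = 0.0


def _unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transformed parameters -> (beta, theta) with theta strictly increasing.

    params = (b1, b2, b3, t1, log d2, log d3); theta = (t1, t1+e^{d2}, ...).
    """
    beta = params[:3]
    theta = np.array([params[3], params[3] + np.exp(params[4]), params[3] + np.exp(params[4]) + np.exp(params[5])])
    return beta, theta


def _cell_probs(beta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """4x4 matrix of P(next = j | prev = i) under the proportional-odds model."""
    eta = np.concatenate([[0.0], beta])  # linear predictor per origin state
    cdf = expit(theta[None, :] - eta[:, None])  # (4 origins, 3 cuts)
    cdf = np.hstack([np.zeros((N_STATES, 1)), cdf, np.ones((N_STATES, 1))])
    return np.diff(cdf, axis=1)


def _nll(params: np.ndarray, counts: np.ndarray, ridge: float) -> float:
    beta, theta = _unpack(params)
    probs = _cell_probs(beta, theta)
    with np.errstate(divide="ignore"):
        ll = float((counts * np.log(np.clip(probs, 1e-300, None))).sum())
    return -ll + ridge * float(params @ params)


def fit_ordered_logit(panel: pd.DataFrame, include_baseline: bool = True) -> OrderedLogitFit:
    """Fit the proportional-odds model to pooled consecutive transitions.

    The log-likelihood sum log[F(theta_y - x beta) - F(theta_{y-1} - x beta)]
    (F logistic, theta_0 = -inf, theta_4 = +inf) is maximized with BFGS from
    an all-zeros start in the transformed parameterization (cutpoints
    t1, t1+e^{d2}, t1+e^{d2}+e^{d3}, so the zero start means theta = (0,1,2)).
    Perfect separation triggers a ridge-stabilized refit (penalty 1e-4) with
    a warning.
    """
    counts = transition_pairs(panel, include_baseline=include_baseline)
    if (counts.sum(axis=1) > 0).sum() < 2:
        raise EstimationError("panel must contain observed pairs from at least two distinct previous states")
    return _fit_counts(counts)


def _fit_counts(counts: np.ndarray, ridge: float = 0.0) -> OrderedLogitFit:
    start = np.zeros(6)
    res = minimize(_nll, start, args=(counts, ridge), method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    beta, theta = _unpack(res.x)
    separated = np.any(np.abs(res.x) > 15)
    if (not res.success or separated) and ridge == 0.0:
        warnings.warn(
            "ordered-logit fit unstable (possible separation); refitting with ridge penalty 1e-4",
            FitWarning,
            stacklevel=2,
        )
        return _fit_counts(counts, ridge=1e-4)

    # covariance of (beta, theta) via the observed information in that space
    def nll_raw(q: np.ndarray) -> float:
        b, th = q[:3], q[3:]
        probs = _cell_probs(b, th)
        with np.errstate(divide="ignore"):
            ll = float((counts * np.log(np.clip(probs, 1e-300, None))).sum())
        return -ll + ridge * float(q @ q)

    q_hat = np.concatenate([beta, theta])
    try:
        hess = approx_hess(q_hat, nll_raw)
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((6, 6), np.nan)
    return OrderedLogitFit(
        beta=beta,
        theta=theta,
        loglike=-_nll(res.x, counts, 0.0),
        converged=bool(res.success),
        cov=cov,
        n_pairs=int(counts.sum()),
        ridge=ridge,
    )


def proportional_odds_matrix(theta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Transition matrix implied by raw proportional-odds parameters.

    Row i is the ordered-logit cell probabilities for origin state i (Normal
    has linear predictor 0, other origins beta_i). Rows sum to 1 exactly by
    the telescoping construction.
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if theta.shape != (3,) or np.any(np.diff(theta) <= 0):
        raise ValueError("theta must be three strictly increasing cutpoints")
    if beta.shape != (3,):
        raise ValueError("beta must have three entries (Mild, Moderate, Severe origins)")
    return _cell_probs(beta, theta)


def logit_to_matrix(fit: OrderedLogitFit) -> TransitionMatrix:
    """Transition matrix (with delta-method standard errors) from a fit."""
    p = _cell_probs(fit.beta, fit.theta)
    se = np.zeros_like(p)
    if np.all(np.isfinite(fit.cov)):
        theta = fit.theta
        eta = np.concatenate([[0.0], fit.beta])
        for i in range(N_STATES):
            f = expit(theta - eta[i]) * (1 - expit(theta - eta[i]))  # logistic density at cuts
            for j in range(N_STATES):
                grad = np.zeros(6)
                # dp/dtheta_j = f_j ; dp/dtheta_{j-1} = -f_{j-1}
                if j < 3:
                    grad[3 + j] += f[j]
                if j > 0:
                    grad[3 + j - 1] -= f[j - 1]
                # dp/dbeta_i = -(f_j - f_{j-1}) for origin i > 0
                if i > 0:
                    upper = f[j] if j < 3 else 0.0
                    lower = f[j - 1] if j > 0 else 0.0
                    grad[i - 1] = -(upper - lower)
                se[i, j] = float(np.sqrt(max(grad @ fit.cov @ grad, 0.0)))
    return TransitionMatrix(p=p, se=se, raw=p.copy())
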