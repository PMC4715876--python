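"""Synthetic patient-level CGI-S panels with the trial's assumed structure.

The pivotal adjunctive-therapy trial's patient-level data are not publicly
deposited, so this module generates panels with the statistical structure
the analysis assumes: each patient's weekly severity path is a first-order
Markov chain on the four states, started from the trial's initial
distribution, observed at baseline and 8 post-baseline weeks; each state is
rendered as a CGI-S integer uniformly within its band (Normal -> 1,
Mild -> {2,3}, Moderate -> {4,5}, Severe -> {6,7}); post-baseline visits are
masked missing completely at random. Identical seeds give identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TransitionMatrix
from .estimation import PANEL_COLUMNS, proportional_odds_matrix
from .states import N_STATES, STATE_TO_CGIS

__all__ = ["PanelSimSpec", "simulate_panel", "generator_from_logit"]


@dataclass
class PanelSimSpec:
    """Specification of a synthetic CGI-S panel."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    n_patients: int = 455
    n_weeks: int = 8
    missing_rate: float = 0.0
    arm: str = "intervention"
    seed: int = 0
    #: optional deterministic state -> CGI-S rule; None = uniform within band
    cgis_rule: dict[int, int] | None = None
    #: monotone dropout instead of independent missingness
    monotone_dropout: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (N_STATES, N_STATES) or np.any(P < 0) or np.any(
            np.abs(P.sum(axis=1) - 1) > 1e-6
        ):
            raise ValueError("transition_matrix must be a row-stochastic 4x4 matrix")


def simulate_panel(spec: PanelSimSpec) -> pd.DataFrame:
    """Generate a panel DataFrame (patient_id, arm, week, cgis).

    ``cgis`` is a nullable integer column; masked visits are NA. Baseline
    (week 0) is always observed.
    """
    rng = np.random.default_rng(spec.seed)
    P = np.asarray(spec.transition_matrix, dtype=float)
    P = P / P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    init = np.asarray(spec.initial_distribution, dtype=float)
    init = init / init.sum()

    n, w = spec.n_patients, spec.n_weeks
    states = np.empty((n, w + 1), dtype=np.int64)
    states[:, 0] = rng.choice(N_STATES, size=n, p=init)
    for t in range(1, w + 1):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)

    if spec.cgis_rule is not None:
        cgis = np.vectorize(spec.cgis_rule.__getitem__)(states)
    else:
        lo = np.array([STATE_TO_CGIS[s][0] for s in range(N_STATES)])
        hi = np.array([STATE_TO_CGIS[s][-1] for s in range(N_STATES)])
        cgis = rng.integers(lo[states], hi[states] + 1)

    if spec.missing_rate > 0:
        if spec.monotone_dropout:
            dropped = rng.random((n, w)) < spec.missing_rate
            mask = np.cumsum(dropped, axis=1) > 0
        else:
            mask = rng.random((n, w)) < spec.missing_rate
        mask = np.hstack([np.zeros((n, 1), dtype=bool), mask])  # baseline observed
    else:
        mask = np.zeros((n, w + 1), dtype=bool)

    panel = pd.DataFrame(
        {
            "patient_id": np.repeat([f"P{i:05d}" for i in range(n)], w + 1),
            "arm": spec.arm,
            "week": np.tile(np.arange(w + 1), n),
            "cgis": pd.array(np.where(mask, -1, cgis).ravel(), dtype="Int64"),
        }
    )
    panel.loc[panel["cgis"] == -1, "cgis"] = pd.NA
    return panel[PANEL_COLUMNS]


def generator_from_logit(theta: np.ndarray, beta: np.ndarray) -> TransitionMatrix:
    """Row-stochastic generator matrix from raw proportional-odds parameters.

    Shares the closed form used by the estimator, so simulate -> fit ->
    matrix round trips cleanly in parameter-recovery tests.
    """
    p = proportional_odds_matrix(theta, beta)
    return TransitionMatrix(p=p, se=np.zeros_like(p), raw=p.copy())
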