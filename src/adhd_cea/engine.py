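"""Two-stage weekly Markov cohort engine with the week-8 responder rule.

Cohort mass is split into on-treatment mass (still transitioning under the
arm's weekly matrix) and off-treatment mass (discontinued, absorbed in its
last observed state). In the base variant all patients remain on treatment
through stage 1 (weeks 1..8); at the end of week 8 mass in the Moderate or
Severe state is considered non-responsive and discontinues permanently, and
the same rule applies to mass newly entering Moderate/Severe in any later
week. Two structural variants alter stage 2:

* ``maintain_on_treatment`` — no discontinuation; all mass transitions (and
  accrues drug cost) for all 52 weeks.
* ``stabilize_after_stage1`` — week-8 absorption as in the base variant,
  then no further transitions at all (occupancy frozen from week 8 on).

Utilities and costs attach to the end-of-cycle state for cycles 1..horizon;
week 0 (baseline) contributes nothing. No half-cycle correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ArmSpec, ModelSettings
from .states import N_STATES

__all__ = ["CohortTrajectory", "run_cohort", "treatment_weeks", "occupancy_at", "microsimulate"]

_NONRESPONSE = np.array([0.0, 0.0, 1.0, 1.0])  # Moderate, Severe


@dataclass
class CohortTrajectory:
    """Weekly occupancy split into on-treatment and absorbed mass.

    ``on[t]``/``off[t]`` are 4-vectors for t = 0..horizon_weeks; row t is the
    end of cycle t (t = 0 is baseline).
    """

    on: np.ndarray
    off: np.ndarray

    @property
    def occupancy(self) -> np.ndarray:
        """Combined on+off occupancy, shape (horizon+1, n_states)."""
        return self.on + self.off

    @property
    def horizon(self) -> int:
        return self.on.shape[0] - 1

    def to_rows(self) -> "list[dict]":
        from .states import STATE_NAMES

        return [
            {"cycle": t, "state": STATE_NAMES[s], "on_mass": float(self.on[t, s]), "off_mass": float(self.off[t, s])}
            for t in range(self.on.shape[0])
            for s in range(N_STATES)
        ]


def run_cohort(arm: ArmSpec, settings: ModelSettings, init: np.ndarray) -> CohortTrajectory:
    """Propagate the cohort through weekly cycles under the arm's matrix.

    Returns the trajectory with on/off mass for every cycle 0..horizon.
    Mass is conserved at every cycle; absorption is state-preserving and
    permanent.
    """
    P = arm.transitions.p
    hw, s1 = settings.horizon_weeks, settings.stage1_weeks
    variant = settings.structural_variant

    on = np.zeros((hw + 1, N_STATES))
    off = np.zeros((hw + 1, N_STATES))
    on[0] = np.asarray(init, dtype=float)

    for t in range(1, hw + 1):
        if variant == "stabilize_after_stage1" and t > s1:
            on[t] = on[t - 1]
            off[t] = off[t - 1]
            continue
        on[t] = on[t - 1] @ P
        off[t] = off[t - 1]
        if variant != "maintain_on_treatment" and t >= s1:
            absorbed = on[t] * _NONRESPONSE
            off[t] = off[t] + absorbed
            on[t] = on[t] - absorbed
    return CohortTrajectory(on=on, off=off)


def treatment_weeks(trajectory: CohortTrajectory, settings: ModelSettings) -> float:
    """Expected weeks on study drug per patient.

    A cycle is charged when the patient enters it on treatment, so a patient
    absorbed at the end of cycle t receives drug through cycle t. With the
    ``drug_charge_final_week`` setting off, the absorption-week charge for
    newly absorbed mass is removed instead.
    """
    weeks = float(trajectory.on[:-1].sum())
    if not settings.drug_charge_final_week:
        newly_absorbed = np.diff(trajectory.off.sum(axis=1))
        weeks -= float(newly_absorbed.sum())
    return weeks


def occupancy_at(trajectory: CohortTrajectory, week: int) -> np.ndarray:
    """Combined (on + off) state distribution at the end of cycle ``week``."""
    if not 0 <= week <= trajectory.horizon:
        raise ValueError(f"week must be in [0, {trajectory.horizon}], got {week}")
    return trajectory.on[week] + trajectory.off[week]


def microsimulate(
    arm: ArmSpec,
    settings: ModelSettings,
    init: np.ndarray,
    n_paths: int,
    rng: np.random.Generator,
) -> tuple[CohortTrajectory, float]:
    """Individual-level simulation of the same two-stage rules.

    Simulates ``n_paths`` patient trajectories and returns the empirical
    trajectory (mean on/off occupancy per cycle) plus the mean number of
    weeks on treatment. Serves as an independent check of the cohort engine:
    occupancies converge to the deterministic values as n_paths grows.
    """
    P = arm.transitions.p
    cum = np.cumsum(P, axis=1)
    hw, s1 = settings.horizon_weeks, settings.stage1_weeks
    variant = settings.structural_variant

    state = rng.choice(N_STATES, size=n_paths, p=np.asarray(init, dtype=float))
    on_treatment = np.ones(n_paths, dtype=bool)

    on = np.zeros((hw + 1, N_STATES))
    off = np.zeros((hw + 1, N_STATES))
    on[0] = np.bincount(state, minlength=N_STATES) / n_paths
    weeks_on = np.zeros(n_paths)

    for t in range(1, hw + 1):
        frozen = variant == "stabilize_after_stage1" and t > s1
        if frozen:
            # occupancy frozen, but non-absorbed patients stay on treatment
            weeks_on[on_treatment] += 1
        else:
            moving = on_treatment
            weeks_on[moving] += 1
            u = rng.random(moving.sum())
            state = state.copy()
            state[moving] = (u[:, None] > cum[state[moving]]).sum(axis=1)
            if variant != "maintain_on_treatment" and t >= s1:
                on_treatment = on_treatment & (state < 2)
        on[t] = np.bincount(state[on_treatment], minlength=N_STATES) / n_paths
        off[t] = np.bincount(state[~on_treatment], minlength=N_STATES) / n_paths

    return CohortTrajectory(on=on, off=off), float(weeks_on.mean())
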