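"""QALYs, cost components, response metrics and incremental comparisons.

Per-arm effectiveness is the time-averaged per-state utility over cycles
1..horizon (QALYs over the 1-year horizon), minus a one-time expected
adverse-event decrement (incidence x disutility x duration / 52 per event).
Costs decompose into drug (daily cost x 7 x expected on-treatment weeks),
medical and productivity components; the Ministry-of-Health (MoH)
perspective totals drug + medical, the societal perspective adds
productivity losses.

Incremental comparisons report incremental QALYs, costs and ICERs per
perspective, the week-8 number needed to treat (NNT) and patient-weeks in
response. ICERs are computed from full-precision internals. When the
incremental QALY is zero the ICER is the string sentinel ``"undefined"``;
when the cost and QALY increments have opposite signs a dominance flag
replaces the ICER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AdverseEvent, ArmSpec, ModelConfig, ModelSettings
from .engine import CohortTrajectory, run_cohort, treatment_weeks

__all__ = [
    "ArmResults",
    "CEComparison",
    "qalys",
    "cost_components",
    "response_metrics",
    "compare_arms",
    "run_arm",
    "run_model",
    "ModelRun",
]

WEEKS_PER_YEAR = 52
DAYS_PER_WEEK = 7

PERSPECTIVES = ("moh", "societal")


@dataclass
class ArmResults:
    """Per-arm outcomes over the model horizon."""

    name: str
    qalys: float
    drug_cost: float
    medical_cost: float
    productivity_cost: float
    response_rate_week8: float
    patient_weeks_response: float
    treatment_weeks: float

    @property
    def total_cost(self) -> dict[str, float]:
        moh = self.drug_cost + self.medical_cost
        return {"moh": moh, "societal": moh + self.productivity_cost}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "qalys": self.qalys,
            "drug_cost": self.drug_cost,
            "medical_cost": self.medical_cost,
            "productivity_cost": self.productivity_cost,
            "total_cost_moh": self.total_cost["moh"],
            "total_cost_societal": self.total_cost["societal"],
            "response_rate_week8": self.response_rate_week8,
            "patient_weeks_response": self.patient_weeks_response,
            "treatment_weeks": self.treatment_weeks,
        }


@dataclass
class CEComparison:
    """Incremental comparison (intervention minus comparator)."""

    incremental_qaly: float
    incremental_cost: dict[str, float]
    icer: dict[str, float | None] = field(default_factory=dict)
    dominance: dict[str, str] = field(default_factory=dict)
    incremental_response_rate: float = 0.0
    nnt_week8: float = math.inf
    incremental_patient_weeks: float = 0.0
    incremental_cost_per_responder_week: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def icer_field(persp: str):
            if self.dominance.get(persp, "none") != "none":
                return self.dominance[persp]
            v = self.icer.get(persp)
            return "undefined" if v is None else v

        return {
            "incremental_qaly": self.incremental_qaly,
            "incremental_cost": dict(self.incremental_cost),
            "icer": {p: icer_field(p) for p in PERSPECTIVES},
            "dominance": dict(self.dominance),
            "incremental_response_rate": self.incremental_response_rate,
            "nnt_week8": "infinite" if math.isinf(self.nnt_week8) else self.nnt_week8,
            "incremental_patient_weeks": self.incremental_patient_weeks,
            "incremental_cost_per_responder_week": {
                p: (v if v is not None else "undefined")
                for p, v in self.incremental_cost_per_responder_week.items()
            },
        }


def qalys(
    trajectory: CohortTrajectory,
    utilities: np.ndarray,
    aes: list[AdverseEvent],
    arm_key: str,
) -> float:
    """Quality-adjusted life years accrued over the horizon.

    Time-averaged utility over cycles 1..horizon (per 52 weeks/year), minus
    the expected one-time adverse-event decrement for this arm.
    """
    occ = trajectory.occupancy[1:]
    base = float((occ @ np.asarray(utilities, dtype=float)).sum())
    decrement = sum(
        ae.incidence.get(arm_key, 0.0) * ae.disutility * ae.duration_weeks / WEEKS_PER_YEAR
        for ae in aes
    )
    return base / WEEKS_PER_YEAR - decrement


def cost_components(
    trajectory: CohortTrajectory,
    weekly_medical: np.ndarray,
    weekly_productivity: np.ndarray,
    arm: ArmSpec,
    settings: ModelSettings,
) -> tuple[float, float, float]:
    """(drug, medical, productivity) cost components in $CA over the horizon."""
    occ = trajectory.occupancy[1:]
    drug = treatment_weeks(trajectory, settings) * DAYS_PER_WEEK * arm.drug_daily
    medical = float((occ @ np.asarray(weekly_medical, dtype=float)).sum())
    productivity = float((occ @ np.asarray(weekly_productivity, dtype=float)).sum())
    return drug, medical, productivity


def _response_mass(trajectory: CohortTrajectory, settings: ModelSettings, week: int) -> float:
    occ = trajectory.occupancy[week]
    return float(occ[list(settings.response_states)].sum())


def _patient_weeks(trajectory: CohortTrajectory, settings: ModelSettings) -> float:
    occ = trajectory.occupancy[1:]
    return float(occ[:, list(settings.response_states)].sum())


def response_metrics(
    traj_intervention: CohortTrajectory,
    traj_comparator: CohortTrajectory,
    settings: ModelSettings,
) -> dict:
    """Week-8 response rates, incremental rate, NNT and patient-weeks in response."""
    s1 = settings.stage1_weeks
    r_i = _response_mass(traj_intervention, settings, s1)
    r_c = _response_mass(traj_comparator, settings, s1)
    inc = r_i - r_c
    nnt = math.inf if inc == 0 else 1.0 / inc
    pw_i = _patient_weeks(traj_intervention, settings)
    pw_c = _patient_weeks(traj_comparator, settings)
    return {
        "response_rate_intervention": r_i,
        "response_rate_comparator": r_c,
        "incremental_response_rate": inc,
        "nnt_week8": nnt,
        "patient_weeks_intervention": pw_i,
        "patient_weeks_comparator": pw_c,
        "incremental_patient_weeks": pw_i - pw_c,
    }


def run_arm(config: ModelConfig, arm_key: str) -> tuple[ArmResults, CohortTrajectory]:
    """Run one arm through the cohort engine and score its outcomes."""
    arm = config.arms[arm_key]
    traj = run_cohort(arm, config.settings, config.initial_distribution)
    q = qalys(traj, config.utilities, config.aes, arm_key)
    drug, medical, productivity = cost_components(
        traj, config.weekly_medical, config.weekly_productivity, arm, config.settings
    )
    results = ArmResults(
        name=arm.name,
        qalys=q,
        drug_cost=drug,
        medical_cost=medical,
        productivity_cost=productivity,
        response_rate_week8=_response_mass(traj, config.settings, config.settings.stage1_weeks),
        patient_weeks_response=_patient_weeks(traj, config.settings),
        treatment_weeks=treatment_weeks(traj, config.settings),
    )
    return results, traj


def compare_arms(
    intervention: ArmResults,
    comparator: ArmResults,
    settings: ModelSettings,
    *,
    incremental_response_rate: float | None = None,
    nnt_week8: float | None = None,
    incremental_patient_weeks: float | None = None,
) -> CEComparison:
    """Incremental cost-effectiveness comparison (intervention - comparator)."""
    dq = intervention.qalys - comparator.qalys
    dc = {
        p: intervention.total_cost[p] - comparator.total_cost[p] for p in PERSPECTIVES
    }
    icer: dict[str, float | None] = {}
    dominance: dict[str, str] = {}
    for p in PERSPECTIVES:
        if dq > 0 and dc[p] < 0:
            dominance[p] = "intervention_dominant"
            icer[p] = None
        elif dq < 0 and dc[p] > 0:
            dominance[p] = "comparator_dominant"
            icer[p] = None
        elif dq == 0:
            dominance[p] = "none"
            icer[p] = None
        else:
            dominance[p] = "none"
            icer[p] = dc[p] / dq

    inc_rate = (
        intervention.response_rate_week8 - comparator.response_rate_week8
        if incremental_response_rate is None
        else incremental_response_rate
    )
    if nnt_week8 is None:
        nnt_week8 = math.inf if inc_rate == 0 else 1.0 / inc_rate
    if incremental_patient_weeks is None:
        incremental_patient_weeks = (
            intervention.patient_weeks_response - comparator.patient_weeks_response
        )
    cost_per_pw = {
        p: (dc[p] / incremental_patient_weeks if incremental_patient_weeks != 0 else None)
        for p in PERSPECTIVES
    }
    return CEComparison(
        incremental_qaly=dq,
        incremental_cost=dc,
        icer=icer,
        dominance=dominance,
        incremental_response_rate=inc_rate,
        nnt_week8=nnt_week8,
        incremental_patient_weeks=incremental_patient_weeks,
        incremental_cost_per_responder_week=cost_per_pw,
    )


@dataclass
class ModelRun:
    """Full deterministic run: both arms plus the incremental comparison."""

    intervention: ArmResults
    comparator: ArmResults
    comparison: CEComparison
    trajectories: dict[str, CohortTrajectory]
    settings: ModelSettings

    def summary(self) -> dict:
        """JSON-serializable summary (suitable for ``write_results``)."""
        return {
            "settings": {
                "structural_variant": self.settings.structural_variant,
                "horizon_weeks": self.settings.horizon_weeks,
                "stage1_weeks": self.settings.stage1_weeks,
            },
            "intervention": self.intervention.to_dict(),
            "comparator": self.comparator.to_dict(),
            "comparison": self.comparison.to_dict(),
        }


def run_model(config: ModelConfig) -> ModelRun:
    """Run both arms through the cohort engine and compare them."""
    res_i, traj_i = run_arm(config, "intervention")
    res_c, traj_c = run_arm(config, "comparator")
    comparison = compare_arms(res_i, res_c, config.settings)
    return ModelRun(
        intervention=res_i,
        comparator=res_c,
        comparison=comparison,
        trajectories={"intervention": traj_i, "comparator": traj_c},
        settings=config.settings,
    )
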