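"""Sensitivity analyses: one-way (tornado), structural variants, and PSA.

The one-way analysis perturbs one dot-addressed scalar at a time to its low
and high bound, reruns the full deterministic model, and reports the ICERs
(dominance recorded as flags, not numbers), sorted by ICER spread.

The probabilistic sensitivity analysis samples all key parameters at once:
transition cells and utilities from beta distributions parameterized by
method of moments from their means and standard errors (rows renormalized
after sampling), costs from triangular distributions with mode at the base
value, and adverse-event durations from uniform distributions. Each draw
reruns the full model; cost-effectiveness acceptability curves use the
net-monetary-benefit rule (lambda * dQ - dC >= 0).

One master seed spawns an independent substream per draw (counter-keyed), so
any single draw is reproducible in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, UncertaintySpec, config_get, config_set
from .outcomes import PERSPECTIVES, ModelRun, run_model

__all__ = [
    "ParamRange",
    "PSAResults",
    "run_owsa",
    "run_variant",
    "sample_psa_draw",
    "run_psa",
    "beta_method_of_moments",
]


class SamplingWarning(UserWarning):
    """A sampled parameter needed adjustment (infeasible SE clipped)."""


@dataclass
class ParamRange:
    """One-way range for a dot-addressed scalar parameter."""

    path: str
    low: float
    high: float
    base: float | None = None

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.path}: low must be <= high")


def run_owsa(config: ModelConfig, ranges: list[ParamRange], perspective: str = "moh") -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    For each range the full model is rerun at the low and at the high value
    with everything else at base. Columns: parameter, low/high bound, ICER at
    each bound (NaN when dominant), dominance flags, and the absolute ICER
    spread; rows are sorted by spread descending then path (dominant
    outcomes sort first — a dominance flip is maximal impact).
    """
    base_run = run_model(config)
    rows = []
    for rng_spec in sorted(ranges, key=lambda r: r.path):
        base_value = config_get(config, rng_spec.path) if rng_spec.base is None else rng_spec.base
        if not rng_spec.low <= base_value <= rng_spec.high:
            raise ValueError(f"{rng_spec.path}: base value {base_value} outside [low, high]")
        out = {"parameter": rng_spec.path, "low": rng_spec.low, "high": rng_spec.high}
        for bound, value in (("low", rng_spec.low), ("high", rng_spec.high)):
            perturbed = config.copy()
            config_set(perturbed, rng_spec.path, value)
            run = run_model(perturbed)
            out[f"icer_{bound}"] = (
                np.nan if run.comparison.icer[perspective] is None else run.comparison.icer[perspective]
            )
            out[f"dominance_{bound}"] = run.comparison.dominance[perspective]
        if np.isnan(out["icer_low"]) or np.isnan(out["icer_high"]):
            out["spread"] = math.inf
        else:
            out["spread"] = abs(out["icer_high"] - out["icer_low"])
        rows.append(out)
    table = pd.DataFrame(rows)
    table["base_icer"] = base_run.comparison.icer[perspective]
    return table.sort_values(["spread", "parameter"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def run_variant(config: ModelConfig, variant: str) -> ModelRun:
    """Full model run under a structural variant (engine semantics)."""
    perturbed = config.copy()
    perturbed.settings.structural_variant = variant  # validated by ModelSettings on load, here by engine
    if variant not in ("base", "maintain_on_treatment", "stabilize_after_stage1"):
        raise ValueError(f"unknown structural variant {variant!r}")
    return run_model(perturbed)


def beta_method_of_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters from a mean and standard error.

    nu = m(1-m)/s^2 - 1; alpha = m*nu, beta = (1-m)*nu. Infeasible standard
    errors (s^2 >= m(1-m)) are clipped to 0.99*sqrt(m(1-m)) with a warning.
    The caller handles the point-mass cases (s = 0 or m in {0, 1}).
    """
    if not 0 < mean < 1:
        raise ValueError("mean must be strictly inside (0, 1)")
    cap = math.sqrt(mean * (1 - mean))
    if se >= cap:
        warnings.warn(
            f"beta SE {se:.4g} infeasible for mean {mean:.4g}; clipping to 0.99*sqrt(m(1-m))",
            SamplingWarning,
            stacklevel=2,
        )
        se = 0.99 * cap
    nu = mean * (1 - mean) / se**2 - 1
    return mean * nu, (1 - mean) * nu


def _sample_beta(rng: np.random.Generator, mean: float, se: float) -> float:
    if se == 0 or mean <= 0 or mean >= 1:
        return mean
    a, b = beta_method_of_moments(mean, se)
    return float(rng.beta(a, b))


def _sample_triangular(rng: np.random.Generator, base: float, low_frac: float, high_frac: float) -> float:
    low, high = base * low_frac, base * high_frac
    if low == high:
        return base
    return float(rng.triangular(low, base, high))


def sample_psa_draw(config: ModelConfig, spec: UncertaintySpec, draw_index: int, seed: int) -> ModelConfig:
    """One perturbed configuration for PSA draw ``draw_index``.

    Reproducible given (seed, draw_index): the draw's generator comes from
    the master SeedSequence spawned at key ``draw_index``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(draw_index,)))
    draw = config.copy()

    for arm in draw.arms.values():
        tm = arm.transitions
        p = np.empty_like(tm.p)
        for i in range(p.shape[0]):
            if spec.dirichlet_rows:
                # alternative sampler: Dirichlet row with concentrations from
                # the beta method-of-moments cell precisions
                alphas = []
                for j in range(p.shape[1]):
                    m, s = float(tm.p[i, j]), float(tm.se[i, j])
                    alphas.append(beta_method_of_moments(m, s)[0] if (s > 0 and 0 < m < 1) else max(m, 1e-8) * 1e6)
                p[i] = rng.dirichlet(alphas)
                continue
            sampled = False
            for j in range(p.shape[1]):
                m, s = float(tm.p[i, j]), float(tm.se[i, j])
                p[i, j] = _sample_beta(rng, m, s)
                sampled = sampled or (s > 0 and 0 < m < 1)
            if sampled:  # an all-point-mass row stays bit-identical to base
                p[i] /= p[i].sum()
        tm.p = p

    for i in range(draw.utilities.shape[0]):
        u = float(draw.utilities[i])
        draw.utilities[i] = _sample_beta(rng, u, spec.utility_se_frac * u)

    for vec in (draw.weekly_medical, draw.weekly_productivity):
        for i in range(vec.shape[0]):
            vec[i] = _sample_triangular(rng, float(vec[i]), spec.cost_low_frac, spec.cost_high_frac)
    for arm in draw.arms.values():
        arm.drug_daily = _sample_triangular(rng, arm.drug_daily, spec.cost_low_frac, spec.cost_high_frac)

    for ae in draw.aes:
        low = ae.duration_weeks * spec.ae_duration_low_frac
        high = ae.duration_weeks * spec.ae_duration_high_frac
        if low < high:
            ae.duration_weeks = float(rng.uniform(low, high))

    return draw


@dataclass
class PSAResults:
    """Draw-level incremental outcomes and derived acceptability curves."""

    draws: pd.DataFrame  # columns: draw, inc_qaly, inc_cost_moh, inc_cost_societal
    wtp_grid: tuple[float, ...]
    wtp_threshold: float

    def ceac(self) -> pd.DataFrame:
        """CEAC points: P(net monetary benefit >= 0) per lambda, per perspective."""
        dq = self.draws["inc_qaly"].to_numpy()
        rows = []
        for lam in self.wtp_grid:
            row = {"wtp": lam}
            for p in PERSPECTIVES:
                dc = self.draws[f"inc_cost_{p}"].to_numpy()
                row[f"prob_{p}"] = float((lam * dq - dc >= 0).mean())
            rows.append(row)
        return pd.DataFrame(rows)

    def probability_cost_effective(self, wtp: float | None = None) -> dict[str, float]:
        lam = self.wtp_threshold if wtp is None else wtp
        dq = self.draws["inc_qaly"].to_numpy()
        return {
            p: float((lam * dq - self.draws[f"inc_cost_{p}"].to_numpy() >= 0).mean())
            for p in PERSPECTIVES
        }


def run_psa(config: ModelConfig, spec: UncertaintySpec | None = None, seed: int = 0) -> PSAResults:
    """Probabilistic sensitivity analysis: rerun the model on each draw."""
    spec = config.uncertainty if spec is None else spec
    records = []
    for d in range(spec.n_sims):
        draw = sample_psa_draw(config, spec, d, seed)
        run = run_model(draw)
        records.append(
            {
                "draw": d,
                "inc_qaly": run.comparison.incremental_qaly,
                "inc_cost_moh": run.comparison.incremental_cost["moh"],
                "inc_cost_societal": run.comparison.incremental_cost["societal"],
            }
        )
    return PSAResults(
        draws=pd.DataFrame.from_records(records),
        wtp_grid=spec.wtp_grid,
        wtp_threshold=config.settings.wtp_threshold,
    )
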