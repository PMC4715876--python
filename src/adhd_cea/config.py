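"""Model configuration: schema, validation, loading and result output.

A model configuration is a single YAML file with sections

``settings, initial_distribution, utilities, costs, arms, aes, uncertainty``

plus optional ``drug_market`` and ``cost_allocation`` sections consumed by
the severity-costing helpers. The packaged base-case fixture
(``adhd_cea/data/base_case.yaml``) carries the published model inputs:
the trial's initial CGI-S distribution, per-state utilities, weekly medical
and productivity costs, daily drug costs and the two weekly transition
matrices with standard errors.

Transition rows are proportionally renormalized at load time when the raw
row sum deviates from 1 (the published combined-GXR Severe row sums to
0.911); any deviation beyond 0.01 is reported through a ``ConfigWarning``,
never silently, and the raw matrix is retained for provenance.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .states import N_STATES, STATE_NAMES, state_index

__all__ = [
    "ConfigError",
    "ConfigSchemaError",
    "ConfigValidationError",
    "ConfigWarning",
    "TransitionMatrix",
    "ArmSpec",
    "AdverseEvent",
    "ModelSettings",
    "UncertaintySpec",
    "ModelConfig",
    "load_config",
    "load_base_case",
    "base_case_path",
    "write_results",
    "config_get",
    "config_set",
]

ROW_SUM_WARN_THRESHOLD = 0.01

ARM_KEYS = ("intervention", "comparator")

VARIANTS = ("base", "maintain_on_treatment", "stabilize_after_stage1")


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigSchemaError(ConfigError):
    """A required section or key is missing or of the wrong shape."""


class ConfigValidationError(ConfigError):
    """A value violates a type invariant (range, sign, ordering)."""


class ConfigWarning(UserWarning):
    """Non-fatal configuration issue (renormalization, monotonicity)."""


def _as_state_vector(mapping: dict[str, float], section: str) -> np.ndarray:
    vec = np.zeros(N_STATES)
    seen = set()
    for name, value in mapping.items():
        idx = state_index(name)
        vec[idx] = float(value)
        seen.add(idx)
    missing = [STATE_NAMES[i] for i in range(N_STATES) if i not in seen]
    if missing:
        raise ConfigSchemaError(f"section {section!r} is missing states {missing}")
    return vec


@dataclass
class TransitionMatrix:
    """Weekly 4x4 transition matrix with per-cell standard errors.

    ``p`` holds the row-renormalized probabilities actually used by the
    engine; ``raw`` retains the probabilities as loaded.
    """

    p: np.ndarray
    se: np.ndarray
    raw: np.ndarray

    @classmethod
    def from_values(
        cls,
        p: Sequence[Sequence[float]],
        se: Sequence[Sequence[float]] | None = None,
        *,
        renormalize: bool = True,
        label: str = "",
    ) -> "TransitionMatrix":
        raw = np.asarray(p, dtype=float)
        if raw.shape != (N_STATES, N_STATES):
            raise ConfigSchemaError(f"transition matrix {label!r} must be {N_STATES}x{N_STATES}, got {raw.shape}")
        if np.any(raw < 0) or np.any(raw > 1):
            raise ConfigValidationError(f"transition matrix {label!r} has probabilities outside [0,1]")
        se_arr = np.zeros_like(raw) if se is None else np.asarray(se, dtype=float)
        if se_arr.shape != raw.shape:
            raise ConfigSchemaError(f"transition SE matrix {label!r} must match the probability matrix shape")
        if np.any(se_arr < 0):
            raise ConfigValidationError(f"transition SE matrix {label!r} has negative entries")
        row_sums = raw.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ConfigValidationError(f"transition matrix {label!r} has a zero row")
        bad = np.abs(row_sums - 1.0) > ROW_SUM_WARN_THRESHOLD
        if renormalize:
            if np.any(bad):
                rows = ", ".join(
                    f"{STATE_NAMES[i]} (sum {row_sums[i]:.3f})" for i in np.flatnonzero(bad)
                )
                warnings.warn(
                    f"transition matrix {label!r}: renormalizing rows deviating from 1: {rows}",
                    ConfigWarning,
                    stacklevel=2,
                )
            p_norm = raw / row_sums[:, None]
        else:
            p_norm = raw.copy()
        return cls(p=p_norm, se=se_arr, raw=raw)

    def to_dict(self) -> dict[str, Any]:
        return {"p": self.raw.tolist(), "se": self.se.tolist()}


@dataclass
class ArmSpec:
    """One comparator arm: label, daily drug cost and weekly transition matrix."""

    name: str
    drug_daily: float
    transitions: TransitionMatrix

    def __post_init__(self) -> None:
        if self.drug_daily < 0:
            raise ConfigValidationError(f"arm {self.name!r}: daily drug cost must be non-negative")


@dataclass
class AdverseEvent:
    """Treatment-emergent adverse event applying a transient utility decrement.

    The decrement is a one-time expected deduction per patient:
    incidence x disutility x duration_weeks / 52.
    """

    name: str
    incidence: dict[str, float]
    disutility: float
    duration_weeks: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.disutility <= 1:
            raise ConfigValidationError(f"AE {self.name!r}: disutility must be in [0,1]")
        if self.duration_weeks <= 0:
            raise ConfigValidationError(f"AE {self.name!r}: duration_weeks must be positive")
        for arm, inc in self.incidence.items():
            if not 0 <= inc <= 1:
                raise ConfigValidationError(f"AE {self.name!r}: incidence for arm {arm!r} must be in [0,1]")


@dataclass
class ModelSettings:
    """Global model settings: horizon, stage boundary, response set, variant."""

    horizon_weeks: int = 52
    stage1_weeks: int = 8
    response_states: tuple[int, ...] = (0, 1)
    structural_variant: str = "base"
    wtp_threshold: float = 50_000.0
    renormalize_rows: bool = True
    # charge drug for the cycle during which a patient transitions into an
    # absorbing state (they took drug that week); False stops one week earlier
    drug_charge_final_week: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.stage1_weeks <= self.horizon_weeks:
            raise ConfigValidationError("require 0 < stage1_weeks <= horizon_weeks")
        if not self.response_states:
            raise ConfigValidationError("response_states must be non-empty")
        if self.structural_variant not in VARIANTS:
            raise ConfigValidationError(
                f"unknown structural_variant {self.structural_variant!r}; expected one of {VARIANTS}"
            )
        self.response_states = tuple(
            state_index(s) if isinstance(s, str) else int(s) for s in self.response_states
        )


@dataclass
class UncertaintySpec:
    """Distribution assumptions for the probabilistic sensitivity analysis.

    Beta (method of moments) for probabilities and utilities, triangular for
    costs (mode at base, bounds as fractions of base) and uniform for AE
    durations. Utility standard errors default to 10% of the mean when the
    configuration does not supply them.
    """

    n_sims: int = 10_000
    utility_se_frac: float = 0.10
    cost_low_frac: float = 0.75
    cost_high_frac: float = 1.25
    ae_duration_low_frac: float = 0.5
    ae_duration_high_frac: float = 1.5
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 105_000, 5_000))
    dirichlet_rows: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigValidationError("n_sims must be >= 1")
        grid = tuple(float(x) for x in self.wtp_grid)
        if any(x < 0 for x in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigValidationError("wtp_grid must be non-negative and strictly increasing")
        self.wtp_grid = grid


@dataclass
class ModelConfig:
    """Validated model configuration (everything a run needs)."""

    settings: ModelSettings
    initial_distribution: np.ndarray
    utilities: np.ndarray
    weekly_medical: np.ndarray
    weekly_productivity: np.ndarray
    arms: dict[str, ArmSpec]
    aes: list[AdverseEvent] = field(default_factory=list)
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    drug_market: dict[str, dict[str, float]] | None = None
    cost_allocation: dict[str, float] | None = None

    @property
    def intervention(self) -> ArmSpec:
        return self.arms["intervention"]

    @property
    def comparator(self) -> ArmSpec:
        return self.arms["comparator"]

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


def _validate_distribution(raw: np.ndarray) -> np.ndarray:
    if np.any(raw < 0) or np.any(raw > 1):
        raise ConfigValidationError("initial_distribution entries must be in [0,1]")
    total = raw.sum()
    if total <= 0:
        raise ConfigValidationError("initial_distribution must have positive mass")
    if abs(total - 1.0) > ROW_SUM_WARN_THRESHOLD:
        warnings.warn(
            f"initial_distribution sums to {total:.4f}; renormalizing", ConfigWarning, stacklevel=2
        )
    return raw / total


def _validate_utilities(u: np.ndarray) -> np.ndarray:
    if np.any(u < 0) or np.any(u > 1):
        raise ConfigValidationError("utilities must be in [0,1]")
    if np.any(np.diff(u) > 0):
        warnings.warn(
            "utilities are not monotone non-increasing with severity", ConfigWarning, stacklevel=2
        )
    return u


def _require(doc: dict, section: str) -> Any:
    if section not in doc or doc[section] is None:
        raise ConfigSchemaError(f"missing required section {section!r}")
    return doc[section]


def from_dict(doc: dict[str, Any]) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed mapping."""
    if not isinstance(doc, dict):
        raise ConfigSchemaError("configuration root must be a mapping")

    settings = ModelSettings(**(doc.get("settings") or {}))

    init = _validate_distribution(_as_state_vector(_require(doc, "initial_distribution"), "initial_distribution"))
    utilities = _validate_utilities(_as_state_vector(_require(doc, "utilities"), "utilities"))

    costs = _require(doc, "costs")
    medical = _as_state_vector(_require(costs, "weekly_medical"), "costs.weekly_medical")
    productivity = _as_state_vector(_require(costs, "weekly_productivity"), "costs.weekly_productivity")
    if np.any(medical < 0) or np.any(productivity < 0):
        raise ConfigValidationError("weekly costs must be non-negative")

    arms_doc = _require(doc, "arms")
    arms: dict[str, ArmSpec] = {}
    for key in ARM_KEYS:
        if key not in arms_doc:
            raise ConfigSchemaError(f"missing required section 'arms.{key}'")
        arm_doc = arms_doc[key]
        trans_doc = _require(arm_doc, "transitions")
        tm = TransitionMatrix.from_values(
            _require(trans_doc, "p"),
            trans_doc.get("se"),
            renormalize=settings.renormalize_rows,
            label=key,
        )
        arms[key] = ArmSpec(
            name=str(arm_doc.get("name", key)),
            drug_daily=float(_require(arm_doc, "drug_daily")),
            transitions=tm,
        )

    aes = [
        AdverseEvent(
            name=str(ae["name"]),
            incidence={k: float(v) for k, v in (ae.get("incidence") or {}).items()},
            disutility=float(ae["disutility"]),
            duration_weeks=float(ae.get("duration_weeks", 4)),
        )
        for ae in (doc.get("aes") or [])
    ]

    uncertainty = UncertaintySpec(**(doc.get("uncertainty") or {}))

    return ModelConfig(
        settings=settings,
        initial_distribution=init,
        utilities=utilities,
        weekly_medical=medical,
        weekly_productivity=productivity,
        arms=arms,
        aes=aes,
        uncertainty=uncertainty,
        drug_market=doc.get("drug_market"),
        cost_allocation=doc.get("cost_allocation"),
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return from_dict(doc)


def base_case_path() -> Path:
    """Path of the packaged base-case configuration fixture."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def load_base_case() -> ModelConfig:
    """Load the packaged base-case configuration (published model inputs)."""
    return load_config(base_case_path())


def to_dict(config: ModelConfig) -> dict[str, Any]:
    """Serialize a configuration back to a plain mapping (raw matrices kept)."""
    state_map = lambda v: {STATE_NAMES[i]: float(v[i]) for i in range(N_STATES)}  # noqa: E731
    out: dict[str, Any] = {
        "settings": {
            "horizon_weeks": config.settings.horizon_weeks,
            "stage1_weeks": config.settings.stage1_weeks,
            "response_states": [STATE_NAMES[i] for i in config.settings.response_states],
            "structural_variant": config.settings.structural_variant,
            "wtp_threshold": config.settings.wtp_threshold,
            "renormalize_rows": config.settings.renormalize_rows,
            "drug_charge_final_week": config.settings.drug_charge_final_week,
        },
        "initial_distribution": state_map(config.initial_distribution),
        "utilities": state_map(config.utilities),
        "costs": {
            "weekly_medical": state_map(config.weekly_medical),
            "weekly_productivity": state_map(config.weekly_productivity),
        },
        "arms": {
            key: {
                "name": arm.name,
                "drug_daily": arm.drug_daily,
                "transitions": arm.transitions.to_dict(),
            }
            for key, arm in config.arms.items()
        },
        "aes": [dataclasses.asdict(ae) for ae in config.aes],
        "uncertainty": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.uncertainty).items()
        },
    }
    if config.drug_market is not None:
        out["drug_market"] = config.drug_market
    if config.cost_allocation is not None:
        out["cost_allocation"] = config.cost_allocation
    return out


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dot-addressed parameter paths (used by the one-way sensitivity analysis)
# ---------------------------------------------------------------------------


def _resolve(config: ModelConfig, path: str):
    """Return (getter, setter) closures for a dot-addressed scalar path."""
    parts = path.split(".")
    try:
        head = parts[0]
        if head == "utilities" and len(parts) == 2:
            i = state_index(parts[1])
            return (lambda: config.utilities[i], lambda v: config.utilities.__setitem__(i, v))
        if head == "initial_distribution" and len(parts) == 2:
            i = state_index(parts[1])

            def set_init(v: float) -> None:
                config.initial_distribution[i] = v
                config.initial_distribution /= config.initial_distribution.sum()

            return (lambda: config.initial_distribution[i], set_init)
        if head == "costs" and len(parts) == 3:
            vec = {"weekly_medical": config.weekly_medical, "weekly_productivity": config.weekly_productivity}[parts[1]]
            i = state_index(parts[2])
            return (lambda: vec[i], lambda v: vec.__setitem__(i, v))
        if head == "arms" and len(parts) >= 3:
            arm = config.arms[parts[1]]
            if parts[2] == "drug_daily" and len(parts) == 3:
                return (lambda: arm.drug_daily, lambda v: setattr(arm, "drug_daily", v))
            if parts[2] == "transitions" and len(parts) == 5:
                i, j = state_index(parts[3]), state_index(parts[4])
                P = arm.transitions.p

                def set_cell(v: float) -> None:
                    P[i, j] = v
                    P[i] /= P[i].sum()

                return (lambda: P[i, j], set_cell)
        if head == "aes" and len(parts) == 3:
            ae = next((a for a in config.aes if a.name == parts[1]), None)
            if ae is not None and hasattr(ae, parts[2]):
                attr = parts[2]
                return (lambda: getattr(ae, attr), lambda v: setattr(ae, attr, v))
        if head == "settings" and len(parts) == 2 and hasattr(config.settings, parts[1]):
            attr = parts[1]
            return (lambda: getattr(config.settings, attr), lambda v: setattr(config.settings, attr, v))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"cannot resolve parameter path {path!r}: {exc}") from exc
    raise ConfigError(f"cannot resolve parameter path {path!r}")


def config_get(config: ModelConfig, path: str) -> float:
    """Read a scalar parameter by dot-addressed path."""
    getter, _ = _resolve(config, path)
    return float(getter())


def config_set(config: ModelConfig, path: str, value: float) -> None:
    """Set a scalar parameter by dot-addressed path (in place).

    Probability-simplex parameters (initial-distribution entries, transition
    cells) are renormalized after the assignment so the simplex constraint
    holds.
    """
    _, setter = _resolve(config, path)
    setter(float(value))


# ---------------------------------------------------------------------------
# results output
# ---------------------------------------------------------------------------


def write_results(results: dict[str, Any], destination: str | Path, format: str = "summary") -> Path:
    """Write computed results to ``destination``.

    ``summary`` writes a JSON document preserving full precision (round-trips
    to 1e-9); ``table`` writes a flat two-column delimited table. ICER and
    NNT sentinels ("undefined", "dominant", "inf") are written as strings.
    """
    destination = Path(destination)
    if format == "summary":
        with open(destination, "w") as fh:
            json.dump(results, fh, indent=2, default=_json_default)
            fh.write("\n")
    elif format == "table":
        flat = _flatten(results)
        with open(destination, "w") as fh:
            fh.write("field,value\n")
            for k, v in flat.items():
                fh.write(f"{k},{v}\n")
    else:
        raise ValueError(f"unknown output format {format!r}")
    return destination


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _flatten(d: dict[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
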