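"""Model inputs for the NSCLC biomarker cost-effectiveness model.

Everything the downstream pipeline consumes lives in a single validated
:class:`ParameterSet`: response rates per PD-L1 stratum, 12-month survival
anchors per treatment arm, utilities and side-effect profiles, unit costs,
discount rates, background mortality and biomarker test performance.
Configurations are read from YAML or JSON; the schema is the package's own
and is versioned via ``schema_version``.

The module also implements the three small pieces of response-rate
arithmetic the model is built on:

* ``conditional_response_to_comparator`` — among responders to the
  combination arm, the fraction that would also respond to the comparator
  arm (the nested-responder assumption: comparator responders are a subset
  of combination responders).
* ``hr_to_response_rate`` — converts a comparator response rate and a
  progression-free-survival hazard ratio into a combination-arm response
  rate by risk scaling (the nonresponse risk is divided by the HR).
* ``nonresponder_crossover_rate`` — among nonresponders to the mono arm,
  the fraction rescued by the combination arm.

"Response" throughout means being progression-free at 12 months.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError as PydanticValidationError,
    model_validator,
)

__all__ = [
    "ConfigurationError",
    "RateDerivationError",
    "PDL1Group",
    "RegimenName",
    "DerivationMode",
    "SideEffect",
    "DurationRule",
    "Regimen",
    "ResponseModel",
    "TestPerformance",
    "ArmSurvival",
    "SurvivalInputs",
    "EconomicInputs",
    "BackgroundMortality",
    "ParameterSet",
    "conditional_response_to_comparator",
    "hr_to_response_rate",
    "nonresponder_crossover_rate",
    "load_parameters",
    "parameters_from_dict",
    "save_parameters",
]

SCHEMA_VERSION = 1

Probability = Annotated[float, Field(ge=0.0, le=1.0)]
NonNegFloat = Annotated[float, Field(ge=0.0)]


class ConfigurationError(ValueError):
    """A configuration file or parameter bundle is malformed or inconsistent."""


class RateDerivationError(ValueError):
    """A derived response rate is undefined for the given inputs."""


class PDL1Group(str, enum.Enum):
    """PD-L1 tumor-proportion-score stratum (<1%, 1-49%, >=50%)."""

    LT1 = "LT1"
    PD1_49 = "PD1_49"
    GE50 = "GE50"


class RegimenName(str, enum.Enum):
    CHEMO = "CHEMO"
    IMMUNO = "IMMUNO"
    IMMUNOCHEMO = "IMMUNOCHEMO"


class DerivationMode(str, enum.Enum):
    """How the combination-arm response rate is obtained.

    RATIO: both arm rates are direct inputs (trial-reported).
    HR_RISK_SCALING: the combination rate is derived from the mono rate by
        dividing the nonresponse risk by the PFS hazard ratio,
        r_combo = 1 - (1 - r_mono) / HR.
    HR_HAZARD_POWER: exploratory alternative treating nonresponse as a
        survival fraction, r_combo = 1 - (1 - r_mono)^(1/HR) ... provided
        for comparison only; risk scaling is the model's convention.
    """

    RATIO = "RATIO"
    HR_RISK_SCALING = "HR_RISK_SCALING"
    HR_HAZARD_POWER = "HR_HAZARD_POWER"


# ---------------------------------------------------------------------------
# derived-rate arithmetic


def conditional_response_to_comparator(r_combo: float, r_mono: float) -> float:
    """P(respond to comparator | respond to combination) = r_mono / r_combo.

    Valid under the nested-responder assumption: every comparator responder
    is also a combination responder, so the joint probability of responding
    to both arms equals ``r_mono``.
    """
    if not 0.0 < r_combo <= 1.0:
        raise RateDerivationError(
            f"combination response rate must be in (0, 1], got {r_combo}"
        )
    if not 0.0 <= r_mono <= 1.0:
        raise RateDerivationError(f"comparator response rate must be in [0, 1], got {r_mono}")
    if r_mono > r_combo:
        raise RateDerivationError(
            "nesting violation: comparator response rate "
            f"{r_mono} exceeds combination response rate {r_combo}"
        )
    return r_mono / r_combo


def hr_to_response_rate(r_base: float, hr: float) -> float:
    """Convert a base response rate and a PFS hazard ratio into the improved
    arm's response rate by risk scaling: the nonresponse risk is divided by
    the hazard ratio, ``1 - (1 - r_base) / hr``, clipped to [0, 1].
    """
    if hr <= 0.0:
        raise RateDerivationError(f"hazard ratio must be positive, got {hr}")
    if not 0.0 <= r_base <= 1.0:
        raise RateDerivationError(f"base response rate must be in [0, 1], got {r_base}")
    return min(1.0, max(0.0, 1.0 - (1.0 - r_base) / hr))


def nonresponder_crossover_rate(r_combo: float, r_mono: float) -> float:
    """Among mono-arm nonresponders, the fraction that responds to the
    combination arm: ``1 - (1 - r_combo) / (1 - r_mono)``.

    Follows from the nested-responder assumption applied in the other
    direction: combination nonresponders are a subset of mono nonresponders.
    """
    if not 0.0 <= r_mono < 1.0:
        raise RateDerivationError(
            f"mono response rate must be in [0, 1) (no nonresponders otherwise), got {r_mono}"
        )
    if r_combo < r_mono:
        raise RateDerivationError(
            f"nesting violation: combination rate {r_combo} below mono rate {r_mono}"
        )
    if r_combo > 1.0:
        raise RateDerivationError(f"combination response rate must be <= 1, got {r_combo}")
    return 1.0 - (1.0 - r_combo) / (1.0 - r_mono)


# ---------------------------------------------------------------------------
# domain types


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SideEffect(_Model):
    """A treatment side effect with prevalence, utility decrement and
    one-time management cost. Disutilities and costs are aggregated
    prevalence-weighted across a regimen's side-effect list."""

    name: str
    prevalence: Probability
    disutility: NonNegFloat
    treatment_cost: NonNegFloat


class DurationRule(_Model):
    """When medication cost stops accruing.

    UNTIL_PROGRESSION: drug cost accrues every cycle spent progression-free.
    FIXED_MONTHS: drug cost accrues for at most ``months`` cycles.
    """

    kind: Literal["UNTIL_PROGRESSION", "FIXED_MONTHS"] = "UNTIL_PROGRESSION"
    months: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_months(self) -> "DurationRule":
        if self.kind == "FIXED_MONTHS" and self.months is None:
            raise ValueError("FIXED_MONTHS duration rule requires 'months'")
        if self.kind == "UNTIL_PROGRESSION" and self.months is not None:
            raise ValueError("UNTIL_PROGRESSION duration rule takes no 'months'")
        return self


class Regimen(_Model):
    med_cost_per_cycle: NonNegFloat
    side_effects: list[SideEffect] = Field(default_factory=list)
    duration_rule: DurationRule = Field(default_factory=DurationRule)


class ResponseModel(_Model):
    """Response rates for the stratum's combination and comparator arms.

    ``r_combo`` is the probability of response (12-month PFS) on the
    combination arm (immunochemotherapy); ``r_mono`` on the comparator arm
    (chemotherapy alone for the <1% and 1-49% strata, immunotherapy alone
    for the >=50% stratum). Under HR-based derivation modes ``r_combo`` is
    computed from ``r_mono`` and ``hr`` rather than given directly.
    """

    r_mono: Probability
    r_combo: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    hr: Optional[float] = Field(default=None, gt=0.0)
    derivation_mode: DerivationMode = DerivationMode.RATIO

    @model_validator(mode="after")
    def _check(self) -> "ResponseModel":
        if self.derivation_mode == DerivationMode.RATIO:
            if self.r_combo is None:
                raise ValueError("RATIO derivation requires r_combo")
        else:
            if self.hr is None:
                raise ValueError(f"{self.derivation_mode.value} derivation requires hr")
        if self.r_mono > self.r_combo_effective + 1e-12:
            raise ValueError(
                "nested-responder assumption violated: "
                f"r_mono={self.r_mono} > r_combo={self.r_combo_effective:.6f}"
            )
        return self

    @property
    def r_combo_effective(self) -> float:
        """Combination-arm response rate, derived if an HR mode is active."""
        if self.derivation_mode == DerivationMode.RATIO:
            assert self.r_combo is not None
            return self.r_combo
        if self.derivation_mode == DerivationMode.HR_RISK_SCALING:
            return hr_to_response_rate(self.r_mono, self.hr)
        # HR_HAZARD_POWER: treat nonresponse as a survival fraction
        return min(1.0, max(0.0, 1.0 - (1.0 - self.r_mono) ** (1.0 / self.hr)))

    @property
    def conditional_comparator_response(self) -> float:
        """P(respond to comparator | respond to combination)."""
        return conditional_response_to_comparator(self.r_combo_effective, self.r_mono)

    @property
    def crossover_rate(self) -> float:
        """P(respond to combination | no response to mono arm)."""
        return nonresponder_crossover_rate(self.r_combo_effective, self.r_mono)


class TestPerformance(_Model):
    sensitivity: Probability = 1.0
    specificity: Probability = 1.0
    test_cost: NonNegFloat = 0.0


class ArmSurvival(_Model):
    """Survival anchors for one treatment arm.

    ``pfs12``/``os12`` are the arm's progression-free and overall survival
    fractions at 12 months; their difference drives the death/progression
    split of nonresponders. ``pfs_anchors`` are (month, survival-fraction)
    points on the progression-free decline of responders, used for
    exponential extrapolation.
    """

    pfs12: Probability
    os12: Probability
    pfs_anchors: list[tuple[float, float]] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "ArmSurvival":
        if self.os12 < self.pfs12:
            raise ValueError(f"os12={self.os12} must be >= pfs12={self.pfs12}")
        prev_t, prev_s = 0.0, math.inf
        for t, s in self.pfs_anchors:
            if t <= prev_t:
                raise ValueError("anchor months must be strictly increasing and positive")
            if not 0.0 < s <= 1.0:
                raise ValueError(f"anchor survival must be in (0, 1], got {s}")
            if s > prev_s:
                raise ValueError("anchor survival must be nonincreasing in time")
            prev_t, prev_s = t, s
        return self


class SurvivalInputs(_Model):
    arms: dict[RegimenName, ArmSurvival]
    mean_time_to_progression_nonresp: float = Field(default=9.0, gt=0.0, lt=12.0)
    mean_post_progression_survival: float = Field(default=5.4, gt=0.0)
    responder_progression_mode: Literal["fitted", "delayed12"] = "fitted"


class EconomicInputs(_Model):
    u_response: Probability
    u_progression: Probability
    state_cost_response: NonNegFloat
    state_cost_progression: NonNegFloat
    biopsy_cost: NonNegFloat
    pdl1_test_cost: NonNegFloat
    discontinuation_cost: NonNegFloat
    terminal_care_cost: NonNegFloat
    discount_rate_health: float = Field(default=0.015, ge=0.0, lt=1.0)
    discount_rate_cost: float = Field(default=0.04, ge=0.0, lt=1.0)
    wtp_wta_threshold: NonNegFloat = 80_000.0
    horizon_cycles: int = Field(default=60, ge=1)
    terminal_care_on_other_cause: bool = True
    half_cycle_correction: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EconomicInputs":
        if self.u_progression > self.u_response:
            raise ValueError(
                f"u_progression={self.u_progression} must not exceed u_response={self.u_response}"
            )
        return self


class BackgroundMortality(_Model):
    """Other-cause (non-disease) mortality per monthly cycle; a scalar or an
    explicit per-cycle schedule (e.g. derived from a national life table)."""

    monthly_other_cause_death: Union[Probability, list[Probability]] = 0.0

    def schedule(self, horizon: int) -> list[float]:
        q = self.monthly_other_cause_death
        if isinstance(q, float) or isinstance(q, int):
            return [float(q)] * horizon
        if len(q) < horizon:
            raise ConfigurationError(
                f"background-mortality schedule has {len(q)} cycles, horizon needs {horizon}"
            )
        return [float(v) for v in q[:horizon]]


class ParameterSet(_Model):
    """The full, validated input bundle for one PD-L1 stratum."""

    schema_version: int = SCHEMA_VERSION
    group: PDL1Group
    regimens: dict[RegimenName, Regimen]
    response: ResponseModel
    survival: SurvivalInputs
    economics: EconomicInputs
    mortality: BackgroundMortality = Field(default_factory=BackgroundMortality)
    test: TestPerformance = Field(default_factory=TestPerformance)

    @model_validator(mode="after")
    def _check_regimens(self) -> "ParameterSet":
        missing = [r.value for r in required_regimens(self.group) if r not in self.regimens]
        if missing:
            raise ValueError(f"group {self.group.value} requires regimens {missing}")
        missing_arms = [
            r.value for r in required_regimens(self.group) if r not in self.survival.arms
        ]
        if missing_arms:
            raise ValueError(f"group {self.group.value} requires survival arms {missing_arms}")
        return self

    def to_config_dict(self) -> dict:
        """Plain-type dict suitable for YAML/JSON serialization."""
        return self.model_dump(mode="json")


def required_regimens(group: PDL1Group) -> tuple[RegimenName, ...]:
    """Regimens referenced by the group's two strategies: the combination
    arm plus the group's comparator arm."""
    if group == PDL1Group.GE50:
        return (RegimenName.IMMUNO, RegimenName.IMMUNOCHEMO)
    return (RegimenName.CHEMO, RegimenName.IMMUNOCHEMO)


def comparator_regimen(group: PDL1Group) -> RegimenName:
    """The mono arm: chemotherapy for <1% and 1-49%, immunotherapy for >=50%."""
    return RegimenName.IMMUNO if group == PDL1Group.GE50 else RegimenName.CHEMO


# ---------------------------------------------------------------------------
# loading / saving


def _format_pydantic_error(exc: PydanticValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def parameters_from_dict(data: dict) -> ParameterSet:
    """Validate a plain dict into a :class:`ParameterSet`.

    Raises :class:`ConfigurationError` with dotted field paths on failure.
    """
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema_version {version}; this package reads version {SCHEMA_VERSION}"
        )
    try:
        return ParameterSet.model_validate(data)
    except PydanticValidationError as exc:
        raise ConfigurationError(_format_pydantic_error(exc)) from exc


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Read and validate a YAML or JSON configuration file."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return parameters_from_dict(data)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet back to YAML or JSON (by file extension)."""
    path = Path(path)
    data = params.to_config_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
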