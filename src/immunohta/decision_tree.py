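"""Decision trees routing a PD-L1 stratum through a treatment strategy.

Each stratum is compared between two strategies:

* **Current practice** — guideline treatment by PD-L1 status alone:
  immunochemotherapy for the <1% and 1-49% strata, immunotherapy alone for
  the >=50% stratum.
* **Biomarker** — a predictive test for immunotherapy response decides the
  regimen. For the <1% and 1-49% strata a positive test keeps the patient
  on immunochemotherapy and a negative test de-escalates to chemotherapy
  alone. For the >=50% stratum a positive test keeps immunotherapy alone
  and a negative test escalates to immunochemotherapy.

The tree's reference "responder" status is defined against the arm the test
is meant to predict: response to immunochemotherapy for the <1%/1-49%
strata and response to immunotherapy alone for the >=50% stratum. Test
sensitivity applies among reference responders and specificity among
reference nonresponders; patients routed to a different arm than the
reference carry their conditional response probability under the
nested-responder assumption. The output is the cohort's starting mass over
(assigned regimen, actual responder status) cells, plus the one-time costs
incurred at the tree stage (biopsy, PD-L1 determination and, in the
biomarker strategy, the biomarker test itself).
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field

from .parameters import (
    ConfigurationError,
    ParameterSet,
    PDL1Group,
    RegimenName,
    comparator_regimen,
)

__all__ = [
    "StrategyName",
    "StrategyDefinition",
    "CellKey",
    "InitialDistribution",
    "initial_distribution",
    "overall_response_rate",
]

_MASS_TOL = 1e-12


class StrategyName(str, enum.Enum):
    CURRENT_PRACTICE = "CURRENT_PRACTICE"
    BIOMARKER = "BIOMARKER"


@dataclass(frozen=True)
class StrategyDefinition:
    """A named strategy for one stratum, with its branch map.

    ``branch_map`` keys are ``"unconditional"`` for current practice and
    ``"positive"``/``"negative"`` for the biomarker strategy.
    """

    name: StrategyName
    group: PDL1Group
    branch_map: dict = field(compare=False)

    @staticmethod
    def standard(name: StrategyName | str, group: PDL1Group) -> "StrategyDefinition":
        name = StrategyName(name)
        combo = RegimenName.IMMUNOCHEMO
        mono = comparator_regimen(group)
        if name == StrategyName.CURRENT_PRACTICE:
            # guideline arm: combo below 50% expression, mono at/above
            default = mono if group == PDL1Group.GE50 else combo
            branch_map = {"unconditional": default}
        elif group == PDL1Group.GE50:
            branch_map = {"positive": mono, "negative": combo}
        else:
            branch_map = {"positive": combo, "negative": mono}
        return StrategyDefinition(name=name, group=group, branch_map=branch_map)


@dataclass(frozen=True)
class CellKey:
    """One leaf of the tree: the assigned regimen and whether the patient
    actually responds to it."""

    regimen: RegimenName
    responder: bool


@dataclass
class InitialDistribution:
    """Cohort mass over (regimen, responder) cells at Markov cycle 0."""

    group: PDL1Group
    strategy: StrategyName
    cells: dict[CellKey, float]
    tree_stage_cost: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.cells.values())
        if any(m < -_MASS_TOL for m in self.cells.values()):
            raise ValueError("cell masses must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell masses must sum to 1, got {total}")

    def mass(self, regimen: RegimenName, responder: bool) -> float:
        return self.cells.get(CellKey(regimen, responder), 0.0)


def initial_distribution(
    params: ParameterSet, strategy: StrategyDefinition
) -> InitialDistribution:
    """Route the cohort through the decision tree of ``strategy``.

    Enumerates (reference responder status) x (test result) branches,
    assigns the branch regimen, and resolves the patient's actual response
    on that regimen via the nested-responder arithmetic.
    """
    if strategy.group != params.group:
        raise ConfigurationError(
            f"strategy group {strategy.group.value} does not match "
            f"parameter group {params.group.value}"
        )
    resp = params.response
    se, sp = params.test.sensitivity, params.test.specificity
    combo = RegimenName.IMMUNOCHEMO
    mono = comparator_regimen(params.group)
    for reg in (combo, mono):
        if reg not in params.regimens:
            raise ConfigurationError(f"regimen {reg.value} missing from parameter set")

    cells: dict[CellKey, float] = defaultdict(float)

    def add(regimen: RegimenName, p_respond: float, mass: float) -> None:
        if mass <= 0.0:
            return
        cells[CellKey(regimen, True)] += mass * p_respond
        cells[CellKey(regimen, False)] += mass * (1.0 - p_respond)

    r_combo = resp.r_combo_effective
    r_mono = resp.r_mono

    if params.group == PDL1Group.GE50:
        # reference status: response to immunotherapy alone (prevalence r_mono)
        prev = r_mono
        if strategy.name == StrategyName.CURRENT_PRACTICE:
            add(mono, 1.0, prev)
            add(mono, 0.0, 1.0 - prev)
        else:
            # IO responders: positive -> stay on mono; negative -> combo,
            # where they respond with certainty (nesting)
            add(mono, 1.0, prev * se)
            add(combo, 1.0, prev * (1.0 - se))
            # IO nonresponders: negative -> combo rescues a fraction;
            # positive (false positive) -> mono, never respond
            add(combo, resp.crossover_rate, (1.0 - prev) * sp)
            add(mono, 0.0, (1.0 - prev) * (1.0 - sp))
    else:
        # reference status: response to immunochemotherapy (prevalence r_combo)
        prev = r_combo
        if strategy.name == StrategyName.CURRENT_PRACTICE:
            add(combo, 1.0, prev)
            add(combo, 0.0, 1.0 - prev)
        else:
            cond = resp.conditional_comparator_response
            # combo responders: positive -> combo; negative (false negative)
            # -> chemo, respond with the conditional probability
            add(combo, 1.0, prev * se)
            add(mono, cond, prev * (1.0 - se))
            # combo nonresponders: negative -> chemo, never respond
            # (nesting); positive (false positive) -> combo, never respond
            add(mono, 0.0, (1.0 - prev) * sp)
            add(combo, 0.0, (1.0 - prev) * (1.0 - sp))

    econ = params.economics
    one_time = econ.biopsy_cost + econ.pdl1_test_cost
    if strategy.name == StrategyName.BIOMARKER:
        one_time += params.test.test_cost

    return InitialDistribution(
        group=params.group,
        strategy=strategy.name,
        cells={key: mass for key, mass in cells.items() if mass > 0.0},
        tree_stage_cost=one_time,
    )


def overall_response_rate(dist: InitialDistribution) -> float:
    """Fraction of the cohort that responds to its assigned regimen."""
    return sum(mass for key, mass in dist.cells.items() if key.responder)
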