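"""Utilities, costs, differential discounting and strategy comparison.

Rewards accrue in continuous monthly increments: cycle ``t`` (t = 1..T)
earns the start-of-cycle occupancy one month of state utility and state
cost, discounted at ``(1 + r)^(-t/12)`` with separate annual rates for
health (1.5% by default) and costs (4.0% by default). One-time costs are
attached to events: tree-stage costs at cycle 0 undiscounted, a
discontinuation cost when medication stops (the progression transition
under treat-until-progression, the fixed stopping cycle otherwise), and a
terminal-care cost on death transitions. Side-effect disutilities and
management costs are prevalence-weighted aggregates per regimen: the
disutility is subtracted as a per-cycle quality-of-life decrement while on
medication; the aggregate cost is amortised evenly over the first twelve
on-medication cycles (side effects are a first-year-of-treatment
phenomenon at these regimens' schedules).

The comparison follows cost-effectiveness quadrant semantics at a single
willingness-to-pay / willingness-to-accept threshold (EUR 80,000 per QALY
by default): in the north-east quadrant (QALYs gained at extra cost) the
ICER is EUR per QALY gained and must fall below the threshold; in the
south-west quadrant (QALYs lost for savings) it is EUR saved per QALY lost
and must exceed the threshold; dominance is decided without division.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .decision_tree import StrategyName
from .markov import CohortTrace
from .parameters import ConfigurationError, ParameterSet, SideEffect
from .survival import (
    DEAD_DISEASE,
    DEAD_OTHER,
    NR_DIE,
    NR_PROG,
    ON_MEDICATION_STATES,
    PREPROGRESSION_STATES,
    PROG,
    RESP,
)

__all__ = [
    "StrategyOutcome",
    "ComparisonResult",
    "aggregate_disutility",
    "aggregate_side_effect_cost",
    "discount_factor",
    "accumulate",
    "compare",
]

#: cycles over which the aggregate side-effect management cost is spread
SIDE_EFFECT_AMORTIZATION_CYCLES = 12

_ZERO_TOL = 1e-12


def aggregate_disutility(side_effects: list[SideEffect]) -> float:
    """Prevalence-weighted sum of side-effect utility decrements."""
    return sum(se.prevalence * se.disutility for se in side_effects)


def aggregate_side_effect_cost(side_effects: list[SideEffect]) -> float:
    """Prevalence-weighted sum of side-effect management costs (EUR)."""
    return sum(se.prevalence * se.treatment_cost for se in side_effects)


def discount_factor(cycle: float, annual_rate: float) -> float:
    """Discount multiplier for a monthly cycle index: (1+r)^(-cycle/12)."""
    if cycle < 0:
        raise ValueError("cycle index must be nonnegative")
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError("annual discount rate must be in [0, 1)")
    return (1.0 + annual_rate) ** (-cycle / 12.0)


@dataclass
class StrategyOutcome:
    """Per-patient discounted and undiscounted QALYs and costs for one
    strategy, with the per-cycle breakdown for audit."""

    qalys: float
    costs: float
    qalys_undiscounted: float
    costs_undiscounted: float
    breakdown: Optional[pd.DataFrame] = field(default=None, repr=False)


@dataclass
class ComparisonResult:
    """Comparator-minus-reference deltas with quadrant-aware ICER."""

    delta_qaly: float
    delta_cost: float
    icer: Optional[float]
    quadrant: str
    cost_effective: bool
    threshold: float

    def describe(self) -> str:
        if self.quadrant == "dominant":
            head = "dominant (more QALYs at lower cost)"
        elif self.quadrant == "dominated":
            head = "dominated (fewer QALYs at higher cost)"
        elif self.quadrant == "cost_minimization":
            head = f"equal QALYs; cost difference EUR {self.delta_cost:,.0f}"
        elif self.quadrant == "per_qaly_gained":
            head = f"EUR {self.icer:,.0f} per QALY gained"
        else:
            head = f"EUR {self.icer:,.0f} saved per QALY lost"
        verdict = "cost-effective" if self.cost_effective else "not cost-effective"
        return f"{head}; {verdict} at EUR {self.threshold:,.0f}/QALY"


def _flows_into(occ: np.ndarray, matrices: np.ndarray, sources: tuple[int, ...], target: int) -> np.ndarray:
    """Mass flowing from ``sources`` into ``target`` during each cycle t=1..T."""
    start = occ[:-1]  # (T, 6)
    src = list(sources)
    return np.einsum("ts,ts->t", start[:, src], matrices[:, src, target])


def accumulate(trace: CohortTrace, params: ParameterSet, strategy: StrategyName | None = None) -> StrategyOutcome:
    """Attach utilities and costs to a cohort trace.

    ``strategy`` is informational; the regimen assignments and the tree-stage
    one-time cost already live on the trace's cells.
    """
    econ = params.economics
    T = trace.horizon
    cycles = np.arange(1, T + 1, dtype=float)
    dq = (1.0 + econ.discount_rate_health) ** (-cycles / 12.0)
    dc = (1.0 + econ.discount_rate_cost) ** (-cycles / 12.0)

    qaly_t = np.zeros(T)
    cost_t = np.zeros(T)

    med_idx = list(ON_MEDICATION_STATES)
    preprog_idx = list(PREPROGRESSION_STATES)

    for cell in trace.cells:
        if cell.key.regimen not in params.regimens:
            raise ConfigurationError(f"regimen {cell.key.regimen.value} missing from parameters")
        reg = params.regimens[cell.key.regimen]
        occ = cell.occupancy
        start = occ[:-1]  # occupancy during cycle t is row t-1
        if econ.half_cycle_correction:
            during = 0.5 * (occ[:-1] + occ[1:])
        else:
            during = start

        rule = reg.duration_rule
        if rule.kind == "FIXED_MONTHS":
            stop = int(rule.months)
            med_gate = (cycles <= stop).astype(float)
        else:
            stop = None
            med_gate = np.ones(T)

        onmed = during[:, med_idx].sum(axis=1) * med_gate
        preprog = during[:, preprog_idx].sum(axis=1)
        prog_occ = during[:, PROG]

        disut = aggregate_disutility(reg.side_effects)
        se_cost = aggregate_side_effect_cost(reg.side_effects)

        qaly_t += (
            preprog * econ.u_response + prog_occ * econ.u_progression - onmed * disut
        ) / 12.0

        amort_gate = (cycles <= SIDE_EFFECT_AMORTIZATION_CYCLES).astype(float)
        cost_t += (
            onmed * reg.med_cost_per_cycle
            + preprog * econ.state_cost_response
            + prog_occ * econ.state_cost_progression
            + onmed * amort_gate * (se_cost / SIDE_EFFECT_AMORTIZATION_CYCLES)
        )

        # event-attached one-time costs use start-of-cycle flows
        mats = cell.schedule.matrices[:T]
        into_prog = _flows_into(occ, mats, (RESP, NR_DIE, NR_PROG), PROG)
        death_dis = _flows_into(occ, mats, (RESP, NR_DIE, NR_PROG, PROG), DEAD_DISEASE)
        death_oth = _flows_into(occ, mats, (RESP, NR_DIE, NR_PROG, PROG), DEAD_OTHER)

        if rule.kind == "UNTIL_PROGRESSION":
            cost_t += into_prog * econ.discontinuation_cost
        else:
            # stopping while progressing before the fixed horizon also ends
            # medication; the remainder stop at the fixed cycle
            gate = (cycles <= stop).astype(float)
            cost_t += into_prog * gate * econ.discontinuation_cost
            if stop is not None and 1 <= stop <= T:
                still_on = occ[stop, med_idx].sum()
                cost_t[stop - 1] += still_on * econ.discontinuation_cost

        terminal = death_dis
        if econ.terminal_care_on_other_cause:
            terminal = terminal + death_oth
        cost_t += terminal * econ.terminal_care_cost

    qalys = float(qaly_t @ dq)
    costs = float(cost_t @ dc) + trace.tree_stage_cost
    qalys_und = float(qaly_t.sum())
    costs_und = float(cost_t.sum()) + trace.tree_stage_cost

    breakdown = pd.DataFrame(
        {
            "cycle": cycles.astype(int),
            "qaly": qaly_t,
            "cost": cost_t,
            "qaly_discounted": qaly_t * dq,
            "cost_discounted": cost_t * dc,
        }
    )
    return StrategyOutcome(
        qalys=qalys,
        costs=costs,
        qalys_undiscounted=qalys_und,
        costs_undiscounted=costs_und,
        breakdown=breakdown,
    )


def compare(
    reference: StrategyOutcome, comparator: StrategyOutcome, threshold: float
) -> ComparisonResult:
    """Comparator vs. reference with quadrant-aware ICER semantics."""
    dqaly = comparator.qalys - reference.qalys
    dcost = comparator.costs - reference.costs

    if abs(dqaly) <= _ZERO_TOL:
        return ComparisonResult(
            delta_qaly=dqaly,
            delta_cost=dcost,
            icer=None,
            quadrant="cost_minimization",
            cost_effective=dcost <= 0.0,
            threshold=threshold,
        )
    if dqaly > 0.0 and dcost <= 0.0:
        return ComparisonResult(dqaly, dcost, None, "dominant", True, threshold)
    if dqaly < 0.0 and dcost >= 0.0:
        return ComparisonResult(dqaly, dcost, None, "dominated", False, threshold)
    icer = dcost / dqaly
    if dqaly > 0.0:
        # QALYs gained at extra cost: EUR per QALY gained (WTP rule)
        return ComparisonResult(
            dqaly, dcost, icer, "per_qaly_gained", icer <= threshold, threshold
        )
    # QALYs lost for savings: EUR saved per QALY lost (WTA rule);
    # dcost/dqaly is positive here and must meet or exceed the threshold
    return ComparisonResult(
        dqaly, dcost, icer, "saved_per_qaly_lost", icer >= threshold, threshold
    )
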