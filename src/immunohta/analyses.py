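"""Analysis layer: headroom, test-accuracy scenarios, one-way DSA, and the
equal-medication-duration scenario for the high-expression stratum.

``run_strategy`` is the end-to-end pipeline for one strategy: decision tree
-> per-cell transition schedules -> cohort trace -> discounted outcomes.
``headroom`` evaluates the value of a perfect test (sensitivity =
specificity = 100%); ``scenario_table`` sweeps a grid of (sensitivity,
specificity) operating points; ``one_way_dsa`` varies single parameters (or
small groups varied jointly, e.g. both state utilities) between low and
high values and reports the ICER swing and any verdict flips.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .decision_tree import (
    InitialDistribution,
    StrategyDefinition,
    StrategyName,
    initial_distribution,
)
from .economics import ComparisonResult, StrategyOutcome, accumulate, compare
from .markov import CohortTrace, run_cohort
from .parameters import (
    ConfigurationError,
    ParameterSet,
    PDL1Group,
    RegimenName,
    parameters_from_dict,
)
from .survival import ON_MEDICATION_STATES, build_schedule

__all__ = [
    "ScenarioSpec",
    "DsaRange",
    "PRINTED_SCENARIOS",
    "ZERO_ACCURACY_SCENARIO",
    "run_strategy",
    "compare_strategies",
    "headroom",
    "scenario_table",
    "one_way_dsa",
    "default_dsa_ranges",
    "medication_duration_scenario",
    "expected_time_on_treatment",
    "with_test_performance",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One biomarker operating point."""

    se: float
    sp: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.se <= 1.0 or not 0.0 <= self.sp <= 1.0:
            raise ValueError("sensitivity and specificity must be in [0, 1]")


#: the three accuracy scenarios evaluated alongside headroom
PRINTED_SCENARIOS = (
    ScenarioSpec(0.75, 0.75, "se75_sp75"),
    ScenarioSpec(0.90, 0.60, "se90_sp60"),
    ScenarioSpec(0.60, 0.90, "se60_sp90"),
)

#: degenerate corner probing the claim that de-escalation stays
#: cost-effective even for a completely uninformative-at-best test
ZERO_ACCURACY_SCENARIO = ScenarioSpec(0.0, 0.0, "se0_sp0")


@dataclass(frozen=True)
class DsaRange:
    """One tornado bar: parameter path(s) varied between low and high.

    ``paths`` are dotted paths into the configuration dict (e.g.
    ``survival.mean_post_progression_survival``); several paths move
    together so ordered quantities (the two state utilities) stay
    consistent. ``mode`` is ``multiplier`` (low/high scale the base value)
    or ``absolute`` (low/high replace it). Utilities are clipped to 1.
    """

    paths: tuple[str, ...]
    low: float
    high: float
    mode: str = "multiplier"
    label: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low bound must not exceed high bound")
        if self.mode not in ("multiplier", "absolute"):
            raise ValueError("mode must be 'multiplier' or 'absolute'")

    @staticmethod
    def of(path: Union[str, Sequence[str]], low: float, high: float, mode: str = "multiplier", label: str = "") -> "DsaRange":
        paths = (path,) if isinstance(path, str) else tuple(path)
        return DsaRange(paths=paths, low=low, high=high, mode=mode, label=label or paths[0])


def with_test_performance(params: ParameterSet, se: float, sp: float) -> ParameterSet:
    """Clone a parameter set with a different biomarker operating point."""
    clone = params.model_copy(deep=True)
    clone.test = params.test.model_copy(update={"sensitivity": se, "specificity": sp})
    return clone


def run_strategy(
    params: ParameterSet,
    strategy: StrategyDefinition | StrategyName | str,
    horizon: Optional[int] = None,
) -> StrategyOutcome:
    """Decision tree -> schedules -> Markov trace -> discounted outcomes."""
    if not isinstance(strategy, StrategyDefinition):
        strategy = StrategyDefinition.standard(strategy, params.group)
    T = horizon if horizon is not None else params.economics.horizon_cycles
    dist = initial_distribution(params, strategy)
    schedules = {
        key: build_schedule(params, key.regimen, key.responder, horizon=T)
        for key in dist.cells
    }
    trace = run_cohort(dist, schedules, T)
    return accumulate(trace, params, strategy.name)


def compare_strategies(params: ParameterSet) -> ComparisonResult:
    """Biomarker strategy vs. current practice at the configured test
    performance and threshold."""
    ref = run_strategy(params, StrategyName.CURRENT_PRACTICE)
    comp = run_strategy(params, StrategyName.BIOMARKER)
    return compare(ref, comp, params.economics.wtp_wta_threshold)


def headroom(params: ParameterSet) -> ComparisonResult:
    """Value of a perfect biomarker: the comparison at Se = Sp = 100%."""
    return compare_strategies(with_test_performance(params, 1.0, 1.0))


def scenario_table(
    params: ParameterSet, scenarios: Sequence[ScenarioSpec] = PRINTED_SCENARIOS
) -> pd.DataFrame:
    """One row per operating point, headroom first."""
    rows = []
    points = [ScenarioSpec(1.0, 1.0, "headroom"), *scenarios]
    for spec in points:
        p = with_test_performance(params, spec.se, spec.sp)
        ref = run_strategy(p, StrategyName.CURRENT_PRACTICE)
        comp = run_strategy(p, StrategyName.BIOMARKER)
        res = compare(ref, comp, p.economics.wtp_wta_threshold)
        rows.append(
            {
                "scenario": spec.label or f"se{spec.se:g}_sp{spec.sp:g}",
                "sensitivity": spec.se,
                "specificity": spec.sp,
                "qalys_current": ref.qalys,
                "costs_current": ref.costs,
                "qalys_biomarker": comp.qalys,
                "costs_biomarker": comp.costs,
                "delta_qaly": res.delta_qaly,
                "delta_cost": res.delta_cost,
                "icer": res.icer,
                "quadrant": res.quadrant,
                "cost_effective": res.cost_effective,
            }
        )
    return pd.DataFrame(rows)


def _set_path(data: dict, path: str, value: float) -> None:
    keys = path.split(".")
    node = data
    for key in keys[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise ConfigurationError(f"DSA parameter path not found: {path}")
        node = node[key]
    if not isinstance(node, dict) or keys[-1] not in node:
        raise ConfigurationError(f"DSA parameter path not found: {path}")
    node[keys[-1]] = value


def _get_path(data: dict, path: str) -> float:
    node = data
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ConfigurationError(f"DSA parameter path not found: {path}")
        node = node[key]
    return node


def _perturbed(params: ParameterSet, rng: DsaRange, which: str) -> ParameterSet:
    data = params.to_config_dict()
    bound = rng.low if which == "low" else rng.high
    for path in rng.paths:
        base = _get_path(data, path)
        value = base * bound if rng.mode == "multiplier" else bound
        if ".u_" in path or path.endswith(("u_response", "u_progression")):
            value = min(1.0, value)
        _set_path(data, path, value)
    return parameters_from_dict(data)


def one_way_dsa(
    params: ParameterSet,
    ranges: Sequence[DsaRange],
    scenario: ScenarioSpec = ScenarioSpec(0.75, 0.75, "se75_sp75"),
) -> pd.DataFrame:
    """Tornado table: for each range, the comparison at the low and high
    value, sorted by ICER swing; verdict flips are flagged."""
    base_params = with_test_performance(params, scenario.se, scenario.sp)
    base = compare_strategies(base_params)
    rows = []
    for rng in ranges:
        res = {}
        for which in ("low", "high"):
            p = _perturbed(base_params, rng, which)
            res[which] = compare_strategies(p)
        icer_low = res["low"].icer
        icer_high = res["high"].icer
        vals = [v for v in (icer_low, icer_high) if v is not None]
        swing = (max(vals) - min(vals)) if len(vals) == 2 else float("nan")
        rows.append(
            {
                "parameter": rng.label or ";".join(rng.paths),
                "low": rng.low,
                "high": rng.high,
                "mode": rng.mode,
                "icer_base": base.icer,
                "icer_low": icer_low,
                "icer_high": icer_high,
                "swing": swing,
                "verdict_base": base.cost_effective,
                "verdict_low": res["low"].cost_effective,
                "verdict_high": res["high"].cost_effective,
                "verdict_changed": (
                    res["low"].cost_effective != base.cost_effective
                    or res["high"].cost_effective != base.cost_effective
                ),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("swing", ascending=False, ignore_index=True)
    return table


def default_dsa_ranges(params: ParameterSet) -> list[DsaRange]:
    """The standard one-way ranges: post-progression survival at 50-150% of
    its base value, and both state utilities varied jointly from 50% of
    their base values up to 1.0."""
    return [
        DsaRange.of(
            "survival.mean_post_progression_survival", 0.5, 1.5,
            label="mean post-progression survival (x0.5..x1.5)",
        ),
        DsaRange.of(
            ("economics.u_response", "economics.u_progression"), 0.5, 1.0,
            mode="multiplier", label="state utilities (x0.5..base)",
        ),
        DsaRange.of(
            ("economics.u_response", "economics.u_progression"), 1.0, 1.0 / max(
                params.economics.u_response, 1e-9
            ),
            mode="multiplier", label="state utilities (base..1.0)",
        ),
    ]


def expected_time_on_treatment(
    params: ParameterSet, strategy: StrategyDefinition | StrategyName | str
) -> float:
    """Expected months on medication per patient under a strategy, i.e. the
    summed start-of-cycle occupancy of the on-medication states gated by
    each regimen's duration rule."""
    if not isinstance(strategy, StrategyDefinition):
        strategy = StrategyDefinition.standard(strategy, params.group)
    T = params.economics.horizon_cycles
    dist = initial_distribution(params, strategy)
    schedules = {
        key: build_schedule(params, key.regimen, key.responder, horizon=T)
        for key in dist.cells
    }
    trace = run_cohort(dist, schedules, T)
    med_idx = list(ON_MEDICATION_STATES)
    total = 0.0
    for cell in trace.cells:
        rule = params.regimens[cell.key.regimen].duration_rule
        stop = rule.months if rule.kind == "FIXED_MONTHS" else T
        onmed = cell.occupancy[:-1, med_idx].sum(axis=1)
        total += onmed[: min(stop, T)].sum()
    return total


def medication_duration_scenario(
    params: ParameterSet, months: Optional[int] = None
) -> ComparisonResult:
    """Equal-total-therapy-duration scenario for the >=50% stratum.

    Both the immunotherapy and immunochemotherapy arms are given the same
    fixed medication duration (default: the expected months on treatment
    under current practice, rounded), removing the cost inflation that
    longer survival on the combination otherwise produces; the comparison
    is re-run at the configured test performance.
    """
    if params.group != PDL1Group.GE50:
        raise ConfigurationError(
            "the equal-duration scenario is defined for the PD-L1 >=50% stratum only"
        )
    if months is None:
        months = int(round(expected_time_on_treatment(params, StrategyName.CURRENT_PRACTICE)))
    data = params.to_config_dict()
    for reg in (RegimenName.IMMUNO.value, RegimenName.IMMUNOCHEMO.value):
        data["regimens"][reg]["duration_rule"] = {"kind": "FIXED_MONTHS", "months": months}
    return compare_strategies(parameters_from_dict(data))
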