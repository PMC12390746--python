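"""Rewards, discounting, event-attached costs, and ICER comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import simple_params, single_cell_dist
from immunohta.analyses import run_strategy
from immunohta.decision_tree import StrategyName
from immunohta.economics import (
    ComparisonResult,
    StrategyOutcome,
    accumulate,
    aggregate_disutility,
    aggregate_side_effect_cost,
    compare,
    discount_factor,
)
from immunohta.markov import run_cohort
from immunohta.parameters import RegimenName, SideEffect
from immunohta.survival import build_schedule


def se(p, d=0.0, c=0.0):
    return SideEffect(name="x", prevalence=p, disutility=d, treatment_cost=c)


class TestAggregates:
    def test_disutility(self):
        assert aggregate_disutility([]) == 0.0
        assert aggregate_disutility([se(0.5, d=0.1)]) == pytest.approx(0.05)
        assert aggregate_disutility([se(0.2, d=0.1), se(0.3, d=0.2)]) == pytest.approx(0.08)

    def test_cost(self):
        assert aggregate_side_effect_cost([]) == 0.0
        assert aggregate_side_effect_cost([se(0.1, c=1000.0)]) == pytest.approx(100.0)
        assert aggregate_side_effect_cost(
            [se(0.2, c=500.0), se(0.5, c=200.0)]
        ) == pytest.approx(200.0)


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, rate, expected",
        [
            (0, 0.04, 1.0),
            (12, 0.04, 1 / 1.04),
            (24, 0.015, 1.015**-2),
            (6, 0.0, 1.0),
        ],
    )
    def test_factor(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, abs=1e-12)

    def test_zero_rates_make_discounted_equal_undiscounted(self, params_lt1):
        p = params_lt1.model_copy(deep=True)
        p.economics = p.economics.model_copy(
            update={"discount_rate_health": 0.0, "discount_rate_cost": 0.0}
        )
        out = run_strategy(p, StrategyName.BIOMARKER)
        assert out.qalys == pytest.approx(out.qalys_undiscounted, abs=1e-9)
        assert out.costs == pytest.approx(out.costs_undiscounted, abs=1e-9)


def run_simple(params, regimen=RegimenName.IMMUNOCHEMO, responder=True, tree_cost=0.0):
    dist = single_cell_dist(regimen, responder, tree_cost)
    key = next(iter(dist.cells))
    sched = build_schedule(params, regimen, key.responder)
    trace = run_cohort(dist, {key: sched}, params.economics.horizon_cycles)
    return accumulate(trace, params)


class TestAccumulate:
    def test_horizon_bound_qalys(self):
        """Perfect utility, no events, no discounting: 60 cycles = 5 QALYs."""
        out = run_simple(simple_params())
        assert out.qalys == pytest.approx(5.0, abs=1e-12)
        assert out.costs == 0.0

    def test_discounted_geometric_sum(self):
        out = run_simple(simple_params(economics={"discount_rate_health": 0.015}))
        expected = sum(1.015 ** (-k / 12) / 12 for k in range(1, 61))
        assert out.qalys == pytest.approx(expected, abs=1e-12)
        assert out.qalys_undiscounted == pytest.approx(5.0, abs=1e-12)

    def test_medication_until_progression_hand_count(self):
        """EUR 1000/cycle until a deterministic progression at cycle 10
        costs exactly EUR 10,000 undiscounted."""
        params = simple_params(
            regimens={"IMMUNOCHEMO": {"med_cost_per_cycle": 1000.0}},
            survival={"arms": {"IMMUNOCHEMO": {"os12": 1.0}}},  # all progress at 9 mo
        )
        out = run_simple(params, responder=False)
        assert out.costs == pytest.approx(10_000.0, abs=1e-9)

    def test_discontinuation_and_terminal_costs_once_each(self):
        """Every progressing patient pays one discontinuation fee and, on
        death, one terminal-care fee; with certain progression and a finite
        horizon the terminal mass is bounded by total deaths."""
        params = simple_params(
            economics={"discontinuation_cost": 300.0, "terminal_care_cost": 7000.0},
            survival={
                "arms": {"IMMUNOCHEMO": {"os12": 1.0}},
                "mean_post_progression_survival": 1.0,  # death the cycle after progression
            },
        )
        out = run_simple(params, responder=False)
        assert out.costs == pytest.approx(300.0 + 7000.0, abs=1e-9)

    def test_side_effect_amortization_totals_aggregate_cost(self):
        """With no events, the aggregate side-effect cost is paid exactly
        once, spread over the first twelve cycles."""
        params = simple_params(
            regimens={
                "IMMUNOCHEMO": {
                    "side_effects": [
                        {"name": "a", "prevalence": 0.2, "disutility": 0.0, "treatment_cost": 600.0}
                    ]
                }
            }
        )
        out = run_simple(params)
        assert out.costs == pytest.approx(0.2 * 600.0, abs=1e-9)

    def test_disutility_reduces_qalys_while_on_medication(self):
        params = simple_params(
            regimens={
                "IMMUNOCHEMO": {
                    "side_effects": [
                        {"name": "a", "prevalence": 0.5, "disutility": 0.1, "treatment_cost": 0.0}
                    ]
                }
            }
        )
        out = run_simple(params)
        assert out.qalys == pytest.approx(5.0 - 0.05 * 60 / 12, abs=1e-12)

    def test_fixed_duration_caps_medication(self):
        params = simple_params(
            regimens={
                "IMMUNOCHEMO": {
                    "med_cost_per_cycle": 1000.0,
                    "duration_rule": {"kind": "FIXED_MONTHS", "months": 6},
                }
            },
            economics={"discontinuation_cost": 250.0},
        )
        out = run_simple(params)
        assert out.costs == pytest.approx(6 * 1000.0 + 250.0, abs=1e-9)

    def test_zero_fixed_duration_means_no_medication_cost(self):
        params = simple_params(
            regimens={
                "IMMUNOCHEMO": {
                    "med_cost_per_cycle": 1000.0,
                    "duration_rule": {"kind": "FIXED_MONTHS", "months": 0},
                }
            }
        )
        out = run_simple(params)
        assert out.costs == 0.0

    def test_tree_stage_cost_not_discounted(self):
        params = simple_params(economics={"discount_rate_cost": 0.04})
        out = run_simple(params, tree_cost=1234.0)
        assert out.costs == pytest.approx(1234.0)

    def test_qalys_monotone_in_utilities(self, params_lt1):
        base = run_strategy(params_lt1, StrategyName.CURRENT_PRACTICE)
        better = params_lt1.model_copy(deep=True)
        better.economics = better.economics.model_copy(
            update={
                "u_response": min(1.0, params_lt1.economics.u_response + 0.05),
                "u_progression": min(1.0, params_lt1.economics.u_progression + 0.05),
            }
        )
        assert run_strategy(better, StrategyName.CURRENT_PRACTICE).qalys > base.qalys


def outcome(q, c):
    return StrategyOutcome(qalys=q, costs=c, qalys_undiscounted=q, costs_undiscounted=c)


class TestCompare:
    def test_savings_per_qaly_lost(self):
        res = compare(outcome(0.825, 155_968.0), outcome(0.780, 125_654.0), 80_000.0)
        assert res.quadrant == "saved_per_qaly_lost"
        assert res.delta_cost == pytest.approx(-30_314.0)
        assert res.icer > 80_000.0
        assert res.cost_effective

    def test_cost_per_qaly_gained(self):
        res = compare(outcome(0.842, 106_922.0), outcome(1.369, 247_347.0), 80_000.0)
        assert res.quadrant == "per_qaly_gained"
        assert res.delta_qaly == pytest.approx(0.527)
        assert not res.cost_effective

    def test_dominance(self):
        assert compare(outcome(1.0, 100.0), outcome(1.2, 50.0), 80_000.0).quadrant == "dominant"
        assert compare(outcome(1.2, 50.0), outcome(1.0, 100.0), 80_000.0).quadrant == "dominated"

    def test_equal_qalys_is_cost_minimization(self):
        res = compare(outcome(1.0, 100.0), outcome(1.0, 90.0), 80_000.0)
        assert res.quadrant == "cost_minimization"
        assert res.icer is None
        assert res.cost_effective

    @given(
        q1=st.floats(0.0, 3.0),
        q2=st.floats(0.0, 3.0),
        c1=st.floats(0.0, 3e5),
        c2=st.floats(0.0, 3e5),
    )
    def test_antisymmetry(self, q1, q2, c1, c2):
        fwd = compare(outcome(q1, c1), outcome(q2, c2), 80_000.0)
        rev = compare(outcome(q2, c2), outcome(q1, c1), 80_000.0)
        assert fwd.delta_qaly == pytest.approx(-rev.delta_qaly)
        assert fwd.delta_cost == pytest.approx(-rev.delta_cost)
        flip = {
            "dominant": "dominated",
            "dominated": "dominant",
            "per_qaly_gained": "saved_per_qaly_lost",
            "saved_per_qaly_lost": "per_qaly_gained",
            "cost_minimization": "cost_minimization",
        }
        assert rev.quadrant == flip[fwd.quadrant]

    def test_describe_mentions_verdict(self):
        res = compare(outcome(1.0, 100.0), outcome(1.2, 50.0), 80_000.0)
        assert "cost-effective" in res.describe()
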