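"""Decision-tree routing: cell masses, test-performance mixing, and the
brute-force enumeration oracle."""

import itertools

import pytest
from hypothesis import given, strategies as st

from immunohta.analyses import with_test_performance
from immunohta.decision_tree import (
    CellKey,
    StrategyDefinition,
    StrategyName,
    initial_distribution,
    overall_response_rate,
)
from immunohta.parameters import (
    ConfigurationError,
    PDL1Group,
    RegimenName,
    conditional_response_to_comparator,
    nonresponder_crossover_rate,
)

COMBO = RegimenName.IMMUNOCHEMO
CHEMO = RegimenName.CHEMO
IMMUNO = RegimenName.IMMUNO


def brute_force_cells(group, r_combo, r_mono, se, sp, strategy):
    """Independent oracle: exhaustive sum over the 2x2x2 (reference status x
    test result x routing) branches using the joint responder table."""
    mono = IMMUNO if group == PDL1Group.GE50 else CHEMO
    prevalence = r_mono if group == PDL1Group.GE50 else r_combo
    cells = {}

    def put(reg, responder, mass):
        if mass > 0:
            cells[(reg, responder)] = cells.get((reg, responder), 0.0) + mass

    for status, test in itertools.product((True, False), ("pos", "neg")):
        p_status = prevalence if status else 1.0 - prevalence
        p_test = (se if test == "pos" else 1.0 - se) if status else (
            1.0 - sp if test == "pos" else sp
        )
        mass = p_status * p_test
        if strategy == StrategyName.CURRENT_PRACTICE:
            reg = mono if group == PDL1Group.GE50 else COMBO
        elif group == PDL1Group.GE50:
            reg = mono if test == "pos" else COMBO
        else:
            reg = COMBO if test == "pos" else mono
        # response on the routed arm given reference status, from the
        # nested joint table
        if group == PDL1Group.GE50:
            if status:
                p_resp = 1.0  # IO responders respond to either arm
            else:
                p_resp = (
                    nonresponder_crossover_rate(r_combo, r_mono) if reg == COMBO else 0.0
                )
        else:
            if status:
                p_resp = (
                    1.0
                    if reg == COMBO
                    else conditional_response_to_comparator(r_combo, r_mono)
                )
            else:
                p_resp = 0.0  # combo nonresponders respond to nothing
        put(reg, True, mass * p_resp)
        put(reg, False, mass * (1.0 - p_resp))
    return cells


def dist_for(params, strategy_name, se=None, sp=None):
    if se is not None:
        params = with_test_performance(params, se, sp)
    strategy = StrategyDefinition.standard(strategy_name, params.group)
    return initial_distribution(params, strategy)


class TestCurrentPractice:
    def test_lt1_masses(self, params_lt1):
        dist = dist_for(params_lt1, StrategyName.CURRENT_PRACTICE)
        assert dist.mass(COMBO, True) == pytest.approx(0.328)
        assert dist.mass(COMBO, False) == pytest.approx(0.672)
        assert set(dist.cells) == {CellKey(COMBO, True), CellKey(COMBO, False)}

    def test_ge50_masses(self, params_ge50):
        dist = dist_for(params_ge50, StrategyName.CURRENT_PRACTICE)
        assert dist.mass(IMMUNO, True) == pytest.approx(0.375)
        assert dist.mass(IMMUNO, False) == pytest.approx(0.625)

    def test_ignores_test_performance(self, params_lt1):
        a = dist_for(params_lt1, StrategyName.CURRENT_PRACTICE, 0.3, 0.9)
        b = dist_for(params_lt1, StrategyName.CURRENT_PRACTICE, 0.9, 0.3)
        assert a.cells == b.cells


class TestBiomarker:
    def test_perfect_test_lt1(self, params_lt1):
        """A perfect test keeps every combo responder on immunochemotherapy
        and routes every combo nonresponder to chemotherapy, where nesting
        means none of them respond."""
        dist = dist_for(params_lt1, StrategyName.BIOMARKER, 1.0, 1.0)
        assert dist.mass(COMBO, True) == pytest.approx(0.328)
        assert dist.mass(CHEMO, False) == pytest.approx(0.672)
        assert overall_response_rate(dist) == pytest.approx(0.328)

    def test_imperfect_test_responder_leak(self, params_lt1):
        """A false-negative combo responder moves to chemotherapy and
        responds with the conditional probability 0.193/0.328."""
        dist = dist_for(params_lt1, StrategyName.BIOMARKER, 0.75, 0.75)
        expected = 0.328 * 0.25 * (0.193 / 0.328)
        assert dist.mass(CHEMO, True) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.04825, abs=5e-5)

    def test_perfect_test_ge50_matches_combo_rate(self, params_ge50):
        """With a perfect test, every IO nonresponder is offered the
        combination, so the overall response rate equals the derived
        immunochemotherapy rate."""
        dist = dist_for(params_ge50, StrategyName.BIOMARKER, 1.0, 1.0)
        assert overall_response_rate(dist) == pytest.approx(
            params_ge50.response.r_combo_effective, abs=1e-12
        )
        assert overall_response_rate(dist) == pytest.approx(0.655, abs=5e-4)

    def test_se1_sp0_reproduces_current_practice(self, params_lt1):
        """Se=1, Sp=0 makes the test always positive, which for the low
        strata is exactly current practice."""
        bio = dist_for(params_lt1, StrategyName.BIOMARKER, 1.0, 0.0)
        cur = dist_for(params_lt1, StrategyName.CURRENT_PRACTICE)
        for key in set(bio.cells) | set(cur.cells):
            assert bio.cells.get(key, 0.0) == pytest.approx(cur.cells.get(key, 0.0))

    def test_response_rate_monotone_in_sensitivity(self, params_lt1):
        rates = [
            overall_response_rate(dist_for(params_lt1, StrategyName.BIOMARKER, se, 0.75))
            for se in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))


@given(
    se=st.floats(0.0, 1.0),
    sp=st.floats(0.0, 1.0),
    strategy=st.sampled_from([StrategyName.CURRENT_PRACTICE, StrategyName.BIOMARKER]),
)
def test_mass_conservation(params_lt1, params_ge50, se, sp, strategy):
    for params in (params_lt1, params_ge50):
        dist = dist_for(params, strategy, se, sp)
        assert sum(dist.cells.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(m >= 0 for m in dist.cells.values())


@pytest.mark.parametrize("group_fixture", ["params_lt1", "params_pd1_49", "params_ge50"])
@pytest.mark.parametrize("se,sp", [(1.0, 1.0), (0.75, 0.75), (0.9, 0.6), (0.0, 0.0), (0.3, 0.8)])
@pytest.mark.parametrize("strategy", [StrategyName.CURRENT_PRACTICE, StrategyName.BIOMARKER])
def test_against_enumeration_oracle(request, group_fixture, se, sp, strategy):
    params = request.getfixturevalue(group_fixture)
    dist = dist_for(params, strategy, se, sp)
    expected = brute_force_cells(
        params.group,
        params.response.r_combo_effective,
        params.response.r_mono,
        se,
        sp,
        strategy,
    )
    got = {(k.regimen, k.responder): m for k, m in dist.cells.items()}
    assert set(got) == set(expected)
    for key in expected:
        assert got[key] == pytest.approx(expected[key], abs=1e-12)


def test_group_mismatch_rejected(params_lt1):
    strategy = StrategyDefinition.standard(StrategyName.BIOMARKER, PDL1Group.GE50)
    with pytest.raises(ConfigurationError):
        initial_distribution(params_lt1, strategy)


def test_tree_stage_costs(params_lt1):
    econ = params_lt1.economics
    base = econ.biopsy_cost + econ.pdl1_test_cost
    cur = dist_for(params_lt1, StrategyName.CURRENT_PRACTICE)
    assert cur.tree_stage_cost == pytest.approx(base)
    priced = params_lt1.model_copy(deep=True)
    priced.test = priced.test.model_copy(update={"test_cost": 500.0})
    bio = dist_for(priced, StrategyName.BIOMARKER)
    assert bio.tree_stage_cost == pytest.approx(base + 500.0)
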