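import copy

import pytest
from hypothesis import HealthCheck, settings

from immunohta.decision_tree import CellKey, InitialDistribution, StrategyName
from immunohta.parameters import ParameterSet, PDL1Group, RegimenName, parameters_from_dict
from immunohta.synthetic import GeneratorConfig, generate_parameter_set

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: generator seed used for "the default synthetic parameters" throughout
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def params_lt1() -> ParameterSet:
    return generate_parameter_set(GeneratorConfig(seed=DEFAULT_SEED, group=PDL1Group.LT1))


@pytest.fixture(scope="session")
def params_pd1_49() -> ParameterSet:
    return generate_parameter_set(GeneratorConfig(seed=DEFAULT_SEED, group=PDL1Group.PD1_49))


@pytest.fixture(scope="session")
def params_ge50() -> ParameterSet:
    return generate_parameter_set(GeneratorConfig(seed=DEFAULT_SEED, group=PDL1Group.GE50))


@pytest.fixture(scope="session")
def all_params(params_lt1, params_pd1_49, params_ge50) -> dict:
    return {
        PDL1Group.LT1: params_lt1,
        PDL1Group.PD1_49: params_pd1_49,
        PDL1Group.GE50: params_ge50,
    }


_SIMPLE_BASE = {
    "group": "LT1",
    "regimens": {
        "CHEMO": {"med_cost_per_cycle": 0.0},
        "IMMUNOCHEMO": {"med_cost_per_cycle": 0.0},
    },
    "response": {"r_combo": 0.328, "r_mono": 0.193, "derivation_mode": "RATIO"},
    "survival": {
        "arms": {
            "CHEMO": {"pfs12": 0.193, "os12": 1.0, "pfs_anchors": [[12.0, 1.0]]},
            "IMMUNOCHEMO": {"pfs12": 0.328, "os12": 1.0, "pfs_anchors": [[12.0, 1.0]]},
        },
        "mean_time_to_progression_nonresp": 9.0,
        "mean_post_progression_survival": 5.4,
    },
    "economics": {
        "u_response": 1.0,
        "u_progression": 1.0,
        "state_cost_response": 0.0,
        "state_cost_progression": 0.0,
        "biopsy_cost": 0.0,
        "pdl1_test_cost": 0.0,
        "discontinuation_cost": 0.0,
        "terminal_care_cost": 0.0,
        "discount_rate_health": 0.0,
        "discount_rate_cost": 0.0,
        "horizon_cycles": 60,
    },
    "mortality": {"monthly_other_cause_death": 0.0},
    "test": {"sensitivity": 1.0, "specificity": 1.0, "test_cost": 0.0},
}


def _deep_update(base: dict, over: dict) -> dict:
    for key, val in over.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def simple_params(**overrides) -> ParameterSet:
    """A stripped-down LT1 parameter set (no hazards, no costs, no
    discounting) for closed-form checks; nested keys are deep-merged over
    the base configuration."""
    data = copy.deepcopy(_SIMPLE_BASE)
    _deep_update(data, overrides)
    return parameters_from_dict(data)


def single_cell_dist(regimen: RegimenName, responder: bool, tree_cost: float = 0.0) -> InitialDistribution:
    """A degenerate starting distribution with the whole cohort in one cell."""
    return InitialDistribution(
        group=PDL1Group.LT1,
        strategy=StrategyName.CURRENT_PRACTICE,
        cells={CellKey(regimen, responder): 1.0},
        tree_stage_cost=tree_cost,
    )
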