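"""Monthly-cycle Markov cohort engine.

The cohort's decision-tree cells evolve independently (the model is linear
in occupancy) through the internal six-state space defined in
:mod:`immunohta.survival`; for reporting they are pooled into five health
states: response on treatment, stable without response, progression, death
from disease, death from other causes. Cycle 0 is the decision-tree
moment; matrix ``t-1`` of a schedule moves the cohort from row ``t-1`` to
row ``t`` of the trace.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .decision_tree import CellKey, InitialDistribution
from .parameters import ConfigurationError, RegimenName
from .survival import (
    ALIVE_STATES,
    INTERNAL_TO_REPORT,
    N_INTERNAL,
    TransitionSchedule,
)

__all__ = ["HealthState", "CellTrace", "CohortTrace", "run_cohort", "evolve_stream", "life_years"]


class HealthState(str, enum.Enum):
    RESPONSE_ON_TREATMENT = "RESPONSE_ON_TREATMENT"
    NONRESP_STABLE = "NONRESP_STABLE"
    PROGRESSION = "PROGRESSION"
    DEATH_DISEASE = "DEATH_DISEASE"
    DEATH_OTHER = "DEATH_OTHER"


REPORT_STATES = tuple(HealthState)


def evolve_stream(mass: float, schedule: TransitionSchedule, horizon: int) -> np.ndarray:
    """Evolve one unit stream: returns internal occupancy, shape (T+1, 6)."""
    if schedule.horizon < horizon:
        raise ConfigurationError(
            f"schedule covers {schedule.horizon} cycles, horizon needs {horizon}"
        )
    occ = np.zeros((horizon + 1, N_INTERNAL))
    occ[0] = mass * schedule.init_internal
    for t in range(1, horizon + 1):
        occ[t] = occ[t - 1] @ schedule.matrices[t - 1]
    return occ


@dataclass
class CellTrace:
    """Occupancy history of one decision-tree cell (a tagged sub-cohort)."""

    key: CellKey
    mass: float
    schedule: TransitionSchedule
    occupancy: np.ndarray  # (T+1, 6) internal states


@dataclass
class CohortTrace:
    """Pooled trace plus the per-cell detail the economics layer needs."""

    cells: list[CellTrace]
    horizon: int
    tree_stage_cost: float = 0.0

    @property
    def occupancy(self) -> np.ndarray:
        """Pooled occupancy over the five reporting states, (T+1, 5)."""
        out = np.zeros((self.horizon + 1, len(REPORT_STATES)))
        for cell in self.cells:
            for s in range(N_INTERNAL):
                out[:, INTERNAL_TO_REPORT[s]] += cell.occupancy[:, s]
        return out

    def validate(self, atol: float = 1e-10) -> None:
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=atol):
            raise ValueError("cohort mass is not conserved across cycles")
        dead = occ[:, 3] + occ[:, 4]
        if np.any(np.diff(dead) < -atol):
            raise ValueError("absorbing-state occupancy decreased")


def run_cohort(
    dist: InitialDistribution,
    schedules: dict[CellKey, TransitionSchedule],
    horizon: int,
) -> CohortTrace:
    """Run every decision-tree cell through its schedule for ``horizon``
    monthly cycles and pool the results."""
    if horizon < 1:
        raise ConfigurationError("horizon must be at least one cycle")
    cells = []
    for key, mass in sorted(
        dist.cells.items(), key=lambda kv: (kv[0].regimen.value, kv[0].responder)
    ):
        if key not in schedules:
            raise ConfigurationError(
                f"no schedule provided for cell ({key.regimen.value}, "
                f"responder={key.responder})"
            )
        occ = evolve_stream(mass, schedules[key], horizon)
        cells.append(CellTrace(key=key, mass=mass, schedule=schedules[key], occupancy=occ))
    trace = CohortTrace(cells=cells, horizon=horizon, tree_stage_cost=dist.tree_stage_cost)
    trace.validate()
    return trace


def life_years(trace: CohortTrace) -> float:
    """Undiscounted life-years per patient over the horizon.

    Cycle ``t`` contributes one month of life for the mass alive at the
    start of the cycle (trace row ``t - 1``).
    """
    total = 0.0
    for cell in trace.cells:
        alive = cell.occupancy[:-1, list(ALIVE_STATES)].sum()
        total += alive
    return total / 12.0
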