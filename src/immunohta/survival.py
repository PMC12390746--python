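"""Survival inputs -> per-cycle transition probabilities.

The cohort model distinguishes three clinical streams:

* **Responders** (progression-free at 12 months by definition) progress at a
  constant monthly hazard obtained by exponential extrapolation of the
  progression-free survival anchors of their assigned arm, and then die from
  progression at a constant hazard matched to the mean post-progression
  survival.
* **Nonresponders** either die or progress within the first 12 months. The
  split between the two streams comes from the gap between the arm's
  12-month PFS and OS. The dying stream follows an exponential within-year
  shape taken from the 12-month OS anchor, renormalised so the stream is
  fully dead by cycle 12. The progressing stream moves to the progression
  state deterministically at the start of the cycle after the mean
  time-to-progression (9 months by default), then follows post-progression
  survival.
* Every alive state additionally faces other-cause (background) mortality,
  applied after the disease event within each cycle; at a monthly step the
  ordering effect is second order.

Schedules are materialised as one 6x6 transition matrix per cycle over an
internal state space that splits the "stable, no response" reporting state
into its dying and progressing streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ConfigurationError, ParameterSet, Regimen, RegimenName

__all__ = [
    "RESP",
    "NR_DIE",
    "NR_PROG",
    "PROG",
    "DEAD_DISEASE",
    "DEAD_OTHER",
    "N_INTERNAL",
    "INTERNAL_TO_REPORT",
    "ON_MEDICATION_STATES",
    "ALIVE_STATES",
    "PREPROGRESSION_STATES",
    "TransitionSchedule",
    "nonresponder_split",
    "monthly_rate_from_anchor",
    "rate_from_anchor",
    "fit_exponential",
    "post_progression_death_prob",
    "nonresponder_death_profile",
    "build_schedule",
]

# internal state indices
RESP, NR_DIE, NR_PROG, PROG, DEAD_DISEASE, DEAD_OTHER = range(6)
N_INTERNAL = 6

#: map internal state -> index into the five reporting health states
#: (RESPONSE_ON_TREATMENT, NONRESP_STABLE, PROGRESSION, DEATH_DISEASE, DEATH_OTHER)
INTERNAL_TO_REPORT = (0, 1, 1, 2, 3, 4)

ON_MEDICATION_STATES = (RESP, NR_DIE, NR_PROG)
PREPROGRESSION_STATES = (RESP, NR_DIE, NR_PROG)
ALIVE_STATES = (RESP, NR_DIE, NR_PROG, PROG)


@dataclass
class TransitionSchedule:
    """Per-cycle transition matrices plus the cell's starting split.

    ``matrices[t]`` moves occupancy from the start to the end of cycle
    ``t + 1``; ``init_internal`` is the distribution over internal states at
    cycle 0 for a unit-mass cell.
    """

    matrices: np.ndarray  # (T, 6, 6)
    init_internal: np.ndarray  # (6,)
    regimen: RegimenName
    responder: bool

    def __post_init__(self) -> None:
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (N_INTERNAL, N_INTERNAL):
            raise ValueError(f"matrices must be (T, 6, 6), got {self.matrices.shape}")
        rows = self.matrices.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition-matrix rows must each sum to 1")
        if np.any(self.matrices < -1e-15):
            raise ValueError("transition probabilities must be nonnegative")

    @property
    def horizon(self) -> int:
        return self.matrices.shape[0]


def nonresponder_split(pfs12: float, os12: float) -> tuple[float, float]:
    """Split nonresponders into (died, progressed) within the first year.

    Among the ``1 - pfs12`` of an arm without response, those not alive at
    12 months died (``1 - os12``) and the remainder (``os12 - pfs12``)
    progressed; the two fractions are returned conditional on being a
    nonresponder and sum to one.
    """
    if not 0.0 <= pfs12 <= 1.0 or not 0.0 <= os12 <= 1.0:
        raise ValueError("pfs12 and os12 must be probabilities")
    if os12 < pfs12:
        raise ValueError(f"os12={os12} must be >= pfs12={pfs12}")
    if pfs12 >= 1.0:
        raise ValueError("pfs12=1 leaves no nonresponders to split")
    denom = 1.0 - pfs12
    p_death = (1.0 - os12) / denom
    p_progress = (os12 - pfs12) / denom
    return p_death, p_progress


def rate_from_anchor(t: float, s_t: float) -> float:
    """Constant exponential rate lambda = -ln(s_t) / t from one anchor."""
    if t <= 0.0:
        raise ValueError(f"anchor month must be positive, got {t}")
    if not 0.0 < s_t <= 1.0:
        raise ValueError(f"anchor survival must be in (0, 1], got {s_t}")
    return -math.log(s_t) / t


def monthly_rate_from_anchor(t: float, s_t: float) -> float:
    """Per-cycle event probability implied by a single survival anchor,
    ``1 - exp(-lambda)`` with ``lambda = -ln(s_t)/t``."""
    return 1.0 - math.exp(-rate_from_anchor(t, s_t))


def fit_exponential(anchors: list[tuple[float, float]]) -> float:
    """Least-squares exponential rate through the origin.

    Fits ``-ln(S) = lambda * t`` to the anchor points, minimising the sum of
    squared residuals in log-survival: ``lambda = sum(t_i y_i) / sum(t_i^2)``
    with ``y_i = -ln(S_i)``. With a single anchor this reduces to the
    closed-form single-anchor rate.
    """
    if not anchors:
        raise ValueError("at least one anchor is required")
    t = np.asarray([a[0] for a in anchors], dtype=float)
    s = np.asarray([a[1] for a in anchors], dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("anchor months must be positive")
    if np.any(s <= 0.0):
        raise ValueError("degenerate anchor: survival fraction of 0 has infinite rate")
    if np.any(s > 1.0):
        raise ValueError("anchor survival fractions must be <= 1")
    y = -np.log(s)
    return float(np.dot(t, y) / np.dot(t, t))


def post_progression_death_prob(mean_pps: float) -> float:
    """Constant per-cycle death probability whose geometric mean sojourn
    equals the mean post-progression survival: ``min(1, 1/mean)`` months."""
    if mean_pps <= 0.0:
        raise ValueError(f"mean post-progression survival must be positive, got {mean_pps}")
    return min(1.0, 1.0 / mean_pps)


def nonresponder_death_profile(os12: float, boundary: int = 12) -> np.ndarray:
    """Conditional per-cycle death probabilities for the dying nonresponder
    stream, cycles 1..boundary.

    The within-year shape is exponential with the rate implied by the arm's
    12-month OS anchor, renormalised so cumulative death reaches the whole
    stream at the boundary; the final cycle's conditional probability is
    therefore exactly 1 (nonresponders who die do so within the first year).
    With ``os12 = 1`` the shape degenerates to uniform.
    """
    if boundary < 1:
        raise ValueError("boundary must be >= 1")
    if not 0.0 < os12 <= 1.0:
        raise ValueError(f"os12 must be in (0, 1], got {os12}")
    t = np.arange(boundary + 1, dtype=float)
    if os12 == 1.0:
        cum = t / boundary
    else:
        lam = rate_from_anchor(12.0, os12)
        cum = (1.0 - np.exp(-lam * t)) / (1.0 - math.exp(-lam * boundary))
    cond = np.empty(boundary)
    for k in range(1, boundary + 1):
        remaining = 1.0 - cum[k - 1]
        cond[k - 1] = 1.0 if remaining <= 0.0 else (cum[k] - cum[k - 1]) / remaining
    cond[-1] = 1.0
    return np.clip(cond, 0.0, 1.0)


def _row(
    p_disease: float, disease_target: int, state: int, q: float
) -> np.ndarray:
    """One transition-matrix row: disease event first, then other-cause
    death applied to those without a disease event this cycle."""
    row = np.zeros(N_INTERNAL)
    stay = 1.0 - p_disease
    row[disease_target] += p_disease
    row[DEAD_OTHER] += stay * q
    row[state] += stay * (1.0 - q)
    return row


def build_schedule(
    params: ParameterSet,
    regimen: Regimen | RegimenName,
    responder: bool,
    horizon: int | None = None,
) -> TransitionSchedule:
    """Assemble the per-cycle transition matrices for one decision-tree cell.

    The matrices cover all internal states, so responder and nonresponder
    cells of the same arm share identical dynamics and differ only in their
    starting state: responders begin progression-free on treatment,
    nonresponders begin split across the dying and progressing streams
    according to the arm's 12-month PFS/OS gap.
    """
    name = regimen if isinstance(regimen, RegimenName) else None
    if name is None:
        for key, reg in params.regimens.items():
            if reg is regimen:
                name = key
                break
        if name is None:
            raise ConfigurationError("regimen object not found in the parameter set")
    if name not in params.survival.arms:
        raise ConfigurationError(f"no survival anchors configured for arm {name.value}")
    arm = params.survival.arms[name]
    T = horizon if horizon is not None else params.economics.horizon_cycles
    if T < 1:
        raise ConfigurationError("horizon must be at least one cycle")

    q = params.mortality.schedule(T)

    lam = fit_exponential(arm.pfs_anchors)
    p_resp_prog = 1.0 - math.exp(-lam)
    p_pps = post_progression_death_prob(params.survival.mean_post_progression_survival)
    death_profile = nonresponder_death_profile(arm.os12)
    jump_cycle = int(round(params.survival.mean_time_to_progression_nonresp)) + 1
    delayed = params.survival.responder_progression_mode == "delayed12"

    mats = np.zeros((T, N_INTERNAL, N_INTERNAL))
    for t in range(1, T + 1):
        m = mats[t - 1]
        qt = q[t - 1]
        # responders on treatment
        p_prog = 0.0 if (delayed and t <= 12) else p_resp_prog
        m[RESP] = _row(p_prog, PROG, RESP, qt)
        # dying nonresponder stream: exhausted by cycle 12
        p_die = death_profile[t - 1] if t <= len(death_profile) else 1.0
        m[NR_DIE] = _row(p_die, DEAD_DISEASE, NR_DIE, qt)
        # progressing nonresponder stream: deterministic jump
        if t == jump_cycle:
            m[NR_PROG] = _row(1.0, PROG, NR_PROG, qt)
        else:
            m[NR_PROG] = _row(0.0, PROG, NR_PROG, qt)
        # progression state
        m[PROG] = _row(p_pps, DEAD_DISEASE, PROG, qt)
        # absorbing states
        m[DEAD_DISEASE, DEAD_DISEASE] = 1.0
        m[DEAD_OTHER, DEAD_OTHER] = 1.0

    init = np.zeros(N_INTERNAL)
    if responder:
        init[RESP] = 1.0
    else:
        p_death, p_progress = nonresponder_split(arm.pfs12, arm.os12)
        init[NR_DIE] = p_death
        init[NR_PROG] = p_progress

    return TransitionSchedule(matrices=mats, init_internal=init, regimen=name, responder=responder)
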