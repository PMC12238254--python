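"""Multi-objective reward components and the composite plan-quality score.

Four task rewards — functional, aesthetic, efficiency, stability — each in
[0, 1], are combined linearly with simplex weights.  Plan quality is
summarised by the TPQS composite: four 0-25 point components weighted with
the AHP-derived clinical priorities (0.30 function / 0.25 aesthetics /
0.25 efficiency / 0.20 stability) and mapped onto a 0-100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .state import PatientState

#: AHP-derived clinical priority weights (function, aesthetics, efficiency, stability)
AHP_WEIGHTS = (0.30, 0.25, 0.25, 0.20)

TASK_NAMES = ("functional", "aesthetic", "efficiency", "stability")


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class RewardVector:
    r_functional: float
    r_aesthetic: float
    r_efficiency: float
    r_stability: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r_functional, self.r_aesthetic,
                         self.r_efficiency, self.r_stability])

    def __post_init__(self):
        for name, v in zip(TASK_NAMES, self.as_array()):
            if not (0.0 <= v <= 1.0):
                raise ContractError(f"r_{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TaskWeights:
    w_functional: float = AHP_WEIGHTS[0]
    w_aesthetic: float = AHP_WEIGHTS[1]
    w_efficiency: float = AHP_WEIGHTS[2]
    w_stability: float = AHP_WEIGHTS[3]

    def as_array(self) -> np.ndarray:
        return np.array([self.w_functional, self.w_aesthetic,
                         self.w_efficiency, self.w_stability])

    def __post_init__(self):
        w = self.as_array()
        if np.any(w < 0):
            raise ContractError("task weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ContractError(f"task weights must sum to 1, got {w.sum()!r}")

    @classmethod
    def uniform(cls) -> "TaskWeights":
        return cls(0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class TPQSInput:
    """Quality components, each scored on 0-25 points."""
    q_function: float
    q_aesthetic: float
    q_efficiency: float
    q_stability: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q_function, self.q_aesthetic,
                         self.q_efficiency, self.q_stability])

    def __post_init__(self):
        for name, v in zip(("function", "aesthetic", "efficiency", "stability"),
                           self.as_array()):
            if not (0.0 <= v <= 25.0):
                raise ContractError(f"q_{name}={v} outside [0, 25] points")


# ----------------------------------------------------------------------
# per-step reward components
# ----------------------------------------------------------------------
#: appointment-interval bounds (weeks) used to normalise per-step time cost
INTERVAL_WEEKS = (4.0, 8.0)
MONTHS_PER_WEEK = 12.0 / 52.0


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def reward_components(s: PatientState, a, s_next: PatientState) -> RewardVector:
    """Evaluate the four task rewards for the transition s -> s_next under a.

    * functional: mean full-scale improvement of occlusal function, TMJ health
      and respiratory indices (each lives on [0, 1]).
    * aesthetic: full-scale improvement of facial harmony (0-10) plus a
      profile-balance proxy (ANB moving toward its ~2 deg norm, scaled per
      10 deg of correction).
    * efficiency: 1 minus the normalised per-step time cost and appointment
      burden; shorter recall intervals cost more visits.
    * stability: (1 - relapse risk) shaped by tissue adaptation.
    """
    fn, fn2 = s.functional, s_next.functional
    d_fn = np.array([fn2.occlusal_function - fn.occlusal_function,
                     fn2.tmj_health - fn.tmj_health,
                     fn2.respiratory - fn.respiratory])
    r_functional = _clip01(float(np.clip(d_fn, 0.0, 1.0).mean()))

    d_harmony = (s_next.soft_tissue.facial_harmony - s.soft_tissue.facial_harmony) / 10.0
    profile_gain = (abs(s.skeletal.anb - 2.0) - abs(s_next.skeletal.anb - 2.0)) / 10.0
    r_aesthetic = _clip01(d_harmony + 0.5 * max(0.0, profile_gain))

    interval = float(np.clip(getattr(a, "interval_weeks", INTERVAL_WEEKS[1]),
                             *INTERVAL_WEEKS))
    dt_months = interval * MONTHS_PER_WEEK
    time_cost = dt_months / (INTERVAL_WEEKS[1] * MONTHS_PER_WEEK)
    # visit burden: 4-week recall = 1 (max), 8-week recall = 0
    burden = (1.0 / interval - 1.0 / INTERVAL_WEEKS[1]) / (1.0 / INTERVAL_WEEKS[0] - 1.0 / INTERVAL_WEEKS[1])
    staged = getattr(a, "timing", "simultaneous") == "staged"
    r_efficiency = _clip01(1.0 - 0.45 * time_cost - 0.45 * burden - (0.1 if staged else 0.0))

    ts = s_next.treatment_status
    r_stability = _clip01((1.0 - ts.relapse_risk) * (0.5 + 0.5 * ts.tissue_adaptation))

    return RewardVector(r_functional, r_aesthetic, r_efficiency, r_stability)


def aggregate_reward(r: RewardVector, w: TaskWeights) -> float:
    """Scalarized reward sum_i w_i r_i; lies in [0, 1] for simplex weights."""
    return float(r.as_array() @ w.as_array())


# ----------------------------------------------------------------------
# TPQS composite and reported comparisons
# ----------------------------------------------------------------------
def compute_tpqs(q: TPQSInput, w: TaskWeights = TaskWeights()) -> float:
    """Composite treatment-plan quality score on the reported 0-100 scale.

    The weighted aggregate of 0-25 point components (simplex weights) lives on
    [0, 25]; the x4 factor maps it onto the 0-100 reporting scale without
    changing any relative comparison.
    """
    return float(4.0 * (q.as_array() @ w.as_array()))


def tpqs_from_state(state: PatientState, horizon_months: float = 36.0) -> TPQSInput:
    """Map a (final) patient state onto the four 0-25 point quality components."""
    fn = state.functional
    q_function = 25.0 * (fn.occlusal_function + fn.tmj_health + fn.respiratory) / 3.0
    q_aesthetic = 25.0 * state.soft_tissue.facial_harmony / 10.0
    ts = state.treatment_status
    q_efficiency = 25.0 * (1.0 - min(1.0, ts.elapsed_months / horizon_months))
    q_stability = 25.0 * (1.0 - ts.relapse_risk) * (0.5 + 0.5 * ts.tissue_adaptation)
    return TPQSInput(*(float(np.clip(v, 0.0, 25.0))
                       for v in (q_function, q_aesthetic, q_efficiency, q_stability)))


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def relative_improvement(new: float, ref: float) -> float:
    """Percent improvement of ``new`` over ``ref`` (one-decimal reporting)."""
    if ref <= 0:
        raise ValueError(f"reference score must be positive, got {ref}")
    return _round_half_away(100.0 * (new - ref) / ref)


def time_reduction(ref_minutes: float, new_minutes: float) -> float:
    """Percent reduction from ``ref_minutes`` to ``new_minutes`` (one decimal)."""
    if ref_minutes <= 0:
        raise ValueError(f"reference time must be positive, got {ref_minutes}")
    return _round_half_away(100.0 * (ref_minutes - new_minutes) / ref_minutes)
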