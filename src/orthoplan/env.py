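"""The treatment MDP: hybrid action space, biomechanical proxy dynamics,
episodic step/reset interface.

Dynamics are a first-order saturating linear-response model per state block:
commanded jaw movements are realised through an exponential-saturation curve
(diminishing returns for large per-step movements), dental alignment relaxes
toward the ideal at a rate driven by force-system effectiveness (diminishing
returns above a documented force threshold), soft-tissue harmony follows a
stated fraction of the skeletal correction, relapse risk rises with per-step
movement magnitude and falls with tissue adaptation, and healing indicators
(bone density, tissue adaptation) recover monotonically with time.  Additive
Gaussian noise (per-block scales, clipped back into range) models response
variability.  All coefficients live in :class:`EnvConfig` with documented
defaults; none are literature claims.

Geometry convention: fixed right-handed head-centred frame in mm;
sagittal = +anterior, vertical = +superior, transverse = +patient-left.
``jaw_move.sagittal`` commands the change in the maxillo-mandibular sagittal
relationship: positive values increase ANB (maxillary advancement and/or
mandibular setback), so class III correction uses positive sagittal commands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import rewards as _rewards
from .cohort import PatientRecord, occlusal_class_from_anb, sample_patient_state
from .rewards import RewardVector, TaskWeights, MONTHS_PER_WEEK
from .state import (
    DEFAULT_SCHEMA,
    MANDIBLE_SLICE,
    MAXILLA_SLICE,
    PatientState,
    validate_state,
)


class ContractViolation(ValueError):
    pass


class UsageError(RuntimeError):
    pass


APPLIANCES = ("brackets", "wires", "elastics")
SOFT_TECHNIQUES = ("VY_advancement", "reduction", "none")
TIMINGS = ("simultaneous", "staged")
PHASE_DECISIONS = ("proceed", "hold", "modify")

JAW_BOUNDS = {"sagittal": (-15.0, 15.0), "vertical": (-10.0, 10.0), "transverse": (-8.0, 8.0)}
FORCE_BOUNDS = (50.0, 300.0)   # g; magnitude 0 additionally encodes "no active appliance"
INTERVAL_BOUNDS = (4.0, 8.0)   # weeks


@dataclass
class TreatmentAction:
    """Hybrid discrete + continuous intervention for one treatment step."""

    sagittal_mm: float = 0.0
    vertical_mm: float = 0.0
    transverse_mm: float = 0.0
    force_g: float = 0.0
    force_dir: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    appliance: str = "brackets"
    soft_tissue_technique: str = "none"
    timing: str = "simultaneous"
    phase_decision: str = "hold"
    interval_weeks: float = 6.0

    def jaw_vector(self) -> np.ndarray:
        """(sagittal, transverse, vertical) -> frame (x, y, z) displacement, mm."""
        return np.array([self.sagittal_mm, self.transverse_mm, self.vertical_mm])

    def validate(self) -> None:
        for name, (lo, hi) in (("sagittal_mm", JAW_BOUNDS["sagittal"]),
                               ("vertical_mm", JAW_BOUNDS["vertical"]),
                               ("transverse_mm", JAW_BOUNDS["transverse"]),
                               ("interval_weeks", INTERVAL_BOUNDS)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ContractViolation(f"{name}={v} outside [{lo}, {hi}]")
        if self.force_g != 0.0 and not (FORCE_BOUNDS[0] <= self.force_g <= FORCE_BOUNDS[1]):
            raise ContractViolation(
                f"force_g={self.force_g} must be 0 or within {FORCE_BOUNDS}")
        d = np.asarray(self.force_dir, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ContractViolation("force_dir must have unit norm")
        for name, vocab in (("appliance", APPLIANCES),
                            ("soft_tissue_technique", SOFT_TECHNIQUES),
                            ("timing", TIMINGS),
                            ("phase_decision", PHASE_DECISIONS)):
            if getattr(self, name) not in vocab:
                raise ContractViolation(f"{name}={getattr(self, name)!r} not in {vocab}")


def clip_action(action: TreatmentAction) -> Tuple[TreatmentAction, Dict[str, float]]:
    """Clip an action into bounds; returns the clipped action and the clips applied."""
    clips: Dict[str, float] = {}

    def cl(name, v, lo, hi):
        c = float(np.clip(v, lo, hi))
        if c != v:
            clips[name] = v
        return c

    sag = cl("sagittal_mm", action.sagittal_mm, *JAW_BOUNDS["sagittal"])
    ver = cl("vertical_mm", action.vertical_mm, *JAW_BOUNDS["vertical"])
    tra = cl("transverse_mm", action.transverse_mm, *JAW_BOUNDS["transverse"])
    force = action.force_g
    if force != 0.0:
        force = cl("force_g", force, *FORCE_BOUNDS)
    interval = cl("interval_weeks", action.interval_weeks, *INTERVAL_BOUNDS)
    d = np.asarray(action.force_dir, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        d, norm = np.array([1.0, 0.0, 0.0]), 1.0
    if abs(norm - 1.0) > 1e-9:
        clips.setdefault("force_dir", float(norm))
    d = d / norm
    out = replace(action, sagittal_mm=sag, vertical_mm=ver, transverse_mm=tra,
                  force_g=force, force_dir=tuple(d), interval_weeks=interval)
    return out, clips


@dataclass
class EnvConfig:
    """Transition-model coefficients and episode settings (package conventions)."""

    horizon_steps: int = 28
    horizon_months: float = 36.0
    gamma: float = 0.99
    seed: int = 0
    # saturating skeletal response
    sat_move_mm: float = 8.0          # per-step saturation scale of realised movement
    bone_gain: float = 0.5            # realised fraction floor; + 0.5 * bone_density
    deg_per_mm: float = 0.5           # ANB change per realised sagittal mm
    anb_target: float = 2.0           # normal sagittal relationship, deg
    # dental response
    force_ref_g: float = 150.0        # diminishing-returns force threshold
    force_bonus: float = 0.2
    k_dental: float = 0.25            # alignment relaxation per month at unit effectiveness
    # soft tissue / functional
    harmony_target: float = 8.5
    soft_ratio: float = 0.6           # fraction of skeletal correction expressed in harmony
    k_functional: float = 0.5         # functional gain per unit correction activity
    # status dynamics
    k_relapse_up: float = 0.15
    k_relapse_down: float = 0.05      # x tissue_adaptation per month
    k_heal: float = 0.08              # bone density / adaptation recovery per month
    # phase gates
    gate_relapse_max: float = 0.45
    gate_bone_min: float = 0.55
    # additive noise scales (0 disables)
    noise_mm: float = 0.05
    noise_deg: float = 0.05
    noise_unit: float = 0.01
    noise_harmony: float = 0.05

    def validate(self) -> None:
        if self.horizon_steps < 1:
            raise ContractViolation(f"horizon_steps={self.horizon_steps} must be >= 1")
        if not (0.0 < self.gamma <= 1.0):
            raise ContractViolation(f"gamma={self.gamma} outside (0, 1]")
        for name in ("noise_mm", "noise_deg", "noise_unit", "noise_harmony"):
            if getattr(self, name) < 0:
                raise ContractViolation(f"{name} must be >= 0")


@dataclass
class StepOutcome:
    next_state: PatientState
    reward: RewardVector
    done: bool
    info: Dict


def _saturate(x: np.ndarray, scale: float) -> np.ndarray:
    """Odd saturating response: |out| <= scale, slope 1 at 0 (diminishing returns)."""
    return np.sign(x) * scale * (1.0 - np.exp(-np.abs(x) / scale))


def force_effectiveness(force_g: float, config: EnvConfig) -> float:
    """Dental response per unit time vs force; linear to the reference force,
    diminishing returns above it."""
    if force_g <= 0:
        return 0.0
    f0 = config.force_ref_g
    base = min(force_g, f0) / f0
    extra = config.force_bonus * (1.0 - math.exp(-max(force_g - f0, 0.0) / f0))
    return base + extra


def simulate_response(state: PatientState, action: TreatmentAction, dt_months: float,
                      params: EnvConfig) -> PatientState:
    """Deterministic noiseless transition core: Response(t) proxy.

    Raises :class:`ContractViolation` for out-of-bounds actions (callers are
    expected to clip first).
    """
    action.validate()
    s = state.copy()
    sk, de, st, fn, ts = s.skeletal, s.dental, s.soft_tissue, s.functional, s.treatment_status

    # --- skeletal: saturating realisation of the commanded jaw vector -----
    commanded = action.jaw_vector()
    realised = _saturate(commanded, params.sat_move_mm) * (
        params.bone_gain + (1.0 - params.bone_gain) * ts.bone_density)
    # positive sagittal = maxilla forward relative to mandible: split the
    # correction between the jaw landmark blocks
    sk.landmarks[MAXILLA_SLICE] += 0.5 * realised
    sk.landmarks[MANDIBLE_SLICE] -= 0.5 * realised
    anb_before = sk.anb
    sk.anb = float(sk.anb + params.deg_per_mm * realised[0])
    sk.snb = sk.sna - sk.anb
    sk.occlusal_class = occlusal_class_from_anb(sk.anb)
    move_mag = float(np.linalg.norm(realised))
    move_frac = move_mag / params.sat_move_mm

    # --- dental: alignment relaxes toward ideal at force-driven rate ------
    eff = force_effectiveness(action.force_g, params)
    if eff > 0.0:
        decay = math.exp(-params.k_dental * eff * dt_months)
        de.tooth_ang *= decay
        direction = np.asarray(action.force_dir)
        # positions drift toward the arch ideal along the commanded direction
        ideal_pull = (1.0 - decay) * 0.3
        de.tooth_pos += ideal_pull * direction * np.sign(
            -(de.tooth_pos @ direction))[:, None] * np.minimum(
                np.abs(de.tooth_pos @ direction), 1.0)[:, None]

    # --- soft tissue: harmony follows skeletal correction ------------------
    correction_gain = (abs(anb_before - params.anb_target)
                       - abs(sk.anb - params.anb_target)) / 10.0
    technique_bonus = 0.05 if action.soft_tissue_technique != "none" else 0.0
    harmony_step = (params.soft_ratio * max(0.0, correction_gain) + technique_bonus * move_frac)
    st.facial_harmony = float(np.clip(
        st.facial_harmony + harmony_step * (params.harmony_target - st.facial_harmony)
        * (10.0 / max(params.harmony_target, 1e-9)), 0.0, 10.0))

    # --- functional: improves with correction + alignment activity ---------
    activity = max(0.0, correction_gain) + 0.2 * eff * dt_months / 2.0
    if activity > 0.0:
        g = min(1.0, params.k_functional * activity)
        fn.occlusal_function = float(np.clip(fn.occlusal_function + g * (0.95 - fn.occlusal_function), 0, 1))
        fn.tmj_health = float(np.clip(fn.tmj_health + 0.6 * g * (0.95 - fn.tmj_health), 0, 1))
        fn.respiratory = float(np.clip(fn.respiratory + 0.4 * g * (0.95 - fn.respiratory), 0, 1))
        if st.facial_harmony > 7.0:
            st.lip_competence = 1

    # --- treatment status: relapse, healing, time ---------------------------
    ts.relapse_risk = float(np.clip(
        ts.relapse_risk + params.k_relapse_up * move_frac
        - params.k_relapse_down * ts.tissue_adaptation * dt_months, 0.0, 1.0))
    heal = params.k_heal * dt_months
    slow = 1.0 / (1.0 + move_frac)     # heavy movement slows healing
    ts.bone_density = float(np.clip(ts.bone_density + heal * slow * (1.0 - ts.bone_density), 0, 1))
    ts.tissue_adaptation = float(np.clip(
        ts.tissue_adaptation + heal * 1.5 * slow * (1.0 - ts.tissue_adaptation), 0, 1))
    ts.elapsed_months = float(ts.elapsed_months + dt_months)
    return s


def action_space_spec(task_type: str) -> dict:
    """Numeric bounds / categorical vocabularies for one treatment-task row."""
    specs = {
        "jaw": {"sagittal_mm": JAW_BOUNDS["sagittal"],
                "vertical_mm": JAW_BOUNDS["vertical"],
                "transverse_mm": JAW_BOUNDS["transverse"]},
        "dental": {"force_g": FORCE_BOUNDS, "force_dir": "unit 3-vector",
                   "appliance": APPLIANCES},
        "soft_tissue": {"technique": SOFT_TECHNIQUES, "timing": TIMINGS},
        "sequencing": {"phase_decision": PHASE_DECISIONS,
                       "interval_weeks": INTERVAL_BOUNDS},
    }
    try:
        return specs[task_type]
    except KeyError:
        raise KeyError(f"unknown task type {task_type!r}; expected one of {sorted(specs)}")


class TreatmentEnv:
    """Episodic treatment environment over one patient record.

    ``reset`` builds the pre-treatment state (phase 1, elapsed 0); ``step``
    clips the action, applies the deterministic response core over the
    commanded recall interval, adds seeded Gaussian response noise, scores the
    transition with the four task rewards, and terminates when phase 4
    completes or the episode exceeds its horizon.
    """

    def __init__(self, config: Optional[EnvConfig] = None,
                 weights: Optional[TaskWeights] = None):
        self.config = config or EnvConfig()
        self.config.validate()
        self.weights = weights or TaskWeights()
        self.state: Optional[PatientState] = None
        self._record: Optional[PatientRecord] = None
        self._rng = np.random.default_rng(self.config.seed)
        self._steps = 0
        self._done = True

    def reset(self, record: PatientRecord, seed: Optional[int] = None) -> PatientState:
        if seed is None:
            seed = self.config.seed
        self._rng = np.random.default_rng(np.random.SeedSequence((seed, record.enrollment_index)))
        self.state = sample_patient_state(record, DEFAULT_SCHEMA, seed=seed)
        self._record = record
        self._steps = 0
        self._done = False
        return self.state

    def step(self, action: TreatmentAction) -> StepOutcome:
        if self._done or self.state is None:
            raise UsageError("step() called on a finished episode; call reset() first")
        cfg = self.config
        action, clips = clip_action(action)
        dt = action.interval_weeks * MONTHS_PER_WEEK

        prev = self.state
        nxt = simulate_response(prev, action, dt, cfg)

        # seeded response noise, clipped back into valid ranges
        if cfg.noise_mm > 0:
            nxt.skeletal.landmarks += self._rng.normal(0, cfg.noise_mm, nxt.skeletal.landmarks.shape)
            nxt.dental.tooth_pos += self._rng.normal(0, cfg.noise_mm, nxt.dental.tooth_pos.shape)
            nxt.soft_tissue.thickness = np.clip(
                nxt.soft_tissue.thickness + self._rng.normal(0, cfg.noise_mm, nxt.soft_tissue.thickness.shape),
                1.0, 25.0)
        if cfg.noise_deg > 0:
            nxt.skeletal.anb = float(nxt.skeletal.anb + self._rng.normal(0, cfg.noise_deg))
            nxt.skeletal.snb = nxt.skeletal.sna - nxt.skeletal.anb
            nxt.skeletal.occlusal_class = occlusal_class_from_anb(nxt.skeletal.anb)
            nxt.dental.tooth_ang += self._rng.normal(0, cfg.noise_deg, nxt.dental.tooth_ang.shape)
        if cfg.noise_unit > 0:
            fb = nxt.functional
            fb.occlusal_function = float(np.clip(fb.occlusal_function + self._rng.normal(0, cfg.noise_unit), 0, 1))
            fb.tmj_health = float(np.clip(fb.tmj_health + self._rng.normal(0, cfg.noise_unit), 0, 1))
            fb.respiratory = float(np.clip(fb.respiratory + self._rng.normal(0, cfg.noise_unit), 0, 1))
        if cfg.noise_harmony > 0:
            nxt.soft_tissue.facial_harmony = float(np.clip(
                nxt.soft_tissue.facial_harmony + self._rng.normal(0, cfg.noise_harmony), 0, 10))

        # phase logic: advance on `proceed` only when stability gates pass
        ts = nxt.treatment_status
        phase_complete = False
        gates_ok = (ts.relapse_risk <= cfg.gate_relapse_max
                    and ts.bone_density >= cfg.gate_bone_min)
        if action.phase_decision == "proceed" and gates_ok:
            if ts.phase == 4:
                phase_complete = True
            else:
                ts.phase += 1

        reward = _rewards.reward_components(prev, action, nxt)
        self._steps += 1
        done = (phase_complete
                or self._steps >= cfg.horizon_steps
                or ts.elapsed_months >= cfg.horizon_months)
        self.state = nxt
        self._done = done
        info = {"clips": clips, "dt_months": dt, "gates_ok": gates_ok,
                "phase_complete": phase_complete, "steps": self._steps}
        return StepOutcome(next_state=nxt, reward=reward, done=done, info=info)
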