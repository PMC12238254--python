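"""Treatment-planning model objects.

:class:`TreatmentPlanner` is the model: it is built from a synthetic (or
user-supplied) cohort plus environment / reward / training configuration, and
``fit()`` trains the multi-task soft actor-critic planner, returning a
:class:`PlannerResults` carrying the learned parameters, the training log,
evaluation diagnostics and a ``summary()`` table.  Planning, simulation and
explanation hang off the results object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import agent as _agent
from .agent import (AgentParams, EncoderSpec, RandomActor, SACPolicyActor,
                    TaskEnv, TrainConfig, evaluate_policy, train)
from .cohort import CohortConfig, PatientRecord, sample_cohort
from .env import (APPLIANCES, PHASE_DECISIONS, SOFT_TECHNIQUES, TIMINGS,
                  EnvConfig, StepOutcome, TreatmentAction, TreatmentEnv)
from .rewards import RewardVector, TaskWeights, compute_tpqs, tpqs_from_state
from .state import FEATURE_DIM, PatientState

CONT_LOW = np.array([-15.0, -10.0, -8.0, 50.0, -1.0, -1.0, -1.0, 4.0])
CONT_HIGH = np.array([15.0, 10.0, 8.0, 300.0, 1.0, 1.0, 1.0, 8.0])
CAT_SIZES = [len(APPLIANCES), len(SOFT_TECHNIQUES), len(TIMINGS), len(PHASE_DECISIONS)]


def decode_action(cont_t: np.ndarray, cat_idx: np.ndarray) -> TreatmentAction:
    """Map normalized policy outputs ([-1,1]^8 + categorical indices) to a
    clinical action."""
    phys = CONT_LOW + (np.clip(cont_t, -1, 1) + 1.0) / 2.0 * (CONT_HIGH - CONT_LOW)
    d = phys[4:7]
    n = np.linalg.norm(d)
    d = d / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
    return TreatmentAction(
        sagittal_mm=float(phys[0]), vertical_mm=float(phys[1]),
        transverse_mm=float(phys[2]), force_g=float(phys[3]),
        force_dir=tuple(d),
        appliance=APPLIANCES[int(cat_idx[0])],
        soft_tissue_technique=SOFT_TECHNIQUES[int(cat_idx[1])],
        timing=TIMINGS[int(cat_idx[2])],
        phase_decision=PHASE_DECISIONS[int(cat_idx[3])],
        interval_weeks=float(phys[7]),
    )


@dataclass
class ObsNormalizer:
    mean: np.ndarray
    std: np.ndarray

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std

    @classmethod
    def fit(cls, records: Sequence[PatientRecord], env_config: EnvConfig,
            n_episodes: int = 5, seed: int = 0) -> "ObsNormalizer":
        """Feature statistics from short random-policy warm-up rollouts."""
        env = TreatmentEnv(env_config)
        rng = np.random.default_rng(seed)
        feats = []
        for ep in range(n_episodes):
            rec = records[ep % len(records)]
            state = env.reset(rec, seed=seed + ep)
            feats.append(state.feature_vector())
            for _ in range(env_config.horizon_steps):
                t = rng.uniform(-1, 1, size=8)
                idx = np.array([rng.integers(0, k) for k in CAT_SIZES])
                out = env.step(decode_action(t, idx))
                feats.append(out.next_state.feature_vector())
                if out.done:
                    break
        feats = np.array(feats)
        return cls(mean=feats.mean(axis=0), std=np.maximum(feats.std(axis=0), 1e-2))


class TreatmentTask(TaskEnv):
    """Agent-facing adapter over :class:`TreatmentEnv` and a cohort."""

    def __init__(self, records: Sequence[PatientRecord], env_config: EnvConfig,
                 normalizer: ObsNormalizer):
        self.records = list(records)
        self.env = TreatmentEnv(env_config)
        self.normalizer = normalizer
        self.obs_dim = FEATURE_DIM
        self.cont_dim = 8
        self.cat_sizes = list(CAT_SIZES)
        self._last_outcome: Optional[StepOutcome] = None

    def reset(self, seed: Optional[int] = None) -> np.ndarray:
        seed = 0 if seed is None else int(seed)
        rec = self.records[seed % len(self.records)]
        state = self.env.reset(rec, seed=seed)
        return self.normalizer(state.feature_vector())

    def step(self, cont_t, cat_idx):
        action = decode_action(np.asarray(cont_t), np.asarray(cat_idx))
        out = self.env.step(action)
        self._last_outcome = out
        return (self.normalizer(out.next_state.feature_vector()),
                out.reward.as_array(), out.done, out.info)


# ----------------------------------------------------------------------
# episode container used by planning/explanation
# ----------------------------------------------------------------------
@dataclass
class EpisodeStep:
    state: PatientState
    action: TreatmentAction
    reward: RewardVector
    next_state: PatientState
    info: Dict


@dataclass
class Episode:
    record_id: str
    steps: List[EpisodeStep]

    @property
    def final_state(self) -> PatientState:
        return self.steps[-1].next_state if self.steps else None  # type: ignore

    def tpqs(self, horizon_months: float = 36.0) -> float:
        return compute_tpqs(tpqs_from_state(self.final_state, horizon_months))


@dataclass
class PlanReport:
    """Recommended plan for one patient (all lengths mm, angles deg, time months)."""
    patient_id: str
    seed: int
    config_hash: str
    actions: List[Dict]
    predicted_trajectory: List[Dict]
    tpqs: float
    explanations: Dict = field(default_factory=dict)


def _config_hash(*objs) -> str:
    payload = json.dumps([_jsonable(o) for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    return obj


# ----------------------------------------------------------------------
# the model / results pair
# ----------------------------------------------------------------------
class TreatmentPlanner:
    """Multi-task RL treatment-planning model over a patient cohort.

    Parameters
    ----------
    records : cohort of patient records (synthetic or user-supplied).
    env_config, weights, train_config : environment dynamics, task weights
        (defaults to the AHP clinical priorities) and SAC training settings.
    """

    def __init__(self, records: Sequence[PatientRecord],
                 env_config: Optional[EnvConfig] = None,
                 weights: Optional[TaskWeights] = None,
                 train_config: Optional[TrainConfig] = None):
        if not records:
            raise ValueError("a non-empty cohort is required")
        self.records = list(records)
        self.env_config = env_config or EnvConfig()
        self.weights = weights or TaskWeights()
        self.train_config = train_config or TrainConfig()
        self.train_config.weights = self.weights
        self.normalizer = ObsNormalizer.fit(
            self.records, self.env_config, seed=self.train_config.seed)

    @classmethod
    def from_cohort_config(cls, cohort_config: CohortConfig, **kwargs) -> "TreatmentPlanner":
        return cls(sample_cohort(cohort_config), **kwargs)

    def make_task(self, records: Optional[Sequence[PatientRecord]] = None) -> TreatmentTask:
        return TreatmentTask(records or self.records, self.env_config, self.normalizer)

    def fit(self) -> "PlannerResults":
        params, log = train(self.make_task, self.train_config)
        return PlannerResults(self, params, log)


class PlannerResults:
    """Fitted planner: learned parameters, training log and diagnostics."""

    def __init__(self, model: TreatmentPlanner, params: AgentParams, log: List[Dict]):
        self.model = model
        self.params = params
        self.log = log
        self.config_hash = _config_hash(model.env_config, model.train_config)

    # -- evaluation ------------------------------------------------------
    def evaluate(self, n_episodes: int = 20, seed: int = 0,
                 deterministic: bool = True) -> Dict:
        task = self.model.make_task()
        return evaluate_policy(task, SACPolicyActor(self.params, deterministic),
                               n_episodes, seed, self.model.weights,
                               self.model.train_config.gamma)

    def random_baseline(self, n_episodes: int = 20, seed: int = 0) -> Dict:
        task = self.model.make_task()
        return evaluate_policy(task, RandomActor(task.cont_dim, task.cat_sizes),
                               n_episodes, seed, self.model.weights,
                               self.model.train_config.gamma)

    # -- planning --------------------------------------------------------
    def policy_sample(self, state: PatientState, seed: int = 0,
                      deterministic: bool = False) -> Tuple[TreatmentAction, float]:
        """Sample a clinical action (and its log-probability) for one state."""
        obs = self.model.normalizer(state.feature_vector())
        fwd = self.params.policy.forward(np.atleast_2d(obs))
        rng = np.random.default_rng(seed)
        t, _, idx, logp, _ = self.params.policy.sample(fwd, rng, deterministic)
        return decode_action(t[0], idx[0]), float(logp[0])

    def simulate(self, record: PatientRecord, seed: int = 0,
                 deterministic: bool = True) -> Episode:
        """Roll the fitted policy over one patient's treatment episode."""
        env = TreatmentEnv(self.model.env_config)
        state = env.reset(record, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 31337)))
        steps: List[EpisodeStep] = []
        for _ in range(self.model.env_config.horizon_steps):
            obs = self.model.normalizer(state.feature_vector())
            fwd = self.params.policy.forward(np.atleast_2d(obs))
            t, _, idx, _, _ = self.params.policy.sample(fwd, rng, deterministic)
            action = decode_action(t[0], idx[0])
            out = env.step(action)
            steps.append(EpisodeStep(state, action, out.reward, out.next_state, out.info))
            state = out.next_state
            if out.done:
                break
        return Episode(record_id=record.id, steps=steps)

    def plan(self, record: PatientRecord, seed: int = 0) -> PlanReport:
        """Deterministic recommended action sequence with predicted outcomes."""
        ep = self.simulate(record, seed=seed, deterministic=True)
        actions, traj = [], []
        elapsed = 0.0
        for st in ep.steps:
            a = st.action
            actions.append({
                "month": round(elapsed, 2),
                "jaw_move_mm": {"sagittal": a.sagittal_mm, "vertical": a.vertical_mm,
                                "transverse": a.transverse_mm},
                "force_g": a.force_g, "appliance": a.appliance,
                "soft_tissue_technique": a.soft_tissue_technique,
                "timing": a.timing, "phase_decision": a.phase_decision,
                "interval_weeks": a.interval_weeks,
            })
            elapsed = st.next_state.treatment_status.elapsed_months
            traj.append({
                "month": round(elapsed, 2),
                "ANB_deg": st.next_state.skeletal.anb,
                "facial_harmony_0_10": st.next_state.soft_tissue.facial_harmony,
                "relapse_risk_0_1": st.next_state.treatment_status.relapse_risk,
                "phase": st.next_state.treatment_status.phase,
                "reward": dict(zip(("functional", "aesthetic", "efficiency", "stability"),
                                   st.reward.as_array().round(4).tolist())),
            })
        return PlanReport(patient_id=record.id, seed=seed,
                          config_hash=self.config_hash, actions=actions,
                          predicted_trajectory=traj,
                          tpqs=ep.tpqs(self.model.env_config.horizon_months))

    # -- reporting -------------------------------------------------------
    def summary(self, n_episodes: int = 20, seed: int = 0) -> str:
        ev = self.evaluate(n_episodes, seed)
        base = self.random_baseline(n_episodes, seed)
        ep_tpqs = self._episode_tpqs()
        lines = [
            "Multi-task SAC treatment planner",
            "=" * 54,
            f"cohort size:              {len(self.model.records)}",
            f"task weights (F/A/E/S):   {tuple(float(v) for v in self.model.weights.as_array().round(3))}",
            f"training steps:           {self.log[-1]['step'] if self.log else 0}",
            f"config hash:              {self.config_hash}",
            "-" * 54,
            f"mean scalarized return:   {ev['scalarized'].mean():8.4f} "
            f"(sd {ev['scalarized'].std():.4f}, n={n_episodes})",
            f"random-policy baseline:   {base['scalarized'].mean():8.4f} "
            f"(sd {base['scalarized'].std():.4f})",
            f"per-task returns (F/A/E/S): "
            f"{tuple(float(v) for v in ev['per_task'].mean(axis=0).round(4))}",
            f"mean episode TPQS (0-100): {np.mean(ep_tpqs):7.2f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def _episode_tpqs(self) -> List[float]:
        # TPQS needs the final clinical state, so run fresh deterministic
        # episodes over a small record sample rather than decoding stored
        # (normalised) observations.
        vals: List[float] = []
        for i, rec in enumerate(self.model.records[: min(10, len(self.model.records))]):
            ep = self.simulate(rec, seed=i, deterministic=True)
            vals.append(ep.tpqs(self.model.env_config.horizon_months))
        return vals

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for name, net in (("policy", self.params.policy),
                          ("critic1", self.params.critic1),
                          ("critic2", self.params.critic2),
                          ("target1", self.params.target1),
                          ("target2", self.params.target2)):
            for i, p in enumerate(net.flat()):
                arrays[f"{name}_{i}"] = p
        arrays["log_alpha"] = self.params.log_alpha
        arrays["norm_mean"] = self.model.normalizer.mean
        arrays["norm_std"] = self.model.normalizer.std
        arrays["meta"] = np.frombuffer(json.dumps({
            "obs_dim": self.params.obs_dim, "cont_dim": self.params.cont_dim,
            "cat_sizes": self.params.cat_sizes, "config_hash": self.config_hash,
        }).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def load(path, model: TreatmentPlanner) -> "PlannerResults":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        rng = np.random.default_rng(0)
        params = AgentParams.init(meta["obs_dim"], meta["cont_dim"], meta["cat_sizes"],
                                  model.train_config.encoder, rng)
        for name, net in (("policy", params.policy), ("critic1", params.critic1),
                          ("critic2", params.critic2), ("target1", params.target1),
                          ("target2", params.target2)):
            for i, p in enumerate(net.flat()):
                p[...] = data[f"{name}_{i}"]
        params.log_alpha[...] = data["log_alpha"]
        model.normalizer = ObsNormalizer(mean=data["norm_mean"], std=data["norm_std"])
        res = PlannerResults(model, params, log=[])
        return res
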