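"""Evaluation metrics, chronological partitioning, policy comparison.

Implements the forecast-accuracy formula (one minus mean relative absolute
error over outcome measures), the normalised efficiency index
Q_outcome / (dT x C_resources), the clinician confidence score (weighted sum
of explainability, evidence strength and consensus alignment), chronological
train/validation/test partitioning, and a paired permutation-test comparison
harness for policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agent import (RandomActor, TaskEnv, multitask_return, per_task_returns,
                    rollout)
from .cohort import PatientRecord
from .rewards import TaskWeights, compute_tpqs, relative_improvement, tpqs_from_state


class DomainError(ValueError):
    pass


# ----------------------------------------------------------------------
# outcome forecast accuracy
# ----------------------------------------------------------------------
@dataclass
class OutcomePanel:
    """Predicted vs actual outcome values over evaluation times.

    ``predicted`` and ``actual`` are DataFrames indexed by evaluation time t
    with one column per outcome measure (m columns, matched shapes).
    """
    predicted: pd.DataFrame
    actual: pd.DataFrame

    def __post_init__(self):
        if list(self.predicted.columns) != list(self.actual.columns) or \
                list(self.predicted.index) != list(self.actual.index):
            raise ValueError("predicted and actual panels must share index and columns")

    @property
    def m(self) -> int:
        return self.predicted.shape[1]


def accuracy_at(panel: OutcomePanel, t) -> float:
    """Forecast accuracy 1 - (1/m) sum_j |yhat_j(t) - y_j(t)| / y_j(t).

    Equals 1 for exact predictions and may be negative for large errors.
    A zero actual value makes the formula undefined and raises
    :class:`DomainError` naming the outcome (no silent epsilon smoothing).
    """
    yhat = panel.predicted.loc[t].to_numpy(dtype=float)
    y = panel.actual.loc[t].to_numpy(dtype=float)
    zero = np.flatnonzero(y == 0.0)
    if zero.size:
        names = [str(panel.actual.columns[i]) for i in zero]
        raise DomainError(f"actual value is zero at t={t!r} for outcome(s) {names}; "
                          "accuracy is undefined there")
    return float(1.0 - np.mean(np.abs(yhat - y) / y))


def efficiency_index(q_outcome: float, dt_treatment: float, c_resources: float = 1.0) -> float:
    """Normalised efficiency Q_outcome / (dT_treatment x C_resources).

    ``c_resources`` is dimensionless with default 1.0.
    """
    if dt_treatment <= 0:
        raise DomainError(f"dt_treatment={dt_treatment} must be > 0")
    if c_resources <= 0:
        raise DomainError(f"c_resources={c_resources} must be > 0")
    return float(q_outcome / (dt_treatment * c_resources))


def confidence_score(explainability: float, evidence_strength: float,
                     consensus_alignment: float,
                     alpha: float = 1.0 / 3.0, beta: float = 1.0 / 3.0,
                     gamma: float = 1.0 / 3.0) -> float:
    """Clinician confidence: alpha*Explainability + beta*EvidenceStrength +
    gamma*ConsensusAlignment with simplex weights; result in [0, 1]."""
    for name, v in (("explainability", explainability),
                    ("evidence_strength", evidence_strength),
                    ("consensus_alignment", consensus_alignment)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{name}={v} outside [0, 1]")
    w = np.array([alpha, beta, gamma])
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise DomainError(f"weights {w.tolist()} must be non-negative and sum to 1")
    return float(w @ [explainability, evidence_strength, consensus_alignment])


# ----------------------------------------------------------------------
# chronological partition
# ----------------------------------------------------------------------
@dataclass
class SplitSpec:
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    key: str = "enrollment_index"

    def __post_init__(self):
        f = np.asarray(self.fractions, float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions {self.fractions} must be non-negative and sum to 1")


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def partition_chronological(records: Sequence[PatientRecord],
                            spec: SplitSpec = SplitSpec()
                            ) -> Tuple[List[PatientRecord], List[PatientRecord], List[PatientRecord]]:
    """Sort by the chronological key ascending and split train/validation/test.

    Sizes are round-half-away-from-zero of fraction x N for train and
    validation; the test split absorbs the remainder so the sizes sum to N.
    Earliest records go to training so later evaluation uses only
    historically available data.
    """
    ordered = sorted(records, key=lambda r: getattr(r, spec.key))
    n = len(ordered)
    n_train = _round_half_away(spec.fractions[0] * n)
    n_val = _round_half_away(spec.fractions[1] * n)
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return (list(ordered[:n_train]), list(ordered[n_train:n_train + n_val]),
            list(ordered[n_train + n_val:]))


# ----------------------------------------------------------------------
# paired permutation test
# ----------------------------------------------------------------------
def paired_permutation_test(x: np.ndarray, y: np.ndarray, n_resamples: int = 2000,
                            seed: int = 0, alternative: str = "two-sided") -> float:
    """Sign-flip permutation test on the mean of paired differences.

    p = (1 + #{resampled |T*| >= |T|}) / (1 + B); suitable for matched-seed
    episode returns with no normality assumption.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    if d.size == 0:
        raise ValueError("empty samples")
    rng = np.random.default_rng(seed)
    t_obs = d.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, d.size))
    t_star = (signs * d).mean(axis=1)
    if alternative == "two-sided":
        count = int(np.sum(np.abs(t_star) >= abs(t_obs)))
    elif alternative == "greater":
        count = int(np.sum(t_star >= t_obs))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + count) / (1 + n_resamples))


# ----------------------------------------------------------------------
# policy comparison harness
# ----------------------------------------------------------------------
@dataclass
class PolicyComparison:
    table: pd.DataFrame
    pairwise: Dict[Tuple[str, str], Dict[str, float]]
    n_episodes: int
    bonferroni_m: int


METRIC_NAMES = ("scalarized", "functional", "aesthetic", "efficiency",
                "stability", "tpqs")


def compare_policies(env_factory: Callable[[], TaskEnv],
                     policies: Dict[str, object], n_episodes: int = 50,
                     seed: int = 0, weights: Optional[TaskWeights] = None,
                     gamma: float = 0.99, n_resamples: int = 2000) -> PolicyComparison:
    """Evaluate >= 2 policies on matched episode seeds and compare them.

    Per policy: mean +/- sd scalarized return, per-task returns and episode
    TPQS (from the final clinical state when the environment exposes one).
    Pairwise: percent relative improvement of mean scalarized return and a
    paired sign-flip permutation p-value, Bonferroni-corrected across the
    reported metrics.
    """
    if len(policies) < 2:
        raise ValueError("at least two policies are required")
    weights = weights or TaskWeights()
    per_policy: Dict[str, Dict[str, np.ndarray]] = {}
    for name, actor in policies.items():
        env = env_factory()
        rng = np.random.default_rng(np.random.SeedSequence((seed, 555)))
        scal, tasks, tpqs = [], [], []
        for ep in range(n_episodes):
            traj = rollout(env, actor, rng, episode_seed=seed * 100_003 + ep)
            scal.append(multitask_return([traj], weights, gamma))
            tasks.append(per_task_returns([traj], gamma))
            inner = getattr(env, "env", None)
            if inner is not None and getattr(inner, "state", None) is not None:
                horizon = getattr(inner.config, "horizon_months", 36.0)
                tpqs.append(compute_tpqs(tpqs_from_state(inner.state, horizon)))
            else:
                tpqs.append(np.nan)
        per_policy[name] = {"scalarized": np.array(scal),
                            "per_task": np.array(tasks), "tpqs": np.array(tpqs)}

    rows = []
    for name, res in per_policy.items():
        row = {"policy": name,
               "mean_return": res["scalarized"].mean(),
               "sd_return": res["scalarized"].std(ddof=1)}
        for i, t in enumerate(("functional", "aesthetic", "efficiency", "stability")):
            row[f"return_{t}"] = res["per_task"][:, i].mean()
        has_tpqs = np.any(np.isfinite(res["tpqs"]))
        row["mean_tpqs"] = float(np.nanmean(res["tpqs"])) if has_tpqs else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("policy")

    m = len(METRIC_NAMES)
    pairwise: Dict[Tuple[str, str], Dict[str, float]] = {}
    names = list(per_policy)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = per_policy[a]["scalarized"], per_policy[b]["scalarized"]
            ref = xb.mean()
            impr = relative_improvement(xa.mean(), ref) if ref > 0 else np.nan
            p_raw = paired_permutation_test(xa, xb, n_resamples, seed=seed + 13)
            pairwise[(a, b)] = {
                "relative_improvement_pct": impr,
                "p_value": p_raw,
                "p_value_bonferroni": min(1.0, p_raw * m),
            }
    return PolicyComparison(table=table, pairwise=pairwise,
                            n_episodes=n_episodes, bonferroni_m=m)
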