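"""Explainability layer over the trained planner.

Four complementary views of a policy or value model:

* **Feature attribution** — a permutation-sampling Shapley estimator (exact
  for additive models, completeness enforced by residual redistribution) and
  a finite-difference integrated-gradients variant; scores can be aggregated
  by anatomical block (skeletal / dental / soft tissue) for at-a-glance
  rendering.
* **Surrogate rules** — a bounded-depth decision tree distilled from the
  policy's discrete action component, with fidelity reported on held-out
  states.
* **Counterfactuals** — minimal clinically-bounded state modifications that
  flip a target predicate, found by greedy feasibility search plus
  coordinate-descent cost polishing with multi-start.
* **Trajectory explanation** — phase-segmented treatment narratives naming
  the dominant reward component per phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.tree import DecisionTreeClassifier, export_text

from .rewards import TASK_NAMES, TaskWeights

COMPLETENESS_TOL = 1e-6


class EvaluationError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# feature attribution
# ----------------------------------------------------------------------
@dataclass
class Attribution:
    contributions: np.ndarray
    feature_names: List[str]
    baseline: np.ndarray
    state: np.ndarray
    target_value: float
    baseline_value: float

    @property
    def completeness_residual(self) -> float:
        return float(self.target_value - self.baseline_value - self.contributions.sum())

    def top_k(self, k: int = 10) -> List[Tuple[str, float]]:
        order = np.argsort(-np.abs(self.contributions))[:k]
        return [(self.feature_names[i], float(self.contributions[i])) for i in order]

    def by_block(self) -> Dict[str, float]:
        """Aggregate scores over anatomical blocks (45/52/40 schema + status)."""
        c = self.contributions
        blocks = {"skeletal": c[:45].sum(), "dental": c[45:97].sum(),
                  "soft_tissue": c[97:137].sum()}
        if len(c) > 137:
            blocks["status"] = c[137:].sum()
        return {k: float(v) for k, v in blocks.items()}


def _batch_eval(model: Callable, X: np.ndarray) -> np.ndarray:
    out = np.asarray(model(X), dtype=float).reshape(-1)
    if not np.all(np.isfinite(out)):
        raise EvaluationError("model returned non-finite values during attribution")
    return out


def attribute(model: Callable[[np.ndarray], np.ndarray], state: np.ndarray,
              baseline: np.ndarray, n_samples: int = 256, seed: int = 0,
              feature_names: Optional[Sequence[str]] = None) -> Attribution:
    """Shapley-sampling attribution of ``model(state) - model(baseline)``.

    ``model`` must accept a (N, d) batch and return N scalars.  ``n_samples``
    random feature permutations are averaged; each permutation's marginal
    contributions telescope exactly, so completeness holds up to numerical
    dust, which is redistributed equally.  Deterministic given ``seed``.
    """
    x = np.asarray(state, dtype=float)
    b = np.asarray(baseline, dtype=float)
    d = x.size
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(d)]
    f_x = float(_batch_eval(model, x[None, :])[0])
    f_b = float(_batch_eval(model, b[None, :])[0])
    contrib = np.zeros(d)
    if not np.allclose(x, b):
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            perm = rng.permutation(d)
            # points[k] = baseline with features perm[:k+1] set to x
            pts = np.tile(b, (d, 1))
            mask = np.zeros(d, dtype=bool)
            for k, j in enumerate(perm):
                mask[j] = True
                pts[k, mask] = x[mask]
            vals = _batch_eval(model, pts)
            prev = np.concatenate([[f_b], vals[:-1]])
            contrib[perm] += vals - prev
        contrib /= n_samples
        residual = (f_x - f_b) - contrib.sum()
        contrib += residual / d
    return Attribution(contributions=contrib, feature_names=names, baseline=b,
                       state=x, target_value=f_x, baseline_value=f_b)


def integrated_gradients(model: Callable, state: np.ndarray, baseline: np.ndarray,
                         n_steps: int = 64, fd_eps: float = 1e-4) -> np.ndarray:
    """Straight-line integrated gradients with central finite differences."""
    x = np.asarray(state, float)
    b = np.asarray(baseline, float)
    d = x.size
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    grads = np.zeros(d)
    eye = np.eye(d) * fd_eps
    for a in alphas:
        z = b + a * (x - b)
        plus = _batch_eval(model, z[None, :] + eye)
        minus = _batch_eval(model, z[None, :] - eye)
        grads += (plus - minus) / (2.0 * fd_eps)
    return (x - b) * grads / n_steps


# ----------------------------------------------------------------------
# surrogate decision rules
# ----------------------------------------------------------------------
@dataclass
class SurrogateRules:
    tree: DecisionTreeClassifier
    feature_names: List[str]
    class_names: List[str]
    fidelity: float
    n_train: int
    n_heldout: int
    trivial: bool = False

    def rules_text(self) -> str:
        if self.trivial:
            return f"always -> {self.class_names[0]} (constant policy)"
        return export_text(self.tree, feature_names=self.feature_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(np.atleast_2d(X))


MIN_SURROGATE_SAMPLE = 50


def fit_surrogate(policy: Callable[[np.ndarray], np.ndarray], states: np.ndarray,
                  max_depth: int = 3, seed: int = 0,
                  feature_names: Optional[Sequence[str]] = None,
                  class_names: Optional[Sequence[str]] = None) -> SurrogateRules:
    """Distill the policy's discrete decision into a bounded-depth tree.

    ``policy`` maps a (N, d) state batch to N integer action labels.  The
    sample is split in half; the tree is fitted on the first half and
    fidelity (agreement with the policy) is reported on the held-out half.
    """
    states = np.asarray(states, float)
    if states.shape[0] < MIN_SURROGATE_SAMPLE:
        raise ValueError(f"need >= {MIN_SURROGATE_SAMPLE} states, got {states.shape[0]}")
    y = np.asarray(policy(states)).astype(int)
    names = (list(feature_names) if feature_names is not None
             else [f"f{i}" for i in range(states.shape[1])])
    half = states.shape[0] // 2
    X_tr, y_tr = states[:half], y[:half]
    X_ho, y_ho = states[half:], y[half:]
    classes = sorted(set(y.tolist()))
    cls_names = (list(class_names) if class_names is not None
                 else [str(c) for c in classes])
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X_tr, y_tr)
    fidelity = float((tree.predict(X_ho) == y_ho).mean())
    trivial = len(set(y_tr.tolist())) == 1
    return SurrogateRules(tree=tree, feature_names=names, class_names=cls_names,
                          fidelity=fidelity, n_train=half,
                          n_heldout=states.shape[0] - half, trivial=trivial)


# ----------------------------------------------------------------------
# counterfactual search
# ----------------------------------------------------------------------
@dataclass
class Counterfactual:
    original: np.ndarray
    modified: np.ndarray
    deltas: np.ndarray
    achieved_margin: float
    sparsity: int
    distance: float
    feasible: bool
    feature_names: List[str] = field(default_factory=list)

    def changed_features(self) -> List[Tuple[str, float, float]]:
        out = []
        for i, d in enumerate(self.deltas):
            if d != 0.0:
                name = self.feature_names[i] if self.feature_names else f"f{i}"
                out.append((name, float(self.original[i]), float(self.modified[i])))
        return out


def _cost(delta: np.ndarray, weights: np.ndarray, lam: float) -> float:
    return float(np.abs(delta) @ weights + lam * np.count_nonzero(delta))


def counterfactual(margin: Callable[[np.ndarray], float], state: np.ndarray,
                   bounds: Tuple[np.ndarray, np.ndarray],
                   lam_sparsity: float = 0.0,
                   mutable_mask: Optional[np.ndarray] = None,
                   grids: Optional[List[np.ndarray]] = None,
                   distance_weights: Optional[np.ndarray] = None,
                   n_starts: int = 8, max_rounds: int = 30,
                   seed: int = 0, feature_names: Optional[Sequence[str]] = None
                   ) -> Counterfactual:
    """Minimal bounded modification of ``state`` achieving ``margin(x) >= 0``.

    Minimises weighted-L1 distance + ``lam_sparsity`` x (#changed features)
    subject to the clinical bounds and an immutability mask, by greedy
    feasibility search over per-feature candidate grids followed by
    coordinate-descent cost polishing, restarted from ``n_starts`` seeds.
    Returns an infeasibility result (``feasible=False``) rather than raising
    when no feasible point is found within the search budget.
    """
    x0 = np.asarray(state, float)
    lo, hi = (np.asarray(b, float) for b in bounds)
    if np.any(x0 < lo - 1e-12) or np.any(x0 > hi + 1e-12):
        raise ValueError("bounds must contain the query state")
    d = x0.size
    mutable = (np.ones(d, bool) if mutable_mask is None
               else np.asarray(mutable_mask, bool))
    w = (np.asarray(distance_weights, float) if distance_weights is not None
         else 1.0 / np.maximum(hi - lo, 1e-9))
    if grids is None:
        grids = [np.linspace(lo[j], hi[j], 41) for j in range(d)]
    rng = np.random.default_rng(seed)

    m0 = float(margin(x0))
    if m0 >= 0.0:
        return Counterfactual(x0, x0.copy(), np.zeros(d), m0, 0, 0.0, True,
                              list(feature_names or []))

    def polish(x: np.ndarray) -> np.ndarray:
        # coordinate descent: shrink cost while staying feasible
        x = x.copy()
        for _ in range(max_rounds):
            improved = False
            for j in np.flatnonzero(mutable):
                best_c = _cost(x - x0, w, lam_sparsity)
                best_v = x[j]
                for v in list(grids[j]) + [x0[j]]:
                    if v == x[j]:
                        continue
                    cand = x.copy()
                    cand[j] = v
                    c = _cost(cand - x0, w, lam_sparsity)
                    if c < best_c - 1e-12 and margin(cand) >= 0.0:
                        best_c, best_v = c, v
                        improved = True
                x[j] = best_v
            if not improved:
                break
        return x

    best: Optional[np.ndarray] = None
    best_cost = np.inf
    for start in range(n_starts):
        x = x0.copy()
        if start > 0:
            # perturb a random subset of mutable features to random grid points
            k = int(rng.integers(1, max(2, mutable.sum() // 2 + 1)))
            for j in rng.choice(np.flatnonzero(mutable), size=min(k, mutable.sum()),
                                replace=False):
                x[j] = rng.choice(grids[j])
        # greedy feasibility: best margin-gain per unit cost
        for _ in range(max_rounds):
            m = float(margin(x))
            if m >= 0.0:
                break
            best_ratio, best_move = 0.0, None
            for j in np.flatnonzero(mutable):
                base_cost = _cost(x - x0, w, lam_sparsity)
                for v in grids[j]:
                    if v == x[j]:
                        continue
                    cand = x.copy()
                    cand[j] = v
                    gain = float(margin(cand)) - m
                    dc = _cost(cand - x0, w, lam_sparsity) - base_cost
                    if gain <= 0:
                        continue
                    ratio = gain / max(dc, 1e-9) if dc > 0 else np.inf
                    if ratio > best_ratio:
                        best_ratio, best_move = ratio, (j, v)
            if best_move is None:
                break
            x[best_move[0]] = best_move[1]
        if float(margin(x)) >= 0.0:
            x = polish(x)
            c = _cost(x - x0, w, lam_sparsity)
            if c < best_cost:
                best, best_cost = x, c

    if best is None:
        return Counterfactual(x0, x0.copy(), np.zeros(d), m0, 0, np.inf, False,
                              list(feature_names or []))
    delta = best - x0
    return Counterfactual(x0, best, delta, float(margin(best)),
                          int(np.count_nonzero(delta)), float(np.abs(delta) @ w),
                          True, list(feature_names or []))


# ----------------------------------------------------------------------
# trajectory explanation
# ----------------------------------------------------------------------
@dataclass
class PhaseSegment:
    phase: int
    start: int                 # step index, inclusive
    end: int                   # step index, inclusive
    dominant_component: str
    component_totals: Dict[str, float]
    key_actions: List[str]


@dataclass
class TrajectoryExplanation:
    segments: List[PhaseSegment]
    justifications: List[Dict]

    def __post_init__(self):
        phases = [s.phase for s in self.segments]
        if phases != sorted(phases):
            raise ValueError("phase ids must be non-decreasing across segments")


def _action_summary(action) -> str:
    parts = []
    jv = np.array([action.sagittal_mm, action.vertical_mm, action.transverse_mm])
    if np.abs(jv).max() > 1.0:
        ax = ["sagittal", "vertical", "transverse"][int(np.abs(jv).argmax())]
        parts.append(f"{ax} jaw correction {jv[np.abs(jv).argmax()]:+.1f} mm")
    if action.force_g > 0:
        parts.append(f"{action.force_g:.0f} g force ({action.appliance})")
    parts.append(f"{action.phase_decision}/{action.interval_weeks:.0f}w")
    return ", ".join(parts)


def explain_trajectory(episode, w: TaskWeights) -> TrajectoryExplanation:
    """Segment one treatment episode by phase and name each phase's dominant
    reward component (argmax of the weight-scaled component sums)."""
    steps = episode.steps
    if not steps:
        raise ValueError("non-empty trajectory required")
    wv = w.as_array()
    segments: List[PhaseSegment] = []
    justifications: List[Dict] = []
    seg_start = 0
    cur_phase = steps[0].state.treatment_status.phase
    sums = np.zeros(4)

    def close(end_idx: int):
        weighted = sums * wv
        dom = TASK_NAMES[int(np.argmax(weighted))]
        actions = [_action_summary(steps[i].action)
                   for i in range(seg_start, min(seg_start + 2, end_idx + 1))]
        segments.append(PhaseSegment(
            phase=cur_phase, start=seg_start, end=end_idx,
            dominant_component=dom,
            component_totals=dict(zip(TASK_NAMES, (sums * wv).round(6).tolist())),
            key_actions=actions))

    for i, st in enumerate(steps):
        phase = st.state.treatment_status.phase
        if phase != cur_phase:
            close(i - 1)
            seg_start, cur_phase, sums = i, phase, np.zeros(4)
        r = st.reward.as_array()
        sums += r
        justifications.append({
            "step": i, "phase": phase,
            "action": _action_summary(st.action),
            "reward_components": dict(zip(TASK_NAMES, r.round(6).tolist())),
            "driver": TASK_NAMES[int(np.argmax(r * wv))],
        })
    close(len(steps) - 1)
    return TrajectoryExplanation(segments=segments, justifications=justifications)


# ----------------------------------------------------------------------
# report rendering
# ----------------------------------------------------------------------
AUDIENCES = ("specialist", "interdisciplinary")


def render_report(explanation, audience: str = "specialist",
                  top_k: int = 10) -> Tuple[str, Dict]:
    """Deterministic template rendering: numeric tables for specialists,
    ranked qualitative statements for interdisciplinary communication."""
    if audience not in AUDIENCES:
        raise ValueError(f"unknown audience {audience!r}; expected one of {AUDIENCES}")
    if isinstance(explanation, Attribution):
        return _render_attribution(explanation, audience, top_k)
    if isinstance(explanation, SurrogateRules):
        return _render_rules(explanation, audience)
    if isinstance(explanation, Counterfactual):
        return _render_counterfactual(explanation, audience)
    if isinstance(explanation, TrajectoryExplanation):
        return _render_trajectory(explanation, audience)
    raise TypeError(f"cannot render {type(explanation).__name__}")


def _render_attribution(att: Attribution, audience: str, top_k: int):
    ranked = att.top_k(top_k)
    doc = {"kind": "attribution", "audience": audience,
           "target_value": att.target_value, "baseline_value": att.baseline_value,
           "top_features": [{"feature": n, "score": s} for n, s in ranked],
           "by_block": att.by_block()}
    lines = ["# Feature attribution", ""]
    if audience == "specialist":
        lines.append(f"target {att.target_value:.4f} vs baseline {att.baseline_value:.4f}")
        lines.append("")
        lines.append("| feature | contribution |")
        lines.append("|---|---|")
        lines += [f"| {n} | {s:+.4f} |" for n, s in ranked]
        lines.append("")
        lines.append("Block totals: " + ", ".join(
            f"{k}: {v:+.4f}" for k, v in att.by_block().items()))
    else:
        for rank, (n, s) in enumerate(ranked, 1):
            direction = "supports" if s >= 0 else "argues against"
            lines.append(f"{rank}. {n} {direction} the recommendation")
    return "\n".join(lines), doc


def _render_rules(rules: SurrogateRules, audience: str):
    doc = {"kind": "rules", "audience": audience, "fidelity": rules.fidelity,
           "trivial": rules.trivial, "rules": rules.rules_text()}
    lines = ["# Surrogate decision rules", ""]
    if audience == "specialist":
        lines.append(f"fidelity on {rules.n_heldout} held-out states: {rules.fidelity:.3f}")
        lines.append("```")
        lines.append(rules.rules_text())
        lines.append("```")
    else:
        lines.append("The planner's discrete choices follow simple clinical rules "
                     f"(agreement {rules.fidelity:.0%} on unseen cases).")
    return "\n".join(lines), doc


def _render_counterfactual(cf: Counterfactual, audience: str):
    changed = cf.changed_features()
    doc = {"kind": "counterfactual", "audience": audience, "feasible": cf.feasible,
           "sparsity": cf.sparsity, "distance": cf.distance,
           "changes": [{"feature": n, "from": a, "to": b} for n, a, b in changed]}
    lines = ["# Counterfactual scenario", ""]
    if not cf.feasible:
        lines.append("No biologically feasible modification achieves the requested "
                     "outcome within clinical bounds.")
    elif not changed:
        lines.append("No modification needed: the current state already satisfies "
                     "the requested outcome.")
    elif audience == "specialist":
        lines.append(f"{cf.sparsity} feature(s) changed, weighted-L1 distance "
                     f"{cf.distance:.4f}, achieved margin {cf.achieved_margin:+.4f}")
        lines.append("")
        lines.append("| feature | from | to |")
        lines.append("|---|---|---|")
        lines += [f"| {n} | {a:.3f} | {b:.3f} |" for n, a, b in changed]
    else:
        for n, a, b in changed:
            verb = "increase" if b > a else "decrease"
            lines.append(f"- {verb} {n} to reach the alternative outcome")
    return "\n".join(lines), doc


def _render_trajectory(tx: TrajectoryExplanation, audience: str):
    doc = {"kind": "trajectory", "audience": audience,
           "segments": [{"phase": s.phase, "steps": [s.start, s.end],
                         "dominant": s.dominant_component,
                         "totals": s.component_totals} for s in tx.segments]}
    lines = ["# Treatment trajectory", ""]
    for s in tx.segments:
        if audience == "specialist":
            lines.append(f"Phase {s.phase} (steps {s.start}-{s.end}): dominant "
                         f"objective = {s.dominant_component}; totals "
                         + ", ".join(f"{k}={v:.3f}" for k, v in s.component_totals.items()))
            lines += [f"  - {a}" for a in s.key_actions]
        else:
            lines.append(f"Phase {s.phase}: focused on the {s.dominant_component} "
                         "objective.")
    return "\n".join(lines), doc
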