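"""Multi-task soft actor-critic planner.

The planner optimises a scalarized multi-objective return with an
entropy-regularised off-policy actor-critic:

* **Vector critics.**  Twin critics each output a 4-vector of task values
  (functional, aesthetic, efficiency, stability); targets and losses are per
  task, and the policy maximises the weight-scalarized element-wise minimum
  of the twins (clipped double-Q).
* **Shared + task-specific encoders.**  Each critic encodes the state with a
  shared trunk followed by per-task feature heads; task value heads consume
  the task features together with the action.
* **Hybrid actions.**  Continuous sub-actions come from a tanh-squashed
  Gaussian head mapped into their clinical bounds; categorical sub-actions
  come from softmax heads.  Critics consume categorical *probability*
  vectors (one-hot for replayed samples), which keeps the actor loss fully
  reparameterized; the categorical entropy enters the soft targets
  analytically.
* **Auto-tuned temperature** toward a configured entropy target.

Determinism: bit-exact reproducibility is promised for serial CPU execution
with fixed seeds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import (Adam, Params, mlp_backward, mlp_forward, mlp_init, softmax,
                  softmax_vjp)
from .rewards import TaskWeights

N_TASKS = 4
LOG2PI = float(np.log(2.0 * np.pi))
LS_MIN, LS_MAX = -5.0, 2.0
_TANH_EPS = 1e-6


class TrainingError(RuntimeError):
    pass


@dataclass
class EncoderSpec:
    """Shared trunk + per-task feature heads (layer widths)."""
    shared_layers: List[int] = field(default_factory=lambda: [64, 64])
    task_specific_layers: List[List[int]] = field(
        default_factory=lambda: [[32]] * N_TASKS)
    activation: str = "tanh"

    def __post_init__(self):
        if not self.shared_layers:
            raise ValueError("at least one shared layer is required")
        if len(self.task_specific_layers) != N_TASKS:
            raise ValueError(f"one task head per reward component ({N_TASKS}) required")


@dataclass
class TrainConfig:
    gamma: float = 0.99
    lr: float = 1e-3
    lr_alpha: float = 3e-3
    batch_size: int = 128
    replay_capacity: int = 100_000
    total_steps: int = 50_000
    start_steps: int = 1_000
    update_every: int = 2
    tau: float = 0.005                     # target-network soft-update rate
    alpha_init: float = 0.2
    auto_alpha: bool = True
    entropy_target: Optional[float] = None  # default: -cont_dim (or 0.2*sum(log K))
    weights: TaskWeights = field(default_factory=TaskWeights)
    seed: int = 0
    eval_every: int = 2_000
    eval_episodes: int = 5
    encoder: EncoderSpec = field(default_factory=EncoderSpec)

    def validate(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma={self.gamma} outside (0, 1]")
        for name in ("lr", "lr_alpha", "batch_size", "replay_capacity", "total_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ----------------------------------------------------------------------
# trunk helpers: MLP whose *output* also passes through the activation
# ----------------------------------------------------------------------
def _trunk_forward(params: Params, x: np.ndarray, act: str):
    y, cache = mlp_forward(params, x, act)
    h = np.tanh(y) if act == "tanh" else np.maximum(y, 0.0)
    return h, (cache, y, h)


def _trunk_backward(params: Params, tcache, dh: np.ndarray, act: str):
    cache, y, h = tcache
    dy = dh * (1.0 - h * h) if act == "tanh" else dh * (y > 0)
    return mlp_backward(params, cache, dy, act)


# ----------------------------------------------------------------------
# state encoder: phi(s) = [h_shared, h_task-specific]
# ----------------------------------------------------------------------
class Encoder:
    """Shared trunk over state features plus per-task feature heads."""

    def __init__(self, obs_dim: int, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.obs_dim = obs_dim
        self.trunk = mlp_init([obs_dim] + spec.shared_layers, rng, spec.activation)
        self.task_heads = [
            mlp_init([spec.shared_layers[-1]] + layers, rng, spec.activation)
            for layers in spec.task_specific_layers]

    @property
    def shared_dim(self) -> int:
        return self.spec.shared_layers[-1]

    @property
    def task_dims(self) -> List[int]:
        return [layers[-1] for layers in self.spec.task_specific_layers]

    def forward(self, obs: np.ndarray):
        h_sh, tcache = _trunk_forward(self.trunk, obs, self.spec.activation)
        tasks, caches = [], []
        for head in self.task_heads:
            h_i, c = _trunk_forward(head, h_sh, self.spec.activation)
            tasks.append(h_i)
            caches.append(c)
        return h_sh, tasks, (tcache, caches)

    def backward(self, cache, dh_sh: np.ndarray, dtasks: Sequence[np.ndarray]):
        tcache, caches = cache
        grads: Params = []
        d_accum = dh_sh.copy()
        head_grads = []
        for head, c, dt in zip(self.task_heads, caches, dtasks):
            g, dh = _trunk_backward(head, c, dt, self.spec.activation)
            head_grads.append(g)
            d_accum += dh
        trunk_grads, dobs = _trunk_backward(self.trunk, tcache, d_accum, self.spec.activation)
        grads = trunk_grads
        for g in head_grads:
            grads = grads + g
        return grads, dobs

    def flat(self) -> Params:
        out = list(self.trunk)
        for head in self.task_heads:
            out += head
        return out


def encode_state(features: np.ndarray, spec: EncoderSpec, encoder: Encoder
                 ) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Evaluate phi(s): (shared features, per-task feature blocks).

    Deterministic; output dimensions follow the spec.  Raises on a feature /
    encoder shape mismatch.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != encoder.obs_dim:
        raise ValueError(f"feature dim {x.shape[1]} != encoder obs_dim {encoder.obs_dim}")
    if encoder.spec.shared_layers != spec.shared_layers:
        raise ValueError("encoder parameters do not match the requested spec")
    h_sh, tasks, _ = encoder.forward(x)
    return h_sh[0], [t[0] for t in tasks]


# ----------------------------------------------------------------------
# policy
# ----------------------------------------------------------------------
class Policy:
    """Squashed-Gaussian continuous heads + categorical heads over a shared trunk."""

    def __init__(self, obs_dim: int, cont_dim: int, cat_sizes: Sequence[int],
                 spec: EncoderSpec, rng: np.random.Generator):
        self.obs_dim, self.cont_dim = obs_dim, cont_dim
        self.cat_sizes = list(cat_sizes)
        self.act = spec.activation
        self.trunk = mlp_init([obs_dim] + spec.shared_layers, rng, self.act)
        h = spec.shared_layers[-1]
        self.mu = mlp_init([h, cont_dim], rng) if cont_dim else []
        self.ls = mlp_init([h, cont_dim], rng) if cont_dim else []
        self.cats = [mlp_init([h, k], rng) for k in self.cat_sizes]

    def flat(self) -> Params:
        out = list(self.trunk) + list(self.mu) + list(self.ls)
        for c in self.cats:
            out += c
        return out

    def forward(self, obs: np.ndarray):
        h, tcache = _trunk_forward(self.trunk, obs, self.act)
        out: Dict = {"h": h, "tcache": tcache}
        if self.cont_dim:
            mu, mu_c = mlp_forward(self.mu, h)
            raw, ls_c = mlp_forward(self.ls, h)
            tr = np.tanh(raw)
            log_std = LS_MIN + 0.5 * (LS_MAX - LS_MIN) * (tr + 1.0)
            out.update(mu=mu, raw=raw, tr=tr, log_std=log_std,
                       mu_cache=mu_c, ls_cache=ls_c)
        logits, probs, caches = [], [], []
        for cat in self.cats:
            z, c = mlp_forward(cat, h)
            logits.append(z)
            probs.append(softmax(z))
            caches.append(c)
        out.update(logits=logits, probs=probs, cat_caches=caches)
        return out

    def sample(self, fwd: Dict, rng: Optional[np.random.Generator],
               deterministic: bool = False):
        """Draw (t, probs, cat_idx, logp, eps) from a forward pass.

        ``t`` is the squashed continuous action in [-1, 1]^d; ``logp`` is the
        joint log-density: Gaussian-with-tanh correction for the continuous
        part plus the negative categorical entropies (the relaxed categorical
        term used throughout training).
        """
        B = fwd["h"].shape[0]
        if self.cont_dim:
            if deterministic:
                eps = np.zeros((B, self.cont_dim))
            else:
                eps = rng.standard_normal((B, self.cont_dim))
            std = np.exp(fwd["log_std"])
            u = fwd["mu"] + std * eps
            t = np.tanh(u)
            logp_cont = (-0.5 * eps ** 2 - fwd["log_std"] - 0.5 * LOG2PI
                         - np.log(1.0 - t ** 2 + _TANH_EPS)).sum(axis=1)
        else:
            eps = np.zeros((B, 0))
            t = np.zeros((B, 0))
            logp_cont = np.zeros(B)
        ent_cat = np.zeros(B)
        idx = []
        for p in fwd["probs"]:
            ent_cat += -(p * np.log(p + 1e-12)).sum(axis=1)
            if deterministic:
                idx.append(p.argmax(axis=1))
            else:
                cum = p.cumsum(axis=1)
                r = rng.random((B, 1))
                idx.append((r > cum).sum(axis=1))
        logp = logp_cont - ent_cat
        return t, fwd["probs"], np.stack(idx, axis=1) if idx else np.zeros((B, 0), int), logp, eps

    def backward(self, fwd: Dict, dmu, dlog_std, dlogits_list) -> Params:
        """Backprop head gradients into a flat gradient list."""
        dh = np.zeros_like(fwd["h"])
        grads: Params = []
        if self.cont_dim:
            draw = dlog_std * 0.5 * (LS_MAX - LS_MIN) * (1.0 - fwd["tr"] ** 2)
            g_mu, dh_mu = mlp_backward(self.mu, fwd["mu_cache"], dmu)
            g_ls, dh_ls = mlp_backward(self.ls, fwd["ls_cache"], draw)
            dh += dh_mu + dh_ls
        else:
            g_mu, g_ls = [], []
        g_cats: Params = []
        for cat, cache, dz in zip(self.cats, fwd["cat_caches"], dlogits_list):
            g, dh_c = mlp_backward(cat, cache, dz)
            g_cats += g
            dh += dh_c
        g_trunk, _ = _trunk_backward(self.trunk, fwd["tcache"], dh, self.act)
        return list(g_trunk) + list(g_mu) + list(g_ls) + g_cats


# ----------------------------------------------------------------------
# vector critic
# ----------------------------------------------------------------------
class Critic:
    """Q_theta(s, a) = [Q^1..Q^4]; shared state trunk, task features, value heads."""

    def __init__(self, obs_dim: int, act_dim: int, spec: EncoderSpec,
                 rng: np.random.Generator, head_hidden: int = 32):
        self.encoder = Encoder(obs_dim, spec, rng)
        self.act_dim = act_dim
        self.spec = spec
        self.heads = [
            mlp_init([d + act_dim, head_hidden, 1], rng, spec.activation)
            for d in self.encoder.task_dims]

    def flat(self) -> Params:
        out = self.encoder.flat()
        for h in self.heads:
            out += h
        return out

    def forward(self, obs: np.ndarray, act: np.ndarray):
        h_sh, tasks, enc_cache = self.encoder.forward(obs)
        qs, caches = [], []
        for h_i, head in zip(tasks, self.heads):
            x = np.concatenate([h_i, act], axis=1)
            q, c = mlp_forward(head, x, self.spec.activation)
            qs.append(q[:, 0])
            caches.append((c, h_i.shape[1]))
        return np.stack(qs, axis=1), (enc_cache, caches)

    def backward(self, cache, dq: np.ndarray):
        """Returns (flat grads, d action)."""
        enc_cache, caches = cache
        dtasks, head_grads = [], []
        da = None
        for i, (head, (c, tdim)) in enumerate(zip(self.heads, caches)):
            g, dx = mlp_backward(head, c, dq[:, i:i + 1], self.spec.activation)
            head_grads.append(g)
            dtasks.append(dx[:, :tdim])
            da = dx[:, tdim:] if da is None else da + dx[:, tdim:]
        B = dq.shape[0]
        enc_grads, _ = self.encoder.backward(
            enc_cache, np.zeros((B, self.encoder.shared_dim)), dtasks)
        grads = enc_grads
        for g in head_grads:
            grads = grads + g
        return grads, da


# ----------------------------------------------------------------------
# agent parameters & spec operations
# ----------------------------------------------------------------------
@dataclass
class AgentParams:
    policy: Policy
    critic1: Critic
    critic2: Critic
    target1: Critic
    target2: Critic
    log_alpha: np.ndarray             # scalar array
    obs_dim: int
    cont_dim: int
    cat_sizes: List[int]

    @classmethod
    def init(cls, obs_dim: int, cont_dim: int, cat_sizes: Sequence[int],
             spec: EncoderSpec, rng: np.random.Generator,
             alpha_init: float = 0.2) -> "AgentParams":
        act_dim = cont_dim + int(sum(cat_sizes))
        policy = Policy(obs_dim, cont_dim, cat_sizes, spec, rng)
        c1 = Critic(obs_dim, act_dim, spec, rng)
        c2 = Critic(obs_dim, act_dim, spec, rng)
        return cls(policy=policy, critic1=c1, critic2=c2,
                   target1=copy.deepcopy(c1), target2=copy.deepcopy(c2),
                   log_alpha=np.array(np.log(alpha_init)),
                   obs_dim=obs_dim, cont_dim=cont_dim, cat_sizes=list(cat_sizes))

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha))


def q_vector(obs: np.ndarray, act_vec: np.ndarray, params: AgentParams) -> np.ndarray:
    """Element-wise minimum of the twin critics' task-value vectors."""
    obs = np.atleast_2d(obs)
    act_vec = np.atleast_2d(act_vec)
    q1, _ = params.critic1.forward(obs, act_vec)
    q2, _ = params.critic2.forward(obs, act_vec)
    out = np.minimum(q1, q2)
    return out[0] if out.shape[0] == 1 else out


def scalarize(q: np.ndarray, w: TaskWeights) -> float:
    """Linear scalarization sum_i w_i q_i."""
    return float(np.asarray(q) @ w.as_array())


def action_to_vec(cont_t: np.ndarray, cat_idx: np.ndarray,
                  cat_sizes: Sequence[int]) -> np.ndarray:
    """Replay encoding: squashed continuous part + one-hot categorical parts."""
    parts = [np.atleast_2d(cont_t)]
    cat_idx = np.atleast_2d(cat_idx)
    for j, k in enumerate(cat_sizes):
        oh = np.zeros((cat_idx.shape[0], k))
        oh[np.arange(cat_idx.shape[0]), cat_idx[:, j]] = 1.0
        parts.append(oh)
    return np.concatenate(parts, axis=1)


# ----------------------------------------------------------------------
# replay buffer
# ----------------------------------------------------------------------
class ReplayBuffer:
    def __init__(self, capacity: int, obs_dim: int, act_dim: int):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim))
        self.act = np.zeros((capacity, act_dim))
        self.rew = np.zeros((capacity, N_TASKS))
        self.nxt = np.zeros((capacity, obs_dim))
        self.done = np.zeros(capacity)
        self.size = 0
        self.ptr = 0

    def push(self, obs, act, rew, nxt, done):
        i = self.ptr
        self.obs[i], self.act[i], self.rew[i], self.nxt[i], self.done[i] = \
            obs, act, rew, nxt, float(done)
        self.ptr = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, self.size, size=batch_size)
        return (self.obs[idx], self.act[idx], self.rew[idx],
                self.nxt[idx], self.done[idx])


# ----------------------------------------------------------------------
# SAC update
# ----------------------------------------------------------------------
class Optimizers:
    def __init__(self, params: AgentParams, config: TrainConfig):
        self.policy = Adam(params.policy.flat(), lr=config.lr)
        self.c1 = Adam(params.critic1.flat(), lr=config.lr)
        self.c2 = Adam(params.critic2.flat(), lr=config.lr)
        self.alpha = Adam([params.log_alpha.reshape(1)], lr=config.lr_alpha)


def _entropy_target(config: TrainConfig, cont_dim: int, cat_sizes: Sequence[int]) -> float:
    if config.entropy_target is not None:
        return config.entropy_target
    if cont_dim > 0:
        return -float(cont_dim)
    return 0.2 * float(np.sum(np.log(cat_sizes)))


def sac_update(batch, params: AgentParams, config: TrainConfig,
               opt: Optimizers, rng: np.random.Generator) -> Dict[str, float]:
    """One gradient step on critics, policy and temperature; targets soft-updated.

    Raises :class:`TrainingError` on non-finite losses.
    """
    obs, act, rew, nxt, done = batch
    B = obs.shape[0]
    w = config.weights.as_array()
    alpha = params.alpha
    gamma = config.gamma

    # ---- critic targets ---------------------------------------------------
    fwd_n = params.policy.forward(nxt)
    t_n, probs_n, _, logp_n, _ = params.policy.sample(fwd_n, rng)
    a_n = np.concatenate([t_n] + list(probs_n), axis=1)
    q1t, _ = params.target1.forward(nxt, a_n)
    q2t, _ = params.target2.forward(nxt, a_n)
    qt = np.minimum(q1t, q2t)
    y = rew + gamma * (1.0 - done)[:, None] * (qt - alpha * logp_n[:, None])

    # ---- critic update ----------------------------------------------------
    critic_losses = []
    for critic, adam in ((params.critic1, opt.c1), (params.critic2, opt.c2)):
        q, cache = critic.forward(obs, act)
        err = q - y
        critic_losses.append(float((err ** 2).sum(axis=1).mean()))
        grads, _ = critic.backward(cache, 2.0 * err / B)
        adam.step(critic.flat(), grads)

    # ---- policy update ----------------------------------------------------
    fwd = params.policy.forward(obs)
    t, probs, _, logp, eps = params.policy.sample(fwd, rng)
    a_pi = np.concatenate([t] + list(probs), axis=1)
    q1, c1_cache = params.critic1.forward(obs, a_pi)
    q2, c2_cache = params.critic2.forward(obs, a_pi)
    qmin = np.minimum(q1, q2)
    policy_loss = float((alpha * logp - qmin @ w).mean())

    mask1 = (q1 <= q2).astype(float)
    da = np.zeros_like(a_pi)
    for critic, cache, mask in ((params.critic1, c1_cache, mask1),
                                (params.critic2, c2_cache, 1.0 - mask1)):
        dq = w[None, :] * mask          # the 1/B of the batch mean is applied below
        _, da_c = critic.backward(cache, dq)
        da += da_c

    cd = params.policy.cont_dim
    if cd:
        da_t = da[:, :cd]
        std = np.exp(fwd["log_std"])
        one_m_t2 = 1.0 - t ** 2
        # d logp / d u for the tanh-Gaussian
        dlogp_du = 2.0 * t * one_m_t2 / (one_m_t2 + _TANH_EPS)
        # dL/du = alpha * dlogp/du - dQbar/du  (dQbar/du = dQbar/dt * (1-t^2))
        dL_du = (alpha * dlogp_du - da_t * one_m_t2) / B
        dmu = dL_du
        dlog_std = dL_du * std * eps + (alpha * -1.0) / B * np.ones_like(std)
    else:
        dmu = np.zeros((B, 0))
        dlog_std = np.zeros((B, 0))

    dlogits = []
    off = cd
    for p in probs:
        k = p.shape[1]
        da_p = da[:, off:off + k]
        # dL/dp = alpha * d(-H)/dp - dQbar/dp
        dL_dp = (alpha * (np.log(p + 1e-12) + 1.0) - da_p) / B
        dlogits.append(softmax_vjp(p, dL_dp))
        off += k

    pgrads = params.policy.backward(fwd, dmu, dlog_std, dlogits)
    opt.policy.step(params.policy.flat(), pgrads)

    # ---- temperature ------------------------------------------------------
    target_h = _entropy_target(config, cd, params.cat_sizes)
    alpha_loss = 0.0
    if config.auto_alpha:
        dlog_alpha = -float((logp + target_h).mean())
        alpha_loss = float(-params.log_alpha * (logp + target_h).mean())
        opt.alpha.step([params.log_alpha.reshape(1)],
                       [np.array([dlog_alpha])])

    # ---- polyak target update --------------------------------------------
    tau = config.tau
    for src, dst in ((params.critic1, params.target1), (params.critic2, params.target2)):
        for ps, pd in zip(src.flat(), dst.flat()):
            pd *= (1.0 - tau)
            pd += tau * ps

    diag = {"critic1_loss": critic_losses[0], "critic2_loss": critic_losses[1],
            "policy_loss": policy_loss, "alpha": params.alpha,
            "alpha_loss": alpha_loss, "mean_logp": float(logp.mean())}
    if not all(np.isfinite(v) for v in diag.values()):
        raise TrainingError(f"non-finite training diagnostics: {diag}")
    return diag


# ----------------------------------------------------------------------
# environment protocol, policies, rollouts
# ----------------------------------------------------------------------
class TaskEnv:
    """Protocol for agent-facing environments.

    Attributes: ``obs_dim``, ``cont_dim``, ``cat_sizes``.
    Methods: ``reset(seed) -> obs``; ``step(cont_t, cat_idx) ->
    (obs, reward_vec4, done, info)``.
    """

    obs_dim: int
    cont_dim: int
    cat_sizes: List[int]

    def reset(self, seed: Optional[int] = None) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def step(self, cont_t, cat_idx):  # pragma: no cover
        raise NotImplementedError


class SACPolicyActor:
    """Thin actor over trained parameters implementing .act(obs, rng, deterministic)."""

    def __init__(self, params: AgentParams, deterministic: bool = True):
        self.params = params
        self.deterministic = deterministic

    def act(self, obs: np.ndarray, rng: np.random.Generator):
        fwd = self.params.policy.forward(np.atleast_2d(obs))
        t, probs, idx, logp, _ = self.params.policy.sample(
            fwd, rng, deterministic=self.deterministic)
        return t[0], idx[0], float(logp[0])


class RandomActor:
    """Uniform random hybrid actions (baseline policy)."""

    def __init__(self, cont_dim: int, cat_sizes: Sequence[int]):
        self.cont_dim = cont_dim
        self.cat_sizes = list(cat_sizes)

    def act(self, obs: np.ndarray, rng: np.random.Generator):
        t = rng.uniform(-1.0, 1.0, size=self.cont_dim)
        idx = np.array([rng.integers(0, k) for k in self.cat_sizes])
        return t, idx, 0.0


@dataclass
class Transition:
    obs: np.ndarray
    cont_t: np.ndarray
    cat_idx: np.ndarray
    reward: np.ndarray            # 4-vector
    next_obs: np.ndarray
    done: bool
    info: Dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Ordered transitions of one episode; ``done`` only at the final tuple."""
    steps: List[Transition]

    def rewards(self) -> np.ndarray:
        return np.array([s.reward for s in self.steps])

    def __post_init__(self):
        for s in self.steps[:-1]:
            if s.done:
                raise ValueError("done=True before the final transition")


def rollout(env: TaskEnv, actor, rng: np.random.Generator,
            episode_seed: Optional[int] = None, max_steps: int = 10_000) -> Trajectory:
    obs = env.reset(seed=episode_seed)
    steps: List[Transition] = []
    for _ in range(max_steps):
        t, idx, _ = actor.act(obs, rng)
        nxt, rew, done, info = env.step(t, idx)
        steps.append(Transition(obs, t, idx, np.asarray(rew, float), nxt, done, info))
        obs = nxt
        if done:
            break
    return Trajectory(steps)


def multitask_return(trajectories: Sequence[Trajectory], w: TaskWeights,
                     gamma: float) -> float:
    """Empirical J(pi): mean over trajectories of sum_t gamma^t sum_i w_i r_{i,t}."""
    if not trajectories:
        raise ValueError("at least one trajectory required")
    wv = w.as_array()
    vals = []
    for traj in trajectories:
        r = traj.rewards()
        disc = gamma ** np.arange(len(r))
        vals.append(float((disc * (r @ wv)).sum()))
    return float(np.mean(vals))


def per_task_returns(trajectories: Sequence[Trajectory], gamma: float) -> np.ndarray:
    out = []
    for traj in trajectories:
        r = traj.rewards()
        disc = gamma ** np.arange(len(r))
        out.append((disc[:, None] * r).sum(axis=0))
    return np.mean(out, axis=0)


def evaluate_policy(env: TaskEnv, actor, n_episodes: int, seed: int,
                    weights: TaskWeights, gamma: float) -> Dict[str, np.ndarray]:
    """Per-episode scalarized and per-task discounted returns under fixed seeds."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 977)))
    scal, tasks, trajs = [], [], []
    for ep in range(n_episodes):
        traj = rollout(env, actor, rng, episode_seed=seed * 100_003 + ep)
        scal.append(multitask_return([traj], weights, gamma))
        tasks.append(per_task_returns([traj], gamma))
        trajs.append(traj)
    return {"scalarized": np.array(scal), "per_task": np.array(tasks),
            "trajectories": trajs}


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------
def train(env_factory: Callable[[], TaskEnv], config: TrainConfig
          ) -> Tuple[AgentParams, List[Dict]]:
    """End-to-end seeded SAC training; returns (params, evaluation log)."""
    config.validate()
    env = env_factory()
    eval_env = env_factory()
    rng = np.random.default_rng(config.seed)
    params = AgentParams.init(env.obs_dim, env.cont_dim, env.cat_sizes,
                              config.encoder, rng, config.alpha_init)
    opt = Optimizers(params, config)
    act_dim = env.cont_dim + int(sum(env.cat_sizes))
    buf = ReplayBuffer(config.replay_capacity, env.obs_dim, act_dim)

    log: List[Dict] = []
    episode = 0
    obs = env.reset(seed=config.seed)
    random_actor = RandomActor(env.cont_dim, env.cat_sizes)
    for step in range(1, config.total_steps + 1):
        if step <= config.start_steps:
            t, idx, _ = random_actor.act(obs, rng)
        else:
            fwd = params.policy.forward(np.atleast_2d(obs))
            ts, _, idxs, _, _ = params.policy.sample(fwd, rng)
            t, idx = ts[0], idxs[0]
        nxt, rew, done, _ = env.step(t, idx)
        buf.push(obs, action_to_vec(t, idx, env.cat_sizes)[0], rew, nxt, done)
        obs = nxt
        if done:
            episode += 1
            obs = env.reset(seed=config.seed + episode)

        if step > config.start_steps and step % config.update_every == 0:
            batch = buf.sample(config.batch_size, rng)
            diag = sac_update(batch, params, config, opt, rng)
        else:
            diag = None

        if step % config.eval_every == 0 or step == config.total_steps:
            ev = evaluate_policy(eval_env, SACPolicyActor(params), config.eval_episodes,
                                 seed=config.seed + 7919, weights=config.weights,
                                 gamma=config.gamma)
            row = {"step": step,
                   "mean_return": float(ev["scalarized"].mean()),
                   "per_task": ev["per_task"].mean(axis=0).tolist()}
            if diag:
                row.update({k: diag[k] for k in ("critic1_loss", "policy_loss", "alpha")})
            log.append(row)
    return params, log
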