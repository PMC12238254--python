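"""Multi-task SAC: critics, scalarization, sampling, updates, training loop."""

import copy

import numpy as np
import pytest

from orthoplan.agent import (AgentParams, EncoderSpec, Optimizers, RandomActor,
                             ReplayBuffer, TaskEnv, TrainConfig, Trajectory,
                             Transition, action_to_vec, encode_state,
                             multitask_return, per_task_returns, q_vector,
                             rollout, sac_update, scalarize, train)
from orthoplan.planner import CAT_SIZES, CONT_HIGH, CONT_LOW, decode_action
from orthoplan.rewards import TaskWeights

SPEC = EncoderSpec(shared_layers=[8, 8], task_specific_layers=[[4]] * 4)


@pytest.fixture()
def params():
    rng = np.random.default_rng(0)
    return AgentParams.init(obs_dim=6, cont_dim=3, cat_sizes=[3, 2], spec=SPEC, rng=rng)


class TestEncoder:
    def test_shapes_and_determinism(self, params):
        x = np.random.default_rng(1).normal(size=6)
        enc = params.critic1.encoder
        shared, tasks = encode_state(x, SPEC, enc)
        shared2, tasks2 = encode_state(x, SPEC, enc)
        assert shared.shape == (8,)
        assert len(tasks) == 4 and all(t.shape == (4,) for t in tasks)
        np.testing.assert_array_equal(shared, shared2)

    def test_shape_mismatch_raises(self, params):
        with pytest.raises(ValueError, match="feature dim"):
            encode_state(np.zeros(5), SPEC, params.critic1.encoder)

    def test_zero_parameters_zero_encoding(self):
        rng = np.random.default_rng(2)
        p = AgentParams.init(6, 2, [2], SPEC, rng)
        for arr in p.critic1.encoder.flat():
            arr[...] = 0.0
        shared, tasks = encode_state(np.ones(6), SPEC, p.critic1.encoder)
        assert np.all(shared == 0.0) and all(np.all(t == 0.0) for t in tasks)

    def test_spec_requires_shared_layer_and_four_heads(self):
        with pytest.raises(ValueError, match="shared layer"):
            EncoderSpec(shared_layers=[])
        with pytest.raises(ValueError, match="task head"):
            EncoderSpec(task_specific_layers=[[4]] * 3)


class TestQVector:
    def test_identical_twins_idempotent_min(self, params):
        params.critic2 = copy.deepcopy(params.critic1)
        obs = np.random.default_rng(3).normal(size=6)
        act = np.random.default_rng(4).normal(size=3 + 5)
        q1, _ = params.critic1.forward(obs[None], act[None])
        np.testing.assert_allclose(q_vector(obs, act, params), q1[0])

    def test_elementwise_min(self, params):
        obs = np.random.default_rng(3).normal(size=(2, 6))
        act = np.random.default_rng(4).normal(size=(2, 8))
        q1, _ = params.critic1.forward(obs, act)
        q2, _ = params.critic2.forward(obs, act)
        np.testing.assert_allclose(q_vector(obs, act, params), np.minimum(q1, q2))

    def test_output_length_is_four_tasks(self, params):
        q = q_vector(np.zeros(6), np.zeros(8), params)
        assert q.shape == (4,)


class TestScalarize:
    def test_unit_vector(self):
        assert scalarize(np.ones(4), TaskWeights()) == pytest.approx(1.0)

    def test_basis_weight(self):
        w = TaskWeights(1.0, 0.0, 0.0, 0.0)
        assert scalarize(np.array([0.7, 9, 9, 9]), w) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        q = np.array([0.3, 0.1, 0.4, 0.2])
        assert scalarize(q, TaskWeights.uniform()) == pytest.approx(0.25)


class TestPolicySampling:
    def test_actions_within_clinical_bounds(self, trained_results):
        """10,000 draws from the trained policy decode inside the action bounds."""
        pol = trained_results.params.policy
        rng = np.random.default_rng(5)
        obs = rng.normal(size=(10_000, pol.obs_dim))
        fwd = pol.forward(obs)
        t, probs, idx, logp, _ = pol.sample(fwd, rng)
        assert np.all(t >= -1.0) and np.all(t <= 1.0)
        assert np.all(np.isfinite(logp))
        for row in range(0, 10_000, 1000):
            a = decode_action(t[row], idx[row])
            a.validate()
            phys = np.array([a.sagittal_mm, a.vertical_mm, a.transverse_mm,
                             a.force_g, *a.force_dir, a.interval_weeks])
            assert np.all(phys[:4] >= CONT_LOW[:4]) and np.all(phys[:4] <= CONT_HIGH[:4])

    def test_deterministic_mode_repeatable(self, params):
        obs = np.random.default_rng(6).normal(size=(1, 6))
        fwd = params.policy.forward(obs)
        a1 = params.policy.sample(fwd, None, deterministic=True)
        a2 = params.policy.sample(fwd, None, deterministic=True)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[2], a2[2])

    def test_categorical_entropy_term_nonpositive_logp_part(self, params):
        # the relaxed categorical contribution to logp is -H(p) <= 0
        obs = np.random.default_rng(7).normal(size=(4, 6))
        fwd = params.policy.forward(obs)
        for p in fwd["probs"]:
            ent = -(p * np.log(p + 1e-12)).sum(axis=1)
            assert np.all(ent >= 0.0)


class _OneStepEnv(TaskEnv):
    """Single-transition environment for myopic-limit checks."""
    obs_dim, cont_dim, cat_sizes = 3, 2, [2]

    def reset(self, seed=None):
        return np.zeros(3)

    def step(self, cont_t, cat_idx):
        return np.zeros(3), np.array([0.4, 0.3, 0.2, 0.1]), True, {}


class TestSacUpdate:
    def _make(self, gamma, lr, alpha=0.0):
        rng = np.random.default_rng(8)
        params = AgentParams.init(3, 2, [2], SPEC, rng)
        cfg = TrainConfig(gamma=gamma, lr=lr, batch_size=16, auto_alpha=False,
                          alpha_init=max(alpha, 1e-8), total_steps=1)
        opt = Optimizers(params, cfg)
        obs = rng.normal(size=(16, 3))
        act = rng.uniform(-1, 1, size=(16, 4))
        rew = np.tile([0.4, 0.3, 0.2, 0.1], (16, 1))
        done = np.ones(16)
        batch = (obs, act, rew, obs, done)
        return params, cfg, opt, batch, rng

    def test_zero_lr_leaves_parameters_unchanged(self):
        params, cfg, opt, batch, rng = self._make(gamma=0.9, lr=1e-12)
        before = [p.copy() for p in params.policy.flat() + params.critic1.flat()]
        sac_update(batch, params, cfg, opt, rng)
        after = params.policy.flat() + params.critic1.flat()
        for b, a in zip(before, after):
            np.testing.assert_allclose(b, a, atol=1e-9)

    def test_myopic_limit_critic_converges_to_reward(self):
        """gamma=0, fixed zero temperature: critic target equals the immediate
        task rewards."""
        params, cfg, opt, batch, rng = self._make(gamma=1.0, lr=3e-3)
        cfg.gamma = 0.0
        for _ in range(400):
            diag = sac_update(batch, params, cfg, opt, rng)
        q, _ = params.critic1.forward(batch[0], batch[1])
        np.testing.assert_allclose(q, batch[2], atol=0.05)
        assert np.isfinite(diag["critic1_loss"])

    def test_losses_finite_and_reported(self):
        params, cfg, opt, batch, rng = self._make(gamma=0.9, lr=1e-3)
        diag = sac_update(batch, params, cfg, opt, rng)
        for key in ("critic1_loss", "critic2_loss", "policy_loss", "alpha"):
            assert np.isfinite(diag[key])


def _toy_trajectory(rewards):
    steps = []
    n = len(rewards)
    for i, r in enumerate(rewards):
        steps.append(Transition(np.zeros(2), np.zeros(0), np.zeros(1, int),
                                np.asarray(r, float), np.zeros(2), i == n - 1))
    return Trajectory(steps)


class TestMultitaskReturn:
    def test_single_step_basis_reward(self):
        traj = _toy_trajectory([[1, 0, 0, 0]])
        assert multitask_return([traj], TaskWeights(), 0.99) == pytest.approx(0.30)

    def test_undiscounted_constant_series(self):
        traj = _toy_trajectory([[0.5] * 4] * 10)
        assert multitask_return([traj], TaskWeights(), 1.0) == pytest.approx(5.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(9)
        trajs = [_toy_trajectory(rng.uniform(0, 1, size=(5, 4))) for _ in range(3)]
        w = TaskWeights(0.4, 0.3, 0.2, 0.1)
        direct = multitask_return(trajs, w, 0.9)
        basis = per_task_returns(trajs, 0.9)
        assert direct == pytest.approx(float(basis @ w.as_array()))

    def test_done_only_at_end_enforced(self):
        steps = [Transition(np.zeros(2), np.zeros(0), np.zeros(1, int),
                            np.zeros(4), np.zeros(2), True)] * 2
        with pytest.raises(ValueError, match="done"):
            Trajectory(steps)


class _LineEnv(TaskEnv):
    """Tiny deterministic chain with a clearly better action."""
    obs_dim, cont_dim, cat_sizes = 2, 0, [2]

    def __init__(self):
        self.s = 0
        self.t = 0

    def reset(self, seed=None):
        self.s, self.t = 0, 0
        return np.eye(2)[self.s]

    def step(self, cont_t, cat_idx):
        a = int(np.asarray(cat_idx).reshape(-1)[0])
        r = np.full(4, 0.9 if a == 1 else 0.1)
        self.t += 1
        return np.eye(2)[self.s], r, self.t >= 10, {}


class TestTrainLoop:
    def _config(self, seed=0):
        return TrainConfig(total_steps=600, start_steps=100, update_every=2,
                           batch_size=32, lr=3e-3, eval_every=200, eval_episodes=2,
                           seed=seed, auto_alpha=False, alpha_init=0.01,
                           encoder=SPEC)

    def test_log_matches_eval_cadence(self):
        _, log = train(_LineEnv, self._config())
        assert [row["step"] for row in log] == [200, 400, 600]

    def test_seeded_rerun_reproduces_eval_sequence(self):
        _, log_a = train(_LineEnv, self._config(seed=4))
        _, log_b = train(_LineEnv, self._config(seed=4))
        assert [r["mean_return"] for r in log_a] == [r["mean_return"] for r in log_b]

    def test_learns_better_action(self):
        params, log = train(_LineEnv, self._config())
        assert log[-1]["mean_return"] > 6.0  # near max 9.0, far above random 5.0


class TestReplayBuffer:
    def test_wraparound_and_sampling(self):
        buf = ReplayBuffer(capacity=8, obs_dim=2, act_dim=3)
        for i in range(12):
            buf.push(np.full(2, i), np.zeros(3), np.zeros(4), np.zeros(2), False)
        assert buf.size == 8
        obs, *_ = buf.sample(4, np.random.default_rng(0))
        assert obs.shape == (4, 2)
        assert obs.min() >= 4  # oldest entries overwritten
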