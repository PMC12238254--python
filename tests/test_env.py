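"""Treatment MDP: dynamics contracts, bounds, determinism, invariants."""

import numpy as np
import pytest

import orthoplan as op
from orthoplan.env import (ContractViolation, EnvConfig, TreatmentAction,
                           TreatmentEnv, UsageError, action_space_spec,
                           clip_action, force_effectiveness)
from orthoplan.rewards import MONTHS_PER_WEEK


@pytest.fixture(scope="module")
def records():
    return op.sample_cohort(op.CohortConfig(n=10, seed=13))


@pytest.fixture(scope="module")
def class_iii_record(records):
    return next(r for r in records if "ClassIII" in r.deformity_labels)


def _sat(x, scale):
    # independent closed form of the documented saturating response curve
    return np.sign(x) * scale * (1.0 - np.exp(-abs(x) / scale))


class TestReset:
    def test_episode_start(self, records, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        st = env.reset(records[0], seed=1)
        assert st.treatment_status.phase == 1
        assert st.treatment_status.elapsed_months == 0.0

    def test_class_iii_negative_anb(self, class_iii_record, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        st = env.reset(class_iii_record, seed=1)
        assert st.skeletal.anb < 0

    def test_determinism(self, records, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        a = env.reset(records[2], seed=4)
        b = env.reset(records[2], seed=4)
        assert np.array_equal(a.feature_vector(), b.feature_vector())


class TestSimulateResponse:
    def test_null_intervention_fixed_point(self, records, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        s = env.reset(records[0], seed=2)
        nxt = op.simulate_response(s, TreatmentAction(), 1.5, quiet_env_config)
        assert np.array_equal(nxt.skeletal.landmarks, s.skeletal.landmarks)
        assert nxt.skeletal.anb == s.skeletal.anb
        assert np.array_equal(nxt.dental.tooth_ang, s.dental.tooth_ang)
        assert nxt.soft_tissue.facial_harmony == s.soft_tissue.facial_harmony
        assert nxt.functional.occlusal_function == s.functional.occlusal_function
        assert nxt.treatment_status.elapsed_months == pytest.approx(
            s.treatment_status.elapsed_months + 1.5)

    def test_positive_sagittal_increases_anb(self, class_iii_record, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        s = env.reset(class_iii_record, seed=2)
        nxt = op.simulate_response(s, TreatmentAction(sagittal_mm=15.0), 1.5,
                                   quiet_env_config)
        assert nxt.skeletal.anb > s.skeletal.anb

    def test_saturation_schedule(self, class_iii_record, quiet_env_config):
        """Two 5 mm moves vs one 10 mm move, checked against the closed-form
        response curve; the larger per-step move carries the larger relapse
        increment."""
        cfg = quiet_env_config
        env = TreatmentEnv(cfg)
        s0 = env.reset(class_iii_record, seed=2)
        bd = s0.treatment_status.bone_density
        gain = cfg.bone_gain + (1 - cfg.bone_gain) * bd

        one = op.simulate_response(s0, TreatmentAction(sagittal_mm=10.0), 1.5, cfg)
        two_a = op.simulate_response(s0, TreatmentAction(sagittal_mm=5.0), 1.5, cfg)
        two = op.simulate_response(two_a, TreatmentAction(sagittal_mm=5.0), 1.5, cfg)

        expected_one = cfg.deg_per_mm * _sat(10.0, cfg.sat_move_mm) * gain
        assert one.skeletal.anb - s0.skeletal.anb == pytest.approx(expected_one, rel=1e-9)
        # healing between steps changes bone density slightly; allow that margin
        expected_two = 2 * cfg.deg_per_mm * _sat(5.0, cfg.sat_move_mm) * gain
        assert two.skeletal.anb - s0.skeletal.anb == pytest.approx(expected_two, rel=0.05)
        # diminishing returns: split schedule realises at least as much movement
        assert two.skeletal.anb >= one.skeletal.anb

        relapse_inc_one = one.treatment_status.relapse_risk - s0.treatment_status.relapse_risk
        relapse_inc_two = two_a.treatment_status.relapse_risk - s0.treatment_status.relapse_risk
        assert relapse_inc_one > relapse_inc_two

    def test_out_of_bounds_action_rejected(self, records, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        s = env.reset(records[0], seed=1)
        with pytest.raises(ContractViolation, match="sagittal"):
            op.simulate_response(s, TreatmentAction(sagittal_mm=20.0), 1.0,
                                 quiet_env_config)

    def test_force_diminishing_returns(self, quiet_env_config):
        cfg = quiet_env_config
        e150 = force_effectiveness(150.0, cfg)
        e300 = force_effectiveness(300.0, cfg)
        e75 = force_effectiveness(75.0, cfg)
        assert e150 == pytest.approx(1.0)
        assert e75 == pytest.approx(0.5)
        # above the documented threshold, returns grow sublinearly
        assert e300 - e150 < e150 - e75


class TestStep:
    def test_zero_noise_step_equals_core_plus_reward(self, records, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        s = env.reset(records[1], seed=3)
        a = TreatmentAction(sagittal_mm=5.0, force_g=150.0, interval_weeks=6.0)
        expected = op.simulate_response(s, a, 6.0 * MONTHS_PER_WEEK, quiet_env_config)
        expected_r = op.reward_components(s, a, expected)
        out = env.step(a)
        assert np.array_equal(out.next_state.feature_vector(),
                              expected.feature_vector())
        assert np.array_equal(out.reward.as_array(), expected_r.as_array())

    def test_clip_recorded(self, records, quiet_env_config):
        env = TreatmentEnv(quiet_env_config)
        env.reset(records[1], seed=3)
        out = env.step(TreatmentAction(sagittal_mm=20.0))
        assert "sagittal_mm" in out.info["clips"]
        clipped, clips = clip_action(TreatmentAction(sagittal_mm=20.0))
        assert clipped.sagittal_mm == 15.0 and clips["sagittal_mm"] == 20.0

    def test_trajectory_determinism(self, records):
        cfg = EnvConfig()  # default noise on
        trajs = []
        for _ in range(2):
            env = TreatmentEnv(cfg)
            env.reset(records[0], seed=6)
            anbs = []
            for k in range(5):
                out = env.step(TreatmentAction(sagittal_mm=3.0, force_g=100.0,
                                               interval_weeks=6.0))
                anbs.append(out.next_state.skeletal.anb)
            trajs.append(anbs)
        assert trajs[0] == trajs[1]

    def test_step_after_done_raises(self, records, quiet_env_config):
        cfg = EnvConfig(horizon_steps=1, noise_mm=0, noise_deg=0, noise_unit=0,
                        noise_harmony=0)
        env = TreatmentEnv(cfg)
        env.reset(records[0], seed=1)
        out = env.step(TreatmentAction())
        assert out.done
        with pytest.raises(UsageError):
            env.step(TreatmentAction())

    def test_state_validity_closure(self, records):
        """Every state visited under random in-bounds actions stays valid."""
        env = TreatmentEnv(EnvConfig())
        rng = np.random.default_rng(0)
        st = env.reset(records[3], seed=9)
        for _ in range(28):
            a = TreatmentAction(
                sagittal_mm=rng.uniform(-15, 15), vertical_mm=rng.uniform(-10, 10),
                transverse_mm=rng.uniform(-8, 8), force_g=rng.uniform(50, 300),
                interval_weeks=rng.uniform(4, 8),
                phase_decision=("proceed", "hold", "modify")[rng.integers(3)])
            out = env.step(a)
            assert op.validate_state(out.next_state) == []
            if out.done:
                break

    def test_bounded_influence(self, records, quiet_env_config):
        """Per-step ANB change is bounded by gain x saturated action magnitude."""
        cfg = quiet_env_config
        env = TreatmentEnv(cfg)
        rng = np.random.default_rng(1)
        s = env.reset(records[4], seed=2)
        for _ in range(50):
            mag = rng.uniform(-15, 15)
            nxt = op.simulate_response(s, TreatmentAction(sagittal_mm=mag), 1.5, cfg)
            bound = cfg.deg_per_mm * min(abs(mag), cfg.sat_move_mm) + 1e-9
            assert abs(nxt.skeletal.anb - s.skeletal.anb) <= bound
            s = nxt

    def test_monotone_correction_until_target(self, class_iii_record, quiet_env_config):
        cfg = quiet_env_config
        env = TreatmentEnv(cfg)
        s = env.reset(class_iii_record, seed=2)
        prev = s.skeletal.anb
        while s.skeletal.anb < cfg.anb_target:
            s = op.simulate_response(s, TreatmentAction(sagittal_mm=15.0), 1.5, cfg)
            assert s.skeletal.anb > prev
            prev = s.skeletal.anb


class TestActionSpaceSpec:
    def test_jaw_bounds(self):
        spec = action_space_spec("jaw")
        assert spec["sagittal_mm"] == (-15.0, 15.0)
        assert spec["vertical_mm"] == (-10.0, 10.0)
        assert spec["transverse_mm"] == (-8.0, 8.0)

    def test_dental_force(self):
        assert action_space_spec("dental")["force_g"] == (50.0, 300.0)

    def test_sequencing_interval(self):
        assert action_space_spec("sequencing")["interval_weeks"] == (4.0, 8.0)

    def test_unknown_task_type(self):
        with pytest.raises(KeyError, match="unknown task type"):
            action_space_spec("prosthetic")
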