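"""Environment dynamics, reward shaping and the SAC training loop."""

import numpy as np
import pytest

from armclone import (
    EnvState,
    ReachingEnv,
    RewardWeights,
    clone_dataset,
    reward,
    step_dynamics,
    train_policy,
)
from armclone.drl import load_policy, save_policy
from armclone.subjects import ANGLE_COLUMNS


def make_state(arm, grid, q=None, moving_point=None):
    return EnvState(
        q=np.zeros(7) if q is None else np.asarray(q, float),
        q_dot=np.zeros(7),
        moving_point=grid.center if moving_point is None else np.asarray(moving_point),
        phase="reach",
        t=0.0,
    )


class TestStepDynamics:
    def test_zero_action_keeps_pose_and_advances_time(self, arm, grid):
        s = make_state(arm, grid)
        s2 = step_dynamics(s, np.zeros(7), arm, dt=0.02)
        np.testing.assert_array_equal(s2.q, s.q)
        assert s2.t == pytest.approx(0.02)

    def test_velocity_integration_arithmetic(self, arm, grid):
        s = make_state(arm, grid)
        a = np.zeros(7)
        a[3] = 1.0  # elbow flexion at full speed
        s2 = step_dynamics(s, a, arm, dt=0.02, max_speed=180.0)
        assert s2.q[3] == pytest.approx(3.6)
        assert s2.q_dot[3] == pytest.approx(180.0)

    def test_clipping_at_joint_limit(self, arm, grid):
        q = np.zeros(7)
        q[3] = arm.joint_limits_deg[3, 1]  # elbow at upper limit
        s = make_state(arm, grid, q=q)
        a = np.zeros(7)
        a[3] = 1.0
        s2 = step_dynamics(s, a, arm, dt=0.02)
        assert s2.q[3] == arm.joint_limits_deg[3, 1]

    def test_determinism(self, arm, grid):
        s = make_state(arm, grid)
        a = np.linspace(-1, 1, 7)
        s1 = step_dynamics(s, a, arm, dt=0.02)
        s2 = step_dynamics(s, a, arm, dt=0.02)
        np.testing.assert_array_equal(s1.q, s2.q)

    def test_invalid_dt(self, arm, grid):
        with pytest.raises(ValueError):
            step_dynamics(make_state(arm, grid), np.zeros(7), arm, dt=0.0)


class TestReward:
    def test_zero_when_all_terms_vanish(self, arm, grid):
        from armclone import forward_kinematics

        tip = forward_kinematics(arm, np.zeros(7)).fingertip
        s = make_state(arm, grid, moving_point=tip)  # palm down at zero pose
        r, terms = reward(s, np.zeros(7), arm, RewardWeights())
        assert r == pytest.approx(0.0, abs=1e-12)
        assert terms.error_p == pytest.approx(0.0, abs=1e-12)
        assert terms.error_o == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self, arm, grid):
        """b=2, c=0.05, d=0.5 with error_p=0.1, |a|^2=1, error_o=0.2 -> -0.35."""
        w = RewardWeights(b=2.0, c=0.05, d=0.5)
        from armclone import forward_kinematics

        q = np.zeros(7)
        q[5] = np.rad2deg(np.arccos(0.8))  # wrist flexion tilts the palm
        pose = forward_kinematics(arm, q)
        assert 1.0 - pose.palm_normal @ [0, 0, -1] == pytest.approx(0.2)
        # moving point 0.1 m from the fingertip
        mp = pose.fingertip + np.array([0.0, 0.1, 0.0])
        s = make_state(arm, grid, q=q, moving_point=mp)
        a = np.zeros(7)
        a[0] = 1.0
        r, terms = reward(s, a, arm, w)
        assert terms.error_p == pytest.approx(0.1)
        assert terms.action_sq == pytest.approx(1.0)
        assert terms.error_o == pytest.approx(0.2)
        assert r == pytest.approx(-0.35)

    def test_never_positive_and_monotone_in_error(self, arm, grid, rng):
        w = RewardWeights()
        for _ in range(200):
            lo, hi = arm.joint_limits_deg[:, 0], arm.joint_limits_deg[:, 1]
            q = rng.uniform(lo, hi)
            mp = rng.uniform([-0.2, -0.5, -0.6], [0.7, 0.5, 0.4])
            s = make_state(arm, grid, q=q, moving_point=mp)
            a = rng.uniform(-1, 1, 7)
            r, terms = reward(s, a, arm, w)
            assert r <= 0.0
            # doubling the position error strictly decreases reward
            from armclone import forward_kinematics

            tip = forward_kinematics(arm, q).fingertip
            far = tip + 2 * (mp - tip)
            r2, _ = reward(make_state(arm, grid, q=q, moving_point=far), a, arm, w)
            if terms.error_p > 1e-9:
                assert r2 < r

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            RewardWeights(b=0.0)
        with pytest.raises(ValueError):
            RewardWeights(c=-0.1)


class TestEnv:
    def test_env_step_deterministic(self, arm, grid, timing):
        env = ReachingEnv(arm, grid, timing)
        a = np.full(7, 0.3)
        obs0 = env.reset(1)
        o1, r1, d1, _ = env.step(a)
        env.reset(1)
        o2, r2, d2, _ = env.step(a)
        np.testing.assert_array_equal(o1, o2)
        assert r1 == r2 and d1 == d2
        assert obs0.shape == (16,)

    def test_episode_length_matches_trial(self, arm, grid, timing):
        env = ReachingEnv(arm, grid, timing)
        env.reset(2)
        done = False
        n = 0
        while not done:
            _, _, done, _ = env.step(np.zeros(7))
            n += 1
        assert n == timing.samples_per_trial - 1

    def test_reset_pose_starts_at_center(self, arm, grid, timing):
        from armclone import forward_kinematics

        env = ReachingEnv(arm, grid, timing)
        env.reset(1)
        tip = forward_kinematics(arm, env.state.q).fingertip
        assert np.linalg.norm(tip - grid.center) < 1e-6


class TestTrainingAndCloning:
    @pytest.fixture(scope="class")
    def tiny_policy(self, arm, grid, timing):
        from armclone.sac import SACConfig

        return train_policy(
            arm,
            grid,
            timing,
            steps=1200,
            seed=3,
            sac_config=SACConfig(learning_starts=300, batch_size=64),
        )

    def test_rejects_nonpositive_steps(self, arm, grid, timing):
        with pytest.raises(ValueError):
            train_policy(arm, grid, timing, steps=0)

    def test_training_log_recorded(self, tiny_policy):
        assert tiny_policy.steps_trained == 1200
        assert len(tiny_policy.episode_returns) >= 4
        assert all(np.isfinite(r) for r in tiny_policy.episode_returns)

    def test_clone_dataset_structure(self, tiny_policy, arm, grid, timing):
        ds = clone_dataset(tiny_policy, arm, grid, timing, repetitions=4)
        assert len(ds) == 32
        assert ds.subject_ids == ["DRL"]
        assert ds.trials[0].angles.shape[1] == len(ANGLE_COLUMNS)
        # deterministic rollouts: identical repetitions of the same target
        t1 = [tr for tr in ds.trials if tr.target_id == 1]
        np.testing.assert_array_equal(t1[0].angles, t1[1].angles)

    def test_clone_requires_trained_policy(self, tiny_policy, arm, grid, timing):
        from dataclasses import replace

        untrained = replace(tiny_policy, steps_trained=0)
        with pytest.raises(ValueError, match="trained"):
            clone_dataset(untrained, arm, grid, timing)

    def test_policy_save_load_roundtrip(self, tiny_policy, arm, grid, timing, tmp_path):
        save_policy(tiny_policy, tmp_path / "pol")
        back = load_policy(tmp_path / "pol")
        env = ReachingEnv(arm, grid, timing)
        obs = env.reset(1)
        np.testing.assert_allclose(
            tiny_policy.agent.act(obs, deterministic=True),
            back.agent.act(obs, deterministic=True),
            atol=1e-12,
        )
        assert back.steps_trained == tiny_policy.steps_trained
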