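"""Reinforcement-learned motion cloning: environment, reward, training, rollout.

The 7-DOF arm tracks a moving reference point that executes the
center-out-center task.  The environment is a velocity-controlled
kinematic integrator: the action commands normalized joint velocities,
joint angles are clipped to their limits, and there is no contact or
torque-level dynamics.  The reward penalizes fingertip tracking error,
action energy and palm-orientation error,

    r(s, a) = -b * error_p - c * ||a||^2 - d * error_o,

so it is never positive and vanishes only when the fingertip sits on
the reference with a still, palm-down hand.  A policy trained with
soft actor-critic on this environment is then rolled out in
deterministic mode over the full trial schedule to extract the
synthetic motion dataset (subject id "DRL").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinematics import ArmModel, forward_kinematics, inverse_kinematics_swivel
from .sac import ReplayBuffer, SACAgent, SACConfig
from .subjects import MotionDataset, MotionTrial
from .task import (
    PhaseTiming,
    TargetGrid,
    moving_point_position,
    moving_point_trajectory,
    trial_schedule,
)

__all__ = [
    "RewardWeights",
    "RewardTerms",
    "EnvState",
    "ReachingEnv",
    "PolicyHandle",
    "step_dynamics",
    "reward",
    "train_policy",
    "clone_dataset",
    "evaluate_tracking",
    "save_policy",
    "load_policy",
]

#: Swivel (deg) of the neutral reset pose, the middle of the surrogate range.
NEUTRAL_SWIVEL_DEG = 27.0

DOWN = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class RewardWeights:
    """Coefficients of the three reward penalties.

    Defaults weight the position term to dominate at typical tracking
    errors (~0.1 m) while the action term discourages bang-bang control.
    """

    b: float = 2.0
    c: float = 0.05
    d: float = 0.5

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("position weight b must be > 0")
        if self.c < 0 or self.d < 0:
            raise ValueError("weights must be nonnegative")

    def to_dict(self) -> dict:
        return {"b": self.b, "c": self.c, "d": self.d}


@dataclass(frozen=True)
class RewardTerms:
    error_p: float  # fingertip-to-reference distance, metres
    action_sq: float  # squared norm of the normalized action
    error_o: float  # 1 - palm_normal . down, in [0, 2]


@dataclass(frozen=True)
class EnvState:
    q: np.ndarray  # 7 joint angles, degrees
    q_dot: np.ndarray  # 7 joint velocities, deg/s
    moving_point: np.ndarray
    phase: str
    t: float


def step_dynamics(
    state: EnvState,
    action: np.ndarray,
    arm: ArmModel,
    dt: float,
    max_speed: float = 180.0,
    grid: TargetGrid | None = None,
    timing: PhaseTiming | None = None,
    target_id: int | None = None,
) -> EnvState:
    """Velocity-integrator transition: q' = clip(q + a * max_speed * dt).

    Inputs are clipped (action to [-1, 1], angles to joint limits), so
    the transition never errors.  When the task context (grid, timing,
    target) is supplied the moving point advances along its trajectory;
    otherwise it is held.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.clip(np.asarray(action, float), -1.0, 1.0)
    lim = arm.joint_limits_deg
    q_new = np.clip(state.q + a * max_speed * dt, lim[:, 0], lim[:, 1])
    t_new = state.t + dt
    if grid is not None and timing is not None and target_id is not None:
        t_ref = min(t_new, timing.trial_duration)
        mp, phase = moving_point_position(grid, timing, target_id, t_ref)
    else:
        mp, phase = state.moving_point, state.phase
    return EnvState(
        q=q_new,
        q_dot=(q_new - state.q) / dt,
        moving_point=mp,
        phase=phase,
        t=t_new,
    )


def reward(
    state: EnvState, action: np.ndarray, arm: ArmModel, w: RewardWeights
) -> tuple[float, RewardTerms]:
    """Reward of the current state/action; always <= 0."""
    pose = forward_kinematics(arm, state.q)
    a = np.clip(np.asarray(action, float), -1.0, 1.0)
    terms = RewardTerms(
        error_p=float(np.linalg.norm(pose.fingertip - state.moving_point)),
        action_sq=float(a @ a),
        error_o=float(1.0 - pose.palm_normal @ DOWN),
    )
    r = -(w.b * terms.error_p + w.c * terms.action_sq + w.d * terms.error_o)
    return float(r), terms


class ReachingEnv:
    """Episode = one center-out-center trial towards one target.

    Actions command all seven joint velocities, but the default backend
    holds the two wrist joints neutral (their commands are masked).
    The five recorded channels then positionally determine the
    fingertip — the same convention the surrogate subjects' inverse
    kinematics uses — and palm-down orientation is achieved through
    elbow pronation alone.  A backend with an actuated wrist can relax
    ``actuated_joints``.
    """

    def __init__(
        self,
        arm: ArmModel,
        grid: TargetGrid,
        timing: PhaseTiming,
        weights: RewardWeights = RewardWeights(),
        max_speed: float = 180.0,
    ):
        self.arm = arm
        self.grid = grid
        self.timing = timing
        self.weights = weights
        self.max_speed = max_speed
        self.neutral_q = inverse_kinematics_swivel(
            arm, grid.center, NEUTRAL_SWIVEL_DEG
        )
        self._lim = arm.joint_limits_deg
        self._q_mid = self._lim.mean(axis=1)
        self._q_half = (self._lim[:, 1] - self._lim[:, 0]) / 2.0
        self._ref = {
            tid: moving_point_trajectory(grid, timing, tid).positions
            for tid in range(1, grid.n_targets + 1)
        }
        # shoulder (3) + elbow (2) actuated; wrist held neutral
        self.actuated_joints = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        self.obs_dim = 16
        self.act_dim = 7
        self.episode_len = timing.samples_per_trial
        self.state: EnvState | None = None
        self.target_id: int | None = None
        self._step_idx = 0

    def _observe(self) -> np.ndarray:
        s = self.state
        q_scaled = (s.q - self._q_mid) / self._q_half
        tip = forward_kinematics(self.arm, s.q).fingertip
        return np.concatenate([q_scaled, tip, s.moving_point, s.moving_point - tip])

    def reset(self, target_id: int) -> np.ndarray:
        self.target_id = target_id
        self._step_idx = 0
        self.state = EnvState(
            q=self.neutral_q.copy(),
            q_dot=np.zeros(7),
            moving_point=self._ref[target_id][0].copy(),
            phase="reach",
            t=0.0,
        )
        return self._observe()

    def step(self, action) -> tuple[np.ndarray, float, bool, RewardTerms]:
        """Apply the action; returns (obs, reward, episode_done, terms)."""
        action = np.asarray(action, float) * self.actuated_joints
        self.state = step_dynamics(
            self.state,
            action,
            self.arm,
            self.timing.dt,
            self.max_speed,
            grid=self.grid,
            timing=self.timing,
            target_id=self.target_id,
        )
        self._step_idx += 1
        r, terms = reward(self.state, action, self.arm, self.weights)
        done = self._step_idx >= self.episode_len - 1
        return self._observe(), r, done, terms


@dataclass
class PolicyHandle:
    """A trained tracking policy plus its training record."""

    agent: SACAgent = field(repr=False)
    training_seed: int
    steps_trained: int
    episode_returns: list[float] = field(repr=False)
    weights: RewardWeights = RewardWeights()
    max_speed: float = 180.0

    @property
    def entropy_weight(self) -> float:
        return self.agent.alpha


def train_policy(
    arm: ArmModel,
    grid: TargetGrid,
    timing: PhaseTiming,
    weights: RewardWeights = RewardWeights(),
    steps: int = 200_000,
    seed: int = 0,
    sac_config: SACConfig = SACConfig(),
    max_speed: float = 180.0,
    progress: bool = False,
) -> PolicyHandle:
    """Train a SAC tracking policy on the reaching environment.

    Episodes are single trials; the target cycles 1..n so all targets
    are visited periodically.  Returns the policy handle with the
    per-episode return log.  Reproducible for a fixed seed in
    single-threaded execution.
    """
    if steps <= 0:
        raise ValueError("steps must be > 0")
    env = ReachingEnv(arm, grid, timing, weights, max_speed)
    rng = np.random.default_rng(seed)
    agent = SACAgent(env.obs_dim, env.act_dim, sac_config, rng)
    buf = ReplayBuffer(
        min(sac_config.buffer_size, max(steps, 10_000)), env.obs_dim, env.act_dim
    )

    episode_returns: list[float] = []
    step = 0
    episode = 0
    while step < steps:
        obs = env.reset(target_id=(episode % grid.n_targets) + 1)
        ep_ret = 0.0
        done = False
        while not done and step < steps:
            if step < sac_config.learning_starts:
                action = rng.uniform(-1.0, 1.0, size=env.act_dim)
            else:
                action = agent.act(obs)
            next_obs, r, done, _ = env.step(action)
            buf.add(obs, action, r, next_obs)
            obs = next_obs
            ep_ret += r
            step += 1
            if (
                step >= sac_config.learning_starts
                and step % sac_config.train_freq == 0
            ):
                agent.update(buf.sample(sac_config.batch_size, rng))
        episode_returns.append(ep_ret)
        episode += 1
        if progress and episode % 20 == 0:
            print(
                f"step {step}/{steps}  episodes {episode}  "
                f"return {np.mean(episode_returns[-20:]):.1f}  "
                f"alpha {agent.alpha:.3f}"
            )
    return PolicyHandle(
        agent=agent,
        training_seed=seed,
        steps_trained=steps,
        episode_returns=episode_returns,
        weights=weights,
        max_speed=max_speed,
    )


def _rollout(
    policy: PolicyHandle,
    env: ReachingEnv,
    target_id: int,
) -> tuple[np.ndarray, list[RewardTerms]]:
    """Deterministic rollout of one trial; returns (q per sample, terms)."""
    obs = env.reset(target_id)
    qs = [env.state.q.copy()]
    terms: list[RewardTerms] = []
    for _ in range(env.episode_len - 1):
        action = policy.agent.act(obs, deterministic=True)
        obs, _, _, tm = env.step(action)
        qs.append(env.state.q.copy())
        terms.append(tm)
    return np.asarray(qs), terms


def clone_dataset(
    policy: PolicyHandle,
    arm: ArmModel,
    grid: TargetGrid,
    timing: PhaseTiming,
    repetitions: int = 4,
) -> MotionDataset:
    """Extract the synthetic motion dataset from deterministic rollouts.

    One trial per (repetition, target) following the trial schedule; the
    five recorded angles are taken from the rolled-out joint vectors.
    Deterministic-mode actions make repeated cloning bit-identical.
    """
    if policy.steps_trained <= 0:
        raise ValueError("policy has not been trained")
    env = ReachingEnv(arm, grid, timing, policy.weights, policy.max_speed)
    trials = []
    schedule = trial_schedule(grid, timing, repetitions)
    per_rep = grid.n_targets
    for k, (tid, _) in enumerate(schedule):
        rep = k // per_rep + 1
        qs, _ = _rollout(policy, env, tid)
        trials.append(
            MotionTrial(
                subject_id="DRL",
                target_id=tid,
                repetition=rep,
                session=1,
                times=np.arange(len(qs)) * timing.dt,
                angles=qs[:, [2, 1, 0, 4, 3]],
                phase_samples=tuple(
                    int(round(d / timing.dt)) for d in timing.phase_durations
                ),
            )
        )
    return MotionDataset(trials=trials, provenance="DRL", grid=grid, timing=timing)


def evaluate_tracking(
    policy: PolicyHandle,
    arm: ArmModel,
    grid: TargetGrid,
    timing: PhaseTiming,
) -> dict:
    """Mean tracking metrics over one deterministic pass of all targets."""
    env = ReachingEnv(arm, grid, timing, policy.weights, policy.max_speed)
    errs, e_orient = [], []
    for tid in range(1, grid.n_targets + 1):
        _, terms = _rollout(policy, env, tid)
        errs.extend(t.error_p for t in terms)
        e_orient.extend(t.error_o for t in terms)
    return {
        "mean_error_p_m": float(np.mean(errs)),
        "max_error_p_m": float(np.max(errs)),
        "mean_error_o": float(np.mean(e_orient)),
    }


# -- persistence -------------------------------------------------------------

def save_policy(policy: PolicyHandle, out_dir) -> None:
    """Persist weights (npz) and a JSON sidecar with the training record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **policy.agent.state_arrays())
    meta = {
        "training_seed": policy.training_seed,
        "steps_trained": policy.steps_trained,
        "entropy_weight": policy.entropy_weight,
        "reward_weights": policy.weights.to_dict(),
        "max_speed_deg_s": policy.max_speed,
        "sac_config": policy.agent.cfg.to_dict(),
        "obs_dim": policy.agent.obs_dim,
        "act_dim": policy.agent.act_dim,
        "episode_returns": policy.episode_returns,
    }
    (out / "policy.json").write_text(json.dumps(meta, indent=1))


def load_policy(policy_dir) -> PolicyHandle:
    src = Path(policy_dir)
    meta = json.loads((src / "policy.json").read_text())
    cfg_d = meta["sac_config"]
    cfg = SACConfig(**{**cfg_d, "hidden": tuple(cfg_d["hidden"])})
    agent = SACAgent(
        meta["obs_dim"], meta["act_dim"], cfg, np.random.default_rng(0)
    )
    with np.load(src / "weights.npz") as arrays:
        agent.load_state_arrays(dict(arrays))
    return PolicyHandle(
        agent=agent,
        training_seed=meta["training_seed"],
        steps_trained=meta["steps_trained"],
        episode_returns=list(meta["episode_returns"]),
        weights=RewardWeights(**meta["reward_weights"]),
        max_speed=meta["max_speed_deg_s"],
    )
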