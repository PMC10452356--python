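"""Soft actor-critic for continuous control, on the NumPy layers of :mod:`.nn`.

The agent maximizes expected return plus policy entropy,

    J(pi) = E[ r(s_t, a_t) + alpha * H(pi(.|s_t)) ],

with a tanh-squashed Gaussian policy, twin Q critics with Polyak-averaged
targets, and automatic tuning of the entropy weight alpha towards a
target entropy of -dim(A).  Episodes end by time limit only, so Bellman
targets always bootstrap.

Gradients are assembled explicitly through the reparameterized action;
they are checked against finite differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .nn import MLP, Adam, soft_update

__all__ = ["SACConfig", "ReplayBuffer", "SACAgent", "TrainingFailureError"]

_LOG_STD_MIN, _LOG_STD_MAX = -5.0, 2.0
_EPS = 1e-6


class TrainingFailureError(RuntimeError):
    """Raised when losses become non-finite during training."""


@dataclass(frozen=True)
class SACConfig:
    hidden: tuple[int, ...] = (64, 64)
    lr: float = 3e-4
    batch_size: int = 256
    gamma: float = 0.99
    tau: float = 0.005
    buffer_size: int = 200_000
    learning_starts: int = 1_000
    train_freq: int = 2  # one gradient update every this many env steps
    target_entropy: float | None = None  # default -act_dim

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["hidden"] = list(self.hidden)
        return d


class ReplayBuffer:
    def __init__(self, capacity: int, obs_dim: int, act_dim: int):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim))
        self.act = np.zeros((capacity, act_dim))
        self.rew = np.zeros(capacity)
        self.next_obs = np.zeros((capacity, obs_dim))
        self.size = 0
        self._pos = 0

    def add(self, obs, act, rew, next_obs):
        i = self._pos
        self.obs[i] = obs
        self.act[i] = act
        self.rew[i] = rew
        self.next_obs[i] = next_obs
        self._pos = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, self.size, size=batch_size)
        return self.obs[idx], self.act[idx], self.rew[idx], self.next_obs[idx]


def _squash_logp(eps, log_std, a):
    """log pi(a|s) of the tanh-squashed Gaussian, per sample (B,)."""
    gauss = -0.5 * eps**2 - log_std - 0.5 * np.log(2.0 * np.pi)
    corr = np.log(1.0 - a**2 + _EPS)
    return (gauss - corr).sum(axis=1)


class SACAgent:
    """Actor, twin critics and their optimizers; update() does one SAC step."""

    def __init__(
        self, obs_dim: int, act_dim: int, cfg: SACConfig, rng: np.random.Generator
    ):
        self.cfg = cfg
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.rng = rng
        sizes_pi = (obs_dim, *cfg.hidden, 2 * act_dim)
        sizes_q = (obs_dim + act_dim, *cfg.hidden, 1)
        self.actor = MLP(sizes_pi, rng)
        self.q1 = MLP(sizes_q, rng)
        self.q2 = MLP(sizes_q, rng)
        self.q1_target = copy.deepcopy(self.q1)
        self.q2_target = copy.deepcopy(self.q2)
        self.opt_actor = Adam(self.actor.params, lr=cfg.lr)
        self.opt_q1 = Adam(self.q1.params, lr=cfg.lr)
        self.opt_q2 = Adam(self.q2.params, lr=cfg.lr)
        self.log_alpha = 0.0
        self._alpha_m = 0.0
        self._alpha_v = 0.0
        self._alpha_t = 0
        self.target_entropy = (
            cfg.target_entropy if cfg.target_entropy is not None else -float(act_dim)
        )
        self.updates = 0

    # -- policy --------------------------------------------------------------
    def _policy_forward(self, obs: np.ndarray):
        out = self.actor.forward(obs)
        mu, log_std = out[:, : self.act_dim], out[:, self.act_dim :]
        clipped = np.clip(log_std, _LOG_STD_MIN, _LOG_STD_MAX)
        mask = (log_std > _LOG_STD_MIN) & (log_std < _LOG_STD_MAX)
        return mu, clipped, mask

    def act(self, obs: np.ndarray, deterministic: bool = False) -> np.ndarray:
        obs = np.atleast_2d(obs)
        mu, log_std, _ = self._policy_forward(obs)
        if deterministic:
            return np.tanh(mu)[0]
        eps = self.rng.standard_normal(mu.shape)
        return np.tanh(mu + np.exp(log_std) * eps)[0]

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha))

    def _actor_grads(self, obs, eps, alpha):
        """Accumulate d/dtheta of mean(alpha logp - min Q) into actor.grads.

        ``eps`` is the reparameterization noise; passing it explicitly
        makes the gradient assembly testable against finite differences.
        Returns (loss, per-sample log-probabilities).
        """
        b = len(obs)
        self.actor.zero_grads()
        self.q1.zero_grads()
        self.q2.zero_grads()
        mu, ls, ls_mask = self._policy_forward(obs)
        std = np.exp(ls)
        a = np.tanh(mu + std * eps)
        logp = _squash_logp(eps, ls, a)
        qin_pi = np.concatenate([obs, a], axis=1)
        q1v = self.q1.forward(qin_pi)[:, 0]
        q2v = self.q2.forward(qin_pi)[:, 0]
        use_q1 = q1v <= q2v
        loss = float(np.mean(alpha * logp - np.minimum(q1v, q2v)))
        d1 = self.q1.backward(np.where(use_q1, -1.0 / b, 0.0)[:, None])
        d2 = self.q2.backward(np.where(use_q1, 0.0, -1.0 / b)[:, None])
        g_a = (d1 + d2)[:, self.obs_dim :]  # dLoss/da from -min Q
        one_m_a2 = 1.0 - a**2
        dlogp_du = 2.0 * a * one_m_a2 / (one_m_a2 + _EPS)
        du = (alpha / b) * dlogp_du + g_a * one_m_a2
        dmu = du
        dls = ((alpha / b) * (-1.0) + du * std * eps) * ls_mask
        self.actor.backward(np.concatenate([dmu, dls], axis=1))
        return loss, logp

    # -- one SAC gradient step ----------------------------------------------
    def update(self, batch) -> dict:
        obs, act, rew, next_obs = batch
        b = len(obs)
        cfg = self.cfg
        alpha = self.alpha

        # Bellman target from the target critics and the current policy.
        mu2, ls2, _ = self._policy_forward(next_obs)
        eps2 = self.rng.standard_normal(mu2.shape)
        a2 = np.tanh(mu2 + np.exp(ls2) * eps2)
        logp2 = _squash_logp(eps2, ls2, a2)
        qin2 = np.concatenate([next_obs, a2], axis=1)
        qt = np.minimum(
            self.q1_target.forward(qin2)[:, 0], self.q2_target.forward(qin2)[:, 0]
        )
        y = rew + cfg.gamma * (qt - alpha * logp2)

        # Critic regression.
        qin = np.concatenate([obs, act], axis=1)
        critic_loss = 0.0
        for q, opt in ((self.q1, self.opt_q1), (self.q2, self.opt_q2)):
            q.zero_grads()
            pred = q.forward(qin)[:, 0]
            err = pred - y
            critic_loss += float(np.mean(err**2))
            q.backward((2.0 * err / b)[:, None])
            opt.step(q.grads)

        # Actor step through the reparameterized action.
        eps = self.rng.standard_normal((b, self.act_dim))
        actor_loss, logp = self._actor_grads(obs, eps, alpha)
        self.opt_actor.step(self.actor.grads)
        self.q1.zero_grads()
        self.q2.zero_grads()

        # Entropy-weight step (Adam on the scalar log_alpha).
        g_alpha = -float(np.mean(logp + self.target_entropy))
        self._alpha_t += 1
        self._alpha_m = 0.9 * self._alpha_m + 0.1 * g_alpha
        self._alpha_v = 0.999 * self._alpha_v + 0.001 * g_alpha**2
        mhat = self._alpha_m / (1 - 0.9**self._alpha_t)
        vhat = self._alpha_v / (1 - 0.999**self._alpha_t)
        self.log_alpha -= cfg.lr * mhat / (np.sqrt(vhat) + 1e-8)

        soft_update(self.q1_target, self.q1, cfg.tau)
        soft_update(self.q2_target, self.q2, cfg.tau)
        self.updates += 1

        if not (np.isfinite(critic_loss) and np.isfinite(actor_loss)):
            raise TrainingFailureError(
                f"non-finite losses at update {self.updates}: "
                f"critic={critic_loss}, actor={actor_loss}"
            )
        return {
            "critic_loss": critic_loss,
            "actor_loss": actor_loss,
            "alpha": self.alpha,
        }

    # -- persistence ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, net in (
            ("actor", self.actor),
            ("q1", self.q1),
            ("q2", self.q2),
            ("q1_target", self.q1_target),
            ("q2_target", self.q2_target),
        ):
            for i, p in enumerate(net.params):
                out[f"{name}_{i}"] = p
        out["log_alpha"] = np.array([self.log_alpha])
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]):
        for name, net in (
            ("actor", self.actor),
            ("q1", self.q1),
            ("q2", self.q2),
            ("q1_target", self.q1_target),
            ("q2_target", self.q2_target),
        ):
            for i, p in enumerate(net.params):
                p[...] = arrays[f"{name}_{i}"]
        self.log_alpha = float(arrays["log_alpha"][0])
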