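"""Twin-delayed deep deterministic policy gradient (TD3) learner.

Standard TD3 machinery - twin critics with a clipped-min bootstrap,
target-policy smoothing, delayed actor updates, Polyak-averaged target
networks - driving the temporal-convolutional actor/critic of
:mod:`chromarl.networks`, with a proportional prioritized experience replay
buffer. Experiences are stored as full SARSA tuples (state, action, reward,
next state, behaviour next action); the bootstrap recomputes the next action
with the smoothed target policy as TD3 prescribes.

All randomness flows from a single seed, and the NumPy networks are
single-threaded, so training logs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import (ActorTCN, Adam, CriticTCN, copy_weights, get_weights,
                       polyak_update, set_weights)

__all__ = ["TD3Config", "ReplayBuffer", "TD3Agent", "train", "TrainingResult",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass
class TD3Config:
    """Hyperparameters. Defaults follow the study protocol where stated
    (learning rate 4e-4, batch 200, 4 gradient rounds per 4 interactions,
    two critic updates per actor update, replay capacity 1e6) and common TD3
    reference values elsewhere (discount 0.99, Polyak 0.005, target noise
    0.2 clipped at 0.5)."""

    learning_rate: float = 4e-4
    batch_size: int = 200
    interactions_per_block: int = 4   # env steps between update blocks
    updates_per_block: int = 4        # gradient rounds per block
    policy_delay: int = 2             # critic rounds per actor round
    discount: float = 0.99
    tau: float = 0.005                # target-network smoothing rate
    target_policy_noise: float = 0.2
    target_noise_clip: float = 0.5
    expl_noise_start: float = 0.3     # exploration noise, linear decay
    expl_noise_end: float = 0.02
    replay_capacity: int = 1_000_000
    per_alpha: float = 0.6            # prioritization exponent
    per_beta_start: float = 0.4       # importance-weight exponent, annealed to 1
    per_eps: float = 1e-6
    uniform_replay: bool = False
    warmup_interactions: int = 400    # random-policy steps before learning
    reward_scale: float = 1e-8        # training-side reward normalization
    n_workers: int = 1
    conv_filters: tuple = (128, 64)
    fc_units: int = 300
    kernel: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.tau, self.discount) <= 0:
            raise ValueError("rates must be positive")
        if self.policy_delay < 1:
            raise ValueError("critic-to-actor update ratio must be >= 1")


class ReplayBuffer:
    """Ring buffer of SARSA tuples with proportional priorities."""

    def __init__(self, capacity: int, obs_shape: tuple, action_dim: int):
        self.capacity = int(capacity)
        self.obs = np.zeros((self.capacity, *obs_shape), dtype=np.float32)
        self.act = np.zeros((self.capacity, action_dim), dtype=np.float32)
        self.rew = np.zeros(self.capacity, dtype=np.float64)
        self.obs2 = np.zeros_like(self.obs)
        self.act2 = np.zeros_like(self.act)   # behaviour next action
        self.done = np.zeros(self.capacity, dtype=np.float64)
        self.priority = np.zeros(self.capacity, dtype=np.float64)
        self.max_priority = 1.0
        self.pos = 0
        self.size = 0

    def __len__(self) -> int:
        return self.size

    def push(self, obs, act, rew, obs2, act2, done) -> None:
        if not np.isfinite(rew):
            raise ValueError("reward must be finite")
        i = self.pos
        self.obs[i], self.act[i], self.rew[i] = obs, act, rew
        self.obs2[i], self.act2[i], self.done[i] = obs2, act2, float(done)
        self.priority[i] = self.max_priority
        self.pos = (self.pos + 1) % self.capacity   # oldest entries evicted
        self.size = min(self.size + 1, self.capacity)

    def sample(self, n: int, rng: np.random.Generator, alpha: float = 0.6,
               beta: float = 1.0, uniform: bool = False):
        if self.size == 0:
            raise RuntimeError("cannot sample from an empty replay buffer")
        if uniform:
            idx = rng.integers(0, self.size, size=n)
            weights = np.ones(n)
        else:
            p = self.priority[:self.size] ** alpha
            p /= p.sum()
            idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
            idx = np.minimum(idx, self.size - 1)
            weights = (self.size * p[idx]) ** (-beta)
            weights /= weights.max()
        return {
            "obs": self.obs[idx].astype(np.float64),
            "act": self.act[idx].astype(np.float64),
            "rew": self.rew[idx],
            "obs2": self.obs2[idx].astype(np.float64),
            "act2": self.act2[idx].astype(np.float64),
            "done": self.done[idx],
            "weights": weights,
            "indices": idx,
        }

    def update_priorities(self, indices: np.ndarray, td_abs: np.ndarray,
                          eps: float = 1e-6) -> None:
        pr = np.abs(td_abs) + eps
        self.priority[indices] = pr
        self.max_priority = max(self.max_priority, float(pr.max()))


class TD3Agent:
    """Actor-critic learner over the TCN networks."""

    def __init__(self, obs_shape: tuple, action_dim: int, config: TD3Config):
        self.config = config
        self.obs_shape = tuple(obs_shape)
        self.action_dim = action_dim
        window, n_features = self.obs_shape
        rng = np.random.default_rng(config.seed)
        kw = dict(conv_filters=config.conv_filters, fc_units=config.fc_units,
                  kernel=config.kernel)
        self.actor = ActorTCN(n_features, window, action_dim, rng, **kw)
        self.critic1 = CriticTCN(n_features, window, action_dim, rng, **kw)
        self.critic2 = CriticTCN(n_features, window, action_dim, rng, **kw)
        self.target_actor = ActorTCN(n_features, window, action_dim, rng, **kw)
        self.target_critic1 = CriticTCN(n_features, window, action_dim, rng, **kw)
        self.target_critic2 = CriticTCN(n_features, window, action_dim, rng, **kw)
        copy_weights(self.actor, self.target_actor)
        copy_weights(self.critic1, self.target_critic1)
        copy_weights(self.critic2, self.target_critic2)
        self.opt_actor = Adam(self.actor.params(), lr=config.learning_rate)
        self.opt_critic1 = Adam(self.critic1.params(), lr=config.learning_rate)
        self.opt_critic2 = Adam(self.critic2.params(), lr=config.learning_rate)
        self._update_count = 0

    # -- acting ---------------------------------------------------------------
    def select_action(self, obs: np.ndarray, noise_scale: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Policy output plus zero-mean Gaussian exploration noise, clipped
        to the [-1, 1] action box. Deterministic when noise_scale is 0."""
        if noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        a = self.actor.forward(np.asarray(obs)[None])[0]
        if noise_scale > 0:
            if rng is None:
                raise ValueError("rng required when noise_scale > 0")
            a = a + rng.normal(0.0, noise_scale, size=a.shape)
        return np.clip(a, -1.0, 1.0)

    # -- losses ---------------------------------------------------------------
    def critic_targets(self, batch: dict, rng: np.random.Generator):
        """Bootstrap targets and per-sample TD errors for both critics.

        y = r + discount * (1 - done) * min(Q1', Q2')(s', a') where a' is the
        target policy's action perturbed by clipped smoothing noise. The
        bootstrap term is dropped on terminal transitions.
        """
        cfg = self.config
        a2 = self.target_actor.forward(batch["obs2"])
        noise = np.clip(
            rng.normal(0.0, cfg.target_policy_noise, size=a2.shape),
            -cfg.target_noise_clip, cfg.target_noise_clip)
        a2 = np.clip(a2 + noise, -1.0, 1.0)
        q1t = self.target_critic1.forward(batch["obs2"], a2)
        q2t = self.target_critic2.forward(batch["obs2"], a2)
        q_boot = np.minimum(q1t, q2t)
        y = batch["rew"] + cfg.discount * (1.0 - batch["done"]) * q_boot
        q1 = self.critic1.forward(batch["obs"], batch["act"])
        q2 = self.critic2.forward(batch["obs"], batch["act"])
        td1, td2 = y - q1, y - q2
        loss = 0.5 * float(np.mean(batch["weights"] * (td1**2 + td2**2)))
        return y, td1, td2, loss

    def actor_loss(self, batch: dict) -> float:
        """Mean of -Q1(s, pi(s)); the critic is only evaluated, not updated."""
        a = self.actor.forward(batch["obs"])
        q = self.critic1.forward(batch["obs"], a)
        return -float(np.mean(q))

    # -- one gradient round ---------------------------------------------------
    def update(self, buffer: ReplayBuffer, rng: np.random.Generator,
               per_beta: float = 1.0) -> dict:
        cfg = self.config
        batch = buffer.sample(cfg.batch_size, rng, alpha=cfg.per_alpha,
                              beta=per_beta, uniform=cfg.uniform_replay)
        y, td1, td2, critic_loss = self.critic_targets(batch, rng)
        if not np.isfinite(critic_loss):
            raise RuntimeError(
                f"critic loss diverged (non-finite) at update "
                f"{self._update_count}; |y| max {np.abs(y).max():.3e}")
        n = cfg.batch_size
        w = batch["weights"]
        # d/dq of 0.5 * mean(w * (y - q)^2)
        self.critic1.backward(-(w * td1) / n)
        self.opt_critic1.step(self.critic1.grads())
        self.critic2.backward(-(w * td2) / n)
        self.opt_critic2.step(self.critic2.grads())
        buffer.update_priorities(batch["indices"],
                                 0.5 * (np.abs(td1) + np.abs(td2)),
                                 eps=cfg.per_eps)

        self._update_count += 1
        info = {"critic_loss": critic_loss}
        if self._update_count % cfg.policy_delay == 0:
            a = self.actor.forward(batch["obs"])
            q = self.critic1.forward(batch["obs"], a)
            info["actor_loss"] = -float(np.mean(q))
            da = self.critic1.backward(-np.ones(n) / n)  # d(-mean q)/dq
            self.actor.backward(da)
            self.opt_actor.step(self.actor.grads())
            polyak_update(self.actor, self.target_actor, cfg.tau)
            polyak_update(self.critic1, self.target_critic1, cfg.tau)
            polyak_update(self.critic2, self.target_critic2, cfg.tau)
        return info

    def policy(self):
        """Deterministic greedy policy callable (obs -> action)."""
        def _pi(obs):
            return self.select_action(obs, noise_scale=0.0)
        return _pi


@dataclass
class TrainingResult:
    agent: TD3Agent
    log: pd.DataFrame
    best_weights: list
    best_score: float

    def best_policy(self):
        """Greedy policy of the best-scoring saved actor."""
        cfg = self.agent.config
        window, n_features = self.agent.obs_shape
        actor = ActorTCN(n_features, window, self.agent.action_dim,
                         np.random.default_rng(0),
                         conv_filters=cfg.conv_filters,
                         fc_units=cfg.fc_units, kernel=cfg.kernel)
        set_weights(actor, self.best_weights)

        def _pi(obs):
            return np.clip(actor.forward(np.asarray(obs)[None])[0], -1.0, 1.0)
        return _pi

    def restore_best(self) -> None:
        set_weights(self.agent.actor, self.best_weights)
        copy_weights(self.agent.actor, self.agent.target_actor)


def train(env_factory, config: TD3Config, n_episodes: int,
          eval_every: int = 10, eval_seed: int = 12345,
          verbose: bool = False) -> TrainingResult:
    """Run the full training protocol and return the learned policy + log.

    ``env_factory(worker_index)`` builds one environment; ``config.n_workers``
    environments are stepped in lockstep, all feeding one replay buffer and
    one learner. Every ``interactions_per_block`` total environment
    interactions the learner performs ``updates_per_block`` gradient rounds
    of ``batch_size`` SARSA samples. Exploration noise decays linearly over
    the planned interaction budget. The best evaluation policy is kept.
    """
    rng = np.random.default_rng(config.seed + 1)
    envs = [env_factory(k) for k in range(config.n_workers)]
    eval_env = env_factory(config.n_workers)  # dedicated evaluation instance
    probe = envs[0].reset(seed=0)
    obs_shape = probe.shape
    agent = TD3Agent(obs_shape, envs[0].action_dim, config)
    buffer = ReplayBuffer(config.replay_capacity, obs_shape, envs[0].action_dim)

    episode_steps = envs[0].episode_steps
    total_planned = n_episodes * episode_steps * config.n_workers
    interactions = 0
    rows = []
    best_score = -np.inf
    best_weights = get_weights(agent.actor)

    def noise_at(step: int) -> float:
        frac = min(step / max(total_planned, 1), 1.0)
        return (config.expl_noise_start
                + frac * (config.expl_noise_end - config.expl_noise_start))

    for ep in range(n_episodes):
        obs = [env.reset(seed=int(rng.integers(0, 2**31 - 1)))
               for env in envs]
        pending = [None] * config.n_workers   # SARSA awaiting its next action
        ep_reward = np.zeros(config.n_workers)
        for _t in range(episode_steps):
            for k, env in enumerate(envs):
                if interactions < config.warmup_interactions:
                    act = rng.uniform(-1.0, 1.0, size=agent.action_dim)
                else:
                    act = agent.select_action(obs[k], noise_at(interactions), rng)
                if pending[k] is not None:
                    s, a, r, s2, d = pending[k]
                    buffer.push(s, a, r, s2, act, d)
                obs2, reward, done, info = env.step(act)
                ep_reward[k] += reward
                r_scaled = reward * config.reward_scale
                if done:
                    buffer.push(obs[k], act, r_scaled, obs2,
                                np.zeros(agent.action_dim), True)
                    pending[k] = None
                else:
                    pending[k] = (obs[k], act, r_scaled, obs2, False)
                obs[k] = obs2
                interactions += 1
                ready = (len(buffer) >= config.batch_size
                         and interactions >= config.warmup_interactions)
                if ready and interactions % config.interactions_per_block == 0:
                    beta = (config.per_beta_start
                            + (1 - config.per_beta_start)
                            * min(interactions / max(total_planned, 1), 1.0))
                    for _ in range(config.updates_per_block):
                        agent.update(buffer, rng, per_beta=beta)

        purity = _final_purity(envs[0])
        row = {"episode": ep, "interactions": interactions,
               "cumulative_reward": float(ep_reward.mean()),
               "purity": purity, "noise": noise_at(interactions),
               "evaluated": False, "eval_score": np.nan}
        if (ep + 1) % eval_every == 0 or ep == n_episodes - 1:
            score = evaluate_episode(agent, eval_env, seed=eval_seed)
            row.update(evaluated=True, eval_score=score)
            if score > best_score:
                best_score = score
                best_weights = get_weights(agent.actor)
        rows.append(row)
        if verbose:
            print(f"episode {ep:4d}  R={row['cumulative_reward']:.4g}  "
                  f"purity={purity:.3f}  eval={row['eval_score']}")

    if not np.isfinite(best_score):
        best_score = max(r["cumulative_reward"] for r in rows)
        best_weights = get_weights(agent.actor)
    return TrainingResult(agent, pd.DataFrame(rows), best_weights, best_score)


def _final_purity(env) -> float:
    try:
        tanks = env._tanks()
        total = tanks.mab_prod + tanks.sm_prod
        return tanks.mab_prod / total if total > 0 else np.nan
    except AttributeError:
        return np.nan


def evaluate_episode(agent: TD3Agent, env, seed: int = 0,
                     column_params=None) -> float:
    """One exploration-free episode; returns the cumulative reward."""
    kwargs = {"seed": seed}
    if column_params is not None:
        kwargs["column_params"] = column_params
    obs = env.reset(**kwargs)
    total = 0.0
    done = False
    while not done:
        act = agent.select_action(obs, noise_scale=0.0)
        obs, reward, done, _ = env.step(act)
        total += reward
    return total


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, agent: TD3Agent, extra: dict | None = None) -> None:
    """Serialize actor/critic weights plus configuration, versioned."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "obs_shape": list(agent.obs_shape),
        "action_dim": agent.action_dim,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(agent.config).items()},
        "extra": extra or {},
    }
    arrays = {}
    for name, net in (("actor", agent.actor), ("critic1", agent.critic1),
                      ("critic2", agent.critic2)):
        for i, p in enumerate(net.params()):
            arrays[f"{name}_{i}"] = p
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TD3Agent:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    cfg_dict = meta["config"]
    cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
    config = TD3Config(**cfg_dict)
    agent = TD3Agent(tuple(meta["obs_shape"]), meta["action_dim"], config)
    for name, net in (("actor", agent.actor), ("critic1", agent.critic1),
                      ("critic2", agent.critic2)):
        for i, p in enumerate(net.params()):
            p[...] = data[f"{name}_{i}"]
    copy_weights(agent.actor, agent.target_actor)
    copy_weights(agent.critic1, agent.target_critic1)
    copy_weights(agent.critic2, agent.target_critic2)
    return agent
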