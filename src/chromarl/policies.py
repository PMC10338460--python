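"""Static benchmark recipes, hold-out evaluation and summary metrics.

The benchmark models how an operator runs a capture step: repeated
load -> wash -> elute cycles at fixed flows and switch times, with the valve
on waste except during elution. Its switch times are calibrated once by a
scripted grid search targeting high purity on the nominal column
(:func:`calibrate_recipe`) and then frozen, since a real recipe would be
fixed ahead of the campaign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .collocation import ConfigurationError
from .env import EPISODE_STEPS, ChromatographyEnv, RandomizationSpec, \
    TankMasses, randomize_column
from .flowsheet import MAX_FLOW, PRODUCT, WASTE, FlowAction
from .params import MAB, SM, ColumnParameters

__all__ = [
    "RecipePhase", "StaticRecipe", "benchmark_recipe", "calibrate_recipe",
    "EpisodeMetrics", "compute_metrics", "metrics_from_masses",
    "evaluate_policy", "run_episode", "generate_holdout_columns", "report",
]


# ---------------------------------------------------------------------------
# static recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecipePhase:
    """One fixed-flow phase of a cyclic recipe."""

    name: str
    duration: float                  # s
    F_feed: float = 0.0
    F_elute: float = 0.0
    F_wash: float = 0.0
    valve: str = WASTE

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("phase durations must be positive")
        for f in (self.F_feed, self.F_elute, self.F_wash):
            if not (0.0 <= f <= MAX_FLOW):
                raise ConfigurationError(
                    f"phase flow {f} outside [0, {MAX_FLOW}]")


@dataclass(frozen=True)
class StaticRecipe:
    """Ordered phases, cycled until the episode time limit (the final phase
    is truncated mid-cycle if the episode ends first)."""

    phases: tuple
    cycle: bool = True

    def action_at(self, t: float, control_interval: float) -> FlowAction:
        """Flow action for the control step starting at time ``t``."""
        total = sum(p.duration for p in self.phases)
        if self.cycle:
            t = t % total
        elif t >= total:
            return FlowAction()
        acc = 0.0
        for p in self.phases:
            acc += p.duration
            if t < acc:
                return FlowAction(F_feed=p.F_feed, F_elute=p.F_elute,
                                  F_wash=p.F_wash, valve=p.valve)
        return FlowAction()

    def raw_action_at(self, step: int, control_interval: float) -> np.ndarray:
        """The recipe's action expressed in the agent's raw [-1, 1] space."""
        a = self.action_at(step * control_interval, control_interval)
        raw_flows = 2.0 * np.array([a.F_feed, a.F_elute, a.F_wash]) / MAX_FLOW - 1.0
        valve = 1.0 if a.valve == PRODUCT else -1.0
        return np.concatenate([raw_flows, [valve]])

    def schedule(self, episode_steps: int, control_interval: float):
        return [self.raw_action_at(k, control_interval)
                for k in range(episode_steps)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"cycle": self.cycle,
                            "phases": [vars(p) for p in self.phases]}, fh)

    @classmethod
    def from_yaml(cls, path) -> "StaticRecipe":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(tuple(RecipePhase(**p) for p in d["phases"]),
                   cycle=d.get("cycle", True))


#: frozen default switch times (s) of the human-style benchmark; produced by
#: ``calibrate_recipe`` on the nominal column (highest product mAb among
#: candidates reaching 99% purity; see docs/methods.md)
DEFAULT_RECIPE_DURATIONS = {"load": 300.0, "wash": 60.0, "elute": 150.0,
                            "elute_delay": 0.0}


def benchmark_recipe(durations: dict | None = None,
                     flow: float = MAX_FLOW) -> StaticRecipe:
    """Human-style constant-flow load/wash/elute cycle.

    Loading and washing run to waste; elution runs to product after a short
    to-waste delay that lets the wash tail clear the outlet. ``durations``
    overrides any of the default phase lengths (seconds).
    """
    d = dict(DEFAULT_RECIPE_DURATIONS)
    if durations:
        d.update(durations)
    phases = [
        RecipePhase("load", d["load"], F_feed=flow, valve=WASTE),
        RecipePhase("wash", d["wash"], F_wash=flow, valve=WASTE),
    ]
    if d.get("elute_delay", 0) > 0:
        phases.append(RecipePhase("elute_delay", d["elute_delay"],
                                  F_elute=flow, valve=WASTE))
    phases.append(RecipePhase("elute", d["elute"], F_elute=flow, valve=PRODUCT))
    return StaticRecipe(tuple(phases))


def calibrate_recipe(env: ChromatographyEnv,
                     load_grid=(150.0, 225.0, 300.0),
                     wash_grid=(60.0, 120.0, 180.0),
                     delay_grid=(15.0, 30.0, 60.0),
                     elute_grid=(90.0, 150.0, 210.0),
                     purity_target: float = 99.0,
                     seed: int = 0) -> tuple:
    """Scripted grid search over benchmark switch times on one column.

    Among candidates reaching ``purity_target`` percent product purity the
    one with the largest product mAb mass wins; if none reaches it, the
    purest candidate wins. Returns (durations dict, per-candidate DataFrame).
    """
    rows = []
    for load, wash, delay, elute in itertools.product(
            load_grid, wash_grid, delay_grid, elute_grid):
        durations = {"load": load, "wash": wash, "elute_delay": delay,
                     "elute": elute}
        recipe = benchmark_recipe(durations)
        metrics, _ = run_episode(env, recipe, seed=seed)
        rows.append({**durations, "purity_pct": metrics.purity_pct,
                     "mab_prod": metrics.mab_prod})
    df = pd.DataFrame(rows)
    ok = df[df.purity_pct >= purity_target]
    best = (ok.sort_values("mab_prod", ascending=False) if len(ok)
            else df.sort_values("purity_pct", ascending=False)).iloc[0]
    durations = {k: float(best[k]) for k in
                 ("load", "wash", "elute_delay", "elute")}
    return durations, df


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EpisodeMetrics:
    """Headline numbers of one episode."""

    reward_score: float
    mab_prod: float               # g
    sm_prod: float                # g
    mab_waste: float              # g
    purity_pct: float             # 100 * mab_prod / (mab_prod + sm_prod)
    recovered_cycled_pct: float   # 100 * mab_prod / (mab_prod + mab_waste)
    recovered_total_pct: float    # 100 * mab_prod / initial feed-vessel mAb
    purity_defined: bool = True
    failed: bool = False
    error: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "reward_score", "mab_prod", "sm_prod", "mab_waste", "purity_pct",
            "recovered_cycled_pct", "recovered_total_pct")}


def metrics_from_masses(mab_prod: float, sm_prod: float, mab_waste: float,
                        initial_feed_mab: float = np.nan,
                        reward_score: float = np.nan) -> EpisodeMetrics:
    """Metric formulas applied to tank masses (g)."""
    denom = mab_prod + sm_prod
    purity_defined = denom > 0
    # tolerated numerical undershoot can leave a tank mass a hair negative;
    # percentages are clamped onto [0, 100]
    clamp = lambda v: float(np.clip(v, 0.0, 100.0))  # noqa: E731
    purity = clamp(100.0 * mab_prod / denom) if purity_defined else 0.0
    cycled = mab_prod + mab_waste
    recovered_cycled = clamp(100.0 * mab_prod / cycled) if cycled > 0 else 0.0
    recovered_total = (clamp(100.0 * mab_prod / initial_feed_mab)
                       if initial_feed_mab and np.isfinite(initial_feed_mab)
                       else np.nan)
    return EpisodeMetrics(reward_score, mab_prod, sm_prod, mab_waste, purity,
                          recovered_cycled, recovered_total,
                          purity_defined=purity_defined)


def compute_metrics(env: ChromatographyEnv) -> EpisodeMetrics:
    """Episode metrics from a finished environment's flowsheet bookkeeping."""
    tanks: TankMasses = env._tanks()
    initial_mab = env.system.initial_feed_mass[MAB]
    return metrics_from_masses(tanks.mab_prod, tanks.sm_prod, tanks.mab_waste,
                               initial_feed_mab=initial_mab,
                               reward_score=env.cumulative_reward)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def run_episode(env: ChromatographyEnv, policy, seed: int = 0,
                column_params: ColumnParameters | None = None):
    """One exploration-free episode under ``policy`` (a callable
    obs -> raw action, or a StaticRecipe). Returns (metrics, env)."""
    obs = env.reset(seed=seed, column_params=column_params)
    h = env.base_params.h
    done = False
    step = 0
    while not done:
        if isinstance(policy, StaticRecipe):
            raw = policy.raw_action_at(step, h)
        else:
            raw = policy(obs)
        obs, _, done, _ = env.step(raw)
        step += 1
    return compute_metrics(env), env


def generate_holdout_columns(base: ColumnParameters | None = None,
                             n_columns: int = 8, S: float = 0.05,
                             seed: int = 2023) -> list:
    """The fixed validation set: ``n_columns`` perturbed columns drawn once
    with scaling factor ``S`` from deterministic per-column seeds."""
    base = base if base is not None else ColumnParameters()
    spec = RandomizationSpec(S=S)
    columns = []
    for k in range(n_columns):
        rng = np.random.default_rng([seed, k])
        columns.append(randomize_column(base, spec, rng))
    return columns


def evaluate_policy(policy, columns: list, env: ChromatographyEnv,
                    seeds: list | None = None) -> pd.DataFrame:
    """One episode per column, no exploration noise.

    A failed episode is recorded (``failed=True``) without aborting the
    batch. Returns a per-column DataFrame; aggregate with ``.mean()`` over
    the metric columns (unweighted arithmetic mean over columns).
    """
    if not columns:
        raise ValueError("need at least one column")
    if seeds is None:
        seeds = list(range(len(columns)))
    rows = []
    for k, (col, seed) in enumerate(zip(columns, seeds)):
        try:
            metrics, _ = run_episode(env, policy, seed=seed, column_params=col)
        except Exception as exc:   # noqa: BLE001 - recorded per column
            metrics = EpisodeMetrics(np.nan, np.nan, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, purity_defined=False,
                                     failed=True, error=str(exc))
        rows.append({"column": k, "seed": seed, "failed": metrics.failed,
                     **metrics.as_dict()})
    return pd.DataFrame(rows)


def report(agent_metrics: pd.DataFrame,
           benchmark_metrics: pd.DataFrame) -> dict:
    """Agent-vs-benchmark summary with productivity / purity deltas."""
    cols = ["reward_score", "mab_prod", "sm_prod", "mab_waste", "purity_pct",
            "recovered_cycled_pct", "recovered_total_pct"]
    a = agent_metrics[cols].mean()
    b = benchmark_metrics[cols].mean()
    out = {
        "agent_mean": a.to_dict(),
        "benchmark_mean": b.to_dict(),
        "productivity_increase_pct":
            100.0 * (a.mab_prod - b.mab_prod) / b.mab_prod
            if b.mab_prod else np.nan,
        "purity_gap_pp": b.purity_pct - a.purity_pct,
    }
    return out


def report_table(summary: dict) -> pd.DataFrame:
    """Tabular rendering of a :func:`report` summary."""
    rows = []
    for key in summary["agent_mean"]:
        rows.append({"metric": key, "agent": summary["agent_mean"][key],
                     "benchmark": summary["benchmark_mean"][key]})
    return pd.DataFrame(rows)
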