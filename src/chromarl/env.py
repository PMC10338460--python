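"""Episodic control environment for the bind-elute process.

An episode runs 3000 s with one control decision every 15 s (200 steps). At
each step the agent commands three upstream flow rates in [0, 2e-6] m^3/s and
the outlet valve routing; it observes a 10-step window of normalized process
features (commanded wash flow, per-component mass fed into the column inlet,
mass leaving the outlet, and approximate mass held in the column).

The reward is staged: a mass-sorting term weighs mAb routed to product
against impurities routed to waste, scaled by the product-tank purity
(floored at 0.1), plus a clean-product excess term, a purity bonus that turns
on above 30% product purity, and an end-of-episode penalty for mAb left in
the column. The per-step reward is the telescoped difference of the
cumulative score.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .collocation import ConfigurationError
from .flowsheet import (MAX_FLOW, PRODUCT, WASTE, ChromatographySystem,
                        FlowAction, VesselState, default_vessels)
from .grm import ColumnSimulator
from .params import MAB, SM, WASH, ColumnParameters

__all__ = [
    "RandomizationSpec", "randomize_column", "RewardConfig", "TankMasses",
    "RewardBreakdown", "reward_mass", "reward_concentration", "reward_clean",
    "penalty_remaining", "reward_purity", "total_reward", "apply_action",
    "make_observation", "ChromatographyEnv", "calibrate_observation_maxima",
    "EPISODE_STEPS", "OBS_WINDOW", "N_FEATURES",
]

EPISODE_STEPS = 200     # 3000 s / 15 s control interval
OBS_WINDOW = 10
N_FEATURES = 13         # wash flow + 3 x per-component (4) mass features

RANDOMIZED_PARAMETERS = ("D_ax", "D_p", "eps_c", "eps_p")


# ---------------------------------------------------------------------------
# column-to-column variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomizationSpec:
    """Multiplicative parameter perturbation x -> x (1 + S*X), X ~ U(-1, 1).

    ``S = 0.2`` is the training condition; hold-out columns use ``S = 0.05``.
    """

    S: float = 0.2
    parameters: tuple = RANDOMIZED_PARAMETERS

    def __post_init__(self):
        if not (0.0 < self.S <= 1.0):
            raise ConfigurationError(f"scaling factor S must be in (0,1], got {self.S}")


def randomize_column(base: ColumnParameters, spec: RandomizationSpec,
                     rng: np.random.Generator) -> ColumnParameters:
    """Perturb the listed parameters with independent uniform errors.

    Each parameter is scaled by ``1 + S*X`` with its own draw of
    ``X ~ U(-1, 1)``; array-valued parameters (per-component dispersion
    coefficients) share one draw, since the perturbation models a property of
    the packed column, not of a solute.
    """
    updates = {}
    for name in spec.parameters:
        x = getattr(base, name)
        X = rng.uniform(-1.0, 1.0)
        updates[name] = x * (1.0 + spec.S * X)
    return base.replace(**updates)


# ---------------------------------------------------------------------------
# reward function
# ---------------------------------------------------------------------------

@dataclass
class TankMasses:
    """Cumulative product/waste tank masses entering the reward, g."""

    mab_prod: float = 0.0
    mab_waste: float = 0.0
    sm_prod: float = 0.0
    sm_waste: float = 0.0


@dataclass(frozen=True)
class RewardConfig:
    alpha: float = 5.0          # mAb-vs-impurity weight in the mass term
    beta: float = 1.0e6         # overall reward scale
    gamma: float = 100.0        # purity-bonus weight
    x_floor: float = 0.1        # purity floor in the concentration term
    #: column-holdup threshold: 5% of the mAb mass loadable in one episode
    #: at maximum flow (0.05 * 2e-6 m^3/s * 1e-8 g/m^3 * 3000 s)
    mab_max: float = 3.0e-12


@dataclass
class RewardBreakdown:
    """All intermediate reward terms for one step."""

    delta_mab: float
    delta_sm: float
    R_mass: float
    R_concentration: float
    R_clean: float
    R_purity: float
    P_remaining: float
    R: float                   # cumulative score
    delta_R: float             # step reward (telescoped difference)


def reward_mass(tanks: TankMasses, cfg: RewardConfig = RewardConfig()) -> float:
    """alpha * (mab_prod - mab_waste) + (sm_waste - sm_prod)."""
    delta_mab = tanks.mab_prod - tanks.mab_waste
    delta_sm = tanks.sm_waste - tanks.sm_prod
    return cfg.alpha * delta_mab + delta_sm


def reward_concentration(tanks: TankMasses,
                         cfg: RewardConfig = RewardConfig()) -> float:
    """Product-tank purity fraction floored at ``x_floor`` (0/0 -> floor)."""
    total = tanks.mab_prod + tanks.sm_prod
    if total <= 0.0:
        return cfg.x_floor
    return max(tanks.mab_prod / total, cfg.x_floor)


def reward_clean(tanks: TankMasses) -> float:
    """max(mab_prod - sm_prod, 0)."""
    return max(tanks.mab_prod - tanks.sm_prod, 0.0)


def penalty_remaining(mab_col: float, done: bool,
                      cfg: RewardConfig = RewardConfig()) -> float:
    """mAb held up in the column, charged only at episode end and only
    above the ``mab_max`` threshold."""
    if mab_col < 0:
        raise ValueError("mab_col must be non-negative")
    if done and mab_col > cfg.mab_max:
        return mab_col
    return 0.0


def reward_purity(R_concentration: float) -> float:
    """Linear purity bonus: 0 at 30% product purity, 1 at 100%."""
    return max((R_concentration - 0.3) / 0.7, 0.0)


def total_reward(tanks: TankMasses, mab_col: float, done: bool,
                 prev_R: float = 0.0,
                 cfg: RewardConfig = RewardConfig()) -> RewardBreakdown:
    """Cumulative score R and its step difference delta_R."""
    R_m = reward_mass(tanks, cfg)
    R_c = reward_concentration(tanks, cfg)
    R_cl = reward_clean(tanks)
    R_p = reward_purity(R_c)
    P = penalty_remaining(mab_col, done, cfg)
    R = cfg.beta * (R_m * R_c + R_cl + cfg.gamma * R_p - P * (1.0 if done else 0.0))
    return RewardBreakdown(
        delta_mab=tanks.mab_prod - tanks.mab_waste,
        delta_sm=tanks.sm_waste - tanks.sm_prod,
        R_mass=R_m, R_concentration=R_c, R_clean=R_cl, R_purity=R_p,
        P_remaining=P, R=R, delta_R=R - prev_R)


# ---------------------------------------------------------------------------
# actions and observations
# ---------------------------------------------------------------------------

def apply_action(raw_action: np.ndarray) -> FlowAction:
    """Map a raw policy output in [-1, 1]^4 onto flows and valve routing.

    The first three entries are affinely mapped to [0, MAX_FLOW] (values
    outside [-1, 1] are clipped); the fourth is thresholded at its midpoint:
    negative -> waste, non-negative -> product.
    """
    a = np.asarray(raw_action, dtype=float)
    if a.shape != (4,) or not np.all(np.isfinite(a)):
        raise ValueError(f"raw action must be a finite 4-vector, got {a!r}")
    flows = np.clip((a[:3] + 1.0) * 0.5, 0.0, 1.0) * MAX_FLOW
    valve = WASTE if a[3] < 0 else PRODUCT
    return FlowAction(F_feed=flows[0], F_elute=flows[1], F_wash=flows[2],
                      valve=valve)


def make_observation(history: list, calibration: np.ndarray,
                     window: int = OBS_WINDOW) -> np.ndarray:
    """Normalized sliding window over per-step feature vectors.

    Returns the last ``window`` rows, left-padded by repeating the earliest
    recorded step; every feature is divided by its calibration maximum and
    clipped to [0, 1].
    """
    if not history:
        raise ValueError("at least one step must be recorded")
    calibration = np.asarray(calibration, dtype=float)
    if calibration.shape != (len(history[0]),) or np.any(calibration <= 0):
        raise ConfigurationError("calibration maxima missing or non-positive")
    rows = history[-window:]
    if len(rows) < window:
        rows = [history[0]] * (window - len(rows)) + rows
    obs = np.asarray(rows, dtype=float) / calibration
    return np.clip(obs, 0.0, 1.0)


def _features(record) -> np.ndarray:
    """Per-step observation features from a flowsheet log record."""
    return np.concatenate((
        [record.action.F_wash],
        record.inlet_mass,
        record.outlet_mass,
        record.column_mass,
    ))


def calibrate_observation_maxima(params: ColumnParameters,
                                 vessels: VesselState | None = None,
                                 episode_steps: int = EPISODE_STEPS,
                                 n_substeps: int = 1) -> np.ndarray:
    """Scripted calibration run producing per-feature normalization maxima.

    Drives the nominal column through a maximum-flow load / elute / wash
    sequence (half the episode loading, then a quarter each eluting and
    washing), records the feature vector at every step and returns the
    element-wise maxima, floored to avoid division by zero.
    """
    system = ChromatographySystem(params, vessels=vessels, n_substeps=n_substeps)
    phases = [
        (episode_steps // 2, FlowAction(F_feed=MAX_FLOW, valve=WASTE)),
        (episode_steps // 4, FlowAction(F_elute=MAX_FLOW, valve=PRODUCT)),
        (episode_steps - episode_steps // 2 - episode_steps // 4,
         FlowAction(F_wash=MAX_FLOW, valve=WASTE)),
    ]
    maxima = np.zeros(N_FEATURES)
    for n_steps, action in phases:
        for _ in range(n_steps):
            rec = system.step(action)
            maxima = np.maximum(maxima, _features(rec))
    maxima[0] = MAX_FLOW  # the commanded wash flow bound is known exactly
    return np.maximum(maxima, 1e-300)


# ---------------------------------------------------------------------------
# the environment
# ---------------------------------------------------------------------------

class ChromatographyEnv:
    """Episodic environment: ``reset(seed) -> obs``,
    ``step(raw_action) -> (obs, reward, terminated, info)``.

    Each ``reset`` draws a fresh perturbed column from the randomization
    spec (domain randomization) unless ``column_params`` pins one, e.g. for
    hold-out evaluation. All randomness flows through the ``reset`` seed, so
    a fixed (seed, action sequence) pair reproduces a trajectory bit for bit.
    """

    def __init__(self, base_params: ColumnParameters | None = None,
                 randomization: RandomizationSpec | None = RandomizationSpec(),
                 reward_config: RewardConfig | None = None,
                 episode_steps: int = EPISODE_STEPS,
                 calibration: np.ndarray | None = None,
                 vessels: VesselState | None = None,
                 n_substeps: int = 1):
        self.base_params = base_params if base_params is not None else ColumnParameters()
        self.randomization = randomization
        self.episode_steps = int(episode_steps)
        self.n_substeps = n_substeps
        self._vessel_template = vessels
        if reward_config is None:
            vt = vessels if vessels is not None else default_vessels()
            mab_max = 0.05 * MAX_FLOW * vt.conc["feed"][MAB] \
                * self.episode_steps * self.base_params.h
            reward_config = RewardConfig(mab_max=mab_max)
        self.reward_config = reward_config
        if calibration is None:
            calibration = calibrate_observation_maxima(
                self.base_params, vessels=vessels,
                episode_steps=self.episode_steps, n_substeps=n_substeps)
        self.calibration = np.asarray(calibration, dtype=float)
        self._rng = np.random.default_rng(0)
        self.system: ChromatographySystem | None = None

    @property
    def observation_shape(self) -> tuple:
        return (OBS_WINDOW, N_FEATURES)

    @property
    def action_dim(self) -> int:
        return 4

    def reset(self, seed: int | None = None,
              column_params: ColumnParameters | None = None) -> np.ndarray:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        if column_params is not None:
            params = column_params
        elif self.randomization is not None:
            params = randomize_column(self.base_params, self.randomization,
                                      self._rng)
        else:
            params = self.base_params
        self.column_params = params
        self.system = ChromatographySystem(params, vessels=self._vessel_template,
                                           n_substeps=self.n_substeps)
        self._step_count = 0
        self._prev_R = 0.0
        self._history: list = [np.zeros(N_FEATURES)]
        return make_observation(self._history, self.calibration)

    def _tanks(self) -> TankMasses:
        tm = self.system.vessels.tank_mass
        return TankMasses(mab_prod=tm[PRODUCT][MAB], mab_waste=tm[WASTE][MAB],
                          sm_prod=tm[PRODUCT][SM], sm_waste=tm[WASTE][SM])

    def step(self, raw_action: np.ndarray):
        if self.system is None:
            raise RuntimeError("call reset() before step()")
        if self._step_count >= self.episode_steps:
            raise RuntimeError("episode finished; call reset()")
        action = apply_action(raw_action)
        rec = self.system.step(action)
        self._step_count += 1
        done = self._step_count >= self.episode_steps
        tanks = self._tanks()
        # tolerated numerical undershoot can leave the column inventory a
        # hair negative; the penalty term is defined for mass >= 0
        mab_col = max(float(rec.column_mass[MAB]), 0.0)
        breakdown = total_reward(tanks, mab_col, done,
                                 prev_R=self._prev_R, cfg=self.reward_config)
        self._prev_R = breakdown.R
        self._history.append(_features(rec))
        obs = make_observation(self._history, self.calibration)
        info = {"reward_breakdown": breakdown, "tanks": tanks,
                "column_mass": rec.column_mass, "action": action,
                "flows": action.flows, "t": rec.t}
        return obs, breakdown.delta_R, done, info

    @property
    def cumulative_reward(self) -> float:
        return self._prev_R
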