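"""Everything around the column: vessels, flow controller, valve, tanks.

Upstream sit three vessels - feed (harvested culture fluid containing the
mAb, impurities and a trace salt background), elution buffer (high salt) and
wash buffer (inert tracer). Their outlets merge in a zero-holdup flow
controller feeding the column inlet; at the outlet a valve routes the stream
to either the product or the waste collection tank. Upstream compositions
are constant within an episode; only volumes deplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import COMPONENTS, MAB, N_COMP, SALT, SM, WASH, ColumnParameters
from .collocation import ConfigurationError
from .grm import ColumnSimulator, ColumnState, column_mass, outlet_concentration

__all__ = ["FlowAction", "VesselState", "ChromatographySystem", "mix_inlet",
           "update_vessels", "route_outlet", "total_mass_balance",
           "MAX_FLOW", "default_vessels"]

MAX_FLOW = 2.0e-6        # upper bound of each commanded flow, m^3/s
PRODUCT, WASTE = "product", "waste"

#: feed-vessel concentrations, g/m^3: trace salt background, the mAb product
#: at one tenth of the impurity level, and the lumped impurities
FEED_CONC = {"salt": 1e-7, "mab": 0.1e-7, "sm": 1e-7, "wash": 0.0}
#: elution buffer: salt only. 10 g/m^3 makes the desorption time constant
#: 1/(k_d * c_salt) = 10 s, shorter than one 15 s control interval, so a
#: load-wash-elute cycle completes well within a 3000 s episode.
ELUTE_SALT_CONC = 10.0
#: wash buffer: inert tracer at the feed's concentration scale
WASH_CONC = 1e-7
#: default upstream volume: exactly exhaustible at MAX_FLOW over 3000 s
DEFAULT_VESSEL_VOLUME = 6.0e-3


class ActionBoundsError(ValueError):
    """A commanded flow left [0, MAX_FLOW] or the valve target is unknown."""


@dataclass
class FlowAction:
    """Commanded upstream flow rates (m^3/s) and outlet routing."""

    F_feed: float = 0.0
    F_elute: float = 0.0
    F_wash: float = 0.0
    valve: str = WASTE

    def __post_init__(self):
        for name in ("F_feed", "F_elute", "F_wash"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or v > MAX_FLOW:
                raise ActionBoundsError(
                    f"{name}={v!r} outside [0, {MAX_FLOW}]")
        if self.valve not in (PRODUCT, WASTE):
            raise ActionBoundsError(f"unknown valve target {self.valve!r}")

    @property
    def flows(self) -> np.ndarray:
        return np.array([self.F_feed, self.F_elute, self.F_wash])

    @property
    def F_in(self) -> float:
        return float(self.flows.sum())


@dataclass
class VesselState:
    """Upstream vessel volumes/compositions and collection-tank inventories."""

    volumes: dict = field(default_factory=dict)        # name -> m^3
    conc: dict = field(default_factory=dict)           # name -> (n_comp,) g/m^3
    tank_mass: dict = field(default_factory=dict)      # tank -> (n_comp,) g
    tank_volume: dict = field(default_factory=dict)    # tank -> m^3

    def copy(self) -> "VesselState":
        return VesselState(
            dict(self.volumes), {k: v.copy() for k, v in self.conc.items()},
            {k: v.copy() for k, v in self.tank_mass.items()},
            dict(self.tank_volume))

    def upstream_mass(self) -> np.ndarray:
        """Per-component mass held in the upstream vessels, g."""
        total = np.zeros(N_COMP)
        for name, V in self.volumes.items():
            total += V * self.conc[name]
        return total


def default_vessels(volume: float = DEFAULT_VESSEL_VOLUME) -> VesselState:
    conc = {
        "feed": np.array([FEED_CONC["salt"], FEED_CONC["mab"],
                          FEED_CONC["sm"], FEED_CONC["wash"]]),
        "elute": np.array([ELUTE_SALT_CONC, 0.0, 0.0, 0.0]),
        "wash": np.array([0.0, 0.0, 0.0, WASH_CONC]),
    }
    return VesselState(
        volumes={"feed": volume, "elute": volume, "wash": volume},
        conc=conc,
        tank_mass={PRODUCT: np.zeros(N_COMP), WASTE: np.zeros(N_COMP)},
        tank_volume={PRODUCT: 0.0, WASTE: 0.0},
    )


def mix_inlet(action: FlowAction, vessels: VesselState):
    """Combine upstream streams: F_in = sum F_i, c_in,i = sum F_j c_j,i / F_in.

    All flows zero is a defined degenerate case with zero inlet
    concentrations. Returns ``(F_in, inlet_conc)``.
    """
    F = {"feed": action.F_feed, "elute": action.F_elute, "wash": action.F_wash}
    F_in = sum(F.values())
    if F_in == 0.0:
        return 0.0, np.zeros(N_COMP)
    conc = sum(F[name] * vessels.conc[name] for name in F) / F_in
    return F_in, conc


def update_vessels(vessels: VesselState, action: FlowAction,
                   h: float) -> tuple[VesselState, FlowAction]:
    """Deplete upstream volumes by F_i*h (dV/dt = F).

    A vessel that would go negative is drained exactly to zero and its flow
    reduced for the step accordingly; the possibly-reduced action actually
    delivered is returned alongside the new vessel state.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    out = vessels.copy()
    delivered = {}
    for name, attr in (("feed", "F_feed"), ("elute", "F_elute"),
                       ("wash", "F_wash")):
        F = getattr(action, attr)
        avail = out.volumes[name]
        take = min(F * h, avail)
        out.volumes[name] = avail - take
        delivered[attr] = take / h
    return out, FlowAction(valve=action.valve, **delivered)


def route_outlet(valve: str, outlet_conc: np.ndarray, F_in: float,
                 h: float, vessels: VesselState) -> VesselState:
    """Accumulate the column effluent, c_i*F_in*h, into exactly one tank."""
    if valve not in (PRODUCT, WASTE):
        raise ActionBoundsError(f"unknown valve target {valve!r}")
    if F_in < 0:
        raise ValueError("F_in must be non-negative")
    out = vessels.copy()
    out.tank_mass[valve] = out.tank_mass[valve] + np.asarray(outlet_conc) * F_in * h
    out.tank_volume[valve] += F_in * h
    return out


@dataclass
class SystemLogRecord:
    t: float
    action: FlowAction
    outlet: np.ndarray
    inlet_mass: np.ndarray
    outlet_mass: np.ndarray
    column_mass: np.ndarray
    tank_mass_product: np.ndarray
    tank_mass_waste: np.ndarray


class ChromatographySystem:
    """Column plus surrounding flowsheet, stepped at the control interval."""

    def __init__(self, params: ColumnParameters,
                 vessels: VesselState | None = None,
                 simulator: ColumnSimulator | None = None,
                 n_substeps: int = 1):
        self.params = params
        self.simulator = simulator if simulator is not None else ColumnSimulator(params)
        self.initial_vessels = (vessels if vessels is not None
                                else default_vessels()).copy()
        self.n_substeps = n_substeps
        self.reset()

    def reset(self) -> None:
        self.vessels = self.initial_vessels.copy()
        self.column = ColumnState.zeros(self.simulator.grid)
        self.t = 0.0
        self.log: list[SystemLogRecord] = []

    @property
    def initial_feed_mass(self) -> np.ndarray:
        """Per-component mass initially in the feed vessel, g."""
        return (self.initial_vessels.volumes["feed"]
                * self.initial_vessels.conc["feed"])

    def step(self, action: FlowAction, h: float | None = None) -> SystemLogRecord:
        """Apply one control action over a step of length ``h`` (default:
        the column solver timestep)."""
        h = self.params.h if h is None else float(h)
        self.vessels, delivered = update_vessels(self.vessels, action, h)
        F_in, inlet_conc = mix_inlet(delivered, self.vessels)
        self.column = self.simulator.step(self.column, F_in, inlet_conc,
                                          h=h, n_substeps=self.n_substeps)
        out_conc = outlet_concentration(self.column)
        # effluent accounted at the end-of-step concentration: the same
        # quadrature backward Euler applies to the column interior, which
        # keeps the discrete system mass balance closed
        self.vessels = route_outlet(delivered.valve, out_conc, F_in, h,
                                    self.vessels)
        self.t += h
        rec = SystemLogRecord(
            t=self.t, action=delivered, outlet=out_conc,
            inlet_mass=inlet_conc * F_in * h,
            outlet_mass=out_conc * F_in * h,
            column_mass=column_mass(self.column, self.params,
                                    self.simulator.grid),
            tank_mass_product=self.vessels.tank_mass[PRODUCT].copy(),
            tank_mass_waste=self.vessels.tank_mass[WASTE].copy(),
        )
        self.log.append(rec)
        return rec

    def total_mass_balance(self) -> np.ndarray:
        """Per-component mass over vessels + tanks + column, g (conserved)."""
        return (self.vessels.upstream_mass()
                + self.vessels.tank_mass[PRODUCT]
                + self.vessels.tank_mass[WASTE]
                + column_mass(self.column, self.params, self.simulator.grid))


def total_mass_balance(system: ChromatographySystem) -> np.ndarray:
    return system.total_mass_balance()


def write_trajectory(path, system: ChromatographySystem) -> None:
    """Episode trajectory log: one row per control step, delimited text."""
    import pandas as pd

    rows = []
    for r in system.log:
        row = {"time_s": r.t, "F_feed": r.action.F_feed,
               "F_elute": r.action.F_elute, "F_wash": r.action.F_wash,
               "valve": r.action.valve}
        for i, name in enumerate(COMPONENTS.names):
            row[f"outlet_{name}"] = r.outlet[i]
            row[f"product_{name}"] = r.tank_mass_product[i]
            row[f"waste_{name}"] = r.tank_mass_waste[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_chromatogram(path, times: np.ndarray, outlet: np.ndarray) -> None:
    """Chromatogram export: time_s plus one outlet column per component."""
    import pandas as pd

    df = pd.DataFrame({"time_s": times})
    for i, name in enumerate(COMPONENTS.names):
        df[f"c_out_{name}"] = outlet[:, i]
    df.to_csv(path, index=False)
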