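"""Physical and numerical parameters of the bind-elute column.

Component convention (fixed across the whole package):

====  ======  =========================================================
idx   name    role
====  ======  =========================================================
0     salt    mobile-phase modulator; inert (never binds)
1     mab     monoclonal antibody, the product; binds via the
              mobile-phase-modulator Langmuir kinetics
2     sm      "spent media" - lumped impurity pseudo-component; inert
3     wash    wash-buffer tracer; inert
====  ======  =========================================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .collocation import ConfigurationError

__all__ = ["ComponentSet", "COMPONENTS", "SALT", "MAB", "SM", "WASH",
           "ColumnParameters"]

SALT, MAB, SM, WASH = 0, 1, 2, 3


@dataclass(frozen=True)
class ComponentSet:
    """Ordered component identifiers and their roles."""

    names: tuple = ("salt", "mab", "sm", "wash")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def binding(self) -> tuple:
        """Names of components with adsorption kinetics."""
        return ("mab",)


COMPONENTS = ComponentSet()
N_COMP = COMPONENTS.n


def _per_component(value_map: dict) -> np.ndarray:
    out = np.zeros(N_COMP)
    for name, v in value_map.items():
        out[COMPONENTS.index(name)] = v
    return out


@dataclass
class ColumnParameters:
    """General-rate-model constants for one column, SI units.

    Defaults are the nominal column of the simulation study: a 0.197 m
    protein-A capture column with four tracked components. Per-component
    arrays follow the (salt, mab, sm, wash) ordering of :data:`COMPONENTS`.
    """

    L: float = 0.197                      # column length, m
    A_c: float = 7.85e-5                  # cross-section area, m^2
    eps_c: float = 0.4                    # interstitial (column) porosity
    eps_p: float = 0.333                  # particle porosity
    r_p: float = 42.5e-5                  # particle radius, m
    D_ax: np.ndarray = field(             # axial dispersion, m^2/s
        default_factory=lambda: np.full(N_COMP, 1e-7))
    D_p: np.ndarray = field(              # pore diffusion, m^2/s
        default_factory=lambda: np.full(N_COMP, 1.2e-6))
    k_f: np.ndarray = field(              # film mass transfer, m/s
        default_factory=lambda: np.full(N_COMP, 8.0e-3))
    k_a: np.ndarray = field(              # adsorption rate, 1/s
        default_factory=lambda: _per_component({"mab": 1.0}))
    k_d: np.ndarray = field(              # desorption rate, 1/s
        default_factory=lambda: _per_component({"mab": 0.01}))
    q_max: np.ndarray = field(            # adsorption capacity, g/m^3
        default_factory=lambda: _per_component({"mab": 1.0}))
    gamma_mpm: float = 0.0                # modulator exponent (adsorption)
    beta_mpm: float = 1.0                 # modulator power (desorption)
    N_z: int = 40                         # axial elements
    N_r: int = 5                          # radial elements
    N_p: int = 4                          # collocation polynomial order
    h: float = 15.0                       # solver timestep, s

    def __post_init__(self):
        for name in ("D_ax", "D_p", "k_f", "k_a", "k_d", "q_max"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 0:
                v = np.full(N_COMP, float(v))
            if v.shape != (N_COMP,):
                raise ConfigurationError(
                    f"{name} must be scalar or length-{N_COMP}, got {v.shape}")
            object.__setattr__(self, name, v)
        self.validate()

    def validate(self) -> None:
        if not (self.L > 0 and self.A_c > 0 and self.r_p > 0):
            raise ConfigurationError("L, A_c and r_p must be positive")
        if not (0 < self.eps_c < 1 and 0 < self.eps_p < 1):
            raise ConfigurationError("porosities must lie in (0, 1)")
        for name in ("D_ax", "D_p", "k_f", "k_a", "k_d", "q_max"):
            if np.any(getattr(self, name) < 0):
                raise ConfigurationError(f"{name} entries must be >= 0")
        if min(self.N_z, self.N_r, self.N_p) < 1:
            raise ConfigurationError("N_z, N_r and N_p must be >= 1")
        if self.h <= 0:
            raise ConfigurationError("timestep h must be positive")
        # salt (the modulator) and the wash tracer never bind
        for name in ("salt", "wash"):
            i = COMPONENTS.index(name)
            if self.k_a[i] != 0 or self.k_d[i] != 0 or self.q_max[i] != 0:
                raise ConfigurationError(f"component '{name}' must be inert")

    def replace(self, **kwargs) -> "ColumnParameters":
        return dataclasses.replace(self, **kwargs)

    # -- flat key/value config round-trip ---------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown column parameters: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ColumnParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
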