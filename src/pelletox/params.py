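"""Kinetic and transport parameters for pellet oxygen simulation.

All parameters live in an hour-based SI-like unit system (m, h, kg m^-3),
the system in which the literature values are tabulated.  Concentration
I/O in mg L^-1 is converted at module boundaries (1 mg L^-1 = 1e-3 kg m^-3).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Literal

#: 1 mg L^-1 in kg m^-3
MG_PER_L = 1e-3
#: 1 micrometre in metres
UM = 1e-6

#: Oxygen saturation of the profiling medium at 37 degC, mg L^-1.
O2_SATURATION_MG_PER_L = 6.7

Variant = Literal["growth_only", "growth_plus_maintenance"]


@dataclass(frozen=True)
class KineticParams:
    """Transport and consumption parameters of the pellet oxygen model.

    Defaults are the literature values used for *Aspergillus niger* pellets:
    bulk oxygen diffusivity at 37 degC, the mycelial hindrance exponent,
    dry hyphal density, and Monod-type consumption constants.

    Attributes
    ----------
    d_bulk : float
        Bulk oxygen diffusion coefficient, m^2 h^-1.
    a : float
        Diffusion hindrance exponent of the hyphal network (dimensionless).
    rho_h : float
        Hyphal dry-weight density, kg m^-3.
    y_xo2 : float
        Biomass yield on oxygen, kg biomass per kg O2.
    k_xo : float
        Monod constant for growth-associated consumption, kg m^-3.
    mu_max : float
        Maximum specific growth rate, h^-1 (0.16 for the regular strain,
        0.24 for the hyperbranching strain).
    m_o2_max : float
        Maximum specific maintenance coefficient, kg O2 (kg biomass)^-1 h^-1.
    k_mo : float
        Monod constant for maintenance consumption, kg m^-3.
    c_crit : float
        Critical oxygen concentration below which no net biomass is formed,
        kg m^-3.
    variant : str
        Consumption law: ``"growth_only"`` (Monod growth term only) or
        ``"growth_plus_maintenance"`` (adds a maintenance term and the
        critical-concentration floor on the growth term).
    """

    d_bulk: float = 8.7e-6
    a: float = 1.76
    rho_h: float = 150.0
    y_xo2: float = 2.77
    k_xo: float = 2.5e-5
    mu_max: float = 0.16
    m_o2_max: float = 7.2e-3
    k_mo: float = 1.5e-5
    c_crit: float = 1e-5
    variant: Variant = "growth_only"

    def __post_init__(self) -> None:
        # complex values are permitted (complex-step sensitivities); the
        # physical constraint applies to the real part
        for name in ("d_bulk", "a", "rho_h", "y_xo2", "k_xo", "mu_max",
                     "m_o2_max", "k_mo", "c_crit"):
            v = getattr(self, name)
            try:
                real = float(v.real if isinstance(v, complex) else v)
            except (TypeError, AttributeError):
                raise ValueError(f"{name} must be a number, got {v!r}")
            if real < 0:
                raise ValueError(f"{name} must be nonnegative, got {v!r}")
        if float(self.y_xo2.real if isinstance(self.y_xo2, complex)
                 else self.y_xo2) <= 0:
            raise ValueError("y_xo2 must be positive")
        if self.variant not in ("growth_only", "growth_plus_maintenance"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def replace(self, **changes) -> "KineticParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KineticParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Literature defaults (regular strain growth rate).
TABLE_DEFAULTS = KineticParams()

#: Growth-rate preset for the hyperbranching strain.
HYPERBRANCHING_PARAMS = KineticParams(mu_max=0.24)
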