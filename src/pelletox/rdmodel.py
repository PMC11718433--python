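"""Steady-state oxygen in a spherical pellet: 1D diffusion-consumption model.

The model is the radially symmetric balance

    dc/dt = (1/r^2) d/dr [ D_eff(r) r^2 dc/dr ] - q(c, ch)

with hindered effective diffusivity D_eff = D_bulk (1 - ch)^a and Monod-type
consumption q, on a uniform 100-node grid with a zero-flux symmetry
condition at the centre and a Dirichlet surface concentration.  The steady
profile is obtained by stiff transient integration from a uniform initial
condition at the surface concentration, mirroring the pseudo-steady-state
assumption: hyphal growth is hours-scale while oxygen equilibrates within
a small fraction of the simulation horizon.

Discretization is a conservative second-order finite-volume scheme: fluxes
are evaluated on cell faces with face-averaged hyphal fraction, so the
discrete solution satisfies an exact cell-wise mass balance.  Time is kept
in the model's native unit system (hour-based parameters); the simulation
clock is reported on the conventional seconds-labelled scale of the
original workflow.

All quantities in this module are SI-like (m, h, kg m^-3); concentration
unit conversion (mg L^-1 <-> kg m^-3) happens in the calling modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .morpho3d import ShellProfile
from .params import KineticParams, MG_PER_L, UM

__all__ = [
    "SimResult", "effective_diffusion", "q_growth", "q_maintenance",
    "consumption", "consumption_derivative", "fraction_to_grid",
    "steady_state_profile", "simulate_shells", "flux_balance",
    "characteristic_times",
]

#: default number of radial grid nodes
N_NODES = 100
#: default simulation horizon on the native clock ("2 s")
T_END = 2.0
#: steady state: max relative concentration change per "ms" below this
STEADY_TOL = 1e-6


@dataclass
class SimResult:
    """Steady-state simulation output on the radial grid.

    ``radii`` in m, ``c_o2`` in kg m^-3.  ``time_to_steady`` is the first
    simulated time (seconds-labelled native clock) at which the maximum
    relative concentration change per millisecond dropped below the steady
    tolerance; ``converged`` says whether that happened within the horizon.
    """

    radii: np.ndarray
    c_o2: np.ndarray
    c_surface: float
    converged: bool
    time_to_steady: float

    @property
    def radii_um(self) -> np.ndarray:
        return self.radii / UM

    @property
    def c_mg_per_l(self) -> np.ndarray:
        return self.c_o2 / MG_PER_L


def effective_diffusion(ch, p: KineticParams):
    """Hindered effective diffusivity D_bulk * (1 - ch)^a in m^2 h^-1."""
    ch = np.asarray(ch)
    if np.any(np.real(ch) >= 1.0):
        raise ValueError("ch must be < 1 (diffusivity would vanish)")
    if np.any(np.real(ch) < 0.0):
        raise ValueError("ch must be >= 0")
    return p.d_bulk * (1.0 - ch) ** p.a


def q_growth(c, ch, p: KineticParams):
    """Growth-associated oxygen consumption, kg m^-3 h^-1.

    q = (rho_h / Y_X/O2) * c/(K_XO + c) * mu_max * ch
    """
    return p.rho_h / p.y_xo2 * c / (p.k_xo + c) * p.mu_max * ch


def q_maintenance(c, ch, p: KineticParams):
    """Growth + maintenance consumption, kg m^-3 h^-1.

    The growth term is floored at zero below the critical concentration
    (net biomass formation stops there); the maintenance term is a separate
    Monod expression that persists at low oxygen.
    """
    growth = (p.rho_h / p.y_xo2 * np.maximum(c - p.c_crit, 0.0)
              / (p.k_xo + c) * p.mu_max * ch)
    maint = p.m_o2_max * p.rho_h * c / (p.k_mo + c) * ch
    return growth + maint


def consumption(c, ch, p: KineticParams):
    if p.variant == "growth_only":
        return q_growth(c, ch, p)
    return q_maintenance(c, ch, p)


def consumption_derivative(c, ch, p: KineticParams):
    """dq/dc, used for the analytic Jacobian of the semi-discrete system."""
    if p.variant == "growth_only":
        return p.rho_h / p.y_xo2 * p.mu_max * ch * p.k_xo / (p.k_xo + c) ** 2
    active = np.real(c) > p.c_crit
    dgrowth = (p.rho_h / p.y_xo2 * p.mu_max * ch
               * (p.k_xo + p.c_crit) / (p.k_xo + c) ** 2) * active
    dmaint = p.m_o2_max * p.rho_h * ch * p.k_mo / (p.k_mo + c) ** 2
    return dgrowth + dmaint


def fraction_to_grid(shells: ShellProfile, n_nodes: int = N_NODES,
                     r_max_um: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a shell profile onto a uniform radial simulation grid.

    Returns ``(radii_m, ch)`` with ``n_nodes`` nodes from 0 to ``r_max_um``
    (default: the outermost shell edge).  Shell values are taken at shell
    mid-radii and linearly interpolated; constant inside the central sphere.
    Values are clamped to [0, 0.999] so the effective diffusivity never
    vanishes.
    """
    if r_max_um is None:
        r_max_um = float(shells.shell_outer_radii[-1])
    if r_max_um > shells.shell_outer_radii[-1] + 1e-9:
        raise ValueError("r_max exceeds the shell profile extent")
    radii_um = np.linspace(0.0, r_max_um, n_nodes)
    ch = shells.interp_fraction(radii_um, border_radius=r_max_um)
    if np.any(ch > 0.999):
        warnings.warn("hyphal fraction clamped to 0.999 on the grid")
        ch = np.minimum(ch, 0.999)
    return radii_um * UM, ch


def _build_operator(ch: np.ndarray, p: KineticParams, r_max: float):
    """Face flux coefficients and cell volumes of the finite-volume scheme."""
    n = len(ch)
    dr = r_max / (n - 1)
    r = np.arange(n) * dr
    r_face = 0.5 * (r[:-1] + r[1:])
    ch_face = 0.5 * (ch[:-1] + ch[1:])
    d_face = effective_diffusion(ch_face, p)
    f_coef = d_face * r_face**2 / dr                       # per-4pi face flux / dc
    edges = np.concatenate(([0.0], r_face, [r_max]))
    vol = (edges[1:]**3 - edges[:-1]**3) / 3.0             # per-4pi cell volumes
    return r, f_coef, vol


def steady_state_profile(ch_grid: np.ndarray, p: KineticParams,
                         c_surface: float, r_max: float,
                         t_end: float = T_END,
                         steady_tol: float = STEADY_TOL,
                         extend_to_steady: bool = False,
                         rtol: float = 1e-6) -> SimResult:
    """Steady-state oxygen profile by transient method-of-lines integration.

    Parameters
    ----------
    ch_grid : array
        Hyphal fraction on a uniform grid from r=0 to ``r_max`` (defines the
        node count).
    c_surface : float
        Dirichlet concentration at the pellet border, kg m^-3.
    r_max : float
        Pellet border radius in m.
    t_end : float
        Simulation horizon on the native clock (default "2 s").
    extend_to_steady : bool
        If the steady criterion is not met within ``t_end``, keep
        integrating (up to 500 time units) until it is.

    Complex-valued parameters are supported for complex-step sensitivities;
    the growth-only consumption law is analytic in its parameters.
    """
    if not (np.real(c_surface) > 0):
        raise ValueError("c_surface must be positive")
    ch_grid = np.asarray(ch_grid)
    n = len(ch_grid)
    if n < 5 or r_max <= 0:
        raise ValueError("need at least 5 grid nodes and positive r_max")

    r, f_coef, vol = _build_operator(ch_grid, p, r_max)
    is_complex = any(np.iscomplexobj(np.asarray(v)) for v in
                     (p.y_xo2, p.mu_max, p.k_xo, p.m_o2_max, p.k_mo,
                      p.c_crit, c_surface))
    dtype = complex if is_complex else float
    cs_real = float(np.real(c_surface))

    def rhs(t, c):
        flux = f_coef * (c[1:] - c[:-1])
        dc = np.empty(n, dtype=c.dtype)
        dc[0] = flux[0] / vol[0]
        dc[1:-1] = (flux[1:] - flux[:-1]) / vol[1:-1]
        dc[-1] = 0.0
        dc[:-1] -= consumption(c[:-1], ch_grid[:-1], p)
        return dc

    # constant tridiagonal diffusion part of the Jacobian
    main = np.zeros(n, dtype=dtype)
    lower = np.zeros(n - 1, dtype=dtype)
    upper = np.zeros(n - 1, dtype=dtype)
    main[0] = -f_coef[0] / vol[0]
    upper[0] = f_coef[0] / vol[0]
    main[1:-1] = -(f_coef[1:] + f_coef[:-1]) / vol[1:-1]
    lower[:-1] = f_coef[:-1] / vol[1:-1]
    upper[1:] = f_coef[1:] / vol[1:-1]
    lower[-1] = 0.0  # Dirichlet node is frozen

    def jac_sparse(t, c):
        d = main.copy()
        d[:-1] = d[:-1] - consumption_derivative(c[:-1], ch_grid[:-1], p)
        return sp.diags([lower, d, upper], [-1, 0, 1], format="csc")

    def jac_banded(t, c):
        d = main.copy()
        d[:-1] = d[:-1] - consumption_derivative(c[:-1], ch_grid[:-1], p)
        band = np.zeros((3, n))
        band[0, 1:] = upper
        band[1] = d
        band[2, :-1] = lower
        return band

    def steady_event(t, c):
        rate = np.max(np.abs(np.real(rhs(t, c))))
        return rate * 1e-3 / cs_real - steady_tol

    # LSODA with a banded Jacobian is fastest but real-only; complex-step
    # sensitivity runs fall back to BDF with a sparse Jacobian
    if is_complex:
        ivp_kw = dict(method="BDF", jac=jac_sparse)
    else:
        ivp_kw = dict(method="LSODA", jac=jac_banded, lband=1, uband=1)

    c0 = np.full(n, c_surface, dtype=dtype)
    sol = solve_ivp(rhs, (0.0, t_end), c0, rtol=rtol,
                    atol=1e-9 * cs_real, events=steady_event, **ivp_kw)
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    t_steady = float(sol.t_events[0][0]) if len(sol.t_events[0]) else np.inf
    converged = np.isfinite(t_steady)
    c = sol.y[:, -1]

    if not converged and extend_to_steady:
        steady_event.terminal = True
        sol = solve_ivp(rhs, (t_end, 500.0), c, rtol=rtol,
                        atol=1e-9 * cs_real, events=steady_event, **ivp_kw)
        if not sol.success:
            raise RuntimeError(f"integrator failed: {sol.message}")
        if len(sol.t_events[0]):
            t_steady = float(sol.t_events[0][0])
            converged = True
        c = sol.y[:, -1]

    if np.min(np.real(c)) < -1e-9 * cs_real:
        raise RuntimeError("negative concentrations beyond solver tolerance")
    return SimResult(radii=r, c_o2=c, c_surface=c_surface,
                     converged=converged, time_to_steady=t_steady)


def simulate_shells(shells: ShellProfile, p: KineticParams,
                    c_surface_mg_per_l: float,
                    r_max_um: float | None = None,
                    n_nodes: int = N_NODES, **kw) -> SimResult:
    """Convenience wrapper: shell profile + surface concentration in mg/L."""
    radii_m, ch = fraction_to_grid(shells, n_nodes=n_nodes, r_max_um=r_max_um)
    return steady_state_profile(ch, p, c_surface_mg_per_l * MG_PER_L,
                                float(radii_m[-1]), **kw)


def flux_balance(sim: SimResult, ch_grid: np.ndarray,
                 p: KineticParams) -> tuple[float, float]:
    """Surface diffusive influx vs volume-integrated consumption, kg h^-1.

    Both sides are evaluated with the discretization's own quadrature: the
    influx is the flux through the outermost interior face plus the sink in
    the surface half-cell; consumption is the cell-volume sum of q.  At a
    converged steady state the two agree to the solver tolerance.
    """
    c = np.real(sim.c_o2)
    r_max = float(sim.radii[-1])
    _, f_coef, vol = _build_operator(np.asarray(ch_grid), p, r_max)
    q = np.real(consumption(c, np.asarray(ch_grid), p))
    influx = f_coef[-1] * (c[-1] - c[-2]) + q[-1] * vol[-1]
    total = np.sum(q * vol)
    return float(4 * np.pi * influx), float(4 * np.pi * total)


def characteristic_times(p: KineticParams, length_scale: float,
                         c_ref: float, ch_ref: float) -> dict:
    """Order-of-magnitude process time scales, in hours.

    ``t_doubling`` = ln2/mu_max (hours-scale growth), ``t_diffusion`` =
    L^2/D_eff (seconds-to-minutes), ``t_reaction`` = c_ref / q(c_ref)
    (seconds).  Their separation justifies the pseudo-steady-state
    treatment of the hyphal fraction during a simulation.
    """
    t_doubling = np.log(2) / p.mu_max if p.mu_max > 0 else np.inf
    t_diffusion = length_scale**2 / effective_diffusion(ch_ref, p)
    q = q_growth(c_ref, ch_ref, p)
    t_reaction = c_ref / q if q > 0 else np.inf
    return {"t_reaction": float(t_reaction),
            "t_diffusion": float(t_diffusion),
            "t_doubling": float(t_doubling)}
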