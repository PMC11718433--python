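"""Per-pellet kinetic parameter estimation and model selection.

Parameters of the consumption law are estimated per pellet by bounded
trust-region nonlinear least squares on the residuals between measured and
simulated oxygen concentrations at each radial position, with a seeded
multistart (log-uniform start points within the bounds).  Sensitivities
are computed by complex-step differentiation when the forward map is
analytic in the free parameters (the growth-only law), and by central
finite differences otherwise (the maintenance law has a kink at the
critical concentration).  Candidate models are ranked by the small-sample
corrected Akaike criterion AICc with k = n_free + 1 (the residual variance
counts as a parameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .params import KineticParams, MG_PER_L
from .profiles import AlignedPellet
from .rdmodel import N_NODES, steady_state_profile

__all__ = [
    "FitSpec", "FitResult", "DEFAULT_BOUNDS", "DEFAULT_CANDIDATES",
    "residual_objective", "fit_parameters", "mean_absolute_error",
    "aicc", "select_model", "one_way_anova",
]

#: fit bounds in model units (kg, m, h); bracket the literature values
#: by at least an order of magnitude on each side
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "y_xo2": (0.1, 30.0),
    "m_o2_max": (1e-5, 0.1),
    "k_xo": (1e-7, 1e-3),
    "k_mo": (1e-7, 1e-3),
    "c_crit": (0.0, 1e-4),
}

#: parameters sampled linear-uniformly at start (lower bound may be 0)
_LINEAR_SAMPLED = {"c_crit"}

#: residual magnitude assigned on forward-solver failure (mg L^-1)
_PENALTY = 1e3

_CSD_STEP = 1e-20


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters, consumption variant, multistart setup."""

    free_parameters: tuple[str, ...] = ("y_xo2",)
    variant: str = "growth_only"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 50
    seed: int = 0
    jacobian_mode: str = "auto"  # auto | complex_step | finite_difference
    #: cap on objective evaluations per start (None: optimizer default)
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("free parameter set must be non-empty")
        unknown = set(self.free_parameters) - set(DEFAULT_BOUNDS)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        for name in self.free_parameters:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi and lo >= 0):
                raise ValueError(f"invalid bounds for {name}: {(lo, hi)}")

    @property
    def uses_complex_step(self) -> bool:
        if self.jacobian_mode == "complex_step":
            return True
        if self.jacobian_mode == "finite_difference":
            return False
        # the maintenance law's max(c - c_crit, 0) breaks analyticity
        return self.variant == "growth_only"


@dataclass
class FitResult:
    estimates: dict
    rss: float
    mae: float
    aicc: float
    n_points: int
    k_effective: int
    start_records: list
    best_start_index: int
    jacobian_mode: str

    def to_dict(self) -> dict:
        return {"estimates": self.estimates, "rss": self.rss, "mae": self.mae,
                "aicc": self.aicc, "n_points": self.n_points,
                "k_effective": self.k_effective,
                "start_records": self.start_records,
                "best_start_index": self.best_start_index,
                "jacobian_mode": self.jacobian_mode}


def _sim_grid(a: AlignedPellet, n_nodes: int = N_NODES):
    """Measurement radii inside the border and ch on the simulation grid.

    When the aligned pellet carries its source shell profile, ch is
    interpolated from the shells directly (the same field the forward
    model uses); otherwise it falls back to the aligned 10-um samples.
    """
    inside = a.inside
    r_meas = a.radii[inside]
    y_exp = a.c_o2[inside]
    grid_um = np.linspace(0.0, a.border_radius, n_nodes)
    if a.shells is not None:
        ch_grid = a.shells.interp_fraction(grid_um,
                                           border_radius=a.border_radius)
    else:
        ch_grid = np.interp(grid_um, a.radii, a.ch)
    return r_meas, y_exp, grid_um, np.minimum(ch_grid, 0.999)


def residual_objective(a: AlignedPellet, p: KineticParams,
                       spec: FitSpec | None = None, n_nodes: int = N_NODES):
    """Residual function y_exp - y_sim (mg L^-1) over the free parameters.

    Returns ``resid(values)`` mapping free-parameter values (model units)
    to the residual vector at each measured radius inside the border.  A
    forward-solver failure yields large penalty residuals so multistart
    optimization survives pathological parameter combinations.
    """
    spec = spec or FitSpec()
    r_meas, y_exp, grid_um, ch_grid = _sim_grid(a, n_nodes)
    if len(r_meas) < 3:
        raise ValueError("need at least 3 in-pellet measurement points")
    c_surface = a.c_max * MG_PER_L
    r_max = a.border_radius * 1e-6

    def resid(values):
        values = np.atleast_1d(values)
        updates = dict(zip(spec.free_parameters, values))
        pp = p.replace(variant=spec.variant, **updates)
        try:
            sim = steady_state_profile(ch_grid, pp, c_surface, r_max)
        except RuntimeError:
            out = np.full(len(r_meas), _PENALTY)
            if any(np.iscomplexobj(np.asarray(v)) for v in values):
                out = out.astype(complex)
            return out
        y_sim = np.interp(r_meas, sim.radii_um.real,
                          sim.c_o2 / MG_PER_L)
        return y_exp - y_sim

    return resid


def _complex_step_jac(resid, n_res):
    def jac(x):
        x = np.atleast_1d(x)
        J = np.empty((n_res, len(x)))
        for k in range(len(x)):
            xc = x.astype(complex)
            xc[k] += 1j * _CSD_STEP
            J[:, k] = np.imag(resid(xc)) / _CSD_STEP
        return J
    return jac


def _sample_starts(spec: FitSpec, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for name in spec.free_parameters:
        lo, hi = spec.bounds[name]
        if name in _LINEAR_SAMPLED or lo <= 0:
            cols.append(rng.uniform(lo, hi, spec.n_starts))
        else:
            cols.append(np.exp(rng.uniform(np.log(lo), np.log(hi),
                                           spec.n_starts)))
    return np.column_stack(cols)


def fit_parameters(a: AlignedPellet, p: KineticParams,
                   spec: FitSpec) -> FitResult:
    """Multistart bounded least squares for the free kinetic parameters."""
    resid = residual_objective(a, p, spec)
    n_res = int(np.sum(a.inside))
    lb = np.array([spec.bounds[n][0] for n in spec.free_parameters])
    ub = np.array([spec.bounds[n][1] for n in spec.free_parameters])
    rng = np.random.default_rng(spec.seed)
    starts = _sample_starts(spec, rng)

    jac = _complex_step_jac(resid, n_res) if spec.uses_complex_step \
        else "3-point"
    records, solutions = [], []
    for x0 in starts:
        try:
            sol = least_squares(lambda x: np.real(resid(x)), x0, jac=jac,
                                bounds=(lb, ub), method="trf",
                                max_nfev=spec.max_nfev)
            records.append(float(sol.cost))
            solutions.append(sol)
        except Exception as exc:  # keep multistart alive
            records.append(np.inf)
            solutions.append(exc)
    finite = [i for i, c in enumerate(records) if np.isfinite(c)]
    if not finite:
        raise RuntimeError(f"all {spec.n_starts} starts failed: "
                           f"{[str(s) for s in solutions]}")
    best = min(finite, key=lambda i: records[i])
    sol = solutions[best]
    res = np.real(resid(sol.x))
    rss = float(np.sum(res**2))
    n = len(res)
    k_free = len(spec.free_parameters)
    return FitResult(
        estimates=dict(zip(spec.free_parameters, map(float, sol.x))),
        rss=rss,
        mae=mean_absolute_error(res, np.zeros_like(res)),
        aicc=aicc(rss, n, k_free),
        n_points=n,
        k_effective=k_free + 1,
        start_records=[float(c) if np.isfinite(c) else None for c in records],
        best_start_index=int(best),
        jacobian_mode="complex_step" if spec.uses_complex_step
        else "finite_difference",
    )


def mean_absolute_error(exp, sim) -> float:
    """MAE = mean |exp_i - sim_i| in the measurement units (mg L^-1)."""
    exp = np.asarray(exp, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if exp.size == 0 or exp.shape != sim.shape:
        raise ValueError("series must be non-empty and equal length")
    return float(np.mean(np.abs(exp - sim)))


def aicc(rss: float, n: int, n_free: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1) with k = n_free + 1 (the
    residual variance is counted as an estimated parameter).
    """
    k = n_free + 1
    if n <= k + 1:
        raise ValueError(f"sample too small for AICc (n={n}, k={k})")
    if rss <= 0:
        raise ValueError("RSS must be positive for AICc")
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def select_model(a: AlignedPellet, p: KineticParams,
                 candidates: list[FitSpec]) -> list[tuple[FitSpec, FitResult]]:
    """Fit every candidate and rank by AICc (ties: fewer free parameters).

    Returns (spec, result) pairs sorted best-first; each result gains a
    ``delta_aicc`` attribute relative to the winner.  Candidates whose fit
    fails are dropped (with a warning), ranking the survivors.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    fitted = []
    for spec in candidates:
        try:
            fitted.append((spec, fit_parameters(a, p, spec)))
        except Exception as exc:
            warnings.warn(f"candidate {spec.free_parameters} failed: {exc}")
    if not fitted:
        raise RuntimeError("all candidates failed")
    fitted.sort(key=lambda sr: (sr[1].aicc, len(sr[0].free_parameters)))
    best_aicc = fitted[0][1].aicc
    for _, res in fitted:
        res.delta_aicc = res.aicc - best_aicc
    return fitted


def default_candidates(n_starts: int = 50, seed: int = 0) -> list[FitSpec]:
    """The shipped candidate list for consumption-model selection."""
    combos = [
        ("growth_only", ("y_xo2",)),
        ("growth_plus_maintenance", ("y_xo2", "m_o2_max")),
        ("growth_only", ("k_xo",)),
        ("growth_plus_maintenance", ("k_xo", "k_mo", "c_crit")),
        ("growth_plus_maintenance",
         ("y_xo2", "m_o2_max", "k_xo", "k_mo", "c_crit")),
    ]
    return [FitSpec(free_parameters=f, variant=v, n_starts=n_starts,
                    seed=seed) for v, f in combos]


DEFAULT_CANDIDATES = default_candidates()


def one_way_anova(groups: list) -> dict:
    """Classic single-factor ANOVA between/within decomposition.

    Returns ``{"F": ..., "p": ..., "significant": ...}`` at alpha = 0.05.
    Identical groups with zero within-variance give F = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(arrays)
    ssw = sum(np.sum((g - g.mean())**2) for g in arrays)
    ssb = sum(len(g) * (g.mean() - allv.mean())**2 for g in arrays)
    if ssw == 0 and ssb == 0:
        return {"F": 0.0, "p": 1.0, "significant": False}
    F, p = stats.f_oneway(*arrays)
    if not np.isfinite(F):  # zero within-variance, distinct means
        F, p = np.inf, 0.0
    return {"F": float(F), "p": float(p), "significant": bool(p < 0.05)}
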