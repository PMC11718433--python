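"""Microelectrode oxygen-profile processing and alignment with shell data.

An oxygen microprofile is measured depth-wise (10 um steps) from outside
the pellet towards its centre, with no direct reference to the pellet
centre.  The pellet border therefore acts as the shared fixed point: on
the oxygen side it is the depth at which 95% of the maximum concentration
is reached, on the image side the radius at which the hyphal fraction
drops to 0.005.  Aligning both at that border puts concentration and
hyphal fraction on one radial coordinate, from which penetration depth,
maximum gradients, and the active part percentage (APP) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .morpho3d import ShellProfile, border_from_fraction

__all__ = [
    "OxygenProfile", "AlignedPellet", "SupplyMetrics",
    "mean_replicate_profile", "oxygen_border", "align",
    "max_central_gradient", "penetration_depth", "active_part_percentage",
    "supply_metrics",
]

#: concentration treated as "zero" for penetration depth, mg L^-1
ZERO_THRESHOLD = 0.05


@dataclass
class OxygenProfile:
    """Replicate oxygen concentrations vs insertion depth.

    ``depths`` in um on a uniform grid (10 um sensor steps);
    ``concentrations`` has one row per replicate, mg L^-1.
    """

    depths: np.ndarray
    concentrations: np.ndarray
    replicate_count: int = 0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.atleast_2d(
            np.asarray(self.concentrations, dtype=float))
        if self.concentrations.shape[1] != self.depths.size:
            raise ValueError("concentration columns must match depths")
        steps = np.diff(self.depths)
        if self.depths.size < 2 or np.any(steps <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("depth grid must be uniform")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.replicate_count == 0:
            self.replicate_count = self.concentrations.shape[0]

    @property
    def step(self) -> float:
        return float(self.depths[1] - self.depths[0])

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = []
        for rep in range(self.concentrations.shape[0]):
            for d, c in zip(self.depths, self.concentrations[rep]):
                rows.append((d, rep, c))
        pd.DataFrame(rows, columns=["depth_um", "replicate",
                                    "o2_mg_per_l"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OxygenProfile":
        import pandas as pd
        df = pd.read_csv(path)
        piv = df.pivot(index="replicate", columns="depth_um",
                       values="o2_mg_per_l").sort_index(axis=1)
        return cls(piv.columns.to_numpy(float), piv.to_numpy())


@dataclass
class AlignedPellet:
    """Hyphal fraction and mean oxygen on a common radial coordinate.

    ``radii`` ascend from the centre; ``border_radius`` is the shared
    border of the oxygen and hyphal-fraction data after alignment, and
    ``c_max`` the maximum of the mean profile (the Dirichlet surface value
    for simulation).
    """

    radii: np.ndarray
    ch: np.ndarray
    c_o2: np.ndarray
    c_max: float
    border_radius: float
    #: source shell profile, kept so simulation grids can be rebuilt from
    #: the original ch field instead of its 10-um resampling
    shells: ShellProfile | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.ch = np.asarray(self.ch, dtype=float)
        self.c_o2 = np.asarray(self.c_o2, dtype=float)
        if not (self.radii.shape == self.ch.shape == self.c_o2.shape):
            raise ValueError("radii, ch and c_o2 must share one grid")

    @property
    def inside(self) -> np.ndarray:
        """Mask of samples at or inside the pellet border."""
        return self.radii <= self.border_radius + 1e-9

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"radius_um": self.radii, "ch": self.ch,
                      "o2_mg_per_l": self.c_o2,
                      "border_radius_um": self.border_radius,
                      }).to_csv(path, index=False)


@dataclass
class SupplyMetrics:
    penetration_depth: float
    app: float
    max_o2_gradient: float
    max_ch_gradient: float


def mean_replicate_profile(p: OxygenProfile) -> OxygenProfile:
    """Pointwise mean over replicates (the 'mean profile')."""
    mean = p.concentrations.mean(axis=0, keepdims=True)
    return OxygenProfile(p.depths, mean, replicate_count=p.replicate_count)


def oxygen_border(p: OxygenProfile, frac: float = 0.95) -> tuple[float, float]:
    """Border depth where the profile reaches ``frac`` of its maximum.

    The mean profile is scanned from the deep end outward (towards shallow
    depths) for the first crossing of frac * c_max, linearly interpolated
    between samples; this avoids boundary-layer dips outside the pellet.
    Returns ``(border_depth_um, c_max)``.
    """
    c = p.concentrations.mean(axis=0)
    c_max = float(c.max())
    if c_max <= 0:
        raise ValueError("profile has no positive maximum")
    thr = frac * c_max
    # scan indices from deepest to shallowest
    for i in range(len(c) - 1, -1, -1):
        if c[i] >= thr:
            if i == len(c) - 1:
                warnings.warn("profile already at threshold at its deep end; "
                              "border set to the deepest sample")
                return float(p.depths[-1]), c_max
            # crossing between depths[i] (>= thr) and depths[i+1] (< thr)
            d0, d1 = p.depths[i], p.depths[i + 1]
            c0, c1 = c[i], c[i + 1]
            d = d0 + (d1 - d0) * (c0 - thr) / (c0 - c1) if c0 > c1 else d0
            return float(d), c_max
    raise ValueError("profile never reaches the border threshold")


def align(p: OxygenProfile, shells: ShellProfile,
          border_frac: float = 0.95, cutoff: float = 0.005) -> AlignedPellet:
    """Map oxygen depths onto pellet radii using the shared border.

    radius = fraction_border - (depth - oxygen_border_depth).  Samples
    mapping to negative radii are discarded with a warning.  The hyphal
    fraction is interpolated onto the same radii (constant inside the
    central sphere, zero beyond the border).
    """
    mean = mean_replicate_profile(p)
    r_border = border_from_fraction(shells, cutoff=cutoff)
    d_border, c_max = oxygen_border(mean, frac=border_frac)
    radii = r_border - (mean.depths - d_border)
    keep = radii >= 0
    if not np.all(keep):
        warnings.warn(f"discarding {np.sum(~keep)} samples beyond the "
                      "pellet centre")
    if np.sum(keep & (radii <= r_border)) < 2:
        raise ValueError("fewer than 2 oxygen samples inside the border")
    radii = radii[keep]
    c = mean.concentrations[0][keep]
    order = np.argsort(radii)
    radii, c = radii[order], c[order]
    ch = shells.interp_fraction(radii, border_radius=r_border)
    return AlignedPellet(radii=radii, ch=ch, c_o2=c, c_max=c_max,
                         border_radius=r_border, shells=shells)


def max_central_gradient(values: np.ndarray, spacing: float,
                         window: tuple[float, float] | None = None,
                         positions: np.ndarray | None = None) -> float:
    """Maximum |gradient| by central second-order finite differences.

    ``gradient_i = (v[i+1] - v[i-1]) / (2*spacing)`` at interior points;
    endpoints are excluded.  ``window`` restricts the maximum to positions
    within a closed interval (requires ``positions``).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 points for a central gradient")
    grad = (values[2:] - values[:-2]) / (2.0 * spacing)
    if window is not None:
        if positions is None:
            raise ValueError("window requires positions")
        pos = np.asarray(positions, dtype=float)[1:-1]
        sel = (pos >= window[0]) & (pos <= window[1])
        if not sel.any():
            raise ValueError("no interior points inside the window")
        grad = grad[sel]
    return float(np.max(np.abs(grad)))


def penetration_depth(a: AlignedPellet,
                      zero_threshold: float = ZERO_THRESHOLD) -> float:
    """Thickness of the outer layer with oxygen above the zero threshold.

    Scanning the aligned profile from the centre outward, the supplied
    layer starts at the first radius where the concentration exceeds
    ``zero_threshold`` (linearly interpolated); its thickness is
    border_radius minus that radius.  A fully oxygenated pellet has
    penetration depth equal to its border radius.
    """
    inside = a.inside
    r = a.radii[inside]
    c = a.c_o2[inside]
    above = c > zero_threshold
    if not above.any():
        warnings.warn("no oxygen above threshold anywhere in the pellet")
        return 0.0
    i = int(np.argmax(above))
    if i == 0:
        return float(a.border_radius)
    # crossing between r[i-1] (below) and r[i] (above)
    r0 = r[i - 1] + (r[i] - r[i - 1]) * (zero_threshold - c[i - 1]) \
        / (c[i] - c[i - 1])
    return float(a.border_radius - r0)


def active_part_percentage(a: AlignedPellet, shells: ShellProfile,
                           depth: float) -> float:
    """Hyphal volume share (%) inside the oxygen-supplied outer layer.

    APP = 100 * (hyphal volume between border-depth and border) / (total
    hyphal volume inside the border), with exact spherical bin volumes and
    partial bins pro-rated by volume.
    """
    border = a.border_radius
    if not 0.0 <= depth <= border + 1e-9:
        raise ValueError("depth must lie in [0, border_radius]")

    def hyphal_volume(r_lo: float, r_hi: float) -> float:
        lo = np.clip(shells.inner_radii, r_lo, r_hi)
        hi = np.clip(shells.shell_outer_radii, r_lo, r_hi)
        vol = 4.0 / 3.0 * np.pi * (hi**3 - lo**3)
        return float(np.sum(shells.fractions * vol))

    total = hyphal_volume(0.0, border)
    if total <= 0:
        raise ValueError("zero total hyphal volume")
    return 100.0 * hyphal_volume(border - depth, border) / total


def supply_metrics(a: AlignedPellet, shells: ShellProfile,
                   zero_threshold: float = ZERO_THRESHOLD) -> SupplyMetrics:
    """Penetration depth, APP and maximum gradients in the supplied layer."""
    depth = penetration_depth(a, zero_threshold=zero_threshold)
    app = active_part_percentage(a, shells, depth)
    window = (a.border_radius - depth, a.border_radius)
    spacing = float(np.median(np.diff(a.radii)))
    try:
        g_o2 = max_central_gradient(a.c_o2, spacing, window=window,
                                    positions=a.radii)
        g_ch = max_central_gradient(a.ch, spacing, window=window,
                                    positions=a.radii)
    except ValueError:
        g_o2 = max_central_gradient(a.c_o2, spacing)
        g_ch = max_central_gradient(a.ch, spacing)
    return SupplyMetrics(penetration_depth=depth, app=app,
                         max_o2_gradient=g_o2, max_ch_gradient=g_ch)
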