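"""Per-pellet workflow orchestration and cohort-level summaries.

``run_pellet`` composes the stages (image -> shells -> alignment -> supply
metrics -> fit) into one record; ``cohort_summary`` filters to spherical
pellets, computes strain-wise means, ANOVA between strains, and the three
prediction-error modes: (1) each pellet's own fitted yield, (2) the cohort
mean yield, (3) the cohort mean yield with a strain-averaged constant
hyphal fraction (the no-tomography scenario).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .fitstats import FitResult, FitSpec, fit_parameters, \
    mean_absolute_error, one_way_anova
from .morpho3d import ShapeMetrics3D, ShellProfile, VoxelImage, \
    binarize_otsu, shape_metrics_3d, shell_bin_volumes, shell_hyphal_fraction
from .params import KineticParams, MG_PER_L
from .profiles import AlignedPellet, OxygenProfile, SupplyMetrics, align, \
    supply_metrics
from .rdmodel import steady_state_profile

__all__ = ["PelletRecord", "run_pellet", "cohort_summary"]


@dataclass
class PelletRecord:
    """Everything derived from one pellet, ready for cohort statistics."""

    pellet_id: str
    strain: str
    shells: ShellProfile
    aligned: AlignedPellet
    shape: ShapeMetrics3D | None
    metrics: SupplyMetrics
    fit: FitResult

    @property
    def is_spherical(self) -> bool:
        return self.shape.is_spherical if self.shape is not None else True

    def to_dict(self) -> dict:
        d = {
            "pellet_id": self.pellet_id,
            "strain": self.strain,
            "border_radius_um": self.aligned.border_radius,
            "penetration_depth_um": self.metrics.penetration_depth,
            "app_percent": self.metrics.app,
            "max_o2_gradient": self.metrics.max_o2_gradient,
            "max_ch_gradient": self.metrics.max_ch_gradient,
            "fit": self.fit.to_dict(),
            "version": __version__,
        }
        if self.shape is not None:
            d["sphericity"] = self.shape.sphericity
            d["axis_ratio"] = self.shape.axis_ratio
            d["is_spherical"] = self.shape.is_spherical
        return d

    def to_json(self, path) -> None:
        d = self.to_dict()
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=float)


def run_pellet(o2: OxygenProfile, params: KineticParams,
               fit_spec: FitSpec, pellet_id: str = "pellet",
               strain: str = "R", image: VoxelImage | None = None,
               shells: ShellProfile | None = None) -> PelletRecord:
    """Run the full per-pellet chain from image/shells + oxygen profile.

    Either a voxel image (binarized if grayscale) or a precomputed shell
    profile must be supplied.  Deterministic for a fixed fit seed.
    """
    if shells is None:
        if image is None:
            raise ValueError("provide a voxel image or a shell profile")
        if not image.is_binary:
            image = binarize_otsu(image)
        shells = shell_hyphal_fraction(image)
    shape = shape_metrics_3d(image, shells) if image is not None else None
    try:
        aligned = align(o2, shells)
        metrics = supply_metrics(aligned, shells)
        fit = fit_parameters(aligned, params, fit_spec)
    except Exception as exc:
        raise RuntimeError(f"pellet {pellet_id}: {exc}") from exc
    return PelletRecord(pellet_id=pellet_id, strain=strain, shells=shells,
                        aligned=aligned, shape=shape, metrics=metrics,
                        fit=fit)


def _mode_mae(rec: PelletRecord, params: KineticParams, y_value: float,
              constant_ch: float | None = None) -> float:
    """MAE of the simulated profile against the pellet's measurements."""
    a = rec.aligned
    inside = a.inside
    r_meas, y_exp = a.radii[inside], a.c_o2[inside]
    grid_um = np.linspace(0.0, a.border_radius, 100)
    if constant_ch is not None:
        ch = np.full(100, min(constant_ch, 0.999))
    elif a.shells is not None:
        ch = np.minimum(
            a.shells.interp_fraction(grid_um, border_radius=a.border_radius),
            0.999)
    else:
        ch = np.minimum(np.interp(grid_um, a.radii, a.ch), 0.999)
    p = params.replace(y_xo2=y_value)
    sim = steady_state_profile(ch, p, a.c_max * MG_PER_L,
                               a.border_radius * 1e-6)
    y_sim = np.interp(r_meas, sim.radii_um, sim.c_o2 / MG_PER_L)
    return mean_absolute_error(y_exp, y_sim)


def _mean_ch(rec: PelletRecord) -> float:
    """Volume-weighted mean hyphal fraction inside the border."""
    shells = rec.shells
    vol = shell_bin_volumes(shells)
    inside = shells.shell_outer_radii <= rec.aligned.border_radius + 1e-9
    if not inside.any():
        inside = np.ones(len(vol), dtype=bool)
    return float(np.sum(shells.fractions[inside] * vol[inside])
                 / np.sum(vol[inside]))


def cohort_summary(records: list[PelletRecord],
                   params: KineticParams) -> dict:
    """Cohort statistics over the spherical pellets.

    Returns per-strain and overall means +/- sd of penetration depth, APP
    and fitted yield, ANOVA p-values between strains, and a per-pellet
    table of the three evaluation-mode MAEs.
    """
    spherical = [r for r in records if r.is_spherical]
    if not spherical:
        raise ValueError("no spherical pellets after filtering")
    y_name = "y_xo2" if "y_xo2" in spherical[0].fit.estimates \
        else list(spherical[0].fit.estimates)[0]
    y_hat = {r.pellet_id: r.fit.estimates[y_name] for r in spherical}
    y_mean = float(np.mean(list(y_hat.values())))
    strain_ch = {}
    for s in {r.strain for r in spherical}:
        strain_ch[s] = float(np.mean([_mean_ch(r) for r in spherical
                                      if r.strain == s]))

    rows = []
    for r in records:
        mode1 = r.fit.mae
        if r.is_spherical:
            mode2 = _mode_mae(r, params, y_mean)
            mode3 = _mode_mae(r, params, y_mean,
                              constant_ch=strain_ch.get(r.strain,
                                                        _mean_ch(r)))
        else:
            mode2 = _mode_mae(r, params, y_mean)
            mode3 = _mode_mae(r, params, y_mean, constant_ch=_mean_ch(r))
        rows.append({"pellet_id": r.pellet_id, "strain": r.strain,
                     "is_spherical": r.is_spherical,
                     "penetration_depth_um": r.metrics.penetration_depth,
                     "app_percent": r.metrics.app,
                     "y_hat": y_hat.get(r.pellet_id,
                                        r.fit.estimates[y_name]),
                     "mae_individual": mode1, "mae_mean_param": mode2,
                     "mae_mean_ch": mode3})
    table = pd.DataFrame(rows)
    sph = table[table.is_spherical]

    def _stats(col):
        out = {"mean": float(sph[col].mean()), "sd": float(sph[col].std())}
        for s, grp in sph.groupby("strain"):
            out[s] = {"mean": float(grp[col].mean()),
                      "sd": float(grp[col].std())}
        return out

    summary = {
        "n_pellets": len(records),
        "n_spherical": len(sph),
        "penetration_depth_um": _stats("penetration_depth_um"),
        "app_percent": _stats("app_percent"),
        "y_xo2": _stats("y_hat"),
        "table": table,
    }
    strains = sorted(sph.strain.unique())
    if len(strains) >= 2:
        for col, key in [("penetration_depth_um", "anova_depth"),
                         ("app_percent", "anova_app"),
                         ("y_hat", "anova_y")]:
            groups = [sph[sph.strain == s][col].to_numpy() for s in strains]
            if all(len(g) >= 2 for g in groups):
                summary[key] = one_way_anova(groups)
    return summary
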