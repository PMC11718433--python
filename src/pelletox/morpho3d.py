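"""Shell-resolved morphometry of 3D pellet images and 2D shape descriptors.

The central quantity is the radial hyphal fraction ch(r): the volume
fraction of hyphal material in concentric 15 um shells around a 50 um
central sphere at the pellet's mass centre.  The module also provides the
sphericity/axis-ratio classification used to filter pellets before
cohort statistics, and the 2D morphology number for projected pellets.

Coordinates are 0-based voxel indices; the physical position of a voxel
centre is (index + 0.5) * voxel_size.  Voxels are assigned to shells by
the distance of their centre to the foreground centroid, without
partial-volume weighting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import binary_erosion

__all__ = [
    "VoxelImage", "Mask2D", "ShellProfile", "ShapeMetrics3D", "Descriptors2D",
    "binarize_otsu", "shell_hyphal_fraction", "border_from_fraction",
    "total_hyphal_volume", "shape_metrics_3d", "descriptors_2d",
    "morphology_number", "shell_bin_volumes",
]

#: sphericity / axis-ratio thresholds of the spherical-pellet filter
AXIS_RATIO_MIN = 0.7
SPHERICITY_MIN = 0.95


@dataclass
class VoxelImage:
    """A 3D voxel image with isotropic physical voxel size in um."""

    voxels: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def is_binary(self) -> bool:
        return self.voxels.dtype == bool or set(np.unique(self.voxels)) <= {0, 1}

    @classmethod
    def from_tiff(cls, path, voxel_size: float) -> "VoxelImage":
        import tifffile
        return cls(tifffile.imread(path), voxel_size)

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, np.asarray(self.voxels, dtype=np.uint8))


@dataclass
class Mask2D:
    """A 2D binary mask of a projected pellet with pixel size in um."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ShellProfile:
    """Radial hyphal-fraction profile ch(r) on concentric shells.

    The first bin is the central sphere of radius ``core_radius``; each
    subsequent bin is a shell of width ``shell_width``.  ``shell_outer_radii``
    holds the outer radius of every bin (ascending), ``fractions`` the
    hyphal volume fraction in each bin.
    """

    shell_outer_radii: np.ndarray
    fractions: np.ndarray
    core_radius: float = 50.0
    shell_width: float = 15.0
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.shell_outer_radii = np.asarray(self.shell_outer_radii, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.shell_outer_radii.shape != self.fractions.shape:
            raise ValueError("radii and fractions must have equal length")
        if self.shell_outer_radii.size == 0:
            raise ValueError("empty shell profile")
        if np.any(np.diff(self.shell_outer_radii) <= 0):
            raise ValueError("shell_outer_radii must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def inner_radii(self) -> np.ndarray:
        return np.concatenate(([0.0], self.shell_outer_radii[:-1]))

    @property
    def mid_radii(self) -> np.ndarray:
        return 0.5 * (self.inner_radii + self.shell_outer_radii)

    def interp_fraction(self, radii: np.ndarray,
                        border_radius: float | None = None) -> np.ndarray:
        """ch linearly interpolated between shell mid-radii.

        Constant inside the central sphere and between the last mid-radius
        and ``border_radius`` (default: outermost shell edge); 0 beyond the
        border.  Values are clamped to [0, 1].  The decline towards the
        pellet edge is carried by the shell values themselves.
        """
        radii = np.asarray(radii, dtype=float)
        if border_radius is None:
            border_radius = float(self.shell_outer_radii[-1])
        out = np.interp(radii, self.mid_radii, self.fractions,
                        left=self.fractions[0], right=self.fractions[-1])
        out = np.where(radii > border_radius, 0.0, out)
        return np.clip(out, 0.0, 1.0)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "shell_outer_radius_um": self.shell_outer_radii,
            "fraction": self.fractions,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, core_radius: float = 50.0, shell_width: float = 15.0,
                 voxel_size: float = 1.0) -> "ShellProfile":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df["shell_outer_radius_um"].to_numpy(),
                   df["fraction"].to_numpy(),
                   core_radius=core_radius, shell_width=shell_width,
                   voxel_size=voxel_size)


@dataclass
class ShapeMetrics3D:
    sphericity: float
    axis_ratio: float
    is_spherical: bool
    total_hyphal_volume: float
    border_radius: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class Descriptors2D:
    area: float
    solidity: float
    feret_diameter: float
    aspect_ratio: float
    aesd: float = field(init=False)
    mn: float = field(init=False)

    def __post_init__(self) -> None:
        self.aesd = 2.0 * np.sqrt(self.area / np.pi)
        self.mn = morphology_number(self)


def binarize_otsu(img: VoxelImage) -> VoxelImage:
    """Binarize a grayscale image with Otsu's threshold (256-bin histogram).

    Foreground (hyphal material) is everything strictly above the threshold
    that maximizes the between-class variance.  Already-binary images are
    passed through with an unchanged foreground set.
    """
    vox = img.voxels
    if np.all(vox == vox.flat[0]):
        raise ValueError("degenerate histogram: constant image")
    thr = threshold_otsu(np.asarray(vox), nbins=256)
    return VoxelImage((vox > thr).astype(np.uint8), img.voxel_size)


def _radial_bins(img: VoxelImage, core_radius: float, shell_width: float):
    """Distances of voxel centres to the foreground centroid, binned."""
    vox = img.voxels.astype(bool)
    if not vox.any():
        raise ValueError("no foreground")
    idx = np.nonzero(vox)
    centroid = np.array([c.mean() for c in idx])  # voxel-index units
    nz, ny, nx = vox.shape
    z = (np.arange(nz) - centroid[0])[:, None, None]
    y = (np.arange(ny) - centroid[1])[None, :, None]
    x = (np.arange(nx) - centroid[2])[None, None, :]
    dist = np.sqrt(z * z + y * y + x * x).astype(np.float32) * img.voxel_size
    bins = np.where(dist < core_radius, 0,
                    1 + np.floor((dist - core_radius) / shell_width)).astype(np.int64)
    return vox, bins


def shell_hyphal_fraction(img: VoxelImage, core_radius: float = 50.0,
                          shell_width: float = 15.0) -> ShellProfile:
    """Hyphal volume fraction per radial bin around the foreground centroid.

    Each bin's fraction is foreground voxels / total in-image voxels in the
    bin, so shells that extend past the image edge are normalized by their
    in-bounds volume.  Trailing bins with no foreground are dropped.
    """
    vox, bins = _radial_bins(img, core_radius, shell_width)
    nbins = int(bins.max()) + 1
    total = np.bincount(bins.ravel(), minlength=nbins)
    fg = np.bincount(bins.ravel(), weights=vox.ravel(), minlength=nbins)
    frac = np.divide(fg, total, out=np.zeros(nbins), where=total > 0)
    last = int(np.max(np.nonzero(fg > 0)))
    frac = frac[: last + 1]
    outer = core_radius + shell_width * np.arange(len(frac))
    outer[0] = core_radius
    return ShellProfile(outer if len(frac) > 1 else np.array([core_radius]),
                        frac, core_radius=core_radius,
                        shell_width=shell_width, voxel_size=img.voxel_size)


def border_from_fraction(shells: ShellProfile, cutoff: float = 0.005) -> float:
    """Pellet border radius from the hyphal-fraction cutoff rule.

    The border is located at the outermost shell whose fraction is still
    >= ``cutoff`` (0.005 rather than 0, to suppress single protruding
    hyphae), linearly interpolated to the exact cutoff crossing against the
    next shell's fraction.  Shell averages are anchored at shell
    mid-radii — a bin average estimates ch at the bin centre — which keeps
    the border within half a shell width of a sharp pellet edge; if the
    outermost shell itself is above the cutoff, its outer radius is
    returned.
    """
    frac = shells.fractions
    above = np.nonzero(frac >= cutoff)[0]
    if above.size == 0:
        raise ValueError(f"all shell fractions below cutoff {cutoff}")
    i = int(above[-1])
    if i == len(frac) - 1:
        return float(shells.shell_outer_radii[i])
    mids = shells.mid_radii
    f_i, f_next = frac[i], frac[i + 1]
    return float(mids[i] + (mids[i + 1] - mids[i])
                 * (f_i - cutoff) / (f_i - f_next))


def shell_bin_volumes(shells: ShellProfile) -> np.ndarray:
    """Exact spherical bin volumes in um^3 (central sphere, then shells)."""
    outer = shells.shell_outer_radii
    inner = shells.inner_radii
    return 4.0 / 3.0 * np.pi * (outer**3 - inner**3)


def total_hyphal_volume(shells: ShellProfile) -> float:
    """Total hyphal volume in um^3: sum of fraction x exact bin volume."""
    return float(np.sum(shells.fractions * shell_bin_volumes(shells)))


def shape_metrics_3d(img: VoxelImage, shells: ShellProfile) -> ShapeMetrics3D:
    """Sphericity, axis ratio and the spherical-pellet classification.

    Sphericity is the surface area of the volume-equivalent sphere divided
    by the convex-hull surface area (hull built on the corner points of
    surface foreground voxels).  Axis ratio is the smallest/largest
    principal axis length from the second-moment tensor of the foreground.
    A pellet is classified spherical when axis_ratio >= 0.7 and
    sphericity >= 0.95.
    """
    vox = img.voxels.astype(bool)
    coords = np.argwhere(vox)
    if len(coords) < 4:
        raise ValueError("need at least 4 foreground voxels for a hull")
    volume = len(coords) * img.voxel_size**3
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    surface = vox & ~binary_erosion(vox)
    surf_coords = np.argwhere(surface)
    corners = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
                        [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]])
    pts = (surf_coords[:, None, :] + corners[None, :, :]).reshape(-1, 3)
    pts = np.unique(pts, axis=0) * img.voxel_size
    hull = ConvexHull(pts)
    sphericity = 4.0 * np.pi * r_eq**2 / hull.area

    cov = np.cov((coords * img.voxel_size).T)
    eig = np.linalg.eigvalsh(cov)
    axis_ratio = float(np.sqrt(max(eig[0], 0.0) / eig[-1]))

    return ShapeMetrics3D(
        sphericity=float(sphericity),
        axis_ratio=axis_ratio,
        is_spherical=bool(axis_ratio >= AXIS_RATIO_MIN
                          and sphericity >= SPHERICITY_MIN),
        total_hyphal_volume=total_hyphal_volume(shells),
        border_radius=border_from_fraction(shells),
    )


def descriptors_2d(mask: Mask2D) -> Descriptors2D:
    """Euclidean descriptors of a projected pellet mask.

    Area from pixel count, solidity from the convex hull, maximum Feret
    (caliper) diameter, and the aspect ratio (>= 1) of the moment-equivalent
    ellipse.  Lengths are in um, areas in um^2.
    """
    if not mask.pixels.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.pixels.astype(np.uint8))[0]
    ps = mask.pixel_size
    area = props.area * ps**2
    if props.axis_minor_length > 0:
        aspect = props.axis_major_length / props.axis_minor_length
    else:  # degenerate (single pixel / line): treat as round
        aspect = 1.0
    feret = props.feret_diameter_max * ps
    if feret == 0:  # single pixel
        feret = ps
    return Descriptors2D(area=float(area), solidity=float(props.solidity),
                         feret_diameter=float(feret), aspect_ratio=float(aspect))


def morphology_number(d: Descriptors2D) -> float:
    """Morphology number: 2*sqrt(area*solidity/pi) / (feret * aspect_ratio).

    A dimensionless roundness/smoothness descriptor normalized so that a
    perfect circle scores 1; elongation, roughness and concavity all lower
    it.
    """
    if d.feret_diameter <= 0 or d.aspect_ratio <= 0:
        raise ValueError("feret diameter and aspect ratio must be positive")
    return float(2.0 * np.sqrt(d.area * d.solidity / np.pi)
                 / (d.feret_diameter * d.aspect_ratio))
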