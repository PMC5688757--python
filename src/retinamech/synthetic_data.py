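"""Synthetic confocal imagery and recoil experiments with known ground truth.

Emulates the three kinds of raw data the analysis pipeline consumes:

* multi-channel confocal z-stacks of a retinal flat-mount, with the bright
  OLM signal confined to a curved or tilted surface z(x, y) inside the
  stack (membrane-style ZO1 channel, soma-style reporter channels, and a
  glial channel filling the space between photoreceptor profiles);
* 2D images of Müller-glial apical processes, with thick bright bands in
  the inter-column space and thin lamellae outlining each profile;
* laser-ablation recoil experiments: tracked photoreceptor centroids around
  a circular lesion, deformed by a known anisotropic affine transform that
  saturates exponentially in time, plus positional noise.

Everything is bit-reproducible for a fixed (parameters, seed) pair, and
every simulation records its ground truth so recovery can be scored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .mosaic_model import ConeSubtype, MosaicLattice

__all__ = [
    "ImageStack3D",
    "AblationExperiment",
    "ExperimentGroup",
    "ChannelSpec",
    "GeometryError",
    "render_zstack",
    "render_glial_band_image",
    "simulate_ablation_recoil",
    "raster_grid",
    "inter_column_offsets",
    "default_channel_spec",
]

#: Default voxel spacing, micrometres: 1.8 um optical-section interval in z,
#: 0.2 um pixels in x/y.
DEFAULT_DZ = 1.8
DEFAULT_PIXEL_SIZE = 0.2


class GeometryError(ValueError):
    """Raised when a requested surface leaves the stack bounds."""


class ExperimentGroup(enum.Enum):
    ABLATION = "ABLATION"
    CONTROL = "CONTROL"


@dataclass
class ImageStack3D:
    """Multi-channel 3D intensity stack with voxel-spacing metadata.

    ``intensities`` has shape (n_channels, nz, ny, nx); ``voxel_size`` is
    (dz, dy, dx) in micrometres; ``origin`` is the (x, y) position in
    micrometres of pixel column/row 0 (z of slice 0 is 0).
    """

    intensities: np.ndarray
    channels: tuple[str, ...]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.channels = tuple(self.channels)
        if self.intensities.ndim != 4 or self.intensities.shape[0] != len(self.channels):
            raise ValueError(
                "intensities must be (n_channels, nz, ny, nx) matching channels"
            )
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.intensities[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    @property
    def z_coords(self) -> np.ndarray:
        """Depth of each slice, micrometres."""
        return np.arange(self.shape[0]) * self.voxel_size[0]


@dataclass
class ChannelSpec:
    """How one channel renders the lattice.

    style     'membrane' (intensity on profile boundaries), 'soma'
              (Gaussian blobs at site centres) or 'glial' (complement of
              profiles, thick in the inter-column space)
    subtypes  which subtypes emit (None = all sites)
    """

    style: str
    subtypes: frozenset[ConeSubtype] | None = None
    amplitude: float = 1.0
    width_um: float | None = None  # membrane thickness / soma sigma override

    def __post_init__(self) -> None:
        if self.style not in ("membrane", "soma", "glial"):
            raise ValueError(f"unknown channel style {self.style!r}")


def default_channel_spec() -> dict[str, ChannelSpec]:
    """ZO1 membrane + Red-cone reporter + glial reporter channels."""
    return {
        "ZO1": ChannelSpec("membrane"),
        "trb2": ChannelSpec("soma", frozenset({ConeSubtype.RED})),
        "gfap": ChannelSpec("glial"),
    }


def raster_grid(
    lattice: MosaicLattice, pixel_size: float, margin: float | None = None
) -> tuple[tuple[int, int], tuple[float, float]]:
    """Pixel-grid shape (ny, nx) and origin (x0, y0) covering the lattice.

    The grid spans the lattice bounding box plus ``margin`` (default one
    lattice spacing) on every side.  All renderers share this mapping:
    pixel (row, col) sits at (x0 + col*pixel_size, y0 + row*pixel_size).
    """
    if margin is None:
        margin = lattice.spacing
    lo = lattice.positions.min(0) - margin
    hi = lattice.positions.max(0) + margin
    nx = int(math.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    ny = int(math.ceil((hi[1] - lo[1]) / pixel_size)) + 1
    return (ny, nx), (float(lo[0]), float(lo[1]))


def _pixel_positions(shape, origin, pixel_size):
    ny, nx = shape
    xs = origin[0] + np.arange(nx) * pixel_size
    ys = origin[1] + np.arange(ny) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _render_pattern(
    lattice: MosaicLattice,
    spec: ChannelSpec,
    shape: tuple[int, int],
    origin: tuple[float, float],
    pixel_size: float,
) -> np.ndarray:
    """2D en-face intensity pattern for one channel (no blur, no noise)."""
    pts = _pixel_positions(shape, origin, pixel_size)
    if spec.subtypes is None:
        sites = lattice.positions
    else:
        m = np.array([s in spec.subtypes for s in lattice.subtypes], dtype=bool)
        sites = lattice.positions[m]
    if len(sites) == 0:
        return np.zeros(shape)

    if spec.style == "membrane":
        # bright where two Voronoi cells of the full site set meet
        tree = cKDTree(lattice.positions)
        d, _ = tree.query(pts, k=2)
        half_gap = 0.5 * (d[:, 1] - d[:, 0])
        w = spec.width_um if spec.width_um else 0.15 * lattice.spacing
        img = spec.amplitude * np.exp(-(half_gap**2) / (2 * w**2))
    elif spec.style == "soma":
        tree = cKDTree(sites)
        d, _ = tree.query(pts, k=1)
        sigma = spec.width_um if spec.width_um else 0.25 * lattice.spacing
        img = spec.amplitude * np.exp(-(d**2) / (2 * sigma**2))
    else:  # glial: complement of photoreceptor profiles
        tree = cKDTree(sites)
        d, _ = tree.query(pts, k=1)
        r_profile = 0.35 * lattice.spacing
        w = spec.width_um if spec.width_um else 0.1 * lattice.spacing
        img = spec.amplitude / (1.0 + np.exp(-(d - r_profile) / w))
    return img.reshape(shape)


def surface_height(
    surface_spec: dict,
    shape: tuple[int, int],
    origin: tuple[float, float],
    pixel_size: float,
) -> np.ndarray:
    """Evaluate the OLM surface depth z(x, y) in micrometres on a pixel grid.

    Modes: ``flat`` (params: z0), ``tilted`` (z0, slope_x, slope_y in
    um/um) and ``spherical_cap`` (z_apex, radius, optional center (cx, cy)
    defaulting to the image centre; depth increases away from the apex).
    """
    ny, nx = shape
    xs = origin[0] + np.arange(nx) * pixel_size
    ys = origin[1] + np.arange(ny) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    mode = surface_spec["mode"]
    p = surface_spec.get("params", {})
    if mode == "flat":
        return np.full(shape, float(p.get("z0", 0.0)))
    if mode == "tilted":
        z0 = float(p.get("z0", 0.0))
        cx = origin[0] + 0.5 * (nx - 1) * pixel_size
        cy = origin[1] + 0.5 * (ny - 1) * pixel_size
        return z0 + p.get("slope_x", 0.0) * (gx - cx) + p.get("slope_y", 0.0) * (gy - cy)
    if mode == "spherical_cap":
        R = float(p["radius"])
        cx, cy = p.get(
            "center",
            (
                origin[0] + 0.5 * (nx - 1) * pixel_size,
                origin[1] + 0.5 * (ny - 1) * pixel_size,
            ),
        )
        rho2 = (gx - cx) ** 2 + (gy - cy) ** 2
        if np.any(rho2 >= R**2):
            raise GeometryError(
                f"spherical cap of radius {R} um does not cover the field"
            )
        return float(p.get("z_apex", 0.0)) + R - np.sqrt(R**2 - rho2)
    raise ValueError(f"unknown surface mode {mode!r}")


def render_zstack(
    lattice: MosaicLattice,
    surface_spec: dict,
    channel_spec: dict[str, ChannelSpec] | None = None,
    psf_sigma: float = 0.4,
    psf_sigma_z: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.5,
    dz: float = DEFAULT_DZ,
    nz: int | None = None,
    margin: float | None = None,
) -> ImageStack3D:
    """Render a confocal-like multi-channel z-stack of the mosaic.

    The 2D channel patterns (see :class:`ChannelSpec`) are blurred laterally
    with ``psf_sigma`` (um), placed at the surface depth with a Gaussian
    axial profile of sigma ``psf_sigma_z`` (um), and corrupted with additive
    Gaussian noise clipped at zero.  The surface must lie inside the stack;
    with ``nz=None`` the stack is sized to contain it with a 4-sigma axial
    buffer.
    """
    if channel_spec is None:
        channel_spec = default_channel_spec()
    shape, origin = raster_grid(lattice, pixel_size, margin)
    zs = surface_height(surface_spec, shape, origin, pixel_size)
    buffer = 4.0 * psf_sigma_z
    if nz is None:
        nz = int(math.ceil((zs.max() + buffer) / dz)) + 1
    zmax = (nz - 1) * dz
    if zs.min() < 0.0 or zs.max() > zmax:
        raise GeometryError(
            f"surface range [{zs.min():.2f}, {zs.max():.2f}] um exits stack "
            f"depth [0, {zmax:.2f}] um"
        )

    rng = np.random.default_rng(seed)
    z_slices = np.arange(nz) * dz
    axial = np.exp(
        -((z_slices[:, None, None] - zs[None, :, :]) ** 2) / (2 * psf_sigma_z**2)
    )
    stacks = []
    names = []
    for name, spec in channel_spec.items():
        pat = _render_pattern(lattice, spec, shape, origin, pixel_size)
        if psf_sigma > 0:
            pat = ndimage.gaussian_filter(pat, psf_sigma / pixel_size)
        vol = pat[None, :, :] * axial
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, vol.shape)
        stacks.append(np.clip(vol, 0.0, None))
        names.append(name)
    return ImageStack3D(
        intensities=np.stack(stacks),
        channels=tuple(names),
        voxel_size=(dz, pixel_size, pixel_size),
        origin=origin,
    )


def inter_column_offsets(lattice: MosaicLattice) -> np.ndarray:
    """Across-column coordinates (um) of the inter-column band centrelines.

    Coordinates are projections onto ``lattice.row_axis`` relative to the
    same origin as the site positions; centrelines sit midway between
    adjacent column lines.
    """
    d = lattice.column_separation
    return (np.arange(lattice.n_columns - 1) + 0.5) * d


def render_glial_band_image(
    lattice: MosaicLattice,
    band_width_px: int,
    lamella_width_px: int,
    pixel_size: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    band_amplitude: float = 1.0,
    lamella_amplitude: float = 0.5,
    margin: float | None = None,
) -> np.ndarray:
    """Render a 2D image of glial apical processes at the OLM.

    Thick bright bands (FWHM ``band_width_px`` pixels) run between columns,
    parallel to the lattice column direction; thin closed lamellae (FWHM
    ``lamella_width_px``) outline every photoreceptor profile.  Requires
    ``band_width_px > lamella_width_px >= 1``.
    """
    if not band_width_px > lamella_width_px >= 1:
        raise ValueError(
            f"need band_width_px > lamella_width_px >= 1, got "
            f"{band_width_px}, {lamella_width_px}"
        )
    shape, origin = raster_grid(lattice, pixel_size, margin)
    pts = _pixel_positions(shape, origin, pixel_size)

    img = np.zeros(shape).ravel()
    if lattice.n_columns >= 2:
        v = lattice.row_axis
        # across-column coordinate of every pixel, relative to column 0's line
        t0 = float(lattice.positions[np.argmax(lattice.column_index == 0)] @ v)
        t = (pts @ v) - t0
        centers = inter_column_offsets(lattice)
        dist = np.min(np.abs(t[:, None] - centers[None, :]), axis=1)
        sigma_b = band_width_px * pixel_size / 2.355  # FWHM -> sigma
        img += band_amplitude * np.exp(-(dist**2) / (2 * sigma_b**2))

    tree = cKDTree(lattice.positions)
    d, _ = tree.query(pts, k=2)
    half_gap = 0.5 * (d[:, 1] - d[:, 0])
    sigma_l = lamella_width_px * pixel_size / 2.355
    img += lamella_amplitude * np.exp(-(half_gap**2) / (2 * sigma_l**2))

    img = img.reshape(shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    return img


@dataclass
class AblationTruth:
    """Ground truth of a simulated recoil experiment."""

    M_true: np.ndarray
    b_true: np.ndarray
    noise_sd: float
    tau_min: float
    hole_center: np.ndarray = field(default_factory=lambda: np.zeros(2))


@dataclass
class AblationExperiment:
    """Tracked centroids around a lesion, pre- and post-ablation.

    ``points_post[k]`` corresponds point-for-point to ``points_pre`` at
    ``times_min[k]`` minutes after ablation.
    """

    points_pre: np.ndarray
    points_post: list[np.ndarray]
    times_min: list[float]
    group: ExperimentGroup
    hole_polygon: np.ndarray | None = None
    truth: AblationTruth | None = None

    def __post_init__(self) -> None:
        self.points_pre = np.asarray(self.points_pre, dtype=float)
        self.points_post = [np.asarray(p, dtype=float) for p in self.points_post]
        self.times_min = [float(t) for t in self.times_min]
        if len(self.points_post) != len(self.times_min):
            raise ValueError("one post point set per timepoint required")
        for p in self.points_post:
            if p.shape != self.points_pre.shape:
                raise ValueError("point correspondence broken: shape mismatch")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("times_min must be strictly increasing")

    def saturation(self, t_min: float) -> float:
        """Fraction of the full deformation reached at time t."""
        assert self.truth is not None
        return 1.0 - math.exp(-t_min / self.truth.tau_min)

    def effective_transform(self, t_min: float) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (M, b) actually applied at time ``t_min``.

        The simulated recoil interpolates between identity and the full
        affine with the saturating factor f(t):  M_t = (1-f) I + f M_full,
        b_t = f b_full, both about the hole centre.
        """
        assert self.truth is not None
        f = self.saturation(t_min)
        M = (1.0 - f) * np.eye(2) + f * self.truth.M_true
        c = self.truth.hole_center
        b = f * self.truth.b_true + c - M @ c
        return M, b


def _rotation(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


def simulate_ablation_recoil(
    lattice: MosaicLattice,
    hole_center: tuple[float, float],
    hole_radius: float,
    strain_true: tuple[float, float] = (1.0, 1.2),
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    times_min: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0),
    noise_sd: float = 0.0,
    group: ExperimentGroup | str = ExperimentGroup.ABLATION,
    seed: int = 0,
    tau_min: float = 20.0,
    n_tracked: int | None = None,
) -> AblationExperiment:
    """Simulate tissue recoil around an ablated glial cell.

    Photoreceptor sites inside the circular hole are lost; the remaining
    sites (optionally only the ``n_tracked`` closest to the hole, emulating
    the profiles immediately surrounding the lesion) recoil toward the full
    affine ``R(rotation_deg) @ P`` about ``hole_center``, where ``P``
    stretches by ``strain_true = (lambda_x, lambda_y)`` perpendicular and
    parallel to the cone columns respectively.  The approach is exponential
    with time constant ``tau_min``; i.i.d. Gaussian positional noise of
    ``noise_sd`` um is added to every tracked centroid at every post time.
    CONTROL experiments apply identity deformation plus the same noise.
    """
    lx, ly = strain_true
    if lx <= 0 or ly <= 0:
        raise ValueError(f"stretch ratios must be positive, got {strain_true}")
    group = ExperimentGroup(group) if not isinstance(group, ExperimentGroup) else group
    c = np.asarray(hole_center, dtype=float)

    r = np.linalg.norm(lattice.positions - c, axis=1)
    outside = r > hole_radius
    if not np.any(outside):
        raise ValueError("no photoreceptors outside the hole to track")
    idx = np.flatnonzero(outside)
    if n_tracked is not None:
        idx = idx[np.argsort(r[idx], kind="stable")[:n_tracked]]
    pts0 = lattice.positions[idx]

    # stretch axes tied to the lattice: x-strain across, y-strain along columns
    ex = lattice.row_axis
    ey = lattice.column_axis
    P = lx * np.outer(ex, ex) + ly * np.outer(ey, ey)
    if group is ExperimentGroup.CONTROL:
        M_full = np.eye(2)
        b_full = np.zeros(2)
    else:
        M_full = _rotation(rotation_deg) @ P
        b_full = np.asarray(translation, dtype=float)

    truth = AblationTruth(
        M_true=M_full, b_true=b_full, noise_sd=noise_sd, tau_min=tau_min, hole_center=c
    )
    rng = np.random.default_rng(seed)
    posts = []
    for t in times_min:
        f = 1.0 - math.exp(-t / tau_min)
        M_t = (1.0 - f) * np.eye(2) + f * M_full
        moved = (pts0 - c) @ M_t.T + c + f * b_full
        if noise_sd > 0:
            moved = moved + rng.normal(0.0, noise_sd, moved.shape)
        posts.append(moved)

    ang = np.linspace(0, 2 * math.pi, 33)
    hole = c + hole_radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return AblationExperiment(
        points_pre=pts0,
        points_post=posts,
        times_min=list(times_min),
        group=group,
        hole_polygon=hole,
        truth=truth,
    )
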