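"""Selective projection of z-stacks at the outer limiting membrane (OLM).

In flat-mounted retinas the OLM — the apical junctional plane where
photoreceptor and glial profiles meet — is a curved, often tilted surface
inside the confocal z-stack.  A maximum projection of the whole stack mixes
signal from other depths; instead, the OLM surface is reconstructed from a
junction channel (ZO1) by smoothing each pixel's z-profile with a Gaussian
kernel and locating its peak, interpolating across low-signal or masked
pixels, and any channel is then projected only within a thin band around
that surface.  The fitted tilt plane of the surface is also used downstream
to correct tracked point coordinates for sample inclination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from .synthetic_data import ImageStack3D

__all__ = [
    "SurfaceMap",
    "Projection2D",
    "TiltPlane",
    "reconstruct_olm_surface",
    "project_at_surface",
    "estimate_tilt",
]


@dataclass
class TiltPlane:
    """Plane n . (x, y, z) = offset with unit normal n (n_z > 0)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("tilt plane normal must be a finite non-zero vector")
        if n[2] < 0:
            n, self.offset = -n, -float(self.offset)
        self.normal = n / norm
        self.offset = float(self.offset) / norm

    @property
    def tilt_angle_deg(self) -> float:
        """Angle between the surface normal and the optical axis."""
        return math.degrees(math.acos(np.clip(self.normal[2], -1.0, 1.0)))

    def z_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.normal
        return (self.offset - nx * x - ny * y) / nz


@dataclass
class SurfaceMap:
    """Reconstructed OLM depth field with per-pixel confidence.

    ``z_of_xy`` is the surface depth in micrometres per (y, x) pixel;
    ``confidence`` in [0, 1] reflects normalized peak prominence (0 on
    masked or signal-free pixels); ``tilt_plane`` is the least-squares
    plane through the surface.
    """

    z_of_xy: np.ndarray
    confidence: np.ndarray
    tilt_plane: TiltPlane | None
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.z_of_xy = np.asarray(self.z_of_xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.z_of_xy.shape != self.confidence.shape:
            raise ValueError("z_of_xy and confidence must share shape")


@dataclass
class Projection2D:
    """A channel selectively projected at the OLM surface."""

    image: np.ndarray
    source_channel: str
    band_halfwidth: float
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)


def _parabolic_refine(profile: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Sub-voxel peak offset (in slices) by 3-point parabola around argmax."""
    nz = profile.shape[0]
    k0 = np.clip(k, 1, nz - 2)
    idx = np.indices(k.shape)
    ym = profile[(k0 - 1, *idx)]
    y0 = profile[(k0, *idx)]
    yp = profile[(k0 + 1, *idx)]
    denom = ym - 2 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (ym - yp) / denom
    delta = np.where(np.abs(denom) > 1e-300, delta, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    # at the stack edges fall back to the integer argmax
    delta = np.where((k >= 1) & (k <= nz - 2), delta, 0.0)
    return delta


def reconstruct_olm_surface(
    stack: ImageStack3D,
    channel: str,
    z_kernel_sigma: float = 1.5,
    xy_smooth_sigma: float = 1.0,
    mask: np.ndarray | None = None,
    confidence_floor: float = 0.1,
    method: str = "argmax",
) -> SurfaceMap:
    """Reconstruct the OLM depth field from a junction channel.

    Per (x, y) pixel the z-profile is smoothed with a Gaussian kernel of
    ``z_kernel_sigma`` micrometres and the depth of its maximum taken
    (``method='argmax'``, refined to sub-voxel precision by parabolic
    interpolation) or its intensity-weighted centroid
    (``method='centroid'``).  Confidence is the smoothed peak prominence
    normalized to [0, 1]; pixels below ``confidence_floor`` — and pixels of
    the optional boolean ``mask``, e.g. manually masked radial fibers — are
    filled by interpolation from confident neighbours.  The field is then
    smoothed in x, y with ``xy_smooth_sigma`` micrometres and a tilt plane
    fitted.
    """
    vol = stack.channel(channel)
    if not np.any(vol > 0):
        raise ValueError(f"channel {channel!r} is identically zero: no surface evidence")
    if z_kernel_sigma <= 0:
        raise ValueError("z_kernel_sigma must be > 0")
    dz, dy, dx = stack.voxel_size
    nz, ny, nx = vol.shape
    if mask is not None and mask.shape != (ny, nx):
        raise ValueError("mask shape must match the stack's (y, x) extent")

    smoothed = ndimage.gaussian_filter1d(vol, sigma=z_kernel_sigma / dz, axis=0)
    peak = smoothed.max(axis=0)
    prominence = peak - np.median(smoothed, axis=0)
    pmax = prominence.max()
    confidence = prominence / pmax if pmax > 0 else np.zeros_like(prominence)
    if mask is not None:
        confidence = np.where(mask, 0.0, confidence)

    if method == "argmax":
        k = smoothed.argmax(axis=0)
        z = (k + _parabolic_refine(smoothed, k)) * dz
    elif method == "centroid":
        zc = stack.z_coords[:, None, None]
        tot = smoothed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(tot > 0, (smoothed * zc).sum(axis=0) / tot, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    valid = confidence >= confidence_floor
    if mask is not None:
        valid &= ~mask
    if valid.sum() < 3:
        raise ValueError("fewer than 3 confident pixels: cannot reconstruct surface")
    if not valid.all():
        gy, gx = np.mgrid[0:ny, 0:nx]
        pts = np.column_stack([gy[valid], gx[valid]])
        z_fill = griddata(pts, z[valid], (gy, gx), method="linear")
        hole = ~np.isfinite(z_fill)
        if hole.any():
            z_fill[hole] = griddata(pts, z[valid], (gy[hole], gx[hole]), method="nearest")
        z = np.where(valid, z, z_fill)

    if xy_smooth_sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=xy_smooth_sigma / dy)
    z = np.clip(z, 0.0, (nz - 1) * dz)

    surface = SurfaceMap(
        z_of_xy=z,
        confidence=confidence,
        tilt_plane=None,
        pixel_size=dy,
        origin=stack.origin,
    )
    surface.tilt_plane = estimate_tilt(surface)
    return surface


def project_at_surface(
    stack: ImageStack3D,
    channel: str,
    surface: SurfaceMap,
    band_halfwidth: float = 2.0,
    reducer: str = "max",
) -> Projection2D:
    """Project a channel within ±``band_halfwidth`` um of the OLM surface.

    Per pixel the ``reducer`` ('max' or 'mean') is applied to the voxels
    whose slice depth lies within the band; the slice nearest the surface
    is always included, so a band narrower than the z-step still yields a
    single-slice projection.
    """
    if band_halfwidth < 0:
        raise ValueError("band_halfwidth must be >= 0")
    if reducer not in ("max", "mean"):
        raise ValueError(f"unknown reducer {reducer!r}")
    vol = stack.channel(channel)
    nz, ny, nx = vol.shape
    if surface.z_of_xy.shape != (ny, nx):
        raise ValueError(
            f"surface shape {surface.z_of_xy.shape} does not match stack {(ny, nx)}"
        )
    dz = stack.voxel_size[0]
    dist = np.abs(stack.z_coords[:, None, None] - surface.z_of_xy[None, :, :])
    band = dist <= band_halfwidth
    nearest = dist.argmin(axis=0)
    band[(nearest, *np.indices((ny, nx)))] = True

    if reducer == "max":
        img = np.where(band, vol, -np.inf).max(axis=0)
    else:
        img = (vol * band).sum(axis=0) / band.sum(axis=0)
    return Projection2D(
        image=img,
        source_channel=channel,
        band_halfwidth=float(band_halfwidth),
        pixel_size=stack.voxel_size[1],
        origin=stack.origin,
    )


def estimate_tilt(surface: SurfaceMap) -> TiltPlane:
    """Confidence-weighted least-squares plane through the surface.

    Fits z = a x + b y + c over pixels in micrometre coordinates and
    returns the plane in normal form.  Rejects degenerate geometry (fewer
    than 3 effective pixels or collinear support).
    """
    z = surface.z_of_xy
    ny, nx = z.shape
    w = surface.confidence.ravel()
    if not np.any(w > 0):
        w = np.ones_like(w)
    xs = surface.origin[0] + np.arange(nx) * surface.pixel_size
    ys = surface.origin[1] + np.arange(ny) * surface.pixel_size
    gx, gy = np.meshgrid(xs, ys)
    A = np.column_stack([gx.ravel(), gy.ravel(), np.ones(z.size)])
    if (w > 0).sum() < 3:
        raise ValueError("tilt estimation needs at least 3 weighted pixels")
    Aw = A * w[:, None]
    ATA = A.T @ Aw
    if np.linalg.matrix_rank(ATA) < 3:
        raise ValueError("degenerate (collinear) support: cannot fit a plane")
    coef = np.linalg.solve(ATA, Aw.T @ z.ravel())
    a, b, c = coef
    # z = a x + b y + c  ->  (-a, -b, 1) . (x, y, z) = c
    return TiltPlane(normal=np.array([-a, -b, 1.0]), offset=c)
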