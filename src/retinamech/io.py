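"""File round-tripping: lattices and point sets as CSV, stacks and
projections as 32-bit TIFF with JSON sidecars, configs and manifests as
JSON.

Conventions fixed across all files: positions in micrometres, angles in
degrees, pixel/voxel sizes explicit in every sidecar.  Image origin is the
top-left pixel; x runs along columns (rightward), y along rows (downward).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mosaic_model import ConeSubtype, MosaicLattice
from .surface_projection import Projection2D, SurfaceMap, TiltPlane
from .synthetic_data import AblationExperiment, ExperimentGroup, ImageStack3D

__all__ = [
    "save_lattice",
    "load_lattice",
    "save_stack",
    "load_stack",
    "save_projection",
    "load_projection",
    "save_surface",
    "load_surface",
    "save_points",
    "load_points",
    "save_json",
    "load_json",
    "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_lattice(lattice: MosaicLattice, path: str | Path) -> None:
    """Lattice sites as CSV plus a JSON sidecar of generation parameters."""
    path = Path(path)
    lattice.to_dataframe().to_csv(path, index=False, lineterminator="\n")
    save_json(
        {
            "column_direction_deg": lattice.column_direction_deg,
            "spacing_um": lattice.spacing,
            "n_repeat_units": lattice.n_repeat_units,
            "n_columns": lattice.n_columns,
            "column_spacing_factor": lattice.column_spacing_factor,
            "jitter_sd_um": lattice.jitter_sd,
            "seed": lattice.seed,
        },
        _sidecar(path),
    )


def load_lattice(path: str | Path) -> MosaicLattice:
    path = Path(path)
    df = pd.read_csv(path)
    meta = load_json(_sidecar(path))
    return MosaicLattice(
        positions=df[["x_um", "y_um"]].to_numpy(),
        subtypes=np.array([ConeSubtype(s) for s in df["subtype"]], dtype=object),
        column_index=df["column_index"].to_numpy(),
        row_index=df["row_index"].to_numpy(),
        column_direction_deg=meta["column_direction_deg"],
        spacing=meta["spacing_um"],
        n_repeat_units=meta["n_repeat_units"],
        n_columns=meta["n_columns"],
        column_spacing_factor=meta["column_spacing_factor"],
        jitter_sd=meta["jitter_sd_um"],
        seed=meta["seed"],
    )


def save_stack(stack: ImageStack3D, path: str | Path) -> None:
    """Multi-page 32-bit float TIFF (C, Z, Y, X) plus JSON metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    save_json(
        {
            "channels": list(stack.channels),
            "voxel_size_um": list(stack.voxel_size),
            "origin_um": list(stack.origin),
        },
        _sidecar(path),
    )


def load_stack(path: str | Path) -> ImageStack3D:
    path = Path(path)
    meta = load_json(_sidecar(path))
    return ImageStack3D(
        intensities=np.asarray(tifffile.imread(path), dtype=float),
        channels=tuple(meta["channels"]),
        voxel_size=tuple(meta["voxel_size_um"]),
        origin=tuple(meta["origin_um"]),
    )


def save_projection(proj: Projection2D, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, proj.image.astype(np.float32))
    save_json(
        {
            "source_channel": proj.source_channel,
            "band_halfwidth_um": proj.band_halfwidth,
            "pixel_size_um": proj.pixel_size,
            "origin_um": list(proj.origin),
        },
        _sidecar(path),
    )


def load_projection(path: str | Path) -> Projection2D:
    path = Path(path)
    meta = load_json(_sidecar(path))
    return Projection2D(
        image=np.asarray(tifffile.imread(path), dtype=float),
        source_channel=meta["source_channel"],
        band_halfwidth=meta["band_halfwidth_um"],
        pixel_size=meta["pixel_size_um"],
        origin=tuple(meta["origin_um"]),
    )


def save_surface(surface: SurfaceMap, path: str | Path) -> None:
    """Depth and confidence as a 2-page 32-bit TIFF; tilt plane in JSON."""
    path = Path(path)
    tifffile.imwrite(
        path, np.stack([surface.z_of_xy, surface.confidence]).astype(np.float32)
    )
    tp = surface.tilt_plane
    save_json(
        {
            "pixel_size_um": surface.pixel_size,
            "origin_um": list(surface.origin),
            "tilt_normal": list(tp.normal) if tp else None,
            "tilt_offset_um": tp.offset if tp else None,
        },
        _sidecar(path),
    )


def load_surface(path: str | Path) -> SurfaceMap:
    path = Path(path)
    meta = load_json(_sidecar(path))
    pages = np.asarray(tifffile.imread(path), dtype=float)
    tp = None
    if meta.get("tilt_normal") is not None:
        tp = TiltPlane(normal=np.array(meta["tilt_normal"]), offset=meta["tilt_offset_um"])
    return SurfaceMap(
        z_of_xy=pages[0],
        confidence=pages[1],
        tilt_plane=tp,
        pixel_size=meta["pixel_size_um"],
        origin=tuple(meta["origin_um"]),
    )


def save_points(experiment: AblationExperiment, path: str | Path) -> None:
    """Tracked centroids as tidy CSV (point_id, time_min, x_um, y_um).

    time_min = 0 rows hold the pre-ablation positions.
    """
    rows = []
    for i, (x, y) in enumerate(experiment.points_pre):
        rows.append({"point_id": i, "time_min": 0.0, "x_um": x, "y_um": y})
    for t, pts in zip(experiment.times_min, experiment.points_post):
        for i, (x, y) in enumerate(pts):
            rows.append({"point_id": i, "time_min": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    save_json({"group": experiment.group.value, "times_min": experiment.times_min},
              _sidecar(Path(path)))


def load_points(path: str | Path) -> AblationExperiment:
    path = Path(path)
    df = pd.read_csv(path)
    meta = load_json(_sidecar(path))
    pre = df[df["time_min"] == 0.0].sort_values("point_id")[["x_um", "y_um"]].to_numpy()
    posts = []
    for t in meta["times_min"]:
        sub = df[df["time_min"] == t].sort_values("point_id")
        posts.append(sub[["x_um", "y_um"]].to_numpy())
    return AblationExperiment(
        points_pre=pre,
        points_post=posts,
        times_min=meta["times_min"],
        group=ExperimentGroup(meta["group"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path, parameters: dict, inputs: list[str | Path] | None = None
) -> None:
    """Reproducibility manifest: package version, parameters, input hashes."""
    from . import __version__

    save_json(
        {
            "retinamech_version": __version__,
            "parameters": parameters,
            "input_sha256": {str(p): _sha256(Path(p)) for p in (inputs or [])},
        },
        path,
    )
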