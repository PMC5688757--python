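"""End-to-end pipelines chaining the analysis stages.

These orchestrations are what the CLI exposes and what the reproduction
script runs: simulate → project → segment → classify for the profile
ratio, and simulate → fit → decompose for strain recovery.
"""

from __future__ import annotations

import numpy as np

from . import (
    mosaic_model,
    profile_segmentation,
    ridge_analysis,
    strain_mechanics,
    surface_projection,
    synthetic_data,
)
from .mosaic_model import ConeSubtype
from .profile_segmentation import RatioResult
from .synthetic_data import ChannelSpec

__all__ = ["profile_ratio_pipeline", "strain_recovery_pipeline"]


def profile_ratio_pipeline(
    include_rods: bool,
    seed: int = 0,
    n_columns: int = 3,
    n_repeat_units: int = 4,
    spacing: float = 5.0,
    pixel_size: float = 0.5,
    noise_sd: float = 0.0,
    jitter_sd: float = 0.0,
    surface_z: float = 9.0,
) -> RatioResult:
    """Red-cone reporter ratio measured by the full imaging pipeline.

    Generates a lattice, renders a ZO1 membrane channel and a Red-cone
    reporter channel as a z-stack with the OLM at ``surface_z``,
    reconstructs the surface, projects both channels at it, watersheds the
    membrane projection with seeds at the true sites, measures reporter
    intensity per profile, classifies with the exact two-cluster solver,
    and returns POSITIVE : NEGATIVE counts.  On a noise-free ideal lattice
    the ratio equals the analytic lattice prediction (1:2 without rods,
    1:4 with rods).
    """
    lattice = mosaic_model.generate_mosaic_lattice(
        n_columns=n_columns,
        n_repeat_units=n_repeat_units,
        spacing=spacing,
        include_rods=include_rods,
        jitter_sd=jitter_sd,
        seed=seed,
    )
    channels = {
        "ZO1": ChannelSpec("membrane"),
        "trb2": ChannelSpec("soma", frozenset({ConeSubtype.RED})),
    }
    stack = synthetic_data.render_zstack(
        lattice,
        surface_spec={"mode": "flat", "params": {"z0": surface_z}},
        channel_spec=channels,
        pixel_size=pixel_size,
        noise_sd=noise_sd,
        seed=seed,
    )
    surface = surface_projection.reconstruct_olm_surface(stack, "ZO1")
    boundary = surface_projection.project_at_surface(stack, "ZO1", surface)
    reporter = surface_projection.project_at_surface(stack, "trb2", surface)
    # delimit the analysed field to the tissue so border profiles are not
    # inflated by the empty image margin
    field = profile_segmentation.field_mask_from_seeds(boundary, lattice.positions)
    profiles = profile_segmentation.segment_profiles(
        boundary, lattice.positions, field_mask=field
    )
    profile_segmentation.measure_intensity(profiles, reporter)
    profile_segmentation.classify_kmeans(profiles, "trb2", seed=seed)
    return profile_segmentation.compute_ratio(profiles)


def strain_recovery_pipeline(
    strain_true: tuple[float, float] = (1.0, 1.2),
    noise_frac: float = 0.02,
    n_tracked: int = 20,
    seed: int = 0,
    spacing: float = 5.0,
    times_min: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0),
    group: str = "ABLATION",
    rotation_deg: float = 0.0,
):
    """Simulate one recoil experiment and run the strain pipeline on it.

    Returns (experiment, per-timepoint StrainResult list, tidy table).
    Columns run along +y (θ_c = 90°); the hole sits at the lattice centre
    and ``n_tracked`` photoreceptors immediately surrounding it are
    tracked with Gaussian noise of ``noise_frac`` times the spacing.
    """
    lattice = mosaic_model.generate_mosaic_lattice(
        n_columns=5, n_repeat_units=4, spacing=spacing
    )
    center = lattice.positions.mean(0)
    experiment = synthetic_data.simulate_ablation_recoil(
        lattice,
        hole_center=tuple(center),
        hole_radius=1.5 * spacing,
        strain_true=strain_true,
        rotation_deg=rotation_deg,
        times_min=times_min,
        noise_sd=noise_frac * spacing,
        group=group,
        seed=seed,
        n_tracked=n_tracked,
    )
    theta_c = ridge_analysis.ColumnDirection(
        theta_c_deg=lattice.column_direction_deg, spectral_peak_magnitude=np.inf
    )
    results, table = strain_mechanics.run_strain_experiment(experiment, theta_c)
    return experiment, results, table
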