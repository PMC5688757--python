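"""Planar tissue strain from tracked photoreceptors around an ablation.

After laser ablation of a Müller glial cell, the surrounding epithelium
recoils; tracking the centroids r_i of photoreceptor profiles before and
after ablation and fitting the affine map r̂_i = M r_i + b by least squares
measures the deformation.  The polar decomposition M = U P separates a
rigid rotation U (image registration across samples) from the pure stretch
P, whose eigenvalues are the principal strains — greater than 1 means
stretching, less than 1 compression.  The eigenvector closer to the cone
column direction carries the y-strain (parallel to the retinal margin), the
other the x-strain.  Residuals of the affine fit, as a fraction of the
typical neighbour distance, diagnose how affine the deformation really is.
Group comparisons use Welch's unequal-variance t-test per axis and an
unequal-covariance two-sample Hotelling T² on the (x, y) strain pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ridge_analysis import ColumnDirection, angular_deviation_deg
from .surface_projection import TiltPlane
from .synthetic_data import AblationExperiment, ExperimentGroup

__all__ = [
    "PointCorrespondence",
    "AffineTransform",
    "StrainResult",
    "correct_tilt",
    "fit_affine",
    "residual_fraction",
    "typical_neighbor_distance",
    "polar_decompose",
    "strain_axes",
    "welch_t_test",
    "hotelling_unequal",
    "run_strain_experiment",
    "compare_strain_groups",
]


@dataclass
class PointCorrespondence:
    """Matched pre/post centroid sets at one post-ablation timepoint."""

    r0: np.ndarray
    rf: np.ndarray
    time_min: float = 0.0
    group: ExperimentGroup = ExperimentGroup.ABLATION

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, dtype=float)
        self.rf = np.asarray(self.rf, dtype=float)
        if self.r0.shape != self.rf.shape or self.r0.ndim != 2 or self.r0.shape[1] != 2:
            raise ValueError("r0 and rf must be matching (n, 2) arrays")
        if len(self.r0) < 3:
            raise ValueError("need at least 3 point correspondences")


@dataclass
class AffineTransform:
    """r̂ = M r + b, with the RMS residual of the fit."""

    M: np.ndarray
    b: np.ndarray
    rms_residual: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.M.T + self.b


@dataclass
class StrainResult:
    """Polar factors and axis-assigned principal strains of one fit."""

    U: np.ndarray
    P: np.ndarray
    eigenvalues: tuple[float, float]
    eigenvectors: np.ndarray  # columns are unit eigenvectors
    x_strain: float
    y_strain: float
    axis_deviation_deg: float
    residual_fraction: float = math.nan
    time_min: float = math.nan
    group: ExperimentGroup | None = None
    axes_indeterminate: bool = False


def correct_tilt(points: np.ndarray, tilt_plane: TiltPlane) -> np.ndarray:
    """Rotate points into the OLM plane, undoing sample tilt.

    2D inputs (n, 2) are interpreted as (x, y) image coordinates of points
    lying ON the tilted plane and are lifted to 3D using the plane; 3D
    inputs (n, 3) are used as-is.  The rotation maps the plane normal onto
    the optical axis, so returned in-plane (x, y) coordinates have true
    in-plane distances.  Identity when the normal is (0, 0, 1).
    """
    n = np.asarray(tilt_plane.normal, dtype=float)
    if not np.all(np.isfinite(n)) or abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("tilt plane normal must be a finite unit vector")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError("points must be (n, 2) or (n, 3)")
    if pts.shape[1] == 2:
        z = tilt_plane.z_at(pts[:, 0], pts[:, 1])
        pts = np.column_stack([pts, z])

    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, ez)
    s = np.linalg.norm(v)
    c = float(n @ ez)
    if s < 1e-15:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)  # Rodrigues
    return (pts @ R.T)[:, :2]


def fit_affine(pc: PointCorrespondence) -> AffineTransform:
    """Least-squares affine fit minimizing Σ‖rf − M r0 − b‖².

    Solved in closed form on mean-centered coordinates (b recovered from
    the centroids), which is exactly the normal-equations solution.
    Collinear r0 is rank-deficient and rejected.
    """
    r0c = pc.r0 - pc.r0.mean(0)
    rfc = pc.rf - pc.rf.mean(0)
    C00 = r0c.T @ r0c
    if np.linalg.matrix_rank(C00, tol=1e-10 * max(1.0, float(np.abs(C00).max()))) < 2:
        raise ValueError("collinear pre-ablation points: affine fit is rank-deficient")
    M = (rfc.T @ r0c) @ np.linalg.inv(C00)
    b = pc.rf.mean(0) - M @ pc.r0.mean(0)
    res = pc.rf - (pc.r0 @ M.T + b)
    rms = float(np.sqrt((res**2).sum(1).mean()))
    return AffineTransform(M=M, b=b, rms_residual=rms)


def residual_fraction(
    pc: PointCorrespondence, t: AffineTransform, neighbor_dist: float
) -> float:
    """RMS residual of the affine fit over the typical neighbour distance."""
    if neighbor_dist <= 0:
        raise ValueError("neighbor_dist must be > 0")
    res = pc.rf - t.apply(pc.r0)
    return float(np.sqrt((res**2).sum(1).mean())) / neighbor_dist


def typical_neighbor_distance(points: np.ndarray) -> float:
    """Median nearest-neighbour distance of a point set, micrometres."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(1)))


def polar_decompose(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar decomposition M = U P, U orthogonal and P symmetric PSD.

    P = (MᵀM)^½ via the eigendecomposition of MᵀM; U = M P⁻¹ (pseudo-
    inverse when M is singular).  For invertible M, U is the unique
    orthogonal factor; tests cross-check against the SVD construction.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2) or not np.all(np.isfinite(M)):
        raise ValueError("M must be a finite 2x2 matrix")
    w, Q = np.linalg.eigh(M.T @ M)
    w = np.clip(w, 0.0, None)
    P = Q @ np.diag(np.sqrt(w)) @ Q.T
    if np.linalg.matrix_rank(P) < 2:
        U = M @ np.linalg.pinv(P)
    else:
        U = M @ np.linalg.inv(P)
        # re-orthogonalize against round-off
        uu, _, vv = np.linalg.svd(U)
        U = uu @ vv
    return U, P


def strain_axes(
    P: np.ndarray, theta_c: ColumnDirection, isotropic_tol: float = 1e-9
) -> tuple[float, float, float, bool]:
    """Assign the eigenvalues of P to the x (across) and y (along) axes.

    The eigenvector whose orientation is circularly closer to the column
    direction θ_c carries the y-strain (along the columns); the other
    carries the x-strain.  Returns (x_strain, y_strain,
    axis_deviation_deg, axes_indeterminate); for an isotropic P the axes
    are indeterminate but the (equal) strains are still returned.
    """
    P = np.asarray(P, dtype=float)
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("P must be symmetric")
    w, V = np.linalg.eigh(P)
    if np.any(w < -1e-10):
        raise ValueError("P must be positive semi-definite")
    angles = np.degrees(np.arctan2(V[1], V[0])) % 180.0
    devs = angular_deviation_deg(angles, theta_c.theta_c_deg)
    if abs(w[1] - w[0]) <= isotropic_tol * max(1.0, abs(w[1])):
        return float(w[0]), float(w[1]), math.nan, True
    iy = int(np.argmin(devs))
    ix = 1 - iy
    return float(w[ix]), float(w[iy]), float(devs[iy]), False


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, two-sided p, Welch–Satterthwaite degrees of freedom).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def hotelling_unequal(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Hotelling T² with unpooled covariances (Yao's test).

    T² = d' S⁻¹ d with S = S₁/n₁ + S₂/n₂ and d the mean difference; the
    p-value uses Yao's moment-matched F approximation
    T² (f − p + 1)/(f p) ~ F(p, f − p + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be (n, p) arrays with matching p")
    p = a.shape[1]
    n1, n2 = len(a), len(b)
    if n1 <= p + 1 or n2 <= p + 1:
        raise ValueError(f"each group needs more than {p + 1} observations")
    d = a.mean(0) - b.mean(0)
    S1 = np.cov(a, rowvar=False) / n1
    S2 = np.cov(b, rowvar=False) / n2
    S = S1 + S2
    if np.linalg.matrix_rank(S) < p:
        raise ValueError("combined covariance is singular")
    Sinv = np.linalg.inv(S)
    t2 = float(d @ Sinv @ d)
    if t2 == 0.0:
        return 0.0, 1.0
    u1 = float(d @ Sinv @ S1 @ Sinv @ d) / t2
    u2 = float(d @ Sinv @ S2 @ Sinv @ d) / t2
    inv_f = u1**2 / (n1 - 1) + u2**2 / (n2 - 1)
    f = 1.0 / inv_f
    stat = t2 * (f - p + 1) / (f * p)
    pval = float(stats.f.sf(stat, p, f - p + 1))
    return t2, pval


def run_strain_experiment(
    experiment: AblationExperiment,
    theta_c: ColumnDirection,
    tilt_plane: TiltPlane | None = None,
) -> tuple[list[StrainResult], pd.DataFrame]:
    """Full strain pipeline for one ablation (or control) experiment.

    Per post-ablation timepoint: optional tilt correction of pre and post
    centroids, affine fit, polar decomposition, axis assignment against
    the column direction, and the residual fraction relative to the median
    nearest-neighbour distance of the pre-ablation points.  Returns the
    per-timepoint results and a tidy table; downstream statistics pool all
    timepoints of a group (see :func:`compare_strain_groups`).
    """
    r0 = experiment.points_pre
    if tilt_plane is not None:
        r0 = correct_tilt(r0, tilt_plane)
    neighbor = typical_neighbor_distance(r0)
    results: list[StrainResult] = []
    rows = []
    for t, rf in zip(experiment.times_min, experiment.points_post):
        if tilt_plane is not None:
            rf = correct_tilt(rf, tilt_plane)
        pc = PointCorrespondence(r0=r0, rf=rf, time_min=t, group=experiment.group)
        aff = fit_affine(pc)
        U, P = polar_decompose(aff.M)
        sx, sy, dev, indet = strain_axes(P, theta_c)
        w, V = np.linalg.eigh(P)
        rf_frac = residual_fraction(pc, aff, neighbor)
        res = StrainResult(
            U=U,
            P=P,
            eigenvalues=(float(w[0]), float(w[1])),
            eigenvectors=V,
            x_strain=sx,
            y_strain=sy,
            axis_deviation_deg=dev,
            residual_fraction=rf_frac,
            time_min=t,
            group=experiment.group,
            axes_indeterminate=indet,
        )
        results.append(res)
        rows.append(
            {
                "time_min": t,
                "group": experiment.group.value,
                "x_strain": sx,
                "y_strain": sy,
                "axis_deviation_deg": dev,
                "residual_fraction": rf_frac,
            }
        )
    return results, pd.DataFrame(rows)


def compare_strain_groups(
    ablation: pd.DataFrame, control: pd.DataFrame
) -> dict[str, float]:
    """Pooled ablation-vs-control statistics on strain tables.

    All post-ablation timepoints are pooled per group; Welch's test is run
    separately on x- and y-strain and Hotelling's unequal-covariance T² on
    the joint (x, y) strain vectors.
    """
    out: dict[str, float] = {}
    for axis in ("x_strain", "y_strain"):
        t, pv, df = welch_t_test(ablation[axis].to_numpy(), control[axis].to_numpy())
        out[f"{axis}_t"] = t
        out[f"{axis}_p"] = pv
        out[f"{axis}_df"] = df
    t2, pv = hotelling_unequal(
        ablation[["x_strain", "y_strain"]].to_numpy(),
        control[["x_strain", "y_strain"]].to_numpy(),
    )
    out["hotelling_T2"] = t2
    out["hotelling_p"] = pv
    return out
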