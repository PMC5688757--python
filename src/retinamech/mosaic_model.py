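"""Ideal adult zebrafish cone-mosaic lattices.

The adult zebrafish retina packs its cone photoreceptors into a crystalline
lattice: single-cell-width *columns* run parallel to the growing retinal
margin, and within every column successive Red cones are separated,
alternately, by a single Blue cone or by a Green-UV-Green triplet.  Adjacent
columns are phase-shifted by half a repeat unit, which makes rows of
alternating UV and Blue cones emerge perpendicular to the columns, and makes
the Red cones trace hexagonal rings with a single (large) UV cone at the
centre of each ring.  Rod photoreceptors, when present, sit at the four
corners of each UV cone, in the inter-column space.

This module builds ideal (optionally jittered) instances of that lattice,
validates the neighbour rules on arbitrary site collections, and derives the
Red : non-Red apical-profile ratio implied by the lattice — 1:2 for a pure
cone lattice and 1:4 once the four rods per UV cone are added.

Coordinates are continuous 2D positions in micrometres; angles are measured
in degrees counterclockwise from the +x axis and columns are treated as
undirected (angles mod 180).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConeSubtype",
    "MosaicLattice",
    "LatticeValidationReport",
    "COLUMN_MOTIF",
    "generate_mosaic_lattice",
    "validate_lattice",
    "expected_profile_ratio",
]


class ConeSubtype(enum.Enum):
    """Photoreceptor classes distinguishable at the OLM (rods included)."""

    RED = "RED"
    GREEN = "GREEN"
    BLUE = "BLUE"
    UV = "UV"
    ROD = "ROD"


#: Subtype sequence of one repeat unit along a column.  Successive REDs are
#: separated alternately by one BLUE and by the GREEN,UV,GREEN triplet.
COLUMN_MOTIF: tuple[ConeSubtype, ...] = (
    ConeSubtype.RED,
    ConeSubtype.BLUE,
    ConeSubtype.RED,
    ConeSubtype.GREEN,
    ConeSubtype.UV,
    ConeSubtype.GREEN,
)

#: Inter-column spacing as a multiple of the intra-column site spacing.
#: sqrt(3) is the unique value for which the six Red cones ringing each UV
#: cone are equidistant from it (a regular hexagon of circumradius
#: 2*spacing), so the ideal lattice satisfies its own hexagonality rule.
DEFAULT_COLUMN_SPACING_FACTOR: float = math.sqrt(3.0)

#: Sites per repeat unit: 6 cones, plus 4 rods when rods are enabled.
CONES_PER_UNIT = len(COLUMN_MOTIF)
RODS_PER_UNIT = 4


@dataclass
class MosaicLattice:
    """A collection of photoreceptor sites with lattice metadata.

    positions        (n, 2) float array, micrometres
    subtypes         (n,) array of :class:`ConeSubtype`
    column_index     (n,) int array — which column a site belongs to
    row_index        (n,) int array — site index along the column (rods
                     inherit the row index of their UV cone)
    """

    positions: np.ndarray
    subtypes: np.ndarray
    column_index: np.ndarray
    row_index: np.ndarray
    column_direction_deg: float
    spacing: float
    n_repeat_units: int
    n_columns: int = 1
    column_spacing_factor: float = DEFAULT_COLUMN_SPACING_FACTOR
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.subtypes = np.asarray(self.subtypes, dtype=object)
        self.column_index = np.asarray(self.column_index, dtype=int)
        self.row_index = np.asarray(self.row_index, dtype=int)
        self.column_direction_deg = float(self.column_direction_deg) % 180.0

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def column_axis(self) -> np.ndarray:
        """Unit vector along the columns."""
        th = math.radians(self.column_direction_deg)
        return np.array([math.cos(th), math.sin(th)])

    @property
    def row_axis(self) -> np.ndarray:
        """Unit vector perpendicular to the columns (along the rows)."""
        th = math.radians(self.column_direction_deg)
        return np.array([-math.sin(th), math.cos(th)])

    @property
    def column_separation(self) -> float:
        """Distance between adjacent column lines, micrometres."""
        return self.spacing * self.column_spacing_factor

    def mask(self, subtype: ConeSubtype) -> np.ndarray:
        return np.array([s is subtype for s in self.subtypes], dtype=bool)

    def positions_of(self, subtype: ConeSubtype) -> np.ndarray:
        return self.positions[self.mask(subtype)]

    @property
    def cone_mask(self) -> np.ndarray:
        return ~self.mask(ConeSubtype.ROD)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "subtype": [s.value for s in self.subtypes],
                "column_index": self.column_index,
                "row_index": self.row_index,
            }
        )


def generate_mosaic_lattice(
    n_columns: int = 3,
    n_repeat_units: int = 4,
    spacing: float = 5.0,
    include_rods: bool = False,
    column_direction_deg: float = 90.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    column_spacing_factor: float = DEFAULT_COLUMN_SPACING_FACTOR,
) -> MosaicLattice:
    """Construct an ideal (optionally jittered) cone-mosaic lattice.

    Each column repeats the six-cone motif ``R,B,R,G,U,G`` with ``spacing``
    micrometres between successive sites.  Adjacent columns are offset along
    the column axis by half a repeat unit (3 sites), which aligns UV cones
    with the Blue cones of neighbouring columns into rows.  With
    ``include_rods`` four rods are placed at the corners of every UV cone,
    at the diagonal midpoints toward the four off-column Red neighbours.

    Positional jitter (``jitter_sd`` > 0) displaces positions but never
    relabels sites; generation is deterministic for a fixed ``seed``.
    """
    if n_columns < 1 or n_repeat_units < 1:
        raise ValueError(
            f"lattice size must be positive, got n_columns={n_columns}, "
            f"n_repeat_units={n_repeat_units}"
        )
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be >= 0, got {jitter_sd}")

    th = math.radians(column_direction_deg)
    u = np.array([math.cos(th), math.sin(th)])  # along columns
    v = np.array([-math.sin(th), math.cos(th)])  # across columns
    d = spacing * column_spacing_factor

    positions: list[np.ndarray] = []
    subtypes: list[ConeSubtype] = []
    col_idx: list[int] = []
    row_idx: list[int] = []
    half_unit = (CONES_PER_UNIT // 2) * spacing
    for c in range(n_columns):
        phase = (c % 2) * half_unit
        for j in range(CONES_PER_UNIT * n_repeat_units):
            pos = (j * spacing + phase) * u + (c * d) * v
            sub = COLUMN_MOTIF[j % CONES_PER_UNIT]
            positions.append(pos)
            subtypes.append(sub)
            col_idx.append(c)
            row_idx.append(j)
            if include_rods and sub is ConeSubtype.UV:
                for su in (-0.5, 0.5):
                    for sv in (-0.5, 0.5):
                        positions.append(pos + su * spacing * u + sv * d * v)
                        subtypes.append(ConeSubtype.ROD)
                        col_idx.append(c)
                        row_idx.append(j)

    pos_arr = np.array(positions, dtype=float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pos_arr = pos_arr + rng.normal(0.0, jitter_sd, pos_arr.shape)

    return MosaicLattice(
        positions=pos_arr,
        subtypes=np.array(subtypes, dtype=object),
        column_index=np.array(col_idx),
        row_index=np.array(row_idx),
        column_direction_deg=column_direction_deg,
        spacing=spacing,
        n_repeat_units=n_repeat_units,
        n_columns=n_columns,
        column_spacing_factor=column_spacing_factor,
        jitter_sd=jitter_sd,
        seed=seed,
    )


@dataclass
class LatticeValidationReport:
    """Outcome of :func:`validate_lattice`."""

    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def _column_sequence_violations(lattice: MosaicLattice) -> list[str]:
    """Check the alternating RED separator rule within every column."""
    out: list[str] = []
    u = lattice.column_axis
    cones = lattice.cone_mask
    for c in np.unique(lattice.column_index):
        sel = np.flatnonzero((lattice.column_index == c) & cones)
        if len(sel) == 0:
            continue
        order = np.argsort(lattice.positions[sel] @ u, kind="stable")
        sel = sel[order]
        subs = [lattice.subtypes[i] for i in sel]
        red_pos = [k for k, s in enumerate(subs) if s is ConeSubtype.RED]
        if len(red_pos) < 2:
            continue
        for a, b in zip(red_pos[:-1], red_pos[1:]):
            between = subs[a + 1 : b]
            ok = between == [ConeSubtype.BLUE] or between == [
                ConeSubtype.GREEN,
                ConeSubtype.UV,
                ConeSubtype.GREEN,
            ]
            if not ok:
                out.append(
                    "column-rule violation in column "
                    f"{c}: sites {sel[a]}..{sel[b]} separated by "
                    f"{[s.value for s in between]} (expected [BLUE] or "
                    "[GREEN, UV, GREEN])"
                )
        # separators must alternate between the two legal forms
        gaps = [red_pos[k + 1] - red_pos[k] for k in range(len(red_pos) - 1)]
        for k in range(len(gaps) - 1):
            if gaps[k] == gaps[k + 1]:
                out.append(
                    f"column-rule violation in column {c}: separators do not "
                    f"alternate around site {sel[red_pos[k + 1]]}"
                )
    return out


def _rod_corner_violations(lattice: MosaicLattice, tol: float) -> list[str]:
    out: list[str] = []
    rod_pos = lattice.positions_of(ConeSubtype.ROD)
    if len(rod_pos) == 0:
        return out
    uv_idx = np.flatnonzero(lattice.mask(ConeSubtype.UV))
    if len(uv_idx) == 0:
        out.append("rod-rule violation: rods present but no UV sites")
        return out
    uv_pos = lattice.positions[uv_idx]
    expected = 0.5 * lattice.spacing * math.hypot(1.0, lattice.column_spacing_factor)
    # assign each rod to its nearest UV cone
    d2 = ((rod_pos[:, None, :] - uv_pos[None, :, :]) ** 2).sum(-1)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(rod_pos)), nearest])
    counts = np.bincount(nearest, minlength=len(uv_idx))
    for k, n in enumerate(counts):
        if n != RODS_PER_UNIT:
            out.append(
                f"rod-rule violation: UV site {uv_idx[k]} has {n} associated "
                f"rods (expected {RODS_PER_UNIT})"
            )
    bad = np.flatnonzero(np.abs(dist - expected) > tol)
    for b in bad[:10]:
        out.append(
            "rod-rule violation: rod at corner distance "
            f"{dist[b]:.3g} um from UV (expected {expected:.3g} um)"
        )
    return out


def _hexagonality_violations(lattice: MosaicLattice, tol: float) -> list[str]:
    """Red cones must ring each interior UV cone as a hexagon.

    REDs form a honeycomb: every interior UV cone has 6 equidistant RED
    neighbours and every interior RED has 3 equidistant RED neighbours.
    """
    out: list[str] = []
    red_pos = lattice.positions_of(ConeSubtype.RED)
    uv_idx = np.flatnonzero(lattice.mask(ConeSubtype.UV))
    if len(red_pos) < 7 or len(uv_idx) == 0:
        return out
    # interior = all honeycomb neighbours exist; the half-unit phase shift
    # leaves ragged column ends, so the along-column margin must cover it
    u, v = lattice.column_axis, lattice.row_axis
    pu = lattice.positions @ u
    pv = lattice.positions @ v
    m_u = (CONES_PER_UNIT / 2 + 2.2) * lattice.spacing
    m_v = 0.9 * lattice.column_separation

    def interior(p: np.ndarray) -> bool:
        return bool(
            pu.min() + m_u < p @ u < pu.max() - m_u
            and pv.min() + m_v < p @ v < pv.max() - m_v
        )

    for i in uv_idx:
        p = lattice.positions[i]
        if not interior(p):
            continue
        d = np.sort(np.linalg.norm(red_pos - p, axis=1))[:6]
        if d[-1] - d[0] > tol:
            out.append(
                f"hexagonality violation: UV site {i} RED ring distances "
                f"span [{d[0]:.3g}, {d[-1]:.3g}] um (tolerance {tol:.3g})"
            )
    red_idx = np.flatnonzero(lattice.mask(ConeSubtype.RED))
    for i in red_idx:
        p = lattice.positions[i]
        if not interior(p):
            continue
        d = np.linalg.norm(red_pos - p, axis=1)
        d = np.sort(d[d > 1e-12])[:3]
        if len(d) == 3 and d[-1] - d[0] > tol:
            out.append(
                f"hexagonality violation: RED site {i} nearest-RED distances "
                f"span [{d[0]:.3g}, {d[-1]:.3g}] um (tolerance {tol:.3g})"
            )
    return out


def validate_lattice(lattice: MosaicLattice, tol: float = 1e-6) -> LatticeValidationReport:
    """Check a lattice against the mosaic neighbour rules.

    Verifies, within a positional tolerance ``tol`` (micrometres):

    * the alternating one-Blue / Green-UV-Green separator rule between
      successive Red cones in every column;
    * four rods at the corners of every UV cone (when rods are present);
    * hexagonality of the Red-cone arrangement (Red rings around interior
      UV cones, equidistant honeycomb neighbours of interior Reds).

    Returns a report whose ``violations`` name each broken rule and the
    offending site indices.
    """
    if lattice.n_sites == 0:
        raise ValueError("cannot validate an empty lattice")
    violations = (
        _column_sequence_violations(lattice)
        + _rod_corner_violations(lattice, tol)
        + _hexagonality_violations(lattice, tol)
    )
    return LatticeValidationReport(passed=not violations, violations=violations)


def expected_profile_ratio(include_rods: bool) -> tuple[float, float]:
    """Predicted ratio of Red to non-Red apical profiles, as ``(1, x)``.

    Counted from one repeat unit of a generated ideal lattice, never
    hard-coded: the six-cone motif holds 2 Red and 4 non-Red cones (1:2);
    adding the 4 rods of the unit's UV cone makes it 1:4.
    """
    unit = generate_mosaic_lattice(
        n_columns=1, n_repeat_units=1, include_rods=include_rods, jitter_sd=0.0
    )
    n_red = int(unit.mask(ConeSubtype.RED).sum())
    n_non = unit.n_sites - n_red
    return (1.0, n_non / n_red)
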