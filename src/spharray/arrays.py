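"""Array layout geometry, spot-to-well assignment, and workflow arithmetic.

The agarose mold arranges up to 66 spheroids in a 6 x 11 grid embedded in a
single block, so one section carries every condition.  This module models the
grid geometry, de-arrays detected spheroid spots back to (row, column) well
identities (with marker wells for orientation), and computes the workflow
economics of arraying versus embedding each condition in a separate block:
section counts through a spheroid's equatorial band, slide counts, and the
reagent fold-saving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, InvalidParameterError, LayoutConfigError


@dataclass(frozen=True)
class ArrayLayout:
    """Grid geometry of a spheroid microarray mold.

    The default 6 x 11 layout holds 66 spheroids; the last column is reserved
    for marker wells (large or multiple spheroids) that orient the grid.
    """

    n_rows: int = 6
    n_cols: int = 11
    pitch: float = 2000.0  # um between well centres
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of well (row 0, col 0)
    marker_columns: frozenset[int] = field(default_factory=lambda: frozenset({10}))

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutConfigError("layout needs >= 1 row and column")
        if self.pitch <= 0:
            raise LayoutConfigError(f"pitch must be > 0, got {self.pitch}")
        if any(c < 0 or c >= self.n_cols for c in self.marker_columns):
            raise LayoutConfigError("marker columns outside [0, n_cols)")

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + col * self.pitch, y0 + row * self.pitch)

    def grid_centers(self) -> np.ndarray:
        """(capacity, 2) array of (x, y) well centres, row-major order."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        x0, y0 = self.origin
        return np.column_stack(
            [x0 + cols.ravel() * self.pitch, y0 + rows.ravel() * self.pitch]
        ).astype(float)


@dataclass(frozen=True)
class SpotAssignment:
    spot_index: int
    centroid: tuple[float, float]
    row: int | None          # None = unassigned
    col: int | None
    residual: float          # um; distance to the assigned node


@dataclass(frozen=True)
class WorkflowPlan:
    n_conditions: int
    replicates_per_condition: int
    slides_per_sample: int
    samples_separate: int    # blocks when each condition is its own sample
    blocks_separate: int
    blocks_array: int
    slides_separate: int
    fold_saving: float


def estimate_origin(
    marker_centroids: list[tuple[float, float]],
    marker_wells: list[tuple[int, int]],
    layout: ArrayLayout,
) -> tuple[float, float]:
    """Least-squares translation fitting known marker wells to their centroids.

    Needs >= 3 correspondences; returns the origin that maps the layout grid
    onto the detections (pitch and axes are taken from the layout).
    """
    if len(marker_centroids) != len(marker_wells):
        raise InvalidParameterError("centroids and wells must correspond 1:1")
    if len(marker_centroids) < 3:
        raise InvalidParameterError(">= 3 marker detections required")
    cents = np.asarray(marker_centroids, dtype=float)
    ideal = np.array(
        [[c * layout.pitch, r * layout.pitch] for r, c in marker_wells], dtype=float
    )
    offset = (cents - ideal).mean(axis=0)
    return (float(offset[0]), float(offset[1]))


def assign_spots(
    centroids: list[tuple[float, float]],
    layout: ArrayLayout,
    tolerance: float | None = None,
    strict: bool = True,
) -> list[SpotAssignment]:
    """Map detected spot centroids to their nearest grid wells.

    Each centroid goes to the nearest well centre; centroids farther than
    ``tolerance`` (default pitch/4, must be < pitch/2) stay unassigned.  In
    strict mode a well takes at most one spot: conflicts are resolved by the
    smaller residual and the loser is unassigned.  Non-strict mode (for marker
    wells that legitimately hold several spheroids) allows sharing.
    """
    if tolerance is None:
        tolerance = layout.pitch / 4
    if not 0 < tolerance < layout.pitch / 2:
        raise InvalidParameterError(
            f"tolerance must be in (0, pitch/2), got {tolerance}"
        )
    nodes = layout.grid_centers()
    out: list[SpotAssignment] = []
    claimed: dict[int, int] = {}  # node index -> index into out
    for i, (x, y) in enumerate(centroids):
        d = np.hypot(nodes[:, 0] - x, nodes[:, 1] - y)
        k = int(np.argmin(d))
        res = float(d[k])
        if res > tolerance:
            out.append(SpotAssignment(i, (x, y), None, None, res))
            continue
        row, col = divmod(k, layout.n_cols)
        if strict and k in claimed and col not in layout.marker_columns:
            prev = out[claimed[k]]
            if res < prev.residual:  # new spot wins; evict the previous one
                out[claimed[k]] = SpotAssignment(
                    prev.spot_index, prev.centroid, None, None, prev.residual
                )
                claimed[k] = len(out)
                out.append(SpotAssignment(i, (x, y), row, col, res))
            else:
                out.append(SpotAssignment(i, (x, y), None, None, res))
            continue
        claimed.setdefault(k, len(out))
        out.append(SpotAssignment(i, (x, y), row, col, res))
    return out


def sections_in_center_band(
    diameter: float, band_fraction: float, thickness: float
) -> int:
    """Sections of given thickness within a central band of a spherical spheroid.

    The band extends ``band_fraction`` of the diameter above and below the
    equatorial midline, so it spans ``2 * band_fraction * diameter`` and holds
    ``floor(2 * band_fraction * diameter / thickness)`` contiguous sections.
    E.g. a 500 um spheroid cut at 4 um within 20% of centre yields 50.
    """
    if thickness <= 0:
        raise InvalidParameterError(f"thickness must be > 0, got {thickness}")
    if diameter <= 0:
        raise InvalidParameterError(f"diameter must be > 0, got {diameter}")
    if not 0 <= band_fraction <= 0.5:
        raise InvalidParameterError(
            f"band_fraction must be in [0, 0.5], got {band_fraction}"
        )
    return int(math.floor(2.0 * band_fraction * diameter / thickness))


def plan_workflow(
    n_conditions: int,
    replicates_per_condition: int,
    slides_per_sample: int = 3,
    layout: ArrayLayout | None = None,
) -> WorkflowPlan:
    """Workflow economics: one array block versus one block per condition.

    With separate embedding every condition is its own sample/block, so a
    screen needs ``n_conditions`` blocks and
    ``n_conditions * slides_per_sample`` slides per protein; arraying fits all
    ``n_conditions * replicates_per_condition`` spheroids in a single block,
    an ``n_conditions``-fold saving in reagents and consumables.
    """
    if layout is None:
        layout = ArrayLayout()
    if n_conditions < 1 or replicates_per_condition < 1:
        raise InvalidParameterError("conditions and replicates must be >= 1")
    n_spots = n_conditions * replicates_per_condition
    if n_spots > layout.capacity:
        raise CapacityError(
            f"{n_spots} spheroids exceed the array capacity of {layout.capacity} "
            f"({layout.n_rows} x {layout.n_cols})"
        )
    return WorkflowPlan(
        n_conditions=n_conditions,
        replicates_per_condition=replicates_per_condition,
        slides_per_sample=slides_per_sample,
        samples_separate=n_conditions,
        blocks_separate=n_conditions,
        blocks_array=1,
        slides_separate=n_conditions * slides_per_sample,
        fold_saving=float(n_conditions),
    )
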