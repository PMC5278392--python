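"""Embedding-depth uniformity analysis of bead-loaded agarose molds.

Whether spheroids loaded into an agarose array settle to a common plane is
validated by embedding opaque beads, cross-sectioning each mold row, and
imaging the cut face.  Each bead's *lower edge* (deepest raster row of its
bounding box, in calibrated um) measures how deep it sits; the per-row
common plane is the median lower edge and every bead's deviation from that
plane is pooled into a histogram (50 um bins) summarised by its interquartile
range and 10th/90th percentiles.

Conventions: 0-based row-major rasters, y increasing downward, half-open
bounding boxes, so lower_edge_y = (box top + box height) * pixel_size.
Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import InvalidParameterError, NoDataError
from .quant import despeckle, morpho_clean, threshold_channel

DEFAULT_MIN_BEAD_AREA_UM2 = 10_000.0
DEFAULT_BIN_WIDTH_UM = 50.0


@dataclass(frozen=True)
class BeadDetection:
    """One detected bead particle on a row cross-section."""

    row_id: int
    area: float           # um^2
    lower_edge_y: float   # um; bounding-box top + height, scaled


@dataclass(frozen=True)
class DepthSummary:
    """Pooled deviations of bead lower edges from their per-row median plane."""

    deviations: np.ndarray          # um, signed; negative = above the plane
    iqr: tuple[float, float]        # 25th, 75th percentile (um)
    p10_p90: tuple[float, float]    # 10th, 90th percentile (um)
    bin_edges: np.ndarray           # um, 50 um pitch, a bin centred on 0
    counts: np.ndarray = field(repr=False)

    @property
    def n_beads(self) -> int:
        return int(self.deviations.size)


def detect_beads(
    img: np.ndarray,
    pixel_size: float,
    min_area: float = DEFAULT_MIN_BEAD_AREA_UM2,
    row_id: int = 0,
) -> list[BeadDetection]:
    """Detect dark bead particles on a light background.

    Isodata ('Default') threshold, despeckle, opening with a 2 px disk, then
    connected components with area >= ``min_area`` (um^2) are kept.  The lower
    edge is the half-open bounding-box bottom row times ``pixel_size``.

    Returns an empty list (with a warning) when nothing survives the filter.
    """
    if pixel_size <= 0:
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if np.ptp(arr) == 0:
        warnings.warn("empty image: no beads detected", stacklevel=2)
        return []
    # beads are dark: threshold the negated image so the mask covers beads
    mask, _ = threshold_channel(-arr, method="isodata")
    mask = morpho_clean(despeckle(mask), radius=2)
    out: list[BeadDetection] = []
    for region in measure.regionprops(measure.label(mask)):
        area_um2 = region.area * pixel_size**2
        if area_um2 < min_area:
            continue
        max_row = region.bbox[2]  # half-open: top + height
        out.append(
            BeadDetection(row_id=row_id, area=float(area_um2),
                          lower_edge_y=float(max_row * pixel_size))
        )
    if not out:
        warnings.warn("no beads passed the area filter", stacklevel=2)
    return out


def deviations_from_median_plane(
    detections: list[BeadDetection],
    bin_width: float = DEFAULT_BIN_WIDTH_UM,
) -> DepthSummary:
    """Deviation of each bead's lower edge from its row's median plane.

    Per row, plane = median(lower_edge_y) and deviation = lower_edge_y - plane;
    deviations are pooled across rows.  The histogram uses ``bin_width`` um
    bins with one bin centred on zero; the IQR and 10th/90th percentiles use
    linear interpolation.
    """
    if not detections:
        raise NoDataError("no bead detections")
    if bin_width <= 0:
        raise InvalidParameterError(f"bin_width must be > 0, got {bin_width}")
    rows: dict[int, list[float]] = {}
    for det in detections:
        rows.setdefault(det.row_id, []).append(det.lower_edge_y)
    deviations = np.concatenate(
        [np.asarray(ys) - np.median(ys) for ys in rows.values()]
    )
    q25, q75 = np.percentile(deviations, [25, 75])
    p10, p90 = np.percentile(deviations, [10, 90])
    edges = _centered_edges(deviations, bin_width)
    counts, _ = np.histogram(deviations, bins=edges)
    return DepthSummary(
        deviations=deviations,
        iqr=(float(q25), float(q75)),
        p10_p90=(float(p10), float(p90)),
        bin_edges=edges,
        counts=counts,
    )


def _centered_edges(values: np.ndarray, width: float) -> np.ndarray:
    """Bin edges at ``width`` pitch with a bin centred on zero, covering values."""
    half = width / 2
    lo = np.floor((values.min() + half) / width) * width - half
    hi = np.ceil((values.max() - half) / width) * width + half
    n = max(int(round((hi - lo) / width)), 1)
    return lo + width * np.arange(n + 1)
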