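"""Percent-positive IHC quantification on H-DAB stained spheroid sections.

Two quantification conventions, mirroring standard immunohistochemistry
practice on spheroid/tissue microarrays:

* **Cytoplasmic stains** (e.g. GFAP, beta-III-tubulin): percent positive =
  100 * area(DAB-positive and tissue) / area(hematoxylin-positive tissue).
* **Nuclear stains** (e.g. Ki-67, SOX-2): nuclei are segmented in the
  hematoxylin and DAB channels (despeckle, median, min/max filters, watershed
  on the distance transform, minimum nuclear size) and percent positive =
  100 * n(DAB nuclei) / n(total nuclei).

Also provides flat-field background-illumination correction, content cropping
of image stacks, and quality-control overlays (green tissue outline, magenta
positive outline).

All masks are boolean rasters the same shape as the source image;
coordinates are 0-based row-major with y increasing downward and rectangles
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation

from .errors import (
    CalibrationError,
    DegenerateBlankError,
    DegenerateThresholdError,
    DimensionError,
    InvalidParameterError,
    NoNucleiError,
    NoTissueError,
)
from .stains import StainSystem, build_stain_system, deconvolve, rgb_to_od

DEFAULT_MIN_NUCLEAR_AREA_UM2 = 20.0
#: OD floor for automatic DAB thresholds: an automatic threshold below this is
#: considered a fit to noise (no true positive mode present) and is raised to
#: the floor, emulating the negative-control calibration a user would apply.
DEFAULT_DAB_OD_FLOOR = 0.1


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropRect:
    """Half-open crop rectangle [top, bottom) x [left, right).

    ``degenerate`` flags the no-foreground case where the full frame is
    returned with a warning.
    """

    top: int
    bottom: int
    left: int
    right: int
    degenerate: bool = False

    def apply(self, img: np.ndarray) -> np.ndarray:
        return img[self.top : self.bottom, self.left : self.right]


@dataclass(frozen=True)
class NucleiLabels:
    """Labelled nuclei: 0 = background, k = nucleus k, after the size filter."""

    labels: np.ndarray
    count: int
    min_area: float  # um^2 actually applied


@dataclass(frozen=True)
class CytoplasmicResult:
    tissue_area_px: int
    dab_area_px: int
    percent_positive: float
    h_threshold: float
    dab_threshold: float
    pixel_size: float | None = None

    @property
    def tissue_area_um2(self) -> float | None:
        return None if self.pixel_size is None else self.tissue_area_px * self.pixel_size**2

    @property
    def dab_area_um2(self) -> float | None:
        return None if self.pixel_size is None else self.dab_area_px * self.pixel_size**2


@dataclass(frozen=True)
class NuclearResult:
    n_nuclei_h: int
    n_nuclei_dab: int
    percent_positive: float
    h_threshold: float | None = None
    dab_threshold: float | None = None


# ---------------------------------------------------------------------------
# illumination correction and cropping
# ---------------------------------------------------------------------------

def correct_background(
    img: np.ndarray,
    blank_field: np.ndarray | None = None,
    smooth_sigma: float | None = None,
) -> np.ndarray:
    """Flat-field correction of uneven brightfield illumination.

    Each channel is divided pixel-wise by a smooth gain field and rescaled so
    the gain field maps to its own channel-wise median (the scene's grey level
    is preserved).  The gain field is the Gaussian-smoothed ``blank_field``
    when one is supplied, otherwise it is estimated from the image itself by a
    large-radius Gaussian blur (default sigma = min(H, W) / 8).

    Raises
    ------
    DegenerateBlankError
        If the smoothed blank field contains non-positive values.
    """
    img = np.asarray(img, dtype=float)
    if blank_field is not None:
        blank = np.asarray(blank_field, dtype=float)
        if blank.shape != img.shape:
            raise DimensionError(
                f"blank field shape {blank.shape} != image shape {img.shape}"
            )
        sigma = 2.0 if smooth_sigma is None else smooth_sigma
        gain = _smooth_channels(blank, sigma)
        if np.any(gain <= 0):
            raise DegenerateBlankError("blank field contains zeros after smoothing")
    else:
        sigma = min(img.shape[0], img.shape[1]) / 8 if smooth_sigma is None else smooth_sigma
        gain = _smooth_channels(img, sigma)
        if np.any(gain <= 0):
            raise DegenerateBlankError("estimated gain field vanishes somewhere")
    axes = (0, 1)
    med = np.median(gain, axis=axes, keepdims=True)
    out = img / gain * med
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _smooth_channels(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return img.astype(float)
    if img.ndim == 3:
        return np.stack(
            [ndi.gaussian_filter(img[..., c].astype(float), sigma) for c in range(img.shape[-1])],
            axis=-1,
        )
    return ndi.gaussian_filter(img.astype(float), sigma)


def crop_to_content(images: list[np.ndarray]) -> CropRect:
    """Smallest rectangle containing all non-background content of a stack.

    A minimum projection across images (and channels) keeps any pixel that is
    dark in *any* image; pixels below an isodata threshold on the projection
    are foreground.  If nothing is darker than background, the full frame is
    returned with ``degenerate=True``.
    """
    if not images:
        raise InvalidParameterError("need at least one image")
    shapes = {im.shape[:2] for im in images}
    if len(shapes) > 1:
        raise DimensionError(f"images differ in shape: {shapes}")
    mins = np.min(
        [np.min(np.asarray(im, dtype=float), axis=-1) if im.ndim == 3 else np.asarray(im, dtype=float)
         for im in images],
        axis=0,
    )
    h, w = mins.shape
    if np.ptp(mins) == 0:
        return CropRect(0, h, 0, w, degenerate=True)
    thr = filters.threshold_isodata(mins)
    fg = mins < thr
    if not fg.any():
        return CropRect(0, h, 0, w, degenerate=True)
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    return CropRect(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def despeckle(raster: np.ndarray) -> np.ndarray:
    """3x3 median filter (ImageJ 'Despeckle'); removes isolated pixels."""
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise DimensionError("despeckle expects a 2-D raster")
    if arr.dtype == bool:
        return ndi.median_filter(arr.astype(np.uint8), size=3).astype(bool)
    return ndi.median_filter(arr, size=3)


def median_filter(raster: np.ndarray, radius: int = 2) -> np.ndarray:
    """Median filter with a disk footprint of the given pixel radius."""
    arr = np.asarray(raster)
    foot = morphology.disk(radius)
    if arr.dtype == bool:
        return ndi.median_filter(arr.astype(np.uint8), footprint=foot).astype(bool)
    return ndi.median_filter(arr, footprint=foot)


def morpho_clean(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological opening (minimum then maximum filter) with a disk.

    Removes specks thinner than ~2*radius while leaving large objects intact
    up to corner rounding; never increases foreground area.
    """
    if radius < 1:
        raise InvalidParameterError(f"radius must be >= 1, got {radius}")
    mask = np.asarray(mask)
    foot = morphology.disk(radius)
    if mask.dtype == bool:
        return morphology.opening(mask.astype(np.uint8), footprint=foot).astype(bool)
    return morphology.opening(mask, footprint=foot)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold_channel(
    density_map: np.ndarray,
    method: str = "isodata",
    value: float | None = None,
) -> tuple[np.ndarray, float]:
    """Threshold one stain-density plane; returns ``(mask, threshold_used)``.

    ``mask = map >= threshold``.  Methods: ``isodata`` (iterative intermeans,
    the 'Default' auto-threshold of common IHC tooling), ``otsu``, or
    ``fixed`` (requires ``value``).  The threshold actually applied is always
    returned so it can be logged with the results.

    Raises
    ------
    DegenerateThresholdError
        Automatic method on a constant-valued map (use ``fixed``).
    """
    arr = np.asarray(density_map, dtype=float)
    if method == "fixed":
        if value is None:
            raise InvalidParameterError("fixed threshold requires a value")
        thr = float(value)
    elif method in ("isodata", "otsu"):
        if np.ptp(arr) == 0:
            raise DegenerateThresholdError(
                "constant-valued map: automatic thresholding is undefined; "
                "use method='fixed'"
            )
        fn = filters.threshold_isodata if method == "isodata" else filters.threshold_otsu
        thr = float(fn(arr))
    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")
    return arr >= thr, thr


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify_cytoplasmic(
    tissue_mask: np.ndarray,
    dab_mask: np.ndarray,
    h_threshold: float = float("nan"),
    dab_threshold: float = float("nan"),
    pixel_size: float | None = None,
) -> CytoplasmicResult:
    """Percent positive area: 100 * area(DAB and tissue) / area(tissue).

    The DAB mask is intersected with the tissue mask (DAB outside tissue is
    artefact), so the ratio is always within [0, 100].
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    dab_mask = np.asarray(dab_mask, dtype=bool)
    if tissue_mask.shape != dab_mask.shape:
        raise DimensionError("tissue and DAB masks differ in shape")
    tissue_area = int(tissue_mask.sum())
    if tissue_area == 0:
        raise NoTissueError("empty tissue mask: percent positive is undefined")
    dab_area = int((dab_mask & tissue_mask).sum())
    return CytoplasmicResult(
        tissue_area_px=tissue_area,
        dab_area_px=dab_area,
        percent_positive=100.0 * dab_area / tissue_area,
        h_threshold=h_threshold,
        dab_threshold=dab_threshold,
        pixel_size=pixel_size,
    )


def segment_nuclei(
    mask: np.ndarray,
    min_area: float = DEFAULT_MIN_NUCLEAR_AREA_UM2,
    pixel_size: float | None = None,
    *,
    min_area_px: float | None = None,
    h_maxima: float = 1.0,
) -> NucleiLabels:
    """Segment nuclei in a binary stain mask.

    Pipeline: despeckle -> median (disk radius 2) -> opening (radius 2) ->
    watershed on the negated Euclidean distance transform with h-maxima
    suppression (splits touching nuclei) -> connected components -> discard
    components smaller than the minimum nuclear area.

    ``min_area`` is in um^2 and requires ``pixel_size`` (um/px); pass
    ``min_area_px`` instead to work in pixel units.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise DimensionError("nuclei mask must be 2-D")
    if min_area_px is None:
        if pixel_size is None:
            raise CalibrationError(
                "min_area is in um^2: a pixel_size (um/px) is required "
                "(or pass min_area_px)"
            )
        min_area_px = min_area / pixel_size**2
        min_area_used = min_area
    else:
        min_area_used = min_area_px * (pixel_size**2 if pixel_size else 1.0)

    clean = morpho_clean(median_filter(despeckle(mask), radius=2), radius=2)
    labels = _watershed_split(clean, h=h_maxima)

    # size filter
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    small = small[small != 0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels, count = _relabel(labels)
    return NucleiLabels(labels=labels, count=count, min_area=float(min_area_used))


def _watershed_split(mask: np.ndarray, h: float = 1.0) -> np.ndarray:
    """Split touching objects by watershed on the negated distance transform."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    # h-maxima suppression prevents over-segmentation from raster ripple
    maxima = morphology.h_maxima(dist, h)
    markers, _ = ndi.label(maxima)
    if markers.max() == 0:  # pathological: fall back to plain labelling
        labelled, _ = ndi.label(mask)
        return labelled.astype(np.int32)
    return segmentation.watershed(-dist, markers, mask=mask).astype(np.int32)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    ids = np.unique(labels)
    ids = ids[ids != 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out, int(ids.size)


def quantify_nuclear(
    h_mask: np.ndarray,
    dab_mask: np.ndarray,
    min_area: float = DEFAULT_MIN_NUCLEAR_AREA_UM2,
    pixel_size: float | None = None,
    *,
    min_area_px: float | None = None,
    mode: str = "union",
    h_threshold: float | None = None,
    dab_threshold: float | None = None,
) -> NuclearResult:
    """Percent positive nuclei: 100 * n(DAB nuclei) / n(total nuclei).

    ``mode='union'`` (default) counts the denominator on the union mask
    H | DAB, since strong DAB deposition can displace the hematoxylin
    counterstain; the percentage is capped at 100.  ``mode='strict'``
    divides the DAB count by the H-channel count directly, uncapped.
    """
    h_mask = np.asarray(h_mask, dtype=bool)
    dab_mask = np.asarray(dab_mask, dtype=bool)
    if h_mask.shape != dab_mask.shape:
        raise DimensionError("H and DAB masks differ in shape")
    if mode not in ("union", "strict"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    kwargs = dict(min_area=min_area, pixel_size=pixel_size, min_area_px=min_area_px)
    denom_mask = (h_mask | dab_mask) if mode == "union" else h_mask
    n_total = segment_nuclei(denom_mask, **kwargs).count
    n_dab = segment_nuclei(dab_mask, **kwargs).count
    if n_total == 0:
        raise NoNucleiError("no nuclei detected in the denominator channel")
    pct = 100.0 * n_dab / n_total
    if mode == "union":
        pct = min(pct, 100.0)
    return NuclearResult(
        n_nuclei_h=n_total,
        n_nuclei_dab=n_dab,
        percent_positive=pct,
        h_threshold=h_threshold,
        dab_threshold=dab_threshold,
    )


# ---------------------------------------------------------------------------
# QC overlay
# ---------------------------------------------------------------------------

GREEN = (0, 255, 0)
MAGENTA = (255, 0, 255)


def make_qc_overlay(
    img: np.ndarray, tissue_mask: np.ndarray, positive_mask: np.ndarray
) -> np.ndarray:
    """Draw 1-px outer contours: green = tissue, magenta = positive (on top)."""
    img = np.asarray(img)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    if img.shape[:2] != tissue_mask.shape or tissue_mask.shape != positive_mask.shape:
        raise DimensionError("image and mask shapes differ")
    out = img.copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    out[_outer_contour(tissue_mask)] = GREEN
    out[_outer_contour(positive_mask)] = MAGENTA  # drawn last: positive wins
    return out


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """One-pixel ring just outside the mask (8-connected dilation minus mask)."""
    if not mask.any():
        return np.zeros_like(mask)
    dilated = ndi.binary_dilation(mask, structure=np.ones((3, 3), bool))
    return dilated & ~mask


# ---------------------------------------------------------------------------
# whole-image pipelines
# ---------------------------------------------------------------------------

def quantify_cytoplasmic_image(
    img: np.ndarray,
    system: StainSystem | None = None,
    h_threshold_mode: str = "isodata",
    dab_threshold_mode: str = "isodata",
    h_threshold_value: float | None = None,
    dab_threshold_value: float | None = None,
    dab_od_floor: float = DEFAULT_DAB_OD_FLOOR,
    background_intensity: float = 255.0,
    pixel_size: float | None = None,
    clean_masks: bool = True,
) -> tuple[CytoplasmicResult, np.ndarray, np.ndarray]:
    """Full cytoplasmic-stain pipeline on one RGB image.

    Deconvolve -> threshold the H plane (tissue) and the DAB plane (positive)
    -> despeckle both masks -> area ratio.  An automatic DAB threshold below
    ``dab_od_floor`` is raised to the floor: on a section with no true DAB the
    automatic split fits noise, and the floor plays the role of the
    negative-control calibration.  Returns ``(result, tissue_mask, dab_mask)``.
    """
    if system is None:
        system = build_stain_system()
    maps = deconvolve(rgb_to_od(img, background_intensity), system)
    tissue_mask, h_thr = threshold_channel(
        maps[..., 0], h_threshold_mode, h_threshold_value
    )
    dab_mask, dab_thr = threshold_channel(
        maps[..., 1], dab_threshold_mode, dab_threshold_value
    )
    if dab_threshold_mode != "fixed" and dab_thr < dab_od_floor:
        dab_thr = dab_od_floor
        dab_mask = maps[..., 1] >= dab_thr
    if clean_masks:
        tissue_mask = despeckle(tissue_mask)
        dab_mask = despeckle(dab_mask)
    result = quantify_cytoplasmic(
        tissue_mask, dab_mask, h_threshold=h_thr, dab_threshold=dab_thr,
        pixel_size=pixel_size,
    )
    return result, tissue_mask, dab_mask


def quantify_nuclear_image(
    img: np.ndarray,
    system: StainSystem | None = None,
    h_threshold_mode: str = "isodata",
    dab_threshold_mode: str = "isodata",
    h_threshold_value: float | None = None,
    dab_threshold_value: float | None = None,
    dab_od_floor: float = DEFAULT_DAB_OD_FLOOR,
    background_intensity: float = 255.0,
    min_area: float = DEFAULT_MIN_NUCLEAR_AREA_UM2,
    pixel_size: float | None = None,
    min_area_px: float | None = None,
    mode: str = "union",
) -> tuple[NuclearResult, np.ndarray, np.ndarray]:
    """Full nuclear-stain pipeline on one RGB image.

    Deconvolve -> threshold H and DAB planes -> watershed nuclei counting in
    each -> percent positive nuclei.  Returns ``(result, h_mask, dab_mask)``.
    """
    if system is None:
        system = build_stain_system()
    maps = deconvolve(rgb_to_od(img, background_intensity), system)
    h_mask, h_thr = threshold_channel(maps[..., 0], h_threshold_mode, h_threshold_value)
    dab_mask, dab_thr = threshold_channel(
        maps[..., 1], dab_threshold_mode, dab_threshold_value
    )
    if dab_threshold_mode != "fixed" and dab_thr < dab_od_floor:
        dab_thr = dab_od_floor
        dab_mask = maps[..., 1] >= dab_thr
    result = quantify_nuclear(
        h_mask, dab_mask, min_area=min_area, pixel_size=pixel_size,
        min_area_px=min_area_px, mode=mode,
        h_threshold=h_thr, dab_threshold=dab_thr,
    )
    return result, h_mask, dab_mask
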