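"""Beer-Lambert colour deconvolution for brightfield H-DAB histology.

Transmitted-light micrographs of sections stained with hematoxylin (blue
nuclear counterstain) and DAB (brown chromogen) mix the two dyes linearly in
optical-density (OD) space: ``od = -log10(I / I0)`` per RGB channel, and the OD
of a pixel is the sum of each stain's density times that stain's unit
absorbance vector.  Unmixing is therefore a 3x3 linear solve per pixel
(Ruifrok-Johnston colour deconvolution).  This module provides the OD
transform, the stain-system construction, the per-pixel unmixing, and the
forward synthesis model used by the synthetic-fixture generator.

Conventions
-----------
* 8-bit images, channel values in [0, 255]; incident (background) intensity
  ``I0`` defaults to 255.
* Intensities below 1 are clamped to 1 before the log so OD stays finite.
* Stain matrices are 3x3 with *rows* = unit-Euclidean-norm OD vectors in the
  order (hematoxylin, DAB, residual).
* Negative unmixed densities (from noise) are retained, never clipped; any
  masking happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, InvalidParameterError, SingularStainSystemError

# Standard H-DAB absorbance vectors (unit-normalised below).  These are the
# widely used published values for hematoxylin and DAB; overridable everywhere.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.268, 0.570, 0.776)

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class StainSystem:
    """A 3-stain unmixing system.

    Attributes
    ----------
    vectors : (3, 3) ndarray
        Rows are unit-norm OD vectors for (hematoxylin, DAB, residual).
    inverse : (3, 3) ndarray
        Satisfies ``inverse @ vectors.T == I``; per-pixel densities are
        ``od @ inverse.T``.
    """

    vectors: np.ndarray
    inverse: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise DimensionError(f"stain matrix must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise SingularStainSystemError("stain vectors must have unit norm")


def build_stain_system(h_vector=HEMATOXYLIN_OD, dab_vector=DAB_OD) -> StainSystem:
    """Build a :class:`StainSystem` from hematoxylin and DAB OD vectors.

    Rows are normalised to unit Euclidean norm; the residual (third) stain is
    the normalised cross product of the two, i.e. orthogonal to both, so the
    system is always nonsingular for non-collinear inputs.

    Raises
    ------
    SingularStainSystemError
        If either vector is zero or the two are collinear.
    """
    h = np.asarray(h_vector, dtype=float)
    d = np.asarray(dab_vector, dtype=float)
    if h.shape != (3,) or d.shape != (3,):
        raise DimensionError("stain vectors must be length-3")
    hn = np.linalg.norm(h)
    dn = np.linalg.norm(d)
    if hn == 0 or dn == 0:
        raise SingularStainSystemError("stain vectors must be nonzero")
    h = h / hn
    d = d / dn
    residual = np.cross(h, d)
    rn = np.linalg.norm(residual)
    if rn < _COLLINEAR_TOL:
        raise SingularStainSystemError("hematoxylin and DAB vectors are collinear")
    vectors = np.vstack([h, d, residual / rn])
    inverse = np.linalg.inv(vectors.T)
    if not np.allclose(inverse @ vectors.T, np.eye(3), atol=1e-9):
        raise SingularStainSystemError("stain system inversion failed")  # pragma: no cover
    return StainSystem(vectors=vectors, inverse=inverse)


def rgb_to_od(pixels: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical density.

    ``od[c] = -log10(max(I[c], 1) / background_intensity)``; intensities are
    clamped to 1 so a dead-black pixel maps to a large finite OD rather than
    infinity.

    Parameters
    ----------
    pixels : (H, W, 3) or (..., 3) array
        Channel intensities in [0, 255].
    background_intensity : float
        Incident white level I0 (default 255); must be positive.
    """
    if background_intensity <= 0:
        raise InvalidParameterError(
            f"background_intensity must be > 0, got {background_intensity}"
        )
    arr = np.asarray(pixels, dtype=float)
    return -np.log10(np.clip(arr, 1.0, None) / background_intensity)


def deconvolve(od: np.ndarray, system: StainSystem) -> np.ndarray:
    """Unmix an OD image into per-stain density maps (H, DAB, residual).

    ``maps = od @ inverse.T`` per pixel.  Values may be slightly negative from
    noise; they are retained so downstream thresholds see the raw signal.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise DimensionError(f"OD image must have 3 channels, got shape {od.shape}")
    return od @ system.inverse.T


def synthesize_rgb(
    maps: np.ndarray, system: StainSystem, background_intensity: float = 255.0
) -> np.ndarray:
    """Forward Beer-Lambert model: render stain density maps as an 8-bit RGB image.

    ``I[c] = I0 * 10**(-(maps @ vectors)[c])``, rounded to the nearest integer
    and clipped to [0, 255].  Inverse of :func:`deconvolve` up to quantisation.
    """
    if background_intensity <= 0:
        raise InvalidParameterError(
            f"background_intensity must be > 0, got {background_intensity}"
        )
    maps = np.asarray(maps, dtype=float)
    if maps.shape[-1] != 3:
        raise DimensionError(f"density maps must have 3 planes, got shape {maps.shape}")
    od = maps @ system.vectors
    intensity = background_intensity * np.power(10.0, -od)
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
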