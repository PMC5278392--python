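"""Ground-truthed synthetic inputs for every spharray pipeline.

Real stained spheroid-array sections are not redistributable, so every
pipeline here is exercised on rendered stand-ins with exact known answers:

* **H-DAB sections** — fields of disk-shaped hematoxylin-absorbing nuclei
  (optionally DAB-positive) or a tissue disk with a DAB-positive subregion of
  exact pixel fraction, rendered through the forward Beer-Lambert model, with
  an optional multiplicative gain field and additive Gaussian noise.
* **Bead-row cross-sections** — dark disks on a light background whose lower
  edges sit at specified calibrated depths, for the embedding-depth analysis.
* **Assay signals** — seeded location-scale draws with a controlled fraction
  of gross outliers, emulating per-spheroid percent-positive readouts.
* **Dose-response tables** — 4PL curves plus seeded noise on the standard
  9-point log-spaced dose grid (0.01-300 uM).

Every generator is a pure function of its spec plus seed (bit-reproducible),
and every truth record is sufficient to compute the downstream statistic
without re-detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FixtureSpecError, InvalidParameterError
from .stains import StainSystem, build_stain_system, synthesize_rgb
from .stats import AssaySignal, four_pl

#: Nine log-evenly spaced doses covering 0.01-300 uM (~half-log steps).
DEFAULT_DOSE_GRID_UM = tuple(np.logspace(np.log10(0.01), np.log10(300.0), 9))


# ---------------------------------------------------------------------------
# H-DAB section rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionSpec:
    """Recipe for one synthetic H-DAB stained section.

    Nuclear mode: every nucleus is a hematoxylin-absorbing disk; nuclei
    flagged positive absorb DAB as well.  Cytoplasmic mode (``tissue_radius``
    set): a uniform-H tissue disk with a DAB-positive subregion covering
    ``cyto_positive_fraction`` of its pixels exactly.
    """

    shape: tuple[int, int] = (256, 256)
    centers: tuple[tuple[float, float], ...] = ()    # (row, col) px
    radii: tuple[float, ...] = ()                    # px
    positive: tuple[bool, ...] = ()
    h_density: float = 0.6       # OD amplitude of hematoxylin
    dab_density: float = 0.8     # OD amplitude of DAB in positive regions
    tissue_center: tuple[float, float] | None = None
    tissue_radius: float | None = None
    cyto_positive_fraction: float | None = None
    gain_amplitude: float = 0.0  # multiplicative gain ramp, 0 = flat field
    noise_sigma: float = 0.0     # additive Gaussian noise, intensity levels
    background_intensity: float = 255.0
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (len(self.centers) == len(self.radii) == len(self.positive)):
            raise FixtureSpecError("centers, radii and positive must align")
        if self.h_density < 0 or self.dab_density < 0:
            raise FixtureSpecError("stain densities must be >= 0")
        h, w = self.shape
        for (r, c), rad in zip(self.centers, self.radii):
            if not (rad <= r <= h - 1 - rad and rad <= c <= w - 1 - rad):
                raise FixtureSpecError(f"nucleus at ({r}, {c}) leaves the frame")
        if self.cyto_positive_fraction is not None and not (
            0.0 <= self.cyto_positive_fraction <= 1.0
        ):
            raise FixtureSpecError("cyto_positive_fraction must be in [0, 1]")


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_section(
    spec: SectionSpec, system: StainSystem | None = None
) -> tuple[np.ndarray, dict]:
    """Render a spec to an 8-bit RGB image plus its ground-truth record.

    The truth record carries exact nucleus counts, positive counts, tissue and
    positive pixel areas, and the positive fraction, so downstream statistics
    can be checked without re-detection.
    """
    if system is None:
        system = build_stain_system()
    h, w = spec.shape
    if not spec.allow_touching:
        pts = np.asarray(spec.centers, dtype=float)
        rads = np.asarray(spec.radii, dtype=float)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(*(pts[i] - pts[j])) < rads[i] + rads[j] + 1:
                    raise FixtureSpecError(
                        f"nuclei {i} and {j} touch; set allow_touching=True"
                    )

    maps = np.zeros((h, w, 3), dtype=float)
    h_union = np.zeros((h, w), dtype=bool)
    pos_union = np.zeros((h, w), dtype=bool)

    if spec.tissue_radius is not None:
        tissue = _disk_mask(spec.shape, spec.tissue_center or (h / 2, w / 2),
                            spec.tissue_radius)
        h_union |= tissue
        frac = spec.cyto_positive_fraction or 0.0
        idx = np.flatnonzero(tissue.ravel())  # row-major: a top band of the disk
        n_pos = int(round(frac * idx.size))
        pos = np.zeros(h * w, dtype=bool)
        pos[idx[:n_pos]] = True
        pos_union |= pos.reshape(h, w)

    for center, radius, is_pos in zip(spec.centers, spec.radii, spec.positive):
        disk = _disk_mask(spec.shape, center, radius)
        h_union |= disk
        if is_pos:
            pos_union |= disk

    maps[..., 0][h_union] = spec.h_density
    maps[..., 1][pos_union] = spec.dab_density

    img = synthesize_rgb(maps, system, spec.background_intensity).astype(float)
    if spec.gain_amplitude:
        ramp = np.linspace(-1.0, 1.0, w)[None, :, None]
        img = img * (1.0 + spec.gain_amplitude * ramp)
    if spec.noise_sigma:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    tissue_area = int(h_union.sum())
    pos_area = int(pos_union.sum())
    truth = {
        "n_nuclei": len(spec.centers),
        "n_positive_nuclei": int(sum(spec.positive)),
        "tissue_area_px": tissue_area,
        "positive_area_px": pos_area,
        "positive_fraction": pos_area / tissue_area if tissue_area else 0.0,
        "nuclear_percent_positive": (
            100.0 * sum(spec.positive) / len(spec.centers) if spec.centers else None
        ),
        "seed": spec.seed,
    }
    return img, truth


def random_nuclear_section(
    n_nuclei: int,
    n_positive: int,
    shape: tuple[int, int] = (256, 256),
    radius: float = 8.0,
    min_gap: float = 4.0,
    seed: int = 0,
    **kwargs,
) -> SectionSpec:
    """Place non-touching nuclei by rejection sampling; first ``n_positive`` are DAB+.

    ``min_gap`` is the minimum edge-to-edge clearance in pixels.
    """
    if n_positive > n_nuclei:
        raise InvalidParameterError("n_positive cannot exceed n_nuclei")
    rng = np.random.default_rng(seed)
    h, w = shape
    min_dist = 2 * radius + min_gap
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 200 * n_nuclei + 1000:
            raise FixtureSpecError(
                f"could not place {n_nuclei} nuclei of radius {radius} "
                f"in a {h}x{w} frame; enlarge the frame"
            )
        cand = (rng.uniform(radius + 1, h - radius - 2),
                rng.uniform(radius + 1, w - radius - 2))
        if all(np.hypot(cand[0] - r, cand[1] - c) >= min_dist for r, c in centers):
            centers.append(cand)
    positive = tuple(i < n_positive for i in range(n_nuclei))
    return SectionSpec(
        shape=shape, centers=tuple(centers), radii=(radius,) * n_nuclei,
        positive=positive, seed=seed, **kwargs,
    )


def touching_pair_section(
    separation_factor: float,
    radius: float = 8.0,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    **kwargs,
) -> SectionSpec:
    """Two nuclei with centres ``separation_factor * radius`` apart (a dumbbell).

    Placed at a seeded random angle about the frame centre, for watershed
    splitting tests at controlled overlap.
    """
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0, np.pi)
    d = separation_factor * radius / 2.0
    cy, cx = shape[0] / 2, shape[1] / 2
    c1 = (cy - d * np.sin(angle), cx - d * np.cos(angle))
    c2 = (cy + d * np.sin(angle), cx + d * np.cos(angle))
    return SectionSpec(
        shape=shape, centers=(c1, c2), radii=(radius, radius),
        positive=(False, False), allow_touching=True, seed=seed, **kwargs,
    )


def cytoplasmic_section(
    positive_fraction: float,
    shape: tuple[int, int] = (256, 256),
    tissue_radius: float = 90.0,
    seed: int = 0,
    **kwargs,
) -> SectionSpec:
    """Tissue disk with a DAB-positive region of exact pixel fraction."""
    return SectionSpec(
        shape=shape,
        tissue_center=(shape[0] / 2, shape[1] / 2),
        tissue_radius=tissue_radius,
        cyto_positive_fraction=positive_fraction,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# bead-row cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadRowSpec:
    """Recipe for bead-row cross-section images with planted lower edges.

    ``depths`` holds, per mold row, the lower-edge depth (um) of each bead.
    All beads share one radius so rasterisation offsets cancel exactly in the
    deviation analysis.
    """

    depths: tuple[tuple[float, ...], ...]
    radius_um: float = 500.0
    pixel_size: float = 25.0     # um/px
    spacing_um: float = 2000.0   # centre-to-centre along the row
    background: int = 220
    bead_value: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.radius_um <= 0:
            raise FixtureSpecError("pixel_size and radius must be > 0")
        if self.spacing_um < 2 * self.radius_um:
            raise FixtureSpecError("beads overlap: spacing < bead diameter")
        for row in self.depths:
            for depth in row:
                if depth < 2 * self.radius_um:
                    raise FixtureSpecError(
                        f"depth {depth} leaves the bead above the frame top"
                    )


def render_bead_rows(spec: BeadRowSpec) -> tuple[list[np.ndarray], dict]:
    """Render one grayscale image per mold row plus the truth record.

    Under the half-open bounding-box convention the detected lower edge of
    each bead equals its planted depth exactly (depths should be multiples of
    ``pixel_size``).
    """
    px = spec.pixel_size
    r_px = int(round(spec.radius_um / px))
    spacing_px = int(round(spec.spacing_um / px))
    all_depths = [d for row in spec.depths for d in row]
    height = int(round(max(all_depths) / px)) + r_px + 4
    images: list[np.ndarray] = []
    truth_rows: list[dict] = []
    for row_id, row_depths in enumerate(spec.depths):
        width = spacing_px * max(len(row_depths), 1) + 2 * r_px
        img = np.full((height, width), spec.background, dtype=np.uint8)
        for i, depth in enumerate(row_depths):
            depth_px = int(round(depth / px))
            cy = depth_px - r_px - 1   # bottom row of the disk = depth_px - 1
            cx = r_px + 2 + i * spacing_px
            # the +0.49 widens the extreme rows of the rasterised disk so the
            # detection filters (despeckle, opening) cannot shave them off
            img[_disk_mask(img.shape, (cy, cx), r_px + 0.49)] = spec.bead_value
            truth_rows.append(
                {"row_id": row_id, "lower_edge_y": depth_px * px,
                 "planted_depth": depth}
            )
        images.append(img)
    return images, {"beads": truth_rows, "pixel_size": px,
                    "n_beads": len(truth_rows)}


# ---------------------------------------------------------------------------
# assay signals and dose-response tables
# ---------------------------------------------------------------------------

def simulate_assay_signal(
    n_sample: int = 23,
    n_control: int = 23,
    medians: tuple[float, float] = (91.0, 5.0),
    spreads: tuple[float, float] = (11.0, 3.0),
    outlier_rate: float = 0.0,
    outlier_shift: float = 50.0,
    seed: int = 0,
) -> tuple[AssaySignal, dict]:
    """Seeded per-spheroid readouts: Gaussian groups plus gross outliers.

    A fraction ``outlier_rate`` of each group is shifted by ``outlier_shift``
    (alternating sign), emulating staining artefacts and uneven positive-cell
    distribution.  Defaults echo a strongly expressed nuclear marker against
    an isotype control.
    """
    if n_sample < 2 or n_control < 2:
        raise InvalidParameterError("each group needs >= 2 values")
    if not 0.0 <= outlier_rate < 1.0:
        raise InvalidParameterError("outlier_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def draw(n, med, sd):
        vals = med + sd * rng.standard_normal(n)
        n_out = int(round(outlier_rate * n))
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            signs = np.where(np.arange(n_out) % 2 == 0, 1.0, -1.0)
            vals[idx] += signs * outlier_shift
        return vals

    sample = draw(n_sample, *_pair(medians, spreads, 0))
    control = draw(n_control, *_pair(medians, spreads, 1))
    truth = {"medians": medians, "spreads": spreads,
             "outlier_rate": outlier_rate, "seed": seed}
    return AssaySignal(sample=sample, control=control), truth


def _pair(medians, spreads, i):
    return medians[i], spreads[i]


def simulate_dose_response(
    top: float = 50.0,
    bottom: float = 0.0,
    ic50: float = 0.9,
    hill: float = 1.0,
    doses: tuple[float, ...] = DEFAULT_DOSE_GRID_UM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """4PL responses on a dose grid plus seeded Gaussian noise.

    Defaults emulate an anti-proliferative titration: ~50% positive untreated,
    full inhibition at high dose, sub-micromolar IC50, on the 9-point
    log-spaced 0.01-300 uM grid.
    """
    x = np.asarray(doses, dtype=float)
    if np.any(x <= 0):
        raise InvalidParameterError("doses must be positive")
    rng = np.random.default_rng(seed)
    y = four_pl(x, top, bottom, np.log10(ic50), hill)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    table = pd.DataFrame({"dose_uM": x, "response": y})
    truth = {"top": top, "bottom": bottom, "ic50": ic50, "hill": hill,
             "noise_sd": noise_sd, "seed": seed}
    return table, truth
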