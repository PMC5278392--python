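# Methods

`spharray` quantifies immunohistochemistry on spheroid tissue microarrays:
many formalin-fixed spheroids embedded in one agarose/paraffin block on a
6 × 11 grid, sectioned once, stained with DAB (brown chromogen at
antibody-bound sites) over a hematoxylin counterstain, and imaged in
brightfield. This note records the models, the parameter choices that
matter, and the limits of what the synthetic validation shows.

## Colour model and deconvolution

Transmitted-light staining follows Beer–Lambert: per RGB channel the optical
density is `od_c = -log10(I_c / I0)` with `I0` the incident white level
(default 255), and co-localised stains add linearly in OD space. A pixel's OD
vector is therefore `od = c_H · v_H + c_DAB · v_DAB + c_res · v_res`, where
the `v` are unit-norm per-stain absorbance vectors and the `c` are stain
densities. Unmixing is the 3 × 3 linear solve `c = od · M⁻ᵀ` with `M` the
row-stacked stain matrix (Ruifrok–Johnston colour deconvolution).

Choices:

- **Stain vectors.** Defaults are the standard published H-DAB pair,
  H = (0.650, 0.704, 0.286), DAB = (0.268, 0.570, 0.776), each normalised to
  unit Euclidean norm. Measured vectors for a particular stainer/scanner can
  be supplied in the config; the third (residual) stain is always the
  normalised cross product of the first two, so it is orthogonal to both and
  the system is nonsingular whenever H and DAB are not collinear.
- **Intensity clamp.** Intensities below 1 are clamped to 1 before the log,
  so a dead-black pixel maps to OD ≈ 2.41 rather than infinity.
- **Negative densities** produced by noise are retained, not clipped;
  thresholds downstream see the raw signal. QC rendering clips at 0 for
  display only.
- **Quantisation limit.** An 8-bit camera resolves OD steps of roughly
  `0.5 / (I · ln 10)` per channel, i.e. ~0.001 OD near white but ~0.09 OD at
  channel OD 2 (I ≈ 2.5 counts). Round-trip recovery through the forward
  model is therefore accurate to 0.01 OD per stain only while per-stain
  densities stay below ≈ 0.6 (transmitted intensity ≥ ~45 counts), and
  degrades hyperbolically toward saturation. Real working IHC densities sit
  in that accurate range; saturated-dark pixels are intrinsically
  low-information in any 8-bit brightfield pipeline.

## Percent-positive quantification

Two conventions, chosen by where the antigen lives:

- **Cytoplasmic stains** (GFAP, βIII-tubulin): tissue mask from thresholding
  the hematoxylin density plane, positive mask from the DAB plane;
  `% positive = 100 · area(DAB ∩ tissue) / area(tissue)`. DAB outside tissue
  is treated as artefact, so the ratio cannot exceed 100.
- **Nuclear stains** (Ki-67, SOX-2): nuclei are segmented independently in
  each plane and `% positive = 100 · n(DAB) / n(total)`.

Thresholding defaults to isodata (iterative intermeans, the usual "Default"
automatic method in IHC tooling), with Otsu or fixed OD values available for
screen reproducibility; the threshold actually applied is always logged in
the results row. One guard: on a section with *no* true DAB, an automatic
threshold fits the noise floor and would mark ~half the tissue positive.
Automatic DAB thresholds below a configurable OD floor (default 0.1 OD) are
therefore raised to the floor — the automated analogue of calibrating the
DAB threshold on a negative control.

Nuclei segmentation pipeline: despeckle (3 × 3 median) → median filter
(disk radius 2 px) → morphological opening (disk radius 2 px) → watershed on
the negated Euclidean distance transform with h-maxima marker suppression
(h = 1 px, preventing over-segmentation from raster ripple) → connected
components → discard objects below the minimum nuclear area. The minimum
area defaults to 20 μm² (a conservative lower bound for mammalian nuclei in
4 μm sections) and requires a μm/px calibration; it is always logged.
The cleaning filters shave a ~1-px rim off every object, so the *effective*
area compared against the filter is slightly below the drawn area — tests
account for this.

Denominator convention for nuclear stains: strong DAB deposition can
displace the hematoxylin counterstain, so by default the total-nuclei count
runs on the union mask H ∪ DAB and the percentage is capped at 100. A
`strict` mode divides the DAB count by the H-channel count directly,
uncapped, for compatibility with the literal two-channel ratio.

Illumination correction divides each channel by a smoothed blank-field image
(or, absent one, by a large-radius Gaussian estimate of the gain field,
σ = min(H, W)/8) and rescales so the blank maps to its own channel median.
Content cropping takes the bounding box of below-isodata pixels on the
minimum projection of the image stack, so every spheroid in a batch survives
the crop.

## Embedding-depth uniformity

Opaque beads embedded in the mold are cross-sectioned per row and imaged
side-on (calibration in the reference setup: 25 μm/px). Detection:
isodata threshold (beads dark on light), despeckle, opening (2 px disk),
particles ≥ 10,000 μm² kept. A bead's **lower edge** is the bottom of its
half-open bounding box times the pixel size (top + height convention,
y down). Per row the common plane is the median lower edge; signed
deviations (negative = above plane) are pooled across rows into a histogram
with 50 μm bins, one bin centred on zero, summarised by the IQR and the
10th/90th percentiles. Percentiles use linear interpolation between order
statistics. Slide levelling is accepted as a manual rotation-angle
pre-processing step rather than auto-detected.

## Screening statistics

Robust Z′: `Z′ = 1 − 3 (MAD_s + MAD_c) / |median_s − median_c|`. The MAD is
scaled by 1.4826 by default (consistent-for-normal convention); an unscaled
mode is provided and the scale is logged, since the two conventions differ
whenever dispersions are non-zero. Z′ ≤ 1 always; assays pass at Z′ > 0.5
(strict). Z′ is invariant under common positive affine transforms of both
groups and is undefined (error) when the medians coincide.

4PL dose–response: `y = bottom + (top − bottom) / (1 + (x / IC50)^hill)`,
parameterised on log10 dose with log10(IC50) as the fitted location
parameter. The bottom can be constrained to zero for markers expected to
vanish at full effect. Zero-dose (untreated) points are mapped to a floor
one log below the smallest nonzero dose before taking logs. Confidence
intervals are Wald intervals on log10(IC50) from the parameter covariance,
exponentiated — asymmetric in μM, always positive. Degenerate (constant)
responses and optimiser non-convergence raise a fit failure carrying
diagnostics. A constrained fit can never beat the free fit's residual sum of
squares; this is asserted in tests.

## Array geometry and workflow arithmetic

The default layout is 6 rows × 11 columns (66 wells), pitch 2,000 μm
(config-mandatory for physical-unit work — the mold print does not fix it),
with column 10 (0-based) reserved for marker wells. De-arraying assigns each
detected spot centroid to its nearest well centre; spots farther than the
tolerance (default pitch/4) stay unassigned, conflicts resolve by the
smaller residual, and marker wells may hold multiple spots. With ≥ 3 marker
detections the grid origin is re-estimated as the least-squares translation,
making assignment invariant to global stage offsets.

Sectioning arithmetic: a band extending fraction *f* of the diameter above
and below a spheroid's midline spans `2 f d` and holds `floor(2 f d / t)`
sections of thickness *t* — 50 sections for d = 500 μm, f = 0.2, t = 4 μm.
Workflow economics: embedding every condition separately needs one block per
condition and `conditions × slides_per_sample` slides; the array needs one
block, an `n_conditions`-fold saving.

## Synthetic fixtures: what they do and do not show

The generators are pure functions of spec + seed (bit-reproducible):

- **Sections** render binary-density disks (nuclei, or a tissue disk whose
  DAB-positive subregion has an *exact* planted pixel fraction) through the
  forward Beer–Lambert model, then apply a multiplicative lateral gain ramp
  and additive Gaussian intensity noise (default σ 2–3 counts in tests).
  Bead rows share a single radius so rasterisation offsets cancel exactly in
  the deviation analysis; the extreme rows of each disk are widened by half
  a pixel so cleaning filters cannot shave the measured lower edge.
- **Assay signals** are Gaussian groups with a planted fraction of gross,
  alternating-sign outliers (default group sizes 23, emulating per-spheroid
  replicate counts typical of one array).
- **Dose–response tables** default to 9 log-evenly spaced doses from 0.01 to
  300 μM (≈ 0.56 decades per step), top 50%, bottom 0, IC50 0.9 μM,
  hill 1 — an anti-proliferative titration profile.

Passing on these fixtures shows the *algorithms* recover known truth under
additive noise, smooth gain fields, touching-object geometry and gross
outliers. It does not establish performance on real histology: paraffin
texture, hematoxylin aggregates, section folds, chromatic scanner effects,
out-of-focus blur and biological heterogeneity of staining are all absent
from the forward model, which is why fixed-threshold and negative-control
calibration paths remain first-class options in the config.

## Numerical conventions

Coordinates are 0-based, row-major, y increasing downward; rectangles and
bounding boxes are half-open. Thresholded masks use `map ≥ threshold`.
Histogram bins are half-open except the last. Batch processing is
sorted-filename order with per-file failure isolation; all randomness flows
through explicit integer seeds, and re-running any simulate/quant command
with identical config and inputs reproduces byte-identical CSV output.

Problem sizes used in the validation suite — 512 × 512 px nuclear sections
(55 nuclei), 256 × 256 px cytoplasmic sections, 40 touching pairs, 27 beads
over 3 simulated molds, 100 Monte-Carlo dose-response fits — were chosen as
the smallest sizes at which the recovery tolerances above are meaningful
(e.g. ±2 percentage points implies ≥ ~10⁴ tissue pixels; split-rate ≥ 95%
needs ≥ 40 trials).
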