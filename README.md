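# spharray

Quantitative image analysis for **spheroid tissue microarrays** — blocks in
which up to 66 fixed spheroids sit on a common 6 × 11 grid so that a single
4 μm section carries every experimental condition. It is written for cell
biologists and screening groups who stain such sections with DAB over a
hematoxylin counterstain and need reproducible, scriptable readouts instead
of interactive per-image thresholding.

## What it computes

- **Colour deconvolution** (Beer–Lambert / Ruifrok–Johnston): per-pixel
  optical density `od = −log10(I/I₀)` is unmixed into hematoxylin, DAB and
  residual densities through a 3 × 3 stain matrix; the forward model is also
  exposed, and drives the synthetic ground-truth generators.
- **Percent-positive IHC quantification**: for cytoplasmic stains,
  `% = 100·area(DAB ∩ tissue)/area(tissue)`; for nuclear stains,
  `% = 100·n(DAB nuclei)/n(total nuclei)` with watershed splitting of
  touching nuclei and a minimum nuclear size. Batch mode emits one CSV row
  per image plus QC overlays (green tissue outline, magenta positive
  outline), with every threshold logged.
- **Embedding-depth uniformity**: bead lower edges from row cross-sections,
  per-row median plane, pooled deviations, 50 μm histogram, IQR and
  10th/90th percentiles.
- **Screening statistics**: robust
  `Z′ = 1 − 3(MAD_s + MAD_c)/|median_s − median_c|` with the strict Z′ > 0.5
  acceptance rule, and 4-parameter logistic dose–response fits
  `y = bottom + (top − bottom)/(1 + (x/IC50)^hill)` with an optional
  bottom = 0 constraint and Wald 95% CI on the IC50.
- **Array utilities**: de-arraying spot centroids to (row, column) wells
  with marker-well support, section-count arithmetic and workflow economics.

Ground-truthed synthetic fixtures (rendered H-DAB sections, bead rows, assay
signals, dose tables) make every pipeline testable without any microscope
data. See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import spharray as sp

# render a section whose DAB-positive area fraction is known exactly,
# with additive noise, then quantify it blind
img, truth = sp.render_section(sp.cytoplasmic_section(0.25, noise_sigma=3.0, seed=7))
res, tissue, dab = sp.quantify_cytoplasmic_image(img)
print(f"planted {100*truth['positive_fraction']:.2f}%  measured {res.percent_positive:.2f}%")
print(f"thresholds used: H {res.h_threshold:.3f} OD, DAB {res.dab_threshold:.3f} OD")

# assay window between stained samples and isotype controls
sig, _ = sp.simulate_assay_signal(medians=(91.0, 5.0), spreads=(11.0, 3.0),
                                  outlier_rate=0.1, seed=1)
z = sp.robust_z_prime(sig)
print(f"robust Z' = {z:.2f} ({sp.classify_assay(z)})")

# dose-response with the bottom constrained to zero
table, _ = sp.simulate_dose_response(top=50, bottom=0, ic50=0.9, hill=1.0,
                                     noise_sd=2.5, seed=1)
fit = sp.fit_4pl(table["dose_uM"], table["response"], constrain_bottom_zero=True)
print(f"IC50 = {fit.ic50:.2f} uM (95% CI {fit.ic50_ci[0]:.2f}-{fit.ic50_ci[1]:.2f})")
```

prints

```
planted 25.00%  measured 24.99%
thresholds used: H 0.301 OD, DAB 0.398 OD
robust Z' = 0.65 (acceptable)
IC50 = 0.78 uM (95% CI 0.57-1.05)
```

The measured positive area tracks the planted truth to a fraction of a
percentage point; the Z′ of 0.65 clears the screening-quality bar despite
10% gross outliers; and the fitted IC50 of 0.78 μM recovers the generating
value 0.9 μM well within its confidence interval at 5%-of-top noise.

## Command line

Each subcommand is a thin wrapper over the library (`--help` for flags):

```sh
spharray quant-cyto IMAGES_DIR --out results/      # % positive area per image
spharray quant-nuclei IMAGES_DIR --out results/ --pixel-size 0.5
spharray depth --manifest rows.csv --out depth/    # bead-depth uniformity
spharray zprime --data signal.csv                  # robust Z'
spharray fit-dr --data doses.csv --constrain-bottom-zero
spharray dearray --spots spots.csv --out wells.csv
spharray simulate section|beads|signal|dr --seed 1 --out fixtures/
spharray sections-calc --diameter 500              # -> 50
spharray plan --conditions 11                      # -> 11-fold saving
```

Defaults (stain vectors, threshold modes, minimum nuclear area, layout
geometry, MAD scaling, seeds) live in a TOML config passed with `--config`;
command-line flags override file values, and the resolved configuration is
echoed into every output directory. Batch results CSVs have a fixed column
order: `image`, thresholds, areas or counts, `percent_positive`.

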