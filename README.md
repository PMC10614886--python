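# spindlemetrics

Quantitative analysis of mitotic-spindle fluorescence microscopy, built
around the measurements used to characterize kinesin-8/KIF18A function
and inhibition: chromosome alignment, motor localization within the
spindle, live-cell relocalization kinetics, mitotic-population statistics
and biochemical dose-response potency.

KIF18A accumulates at the plus-ends of kinetochore microtubules, where it
dampens their dynamics and confines chromosomes to a tight metaphase
plate. Perturbing the motor — by knockdown, by mutations in its alpha-4
helix, or with small-molecule inhibitors — relocalizes it toward the
spindle poles, widens the chromosome distribution, lengthens the spindle,
arrests chromosomally unstable (CIN) cells in mitosis and suppresses
their proliferation. Each of those phenotypes has a standard quantitative
readout, and this package implements all of them as a tested library plus
a thin CLI, together with a synthetic-data generator that produces every
input type with known ground truth so the whole pipeline is verifiable by
parameter recovery.

## The measurements

* **Chromosome alignment (FWHM).** The kinetochore (or DNA) intensity
  distribution along the pole-to-pole axis, measured in a boxed ROI,
  internally normalized to its maximum and fitted with a Gaussian
  `y = offset + A·exp(−(x−µ)²/2σ²)`; the reported statistic is the full
  width at half maximum, FWHM = 2√(2 ln 2)·σ ≈ 2.3548 σ, together with
  the spindle length (Euclidean pole-to-pole distance).
* **Motor localization.** 10-pixel-wide line scans from each γ-tubulin
  pole signal toward the spindle center, channel-normalized, aligned by
  peak γ-tubulin intensity and averaged per pixel distance; the per-scan
  statistic is the distance from pole to maximum motor signal (µm).
* **Relocalization kinetics.** Spindle fluorescence profiles at an
  initial and a final timepoint are resampled to a 0–100 % spindle-length
  grid; the pointwise Final/Initial ratio and its trapezoidal area under
  the curve (plus the area of |ratio − 1|) quantify redistribution of the
  motor from mid-spindle to poles.
* **Population statistics.** Mitotic index (% of counted cells in
  mitosis), multipolar-spindle fraction (% of mitotic cells with > 2
  poles), background-subtracted spindle-ROI expression, and proliferation
  fold change (final/first cell count) normalized to the control mean per
  experiment batch.
* **Dose-response potency.** Percent inhibition
  `100·(positive − sample)/(positive − negative)` from plate controls,
  fitted with the four-parameter logistic (variable-slope) model
  `y = bottom + (top − bottom)/(1 + (IC50/x)^hill)` on log10
  concentration.

## Worked example

```python
import numpy as np
import spindlemetrics as sm

# one synthetic metaphase cell: plate dispersion sigma = 1.5 um,
# motor peaks 4 um from each pole, peak SNR ~ 10
scene = sm.SpindleScene(kinetochore_sigma=1.5, kif18a_peak_distance=4.0, seed=11)
image, truth = sm.generate_spindle_image(scene)
ann = scene.annotation("cell000")

res = sm.chromosome_alignment(image, ann)
print(f"FWHM        {res.fwhm:.3f} um  (truth {truth.true_fwhm:.3f} um)")
print(f"spindle     {res.spindle_length:.2f} um")

o = np.asarray(ann.pole_a); u = np.asarray(ann.pole_b) - o; u = u / np.hypot(*u)
end = o + u * (6.5 / image.pixel_size)
scan = sm.normalize_profile(sm.extract_line_profile(
    image, tuple(o), tuple(end), width_px=10,
    channels=["gamma_tubulin", "kif18a"]))
print(f"pole->motor {sm.distance_to_max(scan):.2f} um  "
      f"(truth {truth.true_peak_distance:.2f} um)")

plate, pt = sm.generate_dose_response(true_ic50=8.2, hill=1.0, cv=0.05, seed=11)
fit, _ = sm.fit_plate(plate)
print(f"IC50        {fit.ic50:.2f} nM (truth {pt.true_ic50} nM), hill {fit.hill:.2f}")
```

prints

```
FWHM        3.530 um  (truth 3.532 um)
spindle     12.00 um
pole->motor 3.90 um  (truth 4.00 um)
IC50        7.77 nM (truth 8.2 nM), hill 1.01
```

i.e. the pipeline recovers the plate width to ≲0.1 %, the motor-peak
distance to within one pixel, and the IC50 of a single noisy plate to a
few percent.

The same stages are available from the shell:

```sh
spindlemetrics simulate --out-dir sim --n-cells 5 --kinetochore-sigma 1.5
spindlemetrics align --annotations sim/annotations.csv \
    --images sim/cell000.tif --images sim/cell001.tif --out fwhm.csv
spindlemetrics doseresponse --in plate.csv --out fit.csv
```

Subcommands: `simulate`, `align`, `localize`, `relocalize`, `counts`,
`growth`, `expression`, `doseresponse`. Each accepts `--config cfg.yaml`
(see `spindlemetrics.config.RunConfig` for the schema and defaults) and
stamps its output CSVs with the config hash and package version.

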