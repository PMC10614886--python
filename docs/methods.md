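# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the parameter defaults and the
numerical choices, in enough detail to reproduce or modify any of them.

## Synthetic spindle model

The generator renders a minimal bipolar metaphase spindle sufficient to
exercise every profile shape the metrics consume. With poles **a**, **b**
(µm), axial coordinate `s` (distance along the pole axis from pole a),
lateral coordinate `q` (signed perpendicular distance) and spindle length
`L = |b − a|`:

| channel | model | default amplitude (a.u.) |
|---|---|---|
| γ-tubulin | isotropic 2D Gaussian at each pole, σ = 0.4 µm | 150 |
| α-tubulin | Gaussian falloff of distance to the pole–pole segment ("stadium"), width 1.0 µm | 80 |
| kinetochore | exp(−(s−L/2)²/2σ_k²) · exp(−q²/2·1.5²) — the metaphase plate | 120 |
| KIF18A | [exp(−(s−d)²/2·0.5²) + exp(−(s−(L−d))²/2·0.5²)] · exp(−q²/2·1.5²) + 0.1 · lattice | 150 |

`σ_k` (`kinetochore_sigma`, default 1.5 µm) is the plate dispersion whose
FWHM (= 2.3548 σ_k) the alignment stage must recover; `d`
(`kif18a_peak_distance`, default 4.0 µm) is the pole-to-motor-peak
distance the localization stage must recover — `d = 0` renders the
pole-accumulated, inhibited-like pattern. A constant background
(default 10 a.u.) is added to every channel.

Noise is Poisson shot noise on the expected counts followed by additive
Gaussian read noise (default SD 2 a.u.), clipped at zero. The defaults
put the peak signal-to-noise ratio near 10
(amplitude / √(amplitude + background) ≈ 120/√134 ≈ 10 on the
kinetochore channel): the source images report no absolute intensity
scale or SNR, so these values are an assumption chosen so that
recovery is demanding but achievable; they are the fixed study
conditions for all recovery tests, not tuning knobs.

Geometry defaults: 12 µm spindle (poles at (3, 5) and (15, 5) µm),
0.1083 µm/px (a typical 60x sCMOS scale; it also makes the documented
6.5 µm scan exactly 60 one-pixel steps), image 167 × 93 px, poles kept
≥ 2 µm from every edge. Positions are continuous µm; rasters sample
pixel centers; index (0, 0) is top-left and 0-based, so pixel (r, c)
sits at (x, y) = (c, r)·pixel_size. Annotations are 0-based pixels with
sub-pixel floats.

The time-lapse generator suppresses the motor channel (above background)
within ±g(t) µm of the spindle midpoint and deposits the removed
intensity into the two pole puncta, conserving total motor intensity per
frame to float precision; g(t) must be non-decreasing. This emulates a
motor trapped on a fluxing lattice: a mid-spindle gap that expands
poleward while poles brighten. Dose-response plates follow the 4PL
inhibition model between a positive (uninhibited, default 10 000 a.u.)
and negative (no-enzyme, default 500 a.u.) control level with
multiplicative Gaussian noise (default CV 5 %, duplicate wells, 8-point
4-fold dilution from 1000 nM). Growth series are deterministic
exponentials with multiplicative noise; count tables are per-field
binomial draws with per-mitotic-cell multipolar Bernoulli labels.

What the generator does **not** emulate: 3D point-spread functions,
photobleaching, cell-to-cell shape variation, chromatic shifts, uneven
illumination, or segmentation difficulty (pole positions are supplied as
annotations, as in the manual workflow). Recovery results on this data
therefore validate the measurement pipeline downstream of cell finding
and annotation, not those upstream steps.

## Profile extraction

Wide line scans sample every pixel along the start→end segment
(`n = round(length_px) + 1` samples including both endpoints) and average
bilinearly interpolated intensities at `width_px` perpendicular offsets,
spaced 1 px and symmetric about the line (width 10 → offsets
−4.5 … +4.5 px). Boxed pole-to-pole profiles use the same machinery with
the perpendicular extent given in µm (default box height 5 µm; the height
of the source workflow's box is not documented, and the kinetochore
band's lateral envelope makes the fitted σ insensitive to it). Fixed-cell
profiles reduce across the width by the mean; live-cell ROI profiles by
the sum (the Final/Initial ratio is invariant to this choice for a fixed
ROI). Scans that leave the raster, including via their width, are
rejected rather than padded. Extraction is linear in image intensity and
is tested to 1e-9 against a naive per-sample, per-offset loop.

Internal normalization divides each channel by its own maximum
(idempotent; flat-zero profiles are rejected).

## Alignment metric

The Gaussian fit includes an additive offset because cytoplasmic
background is nonzero and offset-free fits bias σ upward. Initialization
is moment-based (weighted mean/SD after subtracting the minimum); bounds:
σ ∈ (0, axis length], center on the axis. `curve_fit` non-convergence is
flagged on the result (and excluded from summaries by the CLI), never
silently returned; flat profiles and profiles with < 8 samples are
errors. Every emitted fit satisfies FWHM = 2√(2 ln 2)·σ by construction.
An FWHM exceeding the spindle length is flagged, not rejected — it is a
biologically meaningful "severely unaligned" outcome.

## Localization metric

`distance_to_max` is computed per scan (matching per-scan dot plots of
the assay); the peak of the aligned averaged profile is also exposed.
Alignment shifts are whole samples so that averaging happens per pixel
distance; the mean at each distance uses only the scans covering it.
Ties in an argmax resolve to the first, pole-proximal sample, which also
makes a monotonically decaying (pole-accumulated) motor read exactly 0.
Both half-spindles of a cell are treated as independent scans. Scan
defaults: 6.5 µm long, 10 px wide.

## Relocalization metric

Percent-length resampling linearly interpolates onto a fixed 101-point
0–100 % grid. Ratio positions where the initial profile is at or below
1 % of its maximum are masked, not divided; the AUC requires ≥ 90 % grid
coverage and excludes masked points from the trapezoid. Two areas are
reported: the baseline-0 AUC of the ratio curve (100 for a ratio
identically 1) and the deviation AUC of |ratio − 1| (0 for an unchanged
cell), the latter being the more interpretable discrimination statistic
between static and relocalizing cells.

## Population statistics

Mitotic index pools counts across fields (100·Σmitotic/Σtotal) and keeps
per-field percentages for replicate plotting. Multipolarity counts
mitotic cells with > 2 poles over all scored mitotic cells; monopolar
cells are in the denominator only. Fold change is final/first count per
well; normalization divides by the mean control fold change *within the
same experiment batch*, making the control batch mean exactly 1 and the
statistic invariant to any common rescaling of a batch's counts.
Expression is the mean spindle-ROI intensity minus the mean background-
ROI intensity (rectangular ROIs, non-overlapping); negative corrected
values are kept with a warning.

## Dose-response

Fitting uses log10 concentration with the Hill parameterization above,
equivalent to "log(inhibitor) vs response — variable slope", which is
numerically stable across 4-fold serial dilutions. Bounds: hill ∈
[0.1, 10], log IC50 within two decades of the tested range; a fit pinned
at a bound is flagged as non-converged. Standard errors come from the
covariance of the fit, with the IC50 error mapped from the log scale by
the delta method. Percent inhibition maps the plate's own control means
to exactly 0 and 100; controls are never shared across plates.

## Problem sizes and determinism

Recovery checks use 20 cells per dispersion level (σ ∈ {1, 1.5, 2, 3} µm),
30 scans per peak distance ({0, 2, 4} µm), 10 + 10 time-lapse cells,
100 plates per potency (8.2 and 41.3 nM) and 100 count tables — sizes at
which the medians are stable across seeds while the whole validation
suite runs in well under a minute. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical inputs and
seed give bit-identical rasters, tables and result CSVs.

## Known limitations

- 2D only; cells where both poles are not in one focal plane are out of
  scope, as in the manual single-focal-plane workflow.
- Integer-sample scan alignment quantizes distances to the pixel grid
  (0.108 µm at the default scale); sub-pixel peak localization is not
  attempted because the per-scan statistic is an argmax by definition.
- The hard-edged time-lapse gap is a caricature of the real poleward
  redistribution; it is designed to test the ratio/AUC machinery, not to
  model flux kinetics.
- Mitotic and pole-count labels are inputs; no detection or segmentation
  is performed.
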