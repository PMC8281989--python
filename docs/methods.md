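# Methods

## Scope and data model

`titervision` analyses a live-cell imaging titer assay for lentiviral
vectors. The unit of data is a single-channel grayscale frame
(phase contrast, green fluorescence in green calibrated units GCU, or red
fluorescence in RCU) tagged with well, field (1–4 per well), and hours post
seeding. Area metrics are aggregated over the fields of a well at each
timepoint (areas summed, percentages relative to the summed field area) and
assembled into per-well time series. All areas are pixel counts ×
`pixel_size_um²`; the pixel grid is row-major with the origin at top left.

## Segmentation operators

Fluorescence masks are the composition, in order, of:

1. **Top-hat background subtraction** — the image minus its grayscale
   opening by a discrete disc. The disc radius (default 20 µm) should match
   the largest fluorescent object: anything wider survives the opening and
   is removed as background. Radii are converted to pixels by rounding up,
   which is conservative for object retention.
2. **Threshold** — strictly greater than the calibrated-unit threshold
   (1.3 GCU green, 0.3 RCU red). The strict inequality implements
   "brighter than" the threshold; boundary pixels equal to the threshold are
   background.
3. **Clean-up** — signed boundary refinement: −k erodes by a k-pixel disc,
   +k dilates, 0 is the identity (−1 px green, 0 red, −2 phase).
4. **Area filter** — 8-connected components outside [min, max] µm² are
   removed (≥35 µm² green; 35–1400 µm² red; ≥170 µm² phase). 8-connectivity
   avoids splitting diagonally-touching cell boundaries. Both bounds are
   inclusive.

The edge-split (object splitting) flag exists but is a no-op: the assay
derives area metrics only, and the instrument protocol it follows runs with
edge splitting deactivated.

**Confluence (phase) segmentation.** The vendor's phase algorithm is
proprietary; this package uses a texture segmentation: the local standard
deviation over a window of ~3 µm (≥3 px, odd) converts cell texture into
intensity, which is thresholded at `adjustment × Otsu` of the texture image
(the dimensionless `adjustment`, default 1.0, exposes the segmentation bias
as a multiplicative factor). Two numerical guards handle degenerate fields,
where Otsu would split a unimodal histogram down the middle: if the two
Otsu classes' mean local sd differ by less than 2×, the field is classified
uniformly — all cell if the median local sd exceeds an absolute floor
(`texture_sd_floor`, default 0.03 intensity units), all background
otherwise. A blank noise-only field therefore reads ~0% confluence and a
fully textured field ~100%. The mask is hole-filled, cleaned up (−2 px) and
area-filtered (≥170 µm²).

## Kinetics and titer

- **P2** = `A_FF488 / A_C × 100` may exceed 100% (the green mask can be
  wider than the phase mask); **P3** subtracts the infected-but-dead
  overlap from the numerator and the dead area from the denominator. With
  no dead area the two are identical.
- **Readout time**: the maximum of the raw kinetic curve inside the readout
  window (default: staining time → end of run; the staining-time start is
  our resolution of an ambiguity in when the "measured period" begins).
  Ties break to the earliest time. No smoothing is applied by default,
  matching a raw-maximum readout.
- **Cell number**: `N = (C − b)/m` from an OLS calibration of confluence
  against an offline cell count (validated seeding range 2200–53400
  cells/well). N is computed per well from that well's own confluence at
  the frame closest to the transduction time (ties → earlier frame); a
  plate-mean fallback exists behind a flag. Counts below zero are clipped
  with a warning, and extrapolation outside the calibrated range warns.
- **Titer**: `P·N·D/(V·100)` TU/mL. Replicate wells are titered
  individually (dilution correction per well) and then averaged per sample;
  wells whose peak P lies outside the assay's detection limits are excluded
  from the mean and reported with a flag.

## QC statistics

Sample SD uses the n−1 denominator (standard for assay precision; the
protocol this follows does not specify). CV% = 100·SD/mean, undefined
(flagged) at zero mean. Z′ = 1 − 3(σ_p+σ_n)/|µ_p−µ_n| with the usual
classification (≥0.5 excellent, 0–0.5 marginal, negative below marginal);
the operation takes explicit control statistics rather than guessing which
wells form the baseline. The dose–response over a serial dilution series is
fitted (a) globally against log2(dilution) and (b) linearly on every
contiguous subrange of ≥3 points on a configurable concentration scale —
default `1/dilution`, since responses are linear in concentration at low
MOI. The linear range is the longest subrange with R² ≥ `r2_min` (default
0.95; ties → higher R²); the LLOD/ULOD are the fitted responses at the
range's highest/lowest dilution.

## Stability statistics

Half-lives come from log-linear OLS on ln(titer) vs time: closed-form and
reproducible on the short (4-point) kinetics these studies use; nonpositive
titers are excluded with a warning, a nonpositive decay rate is reported as
not-detectable, and the half-life SE is the delta-method propagation
`ln2·SE_slope/λ²`. Pump passes are `flow·duration/reservoir` rounded half
away from zero — the only convention consistent with the worked examples
(19.5 → 20 and 6.5 → 7). Group-significance testing (t-tests, ANOVA with
post-hoc correction) is delegated to scipy/statsmodels and only surfaced in
reports.

## Synthetic plates

The simulator fixes the study conditions at the assay's defaults: 6×10³
cells seeded per well, infection at 24 h with V = 0.05 mL of a two-fold
dilution series (1:2–1:1024), staining 24 h post infection, imaging every
2 h, true titer 2×10⁷ TU/mL. Per well:

- **Growth**: confluence is flat until attachment (7 h) and then logistic
  with a 24 h doubling time toward a 95% carrying capacity. Confluence and
  cell count are linked by the mean cell footprint (ellipses of 7–11 µm
  radius) over a 3.2×10⁷ µm² well growth area — ~4.8% confluence at
  seeding.
- **Infection**: single-hit Poisson. `MOI = titer·V/(D·N₍24h₎)`,
  `P_inf = 1 − e^(−MOI)`; the realized infected fraction is
  `Binomial(N, P_inf)/N`. This produces saturation at low dilutions and
  linearity at high dilutions — the observed "logarithmic trend" over the
  full series.
- **Green kinetic**: `g(t′) = (t′/τ)^s·e^{s(1−t′/τ)}` with t′ hours since
  staining, peak at τ = 42 h (66 h post infection) and shape s = 2 —
  surface labelling followed by internalization-driven signal loss.
  Per-cell peak intensity is lognormal (mean 3 GCU, CV 25%), so cells cross
  the 1.3 GCU detection threshold asynchronously.
- **Death**: a constant 0.1% dead fraction by default (matching the
  assay's ~99.9% observed viability); dead cells are rendered in red at
  1 RCU from the staining time onward. The infected-but-dead truth overlap
  follows green visibility.
- **Rendering**: cells are non-overlapping ellipses placed by dart throwing
  (≤30% pairwise overlap, with a retry cap); positions persist between
  frames and new cells appear as the well grows — no migration, which is
  sufficient for area metrics. Phase cells are high-variance texture on a
  flat noisy background; green/red cells sit on a smooth per-well
  background bump (removed by the top-hat) plus Gaussian noise. Rendered
  cells carry a one-pixel out-of-focus fringe in the phase texture and the
  green glow, while truth masks are the in-focus ellipses; the clean-up
  erosions of the segmentation chain then recover truth areas instead of
  systematically eroded ones. Intensity statistics were chosen only so
  that the default thresholds recover truth areas within ~10%.
- **Determinism**: every random stream is keyed on (seed, well, field,
  time, channel); a fixed seed reproduces identical tables and pixels.

What the simulator does *not* emulate: photobleaching, focus drift, optical
PSF, cell migration or suspension cells. Passing recovery tests therefore
demonstrates correctness of the measurement chain under the assay's
assumptions, not robustness to those instrument effects.

## Problem sizes and numerical choices

End-to-end recovery runs use 256×256 px frames (1.24 µm/px), one field per
well, 33 wells (10 dilutions × 3 replicates + 3 matrix controls), imaging
timepoints {24, 56, 66, 76, 86, 96} h, a 15-well calibration run at 7 h
(counts 2200–53400), and five independent seeds — sizes chosen so a full
study runs in minutes on one CPU while every stage of the pipeline is
exercised. The recovered titer is the median over in-range wells; it sits
systematically ~10–20% below truth because percent-positive saturates
below the Poisson MOI at finite dilution (the same bias affects any
percent-positive titration; restricting to the detected linear range bounds
it). Half-life recovery uses 200 replicates of 4-point kinetics with 10%
lognormal noise.

## Known limitations

- The vendor's "segmentation adjustment" mapping is unpublished; the
  multiplicative-Otsu interpretation is a stand-in, and measured confluence
  is only comparable across images analysed with the same settings.
- Whether area percentages should be per-field or per-well averages is an
  instrument convention; this package sums over fields.
- Titer accuracy degrades above the linear range (MOI saturation) and below
  the LLOD (counting noise); out-of-range wells are flagged, never
  silently averaged.
- The half-life uncertainty reported is the fit SE; replicate biological SD
  is a separate quantity and must be computed over replicate fits.
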