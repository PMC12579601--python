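# Methods

This note documents the models, numerical conventions, and design
decisions behind the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Colorimetric pipeline

Everything runs at the tristimulus level; no spectral computation is
involved. The calibrated monitor is the usual gamma + primary-matrix
model: linear drive = drive^γ (γ = 2.2 per channel by default), XYZ the
drive-weighted sum of the primaries' tristimulus at full drive. The
default display uses primaries R = (0.6847, 0.3111, 26.4 cd/m²),
G = (0.2138, 0.7263, 69.9), B = (0.1521, 0.0453, 4.8), white
xyY = (0.3304, 0.3526, 101.1), and a neutral background at L\* = 70
(white-point chromaticity at the luminance giving that lightness —
computed, never hard-coded). Gamut membership means all three inverse
linear drives lie in [−tol, 1 + tol], tol = 1e−6 by default; membership is
monotone along chroma rays from the background.

**Cone excitations.** XYZ → LMS uses a Stockman–Sharpe 2° (CIE-2006-style)
matrix. The published matrix rows are rescaled so that two conventions
hold as matrix identities: L + M = Y (luminous-efficiency scaling, using
the weight 1.980647 for L) and S = Z, so the equal-energy white has
S = L + M. The matrix is carried by a `ConeFundamentals` object recorded
in the monitor model and echoed in CLI logs; alternates can be swapped in.
The 2° field was chosen because the tasks are foveal. The choice of
per-channel scale is immaterial to the cone-adaptation model — its
prediction is provably invariant under independent positive rescaling of
the three channels (ratios cancel in the Weber fraction), and the test
suite verifies this numerically.

**Uniform spaces.** CIELUV and CIELAB are the standard CIE formulas with
the cube-root compression and its linear low-end segment, always under an
explicit reference white; round-trips hold to 1e−9 across the gamut. Hue
azimuth is atan2(v\*, u\*) (or b\*, a\*), counterclockwise, degrees in
[0, 360), 0° = +u\*. All user-facing hue I/O is in degrees.

**DKL plane.** The cone-opponent plane is built around the background:
raw coordinates in cone-contrast units, lm = ΔL/L_bg − ΔM/M_bg (constant
S and constant luminance, since ΔM = −ΔL) and s = ΔS/S_bg (constant L and
M). Each axis is then rescaled by the largest radius whose *both* ends
(+r and −r) remain inside the gamut at background luminance, so a unit
circle is always renderable; the binding direction of each axis touches
the boundary at exactly ±1 and the scaling constants are exposed on the
`DKLSpace` object. (An asymmetric per-direction scaling was rejected: it
would make hue circles of radius ≤ 1 non-renderable on one side, defeating
the purpose of gamut scaling.) Conversions demand isoluminance with the
background to a relative 1e−6.

## Prediction models

All models share one partial-adaptation convention: the *effective
adapting colour* is the inducer's hue direction at a fixed matched
strength — CIELUV chroma 27.0 for CIELUV-specified inducers, gamut-scaled
DKL radius 0.47 for DKL-specified ones. These defaults are the
grand-average matched afterimage strengths of the adjustment experiments
the package models; afterimages are visibly less saturated than their
inducers, so complete adaptation is not assumed (it can be emulated by
setting the strength to the inducer chroma). None of the models has a
free parameter.

- **cone** — `LMS_after = bgLMS² / iLMS` per cone (the probe's Weber
  contrast under local adaptation to the inducer, re-embedded under
  global adaptation to the background). The result is generally not
  isoluminant with the background, so by default the predicted
  tristimulus is rescaled to background luminance before chroma is read
  off (u′v′ chromaticity, hence hue, is invariant under this projection;
  all stimuli and matches live in the background-L\* plane). The
  unprojected coordinates are retained in the prediction's `native`
  field.
- **dkl** — `−k · iDKL`. By default k is chosen so the predicted radius
  equals the effective adapting strength (k = strength / inducer radius);
  an explicit k can be configured and leaves the predicted hue unchanged.
  A half-wave-rectified variant (each opponent channel split into two
  single-signed mechanisms adapted separately) is provided and is
  algebraically identical on a neutral background; the suite confirms the
  no-op to 1e−6°.
- **cieluv / cielab** — corresponding colours by white substitution: the
  background's coordinates under the effective adapting colour as white,
  re-embedded under the global white. The adapting white keeps the
  reference white's luminance (chromatic adaptation only), so L\* is
  preserved and the prediction stays isoluminant. At isoluminance the
  CIELUV form reduces to u′v′ subtraction and predicts exactly the
  opponent hue (verified to 1e−6°), with different chroma.
- **ciecam02** — the CAT02 chromatic adaptation transform between the
  adapting and global whites, with the degree of adaptation D from the
  CIECAM02 formula (surround factor F = 1, adapting luminance La =
  background luminance / 5 by default, all overridable; D is not clamped).
  The full appearance-correlate pipeline (J, C, h) is deliberately not
  built: the corresponding-colour step is the part of CIECAM02 that
  defines the afterimage prediction, and a direct transcription of the
  published CAT02 equations serves as the cross-check in the tests.
- **munsell** — the effective adapting colour is located in the
  renotation lattice by CIELAB interpolation (bilinear across the hue ×
  chroma grid of a value plane); its opponent is the hue 50 steps away on
  the 100-step circle at the same value and chroma, mapped back through
  the table. Convention (flagged in the prediction metadata): the value
  plane nearest the background L\* and the inducer's interpolated Munsell
  chroma. Inducers outside the lattice's chroma range raise rather than
  extrapolate.
- **hering** — if the inducer lies fraction t of the arc from one
  unique-hue prototype to the next (cyclic order red, yellow, green,
  blue), the prediction lies fraction t of the arc between their
  opponents (red↔green, yellow↔blue). Prototypes are required
  configuration — they are empirically measured, so no default azimuths
  are baked in. There is no chroma prediction.

Identity behaviour: with adaptation strength 0 every model predicts the
achromatic background (chroma 0, hue flagged undefined as NaN).

Structural properties of the cone model confirmed against a dense
0.5°-grid numeric check during development and asserted at the 72-hue
resolution in the suite: exactly three local maxima of predicted chroma
and six zero crossings of the signed deviation-from-opponency curve;
deviations shrink strictly with adapting chroma and fall below 0.1° at
chroma 0.01 (the subtractive, linearized limit); and the map is not an
involution (double application misses the original hue by > 2° at some
hues).

## Munsell renotation data

The reader accepts the standard renotation layout (hue label such as
"7.5GY", value, chroma, x, y, Y; delimited text). The package does not
bundle the measured RIT renotation table; tests and demos use
`synthetic_renotation_table`, an idealized, smooth stand-in generated by
inverting CIELAB from an analytic hue/value/chroma lattice (monotone hue
warping, chroma-proportional radius). It exercises the interpolation
machinery exactly but is not colorimetric Munsell data, and is labelled
synthetic accordingly.

## Analysis pipeline

Aggregation: skipped trials are excluded everywhere (skip rates are
visible in the trial table); responses are pooled within participant by
circular mean, then across participants by circular mean (chroma by
arithmetic means); direct pooling is available as an option.

Statistics: deviations from opponency are signed circular differences
from inducer + 180° in (−180°, 180°]; hue histograms use left-closed
bins tiling [0, 360) with the first edge at 0 (24 bins of 15° by
default; edge-aligned rather than response-centred, the alternative being
a config choice); circular smoothing is a centre-aligned wrap-around
running mean (window 9 for the sR² figures). Pearson correlations carry
Fisher-z 95% confidence intervals and two-tailed t-distribution p-values;
one-sample t-tests report Cohen's d = mean/sd = t/√n and the
Bonferroni-corrected α when run as a family (signed deviations are
tested, matching confidence intervals of both signs); model comparisons
use paired t-tests across participants on mean absolute hue errors and
exact-binomial sign tests across inducers; chroma errors are compared
after z-scoring measured and predicted chroma separately (sample-sd,
n−1 convention) so only hue-dependent variation counts, and the Hering
model is excluded from chroma comparisons. Histogram simulation draws
10⁵ wrapped-Gaussian samples per inducer by default; the response-noise
sd defaults to the circular sd of responses about each inducer's mean,
estimated from the data, with a config override.

The chroma-series analysis computes, per inducer hue, the circular mean
of matched hues across chroma levels as a reference line, and expresses
measured and predicted hues both as deviations from opponency and as
deviations from their respective reference; hues with a single chroma
level are excluded with a warning.

`AfterimageExperiment.fit()` packages all of this; identical data, seeds
and configuration yield identical result tables.

## Synthetic observers

The generator emulates the two response paradigms. Matching (9
alternatives): the true afterimage hue is the truth model's prediction
plus wrapped-Gaussian noise; the response is the comparison hue at
minimum circular distance (ties to the lower azimuth), with a skip
probability (default 0.02, the order of the reported skip rates).
Adjustment: the settled match is the prediction plus wrapped-Gaussian hue
noise and zero-truncated Gaussian chroma noise (the truncation biases
chroma upward near zero; negligible at the chroma levels used). Default
noise scales (σ_hue = 10°, σ_chroma = 5) are of the order of the
trial-to-trial variability of such adjustments. Noise lives in CIELUV
polar response coordinates — it models matching behaviour, not
physiology. What the generator does *not* emulate: adjustment dynamics,
re-adaptation during adjustment, inter-trial carry-over, participant
heterogeneity in adaptation strength (available as an option but off by
default), and individual cone fundamentals. Passing recovery tests
therefore show that the pipeline identifies the generating mechanism
under the assumed response model, not that human data are noise-free.

Model recovery at the suite's scale (72 inducers, σ_hue 10°, 10
repetitions, 100 seeds per truth model) is decisive in both directions by
the sign test at p < 0.01. Problem sizes throughout the tests (72-hue
circles, 3–5 simulated participants, 10⁴–10⁵ Monte-Carlo draws) were
chosen as the smallest that leave the checked statistics comfortably away
from their thresholds.

## Known limitations

- The link from CIE 1931 tristimulus to Stockman–Sharpe cones by a fixed
  3×3 matrix is the standard practical approximation; individual cone
  sensitivities are out of scope.
- CIECAM02 is represented by its adaptation transform, not the full
  appearance model.
- Munsell predictions are only as good as the supplied renotation table;
  the bundled synthetic lattice is for machinery validation, not
  colorimetry.
- The cone-adaptation chroma is reported in the background-L\* plane by
  projection; at the prediction's own luminance the chroma differs
  (retained in `native`).
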