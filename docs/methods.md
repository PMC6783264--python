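# Methods

This note documents the models, conventions and design choices behind
stimcal, in the order of the calibration/analysis pipeline.

## Pigment template

Opsin sensitivity curves are generated from λmax with the Govardovskii
et al. (2000) A1-retinal nomogram: an α band

S_α(λ) = 1 / (e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D),  x = λmax/λ,

with A = 69.7, B = 28, b = 0.922, C = −14.9, c = 1.104, D = 0.674 and
a = 0.8795 + 0.0459·e^{−(λmax−300)²/11940}, plus an optional β band —
a Gaussian at 189 + 0.315·λmax nm, width −40.5 + 0.195·λmax nm, amplitude
0.26 relative to the α peak.  The β band is what makes mid-wavelength
opsins sensitive to UV primaries and is on by default.  Coefficients are
stored as plain data (`stimcal.opsins.GOVARDOVSKII_A1`) so another
template family can be substituted without code changes; the choice of
nomogram is a configuration, and results that depend on the exact UV tail
(e.g. predicted cross-activation percentages) depend on it.

Curves are normalised to 1 at the grid point nearest λmax.  With the β
band the true maximum can sit one grid step short of λmax; the overshoot
is below 0.1% and intentional, so that S(λmax) = 1 exactly.

Default λmax values (all overridable, nm): mouse S 360, M 508, rod 498;
zebrafish UV 365, S 416, M 480, L 570, rod 501.  These are literature
conventions, not measurements.

## Wavelength grid and the rate sum

All spectra live on a common 300–720 nm grid at 1 nm.  The
photoisomerisation rate is a plain sum over grid points (no Δλ factor),
so the grid step is part of the unit convention: halving the step doubles
the number.  Rates meant to be compared across calibrations must use the
1-nm grid.  A unit test documents this ∝1/step behaviour explicitly.

## Calibration chain

Counts → power uses P_el(λ) = counts/Δt · S_cal(λ) · 10³ with Δt the
integration time (s) and S_cal the spectrometer's µJ/count factor,
linearly interpolated to the measurement grid; extrapolating S_cal
outside its calibrated range is refused rather than guessed.  Constants:
c = 299 792 458 m/s, h = 4.135667·10⁻¹⁵ eV·s, 1 J = 6.242·10¹⁸ eV.
Repeated reads are averaged *before* the Gaussian denoising fit; the fit
includes a constant baseline term (amplitude, centre, width, baseline all
reported), because dark counts give raw spectra a pedestal and omitting
the term biases the width.

### Effective-activation scalar

The activation spectrum S_act(λ) = S_opsin(λ)·S_LED(λ) (LED
peak-normalised) is summarised by the scalar Σ S_act / Σ S_LED — the
LED-shape-weighted mean opsin sensitivity.  For a narrow-band LED at λ₀
this reduces to S_opsin(λ₀), which is the property the summary is chosen
for; it is a declared convention, since only the product curve itself is
uniquely defined.

### Weighting switch

Summing P_E(λ)·A_collect·S_act(λ) applies the LED's normalised shape to a
flux that is already spectrally resolved — i.e. the LED spectrum enters
twice.  This "as printed" convention is the default because it matches
the calibration formula as published for this class of stimulator; the
radiometrically conventional alternative (weight by S_opsin alone) is
available as `weighting="opsin_only"`.  Every qualitative statement the
test suite makes (which LED drives which opsin, cross-activation
ordering) holds under both weightings; absolute rates differ by roughly
the LED's shape factor (~0.5–0.9 for the modelled band-pass LEDs).

## Silent substitution

For a dichromat the counterphase amplitude is I_G = I − I_UV·S_crossact
with S_crossact the ratio of the target opsin's rates under the two LEDs.
The general solver treats the transposed rate matrix as a linear map from
per-LED weights to per-opsin modulations and solves it by least squares;
square full-rank systems are exact (non-target opsin residuals < 10⁻⁹ of
the target modulation), rank-deficient ones warn, and inconsistent
targets raise with per-opsin residuals.  Weights are expressed in
linearised (post-LUT) intensity units; out-of-gamut solutions are flagged,
never silently clipped.

## Gamma LUT

The intensity curve y(x) (pixel value → measured rate) is fitted with
y = K0 + K1/(1 + e^{−(x−K2)/K3}), initialised at K0 = min y,
K1 = range y, K2 = x at half range, K3 = range x / 10, with K1, K3 > 0 so
only rising curves are accepted.  LUT entry v is the drive level whose
fitted intensity equals y(0) + v/255·(y(255) − y(0)), obtained from the
sigmoid's analytic inverse, rounded to 8 bits, forced monotone, endpoints
pinned to 0 and 255.  The `interp` mode inverts the raw measured points
by monotone piecewise-linear interpolation instead; it is the right
choice for noiseless or pre-smoothed series and for intensity curves
outside the sigmoid family (a 4-parameter sigmoid cannot represent a pure
power law to better than ~2% of range, while the interpolating inverse
linearises a 2.2-exponent curve to <0.5%, quantisation included).  The
LUT linearises whatever unit the intensity series carries (typically
P*/s); the unit is recorded in the file metadata, not assumed.

## Spatial resolution

Synthetic checkerboards are binary boards convolved with a Gaussian of σ
in µm (per-channel σ emulates chromatic defocus; the generator does not
model the DMD's mirror grid, fill factor, or diffraction).  Contrast is
I_max − I_min of a row profile taken through checker centres.  Edge
sharpness: the profile is peak-normalised, the first 50%-crossing located,
the position axis rescaled so the bright region's half-maximum width
equals 1, and the sigmoid above fitted to the rising segment
(trough → peak); 1/K3 on this normalised axis is the primary readout,
with the raw-µm-axis value also reported.  Edges steeper than the
sampling grid are capped at K3 = Δx/4 and flagged rather than returning
an unbounded number.  Pixel footprints take a scale in pixels per µm
(note that device documentation often quotes µm/pixel — invert first).

## Blanking/frame-beat simulation

The LED gate is ideal (zero rise/fall): on during the final 20% (default)
of each scan line.  The stimulus level is sampled-and-held at 60 Hz frame
boundaries, reproducing the unsynchronised line/frame beat; LED switching
transients and driver electronics are out of scope.  Default sampling is
100 kHz, ≥20 samples per line enforced.  Smoothing uses a box filter of
100 ms (≈ mouse cone integration time) computed over complete windows
only (cumulative-sum moving mean, O(n)); modulation depth is
(max − min)/mean of that edge-free smoothed trace.  Phase comparisons at
line boundaries carry a 10⁻⁹-of-a-line tolerance to absorb float
representation error, far below one sample.  When the line clock is an
exact multiple of the frame clock and the box spans an integer number of
lines the depth is numerically zero; incommensurate clocks leave a beat
(≈1.5% for 1.7 ms lines under default settings) that matches a
10×-oversampled brute-force computation to <1%.

## Response statistics

ΔR/R uses R = FA/FD with baseline R₀ the mean ratio over a caller-chosen
pre-stimulus window (default first second — the baseline definition is a
package convention).  Rare (<1%) non-positive donor samples are patched
by interpolation with a warning; more are an error.  Traces resample to
500 Hz by linear interpolation.  Detrending is a zero-phase (forward–
backward) Butterworth high-pass, order 2, 0.1 Hz, followed by z-scoring
against the 1–6 s interval; zero-phase filtering is chosen so detrending
cannot shift response timing.

Trial alignment interpolates each repetition onto a common time base
starting at marker + roi_line_index·scan_line_period, correcting the
within-frame offset of ROIs at different image lines; precision is set by
the markers, not the frame period (verified <2 ms phase SD on synthetic
sines).

Qi uses population variances (the ratio is convention-independent for
equal lengths) and the conventional 0.3 threshold as a flag, not a
filter.  SC takes "power" as squared DFT magnitude at the bin nearest the
fundamental, computed on the trial-averaged, mean-subtracted trace with
no window — hence the integer-cycle requirement; an amplitude mode exists
(sign identical, magnitude compressed).

### Synthetic trials

The generator produces sinusoidal responses with green/UV amplitudes
√(1±SC_true) (power ratio exactly realising SC_true) plus i.i.d. Gaussian
noise with variance σn² = σs²(1 − Qi)/(Qi − 1/R), which makes the
expected Qi of an average channel equal the target (σs² = 0.5 is the
mean per-channel signal variance).  Targets at or below the 1/R noise
floor, or above 1, are rejected.  What it does *not* emulate: Ca²⁺
indicator kinetics (responses are phase-locked sinusoids, not filtered
transients), photobleaching drift, correlated noise across time or
trials, or trial-to-trial amplitude adaptation — so recovery results
bound performance on idealised, not real, recordings.

## Problem sizes in tests

The test-suite and acceptance-script simulations use: 5 000 × 10 samples
for the pure-noise Qi check, 3 repetitions × 4 s × 500 Hz for the SC
recovery grid, 2–5 s of gated trace at 96–1000 kHz for the timing checks,
and 1024-pixel-wide checkerboards at 0.5 µm rendering pitch for the
spatial trends.  These sizes give Monte-Carlo error comfortably inside
each stated tolerance while keeping the whole suite in a few seconds.

## Known limitations

* Absolute photoisomerisation rates depend on the chosen pigment
  template and on measured LED spectra; with modelled Gaussian band-pass
  LEDs the numbers are illustrative, and only the qualitative
  LED-opsin separation pattern is asserted.
* The effective-activation scalar and the ΔR/R baseline are declared
  conventions (see above), not uniquely determined quantities.
* The blanking simulator models ideal gating only; measured switching
  transients would soften the beat slightly.
* Group-level statistics across cells (e.g. paired non-parametric tests
  of SC shifts) are left to general-purpose statistics packages.
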