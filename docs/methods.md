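# Methods

This note documents the models, parameter defaults and numerical choices
behind `thrombofret`, in the spirit of a package methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Signal model of the synthetic generator

The generator (`thrombofret.synth`) exists because multi-channel FRET
movies of platelet thrombi are rarely depositable; it renders the complete
forward model with exact ground truth so that segmentation, ratiometrics
and kinetics can be validated end to end.

### 1.1 Flow schedule and cGMP kinetics

A `FlowSchedule` is a list of half-open `(start, end)` on-intervals on a
regular frame grid (default 1 Hz; 0.2 Hz acquisitions are supported by
setting `dt`).  Region cGMP follows first-order relaxation

    dc/dt = (c_target(t) − c) / τ,

with `c_target = c_on` and `τ = tau_on` while flow is on, and
`c_target = c_base`, `τ = tau_off` after cessation.  Integration is exact
per frame (exponential update with piecewise-constant target), so the
traces are not subject to Euler stiffness; a warning is still emitted when
`dt ≥ τ/2` because the transient is then temporally under-resolved.

Defaults: `c_base = 0.1 µM`, `c_on_core = 0.8 µM`,
`c_on_periphery = 4 µM`, `tau_on = 4 s`, `tau_off = 5 s`.  The periphery
level deliberately exceeds the sensor's 3 µM quantification bound so that
saturation handling is exercised; the core level stays in the
well-quantifiable range.  With `tau_off = 5 s` the trace re-enters a ±5 %
band of the step within 3τ = 15 s, comfortably inside the ~20 s return
to baseline that flow-off transients show.  In-vivo absolute
periphery/core concentrations are not measured quantities; these defaults
are plausible, not calibrated to tissue.

### 1.2 Geometry and brightness

The thrombus is a centered disc whose area follows a configurable
growth/dissolution profile (`make_area_profile`: linear or logistic
transitions between knots, unimodal by construction).  An outer annulus of
relative width 0.2 of the current radius is the periphery — the minimal
geometry that exercises the core/periphery logic.

Brightness across the thrombus is the projected thickness of a
hemispherical cap:

    S(d) = A · sqrt(1 − (d/r)²),

i.e. summed CFP+YFP emission = background + S(d).  This is the physically
natural profile for epifluorescence of a mounded platelet aggregate and it
makes the *intensity-erosion* core criterion meaningful: the 20 %-above-
threshold contour sits strictly inside the rim.

The amplitude default `A = 140` counts over a summed background of
2 × 150 counts is chosen so that the forward model and the segmentation
convention are mutually consistent: solving

    core_factor · T = bg_sum + A · sqrt(1 − (1 − w)²)

for the whole-thrombus threshold `T` (with `core_factor = 1.2`, annulus
fraction `w = 0.2`) gives `T = 320` counts, at which (i) the whole-mask
contour cuts the dome at ≈ 0.99 r and (ii) the 1.2 T core contour cuts it
at exactly 0.8 r — the geometric core/periphery boundary.
`consistent_threshold()` returns this matched manual threshold; the
shallow dome contrast relative to background mirrors real epifluorescence
data, where a 20 % intensity criterion erodes a meaningful distance only
because profiles are shallow.  Otsu thresholding remains available for
data without a known forward model.

Default frame geometry is 192 × 192 px at 1 µm/px for flow-chamber
scenarios (preformed thrombus, area 5000 µm², radius ≈ 40 px).  The
growth/dissolution scenario defaults to 160 × 160 px at 0.5 µm/px — the
realistic 40× intravital configuration — because at 1 µm/px the
rasterization of a dissolving ~800 µm² thrombus (16 px radius) alone
contributes ~6 % area error, obscuring what the pipeline itself does.

### 1.3 Sensor mapping and channel rendering

The calibration is a Hill model

    R(c) = R_min + (R_max − R_min) · cⁿ / (EC₅₀ⁿ + cⁿ)

with defaults `EC₅₀ = 0.5 µM`, `n = 1`, `R_min = 1.0`, `R_max = 2.0`,
`c_sat = 3 µM`.  cGi500-class sensors do not publish a single canonical
constant set; all four parameters are configuration and are serialized
with every result, and inverse-calibrated concentrations are therefore
model-dependent by construction.

Per pixel, the expected emission above background is split between the
two channels by photon redistribution at fixed total:

    CFP = S(d) · R/(1+R),     YFP = S(d) / (1+R),     R = R(c).

cGMP binding lowers FRET, so CFP rises while YFP falls (anticorrelated
channels, as a genuine FRET change must show), the total donor+acceptor
emission is conserved, and — the property the whole validation rests on —
the pixelwise CFP/YFP ratio equals the calibration curve exactly in
noise-free rendering, making the Hill inverse an exact decoder of the
forward model below saturation.  A multiplicative channel split of the
form `C₀(1+δθ)` / `Y₀(1−δθ)` was considered and rejected: its ratio is a
Möbius, not Hill, function of occupancy, so no Hill-model inverse could
recover the ground-truth concentration even in principle.

### 1.4 Ca²⁺ coupling and Fura-2 channels

The Ca²⁺ signal is driven by the cGMP excursion normalized to the largest
configured on-level, delayed by `lag` (default 2 s) and sign-coupled
(default anticorrelated: the pre-activated thrombus rests at `ca_high`
and Ca²⁺ falls when cGMP rises — cGMP changes precede Ca²⁺ changes).
Fura-2 channels are rendered by the same photon-redistribution scheme
with the F340/F380 ratio affine in normalized Ca²⁺ between 0.5 and 2.0.
The Ca readout is linear in the drive, while the cGMP readout saturates;
this waveform asymmetry is visible downstream (§3.3).

### 1.5 Noise

Pixel values are Poisson draws of the expected counts (shot noise) plus
additive Gaussian read noise (SD 3 counts), rounded, clipped to uint16
(clip events logged).  Background default is 150 counts per channel
(tissue autofluorescence plus offset).  All draws come from one
`numpy` generator seeded by `NoiseModel.seed`: identical seeds give
bit-identical stacks and ground truth.  With noise disabled the renderer
returns float64 expectations, which is what the exactness tests use.

Not modeled (out of scope): photobleaching, drift/motion, vessel-wall
fluorescence, flowing-platelet streaks, embolization.  Passing tests
therefore demonstrate correctness of the analysis on an idealized,
noise-faithful forward model — not robustness to motion artifacts or
focal drift in real recordings.

## 2. Segmentation

The whole thrombus is segmented per frame from the Gaussian-blurred
(σ = 2 px, reflective boundaries) CFP+YFP sum by a count threshold; the
largest 8-connected component is kept (a single injury site produces one
thrombus; this suppresses speckle), and empty frames are flagged, never
dropped.  The core is `blurred ≥ core_factor × threshold`
(`core_factor = 1.2`) intersected with the whole mask — the intensity
reading of "eroded by a distance defined as ~20 % higher than the
threshold intensity" — and the periphery is the exact set complement
within the whole mask, so `|core| + |periphery| = |whole|` per frame by
construction.  A morphological-erosion core (`core_method="erosion"`) is
available for comparison.  The intensity criterion is applied to the
blurred image (the same image that defines the mask).  Manual thresholds
always win over Otsu and are logged.

## 3. Ratiometrics and kinetics

### 3.1 Traces, normalization, exclusion

Background is the per-frame median of pixels outside the whole mask
dilated by 5 px (or the mean of a user rectangle that must not intersect
the thrombus).  Region traces are means of background-corrected pixels
inside the dynamic masks; R = F480/F535; ΔR/R is normalized to the mean
over a baseline window (default: the 10 valid frames before the first
flow-on event; ≥ 3 valid frames required).  The SNR of a trace is defined
as the peak absolute deviation of R from the baseline mean within the
response window divided by the baseline SD (the literature states the 2.5
cutoff but not the formula; this definition is recorded in output
metadata).  Zero-variance baselines give SNR = ∞ and are retained with a
warning.  A separate *responder* criterion — |ΔR/R| above 3 baseline SDs
for at least 5 consecutive response frames — is used for the null
(flow-off-only) scenario, because the plain maximum over a 60-frame
window exceeds 2.5–3 SDs by chance alone ~15 % of the time.

### 3.2 Inverse calibration

The Hill inverse is algebraic and exact below saturation (round-trip to
1e−9).  Where the inferred concentration reaches `c_sat` (including
ratios at or above `R_max`), the sensor cannot be quantified: the
reported value is the lower bound `c_sat` with `saturated = True`.
Ratios outside `[R_min, R_max]` beyond tolerance are clipped with a
warning.

### 3.3 Kinetics

Growth metrics: `t_max` is the first global maximum (ties → earliest
frame); half-dissolution time is the first crossing of 50 % of the
maximum after the peak, linearly interpolated between bracketing frames,
reported as censored when unreached (never imputed); AUC is trapezoidal
(exact for piecewise-linear profiles) over area minus the pre-injury
baseline (default 0, the laser-injury case), with the unsubtracted
integral reported alongside.  Peak areas subtract the linear chord
between user-chosen borders, so purely linear drifts integrate to zero.

Lead-lag uses normalized cross-correlation of first-differenced traces
(raw-trace correlation would be drift-dominated), optional sign inversion
for anticorrelated pairs, parabolic sub-frame refinement, and a
low-confidence flag below peak correlation 0.5.  An optional Gaussian
pre-smoothing (the pipeline uses σ = 1 frame) suppresses the uncorrelated
shot-noise floor of the derivative correlation without moving the peak.
The estimator is a quantitative addition over visual trace comparison and
is labeled as such in output.  On the generator's own traces the
configured 2 s lag is recovered exactly; through the full imaging
pipeline the estimate is biased ~0.5 s further negative because sensor
saturation compresses the cGMP waveform while the Ca coupling is linear —
a property of the physics, not of the estimator.

Baseline recovery after flow cessation is measured as the time until the
ΔR/R trace re-enters *and stays* within ±0.05 of zero (5 % of the
pre-stimulus baseline ratio).

## 4. Statistics

Welch's t-test replaces Student's when a two-sided F-test of variance
equality rejects at α = 0.05 (the selection criterion is unstated in the
assay conventions; ours is recorded in every result).  Bleeding-time-style
observations stopped at a cap are kept as ties at the cap (midranks) —
rank-preserving and faithful to the stopping rule — rather than
discarded; Mann–Whitney p-values are exact by enumeration for
n_a + n_b ≤ 12 without ties, otherwise tie-corrected asymptotic.  ANOVA +
Tukey HSD uses statsmodels; note that a Tukey-adjusted p can be *smaller*
than a plain two-group t-test p because Tukey pools variance across all
groups (N − k df) — the monotonicity guarantee holds only against the
unadjusted comparison on the same pooled-variance basis, and the test
suite asserts exactly that form.  Type-I calibration of both two-sample
tests is verified by a seeded 2000-replicate null simulation (rejection
rate within [0.035, 0.065] at α = 0.05).

## 5. Determinism, problem sizes, limitations

Every stochastic component is seeded; pipeline runs with identical
configuration and seed produce byte-identical reports (verified by the
SHA-256 manifest).  The validation suite uses desk-scale problem sizes
chosen to keep the full run in tens of seconds while leaving the
statistics well-determined: 240-frame 192² movies for flow scenarios,
300-frame 256² for the segmentation fidelity check, 300-frame 160² at
0.5 µm/px for growth recovery.

Known limitations: no motion correction, spectral bleed-through
correction, or photobleaching compensation; single-thrombus assumption
(largest component); disc geometry in the generator cannot probe
elongated or multi-lobed thrombi; inverse-calibrated concentrations are
conditional on the configured sensor constants; Fura-2 ratios are not
converted to absolute [Ca²⁺].
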