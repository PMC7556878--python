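# Methods

This note documents the models and procedures implemented in vasopipe,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data validation does and does
not demonstrate.

## Vessel diameter

### FWHM (pial arterioles, capillaries)

For a vessel imaged side-on, intensity along a short segment (1–3 µm,
clamped with a warning outside that range) of the vessel's long axis is
averaged to form one cross-axis profile per frame. The diameter is the
full width at half maximum of that profile:

- baseline = median of the outer 10% of samples at each end;
- half-maximum level = baseline + 0.5·(peak − baseline);
- crossings located by linear interpolation between samples, taking the
  pair bracketing and nearest to the global peak (robust to side lobes
  from neighboring vessels).

A profile whose peak does not rise above the baseline by more than the
noise floor (5× the robust SD of the outer samples) raises a no-vessel
error; a missing crossing on one side raises an edge-truncation error.
Frames that fail become NaN in the diameter trace and are later
repaired by the despiker. Linear interpolation on a curved flank has a
bias below |p″|h²/(8|p′|) ≈ 0.1 px for the profiles of interest; the
dominant discretization effect is peak sampling for sub-pixel-centered
narrow Gaussian profiles (≤ 0.15 px), both well inside the half-pixel
accuracy the test suite enforces.

### TiRS (penetrating arterioles)

Penetrating-arteriole cross-sections are not circular and change shape
when they dilate, so the cross-sectional area is measured by
Thresholding in Radon Space — effectively a half-maximum width
measurement along every projection angle:

1. The ROI (a square enclosing the lumen) is background-subtracted
   using the median of its border ring. The border, not the full-ROI
   median, because the vessel occupies a sizeable fraction of the ROI
   and pulls the full median up, leaving a pedestal under every
   projection that biases fitted widths low (measured: −6% at a 25%
   fill fraction).
2. Radon transform over 0–179° in 1° steps (scikit-image).
3. Each projection is thresholded at t₁ = 0.5 of its own peak. A
   convex (elliptical) lumen projects to a scaled semicircle at every
   angle, so the raw projection is fit by least squares with that
   profile (amplitude, center, support half-width, and an optional
   Gaussian blur absorbing the point-spread function), and the strip is
   taken analytically on the fitted, deblurred profile:
   s₀ ± w·√(1 − t₁²). Fitting the whole projection instead of
   interpolating two noisy flank samples keeps the strip unbiased down
   to low SNR; a projection whose smoothed peak stays below 5× the
   projection noise floor is dropped (and its strip interpolated over
   angle).
4. Back to image space through the support function: the strip edges
   over all angles are the 360° support samples of the lumen shrunk by
   √(1 − t₁²). The enclosed area follows from the exact support
   integral A = ½∮(h² − h′²)dθ, evaluated by linearizing about an
   ellipse reference: A ≈ A(h̄) + ∮(h̄ + h̄″)(ĥ − h̄)dθ. The reference
   ellipse is cross-fit on interleaved 45° angle blocks and the linear
   correction evaluated on the held-out blocks (averaged over the two
   splits; a full-sample fit is the fallback when a split fit is
   degenerate).
5. The area is divided by 1 − t₁², which undoes the half-maximum
   shrinkage exactly for elliptical cross-sections, and converted to
   the equivalent-circle diameter D = 2·√(A/π) for comparison with
   pial FWHM diameters. (The compact notation "D = 2A/π" sometimes
   written for this conversion is dimensionally inconsistent; the
   equivalent-circle diameter is the quantity meant.)

Why the support-integral evaluation rather than a pixel count of the
re-thresholded back-projection: any area functional is quadratic in the
measured boundary, so independent per-angle noise enters with a
systematic sign. A strict strip intersection is a minimum statistic and
loses 15–30% of the area at SNR 3 for small lumens; a direct quadratic
evaluation of noisy support samples is biased by the noise variance,
which cannot be estimated from the high-harmonic tail because per-angle
errors are correlated over ~8–12° of angle (neighboring projections
share pixels). Linearizing about a low-degree-of-freedom reference that
is fit on *different* angles than the correction term makes the
estimator linear in the noise, which removes the bias; the residual
shape error is second-order in the reference mismatch and vanishes for
elliptical lumens. Validated at SNR 3 on rendered phantoms: disk areas
(r = 5–20 px) within ~3% (movie-median), ellipse areas within ~4% at
every orientation, rotation spread < 3 points. Per-frame estimates at
r = 5 px, SNR 3 have a right-skewed error distribution (rare fit
blow-ups); the movie-level median is the recommended summary, mirroring
the median filtering applied to diameter traces.

Both thresholds and the angle step are configuration; t₁ = 0.5 makes
the method a true FWHM-at-every-angle.

### Trace conditioning

Frames whose diameter changes from the last accepted frame faster than
16 µm/s are tagged as motion artifacts and replaced by linear
interpolation between the nearest untagged neighbors (nearest-value
extension at the trace ends). Measuring the rate against the last
*accepted* frame tags every frame of a multi-frame spike, whose
internal frame-to-frame differences can be small. Conditioned traces
then receive a five-point running median with symmetrically shrinking
edge windows (monotone traces pass unchanged). Despiking is idempotent
on traces whose underlying signal is below threshold; the median filter
is idempotent on piecewise-constant traces.

## Linescan velocimetry

Rows are successive scan lines (time), columns position along the scan
(space) — the convention is written into the file metadata. Each window
of 128 lines (50% overlap) is mean-subtracted and Radon-transformed
over 1–179°; the angle maximizing the projection variance is refined on
a 0.1° grid within ±1.5°. With tan(θ) the streak slope in px/line,

    v = pixel_size · line_rate · tan(θ),

positive when cells move toward increasing column index. Window length
128 at the default calibration keeps 0.2 mm/s streaks traversing ≥ 25 px
per window; the 0.1° fine step keeps the tan() discretization error
below ~2% at both ends of the 0.2–10 mm/s range. Windows whose best
angle is within 1° of ±90° from the time axis (cells crossing the whole
scan within a line) are unresolvable and carry velocity NaN; vertical
streaks (θ = 0) are genuinely stationary cells, v = 0. The separability
quality metric is (peak variance − mean variance)/peak variance ∈ [0, 1);
clean streaks score ≳ 0.9, pure noise ≲ 0.45, and the quality filter
defaults to a 0.5 floor.

## Locomotion analysis

The encoder velocity is zero-phase low-pass filtered (10 Hz, 5th-order
Butterworth) and the absolute central-difference acceleration is
thresholded at 10⁻⁵ cm/s². The threshold is applied in cm/s² at any
sample rate and is exposed as configuration because its effective
sensitivity depends on the encoder rate. Moving runs separated by less
than 1 s are merged into one event (encoder jitter would otherwise
split bouts).

Two properties of this binarization matter and are handled explicitly:

- On a silent encoder the zero-phase filter's settling tail smears the
  mask ~0.5 s beyond each bout on both sides, so event boundaries are
  refined to the first/last crossing of 10% of the event's peak
  filtered speed (configurable; disable with `refine_fraction=None`).
  With refinement, programmed bout onsets are recovered within ±0.1 s.
- Acceleration is zero on a constant-velocity plateau, so the mask
  interior relies on the stride-frequency velocity fluctuations that
  real running always carries (and that the synthetic generator
  emulates).

Stationary periods are maximal still intervals trimmed by 2 s after the
preceding event and 1 s before the next, dropped below a 1 s minimum.
The basal value of any signal is its mean over stationary periods.
Qualifying LTA events last > 5 s with ≥ 2 s of preceding quiet; the LTA
window is −2…+10 s, normalized by the vehicle-condition basal diameter
of the same vessel. Evoked amplitude is the mean of (LTA − 1) over
3–4 s after onset, in percent.

Onset time is the baseline intercept of a least-squares line through
the LTA samples between 20% and 80% of peak dilation (pre-onset
baseline = mean over −2…0 s). The peak is taken from a 5-sample
smoothed copy and the band restricted to the contiguous rising segment;
without these, the noisy raw peak shifts the band and plateau samples
dipping into it flatten the line, dragging the estimate far negative.
The estimator is exact on linear ramps of any duration ≥ 4 frames and
unbiased ±0.2 s under modest noise; on smooth sigmoid responses the
line intercept systematically leads the true onset (the 20–80% chord of
a curved rise extrapolates early) — a property of the method, reported
as such.

The locomotion-induced dilation metric takes the treatment
pre-locomotion baseline b and the locomotion-evoked level e, both as
fractions of the *vehicle* basal diameter, and reports
(e − b)·100 — the change from the treatment baseline expressed as a
percentage of the vehicle basal. The identity
metric + (b − 1)·100 = (e − 1)·100 ties it to the
relative-to-vehicle-baseline reporting convention. (The two printed
convention checks: b = 0.90, e = 1.05 → 15%; b = 1.10, e = 1.15 → 5%.)

## LFP band power

The LFP is the raw trace band-passed 10–100 Hz (order 4, zero-phase)
with a 60 Hz IIR notch. Gamma power is the variance of the 40–100 Hz
band-passed, notched signal over the masked samples, separately for
stationary ("basal") and locomotion states; variance and integrated PSD
agree by Parseval, and variance is used. The notch quality factor is
45: the mains line has no printed bandwidth, and Q = 45 keeps the
double-pass (zero-phase) skirt's bite out of a 70 Hz in-band tone at
~1% while still suppressing 60 Hz by ~55 dB. Spectra are averaged
modified periodograms (Hann, 1 s windows, 50% overlap) computed per
contiguous state run and combined with run-length weights; state
spectra are normalized pointwise by a reference (vehicle stationary)
spectrum.

## Fiber photometry

Channels: green (GCaMP or GFP) and red (TRITC dextran = cerebral blood
volume), 1.2 kHz.

1. **Bleach fit.** The channel is zero-phase low-passed below 0.1 Hz;
   locomotion periods and the following 15 s are excluded (they carry
   behavior-evoked blood-volume transients, not decay — this exclusion
   is what makes the decay separable at all, since any stationary
   signal with power below 0.1 Hz would be indistinguishable from
   bleaching); a sum of two exponentials
   a₁·exp(−t/τ₁) + a₂·exp(−t/τ₂) + c is fit by nonlinear least
   squares, multi-started over τ ∈ {30, 300, 3000} s pairs because
   two-exponential fits are initialization-sensitive. If no two-term
   start converges, a single exponential is used and flagged. The fit
   runs on a ~12 Hz decimated copy (the decay lives far below 0.1 Hz;
   plain-stride decimation aliases only broadband noise, which the
   0.1 Hz filter removes), at ≥ 60 s of quiet data required. Recovering
   τ₂ = 1000 s against the constant offset needs sessions of a few
   thousand seconds — the ~2 h sessions the generator defaults emulate.
2. **Debleach.** The fitted curve (offset included — scale is
   irrelevant downstream) is subtracted and the residual low-passed
   below 1 Hz. Min–max scaling to [0, 1] is available for display and
   cross-animal comparability, but the attenuation stage consumes the
   *unscaled* debleached channels: min–max rescaling destroys the
   amplitude ratio between channels, making the attenuation coefficient
   unidentifiable (a GFP session's rescaled green-on-red slope is ≈ −1
   regardless of the true coefficient).
3. **Attenuation.** On GFP control animals (no activity-dependent green
   signal) the OLS slope of debleached green on debleached red measures
   hemoglobin absorption; the model coefficient is the mean of the
   per-animal slopes, kept signed (negative: more blood, less green
   light), so the correction `green − coeff·red` adds the absorbed
   fluorescence back.
4. **Correction.** The corrected green channel is band-passed
   0.001–1 Hz (order 4, zero-phase; the 0.001 Hz corner is implemented
   by removing a drift estimated on a ~12 Hz decimated copy, since a
   direct IIR at 10⁻⁶ of the sample rate is numerically fragile) and
   z-scored over the session (mean 0, SD 1 to 10⁻⁶). The red channel
   is band-passed and z-scored the same way. On a 20-minute record the
   0.001 Hz stage spans only ~1.2 corner periods and visibly perturbs
   the slowest components; at the 2 h session scale it is benign.
5. **Events.** Locomotion events ≥ 5 s with ≥ 5 s of preceding quiet
   (evaluated against the preceding event boundary, because the
   binarized mask is smeared around every bout) are grouped into
   duration bins [5–10), [10–15), [15–30), [30–45), [45, ∞) s; the mean
   over the 5 s pre-event window is subtracted per event and bin-wise
   averages of both z-signals computed.

End-to-end at SNR 5 with bleaching and attenuation on, the corrected
z-signal correlates > 0.99 with the programmed calcium; corrected GFP
sessions retain |r| < 0.05 with the blood-volume channel.

## Statistics

Vehicle-vs-treatment diameter comparisons use the mixed model
ΔD[n,a] = γ + β_a with a per-animal random intercept β_a, fit by REML
(statsmodels MixedLM). ΔD is by default the normalized change
(treatment/vehicle − 1), matching percent-change reporting; raw µm
differences are available. Significance of γ uses a t reference with
n_animals − 1 degrees of freedom — the between-within convention for a
between-animal effect; a plain normal approximation is anti-conservative
with half a dozen animals (simulated type-I ≈ 5.0% with the t
reference at 6 animals × 5 vessels). Zero-variance cohorts (e.g. the
all-zero null) short-circuit to γ = value, p = 1 or 0. A single animal
raises a degenerate-design error pointing to a one-sample test.

The scatter-figure variant adds the vehicle diameter as a covariate:
ΔD[n,a] = γ + β_a + α·D[n] with a single shared slope α — a per-vessel
coefficient would be unidentifiable with one observation per vessel.
Noiseless data lying exactly on a line short-circuit to the OLS
solution (REML is singular there).

Bonferroni correction is min(1, p·n_groups) — values above 1 round
down to 1. Gamma-power comparisons between conditions use the paired
t-test on per-animal values (zero-variance differences flagged
degenerate); cross-condition relationships use OLS with two-point fits
flagged (R² = 1, p undefined).

## Synthetic data: what it emulates, and what it does not

Defaults mirror the recording conditions: vessel movies at 8 Hz,
linescans at 2 kHz line rate with 0.5 µm pixels, encoder at 1 kHz (the
encoder rate is not specified by the protocol; 1 kHz is configurable),
LFP at 20 kHz, photometry at 1.2 kHz, cohorts of 6 animals × 5 vessels
with fractional effects and σ_animal = σ_resid = 0.05.

- Movies render a box lumen (pial; analytically convolved with a
  Gaussian PSF, default σ = 1 px, as a difference of error functions)
  or a supersampled anti-aliased ellipse indicator (penetrating),
  over a dim background. Noise is Poisson photon noise at a detector
  gain of one count per intensity unit (raised if the requested SNR
  demands it) plus Gaussian read noise filling the remaining background
  variance; SNR = (peak − background)/background-noise SD. At low SNR
  this is read-noise dominated, as PMT images are at these light
  levels.
- Linescans place dark Gaussian streaks (RBCs absorb, plasma
  fluoresces) at programmed slopes on a periodic domain, with random
  particle positions (regular spacing would alias at steep slopes).
- Encoder traces are exactly zero at rest (an encoder emits no ticks)
  and carry stride-frequency velocity fluctuations during bouts —
  without them an acceleration threshold would only see bout edges.
  `noise_sd` adds measurement noise during movement only.
- LFP is pink noise band-limited below the gamma band plus a 40–100 Hz
  component whose variance is multiplied by the gamma gain during
  bouts, a small broadband sensor floor, and an optional mains line.
  Keeping the background out of the gamma band makes the programmed
  gain recoverable as a power ratio to within ~2%; a full-band 1/f
  background would dilute it.
- Photometry: green = bleach(t) + calcium − c·CBV + noise,
  red = bleach_red(t) + CBV + noise, with the double-exponential decay
  shared (red scaled by 0.7, emulating TRITC excretion). A constant
  calcium trace makes a GFP control session.
- Cohorts draw β_a ~ N(0, σ_animal²) and per-vessel residuals, apply
  ΔD = γ + β_a + ε on the fractional scale, and attach the true
  per-animal effects.

Every generator is a pure function of its arguments including the seed.

Not emulated: vascular trees/branching and 3-D geometry, x–y motion of
raw movies (stacks are assumed registered), slow drifts of imaging
depth, hematocrit/flux variation in linescans, non-stationary gamma
bursts, whisking/fidgeting behavior distinct from locomotion, and any
specific in-vivo effect size. Passing tests therefore demonstrate that
the implementations recover known ground truth under the recording
statistics they emulate — not that any biological effect size is
reproduced, which would require the original raw recordings.

## Problem sizes used in the verification suite

Shape oracles run at SNR 3 with movie-median summaries (64 frames at
r = 5 px down to 12 at r = 20 px; 48 frames per ellipse orientation);
velocimetry at 640 lines per scan; gamma-gain recovery over 20 seeds of
40 s recordings; photometry recovery on one 7200 s session plus three
GFP controls; mixed-model coverage over 200 cohorts and type-I error
over 500 null cohorts. These sizes keep the whole suite within a few
minutes on one core while leaving the Monte-Carlo error of each check
well inside its tolerance.
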