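# vasopipe

Analysis pipeline relating local neural activity to cerebral arteriole
diameter in awake, head-fixed mice. It implements the complete
measurement chain used in chemogenetic / pharmacological studies of
neurovascular coupling:

- **Vessel diameter** from two-photon movies: full-width-at-half-maximum
  (FWHM) for pial arterioles and capillaries, and Thresholding in Radon
  Space (TiRS) for the non-circular cross-sections of penetrating
  arterioles, with the equivalent-circle conversion `D = 2*sqrt(A/pi)`,
  motion-artifact despiking (>16 µm/s) and five-point median filtering.
- **Red-blood-cell velocimetry** from linescan space–time images via the
  Radon transform (streak angle → velocity).
- **Locomotion analysis**: 10 Hz zero-phase filtering and acceleration
  thresholding of the treadmill encoder, stationary-period segmentation
  (2 s / 1 s buffers), qualifying-event extraction (>5 s with ≥2 s prior
  quiet), locomotion-triggered averages (LTA) normalized to the
  vehicle-condition basal diameter, evoked amplitude (3–4 s window),
  20–80% rise-line onset times, and the locomotion-induced dilation
  metric.
- **LFP band power**: 10–100 Hz order-4 zero-phase band-pass with 60 Hz
  notch; gamma-band (40–100 Hz) power split by behavioral state;
  state-resolved spectra normalized to a vehicle reference.
- **Fiber-photometry correction**: double-exponential photobleaching
  fit (locomotion + 15 s excluded), hemoglobin-absorption correction of
  the green channel using the blood-volume (TRITC) channel with a
  coefficient calibrated on GFP control animals, 0.001–1 Hz band-pass,
  z-scoring, and duration-binned locomotion-evoked averages.
- **Statistics**: the linear mixed-effects treatment comparison
  `ΔD[n,a] = γ + β_a (+ α·D[n])` with a per-animal random intercept,
  Bonferroni correction with the round-down-to-1 rule, paired t-tests
  and cross-condition regression.

Every input the pipeline consumes can be generated by the built-in
synthetic module (`vasopipe.synth`) with known ground truth — vessel
movies with programmed lumen geometry and Poisson/read noise, linescans
with programmed velocity, encoder traces with programmed bouts, LFP with
state-dependent gamma power, photometry with programmed bleaching and
attenuation, and multi-animal diameter cohorts — so every stage is
verifiable without any recordings.

## Worked example

Run the end-to-end synthetic demonstration (generates all inputs, runs
every stage, writes TIFF/CSV/JSON intermediates and one report):

```bash
vasopipe demo --seed 1 --outdir demo_out
```

prints (abridged):

```json
{
  "basal_um": 19.86747183346473,
  "evoked_amplitude_pct": 14.536174353232001,
  "onset_time_s": -0.7802398946575685,
  "tirs_area_error_pct": -3.417815866687257,
  "velocity_mm_s": 1.9969538555995503,
  "gamma_power_ratio": 2.0168946032988924,
  "attenuation_coeff": -0.29685939621439367,
  "gamma_hat": -0.2373931089932703,
  "p_corrected": 0.0030785396099520853,
  "metric_examples_pct": {
    "constricted_baseline_example_pct": 15.000000000000002,
    "dilated_baseline_example_pct": 4.999999999999982
  }
}
```

Reading the numbers: the FWHM stage recovers the programmed 20 µm basal
diameter (19.87 µm) and most of the programmed 15% locomotion-evoked
dilation (14.5%); TiRS measures the elliptical penetrating-arteriole
cross-section within 3.4% of its analytic area; the velocimetry stage
recovers the programmed 2 mm/s RBC velocity; the gamma-band power ratio
recovers the programmed 2× locomotion gain; the photometry stage
recovers the programmed hemoglobin-attenuation coefficient (−0.297 vs
−0.3); and the mixed model estimates the programmed treatment effect
γ = −0.25 as −0.237 with a Bonferroni-corrected p of 0.003 over 6
groups. The two `metric_examples_pct` values are the convention check
for the locomotion-induced dilation metric: a vessel constricted to 90%
of vehicle basal that dilates to 105% during locomotion has a 15%
locomotion-induced dilation, and one dilated to 110% that reaches 115%
has 5%. The onset time is the 20–80% rise-line intercept, which leads
the true onset on smooth sigmoid responses (see `docs/methods.md`).

Each stage is also exposed as a subcommand over files
(`vasopipe simulate | diameter | velocity | behavior | ephys |
photometry | stats`); run any of them with `--help`.

## Library use

```python
import numpy as np
from vasopipe import synth
from vasopipe.diameter import fwhm_diameter_trace, despike_trace, median_filter_trace

movie = synth.make_pial_movie(np.full(160, 20.0), pixel_size=0.5, snr=10, seed=0)
trace = median_filter_trace(despike_trace(fwhm_diameter_trace(movie)))
print(trace.values.mean())   # ~20.0 (µm)
```

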