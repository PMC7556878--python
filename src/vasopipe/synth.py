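"""Synthetic raw-data generators with attached ground truth.

Every input the pipeline consumes can be generated here with known ground
truth, emulating the statistical structure of awake-mouse recordings:

* vessel movies (~8 Hz) of a straight pial arteriole or an elliptical
  penetrating-arteriole cross-section, rendered through a Gaussian
  point-spread function with Poisson photon noise plus Gaussian read
  noise;
* linescan space-time images with dark RBC streaks at a programmed
  velocity;
* treadmill-encoder velocity traces with discrete locomotion bouts
  (the encoder reads exactly zero at rest; running carries
  stride-frequency velocity fluctuations, as real treadmill running is
  never constant-velocity — an acceleration-threshold binarization would
  otherwise only see the bout edges);
* 20 kHz electrophysiology with state-dependent gamma-band power;
* 1.2 kHz two-channel photometry with double-exponential photobleaching
  and hemoglobin attenuation of the green channel;
* multi-animal vehicle/treatment diameter cohorts with animal-level
  random effects.

Determinism: every generator is a pure function of its arguments
including ``seed``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .behavior import LocomotionTrace
from .diameter import VesselMovie
from .ephys import LFPRecording
from .errors import InvalidParameterError
from .linescan import LinescanImage
from .photometry import BleachModel, PhotometrySession

__all__ = [
    "make_pial_movie",
    "make_penetrating_movie",
    "make_linescan",
    "make_locomotion_trace",
    "make_lfp",
    "make_photometry",
    "make_cohort",
]

_BACKGROUND = 10.0
_PEAK = 100.0


def _add_noise(clean: np.ndarray, snr: float, rng: np.random.Generator,
               background: float = _BACKGROUND, peak: float = _PEAK) -> np.ndarray:
    """Poisson photon noise plus Gaussian read noise at a requested SNR.

    SNR is defined as (peak - background) / SD of the background noise.
    The detector gain is one count per intensity unit (raised when the
    requested SNR is so high that background shot noise alone would
    exceed the noise budget); Gaussian read noise makes up the remainder
    of the background variance.  At low SNR this is read-noise dominated,
    as a PMT image at these light levels is.
    """
    if not np.isfinite(snr):
        return clean
    if snr <= 0:
        raise InvalidParameterError("snr must be > 0")
    sigma_bg = (peak - background) / snr
    gain = max(1.0, 2.0 * background / sigma_bg**2)
    read_var = sigma_bg**2 - background / gain
    shot = rng.poisson(np.clip(clean, 0, None) * gain) / gain
    out = shot
    if read_var > 0:
        out = out + rng.normal(0.0, math.sqrt(read_var), clean.shape)
    return out


# ---------------------------------------------------------------------------
# vessel movies
# ---------------------------------------------------------------------------

def make_pial_movie(
    diameter_trace: np.ndarray,
    pixel_size: float = 0.5,
    frame_rate: float = 8.0,
    snr: float = 10.0,
    seed: int = 0,
    psf_sigma_px: float = 1.0,
    image_size: tuple[int, int] = (64, 96),
) -> VesselMovie:
    """Movie of a straight, vertical pial vessel of programmed diameter.

    Each frame shows a bright vessel of the per-frame width from
    ``diameter_trace`` (um) on a dark background: a box lumen profile
    convolved with a Gaussian PSF (rendered analytically as a difference
    of error functions), plus Poisson-Gaussian noise at the requested
    SNR.  The vessel axis runs along image rows; ``axis_line`` is set
    accordingly and the ground truth carries the diameter trace.
    """
    diameter_trace = np.asarray(diameter_trace, dtype=float)
    if diameter_trace.ndim != 1 or diameter_trace.size == 0:
        raise InvalidParameterError("diameter_trace must be a non-empty 1-D array")
    if np.any(diameter_trace <= 0):
        raise InvalidParameterError("diameters must be > 0")
    if pixel_size <= 0 or frame_rate <= 0:
        raise InvalidParameterError("pixel_size and frame_rate must be > 0")

    rng = np.random.default_rng(seed)
    h, w = image_size
    center = (w - 1) / 2.0
    cols = np.arange(w, dtype=float)
    s2 = psf_sigma_px * math.sqrt(2.0)

    frames = np.empty((diameter_trace.size, h, w))
    for i, d_um in enumerate(diameter_trace):
        half = 0.5 * d_um / pixel_size
        profile = 0.5 * (erf((cols - center + half) / s2) - erf((cols - center - half) / s2))
        clean = _BACKGROUND + (_PEAK - _BACKGROUND) * profile
        frames[i] = _add_noise(np.broadcast_to(clean, (h, w)).copy(), snr, rng)

    return VesselMovie(
        frames=frames,
        pixel_size=pixel_size,
        frame_rate=frame_rate,
        vessel_class="pial",
        axis_line=((0.0, center), (float(h - 1), center)),
        ground_truth={
            "diameter_um": diameter_trace.copy(),
            "psf_sigma_px": psf_sigma_px,
            "snr": snr,
        },
    )


def make_penetrating_movie(
    lumen_shapes: np.ndarray,
    pixel_size: float = 0.5,
    frame_rate: float = 8.0,
    snr: float = 10.0,
    seed: int = 0,
    psf_sigma_px: float = 1.0,
    image_size: int = 64,
    supersample: int = 4,
) -> VesselMovie:
    """Movie of an elliptical penetrating-arteriole cross-section.

    ``lumen_shapes`` has one row per frame: ``(a_px, b_px, phi_deg)`` —
    ellipse semi-axes in pixels and orientation.  The lumen indicator is
    rendered with ``supersample``-fold antialiasing, blurred by the PSF
    and degraded with Poisson-Gaussian noise.  The analytic area
    ``pi * a * b`` (in px^2 and um^2) is attached as ground truth; it is
    rotation-invariant by construction.
    """
    shapes = np.atleast_2d(np.asarray(lumen_shapes, dtype=float))
    if shapes.shape[1] != 3:
        raise InvalidParameterError("lumen_shapes rows must be (a_px, b_px, phi_deg)")
    if np.any(shapes[:, :2] <= 0):
        raise InvalidParameterError("ellipse semi-axes must be > 0")
    if pixel_size <= 0 or frame_rate <= 0:
        raise InvalidParameterError("pixel_size and frame_rate must be > 0")

    rng = np.random.default_rng(seed)
    n = image_size
    ss = supersample
    c = n // 2  # must match the rotation center used by the Radon transform
    grid = (np.arange(n * ss) - (ss * c + (ss - 1) / 2.0)) / ss
    yy, xx = np.meshgrid(grid, grid, indexing="ij")

    frames = np.empty((shapes.shape[0], n, n))
    for i, (a, b, phi_deg) in enumerate(shapes):
        phi = math.radians(phi_deg)
        u = xx * math.cos(phi) + yy * math.sin(phi)
        v = -xx * math.sin(phi) + yy * math.cos(phi)
        hi_res = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
        lumen = hi_res.reshape(n, ss, n, ss).mean(axis=(1, 3))
        clean = _BACKGROUND + (_PEAK - _BACKGROUND) * lumen
        if psf_sigma_px > 0:
            clean = gaussian_filter(clean, psf_sigma_px)
        frames[i] = _add_noise(clean, snr, rng)

    areas_px2 = math.pi * shapes[:, 0] * shapes[:, 1]
    return VesselMovie(
        frames=frames,
        pixel_size=pixel_size,
        frame_rate=frame_rate,
        vessel_class="penetrating",
        roi=(0, n, 0, n),
        ground_truth={
            "area_px2": areas_px2,
            "area_um2": areas_px2 * pixel_size**2,
            "lumen_shapes": shapes.copy(),
            "psf_sigma_px": psf_sigma_px,
            "snr": snr,
        },
    )


# ---------------------------------------------------------------------------
# linescans
# ---------------------------------------------------------------------------

def make_linescan(
    velocity: float | np.ndarray,
    pixel_size: float = 0.5,
    line_rate: float = 2000.0,
    particle_density: float = 0.3,
    seed: int = 0,
    n_lines: int = 1024,
    n_cols: int = 128,
    snr: float = float("inf"),
    streak_sigma_px: float = 1.0,
    contrast: float = 60.0,
) -> LinescanImage:
    """Space-time image of dark RBC streaks at a programmed velocity.

    ``velocity`` (mm/s, scalar or per line) sets the streak slope: a cell
    at column x advances ``velocity / (pixel_size * line_rate)`` px per
    line (positive = increasing column index).  Cells are dark Gaussian
    streaks of width ``streak_sigma_px`` on a bright plasma background;
    ``particle_density`` is the fraction of the scan length occupied by
    cells (nominal cell length 4 px).  Positions wrap on an extended
    periodic domain so coverage is uniform at any speed.
    """
    if pixel_size <= 0 or line_rate <= 0:
        raise InvalidParameterError("pixel_size and line_rate must be > 0")
    if not 0 < particle_density <= 1:
        raise InvalidParameterError("particle_density must be in (0, 1]")
    v = np.broadcast_to(np.asarray(velocity, dtype=float), (n_lines,))

    rng = np.random.default_rng(seed)
    period = n_cols + 8.0 * streak_sigma_px
    n_cells = max(1, int(round(particle_density * period / 4.0)))
    x0 = rng.uniform(0.0, period, n_cells)

    # px displacement per line: mm/s -> um/s -> px/s -> px/line
    disp = np.concatenate([[0.0], np.cumsum(v[:-1] * 1000.0 / pixel_size / line_rate)])
    pos = (x0[None, :] + disp[:, None]) % period  # (line, cell)

    cols = np.arange(n_cols, dtype=float)
    image = np.full((n_lines, n_cols), _PEAK)
    for k in range(n_cells):
        d = cols[None, :] - pos[:, k][:, None]
        d -= period * np.round(d / period)
        image -= contrast * np.exp(-0.5 * (d / streak_sigma_px) ** 2)
    if np.isfinite(snr):
        image = image + rng.normal(0.0, contrast / snr, image.shape)

    return LinescanImage(
        image=image,
        pixel_size=pixel_size,
        line_rate=line_rate,
        ground_truth={"velocity_mm_s": np.asarray(velocity, dtype=float),
                      "particle_density": particle_density, "snr": snr},
    )


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------

def make_locomotion_trace(
    bout_times: Sequence[tuple[float, float]],
    duration: float = 120.0,
    sample_rate: float = 1000.0,
    peak_speed: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    edge_s: float = 0.3,
    stride_hz: float = 3.0,
    stride_fraction: float = 0.25,
) -> LocomotionTrace:
    """Treadmill-encoder velocity with discrete locomotion bouts.

    The encoder reads exactly zero at rest (no ticks).  Each bout ramps
    to ``peak_speed`` (cm/s) with raised-cosine edges of ``edge_s`` and
    carries stride-frequency velocity fluctuations
    (``stride_fraction * peak_speed`` at ``stride_hz`` with random
    phase/harmonics) — real running is never constant-velocity, and an
    acceleration-threshold binarization relies on this structure to see
    the bout interior.  ``noise_sd`` (cm/s) adds encoder measurement
    noise during movement only.
    """
    if sample_rate <= 0 or duration <= 0:
        raise InvalidParameterError("duration and sample_rate must be > 0")
    if peak_speed <= 0:
        raise InvalidParameterError("peak_speed must be > 0")
    bouts = sorted((float(a), float(b)) for a, b in bout_times)
    for (a0, b0), (a1, _) in zip(bouts, bouts[1:]):
        if a1 < b0:
            raise InvalidParameterError("bouts must be non-overlapping")
    for a, b in bouts:
        if b <= a:
            raise InvalidParameterError("bout offsets must follow onsets")
        if a < 0 or b > duration:
            raise InvalidParameterError("bouts must fall within the trace duration")

    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.zeros(n)
    for a, b in bouts:
        sel = (t >= a) & (t < b)
        tt = t[sel]
        envelope = np.ones(tt.size)
        rise = tt < a + edge_s
        envelope[rise] = 0.5 * (1 - np.cos(math.pi * (tt[rise] - a) / edge_s))
        fall = tt > b - edge_s
        envelope[fall] = 0.5 * (1 - np.cos(math.pi * (b - tt[fall]) / edge_s))
        stride = (np.sin(2 * math.pi * stride_hz * tt + rng.uniform(0, 2 * math.pi))
                  + 0.5 * np.sin(2 * math.pi * 2 * stride_hz * tt + rng.uniform(0, 2 * math.pi)))
        speed = peak_speed * (1.0 + stride_fraction * stride / 1.5)
        if noise_sd > 0:
            speed = speed + rng.normal(0.0, noise_sd, tt.size)
        v[sel] = np.clip(envelope * speed, 0.0, None)

    return LocomotionTrace(
        velocity=v,
        sample_rate=sample_rate,
        ground_truth={"bout_times": bouts, "peak_speed": peak_speed},
    )


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

def _band_noise(n: int, fs: float, f_lo: float, f_hi: float,
                rng: np.random.Generator, pink: bool = False) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [f_lo, f_hi] Hz."""
    spec = (rng.normal(size=n // 2 + 1) + 1j * rng.normal(size=n // 2 + 1))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    env = ((freqs >= f_lo) & (freqs <= f_hi)).astype(float)
    if pink:
        with np.errstate(divide="ignore"):
            env = env / np.sqrt(np.maximum(freqs, f_lo))
        env[0] = 0.0
    x = np.fft.irfft(spec * env, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_lfp(
    bout_mask: np.ndarray,
    sample_rate: float = 20000.0,
    gamma_gain: float = 1.0,
    seed: int = 0,
    gamma_band: tuple[float, float] = (40.0, 100.0),
    gamma_amp: float = 40.0,
    low_band_amp: float = 100.0,
    sensor_noise_amp: float = 4.0,
    line_amp: float = 0.0,
    line_hz: float = 60.0,
) -> LFPRecording:
    """Cortical LFP with state-dependent gamma-band power.

    Pink-noise background band-limited below the gamma band (the
    state-independent low-frequency rhythms), plus a 40-100 Hz
    band-limited component whose variance is multiplied by
    ``gamma_gain`` during locomotion (amplitude scaled by its square
    root), a small broadband sensor-noise floor, and an optional
    ``line_hz`` mains contaminant.  Amplitudes are in uV (SD for the
    stochastic components).  Keeping the background out of the gamma
    band makes the locomotion/basal gamma-power ratio equal
    ``gamma_gain`` up to the sensor-noise dilution (<2% at defaults).
    """
    bout_mask = np.asarray(bout_mask, dtype=bool)
    if bout_mask.ndim != 1 or bout_mask.size == 0:
        raise InvalidParameterError("bout_mask must be a non-empty boolean array")
    if gamma_gain <= 0:
        raise InvalidParameterError("gamma_gain must be > 0")
    rng = np.random.default_rng(seed)
    n = bout_mask.size

    low = low_band_amp * _band_noise(n, sample_rate, 1.0, 0.6 * gamma_band[0], rng, pink=True)
    gamma = gamma_amp * _band_noise(n, sample_rate, gamma_band[0], gamma_band[1], rng)
    scale = np.where(bout_mask, math.sqrt(gamma_gain), 1.0)
    x = low + gamma * scale + rng.normal(0.0, sensor_noise_amp, n)
    if line_amp > 0:
        t = np.arange(n) / sample_rate
        x = x + line_amp * np.sin(2 * math.pi * line_hz * t)

    return LFPRecording(
        samples=x,
        sample_rate=sample_rate,
        ground_truth={"gamma_gain": gamma_gain, "gamma_band": gamma_band,
                      "line_amp": line_amp},
    )


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def make_photometry(
    calcium_trace: np.ndarray,
    cbv_trace: np.ndarray,
    bleach_params: tuple[float, float, float, float, float] = (1.0, 100.0, 0.5, 1000.0, 2.0),
    attenuation_coeff: float = 0.3,
    sample_rate: float = 1200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    red_bleach_scale: float = 0.7,
) -> PhotometrySession:
    """Two-channel photometry with bleaching and hemoglobin attenuation.

    ``green = bleach(t) + calcium - attenuation_coeff * cbv + noise`` and
    ``red = bleach_red(t) + cbv + noise``, where ``bleach`` is the
    double-exponential ``a1*exp(-t/tau1) + a2*exp(-t/tau2) + offset``
    from ``bleach_params`` and the red decay is the same shape scaled by
    ``red_bleach_scale`` (TRITC excretion).  Pass a constant
    ``calcium_trace`` for a GFP control session.
    """
    calcium = np.asarray(calcium_trace, dtype=float)
    cbv = np.asarray(cbv_trace, dtype=float)
    if calcium.shape != cbv.shape or calcium.ndim != 1:
        raise InvalidParameterError("calcium and cbv traces must be equal-length 1-D")
    a1, tau1, a2, tau2, offset = bleach_params
    if tau1 <= 0 or tau2 <= 0:
        raise InvalidParameterError("decay time constants must be > 0")
    rng = np.random.default_rng(seed)

    t = np.arange(calcium.size) / sample_rate
    bleach_g = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + offset
    bleach_r = red_bleach_scale * (a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)) + offset
    green = bleach_g + calcium - attenuation_coeff * cbv
    red = bleach_r + cbv
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, green.shape)
        red = red + rng.normal(0.0, noise_sd, red.shape)

    return PhotometrySession(
        green=green,
        red=red,
        sample_rate=sample_rate,
        ground_truth={
            "calcium": calcium.copy(),
            "cbv": cbv.copy(),
            "bleach": BleachModel(a1=a1, tau1=tau1, a2=a2, tau2=tau2, offset=offset),
            "attenuation_coeff": attenuation_coeff,
            "noise_sd": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def make_cohort(
    gamma: float,
    sigma_animal: float,
    sigma_resid: float,
    n_animals: int = 6,
    vessels_per_animal: int = 5,
    baseline_mean_um: float = 20.0,
    baseline_sd_um: float = 4.0,
    seed: int = 0,
    vessel_class: str = "pial",
):
    """Vehicle/treatment diameter cohort obeying the mixed-effects model.

    Per-vessel fractional diameter changes follow
    ``dD = gamma + beta_a + eps`` with ``beta_a ~ N(0, sigma_animal^2)``
    per animal and ``eps ~ N(0, sigma_resid^2)`` per vessel; treatment
    diameters are ``d_vehicle * (1 + dD)``.  Returns a cohort
    ``pandas.DataFrame`` with the true per-animal effects in ``attrs``.
    """
    import pandas as pd

    if n_animals < 1 or vessels_per_animal < 1:
        raise InvalidParameterError("need at least one animal and one vessel")
    if sigma_animal < 0 or sigma_resid < 0:
        raise InvalidParameterError("variance components must be >= 0")
    rng = np.random.default_rng(seed)

    rows = []
    beta = rng.normal(0.0, sigma_animal, n_animals) if sigma_animal > 0 else np.zeros(n_animals)
    for a in range(n_animals):
        for v in range(vessels_per_animal):
            d_vehicle = max(2.0, rng.normal(baseline_mean_um, baseline_sd_um))
            eps = rng.normal(0.0, sigma_resid) if sigma_resid > 0 else 0.0
            dd = gamma + beta[a] + eps
            rows.append({
                "animal_id": f"m{a:02d}",
                "vessel_id": f"m{a:02d}_v{v:02d}",
                "vessel_class": vessel_class,
                "d_vehicle_um": d_vehicle,
                "d_treatment_um": d_vehicle * (1.0 + dd),
            })
    table = pd.DataFrame(rows)
    table.attrs["ground_truth"] = {
        "gamma": gamma, "sigma_animal": sigma_animal, "sigma_resid": sigma_resid,
        "beta_a": beta.tolist(),
    }
    return table
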