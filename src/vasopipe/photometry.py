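"""Fiber-photometry correction: photobleaching, hemoglobin absorption,
z-scoring, and duration-binned locomotion-evoked averages.

A session carries two channels sampled at 1.2 kHz: green (GCaMP or GFP)
and red (TRITC dextran, reporting cerebral blood volume, CBV).  The
correction chain is:

1.  *Bleach fit* — the channel is low-passed below 0.1 Hz, locomotion
    periods (plus 15 s after each) are excluded, and a sum of two
    exponential decays is fit and subtracted.  This removes GCaMP
    photobleaching and slow TRITC excretion.
2.  *Hemoglobin correction* — increases in local hemoglobin attenuate the
    green fluorescence.  On GFP control animals (no activity-dependent
    signal) the slope of debleached green on debleached red measures the
    attenuation; the mean slope over animals scales the red channel,
    which is then subtracted from the green channel.
3.  The corrected signal is band-passed 0.001-1 Hz (zero-phase) and
    converted to z-scores.

Locomotion events (>=5 s, with >=5 s of preceding quiet) are grouped into
five duration bins and baseline-subtracted averages are computed per bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, sosfiltfilt

from .behavior import BehaviorSegmentation, TriggeredAverage
from .errors import InvalidParameterError, VasopipeError

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometrySession",
    "BleachModel",
    "AttenuationModel",
    "CorrectedPhotometry",
    "DURATION_BINS",
    "fit_bleach",
    "debleach",
    "minmax_normalize",
    "debleach_and_normalize",
    "estimate_attenuation",
    "correct_hemoglobin",
    "zscore",
    "correct_session",
    "event_triggered_photometry",
    "signal_blood_correlation",
]

# locomotion-event duration bins, seconds (upper edge exclusive)
DURATION_BINS: tuple[tuple[float, float], ...] = (
    (5.0, 10.0), (10.0, 15.0), (15.0, 30.0), (30.0, 45.0), (45.0, math.inf),
)


@dataclass
class PhotometrySession:
    """Two-channel fluorescence at 1.2 kHz with behavioral segmentation."""

    green: np.ndarray
    red: np.ndarray
    sample_rate: float
    behavior: BehaviorSegmentation | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape or self.green.ndim != 1:
            raise InvalidParameterError("green and red must be equal-length 1-D arrays")
        if self.sample_rate <= 2:
            raise InvalidParameterError("sample_rate must exceed 2 Hz")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.green.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.green.size / self.sample_rate


@dataclass(frozen=True)
class BleachModel:
    """Sum-of-two-exponentials photobleaching model.

    ``f(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) + offset``; when the
    two-exponential fit failed to converge ``single_exponential`` is set
    and ``a2 = 0``.
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    offset: float
    single_exponential: bool = False

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidParameterError("decay time constants must be > 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.a1 * np.exp(-t / self.tau1)
                + self.a2 * np.exp(-t / self.tau2) + self.offset)


@dataclass(frozen=True)
class AttenuationModel:
    """Hemoglobin attenuation of the green channel by blood volume.

    ``coeff`` is the mean of the per-animal regression slopes of
    debleached green on debleached red (negative: more blood means less
    green fluorescence).  The correction subtracts ``coeff * red`` from
    the green channel.
    """

    coeff: float
    per_animal_slopes: tuple[float, ...]

    @property
    def magnitude(self) -> float:
        return abs(self.coeff)


@dataclass
class CorrectedPhotometry:
    """Z-scored corrected signals: neural (green) and blood volume (red)."""

    gcamp_z: np.ndarray
    cbv_z: np.ndarray
    sample_rate: float
    behavior: BehaviorSegmentation | None = None
    attenuation: AttenuationModel | None = None


# ---------------------------------------------------------------------------
# filtering helpers
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, corner: float, order: int = 4) -> np.ndarray:
    sos = butter(order, corner, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _highpass_slow(x: np.ndarray, fs: float, corner: float, order: int = 4) -> np.ndarray:
    """Zero-phase high-pass at a corner far below the sample rate.

    Filtering at e.g. 0.001 Hz directly at 1.2 kHz is numerically fragile
    and needs reflection padding of one corner period; instead the signal
    is decimated to ~12 Hz (its content is already below 1 Hz here), the
    drift is extracted there and interpolated back to full rate.
    """
    step = max(1, int(round(fs / 12.0)))
    xs = x[::step]
    fs_d = fs / step
    sos = butter(order, corner, btype="low", fs=fs_d, output="sos")
    pad = min(xs.size - 1, int(round(fs_d / corner)))
    drift = sosfiltfilt(sos, xs, padlen=pad)
    t_full = np.arange(x.size) / fs
    t_dec = np.arange(xs.size) * step / fs
    return x - np.interp(t_full, t_dec, drift)


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------

def _double_exp(t: np.ndarray, a1: float, tau1: float, a2: float, tau2: float, c: float) -> np.ndarray:
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def fit_bleach(
    channel: np.ndarray,
    sample_rate: float,
    behavior: BehaviorSegmentation | None = None,
    exclusion_pad_s: float = 15.0,
    tau_starts: tuple[float, ...] = (30.0, 300.0, 3000.0),
) -> BleachModel:
    """Fit the slow decay of a raw fluorescence channel.

    The channel is zero-phase low-passed below 0.1 Hz; locomotion periods
    and the ``exclusion_pad_s`` seconds following each are excluded (they
    carry behavior-evoked blood-volume transients, not decay), and a sum
    of two exponentials is fit by nonlinear least squares.  The fit is
    multi-started over pairs of decay-constant initializations because
    two-exponential fits are initialization-sensitive; if no two-term
    start converges, a single exponential is fit and flagged.
    """
    channel = np.asarray(channel, dtype=float)
    # the decay lives far below 0.1 Hz: decimate to ~12 Hz first, low-pass
    # there, and fit on a ~2 Hz subsample (the 0.1 Hz filter removes any
    # aliased broadband noise from the plain-stride decimation)
    dec = max(1, int(round(sample_rate / 12.0)))
    fs_d = sample_rate / dec
    slow = _lowpass(channel[::dec], fs_d, 0.1)

    include = np.ones(slow.size, dtype=bool)
    if behavior is not None:
        pad = int(round(exclusion_pad_s * fs_d))
        moving = behavior.moving_mask_at(fs_d, slow.size)
        for i0, i1 in _mask_runs(moving):
            include[i0 : min(slow.size, i1 + pad)] = False
    if include.sum() / fs_d < 60.0:
        raise InvalidParameterError("need >= 60 s of locomotion-free data for the decay fit")

    step = max(1, int(round(fs_d / 2.0)))
    idx = np.where(include)[0][::step]
    t = idx / fs_d
    y = slow[idx]

    scale = float(y.max() - y.min())
    offset0 = float(y.min())
    best, best_sse = None, np.inf
    for tau1 in tau_starts:
        for tau2 in tau_starts:
            if tau2 <= tau1:
                continue
            p0 = (0.6 * scale, tau1, 0.4 * scale, tau2, offset0)
            try:
                popt, _ = curve_fit(
                    _double_exp, t, y, p0=p0, maxfev=20000,
                    bounds=([-np.inf, 1e-3, -np.inf, 1e-3, -np.inf],
                            [np.inf, np.inf, np.inf, np.inf, np.inf]),
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((_double_exp(t, *popt) - y) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
    if best is not None:
        a1, tau1, a2, tau2, c = best
        # report the faster component first
        if tau1 > tau2:
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        return BleachModel(a1=a1, tau1=tau1, a2=a2, tau2=tau2, offset=c)

    logger.warning("two-exponential decay fit did not converge; falling back to one term")
    single = lambda tt, a, tau, c: a * np.exp(-tt / tau) + c  # noqa: E731
    popt, _ = curve_fit(single, t, y, p0=(scale, 300.0, offset0), maxfev=20000)
    return BleachModel(a1=popt[0], tau1=popt[1], a2=0.0, tau2=popt[1],
                       offset=popt[2], single_exponential=True)


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    return list(zip(np.where(d == 1)[0], np.where(d == -1)[0]))


def debleach(channel: np.ndarray, sample_rate: float, model: BleachModel) -> np.ndarray:
    """Subtract the fitted decay (offset included) and low-pass below 1 Hz."""
    channel = np.asarray(channel, dtype=float)
    t = np.arange(channel.size) / sample_rate
    residual = channel - model(t)
    return _lowpass(residual, sample_rate, 1.0)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a signal to minimum 0 and maximum 1."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise InvalidParameterError("cannot min-max normalize a constant signal")
    return (x - lo) / (hi - lo)


def debleach_and_normalize(channel: np.ndarray, sample_rate: float, model: BleachModel) -> np.ndarray:
    """Decay-subtracted, <1 Hz low-passed channel scaled to [0, 1]."""
    return minmax_normalize(debleach(channel, sample_rate, model))


# ---------------------------------------------------------------------------
# hemoglobin attenuation
# ---------------------------------------------------------------------------

def estimate_attenuation(gfp_sessions: list[PhotometrySession]) -> AttenuationModel:
    """Hemoglobin attenuation coefficient from GFP control sessions.

    GFP fluorescence has no activity-dependent component, so after
    debleaching, any co-variation of green with the blood-volume (red)
    channel is hemoglobin absorption.  Per animal, the ordinary
    least-squares slope of debleached green on debleached red is
    computed; the model coefficient is the mean slope (negative, since
    more blood absorbs more green light).
    """
    if not gfp_sessions:
        raise InvalidParameterError("at least one GFP session is required")
    slopes = []
    for session in gfp_sessions:
        bleach_g = fit_bleach(session.green, session.sample_rate, session.behavior)
        bleach_r = fit_bleach(session.red, session.sample_rate, session.behavior)
        g = debleach(session.green, session.sample_rate, bleach_g)
        r = debleach(session.red, session.sample_rate, bleach_r)
        r_var = float(np.var(r))
        if r_var == 0:
            raise VasopipeError("red channel is constant; cannot regress")
        slopes.append(float(np.cov(g, r, ddof=0)[0, 1] / r_var))
    return AttenuationModel(coeff=float(np.mean(slopes)), per_animal_slopes=tuple(slopes))


def correct_hemoglobin(
    green_debleached: np.ndarray,
    red_debleached: np.ndarray,
    model: AttenuationModel,
    sample_rate: float,
    band: tuple[float, float] = (0.001, 1.0),
) -> np.ndarray:
    """Remove the blood-volume component from the green channel.

    The red channel scaled by the attenuation coefficient is subtracted
    (the coefficient is negative, so the absorbed fluorescence is added
    back), then the result is zero-phase band-passed 0.001-1 Hz and
    z-scored.
    """
    g = np.asarray(green_debleached, dtype=float)
    r = np.asarray(red_debleached, dtype=float)
    if g.shape != r.shape:
        raise InvalidParameterError("channel shapes differ")
    corrected = g - model.coeff * r
    corrected = _lowpass(corrected, sample_rate, band[1])
    corrected = _highpass_slow(corrected, sample_rate, band[0])
    return zscore(corrected)


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 over the whole session."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise InvalidParameterError("cannot z-score a constant signal")
    return (x - float(np.mean(x))) / sd


def correct_session(
    session: PhotometrySession,
    attenuation: AttenuationModel,
    band: tuple[float, float] = (0.001, 1.0),
) -> CorrectedPhotometry:
    """Full correction chain for one session.

    Both channels are debleached; the green channel is hemoglobin-
    corrected, band-passed and z-scored; the red (CBV) channel is
    band-passed and z-scored the same way.
    """
    fs = session.sample_rate
    bleach_g = fit_bleach(session.green, fs, session.behavior)
    bleach_r = fit_bleach(session.red, fs, session.behavior)
    g = debleach(session.green, fs, bleach_g)
    r = debleach(session.red, fs, bleach_r)
    gcamp_z = correct_hemoglobin(g, r, attenuation, fs, band)
    cbv = _highpass_slow(_lowpass(r, fs, band[1]), fs, band[0])
    return CorrectedPhotometry(
        gcamp_z=gcamp_z,
        cbv_z=zscore(cbv),
        sample_rate=fs,
        behavior=session.behavior,
        attenuation=attenuation,
    )


# ---------------------------------------------------------------------------
# event-triggered analysis
# ---------------------------------------------------------------------------

def event_triggered_photometry(
    corrected: CorrectedPhotometry,
    behavior: BehaviorSegmentation | None = None,
    bins: tuple[tuple[float, float], ...] = DURATION_BINS,
    pre_quiet_s: float = 5.0,
    min_event_s: float = 5.0,
    post_window_s: float = 45.0,
) -> dict[tuple[float, float], dict[str, TriggeredAverage]]:
    """Duration-binned, baseline-subtracted locomotion-evoked averages.

    Events at least ``min_event_s`` long with ``pre_quiet_s`` of
    behavior-free time before onset are grouped by duration into ``bins``.
    The quiet requirement is evaluated against the preceding *event*
    boundary (the binarized mask is smeared symmetrically around each
    bout by the zero-phase filter, so the mask itself is always "moving"
    just before a refined onset).  For each event the mean signal over
    the ``pre_quiet_s`` window before onset is subtracted; bin-wise
    averages of both z-scored signals are returned keyed by bin, each
    holding ``{"gcamp": ..., "cbv": ...}``.
    """
    behavior = behavior or corrected.behavior
    if behavior is None:
        raise InvalidParameterError("behavioral segmentation is required")
    fs = corrected.sample_rate
    n = corrected.gcamp_z.size
    n_pre = int(round(pre_quiet_s * fs))
    n_post = int(round(post_window_s * fs))

    events = sorted(behavior.events)
    qualifying: dict[tuple[float, float], list[tuple[int, int]]] = {b: [] for b in bins}
    for k, (onset, offset) in enumerate(events):
        duration = offset - onset
        if duration < min_event_s:
            continue
        prev_offset = events[k - 1][1] if k > 0 else 0.0
        if onset - prev_offset < pre_quiet_s or onset * fs < n_pre:
            continue
        i = int(round(onset * fs))
        for b in bins:
            if b[0] <= duration < b[1]:
                qualifying[b].append((i, int(round(offset * fs))))
                break

    out: dict[tuple[float, float], dict[str, TriggeredAverage]] = {}
    rel_time = np.arange(-n_pre, n_post) / fs
    for b, events in qualifying.items():
        if not events:
            continue
        traces = {"gcamp": corrected.gcamp_z, "cbv": corrected.cbv_z}
        bin_out = {}
        for name, sig in traces.items():
            segs = []
            for i, _ in events:
                stop = min(n, i + n_post)
                seg = np.full(n_pre + n_post, np.nan)
                seg[: n_pre + stop - i] = sig[i - n_pre : stop]
                seg -= np.nanmean(seg[:n_pre])
                segs.append(seg)
            arr = np.vstack(segs)
            mean = np.nanmean(arr, axis=0)
            k = arr.shape[0]
            sem = (np.nanstd(arr, axis=0, ddof=1) / math.sqrt(k)) if k > 1 else np.zeros_like(mean)
            bin_out[name] = TriggeredAverage(
                rel_time=rel_time, mean=mean, sem=sem, n_events=k,
                normalization_reference=1.0,
            )
        out[b] = bin_out
    return out


def signal_blood_correlation(corrected: CorrectedPhotometry) -> float:
    """Pearson correlation between the neural and blood-volume z-signals."""
    return float(np.corrcoef(corrected.gcamp_z, corrected.cbv_z)[0, 1])
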