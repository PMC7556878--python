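"""Locomotion analysis: binarization, event segmentation, triggered averages.

The treadmill velocity signal is low-pass filtered (10 Hz, fifth-order
Butterworth, zero-phase) and the absolute value of its acceleration is
binarized at a small threshold (1e-5 cm/s^2) to label moving samples.
Qualifying locomotion events (>5 s with >=2 s of preceding quiet) drive
locomotion-triggered averages (LTAs) of vessel diameter, normalized to the
vehicle-condition basal diameter of the same vessel.

Because the binarizing filter is zero-phase, its settling tail on an
otherwise silent encoder smears the moving mask symmetrically around each
bout; event boundaries can optionally be refined to the crossing of a
small fraction of the event's peak (filtered) speed, which recovers
programmed onsets to within the filter transition width.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import (
    InvalidParameterError,
    InvalidRateError,
    NoStationaryPeriodError,
    VasopipeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LocomotionTrace",
    "BehaviorSegmentation",
    "TriggeredAverage",
    "OnsetEstimate",
    "binarize_locomotion",
    "merge_event_gaps",
    "find_stationary_periods",
    "extract_lta_events",
    "refine_event_bounds",
    "segment_behavior",
    "basal_value",
    "locomotion_triggered_average",
    "evoked_amplitude",
    "onset_time",
    "locomotion_induced_metric",
]


@dataclass
class LocomotionTrace:
    """Rotary-encoder treadmill velocity in cm/s."""

    velocity: np.ndarray
    sample_rate: float
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 1:
            raise InvalidParameterError("velocity must be 1-D")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.velocity.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.velocity.size / self.sample_rate


@dataclass
class BehaviorSegmentation:
    """Binarized locomotion with events and stationary periods (seconds)."""

    moving: np.ndarray
    sample_rate: float
    events: list[tuple[float, float]] = field(default_factory=list)
    stationary_periods: list[tuple[float, float]] = field(default_factory=list)

    def moving_mask_at(self, rate: float, n: int) -> np.ndarray:
        """Resample the moving mask to another sampling rate."""
        idx = np.clip((np.arange(n) / rate * self.sample_rate).astype(int), 0, self.moving.size - 1)
        return self.moving[idx]


@dataclass
class TriggeredAverage:
    """Event-aligned mean response, normalized to a reference level."""

    rel_time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    normalization_reference: float

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise InvalidParameterError("a triggered average needs >= 1 event")


@dataclass(frozen=True)
class OnsetEstimate:
    """Dilation onset time relative to locomotion onset, in seconds."""

    time: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# binarization and segmentation
# ---------------------------------------------------------------------------

def binarize_locomotion(
    trace: LocomotionTrace,
    accel_threshold: float = 1e-5,
    cutoff_hz: float = 10.0,
    order: int = 5,
) -> np.ndarray:
    """Boolean moving mask from the treadmill velocity signal.

    Zero-phase low-pass at ``cutoff_hz`` (Butterworth, order 5), then the
    absolute central-difference acceleration (cm/s^2) is compared against
    ``accel_threshold``.  The threshold is applied in cm/s^2 regardless of
    sample rate; its effective sensitivity therefore depends on the
    encoder rate, which is why it is exposed as configuration.
    """
    fs = trace.sample_rate
    if fs <= 2 * cutoff_hz:
        raise InvalidRateError(
            f"sample_rate {fs} Hz too low for a {cutoff_hz} Hz low-pass"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, trace.velocity)
    accel = np.gradient(filtered) * fs
    return np.abs(accel) > accel_threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    stops = np.where(d == -1)[0]
    return list(zip(starts, stops))


def merge_event_gaps(moving: np.ndarray, sample_rate: float, max_gap_s: float = 1.0) -> np.ndarray:
    """Bridge still gaps shorter than ``max_gap_s`` between moving runs.

    Encoder jitter would otherwise split one bout into several events.
    """
    out = moving.copy()
    max_gap = int(round(max_gap_s * sample_rate))
    runs = _runs(~out)
    for start, stop in runs:
        if start == 0 or stop == out.size:
            continue  # leading/trailing stillness is not a gap
        if stop - start < max_gap:
            out[start:stop] = True
    return out


def find_stationary_periods(
    moving: np.ndarray,
    sample_rate: float,
    min_duration: float = 1.0,
    post_event_buffer_s: float = 2.0,
    pre_event_buffer_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Stationary periods in seconds, trimmed by the locomotion buffers.

    Each maximal still interval is trimmed by 2 s after the end of any
    preceding locomotion event and 1 s before the start of the next one;
    intervals shorter than ``min_duration`` are dropped.
    """
    periods = []
    for start, stop in _runs(~moving):
        t0 = start / sample_rate
        t1 = stop / sample_rate
        if start > 0:
            t0 += post_event_buffer_s
        if stop < moving.size:
            t1 -= pre_event_buffer_s
        if t1 - t0 >= min_duration:
            periods.append((t0, t1))
    return periods


def extract_lta_events(
    moving: np.ndarray,
    sample_rate: float,
    min_event_s: float = 5.0,
    pre_quiet_s: float = 2.0,
    merge_gap_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Qualifying locomotion events: duration > ``min_event_s`` with at
    least ``pre_quiet_s`` of no locomotion before onset.

    Moving runs separated by less than ``merge_gap_s`` of stillness are
    treated as one event.  Onsets/offsets are aligned to the first/last
    moving sample of the (merged) run, in seconds.
    """
    merged = merge_event_gaps(moving, sample_rate, merge_gap_s)
    n_quiet = int(round(pre_quiet_s * sample_rate))
    events = []
    for start, stop in _runs(merged):
        if (stop - start) / sample_rate <= min_event_s:
            continue
        if start < n_quiet:
            continue  # not enough trace before onset to certify quiet
        if merged[start - n_quiet : start].any():
            continue
        events.append((start / sample_rate, stop / sample_rate))
    return events


def refine_event_bounds(
    trace: LocomotionTrace,
    events: list[tuple[float, float]],
    fraction: float = 0.1,
    cutoff_hz: float = 10.0,
    order: int = 5,
    search_pad_s: float = 1.5,
) -> list[tuple[float, float]]:
    """Refine event boundaries to the crossing of ``fraction`` of peak speed.

    The acceleration mask is smeared symmetrically by the zero-phase
    filter's settling tail (the encoder is exactly silent at rest), so the
    first/last moving samples lead/lag the true bout edges.  Each boundary
    is moved to the first/last crossing of ``fraction`` of the event's
    peak filtered speed within ``search_pad_s`` of the mask edge.
    """
    fs = trace.sample_rate
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    speed = np.abs(sosfiltfilt(sos, trace.velocity))
    pad = int(round(search_pad_s * fs))
    refined = []
    for onset, offset in events:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        peak = speed[max(0, i0) : i1].max() if i1 > i0 else 0.0
        if peak <= 0:
            refined.append((onset, offset))
            continue
        level = fraction * peak
        above = np.where(speed[max(0, i0 - pad) : i1] >= level)[0]
        new_on = (max(0, i0 - pad) + above[0]) / fs if above.size else onset
        above = np.where(speed[i0 : min(speed.size, i1 + pad)] >= level)[0]
        new_off = (i0 + above[-1] + 1) / fs if above.size else offset
        refined.append((new_on, new_off))
    return refined


def segment_behavior(
    trace: LocomotionTrace,
    accel_threshold: float = 1e-5,
    min_event_s: float = 5.0,
    pre_quiet_s: float = 2.0,
    merge_gap_s: float = 1.0,
    min_stationary_s: float = 1.0,
    refine_fraction: float | None = 0.1,
) -> BehaviorSegmentation:
    """Full behavioral segmentation of a locomotion trace."""
    moving = binarize_locomotion(trace, accel_threshold=accel_threshold)
    merged = merge_event_gaps(moving, trace.sample_rate, merge_gap_s)
    events = extract_lta_events(
        merged, trace.sample_rate, min_event_s, pre_quiet_s, merge_gap_s
    )
    if refine_fraction is not None:
        events = refine_event_bounds(trace, events, fraction=refine_fraction)
    periods = find_stationary_periods(
        merged, trace.sample_rate, min_duration=min_stationary_s
    )
    return BehaviorSegmentation(
        moving=merged,
        sample_rate=trace.sample_rate,
        events=events,
        stationary_periods=periods,
    )


# ---------------------------------------------------------------------------
# basal values and triggered averages
# ---------------------------------------------------------------------------

def basal_value(
    values: np.ndarray,
    sample_rate: float,
    segmentation: BehaviorSegmentation,
) -> float:
    """Mean of a signal over the stationary periods (the 'basal' value)."""
    values = np.asarray(values, dtype=float)
    if not segmentation.stationary_periods:
        raise NoStationaryPeriodError("no stationary periods in segmentation")
    picks = []
    for t0, t1 in segmentation.stationary_periods:
        i0 = int(math.ceil(t0 * sample_rate))
        i1 = int(math.floor(t1 * sample_rate))
        i0, i1 = max(0, i0), min(values.size, i1)
        if i1 > i0:
            picks.append(values[i0:i1])
    if not picks:
        raise NoStationaryPeriodError("stationary periods fall outside the trace")
    pooled = np.concatenate(picks)
    return float(np.nanmean(pooled))


def locomotion_triggered_average(
    values: np.ndarray,
    sample_rate: float,
    events: list[tuple[float, float]],
    normalization_reference: float,
    window: tuple[float, float] = (-2.0, 10.0),
) -> TriggeredAverage:
    """Event-aligned average of a signal, normalized to a reference level.

    ``normalization_reference`` is the vehicle-condition basal diameter of
    the same vessel (um), so the LTA is in fractions of vehicle basal.
    Only events whose full window lies inside the trace contribute.
    """
    values = np.asarray(values, dtype=float)
    if normalization_reference <= 0:
        raise InvalidParameterError("normalization_reference must be > 0")
    w0 = int(round(window[0] * sample_rate))
    w1 = int(round(window[1] * sample_rate))
    if w1 <= w0:
        raise InvalidParameterError("window must have positive length")
    segments = []
    for onset, _ in events:
        i = int(round(onset * sample_rate))
        if i + w0 < 0 or i + w1 > values.size:
            continue
        segments.append(values[i + w0 : i + w1] / normalization_reference)
    if not segments:
        raise VasopipeError("no qualifying event lies fully inside the trace")
    seg = np.vstack(segments)
    mean = np.nanmean(seg, axis=0)
    n = seg.shape[0]
    sem = np.nanstd(seg, axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    rel_time = (np.arange(w0, w1)) / sample_rate
    return TriggeredAverage(
        rel_time=rel_time, mean=mean, sem=sem, n_events=n,
        normalization_reference=normalization_reference,
    )


def evoked_amplitude(lta: TriggeredAverage, window: tuple[float, float] = (3.0, 4.0)) -> float:
    """Evoked response amplitude in percent of the reference level.

    The mean of (LTA - 1) over 3-4 s after locomotion onset, as a
    percentage.
    """
    sel = (lta.rel_time >= window[0]) & (lta.rel_time <= window[1])
    if not sel.any():
        raise InvalidParameterError("evoked window outside the LTA range")
    return float(np.nanmean(lta.mean[sel] - 1.0) * 100.0)


def onset_time(
    lta: TriggeredAverage,
    baseline_window: tuple[float, float] = (-2.0, 0.0),
    band: tuple[float, float] = (0.2, 0.8),
) -> OnsetEstimate:
    """Dilation onset from the 20-80% rise of the triggered average.

    A least-squares line is fit through the samples of the rising phase
    (between locomotion onset and the peak) whose amplitude lies between
    20% and 80% of the peak dilation above the pre-onset baseline; the
    onset is the time where that line crosses the baseline level.  If no
    samples fall in the band (an instantaneous step), the time of the
    first supra-20% sample is returned, flagged degenerate.
    """
    base_sel = (lta.rel_time >= baseline_window[0]) & (lta.rel_time < baseline_window[1])
    if not base_sel.any():
        raise InvalidParameterError("baseline window outside the LTA range")
    baseline = float(np.nanmean(lta.mean[base_sel]))

    # peak from a lightly smoothed copy: the raw sample maximum is inflated
    # by noise, which would shift the 20-80% band up the response
    k = min(5, lta.mean.size)
    smoothed = np.convolve(lta.mean, np.ones(k) / k, mode="same")
    post = lta.rel_time >= 0.0
    peak_idx = int(np.nanargmax(np.where(post, smoothed, -np.inf)))
    peak = float(smoothed[peak_idx])
    amplitude = peak - baseline
    if amplitude <= 0:
        raise VasopipeError("no peak dilation above baseline")

    lo = baseline + band[0] * amplitude
    hi = baseline + band[1] * amplitude
    # the rising phase: from the last sub-20% sample to the first 80%
    # crossing, so band samples come from one contiguous rise and not from
    # noisy plateau samples dipping back into the band
    post_idx = np.where(post)[0]
    above_hi = post_idx[smoothed[post_idx] >= hi]
    i_hi = int(above_hi[0]) if above_hi.size else peak_idx
    below_lo = np.where(post & (np.arange(lta.mean.size) <= i_hi) & (smoothed <= lo))[0]
    i_lo = int(below_lo[-1]) if below_lo.size else int(post_idx[0])

    sel = np.zeros(lta.mean.size, dtype=bool)
    sel[i_lo : i_hi + 1] = True
    sel &= (lta.mean >= lo) & (lta.mean <= hi)
    if sel.sum() < 2:
        supra = np.where(post & (lta.mean >= lo))[0]
        t = float(lta.rel_time[supra[0]]) if supra.size else float(lta.rel_time[peak_idx])
        logger.warning("onset_time: no 20-80%% band samples; degenerate step onset")
        return OnsetEstimate(time=t, degenerate=True)

    t = lta.rel_time[sel]
    y = lta.mean[sel]
    slope, intercept = np.polyfit(t, y, 1)
    if slope <= 0:
        return OnsetEstimate(time=float(t[0]), degenerate=True)
    return OnsetEstimate(time=float((baseline - intercept) / slope), degenerate=False)


def locomotion_induced_metric(treatment_baseline: float, evoked_level: float) -> float:
    """Locomotion-induced dilation in percent of the vehicle basal diameter.

    Both arguments are fractions of the vehicle-condition basal diameter:
    ``treatment_baseline`` is the pre-locomotion baseline under the
    treatment, ``evoked_level`` the locomotion-evoked level.  The metric
    is the change from the treatment pre-locomotion baseline, expressed as
    a percentage of the vehicle basal diameter:

        metric = (evoked_level - treatment_baseline) * 100

    e.g. a vessel constricted to 0.90 of vehicle basal that dilates to
    1.05 during locomotion has a 15% locomotion-induced dilation; one
    dilated to 1.10 that reaches 1.15 has 5%.
    """
    return (evoked_level - treatment_baseline) * 100.0
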