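"""LFP extraction and state-resolved band power.

Raw differential cortical recordings (digitized at 20 kHz) are band-pass
filtered 10-100 Hz (order 4, zero-phase) with a 60 Hz notch to form the
local field potential.  Gamma-band power (40-100 Hz) is the variance of
the band-passed signal, computed separately over stationary ("basal") and
locomotion samples; spectra are averaged modified periodograms normalized
to a reference (vehicle stationary) spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt, welch

from .errors import InvalidParameterError, InvalidRateError

logger = logging.getLogger(__name__)

__all__ = [
    "LFPRecording",
    "BandPower",
    "StateSpectra",
    "extract_lfp",
    "gamma_power",
    "state_spectra",
]

GAMMA_BAND = (40.0, 100.0)


@dataclass
class LFPRecording:
    """Electrophysiology trace in microvolts."""

    samples: np.ndarray
    sample_rate: float
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be 1-D")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class BandPower:
    """Band power (uV^2) split by behavioral state."""

    band: tuple[float, float]
    basal_power: float
    locomotion_power: float

    def __post_init__(self) -> None:
        if self.basal_power < 0 or self.locomotion_power < 0:
            raise InvalidParameterError("powers must be >= 0")

    @property
    def ratio(self) -> float:
        """Locomotion / basal power ratio."""
        return self.locomotion_power / self.basal_power


@dataclass
class StateSpectra:
    """Averaged-periodogram power spectra per behavioral state.

    ``basal`` and ``locomotion`` are PSDs (uV^2/Hz); when built with a
    reference spectrum they are pointwise ratios to it (unitless).
    """

    freq: np.ndarray
    basal: np.ndarray
    locomotion: np.ndarray
    normalized: bool = False


def _notch(x: np.ndarray, fs: float, freq: float = 60.0, q: float = 45.0) -> np.ndarray:
    b, a = iirnotch(freq, q, fs=fs)
    return filtfilt(b, a, x)


def extract_lfp(raw: LFPRecording, band: tuple[float, float] = (10.0, 100.0),
                notch_hz: float = 60.0) -> LFPRecording:
    """Band-pass 10-100 Hz (order 4, zero-phase) plus 60 Hz notch."""
    if raw.sample_rate < 2 * band[1]:
        raise InvalidRateError(
            f"sample_rate {raw.sample_rate} Hz < Nyquist for {band[1]} Hz band edge"
        )
    sos = butter(4, band, btype="bandpass", fs=raw.sample_rate, output="sos")
    x = sosfiltfilt(sos, raw.samples)
    x = _notch(x, raw.sample_rate, notch_hz)
    return LFPRecording(samples=x, sample_rate=raw.sample_rate,
                        ground_truth=raw.ground_truth)


def gamma_power(
    lfp: LFPRecording,
    state_mask: np.ndarray,
    band: tuple[float, float] = GAMMA_BAND,
    notch_hz: float = 60.0,
) -> BandPower:
    """Gamma-band (40-100 Hz) power by behavioral state.

    The signal is band-passed (order 4, zero-phase) with a 60 Hz notch;
    power is the mean squared amplitude over the masked samples —
    ``state_mask`` True marks locomotion, False stationary.
    """
    state_mask = np.asarray(state_mask, dtype=bool)
    if state_mask.shape != lfp.samples.shape:
        raise InvalidParameterError("state_mask must match samples in shape")
    if state_mask.all() or not state_mask.any():
        raise InvalidParameterError("state_mask must contain both states")
    sos = butter(4, band, btype="bandpass", fs=lfp.sample_rate, output="sos")
    x = sosfiltfilt(sos, lfp.samples)
    x = _notch(x, lfp.sample_rate, notch_hz)
    return BandPower(
        band=band,
        basal_power=float(np.mean(x[~state_mask] ** 2)),
        locomotion_power=float(np.mean(x[state_mask] ** 2)),
    )


def _masked_psd(x: np.ndarray, mask: np.ndarray, fs: float, nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD over the contiguous runs of a state mask.

    Runs shorter than one segment are skipped; run periodograms are
    averaged weighted by their number of segments.
    """
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts, stops = np.where(d == 1)[0], np.where(d == -1)[0]
    acc, weight, freqs = None, 0.0, None
    for i0, i1 in zip(starts, stops):
        if i1 - i0 < nperseg:
            continue
        f, p = welch(x[i0:i1], fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
        w = (i1 - i0) / nperseg
        acc = p * w if acc is None else acc + p * w
        weight += w
        freqs = f
    if acc is None:
        raise InvalidParameterError("no state run is long enough for one spectral segment")
    return freqs, acc / weight


def state_spectra(
    lfp: LFPRecording,
    state_mask: np.ndarray,
    reference_spectrum: np.ndarray | None = None,
    segment_s: float = 1.0,
) -> StateSpectra:
    """Power spectra during stationary and locomotion states.

    Averaged modified periodograms (Hann taper, ``segment_s`` windows, 50%
    overlap) per state; if ``reference_spectrum`` is given (the vehicle
    stationary spectrum on the same frequency grid), both spectra are
    divided by it pointwise.
    """
    state_mask = np.asarray(state_mask, dtype=bool)
    if state_mask.shape != lfp.samples.shape:
        raise InvalidParameterError("state_mask must match samples in shape")
    nperseg = int(round(segment_s * lfp.sample_rate))
    freq, basal = _masked_psd(lfp.samples, ~state_mask, lfp.sample_rate, nperseg)
    _, loco = _masked_psd(lfp.samples, state_mask, lfp.sample_rate, nperseg)
    if reference_spectrum is not None:
        reference_spectrum = np.asarray(reference_spectrum, dtype=float)
        if reference_spectrum.shape != basal.shape:
            raise InvalidParameterError("reference spectrum on a different frequency grid")
        with np.errstate(divide="ignore", invalid="ignore"):
            basal = np.where(reference_spectrum > 0, basal / reference_spectrum, np.nan)
            loco = np.where(reference_spectrum > 0, loco / reference_spectrum, np.nan)
        return StateSpectra(freq=freq, basal=basal, locomotion=loco, normalized=True)
    return StateSpectra(freq=freq, basal=basal, locomotion=loco, normalized=False)
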