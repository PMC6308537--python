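"""Filtering, wavelet baseline removal and derivatives for pulse waves.

The preprocessing chain mirrors standard pulse-wave practice: a
zero-phase low-pass filter (default cutoff 50 Hz) strips high-frequency
interference without shifting fiducial timing, then respiratory /
motion baseline wander is removed by subtracting the low-frequency
approximation of a discrete wavelet decomposition (db8, decomposed deep
enough that the approximation band lies below 0.5 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, filtfilt, savgol_filter

from .errors import ParameterError
from .record import PulseRecord

__all__ = [
    "lowpass_filter",
    "remove_baseline",
    "derivatives",
    "preprocess_record",
    "ProcessedRecord",
]


def lowpass_filter(
    samples: np.ndarray, fs: float, cutoff_hz: float = 50.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    A 4th-order Butterworth applied forward-backward (``filtfilt``), so
    the passband gain is within 1% of unity below ``cutoff_hz / 2`` and
    fiducial timing is not skewed by phase delay.

    Raises
    ------
    ParameterError
        If ``fs <= 2 * cutoff_hz`` (cutoff at or above Nyquist).
    """
    samples = np.asarray(samples, dtype=float)
    if fs <= 2.0 * cutoff_hz:
        raise ParameterError(
            f"fs={fs} must exceed twice the cutoff ({cutoff_hz} Hz)"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, samples)


def _baseline_level(fs: float, baseline_cutoff_hz: float) -> int:
    # approximation band of an L-level DWT is [0, fs / 2^(L+1)]
    return max(1, math.ceil(math.log2(fs / baseline_cutoff_hz)) - 1)


def remove_baseline(
    samples: np.ndarray,
    fs: float,
    wavelet: str = "db8",
    baseline_cutoff_hz: float = 0.5,
) -> np.ndarray:
    """Remove baseline wander by wavelet approximation subtraction.

    The signal is decomposed with the given wavelet to the level whose
    approximation band falls below ``baseline_cutoff_hz``; the
    reconstructed approximation (the wander) is subtracted.

    Raises
    ------
    ParameterError
        If the signal is too short to reach the required level.
    """
    samples = np.asarray(samples, dtype=float)
    level = _baseline_level(fs, baseline_cutoff_hz)
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(samples.size, wav.dec_len)
    if level > max_level:
        raise ParameterError(
            f"signal of {samples.size} samples too short for level-{level} "
            f"decomposition (max usable level {max_level})"
        )
    coeffs = pywt.wavedec(samples, wav, level=level)
    # zero every detail band, keep only the approximation -> the wander
    baseline_coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    baseline = pywt.waverec(baseline_coeffs, wav)[: samples.size]
    return samples - baseline


#: Savitzky-Golay derivative window in seconds; wide enough to keep the
#: dicrotic zero-crossings of the first derivative stable under
#: measurement noise, short against the beat period so landmark timing
#: is preserved (the smoother is zero-phase and exact for cubics)
DERIVATIVE_WINDOW_S = 0.08


def derivatives(
    ppw_segment: np.ndarray, fs: float, window_s: float = DERIVATIVE_WINDOW_S
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives by Savitzky-Golay differentiation.

    A cubic Savitzky-Golay smoother (window ``window_s`` seconds, odd
    number of samples) evaluated for its first and second derivative.
    Returns arrays of the same length as the input, in sensor-units per
    second and per second squared.  Exact for polynomials up to degree
    3, including at the edges (polynomial extrapolation fit).
    """
    x = np.asarray(ppw_segment, dtype=float)
    if x.size < 5:
        raise ParameterError("segment must have at least 5 samples")
    w = max(5, int(round(window_s * fs)) | 1)
    if w > x.size:
        w = x.size if x.size % 2 else x.size - 1
    d1 = savgol_filter(x, w, 3, deriv=1, delta=1.0 / fs, mode="interp")
    d2 = savgol_filter(x, w, 3, deriv=2, delta=1.0 / fs, mode="interp")
    return d1, d2


@dataclass
class ProcessedRecord:
    """A record after filtering and baseline removal, with derivatives.

    ``ppw`` is filtered + baseline-removed; ``ppw_filtered`` is filtered
    only (the frame in which amplitude ratios referenced to the sensor
    zero, e.g. PIR, are meaningful); ``ecg`` is the filtered ECG.
    """

    record: PulseRecord
    ppw: np.ndarray
    ppw_filtered: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    ecg: np.ndarray | None

    @property
    def fs(self) -> float:
        return self.record.fs


def preprocess_record(
    record: PulseRecord,
    cutoff_hz: float = 50.0,
    wavelet: str = "db8",
    baseline_cutoff_hz: float = 0.5,
) -> ProcessedRecord:
    """Run the full preprocessing chain on a record."""
    filtered = lowpass_filter(record.ppw, record.fs, cutoff_hz)
    clean = remove_baseline(filtered, record.fs, wavelet, baseline_cutoff_hz)
    d1, d2 = derivatives(clean, record.fs)
    ecg = (
        lowpass_filter(record.ecg, record.fs, cutoff_hz)
        if record.ecg is not None
        else None
    )
    return ProcessedRecord(
        record=record, ppw=clean, ppw_filtered=filtered, d1=d1, d2=d2, ecg=ecg
    )
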