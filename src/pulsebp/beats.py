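"""Beat segmentation and ECG R-peak detection.

Beats are delimited foot-to-foot.  Feet are located at the waveform
minimum immediately preceding each maximum of the first derivative
(the steepest systolic upstroke), which is robust to dicrotic waves and
amplitude drift.  Beats outside 0.3-2 s or containing other than one
systolic peak are discarded and counted.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError
from .preprocessing import ProcessedRecord, derivatives
from .record import Beat

__all__ = ["segment_beats", "detect_r_peaks", "beat_from_samples"]

logger = logging.getLogger(__name__)

MIN_BEAT_S = 0.3
MAX_BEAT_S = 2.0
EDGE_GUARD_S = 1.0


def _upstroke_peaks(d1: np.ndarray, fs: float) -> np.ndarray:
    pos = d1[d1 > 0]
    if pos.size == 0:
        return np.array([], dtype=int)
    p98 = np.percentile(pos, 98)
    if p98 <= 0:
        return np.array([], dtype=int)
    # first pass at a high threshold picks systolic upstrokes only and
    # yields the cardiac period; the second, lower-threshold pass uses a
    # refractory distance from it so steep secondary (dicrotic) rises
    # are not mistaken for upstrokes
    coarse, _ = find_peaks(d1, height=0.6 * p98, distance=max(1, int(MIN_BEAT_S * fs)))
    refractory = max(1, int(MIN_BEAT_S * fs))
    if coarse.size >= 3:
        refractory = max(refractory, int(0.55 * float(np.median(np.diff(coarse)))))
    peaks, _ = find_peaks(d1, height=0.4 * p98, distance=refractory)
    return peaks


def segment_beats(processed: ProcessedRecord) -> list[Beat]:
    """Cut a preprocessed record into foot-to-foot beats.

    Returns an empty list (with a logged warning) when no beats are
    found.  Beats failing the duration gate (0.3-2 s) or the
    single-systolic-peak check are dropped; the count is logged.
    """
    ppw, d1, d2, fs = processed.ppw, processed.d1, processed.d2, processed.fs
    upstrokes = _upstroke_peaks(d1, fs)
    # keep clear of filter edge transients at the record boundaries
    guard = int(EDGE_GUARD_S * fs)
    upstrokes = upstrokes[(upstrokes >= guard) & (upstrokes < ppw.size - guard)]
    if upstrokes.size < 2:
        logger.warning("no beats found in record")
        return []

    # foot = last zero-crossing of the smoothed first derivative before
    # each upstroke peak (the local minimum opening the systolic rise);
    # more stable than a windowed argmin when the diastolic tail is flat
    feet = []
    back = max(1, int(0.35 * fs))
    for p in upstrokes:
        lo = max(0, p - back)
        i = int(p)
        while i > lo and d1[i] > 0:
            i -= 1
        feet.append(i if d1[i] <= 0 else lo + int(np.argmin(ppw[lo : p + 1])))
    feet = np.unique(feet)

    beats: list[Beat] = []
    n_dropped = 0
    for start, end in zip(feet[:-1], feet[1:]):
        start, end = int(start), int(end)
        dur = (end - start) / fs
        if not MIN_BEAT_S <= dur <= MAX_BEAT_S:
            n_dropped += 1
            continue
        seg = ppw[start:end]
        # exactly one systolic (dominant) peak
        prom = 0.5 * np.ptp(seg)
        n_peaks = len(find_peaks(seg, prominence=prom)[0]) if prom > 0 else 0
        if n_peaks != 1:
            n_dropped += 1
            continue
        beats.append(
            Beat(
                start_index=start,
                end_index=end,
                fs=fs,
                ppw_segment=seg,
                d1_segment=d1[start:end],
                d2_segment=d2[start:end],
                raw_segment=processed.ppw_filtered[start:end],
            )
        )
    if n_dropped:
        logger.info("segment_beats: dropped %d beat(s)", n_dropped)
    if not beats:
        logger.warning("no beats passed the duration/peak-count gates")
    return beats


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect ECG R-peaks; returns strictly increasing sample indices.

    An energy-threshold detector: peaks of the squared signal above 20%
    of its 99.5th percentile, separated by at least 0.3 s.  An empty
    array is returned for flat input.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0 or np.ptp(ecg) == 0:
        return np.array([], dtype=int)
    energy = (ecg - np.median(ecg)) ** 2
    height = 0.2 * np.percentile(energy, 99.5)
    if height <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(energy, height=height, distance=max(1, int(MIN_BEAT_S * fs)))
    return peaks.astype(int)


def beat_from_samples(
    ppw_segment: np.ndarray,
    fs: float,
    raw_segment: np.ndarray | None = None,
    start_index: int = 0,
) -> Beat:
    """Wrap a standalone waveform segment as a :class:`Beat`.

    Convenience for working with isolated beats (e.g. synthetic
    templates): derivatives are computed on the segment itself.
    """
    ppw_segment = np.asarray(ppw_segment, dtype=float)
    if ppw_segment.size < 5:
        raise ParameterError("beat segment must have at least 5 samples")
    d1, d2 = derivatives(ppw_segment, fs)
    return Beat(
        start_index=start_index,
        end_index=start_index + ppw_segment.size,
        fs=fs,
        ppw_segment=ppw_segment,
        d1_segment=d1,
        d2_segment=d2,
        raw_segment=raw_segment if raw_segment is not None else ppw_segment,
    )
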