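"""Per-beat landmark (fiducial point) detection on the PPW and derivatives.

Eleven landmarks are located per beat:

* on the waveform itself — A (foot), B (point at the first-derivative
  maximum), C (systolic peak), D (dicrotic foot/notch), E (dicrotic
  peak);
* on the first derivative — F (upstroke onset), G (upstroke peak),
  H (upstroke foot, first zero-crossing after G);
* on the second derivative — N (onset), M (peak), L (foot);

plus the ECG R-peak opening the cardiac cycle, when an ECG channel is
present.

When the dicrotic wave is too weak to produce a zero-crossing pair of
the first derivative on the descending limb, the fallback rule assigns
the maximum of the first derivative inside the search window to both
D and E and flags the beat ``degenerate_dicrotic``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FiducialError
from .record import Beat

__all__ = [
    "FiducialSet",
    "detect_ppw_fiducials",
    "detect_dicrotic",
    "detect_derivative_fiducials",
    "pair_r_peak",
    "detect_fiducials",
    "fiducials_table",
]

#: dicrotic search window as fractions of the beat duration after C
DICROTIC_WINDOW = (0.15, 0.60)
#: onset threshold, as a fraction of the derivative peak, for F and N
ONSET_FRACTION = 0.10
#: physiologic gate on the R-peak -> G delay, seconds
PTT_MIN_S, PTT_MAX_S = 0.05, 0.60


@dataclass
class FiducialSet:
    """Landmark indices for one beat (indices into the beat's segments).

    ``r_peak`` is a record-level sample index into the ECG channel.
    ``degenerate_dicrotic`` marks beats where D and E coincide under the
    fallback rule.
    """

    A: int
    B: int
    C: int
    D: int
    E: int
    F: int
    G: int
    H: int
    N: int
    M: int
    L: int
    r_peak: int | None = None
    degenerate_dicrotic: bool = False

    def __post_init__(self) -> None:
        if not self.A <= self.B <= self.C <= self.D <= self.E:
            raise FiducialError(
                f"landmark ordering violated: A={self.A} B={self.B} C={self.C} "
                f"D={self.D} E={self.E}"
            )
        if self.degenerate_dicrotic and self.D != self.E:
            raise FiducialError("degenerate dicrotic flag requires D == E")


def detect_ppw_fiducials(beat: Beat) -> tuple[int, int, int]:
    """Locate A (foot), B (at d1 maximum) and C (systolic peak).

    A is the minimum opening the systolic rise, found by walking back
    from the upstroke's derivative peak to the last non-positive sample
    of the smoothed first derivative (this coincides with the argmin on
    clean beats but does not jitter across a flat diastolic foot under
    noise).  Ties in argmax/argmin are broken to the first index.
    """
    ppw = beat.ppw_segment
    d1 = beat.d1_segment
    C = int(np.argmax(ppw))
    if C == 0 or C == ppw.size - 1:
        raise FiducialError("no interior systolic maximum; beat unusable")
    g0 = int(np.argmax(d1[: C + 1]))
    i = g0
    while i > 0 and d1[i] > 0:
        i -= 1
    A = i if d1[i] <= 0 or i == 0 else int(np.argmin(ppw[: C + 1]))
    if A == C:
        raise FiducialError("foot and peak coincide; beat unusable")
    B = A + int(np.argmax(d1[A : C + 1]))
    return A, B, C


def detect_dicrotic(
    beat: Beat, C: int, window: tuple[float, float] = DICROTIC_WINDOW
) -> tuple[int, int, bool]:
    """Locate the dicrotic foot D and peak E after the systolic peak.

    The search window spans ``[C + w0*T, C + w1*T]`` in samples, with T
    the beat duration.  In the normal case D is the first upward
    zero-crossing of the first derivative inside the window (after the
    post-systolic descent) and E the subsequent downward zero-crossing
    (the dicrotic summit).  If no crossing pair exists the fallback
    assigns the in-window maximum of the first derivative to both D and
    E, flagged degenerate.
    """
    d1 = beat.d1_segment
    ppw = beat.ppw_segment
    n = ppw.size
    lo = C + int(round(window[0] * n))
    hi = min(n - 1, C + int(round(window[1] * n)))
    if lo >= hi:
        raise FiducialError("dicrotic search window empty; beat unusable")

    D = E = None
    for i in range(lo, hi):
        if d1[i] < 0.0 <= d1[i + 1]:
            D = i + 1
            break
    if D is not None:
        for j in range(D, hi):
            if d1[j] > 0.0 >= d1[j + 1]:
                E = j + 1
                break
        if E is None:
            E = D + int(np.argmax(ppw[D : hi + 1]))
        return D, E, False

    # fallback: monotone decay, no zero-crossing pair in the window
    DE = lo + int(np.argmax(d1[lo : hi + 1]))
    return DE, DE, True


def _onset(deriv: np.ndarray, peak_idx: int, frac: float) -> int:
    """Last index before the peak where the derivative rises through
    ``frac`` of its peak value."""
    thr = frac * deriv[peak_idx]
    i = peak_idx
    while i > 0 and deriv[i - 1] >= thr:
        i -= 1
    return i


def _trough_after(deriv: np.ndarray, peak_idx: int) -> int | None:
    """Deepest negative excursion of a derivative trace after its peak."""
    if peak_idx >= deriv.size - 1:
        return None
    idx = peak_idx + 1 + int(np.argmin(deriv[peak_idx + 1 :]))
    return idx if deriv[idx] < 0 else None


def detect_derivative_fiducials(
    beat: Beat, A: int, C: int, onset_frac: float = ONSET_FRACTION
) -> tuple[int, int, int, int, int, int]:
    """Locate F, G, H on the first derivative and N, M, L on the second.

    G and M are the in-systole argmax of the respective derivative;
    F and N are 10%-of-peak onset crossings before them; H and L the
    feet of the derivative waveforms — their deepest post-peak troughs
    (so d2[M] - d2[L] is the second derivative's full peak-to-trough
    amplitude).  A derivative with no negative excursion after its peak
    (e.g. a pure ramp) makes the beat unusable.
    """
    d1, d2 = beat.d1_segment, beat.d2_segment
    G = A + int(np.argmax(d1[A : C + 1]))
    if d1[G] <= 0:
        raise FiducialError("no positive upstroke in first derivative")
    F = _onset(d1, G, onset_frac)
    H = _trough_after(d1, G)
    if H is None:
        raise FiducialError("no post-peak trough of d1; beat unusable")

    M = A + int(np.argmax(d2[A : C + 1]))
    if d2[M] <= 0:
        raise FiducialError("no positive peak in second derivative")
    N = _onset(d2, M, onset_frac)
    L = _trough_after(d2, M)
    if L is None:
        raise FiducialError("no post-peak trough of d2; beat unusable")
    return F, G, H, N, M, L


def pair_r_peak(
    beat: Beat, G: int, r_peaks: np.ndarray | None, fs: float
) -> int | None:
    """Pair the beat with the R-peak opening its cardiac cycle.

    Returns the latest R-peak preceding the beat's G point (record
    frame) by at least 50 ms and at most 600 ms, or ``None``.
    """
    if r_peaks is None or len(r_peaks) == 0:
        return None
    g_global = beat.start_index + G
    delays = (g_global - np.asarray(r_peaks)) / fs
    ok = (delays >= PTT_MIN_S) & (delays <= PTT_MAX_S)
    if not np.any(ok):
        return None
    return int(np.asarray(r_peaks)[ok][-1])


def detect_fiducials(
    beat: Beat,
    r_peaks: np.ndarray | None = None,
    window: tuple[float, float] = DICROTIC_WINDOW,
    onset_frac: float = ONSET_FRACTION,
) -> FiducialSet:
    """Run the full landmark chain on one beat.

    Raises
    ------
    FiducialError
        If any landmark cannot be located; the beat is unusable.
    """
    A, B, C = detect_ppw_fiducials(beat)
    D, E, degenerate = detect_dicrotic(beat, C, window)
    F, G, H, N, M, L = detect_derivative_fiducials(beat, A, C, onset_frac)
    r = pair_r_peak(beat, G, r_peaks, beat.fs)
    return FiducialSet(
        A=A, B=B, C=C, D=D, E=E, F=F, G=G, H=H, N=N, M=M, L=L,
        r_peak=r, degenerate_dicrotic=degenerate,
    )


def fiducials_table(beats, fiducial_sets, fs: float):
    """Audit dump: one row per (beat, landmark) with index and time.

    Returns a DataFrame with columns beat_id, landmark, sample_index
    (record frame) and time_s, suitable for plotting overlays or
    delimited-text export.
    """
    import pandas as pd

    rows = []
    for beat_id, (beat, fid) in enumerate(zip(beats, fiducial_sets)):
        for name in ("A", "B", "C", "D", "E", "F", "G", "H", "N", "M", "L"):
            idx = beat.start_index + getattr(fid, name)
            rows.append(
                {"beat_id": beat_id, "landmark": name,
                 "sample_index": int(idx), "time_s": idx / fs}
            )
        if fid.r_peak is not None:
            rows.append(
                {"beat_id": beat_id, "landmark": "R",
                 "sample_index": int(fid.r_peak), "time_s": fid.r_peak / fs}
            )
    return pd.DataFrame(rows)
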