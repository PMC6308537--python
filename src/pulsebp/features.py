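"""Waveform features for blood-pressure calibration.

Twenty-one features are computed per beat from the pressure pulse wave
and its first/second derivatives, plus the pulse transit time (PTT,
ECG R-peak to first-derivative peak) when an ECG channel is present.
Beat-level features are averaged to a record-level vector.

Feature catalogue (all times in seconds, amplitudes in sensor units):

====== ===============================================================
name   definition
====== ===============================================================
RtAmCE dicrotic/systolic amplitude ratio (P_E - P_A)/(P_C - P_A)
TmAE   foot -> dicrotic-peak time
TmBE   B -> dicrotic-peak time
TmCD   systolic-peak -> dicrotic-foot time (0 for degenerate beats)
RtTP   TmCD / beat period
K      waveform fullness (Pm - Pd)/(Ps - Pd), Pm the beat mean
K1     systolic fullness: mean over [foot, dicrotic foot]
K2     diastolic fullness: mean over [dicrotic foot, beat end]
AS     ascending discrete area sum_{A..C}(P_i - P_A), normalised by fs
d1_PAm first-derivative peak amplitude d1[G]
d1_TW  first-derivative time width t(H) - t(F)
d2_TAm second-derivative total amplitude d2[M] - d2[L]
d2_PAm second-derivative peak amplitude d2[M]
d2_FAm second-derivative foot amplitude d2[L]
d1_AS  d1 ascending slope d1[G]/(t(G) - t(F))
d1_DS  d1 descending slope |min d1 after G|/(t(H) - t(G))
d1_AA  d1 ascending area sum_{F..C}(d1_i - d1_F), normalised by fs
d2_AS  d2 ascending slope d2[M]/(t(M) - t(N))
d2_DS  d2 descending slope d2[M]/(t(L) - t(M))
d2_AA  d2 ascending area sum_{N..M}(d2_i - d2_N), normalised by fs
PIR    peak/foot intensity ratio in the unshifted (raw) frame
====== ===============================================================

Discrete-area features (AS, d1_AA, d2_AA) are sample sums; they are
reported both raw (``*_raw``) and normalised by the sampling rate so
that their values do not depend on fs.  Models consume the normalised
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beats import detect_r_peaks, segment_beats
from .errors import DegenerateBeatError, FiducialError, RecordRejectedError
from .fiducials import FiducialSet, detect_fiducials
from .preprocessing import preprocess_record
from .record import Beat, PulseRecord

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "k_values",
    "beat_features",
    "record_features",
]

#: the 21 waveform features, in catalogue order; PTT is appended when
#: an ECG channel is available
FEATURE_NAMES: tuple[str, ...] = (
    "RtAmCE", "TmAE", "TmBE", "TmCD", "RtTP",
    "K", "K1", "K2", "AS",
    "d1_PAm", "d1_TW",
    "d2_TAm", "d2_PAm", "d2_FAm",
    "d1_AS", "d1_DS", "d1_AA",
    "d2_AS", "d2_DS", "d2_AA",
    "PIR",
)

RAW_SUM_NAMES: tuple[str, ...] = ("AS_raw", "d1_AA_raw", "d2_AA_raw")


@dataclass
class FeatureVector:
    """Record-level feature vector: per-feature means over accepted beats.

    ``values`` maps feature name to its beat-averaged value (NaN when the
    feature was missing in every beat); ``n_beats`` maps feature name to
    the number of beats that contributed; ``n_accepted`` is the total
    number of beats accepted for the record.
    """

    values: dict[str, float]
    n_beats: dict[str, int] = field(default_factory=dict)
    n_accepted: int = 0

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        s["n_beats"] = self.n_accepted
        return s


def _trapz_mean(y: np.ndarray, fs: float) -> float:
    """Trapezoid-rule mean of a sampled segment over its time span."""
    if y.size < 2:
        raise DegenerateBeatError("segment too short for trapezoid mean")
    return float(np.trapezoid(y, dx=1.0 / fs) / ((y.size - 1) / fs))


def k_values(
    ppw_segment: np.ndarray,
    fs: float,
    fiducials: FiducialSet,
    t1_index: int | None = None,
) -> tuple[float, float, float]:
    """Waveform fullness indices K, K1 and K2 for one beat.

    K normalises the beat's mean pressure between its foot (Pd) and peak
    (Ps): ``K = (Pm - Pd)/(Ps - Pd)``, with Pm the trapezoid-rule mean
    over the full beat.  K1 restricts the mean to the systolic interval
    ``[0, t1]`` and K2 to the diastolic interval ``[t1, T]``, where t1
    is the dicrotic-foot time (overridable via ``t1_index``).

    Raises
    ------
    DegenerateBeatError
        If the beat has no amplitude (Ps == Pd).
    """
    p = np.asarray(ppw_segment, dtype=float)
    pd_ = p[fiducials.A]
    ps = p[fiducials.C]
    if ps == pd_:
        raise DegenerateBeatError("flat beat: Ps == Pd")
    t1 = fiducials.D if t1_index is None else t1_index
    span = ps - pd_
    K = (_trapz_mean(p, fs) - pd_) / span
    K1 = (_trapz_mean(p[: t1 + 1], fs) - pd_) / span if t1 >= 1 else np.nan
    K2 = (_trapz_mean(p[t1:], fs) - pd_) / span if t1 <= p.size - 2 else np.nan
    return float(K), float(K1), float(K2)


def beat_features(beat: Beat, fiducials: FiducialSet, fs: float) -> dict[str, float]:
    """Compute the 21 features (plus PTT and raw area sums) for one beat.

    Missing features (PIR with a non-positive raw foot, PTT without a
    paired R-peak) are NaN, not errors.
    """
    p = beat.ppw_segment
    d1 = beat.d1_segment
    d2 = beat.d2_segment
    f = fiducials
    T = beat.duration

    P1 = p[f.C] - p[f.A]
    P2 = p[f.E] - p[f.A]
    if P1 <= 0:
        raise DegenerateBeatError("non-positive systolic amplitude")

    out: dict[str, float] = {}
    out["RtAmCE"] = P2 / P1
    out["TmAE"] = (f.E - f.A) / fs
    out["TmBE"] = (f.E - f.B) / fs
    if f.degenerate_dicrotic:
        out["TmCD"] = 0.0
        out["RtTP"] = 0.0
    else:
        out["TmCD"] = (f.D - f.C) / fs
        out["RtTP"] = out["TmCD"] / T

    K, K1, K2 = k_values(p, fs, f)
    out["K"], out["K1"], out["K2"] = K, K1, K2

    as_raw = float(np.sum(p[f.A : f.C + 1] - p[f.A]))
    out["AS_raw"] = as_raw
    out["AS"] = as_raw / fs

    out["d1_PAm"] = float(d1[f.G])
    out["d1_TW"] = (f.H - f.F) / fs

    out["d2_TAm"] = float(d2[f.M] - d2[f.L])
    out["d2_PAm"] = float(d2[f.M])
    out["d2_FAm"] = float(d2[f.L])

    out["d1_AS"] = float(d1[f.G] * fs / (f.G - f.F)) if f.G > f.F else np.nan
    d1_min_after_g = float(np.min(d1[f.G :]))
    out["d1_DS"] = (
        abs(d1_min_after_g) * fs / (f.H - f.G) if f.H > f.G else np.nan
    )
    d1aa_raw = float(np.sum(d1[f.F : f.C + 1] - d1[f.F]))
    out["d1_AA_raw"] = d1aa_raw
    out["d1_AA"] = d1aa_raw / fs

    out["d2_AS"] = float(d2[f.M] * fs / (f.M - f.N)) if f.M > f.N else np.nan
    out["d2_DS"] = float(d2[f.M] * fs / (f.L - f.M)) if f.L > f.M else np.nan
    d2aa_raw = float(np.sum(d2[f.N : f.M + 1] - d2[f.N]))
    out["d2_AA_raw"] = d2aa_raw
    out["d2_AA"] = d2aa_raw / fs

    raw = beat.raw_segment if beat.raw_segment is not None else p
    out["PIR"] = float(raw[f.C] / raw[f.A]) if raw[f.A] > 0 else np.nan

    if f.r_peak is not None:
        out["PTT"] = (beat.start_index + f.G - f.r_peak) / fs
    else:
        out["PTT"] = np.nan
    return out


MIN_BEATS_PER_RECORD = 5


def record_features(
    record: PulseRecord,
    cutoff_hz: float = 50.0,
    wavelet: str = "db8",
    baseline_cutoff_hz: float = 0.5,
    dicrotic_window: tuple[float, float] = (0.15, 0.60),
    onset_frac: float = 0.10,
) -> FeatureVector:
    """Extract the record-level feature vector from a raw acquisition.

    Runs preprocessing, beat segmentation, landmark detection and
    per-beat feature computation, then averages each feature over the
    accepted beats (beats where a feature is missing are excluded from
    that feature's mean).

    Raises
    ------
    RecordRejectedError
        If fewer than 5 beats are accepted.
    """
    processed = preprocess_record(record, cutoff_hz, wavelet, baseline_cutoff_hz)
    r_peaks = (
        detect_r_peaks(processed.ecg, record.fs) if processed.ecg is not None else None
    )
    rows: list[dict[str, float]] = []
    for beat in segment_beats(processed):
        try:
            fid = detect_fiducials(
                beat, r_peaks=r_peaks, window=dicrotic_window, onset_frac=onset_frac
            )
            rows.append(beat_features(beat, fid, record.fs))
        except (FiducialError, DegenerateBeatError):
            continue
    if len(rows) < MIN_BEATS_PER_RECORD:
        raise RecordRejectedError(
            f"only {len(rows)} usable beat(s); need >= {MIN_BEATS_PER_RECORD}"
        )
    df = pd.DataFrame(rows)
    means = df.mean(skipna=True)
    counts = df.notna().sum()
    return FeatureVector(
        values={k: float(means[k]) for k in df.columns},
        n_beats={k: int(counts[k]) for k in df.columns},
        n_accepted=len(rows),
    )
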