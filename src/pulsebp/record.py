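"""Data model and text I/O for pulse-wave acquisitions.

A :class:`PulseRecord` is one acquisition: a pressure pulse wave (PPW)
sampled from a skin-contact pressure sensor at the radial artery, an
optional simultaneous ECG channel, the sampling rate, and the reference
cuff blood pressures measured alongside the recording.

On disk a record is a delimited-text signal file (columns: optional
``time``, ``ppw``, optional ``ecg``) plus a JSON sidecar carrying the
metadata (``fs``, ``subject_id``, ``session_time``, optional
``ref_sbp``/``ref_dbp``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

__all__ = ["PulseRecord", "Beat", "read_record", "write_record"]


@dataclass
class PulseRecord:
    """One acquisition of PPW (and optionally ECG) with its metadata.

    Parameters
    ----------
    ppw : ndarray
        Pressure pulse wave samples, sensor units (arbitrary scale).
    fs : float
        Sampling rate in Hz; must be positive.
    ecg : ndarray, optional
        Simultaneous ECG samples; must match ``ppw`` in length.
    subject_id : str
        Opaque subject identifier.
    session_time : str or float
        Timestamp or day-index of the acquisition.
    ref_sbp, ref_dbp : float, optional
        Reference systolic/diastolic pressure in mmHg from a cuff device.
    """

    ppw: np.ndarray
    fs: float
    ecg: np.ndarray | None = None
    subject_id: str = ""
    session_time: str | float = ""
    ref_sbp: float | None = None
    ref_dbp: float | None = None

    def __post_init__(self) -> None:
        self.ppw = np.asarray(self.ppw, dtype=float)
        if self.ppw.ndim != 1 or self.ppw.size == 0:
            raise FormatError("ppw must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.ppw)):
            raise FormatError("ppw contains non-finite samples")
        if not (np.isscalar(self.fs) and np.isfinite(self.fs) and self.fs > 0):
            raise MetadataError(f"fs must be a positive number, got {self.fs!r}")
        self.fs = float(self.fs)
        if self.ecg is not None:
            self.ecg = np.asarray(self.ecg, dtype=float)
            if self.ecg.shape != self.ppw.shape:
                raise FormatError(
                    f"ecg length {self.ecg.size} != ppw length {self.ppw.size}"
                )
            if not np.all(np.isfinite(self.ecg)):
                raise FormatError("ecg contains non-finite samples")
        if self.ref_sbp is not None and self.ref_dbp is not None:
            if not self.ref_sbp > self.ref_dbp:
                raise MetadataError(
                    f"ref_sbp ({self.ref_sbp}) must exceed ref_dbp ({self.ref_dbp})"
                )

    @property
    def n_samples(self) -> int:
        return int(self.ppw.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.ppw.size / self.fs

    def time_axis(self) -> np.ndarray:
        return np.arange(self.ppw.size) / self.fs


@dataclass
class Beat:
    """One foot-to-foot beat cut from a preprocessed record.

    Indices are 0-based; the interval ``[start_index, end_index)`` is
    half-open in record samples.  ``ppw_segment`` is the baseline-removed
    waveform, ``raw_segment`` the filtered but not baseline-removed
    waveform (needed for amplitude-ratio features referenced to the
    sensor's zero), and ``d1_segment``/``d2_segment`` the first and second
    derivatives in sensor-units/s and /s^2.
    """

    start_index: int
    end_index: int
    fs: float
    ppw_segment: np.ndarray
    d1_segment: np.ndarray
    d2_segment: np.ndarray
    raw_segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise FormatError("beat interval must satisfy 0 <= start < end")
        n = len(self.ppw_segment)
        if n != self.end_index - self.start_index:
            raise FormatError("ppw_segment length inconsistent with indices")
        if len(self.d1_segment) != n or len(self.d2_segment) != n:
            raise FormatError("derivative segments must match ppw_segment length")

    @property
    def n_samples(self) -> int:
        return len(self.ppw_segment)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


_META_KEYS = ("fs", "subject_id", "session_time", "ref_sbp", "ref_dbp")


def read_record(signal_path: str | Path, sidecar_path: str | Path) -> PulseRecord:
    """Read a delimited signal file and its JSON metadata sidecar.

    The signal file must have a header row naming at least a ``ppw``
    column; ``ecg`` and ``time`` columns are optional.  If ``time`` is
    present its spacing must agree with the sidecar ``fs`` to 1 part in
    10^3.
    """
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise MetadataError(f"cannot read sidecar {sidecar_path}: {exc}") from exc
    if "fs" not in meta:
        raise MetadataError(f"sidecar {sidecar_path} lacks required key 'fs'")

    df = pd.read_csv(signal_path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    if "ppw" not in df.columns:
        raise FormatError(f"{signal_path}: no 'ppw' column in header")

    fs = meta["fs"]
    if "time" in df.columns and len(df) > 1:
        if not (np.isscalar(fs) and fs and fs > 0):
            raise MetadataError(f"fs must be positive, got {fs!r}")
        dt = np.diff(df["time"].to_numpy(dtype=float))
        if dt.size and not np.allclose(dt, 1.0 / fs, rtol=1e-3, atol=0):
            raise FormatError(
                f"{signal_path}: 'time' spacing inconsistent with fs={fs}"
            )

    try:
        ppw = df["ppw"].to_numpy(dtype=float)
        ecg = df["ecg"].to_numpy(dtype=float) if "ecg" in df.columns else None
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{signal_path}: non-numeric sample values: {exc}") from exc
    return PulseRecord(
        ppw=ppw,
        ecg=ecg,
        fs=fs,
        subject_id=str(meta.get("subject_id", "")),
        session_time=meta.get("session_time", ""),
        ref_sbp=meta.get("ref_sbp"),
        ref_dbp=meta.get("ref_dbp"),
    )


def write_record(
    record: PulseRecord, signal_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write a record to a delimited signal file + JSON sidecar.

    Samples are written with ``repr`` precision so that
    ``read_record(write_record(x))`` round-trips bit-exactly.
    """
    cols = {"ppw": record.ppw}
    if record.ecg is not None:
        cols["ecg"] = record.ecg
    with open(signal_path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in zip(*cols.values()):
            # repr is the shortest exact round-trip representation
            fh.write(",".join(repr(float(v)) for v in row))
            fh.write("\n")
    meta = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "session_time": record.session_time,
        "ref_sbp": record.ref_sbp,
        "ref_dbp": record.ref_dbp,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))
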