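"""Pipeline configuration with lossless JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the extraction/calibration/evaluation pipeline.

    Attributes
    ----------
    cutoff_hz : low-pass filter cutoff, Hz.
    wavelet : wavelet family for baseline removal.
    baseline_cutoff_hz : the baseline approximation band must lie below
        this frequency, Hz.
    dicrotic_window : dicrotic search window as fractions of the beat
        duration after the systolic peak.
    onset_frac : onset threshold for derivative landmarks F and N, as a
        fraction of the derivative peak.
    gamma : trimming fraction of the MPF fusion, in [0, 0.5).
    cp_inclusive : whether |error| equal to a CP threshold counts as
        within it (closed interval).
    welch : Welch (unequal-variance) two-sample t-test for model
        comparison; False selects the pooled-variance flavour.
    seed : base seed for synthetic stages.
    """

    cutoff_hz: float = 50.0
    wavelet: str = "db8"
    baseline_cutoff_hz: float = 0.5
    dicrotic_window: tuple[float, float] = (0.15, 0.60)
    onset_frac: float = 0.10
    gamma: float = 0.1
    cp_inclusive: bool = True
    welch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 0.5:
            raise ParameterError("gamma must lie in [0, 0.5)")
        if self.cutoff_hz <= 0 or self.baseline_cutoff_hz <= 0:
            raise ParameterError("filter cutoffs must be positive")
        self.dicrotic_window = tuple(self.dicrotic_window)  # type: ignore[assignment]
        if not 0 <= self.dicrotic_window[0] < self.dicrotic_window[1]:
            raise ParameterError("dicrotic window fractions must be increasing")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)
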