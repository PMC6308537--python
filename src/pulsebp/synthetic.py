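"""Synthetic pulse-wave records and cohorts with known ground truth.

The generator exists so the whole pipeline is testable without any
recorded data.  A beat is modelled as three Gaussian components
(systolic, reflected, dicrotic) on normalised time plus a slow
exponential diastolic decay; landmark times (foot, systolic peak,
dicrotic foot/peak, first-derivative peak) are computed from the
continuous template on a dense grid, so every detector can be checked
against analytic truth.

Records couple the template to the "true" blood pressure the way real
radial waveforms respond: higher pressure steepens and narrows the
upstroke (larger slope, larger K), advances the dicrotic wave, raises
the heart rate slightly, and shortens the R-peak-to-pulse delay via an
inverse-square-root PTT law.  Additive Gaussian noise at a stated SNR
and a 0.2 Hz sinusoidal baseline drift emulate measurement nuisances.

Cohorts follow a multi-day protocol: a training day with >= 16 records
spread over working hours, then four records on each of several later
test days, with a circadian swing, day-to-day drift and optional
cuff-reference noise.  Two generation modes exist:

``waveform``
    full signal synthesis; features are extracted by the package's own
    pipeline, so the cohort exercises every stage;
``analytic``
    feature tables with exactly linear feature-BP couplings and no
    waveforms; this is the mode in which calibration must recover BP
    exactly, which pins down the correctness of the model layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, RecordRejectedError
from .features import FEATURE_NAMES, record_features
from .record import PulseRecord

__all__ = [
    "BeatTemplate",
    "DEFAULT_TEMPLATE",
    "BPCoupling",
    "generate_beat",
    "generate_record",
    "RecordTruth",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Continuous beat model on normalised time tau in [0, 1).

    Three Gaussian bumps (systolic, reflected, dicrotic) plus an
    exponential diastolic decay.  Setting ``amps[2] = 0`` removes the
    dicrotic wave and produces the degenerate monotone-decay case.
    """

    amps: tuple[float, float, float] = (1.0, 0.38, 0.22)
    centers: tuple[float, float, float] = (0.17, 0.32, 0.58)
    widths: tuple[float, float, float] = (0.065, 0.10, 0.050)
    decay_amp: float = 0.22
    decay_tau: float = 0.16
    period: float = 60.0 / 70.0  # seconds

    def __post_init__(self) -> None:
        if not (self.centers[0] < self.centers[1] < self.centers[2]):
            raise ParameterError("component centers must be increasing")
        if min(self.widths) <= 0 or self.period <= 0 or self.decay_tau <= 0:
            raise ParameterError("widths, period and decay_tau must be positive")
        if min(self.amps) < 0:
            raise ParameterError("component amplitudes must be non-negative")

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate the continuous periodic waveform at normalised times.

        The waveform has period 1 in ``tau`` and is continuous across
        beat boundaries: Gaussian components are wrapped into the
        neighbouring periods, and the diastolic decay launches smoothly
        from the dicrotic wave and runs into the next beat's foot.
        """
        tau = np.asarray(tau, dtype=float) % 1.0
        out = np.zeros_like(tau)
        for k in (-1.0, 0.0, 1.0):
            u = tau + k
            for a, c, w in zip(self.amps, self.centers, self.widths):
                if a > 0:
                    out = out + a * np.exp(-0.5 * ((u - c) / w) ** 2)
            if self.decay_amp > 0:
                v = u - self.centers[2]
                onset = 1.0 / (1.0 + np.exp(-v / 0.03))
                out = out + self.decay_amp * onset * np.exp(
                    -np.clip(v, 0.0, None) / self.decay_tau
                )
        return out

    def landmarks(self, n_dense: int = 12001) -> dict[str, float | None]:
        """Analytic landmark times (seconds from the beat-grid origin).

        Keys: ``foot``, ``peak``, ``dicrotic_foot``, ``dicrotic_peak``
        (the latter two ``None`` when the dicrotic wave is absent),
        ``d1_peak`` (steepest-upstroke time) and ``k`` (the waveform
        fullness the feature extractor should recover).  ``foot`` may be
        slightly negative when the waveform minimum falls just before
        the grid origin.
        """
        tau = np.linspace(-0.45, 1.05, n_dense)
        p = self.evaluate(tau)
        in_core = (tau >= 0.0) & (tau < 0.8)
        i_peak = int(np.flatnonzero(in_core)[np.argmax(p[in_core])])
        before = (tau >= tau[i_peak] - 0.45) & (tau <= tau[i_peak])
        i_foot = int(np.flatnonzero(before)[np.argmin(p[before])])
        d1 = np.gradient(p, tau)
        i_g = i_foot + int(np.argmax(d1[i_foot : i_peak + 1]))

        # first local-min / local-max pair after the systolic peak
        dic_foot = dic_peak = None
        interior = np.arange(i_peak + 1, n_dense - 1)
        mins = interior[(p[interior] < p[interior - 1]) & (p[interior] <= p[interior + 1])]
        for im in mins:
            after = np.arange(im + 1, n_dense - 1)
            maxs = after[(p[after] > p[after - 1]) & (p[after] >= p[after + 1])]
            if maxs.size:
                dic_foot, dic_peak = int(im), int(maxs[0])
                break

        # waveform fullness over one foot-to-foot period, on the same grid
        j = int(np.searchsorted(tau, tau[i_foot] + 1.0))
        j = min(j, n_dense - 1)
        pd_, ps = p[i_foot], p[i_peak]
        pm = np.trapezoid(p[i_foot : j + 1], tau[i_foot : j + 1]) / (
            tau[j] - tau[i_foot]
        )
        k = float((pm - pd_) / (ps - pd_))
        t = lambda i: float(tau[i] * self.period) if i is not None else None
        return {
            "foot": t(i_foot),
            "peak": t(i_peak),
            "dicrotic_foot": t(dic_foot),
            "dicrotic_peak": t(dic_peak),
            "d1_peak": t(i_g),
            "k": k,
        }


DEFAULT_TEMPLATE = BeatTemplate()


def generate_beat(
    template: BeatTemplate, fs: float, duration: float | None = None
) -> tuple[np.ndarray, dict[str, float | None]]:
    """Sample one beat at rate ``fs`` and return it with analytic landmarks.

    The segment starts at the template's foot (so it is a proper
    foot-to-foot beat) and spans ``duration`` seconds (default one
    period).  Landmark times are seconds from the segment start.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    dur = template.period if duration is None else duration
    n = int(round(dur * fs))
    if n < 5:
        raise ParameterError("beat too short at this sampling rate")
    marks = template.landmarks()
    foot_tau = marks["foot"] / template.period
    tau = foot_tau + np.arange(n) / fs / template.period
    shifted = {
        key: (val - marks["foot"] if isinstance(val, float) and key != "k" else val)
        for key, val in marks.items()
    }
    shifted["k"] = marks["k"]
    return template.evaluate(tau), shifted


@dataclass(frozen=True)
class BPCoupling:
    """Monotone mapping from true BP to template parameters and PTT.

    All couplings are affine in ``delta = SBP - 120`` (mmHg); the PTT
    law is ``ptt = ptt_a + ptt_b / sqrt(SBP)`` seconds, the standard
    inverse relation between transit time and pressure.
    """

    base: BeatTemplate = DEFAULT_TEMPLATE
    scale_per_pp: float = 0.03        # amplitude per mmHg pulse pressure
    width_rel_per_mmhg: float = 0.005  # upstroke narrows as SBP rises
    reflected_per_mmhg: float = 0.004
    dicrotic_amp_per_mmhg: float = -0.002
    dicrotic_center_per_mmhg: float = -0.0012
    decay_tau_per_mmhg: float = 0.003  # runoff slows as resistance rises
    hr_base: float = 70.0
    hr_per_mmhg: float = 0.12
    ptt_a: float = 0.05
    ptt_b: float = 2.2
    offset_base: float = 0.8
    offset_per_dbp: float = 0.006

    def template_for(self, sbp: float, dbp: float) -> tuple[BeatTemplate, float, float]:
        """Return (template, amplitude scale, raw-frame DC offset)."""
        delta = sbp - 120.0
        pp = sbp - dbp
        b = self.base
        tmpl = replace(
            b,
            amps=(
                b.amps[0],
                b.amps[1] + self.reflected_per_mmhg * delta,
                max(0.0, b.amps[2] + self.dicrotic_amp_per_mmhg * delta),
            ),
            centers=(
                b.centers[0],
                b.centers[1],
                b.centers[2] + self.dicrotic_center_per_mmhg * delta,
            ),
            widths=(
                b.widths[0] * (1.0 - self.width_rel_per_mmhg * delta),
                b.widths[1],
                b.widths[2],
            ),
            decay_tau=max(0.05, b.decay_tau + self.decay_tau_per_mmhg * delta),
            period=60.0 / (self.hr_base + self.hr_per_mmhg * delta),
        )
        scale = 1.0 + self.scale_per_pp * (pp - 40.0)
        offset = self.offset_base + self.offset_per_dbp * dbp
        return tmpl, scale, offset

    def ptt_for(self, sbp: float) -> float:
        return self.ptt_a + self.ptt_b / np.sqrt(sbp)


def _jitter_template(
    tmpl: BeatTemplate,
    scale: float,
    offset: float,
    ptt: float | None,
    rng: np.random.Generator,
    f: float,
) -> tuple[BeatTemplate, float, float, float | None]:
    """Perturb a record's template by BP-unrelated nuisance variability.

    Emulates respiration, vasomotor tone and sensor-placement changes
    between records: morphology, amplitude, rate, offset and transit
    time all wander a little around their BP-coupled values.  ``f`` is
    the master fraction (0 disables); the per-parameter sigmas below are
    its fixed relative weights.
    """
    if f <= 0:
        return tmpl, scale, offset, ptt
    # per-parameter weights are balanced so that, through its own
    # feature pathway, each physiologic axis contributes a comparable
    # share of BP-unexplained variability (no single axis mimics a
    # coherent pseudo-BP shift for every feature at once)
    g = rng.normal
    a1, a2, a3 = tmpl.amps
    w1, w2, w3 = (w * (1 + g(0, 0.35 * f)) for w in tmpl.widths)
    c1, c2, c3 = tmpl.centers
    c2 = float(np.clip(c2 + g(0, 0.08 * f), c1 + 0.05, c3 - 0.12))
    c3 = float(np.clip(c3 + g(0, 0.08 * f), c2 + 0.12, 0.78))
    jt = replace(
        tmpl,
        amps=(a1, max(0.0, a2 * (1 + g(0, 0.74 * f))), max(0.0, a3 * (1 + g(0, 0.48 * f)))),
        centers=(c1, c2, c3),
        widths=(max(1e-3, w1), max(1e-3, w2), max(1e-3, w3)),
        decay_tau=max(0.05, tmpl.decay_tau * (1 + g(0, 0.35 * f))),
        period=tmpl.period * (1 + g(0, 0.12 * f)),
    )
    scale = scale * (1 + g(0, 0.56 * f))
    offset = offset + g(0, 0.42 * f)
    if ptt is not None:
        ptt = max(0.08, ptt + g(0, 0.06 * f))
    return jt, scale, offset, ptt


DEFAULT_COUPLING = BPCoupling()

ECG_SPIKE_WIDTH_S = 0.012
LEAD_IN_S = 0.7


@dataclass
class RecordTruth:
    """Generator ground truth for one record (times in seconds)."""

    template: BeatTemplate
    foot_times: np.ndarray
    peak_times: np.ndarray
    dicrotic_foot_times: np.ndarray | None
    dicrotic_peak_times: np.ndarray | None
    g_times: np.ndarray
    r_times: np.ndarray | None
    ptt: float | None
    k: float
    scale: float
    offset: float


def generate_record(
    true_sbp: float,
    true_dbp: float,
    fs: float = 2500.0,
    duration: float = 60.0,
    noise_snr_db: float | None = None,
    drift_amp: float = 0.0,
    seed: int | np.random.Generator | None = None,
    include_ecg: bool = True,
    coupling: BPCoupling = DEFAULT_COUPLING,
    morph_jitter: float = 0.0,
    beat_jitter: float = 0.0,
    subject_id: str = "synthetic",
    session_time: str | float = 0.0,
) -> tuple[PulseRecord, RecordTruth]:
    """Synthesise one acquisition at the given true blood pressure.

    ``morph_jitter`` perturbs the whole record's morphology once
    (sensor placement, vasomotor state); ``beat_jitter`` additionally
    perturbs every beat independently (respiration, RR variability,
    per-beat transit-time jitter).  With both at 0 the beat train is
    deterministic in (SBP, DBP); noise, drift phase and jitter consume
    the seed, so a zero-noise record is a pure function of the
    pressures.
    """
    if not true_sbp > true_dbp:
        raise ParameterError("true_sbp must exceed true_dbp")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    tmpl, scale, offset = coupling.template_for(true_sbp, true_dbp)
    ptt_val = float(coupling.ptt_for(true_sbp)) if include_ecg else None
    tmpl, scale, offset, ptt_val = _jitter_template(
        tmpl, scale, offset, ptt_val, rng, morph_jitter
    )
    n_total = int(round(duration * fs))
    t = np.arange(n_total) / fs
    ppw = np.empty(n_total)

    foot_times, peak_times, g_times = [], [], []
    dic_foot_times: list[float] = []
    dic_peak_times: list[float] = []
    r_times_list: list[float] = []

    # beat-by-beat synthesis: each beat may carry its own jittered
    # template; every beat spans one period of its template starting at
    # the template foot, so consecutive beats join near the foot level
    t0 = LEAD_IN_S
    first = True
    record_marks = tmpl.landmarks()
    while t0 < duration:
        if beat_jitter > 0:
            btmpl, bscale, _boff, bptt = _jitter_template(
                tmpl, scale, offset, ptt_val, rng, beat_jitter
            )
            marks = btmpl.landmarks()
        else:
            btmpl, bscale, bptt = tmpl, scale, ptt_val
            marks = record_marks
        foot_tau = marks["foot"] / btmpl.period
        if first:
            # lead-in: periodic continuation of the first beat backwards
            i_lo = 0
            first = False
        else:
            i_lo = int(np.ceil(t0 * fs))
        t_end = t0 + btmpl.period
        i_hi = n_total if t_end >= duration else int(np.ceil(t_end * fs))
        seg_t = t[i_lo:i_hi]
        ppw[i_lo:i_hi] = bscale * btmpl.evaluate(
            foot_tau + (seg_t - t0) / btmpl.period
        )
        if t_end <= duration:  # complete beat: record its ground truth
            foot_times.append(t0)
            peak_times.append(t0 + marks["peak"] - marks["foot"])
            g_times.append(t0 + marks["d1_peak"] - marks["foot"])
            if marks["dicrotic_foot"] is not None:
                dic_foot_times.append(t0 + marks["dicrotic_foot"] - marks["foot"])
                dic_peak_times.append(t0 + marks["dicrotic_peak"] - marks["foot"])
            if bptt is not None:
                r_times_list.append(g_times[-1] - bptt)
        t0 = t_end

    ppw = ppw + offset
    if drift_amp:
        ppw = ppw + drift_amp * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    if noise_snr_db is not None:
        signal_std = float(np.std(ppw - ppw.mean()))
        noise_std = signal_std / 10 ** (noise_snr_db / 20.0)
        ppw = ppw + rng.normal(0.0, noise_std, n_total)

    ecg = None
    r_times = None
    ptt = None
    if include_ecg:
        ptt = ptt_val
        r_times = np.asarray(r_times_list)
        r_times = r_times[r_times > 2 * ECG_SPIKE_WIDTH_S]
        ecg = np.zeros(n_total)
        for rt in r_times:
            ecg += np.exp(-0.5 * ((t - rt) / ECG_SPIKE_WIDTH_S) ** 2)
        if noise_snr_db is not None:
            ecg = ecg + rng.normal(0.0, 10 ** (-noise_snr_db / 20.0), n_total)

    record = PulseRecord(
        ppw=ppw,
        ecg=ecg,
        fs=fs,
        subject_id=subject_id,
        session_time=session_time,
        ref_sbp=float(true_sbp),
        ref_dbp=float(true_dbp),
    )
    truth = RecordTruth(
        template=tmpl,
        foot_times=np.asarray(foot_times),
        peak_times=np.asarray(peak_times),
        dicrotic_foot_times=np.asarray(dic_foot_times) if dic_foot_times else None,
        dicrotic_peak_times=np.asarray(dic_peak_times) if dic_peak_times else None,
        g_times=np.asarray(g_times),
        r_times=r_times,
        ptt=ptt,
        k=float(record_marks["k"]),
        scale=scale,
        offset=offset,
    )
    return record, truth


# --- cohort generation ------------------------------------------------------

#: per-feature (base at SBP 120, slope per mmHg SBP) for the analytic mode;
#: magnitudes are loosely calibrated to waveform-mode extractions, signs
#: follow the physiology (slopes/amplitudes up, dicrotic timing down)
ANALYTIC_COUPLINGS: dict[str, tuple[float, float]] = {
    "RtAmCE": (0.38, -8.0e-4),
    "TmAE": (0.48, -1.2e-3),
    "TmBE": (0.40, -1.1e-3),
    "TmCD": (0.22, -9.0e-4),
    "RtTP": (0.26, -7.0e-4),
    "K": (0.40, 1.0e-3),
    "K1": (0.52, 9.0e-4),
    "K2": (0.28, 8.0e-4),
    "AS": (0.045, 3.0e-4),
    "d1_PAm": (8.0, 6.0e-2),
    "d1_TW": (0.11, -3.0e-4),
    "d2_TAm": (220.0, 1.8),
    "d2_PAm": (130.0, 1.1),
    "d2_FAm": (-90.0, -0.7),
    "d1_AS": (160.0, 1.4),
    "d1_DS": (120.0, 1.0),
    "d1_AA": (0.55, 4.0e-3),
    "d2_AS": (5200.0, 40.0),
    "d2_DS": (3400.0, 26.0),
    "d2_AA": (9.0, 7.0e-2),
    "PIR": (1.45, 2.5e-3),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description for a synthetic multi-day cohort.

    The protocol mirrors a per-subject calibration study: ``n_train``
    records on the training day spread over working hours (09:00-17:00),
    then ``n_per_test_day`` records on each of the ``test_days`` (days
    after training).  The BP trajectory per subject is a circadian
    sinusoid plus Gaussian day-to-day drift plus within-day variability;
    subject means are drawn from ``strata`` (count, mean SBP, mean DBP,
    between-subject SD).
    """

    n_subjects: int = 5
    n_train: int = 16
    test_days: tuple[int, ...] = (1, 3, 6, 8)
    n_per_test_day: int = 4
    mode: str = "waveform"  # or "analytic"
    strata: tuple[tuple[int, float, float, float], ...] | None = None
    sbp_mean: float = 120.0
    dbp_mean: float = 75.0
    between_subject_sd: float = 10.0
    circadian_amp: float = 8.0
    day_drift_sd: float = 3.0
    bp_noise_sd: float = 3.0
    dbp_slope: float = 0.6
    dbp_noise_sd: float = 0.0
    ref_noise_sd: float = 2.0
    # waveform-mode signal parameters
    fs: float = 500.0
    duration: float = 60.0
    noise_snr_db: float | None = 20.0
    drift_amp: float = 0.1
    morph_jitter: float = 0.05
    beat_jitter: float = 0.02
    coupling: BPCoupling = field(default_factory=BPCoupling)

    def __post_init__(self) -> None:
        if self.mode not in ("waveform", "analytic"):
            raise ParameterError(f"unknown cohort mode {self.mode!r}")
        if self.n_subjects < 1 or self.n_train < 2:
            raise ParameterError("need >= 1 subject and >= 2 training records")


@dataclass
class Cohort:
    """Generated cohort: training and testing feature tables.

    ``train``/``test`` rows carry subject_id, day, session_hour, the
    true and reference pressures, and the full feature set.  In
    waveform mode ``records`` optionally holds the raw
    :class:`PulseRecord` objects keyed by (subject_id, day, idx).
    """

    spec: CohortSpec
    train: pd.DataFrame
    test: pd.DataFrame
    records: dict | None = None


def _subject_means(spec: CohortSpec, rng: np.random.Generator):
    if spec.strata is not None:
        means = []
        for count, sbp_m, dbp_m, sd in spec.strata:
            for _ in range(int(count)):
                means.append(
                    (sbp_m + rng.normal(0, sd), dbp_m + rng.normal(0, 0.6 * sd))
                )
        return means
    return [
        (
            spec.sbp_mean + rng.normal(0, spec.between_subject_sd),
            spec.dbp_mean + rng.normal(0, 0.6 * spec.between_subject_sd),
        )
        for _ in range(spec.n_subjects)
    ]


def _bp_at(
    spec: CohortSpec,
    sbp_mean: float,
    dbp_mean: float,
    hour: float,
    day_offset: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    sbp = (
        sbp_mean
        + spec.circadian_amp * np.sin(2 * np.pi * (hour - 6.0) / 24.0)
        + day_offset
        + rng.normal(0, spec.bp_noise_sd)
    )
    dbp = dbp_mean + spec.dbp_slope * (sbp - sbp_mean)
    if spec.dbp_noise_sd:
        dbp += rng.normal(0, spec.dbp_noise_sd)
    if sbp - dbp < 15.0:  # keep a physiologic pulse pressure
        dbp = sbp - 15.0
    return float(sbp), float(dbp)


def _analytic_features(sbp: float) -> dict[str, float]:
    return {
        name: base + slope * (sbp - 120.0)
        for name, (base, slope) in ANALYTIC_COUPLINGS.items()
    }


def generate_cohort(
    spec: CohortSpec,
    seed: int | None = 0,
    keep_records: bool = False,
) -> Cohort:
    """Generate the full multi-day cohort described by ``spec``.

    Deterministic under ``seed``.  In waveform mode each record is
    synthesised and pushed through the package's own feature pipeline;
    records that fail extraction are dropped (rare, logged by the
    pipeline).
    """
    rng = np.random.default_rng(seed)
    means = _subject_means(spec, rng)
    records: dict = {}
    rows_train: list[dict] = []
    rows_test: list[dict] = []

    for s_idx, (sbp_mean, dbp_mean) in enumerate(means):
        sid = f"S{s_idx:03d}"
        day_offsets = {0: 0.0}
        for d in spec.test_days:
            day_offsets[d] = float(rng.normal(0, spec.day_drift_sd))
        sessions: list[tuple[int, float]] = [
            (0, h) for h in np.linspace(9.0, 17.0, spec.n_train)
        ]
        for d in spec.test_days:
            for h in np.sort(rng.uniform(9.0, 17.0, spec.n_per_test_day)):
                sessions.append((d, float(h)))

        for idx, (day, hour) in enumerate(sessions):
            sbp, dbp = _bp_at(spec, sbp_mean, dbp_mean, hour, day_offsets[day], rng)
            row: dict = {
                "subject_id": sid,
                "day": day,
                "session_hour": hour,
                "true_sbp": sbp,
                "true_dbp": dbp,
                "ref_sbp": sbp + rng.normal(0, spec.ref_noise_sd)
                if spec.ref_noise_sd
                else sbp,
                "ref_dbp": dbp + rng.normal(0, spec.ref_noise_sd)
                if spec.ref_noise_sd
                else dbp,
            }
            if spec.mode == "analytic":
                row.update(_analytic_features(sbp))
                row["PTT"] = float(spec.coupling.ptt_for(sbp))
                row["n_beats"] = 0
            else:
                record, _truth = generate_record(
                    sbp,
                    dbp,
                    fs=spec.fs,
                    duration=spec.duration,
                    noise_snr_db=spec.noise_snr_db,
                    drift_amp=spec.drift_amp,
                    seed=rng,
                    coupling=spec.coupling,
                    morph_jitter=spec.morph_jitter,
                    beat_jitter=spec.beat_jitter,
                    subject_id=sid,
                    session_time=f"day{day}_h{hour:.2f}",
                )
                try:
                    fv = record_features(record)
                except RecordRejectedError:
                    continue
                row.update(fv.values)
                row["n_beats"] = fv.n_accepted
                if keep_records:
                    records[(sid, day, idx)] = record
            (rows_train if day == 0 else rows_test).append(row)

    return Cohort(
        spec=spec,
        train=pd.DataFrame(rows_train),
        test=pd.DataFrame(rows_test),
        records=records if keep_records else None,
    )
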