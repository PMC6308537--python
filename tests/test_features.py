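"""Waveform-feature computation: closed forms, invariances, averaging."""

import numpy as np
import pytest

from pulsebp.beats import beat_from_samples
from pulsebp.errors import DegenerateBeatError, RecordRejectedError
from pulsebp.features import FEATURE_NAMES, beat_features, k_values, record_features
from pulsebp.fiducials import FiducialSet, detect_fiducials
from pulsebp.record import PulseRecord
from pulsebp.synthetic import generate_beat, generate_record

FS = 2500.0


def _fid_for(ppw):
    return detect_fiducials(beat_from_samples(ppw, FS))


def _manual_fiducials(n, A, C, D):
    """A minimal FiducialSet for segments where detection is not the point."""
    return FiducialSet(A=A, B=A + 1, C=C, D=D, E=D, F=A, G=A + 1, H=C,
                       N=A, M=A + 1, L=C, degenerate_dicrotic=True)


class TestKValues:
    def test_triangle_k_half(self):
        n = 2000
        up = np.linspace(0.0, 1.0, n // 2, endpoint=False)
        down = np.linspace(1.0, 0.0, n // 2)
        ppw = np.concatenate([up, down])
        fid = _manual_fiducials(n, A=0, C=n // 2 - 1, D=3 * n // 4)
        K, _, _ = k_values(ppw, FS, fid)
        assert K == pytest.approx(0.5, abs=1e-3)

    def test_half_sine_k_two_over_pi(self):
        T = 0.8
        n = int(T * FS)
        t = np.arange(n) / FS
        pd_, ps = 10.0, 20.0
        ppw = pd_ + (ps - pd_) * np.sin(np.pi * t / T)
        fid = _manual_fiducials(n, A=0, C=int(np.argmax(ppw)), D=3 * n // 4)
        K, _, _ = k_values(ppw, FS, fid)
        assert K == pytest.approx(2 / np.pi, rel=0.005)

    def test_constant_tail_gives_k2_zero(self):
        n = 1000
        rise = np.linspace(0.0, 1.0, 200)
        fall = np.linspace(1.0, 0.0, 300)[1:]
        tail = np.zeros(n - len(rise) - len(fall))
        ppw = np.concatenate([rise, fall, tail])
        D = len(rise) + len(fall) - 1
        fid = _manual_fiducials(n, A=0, C=199, D=D)
        _, _, K2 = k_values(ppw, FS, fid)
        assert K2 == pytest.approx(0.0, abs=1e-9)

    def test_flat_beat_degenerate(self):
        fid = _manual_fiducials(100, A=0, C=50, D=70)
        with pytest.raises(DegenerateBeatError):
            k_values(np.ones(100), FS, fid)

    def test_k_bounded_on_generator_beats(self, coupling, rng):
        for _ in range(30):
            sbp = rng.uniform(90, 160)
            tmpl, scale, _ = coupling.template_for(sbp, 0.6 * sbp + 4)
            ppw, _ = generate_beat(tmpl, FS)
            fid = _fid_for(scale * ppw)
            K, K1, K2 = k_values(scale * ppw, FS, fid)
            for v in (K, K1, K2):
                assert 0.0 <= v <= 1.0

    def test_k_matches_dense_oracle(self, coupling):
        tmpl, scale, _ = coupling.template_for(125, 80)
        ppw, marks = generate_beat(tmpl, FS)
        fid = _fid_for(scale * ppw)
        K, _, _ = k_values(scale * ppw, FS, fid)
        assert K == pytest.approx(marks["k"], abs=0.01)


class TestBeatFeatures:
    def _features(self, coupling, sbp=120.0, dbp=80.0, scale_mult=1.0):
        tmpl, scale, offset = coupling.template_for(sbp, dbp)
        ppw, marks = generate_beat(tmpl, FS)
        ppw = scale * scale_mult * ppw
        beat = beat_from_samples(ppw, FS, raw_segment=ppw + offset)
        fid = detect_fiducials(beat)
        return beat_features(beat, fid, FS), marks, fid

    def test_exactly_21_canonical_features(self, coupling):
        out, _, _ = self._features(coupling)
        assert set(FEATURE_NAMES) <= set(out)
        assert len(FEATURE_NAMES) == 21

    def test_timing_features_match_truth(self, coupling):
        out, marks, _ = self._features(coupling)
        assert out["TmAE"] == pytest.approx(marks["dicrotic_peak"] - marks["foot"], abs=0.015)
        assert out["TmCD"] == pytest.approx(
            marks["dicrotic_foot"] - marks["peak"], abs=0.015
        )

    def test_degenerate_dicrotic_zero_features(self):
        from pulsebp.synthetic import BeatTemplate

        tmpl = BeatTemplate(amps=(1.0, 0.25, 0.0), decay_amp=0.0)
        ppw, _ = generate_beat(tmpl, FS)
        beat = beat_from_samples(ppw, FS)
        fid = detect_fiducials(beat)
        assert fid.degenerate_dicrotic
        out = beat_features(beat, fid, FS)
        assert out["TmCD"] == 0.0 and out["RtTP"] == 0.0
        assert out["TmAE"] == pytest.approx(
            out["TmBE"] + (fid.B - fid.A) / FS, abs=1e-9
        )

    def test_amplitude_scaling_invariance_and_equivariance(self, coupling):
        base, _, _ = self._features(coupling, scale_mult=1.0)
        scaled, _, _ = self._features(coupling, scale_mult=3.0)
        for name in ("RtAmCE", "K", "K1", "K2", "RtTP", "TmAE", "TmCD", "d1_TW"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-6), name
        for name in ("d1_PAm", "AS", "d2_PAm", "d1_AA"):
            assert scaled[name] == pytest.approx(3.0 * base[name], rel=1e-6), name

    def test_pir_requires_positive_raw_foot(self, coupling):
        tmpl, scale, _ = coupling.template_for(120, 80)
        ppw, _ = generate_beat(tmpl, FS)
        ppw = scale * ppw
        beat = beat_from_samples(ppw, FS, raw_segment=ppw - 10.0)  # foot below zero
        fid = detect_fiducials(beat)
        out = beat_features(beat, fid, FS)
        assert np.isnan(out["PIR"])

    def test_area_sums_reported_raw_and_normalised(self, coupling):
        out, _, _ = self._features(coupling)
        for name in ("AS", "d1_AA", "d2_AA"):
            assert out[f"{name}_raw"] == pytest.approx(out[name] * FS, rel=1e-9)


class TestRecordFeatures:
    def test_identical_beats_average_to_beat_value(self, clean_record):
        rec, truth = clean_record
        fv = record_features(rec)
        assert fv.n_accepted >= 5
        assert fv.values["K"] == pytest.approx(truth.k, abs=0.01)
        assert fv.values["PTT"] == pytest.approx(truth.ptt, abs=0.005)

    def test_record_without_ecg_has_nan_ptt(self):
        rec, _ = generate_record(120, 80, fs=500, duration=20, include_ecg=False)
        fv = record_features(rec)
        assert np.isnan(fv.values["PTT"])
        assert fv.n_beats["K"] == fv.n_accepted

    def test_too_few_beats_rejected(self):
        rec, _ = generate_record(120, 80, fs=500, duration=20)
        # flatten everything after ~4 s: only ~3 complete beats remain
        ppw = rec.ppw.copy()
        ppw[int(4.0 * 500):] = ppw[int(4.0 * 500)]
        with pytest.raises(RecordRejectedError):
            record_features(PulseRecord(ppw=ppw, fs=500.0))

    def test_missing_feature_bookkeeping(self, clean_record):
        rec, _ = clean_record
        fv = record_features(rec)
        # every canonical feature present in every accepted beat here
        for name in FEATURE_NAMES:
            assert fv.n_beats[name] == fv.n_accepted, name

    def test_time_dilation_scales_time_features(self, coupling):
        from dataclasses import replace

        tmpl, scale, _ = coupling.template_for(120, 80)
        slow = replace(tmpl, period=tmpl.period * 1.2)
        ppw_a, _ = generate_beat(tmpl, FS)
        ppw_b, _ = generate_beat(slow, FS)
        fa = beat_features(
            (ba := beat_from_samples(scale * ppw_a, FS)), detect_fiducials(ba), FS
        )
        fb = beat_features(
            (bb := beat_from_samples(scale * ppw_b, FS)), detect_fiducials(bb), FS
        )
        for name in ("TmAE", "TmBE", "TmCD", "d1_TW"):
            assert fb[name] == pytest.approx(1.2 * fa[name], rel=0.03), name
        for name in ("RtAmCE", "K", "RtTP"):
            assert fb[name] == pytest.approx(fa[name], rel=0.03), name
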