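"""R-peak detection, beat segmentation, and fiducial location."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ppgbp.beats import detect_r_peaks, locate_fiducials, segment_beats
from ppgbp.preprocess import ProcessedSignals, preprocess_record
from ppgbp.synthetic import (
    MorphologyParams,
    SubjectSpec,
    generate_subject,
    template_landmarks,
)

FS = 125.0


def _processed(record):
    return preprocess_record(record)


def _one_beat(morph, noise_sd=0.0, seed=0, pat=0.25, hr=60.0):
    spec = SubjectSpec(
        heart_rate=hr, pat_true=pat, noise_sd=noise_sd, seed=seed,
        morphology=morph, duration=12.0,
    )
    rec = generate_subject(spec)
    proc = _processed(rec)
    r = detect_r_peaks(proc.ecg_f, proc.fs)
    beats = segment_beats(proc, r, abp=rec.abp)
    assert beats, "no beats detected"
    return rec, beats[len(beats) // 2]


class TestDetectRPeaks:
    def test_recovers_ground_truth_times(self, clean_record):
        _, rec = clean_record
        proc = _processed(rec)
        det = detect_r_peaks(proc.ecg_f, proc.fs)
        gt = rec.ground_truth.r_times
        assert abs(len(det) - len(gt)) <= 1
        interior = gt[(gt > 1.0) & (gt < rec.duration - 1.0)]
        errs = np.array([np.min(np.abs(det - x)) for x in interior])
        assert np.max(errs) <= 1.0 / FS

    def test_flat_signal_gives_empty(self):
        assert detect_r_peaks(np.zeros(1000), FS).size == 0

    def test_refractory_at_high_heart_rate(self):
        spec = SubjectSpec(heart_rate=180.0, pat_true=0.15, duration=30.0)
        rec = generate_subject(spec)
        det = detect_r_peaks(_processed(rec).ecg_f, FS)
        assert np.all(np.diff(det) >= 0.2)


class TestSegmentBeats:
    def _proc_of_length(self, n):
        z = np.zeros(n)
        return ProcessedSignals(ecg_f=z, ppg_n=z, vpg=z, apg=z, fs=FS)

    def test_n_minus_one_segments_inside_margins(self):
        proc = self._proc_of_length(int(130 * FS))
        r = np.arange(2.0, 123.0, 1.0)  # 121 R times, margin-safe
        assert len(segment_beats(proc, r)) == 120

    def test_single_pair_spans_interval(self):
        proc = self._proc_of_length(int(20 * FS))
        (beat,) = segment_beats(proc, np.array([10.0, 11.0]))
        assert beat.r_time == 10.0 and beat.r_next == 11.0
        assert beat.start_index == int(round(10.0 * FS))
        assert len(beat.ppg) == int(round(11.0 * FS)) - int(round(10.0 * FS))

    def test_non_monotone_r_sequence_rejected(self):
        proc = self._proc_of_length(int(20 * FS))
        with pytest.raises(ValueError, match="non-monotone"):
            segment_beats(proc, np.array([5.0, 5.0, 6.0]))

    def test_fewer_than_two_r_times_gives_empty(self):
        proc = self._proc_of_length(int(20 * FS))
        assert segment_beats(proc, np.array([5.0])) == []


class TestLocateFiducials:
    def test_two_lobe_landmarks_match_template(self):
        morph = MorphologyParams()
        rec, beat = _one_beat(morph)
        fid = locate_fiducials(beat)
        truth = template_landmarks(morph, 1.0)
        onset_idx = np.argmin(np.abs(rec.ground_truth.r_times - beat.r_time))
        onset = rec.ground_truth.ppg_onset_times[onset_idx]
        for name in ("S", "N", "D"):
            err = abs(fid.time(name) - onset - truth[name]) * FS
            assert err <= 2.0, f"{name} off by {err:.2f} samples"

    def test_single_lobe_has_no_notch_or_diastolic_peak(self):
        morph = MorphologyParams(dicrotic_amplitude=0.0)
        _, beat = _one_beat(morph)
        fid = locate_fiducials(beat)
        for name in ("S", "O", "w", "a", "b"):
            assert fid.has(name), f"{name} should be present"
        assert not fid.has("N") and not fid.has("D")

    def test_projection_amplitudes_equal_lower_level_samples(self):
        _, beat = _one_beat(MorphologyParams(), noise_sd=0.02, seed=4)
        fid = locate_fiducials(beat)
        for q in ("a", "b", "c", "d", "e"):
            if fid.has(q):
                i = fid.points[q].index
                assert fid.points[f"{q}_-2"].value == beat.ppg[i]
                assert fid.points[f"{q}_-1"].value == beat.vpg[i]
                assert fid.points[f"{q}_-2"].time == fid.points[q].time

    def test_translation_equivariance(self):
        spec = SubjectSpec(heart_rate=70.0, pat_true=0.25, duration=20.0)
        rec = generate_subject(spec)
        proc = _processed(rec)
        k = 7
        shifted = ProcessedSignals(
            ecg_f=np.concatenate([np.zeros(k), proc.ecg_f[:-k]]),
            ppg_n=np.concatenate([np.full(k, proc.ppg_n[0]), proc.ppg_n[:-k]]),
            vpg=np.concatenate([np.full(k, proc.vpg[0]), proc.vpg[:-k]]),
            apg=np.concatenate([np.full(k, proc.apg[0]), proc.apg[:-k]]),
            fs=proc.fs,
        )
        r = detect_r_peaks(proc.ecg_f, FS)
        r_shift = detect_r_peaks(shifted.ecg_f, FS)
        b = segment_beats(proc, r)[5]
        bs = segment_beats(shifted, r_shift)[5]
        f, fsh = locate_fiducials(b), locate_fiducials(bs)
        for name in ("O", "S", "w", "a", "b"):
            assert fsh.time(name) - f.time(name) == pytest.approx(k / FS, abs=1e-6)

    @given(
        dic=st.floats(0.25, 0.8),
        delay=st.floats(0.20, 0.34),
        notch=st.floats(0.0, 0.9),
        width=st.floats(0.12, 0.20),
    )
    def test_landmark_ordering_invariant(self, dic, delay, notch, width):
        morph = MorphologyParams(
            systolic_width=width, dicrotic_amplitude=dic,
            dicrotic_delay=delay, notch_depth=notch,
        )
        _, beat = _one_beat(morph)
        fid = locate_fiducials(beat)
        assert fid.valid
        t = fid.time
        assert t("O") <= t("w") + 1e-9 <= t("S") + 1e-9
        apg_seq = [t(q) for q in ("a", "b", "c", "d", "e") if fid.has(q)]
        assert apg_seq == sorted(apg_seq)
        if fid.has("N") and fid.has("D"):
            assert t("S") < t("N") < t("D")
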