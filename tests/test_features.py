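"""Feature-family operators, the ten-feature vector, and aggregation."""

import numpy as np
import pytest

from fiducial_builder import build_random_fiducials
from ppgbp.features import (
    FeatureVector,
    aggregate_subject,
    amplitude,
    apg_composite,
    compute_pat,
    compute_table1_features,
    power_area,
    slope,
    time_span,
    waveform_area,
)

FS = 125.0


@pytest.fixture
def handmade():
    return build_random_fiducials(np.random.default_rng(42))


class TestOperators:
    def test_time_span_is_signed_difference(self, handmade):
        _, fid, idx = handmade
        assert time_span(fid, "S", "c") == pytest.approx(
            (idx["c"] - idx["S"]) / FS
        )
        assert time_span(fid, "S", "S") == 0.0
        assert time_span(fid, "c", "S") == -time_span(fid, "S", "c")

    def test_amplitude_is_baseline_relative(self, handmade):
        beat, fid, idx = handmade
        assert amplitude(fid, "O") == 0.0  # PPG baseline is the onset value
        assert amplitude(fid, "S") == beat.ppg[idx["S"]] - beat.ppg[idx["O"]]
        assert amplitude(fid, "a") == beat.apg[idx["a"]]  # APG baseline: zero

    def test_missing_landmark_gives_nan(self, handmade):
        _, fid, _ = handmade
        del fid.points["D"]
        assert np.isnan(time_span(fid, "S", "D"))
        assert np.isnan(amplitude(fid, "D"))

    def test_slope_hand_value_and_symmetry(self, handmade):
        _, fid, _ = handmade
        s = slope(fid, "S", "c")
        expected = (amplitude(fid, "c") - amplitude(fid, "S")) / time_span(
            fid, "S", "c"
        )
        assert s == pytest.approx(expected)
        assert slope(fid, "c", "S") == pytest.approx(s)
        assert np.isnan(slope(fid, "S", "S"))

    def test_waveform_area_hand_case_and_additivity(self, handmade):
        beat, fid, idx = handmade
        base = beat.ppg[idx["O"]]
        expected = float(np.sum(beat.ppg[idx["S"] : idx["c"] + 1] - base))
        assert waveform_area(beat, fid, "S", "c") == pytest.approx(expected)
        whole = waveform_area(beat, fid, "S", "d")
        split = (
            waveform_area(beat, fid, "S", "c")
            + waveform_area(beat, fid, "c", "d")
            - (beat.ppg[idx["c"]] - base)
        )
        assert whole == pytest.approx(split)
        with pytest.raises(ValueError, match="reversed"):
            waveform_area(beat, fid, "c", "S")

    def test_power_area_is_quadratic_sum(self, handmade):
        beat, fid, idx = handmade
        expected = float(np.sum(beat.ppg[idx["O"] : idx["S"] + 1] ** 2))
        assert power_area(beat, fid, "O", "S") == pytest.approx(expected)
        assert power_area(beat, fid, "O", "S") >= 0.0

    def test_apg_composites(self, handmade):
        _, fid, idx = handmade
        a = fid.value("a")
        b, c, d = fid.value("b"), fid.value("c"), fid.value("d")
        assert apg_composite(fid, "b/a") == pytest.approx(b / a)
        assert apg_composite(fid, "(b-c-d)/a") == pytest.approx((b - c - d) / a)
        with pytest.raises(ValueError, match="unknown"):
            apg_composite(fid, "a/b")


class TestComputePAT:
    def test_pat_is_r_to_b_projection_interval(self, handmade):
        beat, fid, idx = handmade
        expected = idx["b"] / FS - beat.r_time
        assert compute_pat(beat.r_time, fid) == pytest.approx(expected)
        assert fid.time("b_-2") == fid.time("b")

    def test_missing_b_gives_nan_not_zero(self, handmade):
        beat, fid, _ = handmade
        for k in ("b", "b_-1", "b_-2"):
            fid.points.pop(k, None)
        assert np.isnan(compute_pat(beat.r_time, fid))


class TestTable1Vector:
    def test_scale_invariance_classes(self, handmade):
        beat, fid, idx = handmade
        fv = compute_table1_features(beat, fid)
        k = 3.7
        beat.ppg *= k
        beat.vpg *= k
        beat.apg *= k
        # rebuild fiducials over the scaled beat with identical indices
        from ppgbp.beats import Landmark

        for name, lm in list(fid.points.items()):
            sig = {"ppg": beat.ppg, "vpg": beat.vpg, "apg": beat.apg}[lm.level]
            fid.points[name] = Landmark(lm.time, lm.index, float(sig[lm.index]), lm.level)
        fv2 = compute_table1_features(beat, fid)
        for name in ("f1", "f4", "f6", "f8", "f9"):  # ratios: scale-free
            assert fv2.values[name] == pytest.approx(fv.values[name], rel=1e-9)
        for name in ("f2", "f7", "f10"):  # amplitudes/slopes: scale by k
            assert fv2.values[name] == pytest.approx(k * fv.values[name], rel=1e-9)

    def test_missing_inputs_propagate(self, handmade):
        beat, fid, _ = handmade
        for k in ("d", "d_-1", "d_-2"):
            fid.points.pop(k, None)
        fv = compute_table1_features(beat, fid)
        for name in ("f2", "f5", "f6", "f7", "f9"):
            assert np.isnan(fv.values[name])
        assert np.isfinite(fv.values["f3"])


class TestAggregateSubject:
    def _fv(self, x):
        return FeatureVector(pat=x, values={f"f{i}": x for i in range(1, 11)})

    def test_identical_beats_aggregate_to_themselves(self):
        agg = aggregate_subject([self._fv(0.3)] * 5)
        assert agg.pat == 0.3
        assert agg.values["f4"] == 0.3
        assert agg.n_beats == 5

    def test_median_robust_to_single_outlier(self):
        fvs = [self._fv(1.0)] * 99 + [self._fv(1e6)]
        assert aggregate_subject(fvs).values["f1"] == 1.0

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        for n in (5, 6):
            vals = rng.normal(size=n)
            fvs = [self._fv(v) for v in vals]
            s = np.sort(vals)
            expected = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
            assert aggregate_subject(fvs).pat == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject([])
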