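"""Median-beat construction, landmark delineation, morphological features."""

import numpy as np
import pytest

from fibrillens.beat_morphology import (
    Landmarks,
    MedianBeat,
    extract_beat_segments,
    find_landmarks,
    median_beat,
    morphological_features,
)
from fibrillens.errors import DelineationError
from fibrillens.preprocess import bandpass_filter, detect_rpeaks
from fibrillens.synthetic import SynthParams, synth_record

FS = 300.0


def _delineate(rec):
    xf = bandpass_filter(rec.samples, rec.fs)
    rp = detect_rpeaks(xf, rec.fs)
    mb = median_beat(extract_beat_segments(xf, rp, rec.fs), rec.fs)
    return mb, find_landmarks(mb)


class TestBeatSegments:
    def test_window_span_and_length(self):
        x = np.arange(1000.0)
        seg = extract_beat_segments(x, [100], FS)
        assert seg.shape == (1, 211)  # 0.25*300 + 0.45*300 + 1
        np.testing.assert_array_equal(seg[0], x[25:236])

    def test_window_leaving_record_is_dropped(self):
        x = np.arange(1000.0)
        with pytest.raises(DelineationError):
            extract_beat_segments(x, [10], FS)

    def test_one_window_per_interior_peak(self):
        x = np.zeros(3000)
        seg = extract_beat_segments(x, [300, 600, 900, 1200, 1500], FS)
        assert seg.shape[0] == 5


class TestMedianBeat:
    def test_identical_segments_unchanged(self, rng):
        a = rng.normal(size=211)
        mb = median_beat([a, a, a], FS)
        np.testing.assert_array_equal(mb.waveform, a)
        assert mb.r_offset == 75

    def test_outlier_rejected_by_majority(self, rng):
        a = rng.normal(size=211)
        mb = median_beat([a, a + 5000.0, a], FS)
        np.testing.assert_array_equal(mb.waveform, a)

    def test_matches_sort_based_oracle(self, rng):
        seg = rng.normal(size=(6, 50))
        got = median_beat(seg, FS).waveform
        # independent oracle: per-sample sort, mean of the two central ranks
        expected = np.array(
            [(np.sort(seg[:, j])[2] + np.sort(seg[:, j])[3]) / 2 for j in range(50)]
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_unequal_lengths_raise(self):
        from fibrillens.errors import ValidationError

        with pytest.raises(ValidationError):
            median_beat([np.zeros(10), np.zeros(11)], FS)


class TestLandmarks:
    def test_clean_beat_landmarks_match_generator_truth(self, clean_nonaf):
        rec, truth = clean_nonaf
        mb, lm = _delineate(rec)
        ms = 1000.0 / rec.fs
        for name, true_ms in truth.landmarks_ms.items():
            got_ms = (getattr(lm, name) - mb.r_offset) * ms
            assert got_ms == pytest.approx(true_ms, abs=20.0), name

    def test_rp_is_global_absolute_maximum(self, clean_nonaf):
        rec, _ = clean_nonaf
        mb, lm = _delineate(rec)
        assert lm.Rp == int(np.argmax(np.abs(mb.waveform)))

    @pytest.mark.parametrize("af", [False, True])
    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_ordering_invariant_on_generator_beats(self, af, seed):
        rec, _ = synth_record(SynthParams.for_class(af), seed=seed)
        _mb, lm = _delineate(rec)
        assert lm.ordered()

    def test_monotone_tail_reports_missing_landmark(self):
        # ramp after a spike: no sign change after Tp
        w = np.concatenate([np.zeros(60), [5, 100, 5], np.linspace(0, 50, 148)])
        with pytest.raises(DelineationError):
            find_landmarks(MedianBeat(w, 61, FS))


class TestMorphFeatures:
    @staticmethod
    def _toy():
        w = np.zeros(211)
        b_idx = 100 - 24  # baseline 80 ms before Rp at fs 300
        w[b_idx] = 7.0  # non-zero baseline level
        w[40] = 57.0  # Pp: b + 50
        w[100] = 1007.0  # Rp
        w[160] = 207.0  # Tp: b + 200
        lm = Landmarks(Pp=40, Rp=100, Tp=160, QRSon=90, QRSoff=112, Toff=190)
        return MedianBeat(w, 75, FS), lm

    def test_interval_unit_arithmetic(self):
        mb, lm = self._toy()
        f = morphological_features(mb, lm)
        assert f.PpRp == pytest.approx((100 - 40) * 1000 / FS)  # 200 ms
        assert f.QRSonQRSoff == pytest.approx((112 - 90) * 1000 / FS)
        assert f.QRSonToff == pytest.approx(f.QRSonQRSoff + f.QRSoffToff, abs=1e-9)

    def test_amplitudes_relative_to_baseline(self):
        mb, lm = self._toy()
        f = morphological_features(mb, lm)
        assert f.AP == pytest.approx(50.0)
        assert f.AT == pytest.approx(200.0)

    def test_aqrs_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            w = rng.normal(size=211) * 100
            lm = Landmarks(Pp=30, Rp=75, Tp=150, QRSon=60, QRSoff=100, Toff=190)
            f = morphological_features(MedianBeat(w, 75, FS), lm)
            expected = max(w[i] for i in range(60, 101)) - min(
                w[i] for i in range(60, 101)
            )
            assert f.AQRS == pytest.approx(expected, abs=1e-12)

    def test_amplitudes_invariant_to_constant_offset(self):
        mb, lm = self._toy()
        f0 = morphological_features(mb, lm)
        shifted = MedianBeat(mb.waveform + 123.0, mb.r_offset, FS)
        f1 = morphological_features(shifted, lm)
        for name in ("AP", "AQRSon", "AQRS", "AQRSoff", "AT"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), abs=1e-9)

    def test_time_features_invariant_to_amplitude_scaling(self):
        mb, lm = self._toy()
        f0 = morphological_features(mb, lm)
        scaled = MedianBeat(mb.waveform * 3.5, mb.r_offset, FS)
        f1 = morphological_features(scaled, lm)
        for name in ("PpRp", "PpQRSoff", "QRSonQRSoff", "QRSonToff", "QRSoffToff"):
            assert getattr(f1, name) == getattr(f0, name)

    def test_vanishing_ap_caps_the_ratio(self):
        mb, lm = self._toy()
        mb.waveform[40] = mb.waveform[100 - 24]  # AP exactly zero
        f = morphological_features(mb, lm)
        assert abs(f.AQRS_over_AP) == pytest.approx(1e4)
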