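"""Resampling, normalization, windowing, heartbeat extraction, balancing."""

import numpy as np
import pytest

from ecgfusion.core import ECGRecord
from ecgfusion.preprocess import (balance_and_split, extract_heartbeats,
                                  minmax_normalize, normalized_record,
                                  resample_to_250, slide_rhythm_windows)
from ecgfusion.synth import SynthParams, generate_record


class TestResample:
    def test_250_is_identity(self):
        x = np.random.default_rng(0).random(1000)
        assert resample_to_250(x, 250) is not None
        assert np.array_equal(resample_to_250(x, 250), x)

    def test_360_output_length(self):
        x = np.zeros(3600)
        assert len(resample_to_250(x, 360)) == 2500  # ceil(3600 * 25/36)

    def test_tone_survives_resampling(self):
        # 10 Hz sine at 360 Hz must come out at 10 Hz at 250 Hz (FFT oracle)
        t = np.arange(3600) / 360.0
        y = resample_to_250(np.sin(2 * np.pi * 10 * t), 360)
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(len(y), d=1 / 250.0)
        assert abs(freqs[np.argmax(spec)] - 10.0) <= freqs[1]

    def test_unsupported_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_to_250(np.zeros(100), 300)


class TestMinMax:
    def test_linear_map(self):
        assert np.allclose(minmax_normalize([-1, 0, 1]), [0, 0.5, 1])

    def test_identity_on_unit_range(self):
        x = np.array([0.0, 0.25, 1.0])
        assert np.allclose(minmax_normalize(x), x)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            minmax_normalize([5.0, 5.0, 5.0])


class TestWindows:
    def test_count_and_starts_10s(self, clean_record):
        rec = generate_record(SynthParams(duration=10, fs=250, seed=0))
        windows = slide_rhythm_windows(normalized_record(rec))
        assert len(windows) == 8  # floor((2500 - 750)/250) + 1
        assert [w.start_sample for w in windows] == list(range(0, 2000, 250))
        assert all(len(w.samples) == 750 for w in windows)

    def test_exactly_3s_record_gives_one_window(self):
        rec = generate_record(SynthParams(duration=3, fs=250, seed=0))
        assert len(slide_rhythm_windows(normalized_record(rec))) == 1

    def test_shorter_than_3s_gives_empty(self):
        rec = generate_record(SynthParams(duration=2.5, fs=250, seed=0))
        assert slide_rhythm_windows(normalized_record(rec)) == []

    def test_labels_follow_interval_overlap(self):
        sig = np.tile(np.linspace(0, 1, 50), 50)[None, :]
        rec = ECGRecord("r", 250, ["I"], sig,
                        beat_ann=[], rhythm_ann=[(0, "NSR"), (1000, "VT")])
        windows = slide_rhythm_windows(rec)
        # oracle: any-overlap of [start, start+750) with [1000, 2500)
        expected = [int(w.start_sample + 750 > 1000) for w in windows]
        assert [w.label for w in windows] == expected
        assert expected.count(1) >= 1 and expected.count(0) >= 1


class TestHeartbeats:
    def test_n_minus_2_beats(self, clean_record):
        rec = generate_record(SynthParams(duration=10, fs=250, heart_rate=60, seed=0))
        beats = extract_heartbeats(normalized_record(rec))
        assert len(rec.beat_ann) == 10
        assert len(beats) == 8

    def test_excerpt_lengths_at_constant_rr(self):
        rec = normalized_record(generate_record(
            SynthParams(duration=10, fs=250, heart_rate=60, seed=1)))
        for b in extract_heartbeats(rec):
            assert len(b.samples) == 500
            assert b.right_r == 500 and b.left_r == 0 and b.r_index == 250

    def test_abnormal_symbol_labels_beat(self):
        rec = normalized_record(generate_record(SynthParams(
            duration=10, fs=250, heart_rate=60, seed=2,
            anomaly_plan=[{"beat_index": 4, "kind": "wide_qrs"}])))
        beats = extract_heartbeats(rec)
        labels = {b.symbol: b.label for b in beats}
        assert labels["PVC"] == 1 and labels["N"] == 0

    def test_too_few_beats_gives_empty(self):
        sig = np.zeros((1, 1000))
        rec = ECGRecord("r", 250, ["I"], sig, beat_ann=[(100, "N"), (300, "N")])
        assert extract_heartbeats(rec) == []

    def test_spans_tile_with_double_coverage(self):
        rec = normalized_record(generate_record(
            SynthParams(duration=12, fs=250, heart_rate=75, seed=3)))
        beats = extract_heartbeats(rec)
        r = [s for s, _ in rec.beat_ann]
        coverage = np.zeros(rec.n_samples, dtype=int)
        for b in beats:
            coverage[b.start_sample : b.start_sample + len(b.samples)] += 1
        # between R(1) and R(n-2) every sample is covered exactly twice
        assert np.all(coverage[r[1] : r[-2]] == 2)


class TestBalanceAndSplit:
    def test_study_scale_arithmetic(self):
        labels = np.zeros(26_532 + 1_199_065, dtype=int)
        labels[:26_532] = 1
        items = np.arange(len(labels))
        train, test = balance_and_split(list(items), labels, 0.9, seed=0)
        assert len(train) + len(test) == 53_064
        assert len(test) == 5306
        assert len(train) == 47_758

    def test_class_balance_within_one(self):
        rng = np.random.default_rng(1)
        labels = (rng.random(1000) < 0.2).astype(int)
        train, test = balance_and_split(list(range(1000)), labels, 0.9, seed=2)
        for split in (train, test):
            ones = sum(lab for _, lab in split)
            assert abs(ones - (len(split) - ones)) <= 1

    def test_deterministic_under_seed(self):
        labels = np.array([0, 1] * 50)
        a = balance_and_split(list(range(100)), labels, 0.9, seed=3)
        b = balance_and_split(list(range(100)), labels, 0.9, seed=3)
        assert a == b

    def test_one_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_and_split([1, 2, 3], [0, 0, 0], 0.9, seed=0)


def test_normalized_record_rescales_annotations():
    rec = generate_record(SynthParams(duration=10, fs=360, heart_rate=60, seed=4))
    out = normalized_record(rec)
    assert out.fs == 250
    assert out.signal.min() == 0.0 and out.signal.max() == 1.0
    for (orig, _), (scaled, _) in zip(rec.beat_ann, out.beat_ann):
        assert scaled == min(int(round(orig * 250 / 360)), out.n_samples - 1)
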