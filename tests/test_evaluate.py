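"""Confusion/metric arithmetic and the two-stage detector's bookkeeping."""

import numpy as np
import pytest

from ecgfusion.core import Heartbeat, Segment
from ecgfusion.evaluate import (ConfusionCounts, confusion, detect_anomalies,
                                metrics)
from ecgfusion.preprocess import normalized_record
from ecgfusion.synth import SynthParams, generate_record


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_complete_disagreement(self):
        c = confusion([1, 0], [0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 1, 0, 1)

    def test_counts_partition_the_items(self):
        rng = np.random.default_rng(0)
        pred, true = rng.integers(0, 2, 500), rng.integers(0, 2, 500)
        assert confusion(pred, true).total == 500

    def test_brute_force_agreement_on_random_labels(self):
        rng = np.random.default_rng(1)
        pred, true = rng.integers(0, 2, 200), rng.integers(0, 2, 200)
        c = confusion(pred, true)
        expect = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, true):
            expect[{(1, 1): "tp", (1, 0): "fp", (0, 0): "tn", (0, 1): "fn"}[(p, t)]] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == tuple(expect.values())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])


class TestMetrics:
    def test_best_rhythm_row(self):
        m = metrics(ConfusionCounts(tp=2646, fp=4, tn=2649, fn=7)).rounded()
        assert m == {"sen": 99.74, "far": 0.15, "ppv": 99.85, "acc": 99.79}

    def test_best_heartbeat_row(self):
        m = metrics(ConfusionCounts(tp=2396, fp=11, tn=2414, fn=29)).rounded()
        assert m == {"sen": 98.80, "far": 0.45, "ppv": 99.54, "acc": 99.18}

    def test_perfect_predictor(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (m.sen, m.far, m.ppv, m.acc) == (100.0, 0.0, 100.0, 100.0)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.sen is None and m.ppv is None
        assert m.far == 0.0 and m.acc == 100.0
        assert m.rounded()["sen"] is None

    def test_full_precision_retained_internally(self):
        m = metrics(ConfusionCounts(tp=2646, fp=4, tn=2649, fn=7))
        assert m.sen == pytest.approx(100.0 * 2646 / 2653)
        assert m.sen != m.rounded()["sen"]


def _const_scorer(value):
    return lambda item: value


def _rhythm_oracle(record):
    """Scores 1.0 for windows overlapping a planted abnormal interval, else 0."""
    abnormal = [(a, b) for a, b, sym in record.rhythm_intervals() if sym != "NSR"]

    def score(seg):
        end = seg.start_sample + len(seg.samples)
        return 1.0 if any(a < end and seg.start_sample < b for a, b in abnormal) else 0.0

    return score


class TestDetector:
    def test_all_normal_record_scans_every_beat(self):
        rec = normalized_record(generate_record(
            SynthParams(duration=20, fs=250, heart_rate=60, seed=51)))
        report = detect_anomalies(rec, _const_scorer(0.0), _const_scorer(0.0))
        assert report.rhythm_intervals == []
        assert len(report.beat_flags) == len(rec.beat_ann) - 2
        assert report.skipped_beats == []

    def test_abnormal_span_flagged_and_inner_beats_skipped(self):
        rec = normalized_record(generate_record(SynthParams(
            duration=30, fs=250, heart_rate=60, seed=52,
            rhythm_plan=[{"start_beat": 10, "end_beat": 15, "symbol": "VT"}])))
        report = detect_anomalies(rec, _rhythm_oracle(rec), _const_scorer(0.0))
        planted = [iv for iv in rec.rhythm_intervals() if iv[2] == "VT"][0]
        assert len(report.rhythm_intervals) == 1
        a, b = report.rhythm_intervals[0]
        assert a < planted[1] and planted[0] < b  # overlap
        for r in report.skipped_beats:
            assert any(x <= r < y for x, y in report.rhythm_intervals)

    def test_every_beat_dispatched_exactly_once(self):
        rec = normalized_record(generate_record(SynthParams(
            duration=30, fs=250, heart_rate=75, seed=53,
            rhythm_plan=[{"start_beat": 5, "end_beat": 12, "symbol": "AFIB"}])))
        report = detect_anomalies(rec, _rhythm_oracle(rec), _const_scorer(1.0))
        scanned = {s for s, _, _ in report.beat_flags}
        skipped = set(report.skipped_beats)
        assert scanned.isdisjoint(skipped)
        assert len(scanned) + len(skipped) == len(rec.beat_ann) - 2

    def test_short_record_gives_empty_report_with_warning(self):
        rec = normalized_record(generate_record(
            SynthParams(duration=2.5, fs=250, heart_rate=60, seed=54)))
        with pytest.warns(UserWarning, match="shorter than 3 s"):
            report = detect_anomalies(rec, _const_scorer(0.0), _const_scorer(0.0))
        assert report.rhythm_intervals == [] and report.beat_flags == []

    def test_missing_model_rejected(self):
        rec = normalized_record(generate_record(SynthParams(duration=5, seed=55)))
        with pytest.raises(ValueError):
            detect_anomalies(rec, None, _const_scorer(0.0))
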