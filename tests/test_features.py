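"""Moment formulas vs brute-force oracles; feature-vector schemas; the scaler."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgfusion.core import Heartbeat, Segment
from ecgfusion.features import (HEARTBEAT_FEATURE_NAMES, RHYTHM_FEATURE_NAMES,
                                FeatureScaler, apply_scaler, fit_scaler,
                                heartbeat_features, kurtosis, rhythm_features,
                                skewness, variance)
from ecgfusion.preprocess import (extract_heartbeats, normalized_record,
                                  slide_rhythm_windows)
from ecgfusion.synth import SynthParams, generate_record


def _brute_moments(x):
    """Independent one-pass moment sums (the oracle)."""
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    sd = m2**0.5
    return m3 / sd**3, m4 / sd**4, sum((v - mu) ** 2 for v in x) / (n - 1)


finite_arrays = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=3, max_size=50,
).filter(lambda xs: max(xs) - min(xs) > 1e-6)


class TestMoments:
    def test_symmetric_sample_has_zero_skewness(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_quarter_closed_form(self):
        # Bernoulli(p): skewness = (1 - 2p) / sqrt(p(1-p)); here p = 1/4
        assert skewness([0, 0, 0, 1]) == pytest.approx(2 / np.sqrt(3), abs=1e-12)
        assert skewness([0, 0, 0, 1]) == pytest.approx(1.1547, abs=1e-4)

    def test_negation_flips_skewness(self):
        x = np.array([0.1, 0.5, 0.9, 3.0])
        assert skewness(-x) == pytest.approx(-skewness(x), abs=1e-12)

    def test_two_point_kurtosis_is_one(self):
        assert kurtosis([-1, 1, -1, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_kurtosis_approaches_three(self):
        x = np.random.default_rng(5).standard_normal(100_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.1)
        assert kurtosis(x, excess=True) == pytest.approx(0.0, abs=0.1)

    def test_kurtosis_affine_invariance(self):
        x = np.array([0.0, 1.0, 1.5, 4.0, -2.0])
        assert kurtosis(3.7 * x - 2.0) == pytest.approx(kurtosis(x), abs=1e-10)

    def test_variance_examples(self):
        assert variance([0.0, 2.0]) == pytest.approx(2.0)
        assert variance([3.0, 3.0, 3.0]) == 0.0

    @pytest.mark.parametrize("fn", [skewness, kurtosis])
    def test_constant_input_rejected(self, fn):
        with pytest.raises(ValueError, match="sigma = 0"):
            fn([2.0, 2.0, 2.0])

    def test_variance_needs_two_samples(self):
        with pytest.raises(ValueError):
            variance([1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(finite_arrays)
    def test_agreement_with_brute_force(self, xs):
        sk, ku, va = _brute_moments(xs)
        assert skewness(xs) == pytest.approx(sk, abs=1e-9, rel=1e-9)
        assert kurtosis(xs) == pytest.approx(ku, abs=1e-9, rel=1e-9)
        assert variance(xs) == pytest.approx(va, abs=1e-9, rel=1e-9)


@pytest.fixture(scope="module")
def nsr_record():
    return normalized_record(generate_record(
        SynthParams(duration=20, fs=250, heart_rate=60, seed=41)))


class TestRhythmFeatures:
    def test_schema_length_and_order(self, nsr_record):
        seg = slide_rhythm_windows(nsr_record)[3]
        v = rhythm_features(seg)
        assert v.shape == (9,)
        assert len(RHYTHM_FEATURE_NAMES) == 9

    def test_clean_nsr_values(self, nsr_record):
        seg = slide_rhythm_windows(nsr_record)[3]
        v = dict(zip(RHYTHM_FEATURE_NAMES, rhythm_features(seg)))
        assert v["n_r_pan_tompkins"] == 3.0
        assert v["n_r_seeht"] == 3.0
        assert v["avg_rr"] == pytest.approx(1.0, abs=0.02)
        assert v["avg_qrs"] > 0 and v["avg_pr"] > 0 and v["avg_qt"] > 0

    def test_flat_segment_is_total_zeros_where_undefined(self):
        seg = Segment(samples=np.zeros(750), fs=250, label=0)
        v = dict(zip(RHYTHM_FEATURE_NAMES, rhythm_features(seg)))
        assert v["n_r_pan_tompkins"] == 0 and v["n_r_seeht"] == 0
        assert v["skewness"] == 0 and v["kurtosis"] == 0 and v["variance"] == 0
        assert v["avg_rr"] == v["avg_qrs"] == v["avg_pr"] == v["avg_qt"] == 0

    def test_deterministic(self, nsr_record):
        seg = slide_rhythm_windows(nsr_record)[2]
        assert np.array_equal(rhythm_features(seg), rhythm_features(seg))


class TestHeartbeatFeatures:
    def test_schema_and_all_positive_on_normal_beat(self, nsr_record):
        beat = extract_heartbeats(nsr_record)[4]
        v = heartbeat_features(beat)
        assert v.shape == (11,)
        assert len(HEARTBEAT_FEATURE_NAMES) == 11
        assert np.all(v > 0)

    def test_absent_p_zeros_p_entries_only(self):
        rec = normalized_record(generate_record(SynthParams(
            duration=20, fs=250, heart_rate=60, seed=42,
            anomaly_plan=[{"beat_index": 5, "kind": "absent_p"}])))
        beat = [b for b in extract_heartbeats(rec) if b.symbol == "J"][0]
        v = dict(zip(HEARTBEAT_FEATURE_NAMES, heartbeat_features(beat)))
        assert v["p_amp"] == 0.0 and v["pr_len"] == 0.0
        for name in ("r_amp", "rr_left", "rr_right", "qrs_len", "qt_len", "t_amp"):
            assert v[name] > 0


class TestScaler:
    def test_training_columns_span_unit_interval(self):
        rng = np.random.default_rng(6)
        train = rng.random((20, 5)) * 10 - 3
        scaled = apply_scaler(fit_scaler(train), train)
        assert np.allclose(scaled.min(axis=0), 0.0)
        assert np.allclose(scaled.max(axis=0), 1.0)

    def test_out_of_range_clipped(self):
        scaler = fit_scaler(np.array([[0.0, 0.0], [1.0, 2.0]]))
        out = apply_scaler(scaler, np.array([5.0, -1.0]))
        assert out.tolist() == [1.0, 0.0]

    def test_constant_feature_maps_to_zero(self):
        scaler = fit_scaler(np.array([[1.0, 7.0], [2.0, 7.0]]))
        assert apply_scaler(scaler, np.array([1.5, 7.0])).tolist() == [0.5, 0.0]

    def test_json_round_trip(self):
        scaler = fit_scaler(np.array([[0.0, -2.0], [4.0, 2.0]]))
        back = FeatureScaler.from_json(scaler.to_json())
        v = np.array([1.0, 0.0])
        assert np.array_equal(apply_scaler(back, v), apply_scaler(scaler, v))
        json.loads(scaler.to_json())  # well-formed document

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.array([[1.0, 2.0]]))
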