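"""Handcrafted feature vectors and the statistical moments they build on.

Rhythm segments get a 9-entry vector; single heartbeats an 11-entry vector.
The moment conventions are deliberately mixed and honored literally: skewness
and kurtosis use *population* central moments (``mu3 / sigma^3`` and
``mu4 / sigma^4``, non-excess), while variance uses the ``N - 1`` sample
denominator.  Interval averages include beats whose waves went undetected
(their intervals are 0 by the zero-sentinel rule) rather than skipping them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import Heartbeat, Segment
from .delineate import DelineatorConfig, delineate_beat, measure_intervals
from .rpeak import DetectorConfig, pan_tompkins, seeht

__all__ = [
    "skewness", "kurtosis", "variance",
    "RHYTHM_FEATURE_NAMES", "HEARTBEAT_FEATURE_NAMES",
    "rhythm_features", "heartbeat_features",
    "FeatureScaler", "fit_scaler", "apply_scaler",
]

#: Fixed schema of the 9-dim rhythm vector (order is part of the contract —
#: trained merged-model weights depend on it).
RHYTHM_FEATURE_NAMES = (
    "n_r_pan_tompkins", "n_r_seeht", "skewness", "kurtosis", "variance",
    "avg_rr", "avg_qrs", "avg_pr", "avg_qt",
)

#: Fixed schema of the 11-dim heartbeat vector.
HEARTBEAT_FEATURE_NAMES = (
    "r_amp", "rr_left", "rr_right", "skewness", "kurtosis", "variance",
    "qrs_len", "pr_len", "qt_len", "p_amp", "t_amp",
)


def _moments(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    sigma = np.sqrt(np.mean((x - mu) ** 2))
    return mu, sigma


def skewness(x: np.ndarray) -> float:
    """Third standardized moment ``mu3 / sigma^3`` (population convention)."""
    x = np.asarray(x, dtype=float)
    mu, sigma = _moments(x)
    if sigma == 0:
        raise ValueError("skewness undefined for a constant signal (sigma = 0)")
    return float(np.mean((x - mu) ** 3) / sigma**3)


def kurtosis(x: np.ndarray, excess: bool = False) -> float:
    """Fourth standardized moment ``mu4 / sigma^4``.

    Non-excess by default (a Gaussian gives 3); pass ``excess=True`` to
    subtract 3.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma = _moments(x)
    if sigma == 0:
        raise ValueError("kurtosis undefined for a constant signal (sigma = 0)")
    k = float(np.mean((x - mu) ** 4) / sigma**4)
    return k - 3.0 if excess else k


def variance(x: np.ndarray) -> float:
    """Sample variance with the ``N - 1`` denominator."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("variance needs at least 2 samples")
    mu = x.mean()
    return float(np.sum(np.abs(x - mu) ** 2) / (x.size - 1))


def _safe_moment(fn, x) -> float:
    """0 for constant input — feature vectors must stay total."""
    try:
        return fn(x)
    except ValueError:
        return 0.0


def rhythm_features(segment: Segment | np.ndarray, fs: float = 250.0,
                    detector_config: DetectorConfig | None = None,
                    delineator_config: DelineatorConfig | None = None) -> np.ndarray:
    """The 9-dim rhythm feature vector for one 3-second segment.

    Runs both R detectors; their detection counts are the first two entries.
    Every beat the Pan–Tompkins detector finds is delineated and its QRS / PR /
    QT intervals measured; averages include undetected-wave zeros.  Moments are
    computed over the raw segment samples.  A segment with no detected beats
    yields zero counts and zero averages.
    """
    x = segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if isinstance(segment, Segment):
        fs = segment.fs
    pt = pan_tompkins(x, fs, detector_config)
    se = seeht(x, fs, detector_config)

    r = pt.r_indices
    avg_rr = float(np.mean(np.diff(r)) / fs) if len(r) >= 2 else 0.0
    qrs, pr, qt = [], [], []
    if len(r) >= 1:
        rr_med = int(np.median(np.diff(r))) if len(r) >= 2 else int(fs)
        for i, ri in enumerate(r):
            left = int(r[i - 1]) if i > 0 else max(0, int(ri) - rr_med)
            right = int(r[i + 1]) if i + 1 < len(r) else min(len(x), int(ri) + rr_med)
            fid = delineate_beat(x, fs, int(ri), left, right, delineator_config)
            iv = measure_intervals(fid, left, right, fs, x)
            qrs.append(iv.qrs_len)
            pr.append(iv.pr_len)
            qt.append(iv.qt_len)

    return np.array([
        float(len(pt)), float(len(se)),
        _safe_moment(skewness, x), _safe_moment(kurtosis, x),
        _safe_moment(variance, x),
        avg_rr,
        float(np.mean(qrs)) if qrs else 0.0,
        float(np.mean(pr)) if pr else 0.0,
        float(np.mean(qt)) if qt else 0.0,
    ])


def heartbeat_features(beat: Heartbeat,
                       delineator_config: DelineatorConfig | None = None) -> np.ndarray:
    """The 11-dim heartbeat feature vector for one R-to-R-bounded excerpt.

    Fiducials come from the delineator; amplitudes are read off the normalized
    excerpt; undetected waves contribute 0 to both their interval and their
    amplitude entries.
    """
    x = beat.samples
    fid = delineate_beat(x, beat.fs, beat.r_index, beat.left_r,
                         min(beat.right_r, len(x) - 1), delineator_config)
    iv = measure_intervals(fid, beat.left_r, beat.right_r, beat.fs, x)
    return np.array([
        iv.r_amp, iv.rr_left, iv.rr_right,
        _safe_moment(skewness, x), _safe_moment(kurtosis, x),
        _safe_moment(variance, x),
        iv.qrs_len, iv.pr_len, iv.qt_len, iv.p_amp, iv.t_amp,
    ])


@dataclass
class FeatureScaler:
    """Trainable per-feature min–max scaler onto [0, 1].

    Fit on training vectors only; applying to out-of-range test values clips
    into [0, 1].  A feature constant across training maps to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, v: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(v, dtype=float))
        span = self.maxs - self.mins
        out = np.zeros_like(v)
        nz = span > 0
        out[:, nz] = (v[:, nz] - self.mins[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0).squeeze()

    def to_json(self) -> str:
        return json.dumps({"mins": self.mins.tolist(), "maxs": self.maxs.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        d = json.loads(text)
        return cls(np.asarray(d["mins"], float), np.asarray(d["maxs"], float))


def fit_scaler(train_vectors: np.ndarray) -> FeatureScaler:
    """Learn per-feature (min, max) over the training set."""
    v = np.atleast_2d(np.asarray(train_vectors, dtype=float))
    if v.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    return FeatureScaler(mins=v.min(axis=0), maxs=v.max(axis=0))


def apply_scaler(scaler: FeatureScaler, v: np.ndarray) -> np.ndarray:
    return scaler.transform(v)
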