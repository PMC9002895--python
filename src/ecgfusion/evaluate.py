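"""Confusion counts, detection metrics, and the end-to-end two-stage detector.

The positive class is always *abnormal* (label 1).  Metrics are the four used
throughout the arrhythmia-detection literature:

    SEN = TP / (TP + FN)            sensitivity (true-positive rate)
    FAR = FP / (FP + TN)            false-alarm rate = 1 - specificity
    PPV = TP / (TP + FP)            positive predictive value
    ACC = (TP + TN) / total         accuracy

reported as percentages; display rounding is half-up to two decimals while
full precision is retained internally.  A zero denominator makes the metric
undefined (``None``), never silently 0.

The two-stage detector first scores every 3-second window on both leads and
fuses the per-lead scores; beats whose central R falls only inside *normal*
fused windows are then scored by the heartbeat model — abnormal rhythm spans
are reported as intervals, and irregular beats inside normal rhythm as
individual flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .core import ECGRecord
from .model import fuse_leads
from .preprocess import extract_heartbeats, slide_rhythm_windows

__all__ = ["ConfusionCounts", "Metrics", "confusion", "metrics",
           "DetectionReport", "detect_anomalies"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """SEN/FAR/PPV/ACC as percentages; ``None`` marks an undefined metric."""

    sen: float | None
    far: float | None
    ppv: float | None
    acc: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Half-up display rounding, as in published result tables."""
        q = Decimal(10) ** -ndigits

        def r(v):
            return None if v is None else float(Decimal(repr(v)).quantize(q, ROUND_HALF_UP))

        return {"sen": r(self.sen), "far": r(self.far), "ppv": r(self.ppv), "acc": r(self.acc)}


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    """Count TP/FP/TN/FN with abnormal (1) as the positive class."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """The four detection metrics, in percent, at full precision."""
    div = lambda a, b: 100.0 * a / b if b > 0 else None  # noqa: E731
    return Metrics(
        sen=div(c.tp, c.tp + c.fn),
        far=div(c.fp, c.fp + c.tn),
        ppv=div(c.tp, c.tp + c.fp),
        acc=div(c.tp + c.tn, c.total),
    )


@dataclass
class DetectionReport:
    """Output of the two-stage detector.

    ``rhythm_intervals`` are merged half-open ``(start, end)`` sample spans
    fused-classified abnormal; ``beat_flags`` are ``(sample, label, score)``
    for every beat scanned by stage 2; ``skipped_beats`` are R samples inside
    abnormal rhythm, not beat-scanned.
    """

    rhythm_intervals: list[tuple[int, int]]
    window_scores: list[dict]
    beat_flags: list[tuple[int, int, float]]
    skipped_beats: list[int]

    def to_dict(self) -> dict:
        return {
            "rhythm_intervals": [list(iv) for iv in self.rhythm_intervals],
            "beat_flags": [[s, l, round(y, 6)] for s, l, y in self.beat_flags],
            "skipped_beats": list(self.skipped_beats),
        }


def _merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def detect_anomalies(record: ECGRecord, rhythm_scorer, beat_scorer) -> DetectionReport:
    """Run the two-stage detector over a normalized 250 Hz record.

    ``rhythm_scorer(segment) -> score`` and ``beat_scorer(heartbeat) -> score``
    are scoring callables in [0, 1] (typically trained merged models behind a
    featurizing wrapper; stubs work for plumbing tests).  Each may also be a
    pair of callables, one per lead — the usual case, since one model is
    trained per lead.  Scores from the record's two leads are fused per
    window / beat.
    """
    if rhythm_scorer is None or beat_scorer is None:
        raise ValueError("both a rhythm scorer and a beat scorer are required")

    def per_lead(scorer):
        pair = list(scorer) if isinstance(scorer, (tuple, list)) else [scorer, scorer]
        if len(pair) != 2 or not all(callable(s) for s in pair):
            raise ValueError("scorer must be a callable or a pair of callables")
        return pair

    rhythm_pair, beat_pair = per_lead(rhythm_scorer), per_lead(beat_scorer)
    fs = int(record.fs)
    per_lead_windows = [slide_rhythm_windows(record, lead) for lead in range(len(record.leads))]
    if not per_lead_windows[0]:
        warnings.warn(f"record {record.record_id} shorter than 3 s; empty report")
        return DetectionReport([], [], [], [])

    abnormal_spans: list[tuple[int, int]] = []
    window_scores = []
    for windows in zip(*per_lead_windows):
        y1 = float(rhythm_pair[0](windows[0]))
        y2 = float(rhythm_pair[1](windows[1])) if len(windows) > 1 else y1
        fused = fuse_leads(y1, y2)
        start = windows[0].start_sample
        window_scores.append({"start": start, "y1": y1, "y2": y2,
                              "y": fused.y, "label": fused.label})
        if fused.label == 1:
            abnormal_spans.append((start, start + 3 * fs))
    intervals = _merge_intervals(abnormal_spans)

    per_lead_beats = [extract_heartbeats(record, lead) for lead in range(len(record.leads))]
    beat_flags, skipped = [], []
    for beats in zip(*per_lead_beats):
        r_abs = beats[0].start_sample + beats[0].r_index
        if any(a <= r_abs < b for a, b in intervals):
            skipped.append(r_abs)
            continue
        y1 = float(beat_pair[0](beats[0]))
        y2 = float(beat_pair[1](beats[1])) if len(beats) > 1 else y1
        fused = fuse_leads(y1, y2)
        beat_flags.append((r_abs, fused.label, fused.y))
    return DetectionReport(intervals, window_scores, beat_flags, skipped)
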