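"""Signal preprocessing: resampling, normalization, windowing, balancing.

The pipeline brings every record to 250 Hz, min–max normalizes each lead to
[0, 1], cuts 3-second rhythm windows with a 1-second step, extracts single
heartbeats bounded by the neighbouring R peaks, and balances the two classes
by down-sampling the majority before a 90/10 train/test split.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import ECGRecord, Heartbeat, Segment
from .wfdb_io import LabelMap, label_beat, label_rhythm

__all__ = [
    "resample_to_250", "minmax_normalize", "normalized_record",
    "slide_rhythm_windows", "extract_heartbeats", "balance_and_split",
]

TARGET_FS = 250
WINDOW_SECONDS = 3
STEP_SECONDS = 1


def resample_to_250(signal: np.ndarray, fs: float) -> np.ndarray:
    """Bring a signal to 250 Hz.

    360 Hz input is resampled by the rational factor 25/36 using polyphase
    filtering with a Kaiser-window FIR anti-aliasing low-pass (the behaviour
    of MATLAB's ``resample``); the output length is ``ceil(N * 25/36)``.
    250 Hz input is returned unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if fs == 250:
        return signal
    if fs == 360:
        return sps.resample_poly(signal, 25, 36, window=("kaiser", 5.0))
    raise ValueError(f"unsupported sampling rate {fs}; expected 250 or 360")


def minmax_normalize(signal: np.ndarray) -> np.ndarray:
    """Map a signal linearly onto [0, 1]: ``(v - min) / (max - min)``."""
    signal = np.asarray(signal, dtype=float)
    lo, hi = signal.min(), signal.max()
    if hi == lo:
        raise ValueError("constant signal: min-max normalization undefined (zero range)")
    return (signal - lo) / (hi - lo)


def normalized_record(record: ECGRecord) -> ECGRecord:
    """Resample a record to 250 Hz and normalize each lead to [0, 1].

    Annotation sample indices are rescaled by the same rational factor.
    Normalization is per record per lead, before any windowing.
    """
    factor = TARGET_FS / record.fs
    leads = [minmax_normalize(resample_to_250(record.signal[i], record.fs))
             for i in range(record.signal.shape[0])]
    n = len(leads[0])
    scale = lambda s: min(int(round(s * factor)), n - 1)  # noqa: E731
    return ECGRecord(
        record_id=record.record_id, fs=TARGET_FS, leads=list(record.leads),
        signal=np.vstack(leads),
        beat_ann=[(scale(s), sym) for s, sym in record.beat_ann],
        rhythm_ann=[(scale(s), sym) for s, sym in record.rhythm_ann],
    )


def slide_rhythm_windows(record: ECGRecord, lead: int | str = 0,
                         label_map: LabelMap | None = None) -> list[Segment]:
    """Cut 3-second windows with 1-second step from one lead.

    Window size is ``3 * fs`` samples and the step is ``fs`` samples; a
    trailing partial window is discarded.  A window is labeled 1 (abnormal)
    if its span overlaps any abnormal rhythm interval, else 0.
    """
    fs = int(record.fs)
    x = record.lead(lead)
    lead_name = lead if isinstance(lead, str) else record.leads[lead]
    wlen, step = WINDOW_SECONDS * fs, STEP_SECONDS * fs
    n = len(x)
    if n < wlen:
        return []
    abnormal = [(a, b) for a, b, sym in record.rhythm_intervals()
                if label_rhythm(sym, label_map) == 1]
    out = []
    for start in range(0, n - wlen + 1, step):
        end = start + wlen
        label = int(any(a < end and start < b for a, b in abnormal))
        out.append(Segment(samples=x[start:end], fs=fs, label=label,
                           record_id=record.record_id, lead=lead_name,
                           start_sample=start))
    return out


def extract_heartbeats(record: ECGRecord, lead: int | str = 0,
                       label_map: LabelMap | None = None) -> list[Heartbeat]:
    """Extract one excerpt per annotated beat, bounded by neighbouring R peaks.

    Beat *i* (0-based, ``1 <= i <= n-2``) spans ``[R(i-1), R(i+1))`` — the R
    peak of the previous heartbeat to the following R peak, half-open so
    consecutive beats never share a sample.  The first and last annotated
    beats have no bounding neighbour and are skipped; fewer than 3 annotated
    beats yields an empty list.
    """
    x = record.lead(lead)
    lead_name = lead if isinstance(lead, str) else record.leads[lead]
    beats = record.beat_ann
    if len(beats) < 3:
        return []
    out = []
    for i in range(1, len(beats) - 1):
        left, (r, sym), right = beats[i - 1][0], beats[i], beats[i + 1][0]
        out.append(Heartbeat(
            samples=x[left:right], fs=record.fs,
            r_index=r - left, left_r=0, right_r=right - left,
            label=label_beat(sym, label_map), symbol=sym,
            record_id=record.record_id, lead=lead_name, start_sample=left,
        ))
    return out


def balance_and_split(items: list, labels, train_frac: float = 0.9,
                      seed: int = 0) -> tuple[list, list]:
    """Balance classes by majority down-sampling, then split train/test.

    The majority class is down-sampled uniformly at random (seeded) to the
    minority count.  The test set takes ``floor((1 - train_frac) * total)``
    items, drawn per class so both splits keep the 50-50 balance within one
    item; the remainder is the training set.  Both splits are shuffled.

    Returns ``(train, test)`` as lists of ``(item, label)`` pairs.
    """
    labels = np.asarray(labels)
    if len(items) != len(labels):
        raise ValueError("items and labels must have equal length")
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    k = min(len(idx0), len(idx1))
    keep0 = rng.choice(idx0, size=k, replace=False) if len(idx0) > k else idx0.copy()
    keep1 = rng.choice(idx1, size=k, replace=False) if len(idx1) > k else idx1.copy()
    rng.shuffle(keep0)
    rng.shuffle(keep1)

    total = 2 * k
    # round before flooring so 0.1 * 400 is 40, not floor(39.999...)
    n_test = int(np.floor(round((1.0 - train_frac) * total, 9)))
    n_test0 = n_test // 2
    n_test1 = n_test - n_test0
    if n_test % 2 and rng.integers(2):  # seeded coin for the odd leftover
        n_test0, n_test1 = n_test1, n_test0

    test_idx = np.concatenate([keep0[:n_test0], keep1[:n_test1]])
    train_idx = np.concatenate([keep0[n_test0:], keep1[n_test1:]])
    rng.shuffle(test_idx)
    rng.shuffle(train_idx)
    train = [(items[i], int(labels[i])) for i in train_idx]
    test = [(items[i], int(labels[i])) for i in test_idx]
    return train, test
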