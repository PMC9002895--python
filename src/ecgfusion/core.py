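"""Core domain containers shared across the pipeline.

An :class:`ECGRecord` holds multi-lead sampled voltages together with the two
annotation streams the databases provide: per-beat annotations (sample index of
the R apex plus a beat-type symbol) and rhythm annotations (onset sample plus a
rhythm symbol, valid until the next onset).  :class:`Segment` and
:class:`Heartbeat` are labeled excerpts that carry provenance back to the
record they came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Rhythm vocabulary (MIT-BIH + European ST-T rhythm types).
RHYTHM_SYMBOLS = {
    "NSR": "Normal sinus rhythm",
    "AB": "Atrial bigeminy",
    "AFIB": "Atrial fibrillation",
    "AFL": "Atrial flutter",
    "B": "Ventricular bigeminy",
    "BII": "2nd degree heart block",
    "B3": "3rd degree heart block",
    "IVR": "Idioventricular rhythm",
    "NOD": "Nodal (A-V junctional) rhythm",
    "P": "Paced rhythm",
    "PREX": "Pre-excitation (WPW)",
    "SAB": "Sino-atrial block",
    "SBR": "Sinus bradycardia",
    "SVTA": "Supraventricular tachyarrhythmia",
    "T": "Ventricular trigeminy",
    "VFL": "Ventricular flutter",
    "VT": "Ventricular tachycardia",
}

#: Heartbeat vocabulary (beat-type symbols).
BEAT_SYMBOLS = {
    "N": "Normal beat",
    "LBBB": "Left bundle branch block beat",
    "RBBB": "Right bundle branch block beat",
    "PAC": "Atrial premature beat",
    "a": "Aberrated atrial premature beat",
    "J": "Nodal (junctional) premature beat",
    "S": "Supraventricular premature beat",
    "PVC": "Premature ventricular contraction",
    "F": "Fusion of ventricular and normal beat",
    "e": "Atrial escape beat",
    "j": "Nodal (junctional) escape beat",
    "E": "Ventricular escape beat",
    "P": "Paced beat",
    "f": "Fusion of paced and normal beat",
    "Q": "Unclassified beat",
}


@dataclass
class ECGRecord:
    """A multi-lead ECG record with beat and rhythm annotations.

    Parameters
    ----------
    record_id : str
        Identifier (e.g. ``"100"`` or ``"syn-000"``).
    fs : float
        Sampling frequency in Hz.
    leads : list of str
        Ordered lead names; ``signal`` rows follow this order.
    signal : ndarray, shape (n_leads, n_samples)
        Voltage series, one row per lead.
    beat_ann : list of (int, str)
        ``(sample_index, beat_symbol)`` pairs, strictly increasing in sample.
    rhythm_ann : list of (int, str)
        ``(onset_sample, rhythm_symbol)`` pairs, strictly increasing.  Each
        onset is valid until the next one (half-open intervals).
    """

    record_id: str
    fs: float
    leads: list[str]
    signal: np.ndarray
    beat_ann: list[tuple[int, str]] = field(default_factory=list)
    rhythm_ann: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if len(self.leads) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.leads)} lead names but signal has "
                f"{self.signal.shape[0]} rows"
            )
        n = self.signal.shape[1]
        for stream, name in ((self.beat_ann, "beat_ann"), (self.rhythm_ann, "rhythm_ann")):
            idx = [s for s, _ in stream]
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"{name} sample index outside [0, {n})")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"{name} sample indices must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def lead(self, lead: int | str) -> np.ndarray:
        """Return one lead's samples by index or name."""
        if isinstance(lead, str):
            lead = self.leads.index(lead)
        return self.signal[lead]

    def rhythm_intervals(self) -> list[tuple[int, int, str]]:
        """Rhythm annotations as half-open ``(start, end, symbol)`` intervals.

        The final interval extends to the end of the record.  A record with no
        rhythm annotations yields a single NSR interval covering everything.
        """
        ann = self.rhythm_ann or [(0, "NSR")]
        out = []
        for k, (start, sym) in enumerate(ann):
            end = ann[k + 1][0] if k + 1 < len(ann) else self.n_samples
            out.append((start, end, sym))
        return out


@dataclass
class Segment:
    """A 3-second rhythm window cut from one lead of a record."""

    samples: np.ndarray
    fs: float
    label: int
    record_id: str = ""
    lead: str = ""
    start_sample: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class Heartbeat:
    """A single-beat excerpt bounded by the neighbouring R peaks.

    The excerpt spans ``[R(i-1), R(i+1))`` of the source record; ``r_index``,
    ``left_r`` and ``right_r`` are sample offsets *within* the excerpt, so
    ``left_r == 0`` always and ``right_r == len(samples)``.
    """

    samples: np.ndarray
    fs: float
    r_index: int
    left_r: int
    right_r: int
    label: int
    symbol: str = "N"
    record_id: str = ""
    lead: str = ""
    start_sample: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (0 <= self.left_r < self.r_index < self.right_r <= len(self.samples)):
            raise ValueError(
                "require 0 <= left_r < r_index < right_r <= len(samples), got "
                f"{self.left_r}, {self.r_index}, {self.right_r}, {len(self.samples)}"
            )
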