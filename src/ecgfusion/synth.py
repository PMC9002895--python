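"""Seedable synthetic two-lead ECG generator.

Every downstream stage (windowing, R-peak detection, delineation, features,
spectrograms, training) is exercised on records from this module, so no
database download is ever required.  Each heartbeat is a sum of Gaussian bumps
— one per P, Q, R, S, T wave — centred around equally spaced R times.  The
morphology is a controllable surrogate, not a clinical simulation: it yields
waves that both R detectors and the delineator can find, with known ground
truth for every fiducial.

Anomaly kinds and the beat symbols they are annotated with:

``premature``
    The beat arrives early: the preceding R-to-R gap is shortened by a fixed
    factor (default 0.6) and the P bump is removed.  Annotated ``PVC``.
``wide_qrs``
    Q, R and S widths are doubled.  Annotated ``PVC``.
``absent_p``
    The P bump is removed, timing untouched.  Annotated ``J``.
``tall_t``
    T amplitude tripled.  Annotated ``Q`` (unclassified).

Wave widths are given as approximate full durations in seconds; the Gaussian
sigma used is ``width / 4`` so that ~95% of the bump's mass falls inside the
stated duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ECGRecord

__all__ = ["WaveSpec", "SynthParams", "generate_record", "generate_dataset",
           "DEFAULT_WAVES", "ANOMALY_SYMBOLS"]


@dataclass(frozen=True)
class WaveSpec:
    """One Gaussian bump: amplitude (normalized units), full width (s),
    centre offset from the R apex (s)."""

    amplitude: float
    width: float
    offset: float

    @property
    def sigma(self) -> float:
        return self.width / 4.0


#: Default physiologic-ish morphology (amplitudes in normalized units).
DEFAULT_WAVES: dict[str, WaveSpec] = {
    "P": WaveSpec(0.10, 0.08, -0.16),
    "Q": WaveSpec(-0.15, 0.03, -0.045),
    "R": WaveSpec(1.00, 0.05, 0.0),
    "S": WaveSpec(-0.25, 0.03, 0.045),
    "T": WaveSpec(0.30, 0.12, 0.25),
}

#: Beat symbol each anomaly kind is annotated with (Table-2 vocabulary).
ANOMALY_SYMBOLS = {"premature": "PVC", "wide_qrs": "PVC", "absent_p": "J", "tall_t": "Q"}

#: Lead 2 is lead 1 scaled by this fixed factor (independent noise).
LEAD2_SCALE = 0.6

#: RR shortening factor for premature beats.
PREMATURE_RR_FACTOR = 0.6


@dataclass
class SynthParams:
    """Parameters of one synthetic record.

    ``anomaly_plan`` entries are ``{"beat_index": int, "kind": str}``;
    ``rhythm_plan`` entries are ``{"start_beat": int, "end_beat": int,
    "symbol": str}`` with end_beat inclusive.
    """

    duration: float = 10.0
    fs: float = 250.0
    heart_rate: float = 60.0
    first_r_offset: float = 0.5
    waves: dict[str, WaveSpec] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    noise_sd: float = 0.0
    anomaly_plan: list[dict] = field(default_factory=list)
    rhythm_plan: list[dict] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.fs not in (250, 360):
            raise ValueError(f"fs must be 250 or 360, got {self.fs}")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for w in self.waves.values():
            if w.width <= 0:
                raise ValueError("wave widths must be > 0")


def _beat_times(params: SynthParams) -> np.ndarray:
    """Nominal R times (s): first_r_offset, then every 60/heart_rate."""
    rr = 60.0 / params.heart_rate
    n_beats = int(np.floor((params.duration - params.first_r_offset) / rr)) + 1
    return params.first_r_offset + rr * np.arange(n_beats)


def expected_beat_count(duration: float, fs: float, heart_rate: float,
                        first_r_offset: float = 0.5) -> int:
    """Number of beats an unmodified plan actually yields.

    ``floor((duration - first_r_offset) * heart_rate / 60) + 1``, minus any
    trailing beat whose apex sample rounds past the record end.
    """
    rr = 60.0 / heart_rate
    times = first_r_offset + rr * np.arange(
        int(np.floor((duration - first_r_offset) / rr)) + 1)
    n = int(round(duration * fs))
    return int(np.sum(np.round(times * fs) < n))


def generate_record(params: SynthParams) -> ECGRecord:
    """Generate one annotated two-lead record.

    Beat annotations carry one entry per R at the R-apex sample, symbol ``N``
    unless the anomaly plan overrides it.  Rhythm annotations default to a
    single NSR onset at sample 0.  Identical params (including seed) give a
    bit-identical record.
    """
    params.validate()
    rr = 60.0 / params.heart_rate
    times = _beat_times(params)
    n_beats = len(times)

    plan: dict[int, str] = {}
    for entry in params.anomaly_plan:
        i, kind = int(entry["beat_index"]), entry["kind"]
        if not 0 <= i < n_beats:
            raise ValueError(f"anomaly_plan beat_index {i} out of range [0, {n_beats})")
        if kind not in ANOMALY_SYMBOLS:
            raise ValueError(f"unknown anomaly kind {kind!r}")
        plan[i] = kind

    # Premature beats shift themselves and every later beat earlier, so only
    # the gap *before* the premature beat deviates from nominal.
    shift = 0.0
    times = times.copy()
    for i in range(n_beats):
        if plan.get(i) == "premature":
            shift += (1.0 - PREMATURE_RR_FACTOR) * rr
        times[i] -= shift

    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    r_samples = np.round(times * params.fs).astype(int)
    r_samples = r_samples[(r_samples >= 0) & (r_samples < n)]
    n_beats = len(r_samples)

    clean = np.zeros(n)
    for i, rs in enumerate(r_samples):
        kind = plan.get(i)
        center = rs / params.fs
        for name, w in params.waves.items():
            if name == "P" and kind in ("premature", "absent_p"):
                continue
            amp, sigma, offset = w.amplitude, w.sigma, w.offset
            if kind == "wide_qrs" and name in ("Q", "R", "S"):
                # the whole complex dilates: widths and Q/S offsets double
                sigma *= 2.0
                offset *= 2.0
            if kind == "tall_t" and name == "T":
                amp *= 3.0
            mu = center + offset
            clean += amp * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))

    rng = np.random.default_rng(params.seed)
    lead1 = clean + rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else clean.copy()
    lead2 = LEAD2_SCALE * clean
    if params.noise_sd > 0:
        lead2 = lead2 + rng.normal(0.0, params.noise_sd, n)

    beat_ann = [(int(rs), ANOMALY_SYMBOLS.get(plan.get(i), "N") if plan.get(i) else "N")
                for i, rs in enumerate(r_samples)]

    rhythm_ann = _rhythm_annotations(params.rhythm_plan, r_samples, rr, params.fs, n)

    return ECGRecord(
        record_id=f"syn-{params.seed:03d}",
        fs=params.fs,
        leads=["MLII", "V1"],
        signal=np.vstack([lead1, lead2]),
        beat_ann=beat_ann,
        rhythm_ann=rhythm_ann,
    )


def _rhythm_annotations(rhythm_plan, r_samples, rr, fs, n) -> list[tuple[int, str]]:
    """Onsets from the rhythm plan; NSR at sample 0 and resumed after each span.

    A span's onset sits midway between the previous R and its first beat (or at
    0); NSR resumes midway after its last beat.
    """
    half = int(round(0.5 * rr * fs))
    ann: list[tuple[int, str]] = [(0, "NSR")]
    for entry in sorted(rhythm_plan, key=lambda e: e["start_beat"]):
        s, e, sym = int(entry["start_beat"]), int(entry["end_beat"]), entry["symbol"]
        if not (0 <= s <= e < len(r_samples)):
            raise ValueError(f"rhythm_plan span [{s}, {e}] out of range")
        onset = max(0, int(r_samples[s]) - half)
        ann.append((onset, sym))
        if e + 1 < len(r_samples):
            ann.append((int(r_samples[e]) + half, "NSR"))
    # Deduplicate / enforce strictly increasing onsets (later entries win).
    out: list[tuple[int, str]] = []
    for onset, sym in sorted(ann, key=lambda a: a[0]):
        if out and onset <= out[-1][0]:
            if onset == out[-1][0]:
                out[-1] = (onset, sym) if sym != "NSR" or out[-1][1] == "NSR" else out[-1]
                continue
        out.append((onset, sym))
    return [(o, s) for o, s in out if o < n]


def generate_dataset(n_records: int, params_grid: list[SynthParams] | None = None,
                     seed: int = 0) -> list[ECGRecord]:
    """Generate ``n_records`` records, cycling through ``params_grid``.

    Per-record seeds derive from the master seed by the fixed affine hash
    ``(seed * 100003 + 7919 * i) mod 2**31`` so datasets reproduce across
    platforms.  Record ids are ``syn-000``, ``syn-001``, ...
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if not params_grid:
        params_grid = [SynthParams()]
    records = []
    for i in range(n_records):
        base = params_grid[i % len(params_grid)]
        sub = replace(base, seed=(seed * 100003 + 7919 * i) % 2**31)
        rec = generate_record(sub)
        rec.record_id = f"syn-{i:03d}"
        records.append(rec)
    return records
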