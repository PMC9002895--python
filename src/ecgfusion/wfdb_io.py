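"""Reading and writing WFDB records and annotations, and symbol → label maps.

Implements the subset of the PhysioNet WFDB format family the target databases
use: ``.hea`` header, ``.dat`` signal in format 16 (16-bit little-endian,
interleaved; written and read) or format 212 (12-bit packed pairs; read only),
and the MIT ``.atr`` annotation format.  Beat annotations are stored with the
standard MIT annotation codes; rhythm changes are stored as RHYTHM ('+')
annotations whose aux string is ``(SYMBOL``, the usual aux-note convention.

Sample indices are 0-based throughout and preserved exactly on read, so
R-to-R beat extraction never sees an off-by-one.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BEAT_SYMBOLS, RHYTHM_SYMBOLS, ECGRecord

__all__ = ["LabelMap", "read_record", "write_record", "label_rhythm", "label_beat"]

# MIT annotation code <-> package beat symbol.
_CODE_TO_BEAT = {
    1: "N", 2: "LBBB", 3: "RBBB", 4: "a", 5: "PVC", 6: "F", 7: "J", 8: "PAC",
    9: "S", 10: "E", 11: "j", 12: "P", 13: "Q", 34: "e", 38: "f",
}
_BEAT_TO_CODE = {v: k for k, v in _CODE_TO_BEAT.items()}
_RHYTHM_CODE = 28  # '+', aux carries "(SYMBOL"
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

# PhysioNet aux rhythm strings that differ from the Table-1 vocabulary.
_AUX_ALIASES = {"N": "NSR", "SBR": "SBR", "VFL": "VFL"}


@dataclass
class LabelMap:
    """Binary label mapping: normal symbols -> 0, everything else -> 1.

    ``beat_excluded`` lists beat types dropped from heartbeat-stage datasets
    because they do not occur inside normal rhythms in the target databases;
    it is configuration, not a hard-coded rule, because the source material
    is ambiguous about paced beats.
    """

    rhythm_normal: frozenset[str] = frozenset({"NSR"})
    beat_normal: frozenset[str] = frozenset({"N"})
    beat_excluded: frozenset[str] = frozenset({"P", "RBBB"})
    strict: bool = False

    def __post_init__(self) -> None:
        if not self.rhythm_normal or not self.beat_normal:
            raise ValueError("normal symbol sets must be non-empty")

    def label_rhythm(self, symbol: str) -> int:
        if self.strict and symbol not in RHYTHM_SYMBOLS:
            raise KeyError(f"unknown rhythm symbol {symbol!r}")
        return 0 if symbol in self.rhythm_normal else 1

    def label_beat(self, symbol: str) -> int:
        if self.strict and symbol not in BEAT_SYMBOLS:
            raise KeyError(f"unknown beat symbol {symbol!r}")
        return 0 if symbol in self.beat_normal else 1


_DEFAULT_MAP = LabelMap()


def label_rhythm(symbol: str, label_map: LabelMap | None = None) -> int:
    """NSR -> 0; every other rhythm symbol -> 1 (abnormal)."""
    return (label_map or _DEFAULT_MAP).label_rhythm(symbol)


def label_beat(symbol: str, label_map: LabelMap | None = None) -> int:
    """N -> 0; every other beat symbol -> 1 (abnormal)."""
    return (label_map or _DEFAULT_MAP).label_beat(symbol)


# ---------------------------------------------------------------------------
# writing


def write_record(record: ECGRecord, directory: str | Path, fmt: int = 16,
                 gain: float = 200.0) -> Path:
    """Write ``record`` as ``<directory>/<record_id>.{hea,dat,atr}``.

    Voltages are digitized as ``round(v * gain)`` (baseline 0); format 16
    only.  Returns the header path.
    """
    if fmt != 16:
        raise ValueError("only format 16 is supported for writing")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    nsig, nsamp = record.signal.shape[0], record.signal.shape[1]

    digital = np.round(record.signal * gain).astype(np.int16)
    checksums = [int(np.sum(digital[i], dtype=np.int16)) for i in range(nsig)]

    lines = [f"{name} {nsig} {record.fs:g} {nsamp}"]
    for i, lead in enumerate(record.leads):
        lines.append(
            f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(digital[i, 0])} "
            f"{checksums[i]} 0 {lead}"
        )
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")

    (directory / f"{name}.dat").write_bytes(
        digital.T.reshape(-1).astype("<i2").tobytes()
    )
    _write_annotations(directory / f"{name}.atr", record)
    return hea


def _write_annotations(path: Path, record: ECGRecord) -> None:
    """Merge beat and rhythm streams by sample and emit MIT format."""
    events: list[tuple[int, int, str | None]] = []  # (sample, code, aux)
    for s, sym in record.beat_ann:
        code = _BEAT_TO_CODE.get(sym)
        if code is None:
            warnings.warn(f"beat symbol {sym!r} has no MIT code; writing as Q")
            code = 13
        events.append((s, code, None))
    for s, sym in record.rhythm_ann:
        events.append((s, _RHYTHM_CODE, "(" + sym))
    events.sort(key=lambda e: (e[0], e[1] != _RHYTHM_CODE))

    out = bytearray()
    prev = 0
    for sample, code, aux in events:
        dt = sample - prev
        if dt >= 1024 or dt < 0:
            # SKIP: 4-byte interval in PDP-11 byte order, then the event at dt 0
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (code << 10) | dt)
        if aux is not None:
            data = aux.encode("ascii")
            out += struct.pack("<H", (_AUX << 10) | len(data))
            out += data
            if len(data) % 2:
                out += b"\x00"
        prev = sample
    out += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# reading


def read_record(path: str | Path) -> ECGRecord:
    """Read ``<path>.{hea,dat,atr}`` into an :class:`ECGRecord`.

    Voltages are converted to physical units via each signal's gain/baseline.
    Beat and rhythm annotations are separated: RHYTHM ('+') annotations with a
    ``(SYMBOL`` aux feed the rhythm stream; annotations with beat codes feed
    the beat stream.  A record with no rhythm annotations gets the fallback
    ``[(0, "NSR")]``.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix else path
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    header = _parse_header(hea)

    dat = base.parent / header["files"][0]
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    signal = _read_signal(dat, header)

    atr = base.with_suffix(".atr")
    if not atr.exists():
        raise FileNotFoundError(f"missing annotation file {atr}")
    beat_ann, rhythm_ann = _read_annotations(atr)
    if not rhythm_ann:
        rhythm_ann = [(0, "NSR")]

    return ECGRecord(
        record_id=header["name"], fs=header["fs"], leads=header["leads"],
        signal=signal, beat_ann=beat_ann, rhythm_ann=rhythm_ann,
    )


def _parse_header(hea: Path) -> dict:
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    name, nsig, fs, nsamp = first[0], int(first[1]), float(first[2]), int(first[3])
    files, fmts, gains, baselines, leads = [], [], [], [], []
    for i, ln in enumerate(lines[1 : 1 + nsig]):
        parts = ln.split()
        files.append(parts[0])
        fmts.append(int(parts[1].split("x")[0]))
        gspec = parts[2] if len(parts) > 2 else "200"
        g = gspec.split("/")[0]
        if "(" in g:
            g, b = g.split("(")
            baselines.append(int(b.rstrip(")")))
        else:
            baselines.append(0)
        gains.append(float(g) if float(g) != 0 else 200.0)
        leads.append(parts[-1] if len(parts) > 8 else f"sig{i}")
    if len(set(files)) != 1:
        raise ValueError("multi-file signal groups are not supported")
    return {"name": name, "nsig": nsig, "fs": fs, "nsamp": nsamp, "files": files,
            "fmt": fmts[0], "gains": gains, "baselines": baselines, "leads": leads}


def _read_signal(dat: Path, header: dict) -> np.ndarray:
    raw = dat.read_bytes()
    nsig, nsamp, fmt = header["nsig"], header["nsamp"], header["fmt"]
    if fmt == 16:
        need = 2 * nsig * nsamp
        if len(raw) < need:
            raise ValueError(f"truncated signal file {dat}: {len(raw)} bytes, need {need}")
        digital = np.frombuffer(raw[:need], dtype="<i2").reshape(nsamp, nsig).T.astype(float)
    elif fmt == 212:
        if nsig != 2:
            raise ValueError("format 212 is only supported for 2-signal records")
        need = 3 * nsamp  # one (sig0, sig1) pair per 3 bytes
        if len(raw) < need:
            raise ValueError(f"truncated signal file {dat}: {len(raw)} bytes, need {need}")
        b = np.frombuffer(raw[:need], dtype=np.uint8).reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        digital = np.vstack([s0, s1]).astype(float)
    else:
        raise ValueError(f"unsupported signal format {fmt}")
    gains = np.asarray(header["gains"])[:, None]
    baselines = np.asarray(header["baselines"])[:, None]
    return (digital - baselines) / gains


def _read_annotations(atr: Path) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    raw = atr.read_bytes()
    beat, rhythm = [], []
    pos, sample = 0, 0
    last_beat_like: int | None = None
    while pos + 1 < len(raw):
        word = struct.unpack_from("<H", raw, pos)[0]
        pos += 2
        code, dt = word >> 10, word & 0x3FF
        if code == 0 and dt == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", raw, pos)
            pos += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            sample += interval
            continue
        if code == _AUX:
            aux = raw[pos : pos + dt].decode("ascii", errors="replace").rstrip("\x00")
            pos += dt + (dt % 2)
            if aux.startswith("("):
                sym = aux[1:]
                sym = _AUX_ALIASES.get(sym, sym)
                if sym not in RHYTHM_SYMBOLS:
                    warnings.warn(f"unknown rhythm symbol {sym!r}; retained")
                if last_beat_like is not None:
                    rhythm.append((last_beat_like, sym))
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        sample += dt
        if code == _RHYTHM_CODE:
            last_beat_like = sample  # aux that follows names the rhythm
            continue
        sym = _CODE_TO_BEAT.get(code)
        if sym is None:
            warnings.warn(f"unknown annotation code {code}; retained as Q")
            sym = "Q"
        beat.append((sample, sym))
        last_beat_like = sample
    beat.sort()
    rhythm.sort()
    # drop duplicate onsets (keep the last annotation at a sample)
    dedup: list[tuple[int, str]] = []
    for s, sym in rhythm:
        if dedup and dedup[-1][0] == s:
            dedup[-1] = (s, sym)
        else:
            dedup.append((s, sym))
    return beat, dedup
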