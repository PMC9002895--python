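"""STFT spectrograms and their rendering as fixed-size images.

The STFT uses a Hann (Hanning) taper — its [0, 1] amplitude range matches the
normalized ECG — with a window of 167 samples for 3-second rhythm segments and
28 samples for single heartbeats.  The hop defaults to 50% overlap and the DFT
length to the window length (no zero padding).  Power is rendered to an
8-bit image, 875 x 656 pixels by default (width x height, the time axis being
the longer one), either through a fixed jet-like RGB colormap or directly as
grayscale intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize as _resize

__all__ = ["STFTMatrix", "hanning_window", "stft", "render", "save_png",
           "RHYTHM_WINDOW_LEN", "HEARTBEAT_WINDOW_LEN", "DB_FLOOR"]

RHYTHM_WINDOW_LEN = 167     # samples at 250 Hz = 0.668 s
HEARTBEAT_WINDOW_LEN = 28   # samples at 250 Hz = 0.112 s
DB_FLOOR = -100.0           # dB floor so empty bins stay finite

# Fixed 256-entry jet-like lookup table (uint8 RGB), materialized once.
_JET_LUT = (np.asarray(colormaps["jet"](np.linspace(0, 1, 256)))[:, :3] * 255).astype(np.uint8)


@dataclass
class STFTMatrix:
    """One-sided power spectrogram: ``power[f, m]`` over F bins x k columns."""

    power: np.ndarray
    window_len: int
    hop: int
    fs: float

    @property
    def k(self) -> int:
        return self.power.shape[1]

    @property
    def n_bins(self) -> int:
        return self.power.shape[0]


def hanning_window(L: int) -> np.ndarray:
    """Symmetric Hann taper of length ``L``: zero endpoints, values in [0, 1]."""
    if L < 2:
        raise ValueError("window length must be >= 2")
    return np.hanning(L)


def stft(signal: np.ndarray, L: int = RHYTHM_WINDOW_LEN, hop: int | None = None,
         n_fft: int | None = None, fs: float = 250.0) -> STFTMatrix:
    """Short-time Fourier transform power matrix.

    Column ``m`` is ``|DFT(w * signal[m*hop : m*hop + L])|^2`` over the
    one-sided spectrum; the column count is ``floor((N - L)/hop) + 1`` with no
    padding.  ``hop`` defaults to ``floor(L/2)`` (50% overlap) and ``n_fft``
    to ``L``.
    """
    x = np.asarray(signal, dtype=float)
    if hop is None:
        hop = L // 2
    if n_fft is None:
        n_fft = L
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if len(x) < L:
        raise ValueError(f"signal of {len(x)} samples is shorter than window {L}")
    w = hanning_window(L)
    k = (len(x) - L) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, L)[::hop][:k]
    spec = np.fft.rfft(frames * w, n=n_fft, axis=1)
    return STFTMatrix(power=(np.abs(spec) ** 2).T, window_len=L, hop=hop, fs=fs)


def render(matrix: STFTMatrix, mode: str = "gray", height: int = 656,
           width: int = 875) -> np.ndarray:
    """Render a power matrix to an 8-bit image of shape (height, width, C).

    Power goes to dB with a floor at -100 dB, is linearly rescaled to
    [0, 255], oriented with frequency increasing upward (row 0 = highest
    frequency) and time left to right, bilinearly resized, and quantized.
    ``mode="rgb"`` applies the fixed jet-like colormap (C = 3); ``"gray"``
    writes intensity directly (C = 1).  All-zero power gives a uniform
    minimum-intensity image, never NaN.
    """
    if mode not in ("rgb", "gray"):
        raise ValueError(f"mode must be 'rgb' or 'gray', got {mode!r}")
    p = np.asarray(matrix.power if isinstance(matrix, STFTMatrix) else matrix, dtype=float)
    if p.size == 0:
        raise ValueError("empty power matrix")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(p)
    db = np.maximum(db, DB_FLOOR)
    top = db.max()
    scaled = np.zeros_like(db) if top <= DB_FLOOR else (db - DB_FLOOR) / (top - DB_FLOOR) * 255.0
    scaled = np.flipud(scaled)  # row 0 = highest frequency
    img = _resize(scaled, (height, width), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    intensity = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if mode == "gray":
        return intensity[:, :, None]
    return _JET_LUT[intensity]


def save_png(image: np.ndarray, path: str | Path) -> Path:
    """Write a rendered image (H x W x {1, 3} uint8) as a PNG file."""
    path = Path(path)
    arr = image[:, :, 0] if image.shape[2] == 1 else image
    Image.fromarray(arr).save(path)
    return path
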