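"""Two independent R-peak detectors.

Both the Pan–Tompkins detector and the Shannon-energy-envelope Hilbert
transform (SEEHT) detector are run on every rhythm segment: their *detection
counts* are features in their own right, because the two algorithms degrade
differently on distorted beats.  The pipeline always carries both counts and
never merges them.

All constants the original algorithm descriptions leave open (band edges,
integrator length, threshold update coefficients, smoothing window,
refractory period) live in :class:`DetectorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["RPeakResult", "DetectorConfig", "pan_tompkins", "seeht"]


@dataclass(frozen=True)
class DetectorConfig:
    band_low: float = 5.0          # Hz, band-pass lower edge (PT)
    band_high: float = 15.0        # Hz, band-pass upper edge (PT)
    integrate_ms: float = 150.0    # PT moving-window integrator length
    refractory_ms: float = 200.0   # minimum R-to-R spacing
    refine_ms: float = 50.0        # half-width of the apex-refinement window
    seeht_band: tuple[float, float] = (5.0, 25.0)
    seeht_smooth_ms: float = 150.0  # envelope smoothing window
    envelope_floor: float = 0.01   # fraction of the envelope max; below = noise


@dataclass
class RPeakResult:
    """Detected R apices: strictly increasing sample indices."""

    r_indices: np.ndarray
    detector: str

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.r_indices)


def _check_input(signal: np.ndarray, fs: float) -> np.ndarray:
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2 * fs:
        raise ValueError(f"signal too short: {len(signal)} samples, need >= {int(2 * fs)}")
    return signal


def _refine(signal: np.ndarray, peaks: list[int], fs: float, cfg: DetectorConfig) -> np.ndarray:
    """Move each peak to the local maximum of the raw signal within +/-refine_ms."""
    half = int(round(cfg.refine_ms / 1000.0 * fs))
    out = []
    for p in peaks:
        a, b = max(0, p - half), min(len(signal), p + half + 1)
        out.append(a + int(np.argmax(signal[a:b])))
    return np.asarray(sorted(set(out)), dtype=int)


def _enforce_refractory(signal: np.ndarray, peaks: np.ndarray, fs: float,
                        cfg: DetectorConfig) -> np.ndarray:
    """Drop the smaller of any two peaks closer than the refractory period."""
    min_gap = cfg.refractory_ms / 1000.0 * fs
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_gap:
            if signal[p] > signal[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def pan_tompkins(signal: np.ndarray, fs: float = 250.0,
                 config: DetectorConfig | None = None) -> RPeakResult:
    """Pan–Tompkins QRS detection.

    Classic chain: band-pass (~5–15 Hz), differentiate, square, moving-window
    integrate (150 ms), then adaptive dual thresholds with search-back and a
    200 ms refractory period.  The band-pass and integrator are applied
    zero-phase / centred so integrated peaks stay aligned with the R apex,
    which is finally refined to the local signal maximum within +/-50 ms.
    """
    cfg = config or DetectorConfig()
    signal = _check_input(signal, fs)
    if np.ptp(signal) == 0:
        return RPeakResult(np.empty(0, dtype=int), "pan_tompkins")

    sos = sps.butter(2, [cfg.band_low, cfg.band_high], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, signal)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(round(cfg.integrate_ms / 1000.0 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    min_dist = max(1, int(round(cfg.refractory_ms / 1000.0 * fs)))
    cand, _ = sps.find_peaks(mwi, distance=min_dist)
    if len(cand) == 0:
        return RPeakResult(np.empty(0, dtype=int), "pan_tompkins")

    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    accepted: list[int] = []
    rr_hist: list[float] = []
    rejected: list[int] = []
    for p in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            # search-back first: a long gap may hide a missed beat among
            # previously rejected candidates above the lower threshold
            if accepted and rr_hist:
                avg_rr = float(np.mean(rr_hist[-8:]))
                if p - accepted[-1] > 1.66 * avg_rr:
                    back = [q for q in rejected
                            if accepted[-1] + min_dist < q < p - min_dist
                            and mwi[q] > 0.5 * thr1]
                    if back:
                        q = max(back, key=lambda i: mwi[i])
                        spki = 0.25 * mwi[q] + 0.75 * spki
                        rr_hist.append(q - accepted[-1])
                        accepted.append(int(q))
            if accepted:
                rr_hist.append(p - accepted[-1])
            accepted.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            rejected.append(int(p))
            npki = 0.125 * mwi[p] + 0.875 * npki

    peaks = _refine(signal, accepted, fs, cfg)
    peaks = _enforce_refractory(signal, peaks, fs, cfg)
    return RPeakResult(peaks, "pan_tompkins")


def seeht(signal: np.ndarray, fs: float = 250.0,
          config: DetectorConfig | None = None) -> RPeakResult:
    """Shannon-energy-envelope Hilbert-transform R detection.

    Chain: band-pass, first difference, amplitude normalization, Shannon
    energy ``s = -d^2 ln(d^2)``, zero-phase envelope smoothing (~150 ms),
    Hilbert transform of the mean-removed envelope, R located at
    positive-to-negative zero crossings of the imaginary (odd) component,
    refined to the local signal maximum within +/-50 ms, 200 ms refractory.
    """
    cfg = config or DetectorConfig()
    signal = _check_input(signal, fs)
    if np.ptp(signal) == 0:
        return RPeakResult(np.empty(0, dtype=int), "seeht")

    sos = sps.butter(2, list(cfg.seeht_band), btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, signal)
    d = np.diff(bp, prepend=bp[0])
    dmax = np.abs(d).max()
    if dmax == 0:
        return RPeakResult(np.empty(0, dtype=int), "seeht")
    d = d / dmax
    d2 = d**2
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = np.where(d2 > 0, -d2 * np.log(d2), 0.0)

    win = max(1, int(round(cfg.seeht_smooth_ms / 1000.0 * fs)))
    env = np.convolve(shannon, np.ones(win) / win, mode="same")
    centered = env - env.mean()
    odd = np.imag(sps.hilbert(centered))

    # The envelope apex is where its Hilbert transform crosses zero.  With
    # scipy's sign convention (analytic signal x + iH[x]) that is a
    # negative-to-positive crossing of the imaginary part; descriptions using
    # the opposite Hilbert sign call the same instant positive-to-negative.
    floor = cfg.envelope_floor * env.max()
    crossings = np.flatnonzero((odd[:-1] < 0) & (odd[1:] >= 0))
    crossings = [int(c) for c in crossings if env[c] > floor]

    peaks = _refine(signal, crossings, fs, cfg)
    peaks = _enforce_refractory(signal, peaks, fs, cfg)
    return RPeakResult(peaks, "seeht")
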