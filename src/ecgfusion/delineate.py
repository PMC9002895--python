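"""P-QRS-T fiducial detection and interval measurement.

The delineator follows the ecgpuwave idea: given an R apex, it defines search
windows before and after the QRS complex, finds the maximum and minimum of the
(lightly smoothed) first derivative in each window, and places the wave peak at
the derivative zero-crossing between them — a wave apex is exactly where the
first derivative changes sign.  Windows whose derivative never rises above a
noise floor yield MISSING fiducials, and the corresponding interval lengths and
peak amplitudes are reported as 0, never as an error.

Search-window geometry (all configurable): the P window spans 200 ms and ends
40 ms before QRS onset; the T window starts 80 ms after QRS offset and spans
``min(400 ms, 0.6 * RR)``.  The noise floor is 5% of the beat's peak derivative
magnitude (reached inside the QRS), so flat or absent waves go MISSING.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FiducialSet", "IntervalSet", "DelineatorConfig",
           "delineate_beat", "measure_intervals"]

MISSING = None


@dataclass(frozen=True)
class DelineatorConfig:
    p_window_s: float = 0.200      # P search window length
    p_gap_s: float = 0.040         # gap between P window end and QRS onset
    t_gap_s: float = 0.080         # gap between QRS offset and T window start
    t_window_s: float = 0.400      # T search window cap
    t_rr_frac: float = 0.6         # T window also capped at this fraction of RR
    qrs_half_s: float = 0.050      # Q/S search half-width around R
    smooth_samples: int = 5        # moving-average length for the derivative
    noise_frac: float = 0.05       # noise floor as fraction of peak |derivative|


@dataclass
class FiducialSet:
    """Per-beat fiducial samples; MISSING (None) when a wave is not found."""

    r_peak: int
    p_peak: int | None = MISSING
    q: int | None = MISSING
    s: int | None = MISSING
    t_peak: int | None = MISSING
    qrs_on: int | None = MISSING
    qrs_off: int | None = MISSING

    def shifted(self, delta: int) -> "FiducialSet":
        mv = lambda v: None if v is None else v + delta  # noqa: E731
        return FiducialSet(r_peak=self.r_peak + delta, p_peak=mv(self.p_peak),
                           q=mv(self.q), s=mv(self.s), t_peak=mv(self.t_peak),
                           qrs_on=mv(self.qrs_on), qrs_off=mv(self.qrs_off))


@dataclass
class IntervalSet:
    """Interval lengths (s) and peak amplitudes; 0 exactly when the defining
    fiducial is MISSING (the zero-sentinel rule)."""

    rr_left: float
    rr_right: float
    qrs_len: float
    pr_len: float
    qt_len: float
    p_amp: float
    r_amp: float
    t_amp: float


def _smooth_derivative(signal: np.ndarray, n: int) -> np.ndarray:
    d = np.gradient(np.asarray(signal, dtype=float))
    if n > 1:
        d = np.convolve(d, np.ones(n) / n, mode="same")
    return d


def _wave_peak(deriv: np.ndarray, a: int, b: int, floor: float) -> int | None:
    """Wave apex inside window [a, b): the derivative zero-crossing between the
    window's derivative extremes.  Returns MISSING for degenerate or flat
    windows."""
    if b - a < 3 or a < 0 or b > len(deriv):
        return MISSING
    w = deriv[a:b]
    if np.abs(w).max() < floor:
        return MISSING
    imax, imin = int(np.argmax(w)), int(np.argmin(w))
    lo, hi = (imax, imin) if imax < imin else (imin, imax)
    if lo == hi:
        return MISSING
    seg = w[lo : hi + 1]
    sign = np.sign(seg)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    exact = np.flatnonzero(sign == 0)
    if len(exact):
        return a + lo + int(exact[0])
    if len(crossings) == 0:
        return MISSING
    c = int(crossings[0])
    # choose the sample nearer the true zero
    idx = c if abs(seg[c]) <= abs(seg[c + 1]) else c + 1
    return a + lo + idx


def delineate_beat(signal: np.ndarray, fs: float, r_index: int,
                   left_r: int, right_r: int,
                   config: DelineatorConfig | None = None) -> FiducialSet:
    """Locate P, Q, S, T and the QRS boundaries around one R apex.

    ``signal`` is the excerpt (or whole record lead) the indices refer to;
    ``left_r``/``right_r`` are the bounding R peaks used to limit the search.
    Degenerate windows (outside the excerpt) and flat windows give MISSING
    fiducials — never an exception.
    """
    cfg = config or DelineatorConfig()
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if not 0 <= r_index < n:
        raise ValueError(f"r_index {r_index} outside signal of length {n}")
    deriv = _smooth_derivative(signal, cfg.smooth_samples)
    half = int(round(cfg.qrs_half_s * fs))
    floor = cfg.noise_frac * float(
        np.abs(deriv[max(0, r_index - 2 * half): r_index + 2 * half + 1]).max()
    )

    fid = FiducialSet(r_peak=r_index)

    # QRS onset / offset: walk outward from R until the derivative *stays*
    # below the noise floor for a short run (a single sub-floor sample can be
    # a wave apex inside the complex, not its boundary)
    run = max(3, cfg.smooth_samples)
    below = np.abs(deriv) <= floor

    def _boundary(direction: int) -> int | None:
        lim = max(0, min(n - 1, r_index + direction * 3 * half))
        i = r_index + direction
        streak = 0
        while (i >= lim) if direction < 0 else (i <= lim):
            streak = streak + 1 if below[i] else 0
            if streak >= run:
                return i - direction * (run - 1)
            i += direction
        return lim

    fid.qrs_on = _boundary(-1)
    fid.qrs_off = _boundary(+1)

    # Q and S: local minima flanking R inside [qrs_on, qrs_off]
    if fid.qrs_on is not None:
        a, b = fid.qrs_on, r_index
        if b - a >= 2:
            fid.q = a + int(np.argmin(signal[a:b]))
    if fid.qrs_off is not None:
        a, b = r_index + 1, fid.qrs_off + 1
        if b - a >= 2:
            fid.s = a + int(np.argmin(signal[a:b]))

    # P: 200 ms window ending 40 ms before QRS onset
    if fid.qrs_on is not None:
        b = fid.qrs_on - int(round(cfg.p_gap_s * fs))
        a = b - int(round(cfg.p_window_s * fs))
        a = max(a, left_r)
        if a >= 0 and b <= n:
            fid.p_peak = _wave_peak(deriv, a, b, floor)

    # T: window starting 80 ms after QRS offset, capped at 0.6 RR
    if fid.qrs_off is not None:
        rr_right = (right_r - r_index) / fs
        span = min(cfg.t_window_s, cfg.t_rr_frac * rr_right)
        a = fid.qrs_off + int(round(cfg.t_gap_s * fs))
        b = min(a + int(round(span * fs)), right_r, n)
        fid.t_peak = _wave_peak(deriv, a, b, floor)

    # enforce the ordering invariant; drop fiducials that violate it
    if fid.p_peak is not None and fid.qrs_on is not None and fid.p_peak >= fid.qrs_on:
        fid.p_peak = MISSING
    if fid.t_peak is not None and fid.qrs_off is not None and fid.t_peak <= fid.qrs_off:
        fid.t_peak = MISSING
    return fid


def measure_intervals(fiducials: FiducialSet, left_r: int, right_r: int,
                      fs: float, signal: np.ndarray) -> IntervalSet:
    """Interval lengths and peak amplitudes from a fiducial set.

    PR is measured P-peak to R-peak and QT is Q to T-peak (the delineator
    works on peaks, not wave onsets).  Whenever a defining fiducial is
    MISSING the value is 0, following the zero-sentinel rule.
    """
    signal = np.asarray(signal, dtype=float)
    f = fiducials
    qrs_len = (f.qrs_off - f.qrs_on) / fs if f.qrs_on is not None and f.qrs_off is not None else 0.0
    pr_len = (f.r_peak - f.p_peak) / fs if f.p_peak is not None else 0.0
    qt_len = (f.t_peak - f.q) / fs if f.t_peak is not None and f.q is not None else 0.0
    return IntervalSet(
        rr_left=(f.r_peak - left_r) / fs,
        rr_right=(right_r - f.r_peak) / fs,
        qrs_len=qrs_len,
        pr_len=pr_len,
        qt_len=qt_len,
        p_amp=float(signal[f.p_peak]) if f.p_peak is not None else 0.0,
        r_amp=float(signal[f.r_peak]),
        t_amp=float(signal[f.t_peak]) if f.t_peak is not None else 0.0,
    )
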