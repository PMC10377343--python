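"""Reference heart-rate labels: QRS detection, tachogram, device alignment.

The chest-strap ECG is the label source.  R-peaks are located with the
classic Pan--Tompkins chain (band-pass, derivative, squaring, moving-window
integration, adaptive dual thresholds with refractory period); the tachogram
converts inter-beat intervals to instantaneous HR; the two devices are
aligned by cross-correlating their accelerometer norms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import remove_baseline, vector_norm

__all__ = ["Tachogram", "pan_tompkins", "hr_from_tachogram", "synchronize",
           "SyncError"]


class SyncError(RuntimeError):
    """Raised when the two devices cannot be synchronized."""


@dataclass(frozen=True)
class Tachogram:
    """R-peak times with derived inter-beat intervals."""

    r_peak_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, dtype=float)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        object.__setattr__(self, "r_peak_times", t)

    @property
    def ibi(self) -> np.ndarray:
        """Inter-beat intervals in seconds; one fewer entry than peaks."""
        return np.diff(self.r_peak_times)


def pan_tompkins(ecg: np.ndarray, fs: float = 250.0) -> np.ndarray:
    """Detect R-peak times (seconds) in a single-lead ECG.

    Stages: zero-phase 5--15 Hz band-pass, five-point derivative, squaring,
    150-ms moving-window integration, then an adaptive dual-threshold peak
    search (signal/noise level update coefficients 0.125 / threshold factor
    0.25) with a 200-ms refractory period and a 1.66*RR search-back.
    Detection is invariant to amplitude scaling; a flat signal yields an
    empty result.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 5 * fs:
        raise ValueError(f"need at least 5 s of ECG, got {len(ecg) / fs:.2f} s")
    if np.ptp(ecg) < 1e-12:
        return np.empty(0)

    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)

    deriv_kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, deriv_kernel[::-1], mode="same")
    squared = deriv**2

    win = max(int(round(0.150 * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated signal
    cand, _ = sps.find_peaks(integrated, distance=refractory)
    if len(cand) == 0:
        return np.empty(0)

    spki = float(np.max(integrated[: int(2 * fs)])) * 0.25
    npki = float(np.mean(integrated[: int(2 * fs)])) * 0.5
    peaks: list[int] = []
    rr_avg = None

    def accept(idx: int) -> None:
        nonlocal spki
        spki = 0.125 * integrated[idx] + 0.875 * spki
        peaks.append(idx)

    i = 0
    while i < len(cand):
        idx = cand[i]
        threshold = npki + 0.25 * (spki - npki)
        if integrated[idx] > threshold:
            accept(idx)
            if len(peaks) >= 3:
                rr_avg = float(np.mean(np.diff(peaks[-9:])))
        else:
            npki = 0.125 * integrated[idx] + 0.875 * npki
            # search-back: if no beat for 1.66 * average RR, take the best
            # rejected candidate above half threshold
            if rr_avg is not None and peaks and idx - peaks[-1] > 1.66 * rr_avg:
                window = [c for c in cand[: i + 1] if peaks[-1] + refractory < c <= idx]
                if window:
                    best = max(window, key=lambda c: integrated[c])
                    if integrated[best] > 0.5 * threshold:
                        accept(best)
        i += 1

    if not peaks:
        return np.empty(0)

    # refine each detection to the band-passed R-wave maximum nearby
    half = int(round(0.10 * fs))
    refined = []
    for idx in peaks:
        i0, i1 = max(idx - half, 0), min(idx + half + 1, len(bp))
        refined.append(i0 + int(np.argmax(bp[i0:i1])))
    refined = np.unique(refined)
    # enforce refractory period after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(r)
    return np.asarray(keep, dtype=float) / fs


def hr_from_tachogram(tach: Tachogram) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous HR in bpm, one value per inter-beat interval.

    ``hr[i] = 60 / ibi[i]``, timestamped at the later peak of the interval.
    Returns ``(times, hr_bpm)``.
    """
    if len(tach.r_peak_times) < 2:
        raise ValueError("need at least 2 R-peaks to compute instantaneous HR")
    ibi = tach.ibi
    if np.any(ibi <= 0):
        raise ValueError("inter-beat intervals must be positive")
    return tach.r_peak_times[1:], 60.0 / ibi


def synchronize(
    wrist_accel_norm: np.ndarray,
    ref_accel: np.ndarray,
    fs_wrist: float = 10.0,
    fs_ref: float = 100.0,
    max_lag: float = 30.0,
) -> float:
    """Clock offset (s) of the reference device relative to the wristband.

    The reference 3-axis accelerometer is reduced to its vector norm,
    downsampled to the wrist rate, and both baseline-removed norms are
    cross-correlated over lags in ``[-max_lag, +max_lag]``.  A positive
    result means the reference stream is delayed; shifting its timestamps by
    the negated result aligns the streams.
    """
    wrist = np.asarray(wrist_accel_norm, dtype=float)
    ref = np.asarray(ref_accel, dtype=float)
    if ref.ndim == 2:
        ref_norm = vector_norm(ref[:, 0], ref[:, 1], ref[:, 2])
    else:
        ref_norm = ref
    if len(wrist) / fs_wrist < 60.0 or len(ref_norm) / fs_ref < 60.0:
        raise ValueError("need at least 60 s of overlapping accelerometer data")

    step = int(round(fs_ref / fs_wrist))
    ref_ds = sps.decimate(ref_norm, step, ftype="fir", zero_phase=True)

    a = remove_baseline(wrist, fs_wrist, window_s=2.0)
    b = remove_baseline(ref_ds, fs_wrist, window_s=2.0)
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    if np.std(a) < 1e-6 or np.std(b) < 1e-6:
        raise SyncError("cannot synchronize: both accelerometer streams are motionless")

    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    max_shift = int(round(max_lag * fs_wrist))
    xc = sps.correlate(b, a, mode="full")
    lags = sps.correlation_lags(n, n, mode="full")
    sel = np.abs(lags) <= max_shift
    best = lags[sel][int(np.argmax(xc[sel]))]
    return float(best) / fs_wrist
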