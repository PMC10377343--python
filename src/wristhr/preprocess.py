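"""Signal conditioning: baseline removal, IMU norms, PPG filtering, windowing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from . import simulate as sim

__all__ = [
    "ProcessedSession",
    "Window",
    "remove_baseline",
    "vector_norm",
    "filter_ppg",
    "resample_temperature",
    "process_session",
    "window_session",
]


def remove_baseline(x: np.ndarray, fs: float, window_s: float = 2.0) -> np.ndarray:
    """Subtract a centered moving average of length ``window_s`` seconds."""
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    if win < 1:
        raise ValueError("baseline window must cover at least one sample")
    if len(x) < win:
        raise ValueError(
            f"series of {len(x)} samples is shorter than the {win}-sample baseline window"
        )
    return x - uniform_filter1d(x, size=win, mode="nearest")


def vector_norm(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError(f"axis length mismatch: {len(x)}, {len(y)}, {len(z)}")
    return np.sqrt(x * x + y * y + z * z)


def filter_ppg(ppg: np.ndarray, cfg=None, fs: float = sim.PPG_RATE) -> np.ndarray:
    """Band-pass then smooth the raw PPG.

    Zero-phase 4th-order Butterworth band-pass (0.6--3 Hz by default)
    followed by a zero-phase 41-tap Hamming FIR low-pass at 4 Hz.  Requires
    at least 10 s of signal for filter settling.
    """
    from .session_io import PipelineConfig  # local import: avoid cycle

    if cfg is None:
        cfg = PipelineConfig()
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < 10 * fs:
        raise ValueError(f"need at least 10 s of PPG, got {len(ppg) / fs:.2f} s")
    low, high = cfg.bandpass
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, ppg)
    taps = sps.firwin(cfg.lowpass_order, cfg.lowpass_cutoff_hz, window="hamming", fs=fs)
    return sps.filtfilt(taps, [1.0], out)


def resample_temperature(
    temp: np.ndarray, fs_in: float = sim.TEMP_RATE, fs_out: float = 1.0
) -> np.ndarray:
    """Sample-and-hold upsampling of the slow temperature channel."""
    factor = int(round(fs_out / fs_in))
    return np.repeat(np.asarray(temp, dtype=float), factor)


@dataclass
class ProcessedSession:
    """Conditioned channels on the wristband clock."""

    ppg_filtered: np.ndarray  # @ 20 Hz
    accel_norm: np.ndarray  # @ 10 Hz
    gyro_norm: np.ndarray  # @ 10 Hz
    temperature: np.ndarray  # @ 1 Hz
    task_track: np.ndarray  # activity id per PPG sample
    hr_trace: np.ndarray | None = None  # bpm per PPG sample, aligned
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.ppg_filtered) / sim.PPG_RATE


def process_session(
    raw: sim.RawSession,
    cfg=None,
    hr_source: str = "reference",
) -> ProcessedSession:
    """Condition a raw session and attach the aligned ground-truth HR trace.

    ``hr_source``: "reference" runs QRS detection on the reference ECG and
    aligns it via accelerometer cross-correlation; "truth" uses the
    simulator's own HR track; "none" leaves the trace absent.
    """
    from . import ground_truth as gt  # local import: avoid cycle

    accel_bl = np.column_stack(
        [remove_baseline(raw.accel[:, i], sim.IMU_RATE) for i in range(3)]
    )
    gyro_bl = np.column_stack(
        [remove_baseline(raw.gyro[:, i], sim.IMU_RATE) for i in range(3)]
    )
    accel_norm = vector_norm(accel_bl[:, 0], accel_bl[:, 1], accel_bl[:, 2])
    gyro_norm = vector_norm(gyro_bl[:, 0], gyro_bl[:, 1], gyro_bl[:, 2])

    ppg_f = filter_ppg(raw.ppg, cfg)
    temp1 = resample_temperature(raw.temperature)

    t20 = np.arange(len(raw.ppg)) / sim.PPG_RATE
    hr_trace = None
    meta: dict = {}
    if hr_source == "truth":
        if raw.true_hr_track is None:
            raise ValueError("session has no simulator HR track")
        hr_trace = np.asarray(raw.true_hr_track, dtype=float)
    elif hr_source == "reference":
        if not raw.has_reference:
            raise ValueError("session is reference-free; no ECG to derive labels from")
        peaks = gt.pan_tompkins(raw.reference_ecg, sim.ECG_RATE)
        times, hr = gt.hr_from_tachogram(gt.Tachogram(peaks))
        lag = gt.synchronize(accel_norm, raw.reference_accel)
        hr_trace = np.interp(t20, times - lag, hr, left=hr[0], right=hr[-1])
        meta["sync_lag"] = lag
    elif hr_source != "none":
        raise ValueError(f"unknown hr_source {hr_source!r}")

    return ProcessedSession(
        ppg_filtered=ppg_f,
        accel_norm=accel_norm,
        gyro_norm=gyro_norm,
        temperature=temp1,
        task_track=raw.task_track,
        hr_trace=hr_trace,
        meta=meta,
    )


@dataclass
class Window:
    """One labelled 6-s analysis window with per-channel slices."""

    t_start: float
    ppg: np.ndarray  # @ 20 Hz
    accel_norm: np.ndarray  # @ 10 Hz
    gyro_norm: np.ndarray  # @ 10 Hz
    temperature: np.ndarray  # @ 1 Hz
    label_task: int
    label_hr: float | None


def window_session(proc: ProcessedSession, cfg=None) -> list[Window]:
    """Slice a processed session into labelled fixed-length windows.

    The task class is the majority activity group inside the window (ties
    broken toward the earlier segment); the HR label is the mean of the
    aligned ground-truth trace.  A partial trailing window is dropped.
    """
    from .session_io import PipelineConfig

    if cfg is None:
        cfg = PipelineConfig()
    wl, hop = cfg.window_length, cfg.window_hop
    dur = proc.duration
    if dur < wl:
        raise ValueError(f"session of {dur:.1f} s is shorter than one {wl}-s window")

    groups20 = np.array(
        [sim.ACTIVITY_GROUP[a] for a in proc.task_track], dtype=int
    )
    windows: list[Window] = []
    n_windows = int(np.floor((dur - wl) / hop)) + 1
    for k in range(n_windows):
        t0 = k * hop
        s20 = slice(int(round(t0 * sim.PPG_RATE)), int(round((t0 + wl) * sim.PPG_RATE)))
        s10 = slice(int(round(t0 * sim.IMU_RATE)), int(round((t0 + wl) * sim.IMU_RATE)))
        s1 = slice(int(round(t0)), int(round(t0 + wl)))

        g = groups20[s20]
        counts = np.bincount(g, minlength=4)[1:]
        best = counts.max()
        tied = [c + 1 for c in range(3) if counts[c] == best]
        if len(tied) == 1:
            label = tied[0]
        else:  # tie -> group seen earliest in the window
            first_pos = {int(gr): int(np.argmax(g == gr)) for gr in tied}
            label = min(tied, key=lambda gr: first_pos[gr])

        hr = None
        if proc.hr_trace is not None:
            hr = float(np.mean(proc.hr_trace[s20]))
        windows.append(
            Window(
                t_start=float(t0),
                ppg=proc.ppg_filtered[s20],
                accel_norm=proc.accel_norm[s10],
                gyro_norm=proc.gyro_norm[s10],
                temperature=proc.temperature[s1],
                label_task=int(label),
                label_hr=hr,
            )
        )
    return windows
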