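"""Per-window feature battery (63 columns) and z-score normalization.

Each window yields 18 features from the filtered PPG (14 statistics, mean
first and second time-derivative, fundamental frequency, accumulated
spectral energy) and 15 features (14 statistics + energy) from each of the
accelerometer norm, gyroscope norm and temperature channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate as sim
from .preprocess import Window

log = logging.getLogger(__name__)

__all__ = [
    "STAT_NAMES",
    "feature_catalogue",
    "stat_battery",
    "feature_battery",
    "featurize",
    "WindowTable",
    "NormStats",
    "fit_norm",
    "apply_norm",
]

_EPS = 1e-9

STAT_NAMES = (
    "mean",
    "median",
    "sd",
    "mad",
    "p25",
    "p75",
    "iqr",
    "skewness",
    "kurtosis",
    "mode",
    "trimmed_mean",
    "geometric_mean",
    "harmonic_mean",
    "variance",
)

_SIGNALS = ("ppg", "accel", "gyro", "temp")


def feature_catalogue() -> list[str]:
    """Ordered column names: 18 PPG + 15 accel + 15 gyro + 15 temp = 63."""
    cols = [f"ppg_{s}" for s in STAT_NAMES]
    cols += ["ppg_d1_mean", "ppg_d2_mean", "ppg_fund_freq", "ppg_energy"]
    for sig in ("accel", "gyro", "temp"):
        cols += [f"{sig}_{s}" for s in STAT_NAMES]
        cols.append(f"{sig}_energy")
    assert len(cols) == 63
    return cols


def stat_battery(x: np.ndarray) -> np.ndarray:
    """The 14 summary statistics of one window.

    Conventions: sample (n-1) denominator for sd/variance; skewness and
    kurtosis are the bias-uncorrected moment ratios (kurtosis non-excess),
    reported as 0 for a constant window; mode is the midpoint of the tallest
    bin of a 10-bin histogram; the truncated mean trims 10% from each tail;
    geometric and harmonic means act on |x| + 1e-9.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:  # constant window: spread and shape are exactly zero
        c = float(x[0])
        g = abs(c) + _EPS
        return np.array([c, c, 0.0, 0.0, c, c, 0.0, 0.0, 0.0, c, c, g, g, 0.0])
    mean = x.sum() / n
    dev = x - mean
    m2 = np.sum(dev**2) / n
    var = np.sum(dev**2) / (n - 1) if n > 1 else 0.0
    sd = np.sqrt(var)
    if m2 > 0:
        skew = (np.sum(dev**3) / n) / m2**1.5
        kurt = (np.sum(dev**4) / n) / m2**2
    else:
        skew = kurt = 0.0
    p25, med, p75 = np.percentile(x, [25.0, 50.0, 75.0])
    counts, edges = np.histogram(x, bins=10)
    b = int(np.argmax(counts))
    mode = 0.5 * (edges[b] + edges[b + 1])

    k = int(np.floor(0.10 * n))
    xs = np.sort(x)
    trimmed = xs[k : n - k].mean()

    ax = np.abs(x) + _EPS
    gmean = float(np.exp(np.mean(np.log(ax))))
    hmean = float(n / np.sum(1.0 / ax))

    return np.array(
        [mean, med, sd, np.mean(np.abs(dev)), p25, p75, p75 - p25,
         skew, kurt, mode, trimmed, gmean, hmean, var]
    )


def accumulated_energy(x: np.ndarray) -> float:
    """Spectral energy: real part of sum(FFT(x) * conj(FFT(x)))."""
    f = np.fft.fft(np.asarray(x, dtype=float))
    return float(np.real(np.sum(f * np.conj(f))))


def fundamental_frequency(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.6, 3.0), nfft: int = 2048
) -> float:
    """Location (Hz) of the largest magnitude-spectrum peak inside ``band``."""
    x = np.asarray(x, dtype=float)
    nfft = max(nfft, len(x))
    spec = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[mask][np.argmax(spec[mask])])


def feature_battery(window: Window, band: tuple[float, float] = (0.6, 3.0)) -> np.ndarray:
    """Compute the 63-feature vector of one window."""
    expected = {
        "ppg": window.ppg,
        "accel": window.accel_norm,
        "gyro": window.gyro_norm,
        "temp": window.temperature,
    }
    rates = {"ppg": sim.PPG_RATE, "accel": sim.IMU_RATE, "gyro": sim.IMU_RATE, "temp": 1.0}
    for name, arr in expected.items():
        if len(arr) < 2:
            raise ValueError(f"window channel {name!r} has too few samples ({len(arr)})")

    out: list[float] = []
    ppg = np.asarray(window.ppg, dtype=float)
    out.extend(stat_battery(ppg))
    d1 = np.diff(ppg) * sim.PPG_RATE
    d2 = np.diff(ppg, n=2) * sim.PPG_RATE**2
    out.append(float(np.mean(d1)))
    out.append(float(np.mean(d2)))
    out.append(fundamental_frequency(ppg, sim.PPG_RATE, band))
    out.append(accumulated_energy(ppg))
    for name in ("accel", "gyro", "temp"):
        arr = np.asarray(expected[name], dtype=float)
        out.extend(stat_battery(arr))
        out.append(accumulated_energy(arr))
    vec = np.asarray(out)
    if len(vec) != 63 or not np.all(np.isfinite(vec)):
        raise ValueError("feature battery must produce 63 finite values")
    return vec


@dataclass
class WindowTable:
    """Feature matrix with task-class and HR labels.

    ``df`` holds the feature columns (catalogue order) plus ``label_hr`` and
    ``label_task``; extra non-feature columns (e.g. ``user``, ``t_start``)
    are carried through but never treated as features.
    """

    df: pd.DataFrame
    catalogue: list[str] = field(default_factory=feature_catalogue)

    def __post_init__(self) -> None:
        missing = [c for c in self.catalogue + ["label_hr", "label_task"]
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"window table missing columns: {missing[:5]}")
        if len(self.df):
            tasks = set(self.df["label_task"].unique())
            if not tasks <= {1, 2, 3}:
                raise ValueError(f"label_task values outside {{1,2,3}}: {sorted(tasks)}")
            feats = self.features
            if not np.all(np.isfinite(feats)):
                raise ValueError("window table contains non-finite feature values")

    @property
    def features(self) -> np.ndarray:
        return self.df[self.catalogue].to_numpy(dtype=float)

    @property
    def label_task(self) -> np.ndarray:
        return self.df["label_task"].to_numpy(dtype=int)

    @property
    def label_hr(self) -> np.ndarray:
        return self.df["label_hr"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


def featurize(
    windows: list[Window],
    band: tuple[float, float] = (0.6, 3.0),
    user: str | int | None = None,
) -> WindowTable:
    """Build a window table from labelled windows."""
    cols = feature_catalogue()
    rows = np.array([feature_battery(w, band) for w in windows]).reshape(-1, 63)
    df = pd.DataFrame(rows, columns=cols)
    df["label_hr"] = [w.label_hr if w.label_hr is not None else np.nan for w in windows]
    df["label_task"] = [w.label_task for w in windows]
    df["t_start"] = [w.t_start for w in windows]
    if user is not None:
        df["user"] = user
    return WindowTable(df)


@dataclass(frozen=True)
class NormStats:
    """Training-split z-score statistics for the retained feature columns."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("normalization sd must be strictly positive")


def fit_norm(table: WindowTable) -> NormStats:
    """Estimate per-feature mean and sd; constant columns are dropped."""
    if len(table) == 0:
        raise ValueError("cannot fit normalization on an empty table")
    feats = table.features
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=1) if len(table) > 1 else np.zeros(feats.shape[1])
    keep = sd > 0
    dropped = [c for c, k in zip(table.catalogue, keep) if not k]
    if dropped:
        log.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
    names = tuple(c for c, k in zip(table.catalogue, keep) if k)
    return NormStats(names=names, mean=mean[keep], sd=sd[keep])


def apply_norm(table: WindowTable, stats: NormStats) -> WindowTable:
    """Z-score a table with training statistics (restricting to retained columns)."""
    unknown = [c for c in stats.names if c not in table.df.columns]
    if unknown:
        raise ValueError(f"normalization stats reference unknown columns: {unknown[:5]}")
    df = table.df.copy()
    names = list(stats.names)
    df[names] = (df[names].to_numpy(dtype=float) - stats.mean) / stats.sd
    df = df[[c for c in df.columns if c in names or c not in table.catalogue]]
    return WindowTable(df, catalogue=names)
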