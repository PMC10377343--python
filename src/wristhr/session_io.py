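"""Session / table persistence, pipeline configuration, diagnostics.

A session is written as a directory of plain CSV files (one per channel,
full double precision) plus ``meta.json``; window tables are single CSV
files with 63 feature columns and the two label columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .features import WindowTable, feature_catalogue

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SessionFormatError",
    "save_session",
    "load_session",
    "save_window_table",
    "load_window_table",
]

_FLOAT_FMT = "%.17g"


class SessionFormatError(ValueError):
    """A session directory or table file violates the storage contract."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters; every random choice flows from ``seed``."""

    window_length: float = 6.0
    window_hop: float = 1.0
    bandpass: tuple[float, float] = (0.6, 3.0)
    lowpass_cutoff_hz: float = 4.0
    lowpass_order: int = 41
    n_classifier_features: int = 9
    n_regressor_features: int = 15
    split_fraction: float = 0.70
    cv_folds: int = 5
    seed: int = 0
    # classifier ensemble (tuned defaults)
    clf_n_learners: int = 492
    clf_learning_rate: float = 0.34449
    clf_max_splits: int = 204
    # Gaussian-process regressor initial kernel values (refit at training)
    gp_kernel_scale: float = 0.55637
    gp_signal_sd: float = 14.331
    gp_noise_sigma: float = 69.2202
    # bagged-trees regressor
    bag_n_learners: int = 14
    bag_min_leaf: int = 3

    def __post_init__(self) -> None:
        low, high = self.bandpass
        if not (0 < low < high < sim.PPG_RATE / 2):
            raise ValueError(f"bandpass {self.bandpass} must satisfy 0 < low < high < Nyquist")
        if not (0 < self.window_hop <= self.window_length):
            raise ValueError("window hop must satisfy 0 < hop <= window_length")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "bandpass" in data:
            data["bandpass"] = tuple(data["bandpass"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["bandpass"] = list(data["bandpass"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# sessions

_CHANNEL_FILES = {
    "ppg": ("ppg.csv", sim.PPG_RATE, 1),
    "accel": ("accel.csv", sim.IMU_RATE, 3),
    "gyro": ("gyro.csv", sim.IMU_RATE, 3),
    "temperature": ("temperature.csv", sim.TEMP_RATE, 1),
}
_OPTIONAL_FILES = {
    "reference_ecg": ("ecg.csv", sim.ECG_RATE, 1),
    "reference_accel": ("ref_accel.csv", sim.REF_ACCEL_RATE, 3),
}


def _write_channel(path: Path, data: np.ndarray, rate: float, names: list[str]) -> None:
    t = np.arange(len(data)) / rate
    arr = np.column_stack([t, data]) if data.ndim > 1 else np.column_stack([t, data])
    header = ",".join(["time_s"] + names)
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt=_FLOAT_FMT)


def save_session(session: sim.RawSession, path: str | Path) -> None:
    """Write one session as a directory of CSVs plus ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_channel(path / "ppg.csv", session.ppg, sim.PPG_RATE, ["value"])
    _write_channel(path / "accel.csv", session.accel, sim.IMU_RATE, ["ax", "ay", "az"])
    _write_channel(path / "gyro.csv", session.gyro, sim.IMU_RATE, ["gx", "gy", "gz"])
    _write_channel(path / "temperature.csv", session.temperature, sim.TEMP_RATE, ["value"])
    if session.reference_ecg is not None:
        _write_channel(path / "ecg.csv", session.reference_ecg, sim.ECG_RATE, ["value"])
    if session.reference_accel is not None:
        _write_channel(path / "ref_accel.csv", session.reference_accel,
                       sim.REF_ACCEL_RATE, ["ax", "ay", "az"])

    t20 = np.arange(len(session.ppg)) / sim.PPG_RATE
    labels = pd.DataFrame({"time_s": t20, "activity": session.task_track})
    if session.true_hr_track is not None:
        labels["true_hr"] = session.true_hr_track
    labels.to_csv(path / "labels.csv", index=False, float_format=_FLOAT_FMT)

    meta = {
        "rates": {
            "ppg": sim.PPG_RATE,
            "accel": sim.IMU_RATE,
            "gyro": sim.IMU_RATE,
            "temperature": sim.TEMP_RATE,
            "reference_ecg": sim.ECG_RATE,
            "reference_accel": sim.REF_ACCEL_RATE,
        },
        "clock_offset": session.clock_offset,
        "groups": sim.ACTIVITY_GROUP,
        **{k: v for k, v in session.meta.items() if k != "r_peak_times"},
    }
    if "r_peak_times" in session.meta:
        meta["r_peak_times"] = [float(x) for x in session.meta["r_peak_times"]]
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def _read_channel(path: Path, name: str, rate: float, ncols: int) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SessionFormatError(f"channel {name!r}: non-monotone timestamps")
        observed = 1.0 / np.median(dt)
        if abs(observed - rate) / rate > 0.01:
            raise SessionFormatError(
                f"channel {name!r}: data sampled at {observed:.3g} Hz but the session "
                f"declares {rate:g} Hz"
            )
    vals = df.drop(columns=["time_s"]).to_numpy(dtype=float)
    if vals.shape[1] != ncols:
        raise SessionFormatError(f"channel {name!r}: expected {ncols} value column(s)")
    return vals[:, 0] if ncols == 1 else vals


def load_session(path: str | Path) -> sim.RawSession:
    """Read a session directory back into a :class:`RawSession`.

    Sessions lacking the reference-device files load fine and are flagged
    reference-free (``has_reference`` False).
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionFormatError(f"{path} is not a session directory (no meta.json)")
    meta = json.loads(meta_path.read_text())
    rates = meta.get("rates", {})

    channels = {}
    for key, (fname, default_rate, ncols) in _CHANNEL_FILES.items():
        f = path / fname
        if not f.exists():
            raise SessionFormatError(f"mandatory channel file {fname!r} is missing")
        channels[key] = _read_channel(f, key, float(rates.get(key, default_rate)), ncols)
    for key, (fname, default_rate, ncols) in _OPTIONAL_FILES.items():
        f = path / fname
        channels[key] = (
            _read_channel(f, key, float(rates.get(key, default_rate)), ncols)
            if f.exists()
            else None
        )
    if channels["reference_ecg"] is None:
        log.info("session %s is reference-free", path)

    labels = pd.read_csv(path / "labels.csv", float_precision="round_trip")
    task_track = labels["activity"].to_numpy()
    true_hr = labels["true_hr"].to_numpy() if "true_hr" in labels else None

    session_meta = {
        k: v
        for k, v in meta.items()
        if k not in ("rates", "clock_offset", "groups")
    }
    if "r_peak_times" in session_meta:
        session_meta["r_peak_times"] = np.asarray(session_meta["r_peak_times"])
    session = sim.RawSession(
        ppg=channels["ppg"],
        accel=channels["accel"],
        gyro=channels["gyro"],
        temperature=channels["temperature"],
        task_track=task_track,
        true_hr_track=true_hr,
        reference_ecg=channels["reference_ecg"],
        reference_accel=channels["reference_accel"],
        clock_offset=float(meta.get("clock_offset", 0.0)),
        meta=session_meta,
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# window tables


def save_window_table(table: WindowTable, path: str | Path) -> None:
    """Write a validated window table to CSV (63 features + the two labels)."""
    tasks = set(table.df["label_task"].unique()) if len(table) else set()
    if not tasks <= {1, 2, 3}:
        raise ValueError(f"refusing to save table with label_task outside {{1,2,3}}: {sorted(tasks)}")
    cols = list(table.catalogue) + ["label_hr", "label_task"]
    extra = [c for c in ("user", "t_start") if c in table.df.columns]
    table.df[cols + extra].to_csv(Path(path), index=False, float_format=_FLOAT_FMT)
    Path(str(path) + ".catalogue.json").write_text(
        json.dumps(list(table.catalogue), indent=0)
    )


def load_window_table(path: str | Path) -> WindowTable:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    cat_file = Path(str(path) + ".catalogue.json")
    catalogue = (
        json.loads(cat_file.read_text()) if cat_file.exists() else feature_catalogue()
    )
    feature_cols = [c for c in df.columns if c not in ("label_hr", "label_task", "user", "t_start")]
    if feature_cols != list(catalogue):
        raise SessionFormatError(
            f"window table has {len(feature_cols)} feature columns, "
            f"expected the {len(catalogue)}-column catalogue"
        )
    return WindowTable(df, catalogue=list(catalogue))
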