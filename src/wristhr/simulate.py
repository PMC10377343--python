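"""Synthetic wearable-session generator.

Produces multirate recordings (wrist PPG + IMU + skin temperature, plus an
optional chest reference with ECG and accelerometer) for a scripted activity
protocol.  The PPG channel is generated through a Beer--Lambert intensity
model ``Io = Ii * exp(-k(t))`` whose exponent collects the cardiac pulsatile
term, slow basal drift, a mechanical artifact coupled to wrist acceleration
and a vascular artifact driven by a finger-movement burst process that is
invisible to the wrist IMU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ACTIVITIES",
    "ACTIVITY_GROUP",
    "DEFAULT_PROTOCOL",
    "PPG_RATE",
    "IMU_RATE",
    "TEMP_RATE",
    "ECG_RATE",
    "REF_ACCEL_RATE",
    "ProtocolSchedule",
    "Segment",
    "UserPhysiology",
    "ArtifactModel",
    "RawSession",
    "make_schedule",
    "simulate_hr_trace",
    "simulate_session",
    "sample_physiology",
]

ACTIVITIES = ("A_rest", "B_read", "C_write", "D_walk_slow", "E_walk_fast")

#: activity -> movement group (1 rest, 2 finger movement, 3 displacement)
ACTIVITY_GROUP = {
    "A_rest": 1,
    "B_read": 2,
    "C_write": 2,
    "D_walk_slow": 3,
    "E_walk_fast": 3,
}

#: default acquisition protocol, (activity, minutes); 9 segments, 29 min total
DEFAULT_PROTOCOL = (
    ("A_rest", 5.0),
    ("B_read", 3.0),
    ("A_rest", 2.0),
    ("D_walk_slow", 5.0),
    ("A_rest", 2.0),
    ("C_write", 3.0),
    ("A_rest", 2.0),
    ("E_walk_fast", 5.0),
    ("A_rest", 2.0),
)

PPG_RATE = 20.0
IMU_RATE = 10.0
TEMP_RATE = 0.1
ECG_RATE = 250.0
REF_ACCEL_RATE = 100.0

#: nominal gait step frequency (Hz) per walking activity
STEP_FREQUENCY = {"D_walk_slow": 1.6, "E_walk_fast": 2.0}


@dataclass(frozen=True)
class Segment:
    activity: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(
                f"unknown activity id {self.activity!r}; expected one of {ACTIVITIES}"
            )
        if not self.duration_s > 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration_s}")

    @property
    def group(self) -> int:
        return ACTIVITY_GROUP[self.activity]


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered activity segments covering one recording session."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol schedule must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Segment start times plus the final end time (len = n_segments + 1)."""
        return np.concatenate([[0.0], np.cumsum([s.duration_s for s in self.segments])])

    def activity_at(self, times: np.ndarray) -> np.ndarray:
        """Activity id for each time point (end time maps to the last segment)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.boundaries, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        ids = np.array([s.activity for s in self.segments])
        return ids[idx]

    def group_at(self, times: np.ndarray) -> np.ndarray:
        acts = self.activity_at(times)
        lut = np.vectorize(ACTIVITY_GROUP.get)
        return lut(acts).astype(int)

    def to_list(self) -> list[tuple[str, float]]:
        return [(s.activity, s.duration_s / 60.0) for s in self.segments]


def make_schedule(spec: list[tuple[str, float]] | None = None) -> ProtocolSchedule:
    """Build a protocol schedule from ``(activity_id, minutes)`` pairs.

    Without ``spec`` the default nine-segment acquisition protocol is
    returned (rest / read / rest / walk-slow / rest / write / rest /
    walk-fast / rest; 29 minutes total).
    """
    if spec is None:
        spec = list(DEFAULT_PROTOCOL)
    segments = tuple(Segment(act, minutes * 60.0) for act, minutes in spec)
    return ProtocolSchedule(segments)


@dataclass(frozen=True)
class UserPhysiology:
    """Per-user parameters of the ground-truth cardiovascular model."""

    resting_hr: float = 65.0
    #: steady-state HR elevation (bpm) per activity id; the modest defaults
    #: keep the pooled HR spread near the observed ~10 bpm population sd, so
    #: most HR variance is between users rather than between activities
    hr_delta_per_activity: dict[str, float] = field(
        default_factory=lambda: {
            "A_rest": 0.0,
            "B_read": 2.0,
            "C_write": 3.0,
            "D_walk_slow": 6.0,
            "E_walk_fast": 10.0,
        }
    )
    hr_time_constant: float = 35.0
    ibi_jitter_sd: float = 0.030
    base_temperature: float = 34.0
    temp_coupling_gain: float = 0.02
    temp_lag: float = 60.0
    ppg_ac_amplitude: float = 0.10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.resting_hr <= 100.0):
            raise ValueError(f"resting_hr must lie in [40, 100], got {self.resting_hr}")
        d = self.hr_delta_per_activity
        missing = set(ACTIVITIES) - set(d)
        if missing:
            raise ValueError(f"hr_delta_per_activity missing activities: {sorted(missing)}")
        if any(v < 0 for v in d.values()):
            raise ValueError("hr deltas must be non-negative")
        ordered = [d["A_rest"], min(d["B_read"], d["C_write"]),
                   d["D_walk_slow"], d["E_walk_fast"]]
        if any(a > b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("hr deltas must be non-decreasing: rest <= read/write <= walk")
        if self.temp_lag < 0:
            raise ValueError("temp_lag must be >= 0")
        if self.hr_time_constant <= 0:
            raise ValueError("hr_time_constant must be > 0")

    def target_hr(self, activity: str) -> float:
        return self.resting_hr + self.hr_delta_per_activity[activity]


def sample_physiology(rng: np.random.Generator, seed: int | None = None) -> UserPhysiology:
    """Draw a random user.

    Resting HR ~ Normal(65, 8^2) truncated to [45, 85].  The basal skin
    temperature is anchored to the resting HR (common metabolic driver) plus
    a small idiosyncratic offset, so the temperature level is an
    approximately user-independent proxy of absolute HR.
    """
    while True:
        resting = float(rng.normal(65.0, 8.0))
        if 45.0 <= resting <= 85.0:
            break
    gain = 0.02
    base_temp = 32.7 + gain * resting + float(rng.uniform(-0.05, 0.05))
    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1))
    return UserPhysiology(
        resting_hr=resting,
        base_temperature=base_temp,
        temp_coupling_gain=gain,
        random_seed=seed,
    )


@dataclass(frozen=True)
class ArtifactModel:
    """Beer--Lambert PPG model and per-channel noise levels.

    ``mmec_gain`` couples wrist acceleration into the optical path length
    (sensor displacement); ``mvascular_gain`` couples a finger-movement burst
    process into the tissue-concentration term.  Both enter the exponent of
    ``Io = input_intensity * exp(-k(t))``, which keeps ``0 < Io <= Ii``.
    """

    input_intensity: float = 1.0
    baseline_absorbance: float = 1.0
    mmec_gain: float = 0.70
    mvascular_gain: float = 0.35
    respiration_amplitude: float = 0.03
    respiration_freq: float = 0.25
    thermo_drift_per_hour: float = 0.05
    #: in-band perfusion/micro-motion noise on the optical path (always on;
    #: models the soft wristband attachment that degrades even rest windows)
    perfusion_noise_sd: float = 0.024
    #: near-cardiac vasomotor tone: a per-user narrowband component a few bpm
    #: away from the resting pulse frequency.  It models the multi-peaked
    #: spectra seen with soft wristband attachment: the dominant in-band peak
    #: flips between the cardiac peak and this tone from window to window
    distractor_rel_amp: float = 0.5
    distractor_offset_bpm: tuple[float, float] = (4.0, 9.0)
    ppg_noise_sd: float = 0.003
    accel_noise_sd: float = 0.012
    gyro_noise_sd: float = 0.6
    temp_noise_sd: float = 0.0005
    #: optional vasomotor alternation of the temperature readout whose
    #: amplitude grows with (lagged) HR; 0 disables it, leaving readout
    #: quantization as the only source of within-window temperature texture
    temp_fluct_base: float = 0.0
    #: sensor readout resolution in deg C (typical digital skin-temp sensor)
    temp_quantum: float = 0.02
    temp_drift_per_hour: float = 0.08
    ecg_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.mmec_gain < 0 or self.mvascular_gain < 0:
            raise ValueError("artifact gains must be non-negative")
        if self.input_intensity <= 0:
            raise ValueError("input_intensity must be > 0")


@dataclass
class RawSession:
    """One multirate recording.

    Channels are stored as plain arrays sampled at the class-level rates
    (``PPG_RATE`` etc.); sample ``i`` of a channel with rate ``r`` is taken at
    ``i / r`` seconds on the device's own clock.  The reference device clock
    is shifted by ``clock_offset`` relative to the wristband.
    """

    ppg: np.ndarray
    accel: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)
    temperature: np.ndarray
    task_track: np.ndarray  # activity id per PPG sample
    true_hr_track: np.ndarray | None = None  # bpm per PPG sample (simulator only)
    reference_ecg: np.ndarray | None = None
    reference_accel: np.ndarray | None = None  # (n, 3)
    clock_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.ppg) / PPG_RATE

    @property
    def has_reference(self) -> bool:
        return self.reference_ecg is not None

    def validate(self) -> None:
        dur = self.duration
        checks = [
            ("accel", len(self.accel), IMU_RATE),
            ("gyro", len(self.gyro), IMU_RATE),
            ("temperature", len(self.temperature), TEMP_RATE),
        ]
        if self.reference_ecg is not None:
            checks.append(("reference_ecg", len(self.reference_ecg), ECG_RATE))
        if self.reference_accel is not None:
            checks.append(("reference_accel", len(self.reference_accel), REF_ACCEL_RATE))
        for name, n, rate in checks:
            expect = int(round(dur * rate))
            if abs(n - expect) > 1:
                raise ValueError(
                    f"channel {name!r} has {n} samples, expected ~{expect} "
                    f"for a {dur:.1f}-s session at {rate} Hz"
                )
        if len(self.task_track) != len(self.ppg):
            raise ValueError("task_track must have one entry per PPG sample")


# ---------------------------------------------------------------------------
# ground-truth heart rate


def simulate_hr_trace(
    schedule: ProtocolSchedule,
    phys: UserPhysiology,
    rate: float = PPG_RATE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous HR trace and R-peak times for one session.

    The HR relaxes exponentially (time constant ``hr_time_constant``) toward
    the activity-dependent target; R-peaks are produced by integrating the
    instantaneous beat rate and firing at integer phase crossings, with
    independent Gaussian jitter added to each inter-beat interval.

    Returns ``(times, hr_bpm, r_peak_times)``.
    """
    dt = 1.0 / rate
    n = int(round(schedule.total_duration * rate))
    times = np.arange(n) * dt
    hr = np.empty(n)

    # piecewise-exact first-order relaxation
    current = phys.target_hr(schedule.segments[0].activity)
    bounds = schedule.boundaries
    for seg, t0, t1 in zip(schedule.segments, bounds[:-1], bounds[1:]):
        target = phys.target_hr(seg.activity)
        mask = (times >= t0) & (times < t1)
        tt = times[mask] - t0
        hr[mask] = target + (current - target) * np.exp(-tt / phys.hr_time_constant)
        current = target + (current - target) * math.exp(
            -(t1 - t0) / phys.hr_time_constant
        )

    # integrate-and-fire beat generator: nominal peaks at integer crossings of
    # the cumulative beat phase, then per-interval Gaussian jitter
    phase = np.concatenate([[0.0], np.cumsum((hr[:-1] + hr[1:]) / 2.0 / 60.0 * dt)])
    n_beats = int(math.floor(phase[-1]))
    if n_beats < 1:
        return times, hr, np.empty(0)
    nominal = np.interp(np.arange(1, n_beats + 1, dtype=float), phase, times)

    rng = np.random.default_rng(np.random.SeedSequence([phys.random_seed, 101]))
    ibis = np.diff(np.concatenate([[0.0], nominal]))
    if phys.ibi_jitter_sd > 0:
        ibis = ibis + rng.normal(0.0, phys.ibi_jitter_sd, size=len(ibis))
        ibis = np.maximum(ibis, 0.25)
    peaks = np.cumsum(ibis)
    peaks = peaks[peaks < schedule.total_duration]
    return times, hr, peaks


# ---------------------------------------------------------------------------
# channel synthesis helpers (all driven by a caller-supplied Generator)


def _pulse_waveform(t20: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Two-lobe (systolic + dicrotic) pulse train on the PPG time grid."""
    out = np.zeros_like(t20)
    dt = t20[1] - t20[0] if len(t20) > 1 else 0.05
    # local template support: 0.8 s after each beat
    width = int(round(0.9 / dt))
    for tp in peaks:
        i0 = int(round(tp / dt))
        i1 = min(i0 + width, len(t20))
        if i0 >= len(t20):
            break
        tt = t20[i0:i1] - tp
        out[i0:i1] += np.exp(-0.5 * ((tt - 0.12) / 0.075) ** 2)
        out[i0:i1] += 0.40 * np.exp(-0.5 * ((tt - 0.38) / 0.12) ** 2)
    return out


def _burst_train(
    rng: np.random.Generator,
    t: np.ndarray,
    active: np.ndarray,
    mean_gap: float,
    duration: float,
    freq_range: tuple[float, float],
    amp_range: tuple[float, float],
    decay: float,
) -> np.ndarray:
    """Sparse damped-oscillation bursts confined to ``active`` samples."""
    out = np.zeros_like(t)
    if not active.any():
        return out
    dt = t[1] - t[0]
    width = int(round(duration / dt))
    # candidate onset times over the whole session; keep those in active spans
    tcur = float(rng.uniform(0.0, mean_gap))
    end = t[-1]
    while tcur < end:
        i0 = int(round(tcur / dt))
        if 0 <= i0 < len(t) and active[i0]:
            i1 = min(i0 + width, len(t))
            tt = t[i0:i1] - tcur
            f = rng.uniform(*freq_range)
            a = rng.uniform(*amp_range)
            ph = rng.uniform(0, 2 * np.pi)
            out[i0:i1] += a * np.exp(-tt / decay) * np.sin(2 * np.pi * f * tt + ph)
        else:
            # keep the draw sequence independent of the activity layout
            rng.uniform(*freq_range)
            rng.uniform(*amp_range)
            rng.uniform(0, 2 * np.pi)
        tcur += rng.exponential(mean_gap) + 0.3
    return out


def _gait_oscillation(
    rng: np.random.Generator,
    t: np.ndarray,
    schedule: ProtocolSchedule,
    amp: float,
    harmonic_frac: float,
) -> np.ndarray:
    """Periodic gait component active in walking segments only."""
    out = np.zeros_like(t)
    bounds = schedule.boundaries
    for seg, t0, t1 in zip(schedule.segments, bounds[:-1], bounds[1:]):
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        if seg.activity not in STEP_FREQUENCY:
            continue
        f = STEP_FREQUENCY[seg.activity]
        mask = (t >= t0) & (t < t1)
        tt = t[mask]
        out[mask] = amp * (
            np.sin(2 * np.pi * f * tt + ph1)
            + harmonic_frac * np.sin(2 * np.pi * 2 * f * tt + ph2)
        )
    return out


def _ecg_trace(
    rng: np.random.Generator,
    t250: np.ndarray,
    peaks: np.ndarray,
    noise_sd: float,
) -> np.ndarray:
    """Reference ECG: Gaussian-sum QRS template at each R-peak plus wander."""
    ecg = np.zeros_like(t250)
    dt = t250[1] - t250[0]
    half = int(round(0.45 / dt))
    comps = (  # (amplitude, offset s, width s): Q, R, S, T
        (-0.15, -0.040, 0.020),
        (1.00, 0.000, 0.012),
        (-0.25, 0.035, 0.018),
        (0.30, 0.300, 0.070),
    )
    for tp in peaks:
        ic = int(round(tp / dt))
        i0, i1 = max(ic - half, 0), min(ic + half, len(t250))
        if i0 >= len(t250):
            break
        tt = t250[i0:i1] - tp
        for a, off, w in comps:
            ecg[i0:i1] += a * np.exp(-0.5 * ((tt - off) / w) ** 2)
    ph = rng.uniform(0, 2 * np.pi)
    ecg += 0.15 * np.sin(2 * np.pi * 0.18 * t250 + ph)
    ecg += rng.normal(0.0, noise_sd, size=len(t250))
    return ecg


# ---------------------------------------------------------------------------
# full session


def simulate_session(
    schedule: ProtocolSchedule,
    phys: UserPhysiology,
    artifact: ArtifactModel | None = None,
    *,
    with_reference: bool = True,
    clock_offset: float | None = None,
) -> RawSession:
    """Generate one complete multirate session.

    Deterministic given ``(schedule, phys, artifact, clock_offset)``; all
    randomness derives from ``phys.random_seed``.  If ``clock_offset`` is
    None it is drawn uniformly from [-5, +5] s.
    """
    if artifact is None:
        artifact = ArtifactModel()
    dur = schedule.total_duration
    rng = np.random.default_rng(np.random.SeedSequence([phys.random_seed, 202]))

    t_hr, hr, peaks = simulate_hr_trace(schedule, phys, rate=PPG_RATE)
    t20 = t_hr
    n20 = len(t20)
    t10 = np.arange(int(round(dur * IMU_RATE))) / IMU_RATE
    group10 = schedule.group_at(t10)

    # --- wrist IMU -----------------------------------------------------
    accel = rng.normal(0.0, artifact.accel_noise_sd, size=(len(t10), 3))
    gyro = rng.normal(0.0, artifact.gyro_noise_sd, size=(len(t10), 3))

    gait_x = _gait_oscillation(rng, t10, schedule, amp=0.40, harmonic_frac=0.35)
    gait_z = _gait_oscillation(rng, t10, schedule, amp=0.55, harmonic_frac=0.30)
    gait_y = _gait_oscillation(rng, t10, schedule, amp=0.20, harmonic_frac=0.25)
    accel[:, 0] += gait_x
    accel[:, 1] += gait_y
    accel[:, 2] += gait_z

    swing = _gait_oscillation(rng, t10, schedule, amp=35.0, harmonic_frac=0.20)
    gyro[:, 0] += swing
    gyro[:, 1] += 0.6 * _gait_oscillation(rng, t10, schedule, amp=35.0, harmonic_frac=0.2)

    finger10 = schedule.group_at(t10) == 2
    # finger/wrist rotation shows up in the gyro but (sub-noise) in the accel
    gyro_burst = _burst_train(
        rng, t10, finger10, mean_gap=2.2, duration=0.8,
        freq_range=(2.0, 4.0), amp_range=(8.0, 25.0), decay=0.25,
    )
    gyro[:, 0] += gyro_burst
    gyro[:, 2] += 0.5 * gyro_burst
    accel[:, 0] += 0.25 * artifact.accel_noise_sd * np.tanh(np.abs(gyro_burst) / 20.0)

    # --- PPG (Beer--Lambert exponent) ----------------------------------
    pulse = _pulse_waveform(t20, peaks)
    resp_ph = rng.uniform(0, 2 * np.pi)
    basal = (
        artifact.respiration_amplitude
        * np.sin(2 * np.pi * artifact.respiration_freq * t20 + resp_ph)
        + artifact.thermo_drift_per_hour * t20 / 3600.0
    )

    # mechanical artifact: signed wrist acceleration coupled into path length
    a_signed = 0.5 * (accel[:, 0] + accel[:, 2])
    m20 = np.interp(t20, t10, a_signed)

    finger20 = schedule.group_at(t20) == 2
    v20 = _burst_train(
        rng, t20, finger20, mean_gap=1.6, duration=1.1,
        freq_range=(0.9, 1.9), amp_range=(0.6, 1.6), decay=0.45,
    )

    distractor = np.zeros(n20)
    if artifact.distractor_rel_amp > 0:
        lo, hi = artifact.distractor_offset_bpm
        offset = float(rng.uniform(lo, hi)) * float(rng.choice([-1.0, 1.0]))
        f_tone = (phys.resting_hr + offset) / 60.0
        ph_tone = rng.uniform(0, 2 * np.pi)
        distractor = (
            artifact.distractor_rel_amp
            * phys.ppg_ac_amplitude
            * np.sin(2 * np.pi * f_tone * t20 + ph_tone)
        )

    perfusion = np.zeros(n20)
    if artifact.perfusion_noise_sd > 0:
        from scipy import signal as sps

        sos = sps.butter(2, [0.6, 3.0], btype="bandpass", fs=PPG_RATE, output="sos")
        white = rng.normal(0.0, 1.0, size=n20)
        colored = sps.sosfilt(sos, white)
        perfusion = colored / (np.std(colored) + 1e-12) * artifact.perfusion_noise_sd

    exponent = (
        artifact.baseline_absorbance
        + phys.ppg_ac_amplitude * pulse
        + basal
        + distractor
        + perfusion
        + artifact.mmec_gain * m20
        + artifact.mvascular_gain * v20
    )
    exponent = np.maximum(exponent, 0.0)
    ppg = artifact.input_intensity * np.exp(-exponent)
    ppg = ppg + rng.normal(0.0, artifact.ppg_noise_sd, size=n20)

    # --- temperature ----------------------------------------------------
    t01 = np.arange(int(round(dur * TEMP_RATE))) / TEMP_RATE
    hr_lagged = np.interp(t01 - phys.temp_lag, t_hr, hr, left=hr[0])
    # perfusion microfluctuation: amplitude and up/down asymmetry follow the
    # lagged HR ("sympathetic tone"), so spread- and shape-type statistics of
    # the temperature channel remain HR-informative
    # vasomotor oscillation: sample-to-sample alternation whose amplitude
    # grows with sympathetic tone; below the readout quantum it is invisible,
    # above it it produces quantized steps, so the spread/shape statistics of
    # the quantized channel increase monotonically with (lagged) HR
    tone = np.clip((hr_lagged - 45.0) / 40.0, 0.0, 1.25)
    amp = artifact.temp_fluct_base * tone**1.5
    fluct = amp * (-1.0) ** np.arange(len(t01))
    temperature = (
        phys.base_temperature
        + phys.temp_coupling_gain * (hr_lagged - phys.resting_hr)
        + artifact.temp_drift_per_hour * t01 / 3600.0
        + fluct
        + rng.normal(0.0, artifact.temp_noise_sd, size=len(t01))
    )
    if artifact.temp_quantum > 0:
        temperature = np.round(temperature / artifact.temp_quantum) * artifact.temp_quantum

    # --- reference device ----------------------------------------------
    ecg = ref_accel = None
    if clock_offset is None:
        clock_offset = float(rng.uniform(-5.0, 5.0))
    if with_reference:
        t250 = np.arange(int(round(dur * ECG_RATE))) / ECG_RATE
        ecg = _ecg_trace(rng, t250, peaks, artifact.ecg_noise_sd)
        t100 = np.arange(int(round(dur * REF_ACCEL_RATE))) / REF_ACCEL_RATE
        ref_accel = np.empty((len(t100), 3))
        for ax in range(3):
            ref_accel[:, ax] = np.interp(t100 - clock_offset, t10, accel[:, ax])
        ref_accel += rng.normal(0.0, 0.01, size=ref_accel.shape)

    session = RawSession(
        ppg=ppg,
        accel=accel,
        gyro=gyro,
        temperature=temperature,
        task_track=schedule.activity_at(t20),
        true_hr_track=hr,
        reference_ecg=ecg,
        reference_accel=ref_accel,
        clock_offset=float(clock_offset),
        meta={
            "schedule": schedule.to_list(),
            "seed": phys.random_seed,
            "resting_hr": phys.resting_hr,
            "r_peak_times": peaks,
        },
    )
    session.validate()
    return session
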