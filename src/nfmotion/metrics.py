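"""Movement-quality metrics aligned with MDS-UPDRS III scoring logic.

Per task execution the full metric vector covers: signal magnitude,
rate, mean peak speed, mean amplitude, total displacement, two smoothness
measures (spectral arc length and log-dimensionless jerk), halts and
interval statistics, and amplitude decrement (first/second-half change
and a time-regression slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import imu as _imu
from . import kinematics as _kin
from .imu import ImuRecording, MovementSignal

__all__ = [
    "MetricSet",
    "magnitude",
    "rate",
    "mean_peak",
    "mean_amplitude",
    "total_displacement",
    "sparc",
    "log_dimensionless_jerk",
    "intervals_and_halts",
    "decrement",
    "compute_metric_set",
]


@dataclass(frozen=True)
class MetricSet:
    """Per-execution metric vector. Fields not defined for the task are NaN."""

    task: str
    acceleration_magnitude_mean: float = math.nan   # m/s^2, FS only
    angular_velocity_magnitude_mean: float = math.nan  # deg/s, HPS only
    rate_per_s: float = math.nan
    mean_peak_velocity: float = math.nan            # m/s or deg/s
    mean_amplitude: float = math.nan                # m or deg
    total_displacement: float = math.nan            # m or deg
    sparc: float = math.nan                         # unitless, <= 0
    log_dimensionless_jerk: float = math.nan
    n_halts: int = 0
    mean_interval_s: float = math.nan
    amplitude_change: float = math.nan
    amplitude_slope: float = math.nan
    n_movements: int = 0

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def magnitude(x: Sequence[float], y: Sequence[float], z: Sequence[float]) -> np.ndarray:
    """Element-wise Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("component series must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def rate(n_peaks: int, duration: float) -> float:
    """Movements per second: N_peaks / T."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return n_peaks / duration


def mean_peak(segments: Sequence[_kin.MovementSegment]) -> float:
    """Mean of per-movement peak speeds."""
    if len(segments) == 0:
        raise ValueError("no movement segments")
    return float(np.mean([s.peak_speed for s in segments]))


def mean_amplitude(segments: Sequence[_kin.MovementSegment]) -> float:
    """Mean of per-movement amplitude magnitudes."""
    if len(segments) == 0:
        raise ValueError("no movement segments")
    return float(np.mean([abs(s.amplitude) for s in segments]))


def total_displacement(displacement: Sequence[float]) -> float:
    """Sum of absolute successive displacement differences over the window."""
    d = np.asarray(displacement, dtype=float)
    if d.size == 0:
        raise ValueError("empty displacement series")
    return float(np.sum(np.abs(np.diff(d))))


def sparc(
    speed: Sequence[float],
    fs: float,
    padlevel: int = 4,
    fc: float = 10.0,
    amp_th: float = 0.05,
) -> float:
    """Spectral arc length of a speed profile (more negative = less smooth).

    Negative arc length of the amplitude-normalized Fourier magnitude
    spectrum over [0, fc], restricted to the frequency span where the
    normalized magnitude exceeds ``amp_th`` (adaptive cutoff). Published
    defaults: zero-padding level 4, fc = 10 Hz, threshold 0.05.
    """
    v = np.asarray(speed, dtype=float)
    if len(v) < fs:
        raise ValueError("speed profile must be at least 1 s long")
    if not np.any(v):
        raise ValueError("all-zero speed profile")
    nfft = int(2 ** np.ceil(np.log2(len(v)) + padlevel))
    f = np.arange(0, fs, fs / nfft)
    Mf = np.abs(np.fft.fft(v, nfft))
    Mf = Mf / Mf.max()
    sel = np.nonzero(f <= fc)[0]
    f_sel, M_sel = f[sel], Mf[sel]
    above = np.nonzero(M_sel >= amp_th)[0]
    lo, hi = above[0], above[-1]
    f_sel, M_sel = f_sel[lo : hi + 1], M_sel[lo : hi + 1]
    df = np.diff(f_sel) / (f_sel[-1] - f_sel[0])
    dM = np.diff(M_sel)
    return float(-np.sum(np.sqrt(df ** 2 + dM ** 2)))


def log_dimensionless_jerk(velocity: Sequence[float], fs: float) -> float:
    """-ln( (T^3 / v_peak^2) * integral |dv/dt|^2 dt ).

    T is the window duration, v_peak the maximum absolute velocity, and
    the derivative is taken by central differences. Higher (less
    negative) values indicate smoother movement.
    """
    v = np.asarray(velocity, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 samples")
    v_peak = np.max(np.abs(v))
    if v_peak == 0:
        raise ValueError("zero peak velocity")
    dt = 1.0 / fs
    T = (len(v) - 1) * dt
    dv = np.gradient(v, dt)
    integral = np.trapezoid(dv ** 2, dx=dt)
    return float(-np.log((T ** 3 / v_peak ** 2) * integral))


def intervals_and_halts(peak_times: Sequence[float]) -> Tuple[float, int]:
    """Mean inter-movement interval and halt count (mu + 2 sigma rule).

    A halt is an interval strictly exceeding the mean of all intervals
    plus twice their (population) standard deviation.
    """
    t = np.asarray(peak_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 peaks")
    intervals = np.diff(t)
    mu = float(np.mean(intervals))
    sigma = float(np.std(intervals))
    n_halts = int(np.sum(intervals > mu + 2.0 * sigma))
    return mu, n_halts


def decrement(
    segments: Sequence[_kin.MovementSegment],
    peak_times: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """Amplitude decrement: first/second-half change and OLS slope vs time.

    Delta A = mean amplitude of the first half of movements minus the
    second half; with an odd count the middle movement goes to the first
    half. The slope is the least-squares fit of |A_i| against peak time.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    amps = np.array([abs(s.amplitude) for s in segments], dtype=float)
    if peak_times is None:
        times = np.array([s.t_peak for s in segments], dtype=float)
    else:
        times = np.asarray(peak_times, dtype=float)
    half = (len(amps) + 1) // 2  # middle movement assigned to the first half
    delta_a = float(np.mean(amps[:half]) - np.mean(amps[half:]))
    slope = float(np.polyfit(times, amps, 1)[0])
    return delta_a, slope


def _fs_chain(rec: ImuRecording, window, cfg: dict):
    sig = _imu.to_global_frame(rec, "accel")
    sig = _imu.gravity_compensate(sig)
    sig = _imu.highpass(sig, cfg["highpass_cutoff_hz"])
    vert = _imu.component(sig, 2)
    if window is None:
        window = _imu.segment_task(vert)
    sig = _imu.crop(sig, window)
    sig = _imu.downsample(sig, cfg["target_fs_hz"])
    vert = _imu.component(sig, 2)
    peaks = _kin.detect_peaks(
        vert, cfg["peaks_min_distance_s"], cfg.get("peaks_min_prominence")
    )
    if peaks.size == 0:
        raise ValueError("no movement peaks detected in window")
    series = _kin.integrate_zupt(vert, peaks)
    segs = _kin.build_segments(series, peaks, amplitude_mode="excursion")
    mag = magnitude(sig.value[:, 0], sig.value[:, 1], sig.value[:, 2])
    return sig, series, segs, peaks, mag, window


def _hps_chain(rec: ImuRecording, window, cfg: dict):
    sig = _imu.to_global_frame(rec, "gyro")
    sig = _imu.highpass(sig, cfg["highpass_cutoff_hz"])
    if window is None:
        window = _imu.segment_task(sig)
    sig = _imu.crop(sig, window)
    sig = _imu.downsample(sig, cfg["target_fs_hz"])
    axis = _kin.select_axis(sig.value, cfg.get("axis_selection", "auto"))
    omega = _imu.component(sig, axis)
    peaks = _kin.detect_peaks(
        omega, cfg["peaks_min_distance_s"], cfg.get("peaks_min_prominence")
    )
    if peaks.size == 0:
        raise ValueError("no movement peaks detected in window")
    series = _kin.angular_displacement(omega)
    segs = _kin.build_segments(series, peaks, amplitude_mode="signed")
    mag = magnitude(sig.value[:, 0], sig.value[:, 1], sig.value[:, 2])
    return sig, series, segs, peaks, mag, window


DEFAULT_CONFIG = {
    "highpass_cutoff_hz": 0.5,
    "target_fs_hz": 50.0,
    "peaks_min_distance_s": 0.25,
    "peaks_min_prominence": None,
    "axis_selection": "auto",
}


def compute_metric_set(
    rec: ImuRecording,
    window: Optional[Tuple[float, float]] = None,
    config: Optional[dict] = None,
) -> MetricSet:
    """Run the task-specific processing chain and fill every metric field.

    FS uses the accelerometer path (frame transform, gravity compensation,
    high-pass, ZUPT double integration on the global vertical axis); HPS
    uses the gyroscope path (frame transform, high-pass, single
    integration on the dominant rotation axis).
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if rec.task == "FS":
        sig, series, segs, peaks, mag, window = _fs_chain(rec, window, cfg)
    elif rec.task == "HPS":
        sig, series, segs, peaks, mag, window = _hps_chain(rec, window, cfg)
    else:
        raise ValueError(f"unknown task {rec.task!r}")

    duration = window[1] - window[0]
    peak_times = [s.t_peak for s in segs]
    mean_interval, n_halts = (
        intervals_and_halts(peak_times) if len(peak_times) >= 2 else (math.nan, 0)
    )
    delta_a, slope = (
        decrement(segs) if len(segs) >= 2 else (math.nan, math.nan)
    )
    speed = np.abs(series.velocity)
    common = dict(
        task=rec.task,
        rate_per_s=rate(len(peaks), duration),
        mean_peak_velocity=mean_peak(segs),
        mean_amplitude=mean_amplitude(segs),
        total_displacement=total_displacement(series.displacement),
        sparc=sparc(speed, sig.fs),
        log_dimensionless_jerk=log_dimensionless_jerk(series.velocity, sig.fs),
        n_halts=n_halts,
        mean_interval_s=mean_interval,
        amplitude_change=delta_a,
        amplitude_slope=slope,
        n_movements=len(segs),
    )
    if rec.task == "FS":
        return MetricSet(acceleration_magnitude_mean=float(np.mean(mag)), **common)
    return MetricSet(angular_velocity_magnitude_mean=float(np.mean(mag)), **common)
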