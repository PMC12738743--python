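"""Synthetic IMU and LFP generators with closed-form ground truth.

Every generator draws its randomness from one explicit seed through a
``numpy.random.Generator``; with the seed fixed the output is
bit-reproducible.

Stomp pulses use a compactly supported C^2 stroke: vertical displacement
d(t) = h * sin^4(pi * t / Tp) on [0, Tp], so velocity and acceleration
are analytic, velocity vanishes at both pulse edges, the displacement
peak equals the scheduled step height h, and the peak velocity is
h/Tp * (3*sqrt(3)/4)*pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .imu import G_MPS2, ImuRecording
from .lfp import LfpSession, feedback_band
from .protocol import SessionProtocol

__all__ = [
    "FsGroundTruth",
    "HpsGroundTruth",
    "LfpGroundTruth",
    "gen_fs_recording",
    "gen_hps_recording",
    "gen_lfp_session",
    "gen_paired_cohort",
    "PULSE_PEAK_VEL_COEF",
]

# max of d/dtau sin^4(pi tau) = 4 pi sin^3 cos at tau = 1/3
PULSE_PEAK_VEL_COEF = 3.0 * np.sqrt(3.0) / 4.0 * np.pi


@dataclass(frozen=True)
class FsGroundTruth:
    """Scheduled truth for a foot-stomping recording."""

    step_times: np.ndarray       # s, pulse centres, strictly increasing
    step_heights: np.ndarray     # m
    peak_velocities: np.ndarray  # m/s
    injected_halt_indices: Tuple[int, ...]
    decrement_slope: float       # m per second of amplitude drift
    n_steps: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.step_times) <= 0):
            raise ValueError("step_times must be strictly increasing")
        if not (len(self.step_times) == len(self.step_heights)
                == len(self.peak_velocities) == self.n_steps):
            raise ValueError("per-step lists must have length n_steps")
        if np.any(self.step_heights <= 0):
            raise ValueError("step heights must be positive")

    @property
    def rate_hz(self) -> float:
        return (self.n_steps - 1) / (self.step_times[-1] - self.step_times[0])


@dataclass(frozen=True)
class HpsGroundTruth:
    """Scheduled truth for a hand pronation-supination recording."""

    turn_times: np.ndarray             # s, pulse centres
    turn_amplitudes: np.ndarray        # signed degrees, alternating
    peak_angular_velocities: np.ndarray  # deg/s
    n_turns: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.turn_times) <= 0):
            raise ValueError("turn_times must be strictly increasing")
        signs = np.sign(self.turn_amplitudes)
        if np.any(signs[:-1] * signs[1:] >= 0):
            raise ValueError("turn amplitudes must alternate in sign")


@dataclass(frozen=True)
class LfpGroundTruth:
    """Generating parameters of a synthetic LFP session."""

    beta_peak_hz: float
    modulation_by_segment: Dict[str, float]
    background_exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (13.0 <= self.beta_peak_hz <= 30.0):
            raise ValueError("beta_peak_hz must lie in [13, 30]")
        if any(v <= 0 for v in self.modulation_by_segment.values()):
            raise ValueError("modulation factors must be positive")


def _orientation_quats(t: np.ndarray, tilt_deg: float, drift_dps: float) -> Tuple[np.ndarray, Rotation]:
    """Scalar-first quats for a fixed tilt about x plus slow drift about z."""
    tilt = Rotation.from_euler("x", tilt_deg, degrees=True)
    drift = Rotation.from_euler("z", (drift_dps * t)[:, None], degrees=True)
    rot = drift * tilt  # sensor -> global
    return rot.as_quat(scalar_first=True), rot


def _pulse_profiles(
    t: np.ndarray, centres: np.ndarray, scales: np.ndarray, pulse_dur: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum of sin^4 pulses: displacement, velocity, acceleration arrays."""
    disp = np.zeros_like(t)
    vel = np.zeros_like(t)
    acc = np.zeros_like(t)
    for c, h in zip(centres, scales):
        tau = (t - (c - pulse_dur / 2.0)) / pulse_dur
        m = (tau >= 0.0) & (tau <= 1.0)
        s = np.sin(np.pi * tau[m])
        co = np.cos(np.pi * tau[m])
        disp[m] += h * s ** 4
        vel[m] += h * 4.0 * np.pi * s ** 3 * co / pulse_dur
        acc[m] += h * 4.0 * np.pi ** 2 * s ** 2 * (4.0 * co ** 2 - 1.0) / pulse_dur ** 2
    return disp, vel, acc


def gen_fs_recording(
    n_steps: int = 10,
    rate_hz: float = 1.5,
    base_height: float = 0.12,
    decrement_slope: float = 0.0,
    halt_spec: Optional[Dict[int, float]] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    fs: float = 200.0,
    pulse_duration: Optional[float] = None,
    tilt_deg: float = 15.0,
    drift_dps: float = 0.0,
    side: str = "right",
) -> Tuple[ImuRecording, FsGroundTruth]:
    """Generate a seated foot-stomping recording plus its ground truth.

    ``halt_spec`` maps inter-step interval indices (0-based, interval i is
    between steps i and i+1) to multiplicative stretch factors.
    ``decrement_slope`` shifts step heights linearly in time (m/s).
    Gaussian noise of ``noise_sd`` m/s^2 is added to the sensor-frame
    acceleration.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    halt_spec = dict(halt_spec or {})
    for idx in halt_spec:
        if idx < 0 or idx >= n_steps - 1:
            raise ValueError(
                f"halt_spec interval index {idx} out of range for {n_steps} steps"
            )
    rng = np.random.default_rng(seed)

    intervals = np.full(max(n_steps - 1, 0), 1.0 / rate_hz)
    for idx, factor in halt_spec.items():
        intervals[idx] *= factor
    margin = 1.0
    step_times = margin + np.concatenate(([0.0], np.cumsum(intervals)))
    heights = base_height + decrement_slope * (step_times - step_times[0])
    if np.any(heights <= 0):
        raise ValueError("decrement_slope drives step heights non-positive")
    pulse_dur = pulse_duration or min(0.3, 0.5 / rate_hz)

    duration = step_times[-1] + pulse_dur / 2.0 + margin
    t = np.arange(int(round(duration * fs))) / fs
    _, _, acc_z = _pulse_profiles(t, step_times, heights, pulse_dur)

    a_global = np.zeros((len(t), 3))
    a_global[:, 2] = acc_z
    quat, rot = _orientation_quats(t, tilt_deg, drift_dps)
    specific_force = a_global + np.array([0.0, 0.0, G_MPS2])
    f_sensor = rot.apply(specific_force, inverse=True)
    accel_g = f_sensor / G_MPS2 + rng.normal(0.0, noise_sd / G_MPS2, (len(t), 3))
    gyro = rng.normal(0.0, 0.1, (len(t), 3))

    rec = ImuRecording(t=t, accel=accel_g, gyro=gyro, quat=quat, fs=fs,
                       placement="ankle", task="FS", side=side)
    truth = FsGroundTruth(
        step_times=step_times,
        step_heights=heights,
        peak_velocities=PULSE_PEAK_VEL_COEF * heights / pulse_dur,
        injected_halt_indices=tuple(sorted(halt_spec)),
        decrement_slope=decrement_slope,
        n_steps=n_steps,
    )
    return rec, truth


def gen_hps_recording(
    n_turns: int = 10,
    rate_hz: float = 1.5,
    amplitude_deg: float = 160.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    fs: float = 200.0,
    tilt_deg: float = 10.0,
) -> Tuple[ImuRecording, HpsGroundTruth]:
    """Generate alternating wrist-rotation gyro pulses plus ground truth.

    Each pulse is omega(t) = +/- (2A/Tp) sin^2(pi t/Tp), whose integral is
    exactly +/- ``amplitude_deg``.
    """
    if n_turns < 1:
        raise ValueError("n_turns must be >= 1")
    if rate_hz <= 0 or amplitude_deg <= 0:
        raise ValueError("rate_hz and amplitude_deg must be positive")
    rng = np.random.default_rng(seed)

    margin = 1.0
    period = 1.0 / rate_hz
    pulse_dur = 0.7 * period
    centres = margin + np.arange(n_turns) * period
    signs = (-1.0) ** np.arange(n_turns)
    duration = centres[-1] + pulse_dur / 2.0 + margin
    t = np.arange(int(round(duration * fs))) / fs

    omega = np.zeros_like(t)
    for c, sgn in zip(centres, signs):
        tau = (t - (c - pulse_dur / 2.0)) / pulse_dur
        m = (tau >= 0.0) & (tau <= 1.0)
        omega[m] += sgn * (2.0 * amplitude_deg / pulse_dur) * np.sin(np.pi * tau[m]) ** 2

    quat, rot = _orientation_quats(t, tilt_deg, 0.0)
    omega_global = np.zeros((len(t), 3))
    omega_global[:, 0] = omega
    gyro = rot.apply(omega_global, inverse=True)
    gyro = gyro + rng.normal(0.0, noise_sd, (len(t), 3))
    accel_g = rot.apply(np.tile([0.0, 0.0, G_MPS2], (len(t), 1)), inverse=True) / G_MPS2
    accel_g = accel_g + rng.normal(0.0, 0.005, (len(t), 3))

    rec = ImuRecording(t=t, accel=accel_g, gyro=gyro, quat=quat, fs=fs,
                       placement="wrist", task="HPS")
    truth = HpsGroundTruth(
        turn_times=centres,
        turn_amplitudes=signs * amplitude_deg,
        peak_angular_velocities=np.full(n_turns, 2.0 * amplitude_deg / pulse_dur),
        n_turns=n_turns,
    )
    return rec, truth


def _one_over_f_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std() * sd


def gen_lfp_session(
    protocol: SessionProtocol,
    truth: LfpGroundTruth,
    fs_raw: float = 250.0,
    seed: int = 0,
    base_beta_amp: float = 1.0,
    background_sd: float = 0.5,
    power_window_s: float = 6.0,
) -> LfpSession:
    """Generate a raw LFP channel and its 2 Hz band-power stream.

    The raw channel is a 1/f^exponent Gaussian background plus a beta
    sinusoid whose amplitude in each protocol segment is
    ``base_beta_amp`` times the segment's modulation factor. The band
    power is the trailing ``power_window_s`` mean of the squared signal
    band-passed to the feedback band, emitted every 0.5 s.
    """
    low, high = feedback_band(truth.beta_peak_hz)
    if high >= fs_raw / 2.0:
        raise ValueError(
            f"feedback band upper edge {high} Hz exceeds Nyquist {fs_raw / 2} Hz"
        )
    rng = np.random.default_rng(seed)
    windows = protocol.windows()
    duration = protocol.duration
    n = int(round(duration * fs_raw))
    t = np.arange(n) / fs_raw

    amp = np.full(n, base_beta_amp)
    for label, t0, t1 in windows:
        factor = truth.modulation_by_segment.get(label, 1.0)
        amp[(t >= t0) & (t < t1)] = base_beta_amp * factor
    phase = rng.uniform(0.0, 2.0 * np.pi)
    raw = amp * np.sin(2.0 * np.pi * truth.beta_peak_hz * t + phase)
    raw = raw + _one_over_f_noise(n, truth.background_exponent, background_sd, rng)

    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs_raw, output="sos")
    inst_power = sps.sosfiltfilt(sos, raw) ** 2
    step = 0.5
    # sample k (timestamp k*step) summarizes the trailing window ending at
    # (k+1)*step, so every sample lies inside a half-open protocol segment
    bp_t = np.arange(int(round(duration / step))) * step
    win_n = int(round(power_window_s * fs_raw))
    csum = np.concatenate(([0.0], np.cumsum(inst_power)))
    bp = np.empty(len(bp_t))
    for i, tt in enumerate(bp_t):
        hi = min(int(round((tt + step) * fs_raw)), n)
        lo = max(hi - win_n, 0)
        bp[i] = (csum[hi] - csum[lo]) / (hi - lo)

    segments = tuple((lab, t0, t1) for lab, t0, t1 in windows)
    return LfpSession(beta_peak_hz=truth.beta_peak_hz, band_power_t=bp_t,
                      band_power=bp, segments=segments, raw=raw, fs_raw=fs_raw)


def gen_paired_cohort(
    n_subjects: int, true_smd: float, sd: float = 1.0, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired pre/post cohort with a known paired standardized mean
    difference: pre ~ N(0, sd), post = pre + N(true_smd * sd, sd)."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    pre = rng.normal(0.0, sd, n_subjects)
    diff = rng.normal(true_smd * sd, sd, n_subjects)
    return pre, pre + diff
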