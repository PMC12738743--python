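"""IMU preprocessing: frame transformation, gravity compensation, filtering,
resampling, and active-movement segmentation.

Conventions
-----------
* Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and encode the
  *active* rotation taking sensor-frame vectors into the global frame.
* On-disk units are ``g`` for acceleration and ``deg/s`` for angular
  velocity; SI units (m/s^2) appear only after :func:`gravity_compensate`.
* All operations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

G_MPS2 = 9.81  # gravity constant used for unit conversion and compensation

__all__ = [
    "ImuRecording",
    "MovementSignal",
    "to_global_frame",
    "gravity_compensate",
    "highpass",
    "downsample",
    "segment_task",
    "component",
    "crop",
]


@dataclass(frozen=True)
class ImuRecording:
    """Fixed-rate triaxial IMU recording with orientation quaternions.

    Attributes
    ----------
    t : (N,) array of seconds on a uniform grid.
    accel : (N, 3) array in g.
    gyro : (N, 3) array in deg/s.
    quat : (N, 4) array, scalar-first unit quaternions (sensor -> global).
    fs : sampling rate in Hz (nominal 200).
    placement : ``"ankle"`` or ``"wrist"``.
    task : ``"FS"`` or ``"HPS"``.
    side : ``"left"`` or ``"right"``.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray
    fs: float
    placement: str = "ankle"
    task: str = "FS"
    side: str = "right"

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("accel", "gyro"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        if self.quat.shape != (n, 4):
            raise ValueError(f"quat must have shape ({n}, 4)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            idx = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(f"quaternion norm deviates from 1 at sample {idx}")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class MovementSignal:
    """A processed time series (scalar or 3-vector) tagged with frame/units."""

    t: np.ndarray
    value: np.ndarray
    fs: float
    frame: str  # "sensor" | "global"
    units: str  # "g" | "m/s^2" | "dps"

    def __post_init__(self) -> None:
        if len(self.t) != len(self.value):
            raise ValueError("t and value must have equal length")
        if np.any(~np.isfinite(np.asarray(self.value, dtype=float))):
            raise ValueError("signal contains non-finite values")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` by scalar-first quaternions ``q`` (row-wise).

    Uses v' = v + 2 w (u x v) + 2 u x (u x v) with u the vector part,
    which avoids building rotation matrices.
    """
    w = q[:, :1]
    u = q[:, 1:]
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def to_global_frame(rec: ImuRecording, source: str = "accel") -> MovementSignal:
    """Rotate the ``accel`` (or ``gyro``) stream into the global frame.

    Each sample is rotated by its own orientation quaternion. Units are
    unchanged (g for accel, deg/s for gyro).
    """
    norms = np.linalg.norm(rec.quat, axis=1)
    bad = np.nonzero(np.abs(norms - 1.0) > 1e-2)[0]
    if bad.size:
        raise ValueError(f"quaternion norm deviates by > 1e-2 at sample {bad[0]}")
    q = rec.quat / norms[:, None]
    if source == "accel":
        v, units = rec.accel, "g"
    elif source == "gyro":
        v, units = rec.gyro, "dps"
    else:
        raise ValueError("source must be 'accel' or 'gyro'")
    return MovementSignal(t=rec.t, value=_quat_rotate(q, v), fs=rec.fs,
                          frame="global", units=units)


def gravity_compensate(sig: MovementSignal) -> MovementSignal:
    """Convert g -> m/s^2 and subtract gravity from the global z-axis."""
    if sig.frame != "global":
        raise ValueError("gravity compensation requires a global-frame signal")
    if sig.units != "g":
        raise ValueError("gravity compensation expects input in g")
    if sig.value.ndim != 2 or sig.value.shape[1] != 3:
        raise ValueError("expected a 3-vector series")
    out = sig.value * G_MPS2
    out = out.copy()
    out[:, 2] -= G_MPS2
    return replace(sig, value=out, units="m/s^2")


def highpass(sig: MovementSignal, cutoff: float = 0.5) -> MovementSignal:
    """Zero-phase 4th-order Butterworth high-pass filter.

    Only the 0.5 Hz cutoff is part of the processing contract; the
    forward-backward Butterworth realization is a documented choice that
    preserves peak timing.
    """
    nyq = sig.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(4, cutoff, btype="highpass", fs=sig.fs, output="sos")
    out = sps.sosfiltfilt(sos, sig.value, axis=0)
    return replace(sig, value=out)


def downsample(sig: MovementSignal, target_fs: float = 50.0) -> MovementSignal:
    """Anti-alias filter and resample to ``target_fs`` (polyphase)."""
    if target_fs > sig.fs:
        raise ValueError("target_fs must not exceed the source rate")
    if np.isclose(target_fs, sig.fs):
        return sig
    from fractions import Fraction

    frac = Fraction(target_fs / sig.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(sig.value, up, down, axis=0, padtype="line")
    t = sig.t[0] + np.arange(len(out)) / target_fs
    return replace(sig, t=t, value=out, fs=target_fs)


def _envelope(x: np.ndarray, fs: float, window_s: float = 0.25) -> np.ndarray:
    """Moving-RMS envelope of a (possibly multi-axis) signal."""
    if x.ndim == 2:
        power = np.sum(x.astype(float) ** 2, axis=1)
    else:
        power = x.astype(float) ** 2
    n = max(int(round(window_s * fs)), 1)
    kernel = np.ones(n) / n
    return np.sqrt(np.convolve(power, kernel, mode="same"))


def segment_task(
    sig: MovementSignal,
    protocol_hint: Optional[Tuple[float, float]] = None,
    threshold_factor: float = 5.0,
    pad_s: float = 0.15,
) -> Tuple[float, float]:
    """Locate the active-movement window.

    With ``protocol_hint`` (manual mode) the hint is returned verbatim.
    Otherwise the envelope (moving RMS, 250 ms) is thresholded at
    ``threshold_factor`` times the median envelope of the first 0.5 s,
    and the smallest window containing all supra-threshold samples,
    padded by ``pad_s``, is returned.
    """
    if protocol_hint is not None:
        return (float(protocol_hint[0]), float(protocol_hint[1]))
    if sig.duration < 1.0:
        raise ValueError("signal shorter than 1 s")
    env = _envelope(np.asarray(sig.value), sig.fs)
    n_ref = max(int(round(0.5 * sig.fs)), 1)
    thr = threshold_factor * np.median(env[:n_ref])
    active = np.nonzero(env > thr)[0]
    if active.size == 0:
        raise ValueError("no active movement detected")
    t0 = max(float(sig.t[active[0]]) - pad_s, float(sig.t[0]))
    t1 = min(float(sig.t[active[-1]]) + pad_s, float(sig.t[-1]))
    return (t0, t1)


def crop(sig: MovementSignal, window: Tuple[float, float]) -> MovementSignal:
    """Restrict a signal to a half-open time window [start, end)."""
    mask = (sig.t >= window[0]) & (sig.t < window[1])
    if not np.any(mask):
        raise ValueError("window contains no samples")
    return replace(sig, t=sig.t[mask], value=sig.value[mask])


def component(sig: MovementSignal, axis: int) -> MovementSignal:
    """Extract one axis of a 3-vector signal as a scalar signal."""
    if sig.value.ndim != 2:
        raise ValueError("signal is already scalar")
    return replace(sig, value=sig.value[:, axis])
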