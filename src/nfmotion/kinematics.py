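"""Peak-anchored integration with zero-velocity updates and per-movement
segmentation.

The drift-control strategy: velocity is integrated per inter-peak segment
and linearly detrended so that it is exactly zero at both segment
boundaries (the limb is at rest between repetitions of a cyclic task).
Displacement is re-integrated from the corrected velocity and reset to
zero at each segment start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .imu import MovementSignal

__all__ = [
    "MovementSegment",
    "KinematicSeries",
    "detect_peaks",
    "segment_bounds",
    "integrate_zupt",
    "angular_displacement",
    "build_segments",
    "select_axis",
]


@dataclass(frozen=True)
class MovementSegment:
    """One movement repetition (a stomp or a wrist turn)."""

    index: int
    t_start: float
    t_peak: float
    t_end: float
    peak_speed: float  # m/s (FS) or deg/s (HPS)
    amplitude: float   # m (FS vertical excursion) or signed degrees (HPS)


@dataclass(frozen=True)
class KinematicSeries:
    """Velocity and displacement derived from a movement signal window."""

    t: np.ndarray
    velocity: np.ndarray
    displacement: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.velocity) == len(self.displacement)):
            raise ValueError("t, velocity, displacement must share length")


def detect_peaks(
    sig: MovementSignal,
    min_distance: float = 0.25,
    min_prominence: Optional[float] = None,
) -> np.ndarray:
    """Find local maxima of ``|signal|`` subject to distance/prominence.

    Default prominence is 2x the median absolute deviation of the signal
    with a floor of 2% of its maximum (guards against low-amplitude noise
    bumps in rest gaps), a conservative and tunable stand-in for visual
    verification. An empty result is a valid return.
    """
    x = np.abs(np.asarray(sig.value, dtype=float))
    if x.ndim != 1:
        raise ValueError("peak detection requires a 1-D signal")
    if min_prominence is None:
        mad = np.median(np.abs(x - np.median(x)))
        min_prominence = max(2.0 * mad, 0.02 * x.max())
        if min_prominence == 0.0:
            min_prominence = 1e-6
    distance = max(int(round(min_distance * sig.fs)), 1)
    peaks, _ = find_peaks(x, distance=distance, prominence=min_prominence)
    return peaks


def segment_bounds(n_samples: int, peaks: Sequence[int]) -> List[tuple]:
    """Inter-peak midpoint boundaries; first/last extended to window edges."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("at least one peak required")
    mids = ((peaks[:-1] + peaks[1:]) // 2).tolist()
    starts = [0] + mids
    ends = mids + [n_samples - 1]
    return list(zip(starts, ends))


def integrate_zupt(sig: MovementSignal, peaks: Sequence[int]) -> KinematicSeries:
    """Double integration with per-segment zero-velocity updates.

    Within each inter-peak segment the cumulative trapezoidal integral of
    acceleration is linearly detrended so velocity is exactly zero at both
    boundaries, then integrated again for displacement (reset to zero at
    each segment start).
    """
    a = np.asarray(sig.value, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a scalar acceleration signal")
    n = len(a)
    dt = 1.0 / sig.fs
    velocity = np.zeros(n)
    displacement = np.zeros(n)
    for k, (i0, i1) in enumerate(segment_bounds(n, peaks)):
        if i1 - i0 + 1 < 3:
            raise ValueError(f"segment {k} shorter than 3 samples")
        seg = a[i0 : i1 + 1]
        v = cumulative_trapezoid(seg, dx=dt, initial=0.0)
        # boundary-anchored linear detrend: v[0] is already 0, remove the
        # ramp that would leave a residual at the segment end
        ramp = np.linspace(0.0, v[-1], len(v))
        v -= ramp
        d = cumulative_trapezoid(v, dx=dt, initial=0.0)
        velocity[i0 : i1 + 1] = v
        displacement[i0 : i1 + 1] = d
    return KinematicSeries(t=sig.t, velocity=velocity,
                           displacement=displacement, fs=sig.fs)


def angular_displacement(sig: MovementSignal) -> KinematicSeries:
    """Single trapezoidal integration of angular velocity; no drift update."""
    w = np.asarray(sig.value, dtype=float)
    if w.ndim != 1:
        raise ValueError("expected a scalar angular-velocity signal")
    theta = cumulative_trapezoid(w, dx=1.0 / sig.fs, initial=0.0)
    return KinematicSeries(t=sig.t, velocity=w, displacement=theta, fs=sig.fs)


def build_segments(
    series: KinematicSeries,
    peaks: Sequence[int],
    amplitude_mode: str = "excursion",
) -> List[MovementSegment]:
    """Materialize one :class:`MovementSegment` per detected peak.

    ``amplitude_mode="excursion"`` (FS): amplitude = max displacement in
    the segment minus displacement at the segment start.
    ``amplitude_mode="signed"`` (HPS): amplitude = displacement at segment
    end minus at segment start (signed turn angle between reversals).
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("peaks must be non-empty")
    if amplitude_mode not in ("excursion", "signed"):
        raise ValueError("amplitude_mode must be 'excursion' or 'signed'")
    out: List[MovementSegment] = []
    for k, ((i0, i1), p) in enumerate(
        zip(segment_bounds(len(series.t), peaks), peaks)
    ):
        vel = series.velocity[i0 : i1 + 1]
        disp = series.displacement[i0 : i1 + 1]
        if amplitude_mode == "excursion":
            amp = float(np.max(disp) - disp[0])
        else:
            amp = float(disp[-1] - disp[0])
        out.append(
            MovementSegment(
                index=k,
                t_start=float(series.t[i0]),
                t_peak=float(series.t[p]),
                t_end=float(series.t[i1]),
                peak_speed=float(np.max(np.abs(vel))),
                amplitude=amp,
            )
        )
    return out


def select_axis(value: np.ndarray, selection: str = "auto") -> int:
    """Pick the movement axis: highest variance (auto) or explicit x/y/z."""
    if selection == "auto":
        return int(np.argmax(np.var(np.asarray(value, dtype=float), axis=0)))
    try:
        return {"x": 0, "y": 1, "z": 2}[selection]
    except KeyError:
        raise ValueError("axis selection must be 'auto', 'x', 'y' or 'z'")
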