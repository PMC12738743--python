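"""Subthalamic beta-band power analysis.

Covers the 2 Hz band-power stream (power in a 5 Hz band centred on the
individual beta-peak), per-block median normalization against the block's
initial rest period, block summaries, spectral validation of the
configured beta-peak, a complex-Morlet time-frequency representation,
responder classification, and pre/post change scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "LfpSession",
    "BlockSummary",
    "SpectrumResult",
    "feedback_band",
    "normalize_block",
    "normalize_session",
    "block_summaries",
    "spectrum_and_peak",
    "tfr_morlet",
    "classify_responder",
    "beta_change",
    "segment_values",
]

BETA_HALF_BAND_HZ = 2.5  # feedback band = beta-peak +/- 2.5 Hz


@dataclass(frozen=True)
class LfpSession:
    """One recording session of band-power (2 Hz) plus optional raw LFP.

    ``segments`` are half-open labelled windows ``(label, t_start, t_end)``
    with labels of the form ``"<block>_<phase>"``; ``"<block>_rest"`` is
    the block's normalization baseline.
    """

    beta_peak_hz: float
    band_power_t: np.ndarray
    band_power: np.ndarray
    segments: Tuple[Tuple[str, float, float], ...]
    raw: Optional[np.ndarray] = None
    fs_raw: Optional[float] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.band_power_t) != len(self.band_power):
            raise ValueError("band_power_t and band_power must share length")
        ivals = sorted((t0, t1) for _, t0, t1 in self.segments)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1 - 1e-9:
                raise ValueError("segments overlap")

    @property
    def band(self) -> Tuple[float, float]:
        return feedback_band(self.beta_peak_hz)

    def segment_window(self, label: str) -> Tuple[float, float]:
        for lab, t0, t1 in self.segments:
            if lab == label:
                return (t0, t1)
        raise KeyError(f"no segment labelled {label!r}")

    @property
    def blocks(self) -> List[str]:
        seen: List[str] = []
        for lab, _, _ in self.segments:
            b = lab.rsplit("_", 1)[0]
            if b not in seen:
                seen.append(b)
        return seen


@dataclass(frozen=True)
class BlockSummary:
    label: str
    median_normalized_power: float

    @property
    def pct_change_vs_baseline(self) -> float:
        return (self.median_normalized_power - 1.0) * 100.0


@dataclass(frozen=True)
class SpectrumResult:
    freqs: np.ndarray
    power: np.ndarray
    estimated_peak_hz: float
    offset_vs_configured_hz: Optional[float]
    low_confidence: bool


def feedback_band(beta_peak_hz: float) -> Tuple[float, float]:
    """The 5 Hz feedback band: (peak - 2.5, peak + 2.5) Hz.

    Peaks outside the canonical 13-30 Hz beta range trigger a warning but
    are accepted (the device allows them).
    """
    if not (13.0 <= beta_peak_hz <= 30.0):
        warnings.warn(
            f"beta-peak {beta_peak_hz} Hz outside the 13-30 Hz beta range",
            stacklevel=2,
        )
    return (beta_peak_hz - BETA_HALF_BAND_HZ, beta_peak_hz + BETA_HALF_BAND_HZ)


def segment_values(session: LfpSession, label: str) -> np.ndarray:
    """Band-power samples falling in a labelled half-open window."""
    t0, t1 = session.segment_window(label)
    mask = (session.band_power_t >= t0) & (session.band_power_t < t1)
    return session.band_power[mask]


def normalize_block(power: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Divide a power series by the median of its baseline-rest samples."""
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    med = float(np.median(baseline))
    if med == 0.0:
        raise ValueError("zero median in baseline window")
    return np.asarray(power, dtype=float) / med


def normalize_session(session: LfpSession) -> LfpSession:
    """Normalize each block by the median of its initial rest segment."""
    out = session.band_power.astype(float).copy()
    for block in session.blocks:
        rest_label = f"{block}_rest"
        try:
            rest = segment_values(session, rest_label)
        except KeyError:
            warnings.warn(f"block {block!r} has no rest segment; left unscaled")
            continue
        labels = [lab for lab, _, _ in session.segments
                  if lab.rsplit("_", 1)[0] == block]
        mask = np.zeros(len(out), dtype=bool)
        for lab in labels:
            t0, t1 = session.segment_window(lab)
            mask |= (session.band_power_t >= t0) & (session.band_power_t < t1)
        out[mask] = normalize_block(out[mask], rest)
    return replace(session, band_power=out, normalized=True)


def block_summaries(session: LfpSession) -> List[BlockSummary]:
    """Per-segment median normalized power and % change vs baseline."""
    if not session.normalized:
        session = normalize_session(session)
    out = []
    for lab, _, _ in session.segments:
        vals = segment_values(session, lab)
        if vals.size == 0:
            warnings.warn(f"segment {lab!r} contains no samples; omitted")
            continue
        out.append(BlockSummary(label=lab, median_normalized_power=float(np.median(vals))))
    return out


def spectrum_and_peak(
    raw: np.ndarray,
    fs_raw: float,
    configured_peak_hz: Optional[float] = None,
    prominence_ratio: float = 2.0,
) -> SpectrumResult:
    """Welch spectrum and beta-peak estimate (argmax in 13-30 Hz).

    Welch parameters: 2 s Hann segments, 50 % overlap. The estimate is
    flagged low-confidence when the in-band peak is less than
    ``prominence_ratio`` times the in-band median power.
    """
    if raw is None:
        raise ValueError("raw channel absent")
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 0 or raw.size == 0:
        raise ValueError("raw channel absent")
    if len(raw) < 10 * fs_raw:
        raise ValueError("need at least 10 s of raw signal")
    nperseg = int(2 * fs_raw)
    f, pxx = sps.welch(raw, fs=fs_raw, nperseg=nperseg, noverlap=nperseg // 2,
                       window="hann")
    band = (f >= 13.0) & (f <= 30.0)
    fb, pb = f[band], pxx[band]
    est = float(fb[np.argmax(pb)])
    low_conf = bool(np.max(pb) < prominence_ratio * np.median(pb))
    offset = None if configured_peak_hz is None else float(configured_peak_hz - est)
    return SpectrumResult(freqs=f, power=pxx, estimated_peak_hz=est,
                          offset_vs_configured_hz=offset, low_confidence=low_conf)


def _morlet_kernel(freq: float, fs: float, bandwidth: float, center: float) -> np.ndarray:
    """Complex Morlet wavelet sampled for one analysis frequency.

    The mother wavelet is (pi*B)^(-1/2) exp(-t^2/B) exp(2i*pi*C*t); at
    scale s = C/f its instantaneous frequency is f. L1 normalization so a
    unit sinusoid yields a scale-independent ridge magnitude.
    """
    s = center / freq  # seconds
    sd_t = s * np.sqrt(bandwidth / 2.0)
    half = max(int(np.ceil(5.0 * sd_t * fs)), 1)
    t = np.arange(-half, half + 1) / fs
    psi = (np.pi * bandwidth) ** -0.5 * np.exp(-((t / s) ** 2) / bandwidth) \
        * np.exp(2j * np.pi * freq * t)
    return psi / (s * fs)


def tfr_morlet(
    raw: np.ndarray,
    fs_raw: float,
    freqs: Sequence[float],
    bandwidth: float = 0.5,
    center: float = 5.0,
    smooth: bool = True,
    sg_window: int = 21,
    sg_order: int = 3,
) -> np.ndarray:
    """Complex-Morlet time-frequency power matrix (freqs x time).

    Wavelet family cmor with bandwidth 0.5 and centre frequency 5.0;
    power is the squared transform magnitude, optionally smoothed along
    time with a Savitzky-Golay filter (window 21 samples, order 3 - the
    stated length 20 is even, which the filter definition rejects, so the
    nearest odd length is used).
    """
    raw = np.asarray(raw, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs_raw / 2):
        raise ValueError("analysis frequencies must lie in (0, Nyquist)")
    power = np.empty((len(freqs), len(raw)))
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(float(f), fs_raw, bandwidth, center)
        w = sps.fftconvolve(raw.astype(complex), kern, mode="same")
        power[i] = np.abs(w) ** 2
    if smooth and len(raw) > sg_window:
        power = sps.savgol_filter(power, sg_window, sg_order, axis=1)
    return power


def classify_responder(session: LfpSession) -> str:
    """``"responder"`` iff the third training block's downregulation phase
    has median normalized power strictly below 1.0 (ties are
    non-responders)."""
    if not session.normalized:
        session = normalize_session(session)
    try:
        vals = segment_values(session, "nf3_down")
    except KeyError:
        raise ValueError("third neurofeedback training block missing")
    if vals.size == 0:
        raise ValueError("third neurofeedback training block empty")
    return "responder" if float(np.median(vals)) < 1.0 else "non_responder"


def beta_change(pre: np.ndarray, post: np.ndarray) -> float:
    """Delta-beta = median(pre) - median(post); larger = more reduction."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("empty segment")
    return float(np.median(pre) - np.median(post))
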