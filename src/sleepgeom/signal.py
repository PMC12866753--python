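"""Deterministic signal transforms shared by all pipeline stages.

All binning uses a single 0-based, half-open frame convention: frame ``k``
covers ``[k*dt, (k+1)*dt)`` and a frame belongs to a time window ``[t0, t1)``
iff its start time lies inside the window (see :func:`frames_in_window`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class Raster:
    """Neurons x frames non-negative activity matrix with its frame duration."""

    counts: np.ndarray          # (n_neurons, n_frames)
    frame_duration: float       # seconds

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (neurons x frames)")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_duration

    def frame_times(self) -> np.ndarray:
        """Start time of every frame."""
        return np.arange(self.n_frames) * self.frame_duration


@dataclass
class BandPowerTrace:
    values: np.ndarray
    band: tuple[float, float]
    smoothing_window: float
    source_rate: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < self.source_rate / 2):
            raise ValueError("band must satisfy 0 < low < high < rate/2")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("power values must be non-negative")


def frames_in_window(t0: float, t1: float, frame_duration: float, n_frames: int) -> np.ndarray:
    """Indices of frames whose start time lies in the half-open window [t0, t1)."""
    first = int(np.ceil(t0 / frame_duration - 1e-9))
    last = int(np.ceil(t1 / frame_duration - 1e-9))  # exclusive
    first = max(first, 0)
    last = min(last, n_frames)
    if last <= first:
        return np.empty(0, dtype=int)
    return np.arange(first, last)


def neuropil_correct(f_measured: np.ndarray, f_neuropil: np.ndarray, coeff: float = 0.7) -> np.ndarray:
    """Subtract scaled neuropil fluorescence: ``F_measured - coeff * F_neuropil``."""
    f_measured = np.asarray(f_measured, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_measured.shape != f_neuropil.shape:
        raise ValueError("measured and neuropil traces must have the same shape")
    return f_measured - coeff * f_neuropil


def gaussian_kernel(sd: float, frame_duration: float) -> np.ndarray:
    """Unit-area Gaussian kernel sampled at the frame rate, truncated at +-4 SD."""
    if sd <= 0:
        return np.ones(1)
    half = int(np.ceil(4.0 * sd / frame_duration))
    x = np.arange(-half, half + 1) * frame_duration
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def events_to_raster(
    event_times: list[np.ndarray],
    frame_duration: float,
    session_duration: float,
    smooth_sd: float = 0.1,
) -> Raster:
    """Bin per-neuron event times into frames and smooth with a Gaussian kernel.

    Events are counted in half-open frames ``[k*dt, (k+1)*dt)``; the smoothing
    kernel has unit area, so total mass is conserved up to edge truncation.
    """
    if smooth_sd < 0:
        raise ValueError("smooth_sd must be non-negative")
    n_frames = int(np.ceil(session_duration / frame_duration - 1e-9))
    counts = np.zeros((len(event_times), n_frames))
    for i, times in enumerate(event_times):
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            continue
        if np.any(times < 0) or np.any(times >= session_duration):
            raise ValueError("event times must lie within [0, session_duration)")
        idx = np.floor(times / frame_duration).astype(int)
        np.add.at(counts[i], idx, 1.0)
    if smooth_sd > 0:
        kernel = gaussian_kernel(smooth_sd, frame_duration)
        counts = np.apply_along_axis(np.convolve, 1, counts, kernel, mode="same")
        counts = np.clip(counts, 0.0, None)
    return Raster(counts=counts, frame_duration=frame_duration)


def bandpass(x: np.ndarray, rate: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass filter.

    Corner frequencies are widened to compensate the double (forward and
    reverse) application, so the effective -3 dB edges of the overall
    response sit at the stated band limits.
    """
    lo, hi = band
    nyq = rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError("band must lie strictly inside the Nyquist range")
    # |H|^4 = 1/2 at the stated edges -> design bandwidth B / 0.414^(1/2n)
    factor = (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
    f0_sq = lo * hi
    bw = (hi - lo) / factor
    hi_c = (bw + np.sqrt(bw**2 + 4 * f0_sq)) / 2.0
    lo_c = hi_c - bw
    hi_c = min(hi_c, 0.99 * nyq)
    sos = sps.butter(order, [lo_c / nyq, hi_c / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return np.asarray(x, dtype=float)
    if window_samples > len(x):
        raise ValueError("smoothing window longer than signal")
    kernel = np.ones(window_samples) / window_samples
    # reflect-pad so the smoothed trace keeps the input length without edge bias
    pad = window_samples // 2
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="reflect")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]
    return out


def band_power(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float],
    smooth_window: float = 0.0,
    mode: str = "power",
) -> BandPowerTrace:
    """Band-limited instantaneous power (or amplitude) via the analytic signal.

    The signal is zero-phase band-pass filtered, the Hilbert envelope taken,
    and (for ``mode="power"``) squared, then smoothed with a moving average of
    the requested window length.
    """
    if mode not in ("power", "amplitude"):
        raise ValueError("mode must be 'power' or 'amplitude'")
    filtered = bandpass(x, rate, band)
    envelope = np.abs(sps.hilbert(filtered))
    values = envelope**2 if mode == "power" else envelope
    if smooth_window > 0:
        values = moving_average(values, int(round(smooth_window * rate)))
    return BandPowerTrace(
        values=np.clip(values, 0.0, None),
        band=band,
        smoothing_window=smooth_window,
        source_rate=rate,
    )


def window_average(
    x: np.ndarray,
    rate: float,
    window: tuple[float, float],
    normalizer: str = "raw",
) -> float:
    """Mean of a trace over the half-open window [t0, t1).

    ``normalizer="whole"`` first divides the trace by its mean over the whole
    recording (the evoked-potential comparison convention).
    """
    x = np.asarray(x, dtype=float)
    t0, t1 = window
    i0 = int(np.ceil(t0 * rate - 1e-9))
    i1 = int(np.ceil(t1 * rate - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, len(x))
    if i1 <= i0:
        raise ValueError("empty window")
    if normalizer == "whole":
        denom = x.mean()
        if denom == 0:
            raise ValueError("whole-recording mean is zero; cannot normalize")
        x = x / denom
    elif normalizer != "raw":
        raise ValueError("normalizer must be 'raw' or 'whole'")
    return float(x[i0:i1].mean())


def zscore_columns(x: np.ndarray) -> np.ndarray:
    """Z-score each column (neuron) over all rows (frames)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column encountered; cannot z-score")
    return (x - x.mean(axis=0)) / sd
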