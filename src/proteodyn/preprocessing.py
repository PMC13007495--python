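"""Preprocessing applied before metric computation.

Four operators: zero-phase high-pass detrending (0.0001 Hz default) to strip
slow baseline drift, exclusion of the first seconds after each optical
stimulus, running-median baseline separation, and Savitzky-Golay slope
estimation for transient-rate quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording, WindowGrid


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessSpec:
    """Preprocessing parameters.

    highpass_cutoff : Hz, default 1e-4 (removes drift/DC before phase analysis)
    stimulus_exclusion : s removed after each optical pulse, default 10
    median_window : samples for the running-median baseline, default 10000
    savgol_points : odd filter length for slope estimation, default 5
    savgol_order : local polynomial order, default 2
    slope_window : samples per sliding slope window, default 100
    """

    highpass_cutoff: float = 1e-4
    stimulus_exclusion: float = 10.0
    median_window: int = 10000
    savgol_points: int = 5
    savgol_order: int = 2
    slope_window: int = 100

    def __post_init__(self) -> None:
        if self.highpass_cutoff <= 0:
            raise PreprocessError("highpass_cutoff must be > 0")
        if self.savgol_points % 2 == 0 or self.savgol_points <= self.savgol_order:
            raise PreprocessError("savgol_points must be odd and > savgol_order")
        if self.median_window < 1 or self.slope_window < 1:
            raise PreprocessError("windows must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(**d)


def highpass(recording: Recording, cutoff: float = 1e-4) -> Recording:
    """Zero-phase (forward-backward) 2nd-order Butterworth high-pass.

    Applied per channel; removes DC and drift slower than ``cutoff`` without
    phase distortion, which matters downstream where instantaneous phase is
    extracted.
    """
    nyq = recording.sampling_rate / 2.0
    if cutoff >= nyq:
        raise PreprocessError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(2, cutoff / nyq, btype="highpass", output="sos")
    filtered = np.array([signal.sosfiltfilt(sos, ch) for ch in recording.voltages])
    return Recording(
        voltages=filtered,
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
        stimulus_events=recording.stimulus_events,
        units_per_channel=recording.units_per_channel,
        times=recording.times.copy(),
    )


def exclusion_mask(recording: Recording, exclusion: float = 10.0) -> np.ndarray:
    """Boolean mask of retained samples: False inside ``[onset, onset+exclusion)``
    for every stimulus event. Overlapping spans union without double counting;
    an empty event list yields an all-True mask."""
    mask = np.ones(recording.n_samples, dtype=bool)
    fs = recording.sampling_rate
    for onset in recording.stimulus_events:
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.ceil((onset + exclusion) * fs - 1e-9))
        mask[max(i0, 0) : min(i1, recording.n_samples)] = False
    return mask


def exclude_stimulus_transients(
    recording: Recording, exclusion: float = 10.0
) -> tuple[Recording, np.ndarray]:
    """Return the recording unchanged together with the retained-sample mask.

    Masked samples are never imputed: windows overlapping a masked gap are
    dropped wholesale (see :func:`valid_windows`) so all retained windows stay
    statistically comparable.
    """
    return recording, exclusion_mask(recording, exclusion)


def valid_windows(grid: WindowGrid, mask: np.ndarray) -> np.ndarray:
    """Boolean selector of windows fully inside retained (True) samples."""
    keep = np.empty(grid.n_windows, dtype=bool)
    for w, sl in enumerate(grid.slices()):
        keep[w] = bool(np.all(mask[sl]))
    return keep


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with shrinking windows at the edges (no padding)."""
    if window < 1:
        raise PreprocessError("median window must be >= 1")
    if window > len(x):
        raise PreprocessError("median window exceeds signal length")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def median_baseline(
    recording: Recording, window: int = 10000
) -> tuple[Recording, Recording]:
    """Split each channel into a running-median baseline and its residual.

    The baseline captures the slow (nonvolatile) component; the residual
    isolates transients for the fast-regime analysis.
    """
    base = np.array([running_median(ch, window) for ch in recording.voltages])
    def _like(v):
        return Recording(
            voltages=v,
            sampling_rate=recording.sampling_rate,
            channel_labels=recording.channel_labels,
            stimulus_events=recording.stimulus_events,
            units_per_channel=recording.units_per_channel,
            times=recording.times.copy(),
        )
    return _like(base), _like(recording.voltages - base)


def savgol_slope(
    channel: np.ndarray,
    sampling_rate: float,
    savgol_points: int = 5,
    savgol_order: int = 2,
) -> np.ndarray:
    """First derivative (mV/s) via the analytic derivative of the local
    Savitzky-Golay polynomial, scaled by the sampling interval."""
    if len(channel) < savgol_points:
        raise PreprocessError("input shorter than the Savitzky-Golay window")
    return signal.savgol_filter(
        channel, savgol_points, savgol_order, deriv=1, delta=1.0 / sampling_rate
    )


def max_slope(
    channel: np.ndarray,
    sampling_rate: float,
    slope_window: int = 100,
    savgol_points: int = 5,
    savgol_order: int = 2,
) -> float:
    """Maximum absolute slope (mV/s) over all sliding windows.

    The per-window maxima of |dV/dt| are scanned with windows of
    ``slope_window`` samples; their maximum equals the global maximum of the
    smoothed derivative, which is what is returned.
    """
    d = savgol_slope(channel, sampling_rate, savgol_points, savgol_order)
    if len(d) < slope_window:
        slope_window = len(d)
    return float(np.max(np.abs(d)))
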