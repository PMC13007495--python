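"""Core containers for multichannel voltage recordings and sliding-window grids.

A recording is an 8-channel (by default) set of differential voltage traces
sampled at a constant rate. Channels carry millivolt data except for a
possible stimulus-input channel carried in volts, which is flagged so it can
be excluded from mV-domain metrics. Tabular I/O follows the convention of
data-logger text exports: a header row of channel labels, an optional leading
``time`` column, and one numeric column per channel.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_CHANNEL_LABELS = tuple(f"Ch{c}" for c in "ABCDEFGH")

_TIME_STEP_RTOL = 1e-9
_RATE_MISMATCH_RTOL = 1e-3


class RecordingError(ValueError):
    """Raised for invalid recording construction or parsing."""


@dataclass
class Recording:
    """Uniformly sampled multichannel voltage recording.

    Parameters
    ----------
    voltages:
        Array of shape ``(n_channels, n_samples)``. Millivolts unless the
        channel's entry in ``units_per_channel`` is ``"V"``.
    sampling_rate:
        Samples per second (Hz). Required; never inferred silently because
        recordings in this domain exist at both 1 Hz (long spontaneous
        monitoring) and 1 kHz (stimulus-locked acquisition).
    channel_labels:
        One identifier per channel, default ``ChA``..``ChH``.
    stimulus_events:
        Onset times of optical stimuli, in seconds (may be empty).
    units_per_channel:
        ``"mV"`` or ``"V"`` per channel; ``"V"`` marks a stimulus input.
    times:
        Optional explicit time axis; synthesized as ``i / sampling_rate``
        when omitted.
    """

    voltages: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = ()
    stimulus_events: tuple[float, ...] = ()
    units_per_channel: tuple[str, ...] = ()
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages, dtype=float))
        if self.sampling_rate <= 0:
            raise RecordingError("sampling_rate must be positive")
        n_ch, n_s = self.voltages.shape
        if n_ch < 1 or n_s < 1:
            raise RecordingError("recording needs at least one channel and one sample")
        if not self.channel_labels:
            self.channel_labels = tuple(DEFAULT_CHANNEL_LABELS[:n_ch]) if n_ch <= 8 else tuple(
                f"Ch{i}" for i in range(n_ch)
            )
        if len(self.channel_labels) != n_ch:
            raise RecordingError("channel_labels length must match channel count")
        if not self.units_per_channel:
            self.units_per_channel = ("mV",) * n_ch
        if len(self.units_per_channel) != n_ch:
            raise RecordingError("units_per_channel length must match channel count")
        for u in self.units_per_channel:
            if u not in ("mV", "V"):
                raise RecordingError(f"unknown unit {u!r}; expected 'mV' or 'V'")
        if self.times is None:
            self.times = np.arange(n_s) / self.sampling_rate
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (n_s,):
                raise RecordingError("times length must match sample count")
            self._validate_times()
        self.stimulus_events = tuple(float(t) for t in self.stimulus_events)

    def _validate_times(self) -> None:
        dt = np.diff(self.times)
        if len(dt) == 0:
            return
        if np.any(dt <= 0):
            raise RecordingError("time column must be strictly increasing")
        step = 1.0 / self.sampling_rate
        if np.max(np.abs(dt - step)) > _TIME_STEP_RTOL * max(step, 1.0) + _TIME_STEP_RTOL:
            # allow a looser overall-rate check before failing hard
            implied = 1.0 / np.mean(dt)
            if abs(implied - self.sampling_rate) / self.sampling_rate > _RATE_MISMATCH_RTOL:
                raise RecordingError(
                    f"time column implies {implied:.6g} Hz but sampling_rate is "
                    f"{self.sampling_rate:.6g} Hz (>0.1% mismatch)"
                )

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's trace by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"no channel {label!r}") from exc
        return self.voltages[idx]

    def mv_channel_indices(self) -> list[int]:
        """Indices of channels carried in millivolts (metric domain)."""
        return [i for i, u in enumerate(self.units_per_channel) if u == "mV"]

    def select(self, labels: list[str]) -> "Recording":
        """Sub-recording restricted to the given channels, order preserved."""
        idx = [self.channel_labels.index(l) for l in labels]
        return Recording(
            voltages=self.voltages[idx],
            sampling_rate=self.sampling_rate,
            channel_labels=tuple(labels),
            stimulus_events=self.stimulus_events,
            units_per_channel=tuple(self.units_per_channel[i] for i in idx),
            times=self.times.copy(),
        )


@dataclass
class WindowGrid:
    """Sliding-window coordinates: fixed length, fixed step, full windows only."""

    window_length: int
    step: int
    window_starts: np.ndarray

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise RecordingError("window_length must be >= 2")
        if not (1 <= self.step <= self.window_length):
            raise RecordingError("step must satisfy 1 <= step <= window_length")
        self.window_starts = np.asarray(self.window_starts, dtype=int)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def centers(self, sampling_rate: float) -> np.ndarray:
        """Window-center times in seconds."""
        return (self.window_starts + (self.window_length - 1) / 2.0) / sampling_rate

    def slices(self):
        for s in self.window_starts:
            yield slice(int(s), int(s) + self.window_length)


@dataclass
class WindowedMetricTrace:
    """One scalar metric value per analysis window."""

    metric_name: str
    window_centers: np.ndarray
    values: np.ndarray
    channel: str | None = None

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.window_centers.shape != self.values.shape:
            raise RecordingError("window_centers and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise RecordingError("metric values must be finite")


def make_windows(recording: Recording, window_length: int, step: int) -> WindowGrid:
    """Build the sliding-window grid: starts 0, step, 2*step, ...

    Partial trailing windows are dropped so every window holds exactly
    ``window_length`` samples; the count is ``floor((L - N)/step) + 1``.
    """
    L = recording.n_samples
    if window_length > L:
        raise RecordingError(
            f"window_length {window_length} exceeds recording length {L}"
        )
    starts = np.arange(0, L - window_length + 1, step, dtype=int)
    return WindowGrid(window_length=window_length, step=step, window_starts=starts)


def _detect_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_recording(
    path: str | Path,
    sampling_rate: float,
    units_map: dict[str, str] | None = None,
    stimulus_events: tuple[float, ...] = (),
) -> Recording:
    """Read a delimited-text logger export into a :class:`Recording`.

    The file must have a header row; a leading column named ``time`` (case
    insensitive) is used as the time axis and cross-checked against
    ``sampling_rate``, otherwise timestamps are synthesized. Delimiter is
    auto-detected among comma/tab/semicolon. A JSON sidecar written by
    :func:`write_recording` (``<path>.json``) is honoured for units and
    stimulus events unless overridden by the arguments.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = _detect_delimiter(text.splitlines()[0] if text else "")
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    rows = [r for r in reader if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise RecordingError(f"{path}: need a header row and at least one data row")
    header = [h.strip() for h in rows[0]]
    has_time = header[0].lower() in ("time", "time_s", "t", "times")
    labels = header[1:] if has_time else header
    ncols = len(header)
    data = np.empty((len(rows) - 1, ncols), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncols or any(not c.strip() for c in row):
            raise RecordingError(f"{path}: ragged or missing cell on line {i}")
        try:
            data[i - 2] = [float(c) for c in row]
        except ValueError as exc:
            raise RecordingError(f"{path}: non-numeric cell on line {i}") from exc

    times = data[:, 0] if has_time else None
    voltages = (data[:, 1:] if has_time else data).T

    sidecar = path.with_suffix(path.suffix + ".json")
    units = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        units = meta.get("units_per_channel")
        if not stimulus_events:
            stimulus_events = tuple(meta.get("stimulus_events", ()))
    if units_map is not None:
        units = [units_map.get(l, "mV") for l in labels]

    return Recording(
        voltages=voltages,
        sampling_rate=sampling_rate,
        channel_labels=tuple(labels),
        stimulus_events=stimulus_events,
        units_per_channel=tuple(units) if units else (),
        times=times,
    )


def write_recording(recording: Recording, path: str | Path, delimiter: str = ",") -> None:
    """Write a recording as delimited text plus a JSON metadata sidecar.

    Voltages are written with 17 significant digits so a read-back round-trip
    is lossless at double precision.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["time", *recording.channel_labels])
        for i in range(recording.n_samples):
            writer.writerow(
                [f"{recording.times[i]:.17g}"]
                + [f"{v:.17g}" for v in recording.voltages[:, i]]
            )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "sampling_rate": recording.sampling_rate,
                "units_per_channel": list(recording.units_per_channel),
                "stimulus_events": list(recording.stimulus_events),
            },
            indent=2,
        )
    )
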