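"""Image-encoded optical stimulation: grayscale image -> 0-5 V voltage train,
recorded potentials -> reconstructed image, and stimulus-response statistics.

Encoding flattens the image row by row and maps 8-bit intensity to voltage by
division by 51 (0-255 -> 0-5 V, i.e. 5/255 ~ 0.0196 V per intensity unit) at
one pixel per sample (default 1 ms). Decoding normalizes recorded potentials
to 0-5 V by 5th/95th-percentile scaling, inverts the ÷51 map, reshapes
row-major, and finally applies CLAHE as a display-only contrast step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from skimage import exposure

from .recording import Recording

DEFAULT_DIVISOR = 51.0   # intensity units per volt: 255/5
VOLTS_PER_UNIT = 5.0 / 255.0


class OpticalError(ValueError):
    pass


@dataclass
class StimulusImageMap:
    """Record of an image->voltage encoding (bidirectional provenance)."""

    height: int
    width: int
    intensities: np.ndarray       # 0-255, row-major flattened
    volts_per_unit: float = VOLTS_PER_UNIT
    dt: float = 0.001             # s per pixel
    divisor: float = DEFAULT_DIVISOR

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def duration(self) -> float:
        return self.n_pixels * self.dt


@dataclass
class ReconstructionSpec:
    """Decode parameters: percentile normalization bounds, output shape
    (rows, cols), and CLAHE contrast settings (clip 2.0, 8x8 tiles)."""

    p_low_pct: float = 5.0
    p_high_pct: float = 95.0
    out_shape: tuple[int, int] = (300, 400)   # (rows, cols) = 400x300 pixels wide x high
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.p_low_pct >= self.p_high_pct:
            raise OpticalError("p_low_pct must be < p_high_pct")


def load_grayscale(path) -> np.ndarray:
    """Load an image as 8-bit grayscale (standard luminance weighting for
    color inputs, via Pillow mode "L")."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def image_to_voltage(
    image: np.ndarray,
    dt: float = 0.001,
    divisor: float = DEFAULT_DIVISOR,
) -> tuple[StimulusImageMap, np.ndarray, np.ndarray]:
    """Encode a grayscale raster into a voltage time series.

    Returns (map record, times, volts): row-major flatten, V = I/divisor in
    [0, 5] V, t_i = i*dt. Pixel 255 -> 5.0 V, pixel 0 -> 0 V.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise OpticalError("empty image")
    if img.ndim != 2:
        raise OpticalError("expected a single-channel (grayscale) image")
    intens = img.astype(float).ravel(order="C")
    volts = intens / divisor
    times = np.arange(intens.size) * dt
    rec = StimulusImageMap(
        height=img.shape[0], width=img.shape[1],
        intensities=img.ravel(order="C").copy(),
        volts_per_unit=1.0 / divisor, dt=dt, divisor=divisor,
    )
    return rec, times, volts


def percentile_normalize(
    potentials: np.ndarray, p_low_pct: float = 5.0, p_high_pct: float = 95.0
) -> tuple[np.ndarray, float, float]:
    """Scale potentials to 0-5 V between their p_low/p_high percentiles,
    clipped to [0, 5]. Unit-free: gain and offset are absorbed, so raw mV
    potentials decode without an explicit unit conversion."""
    p = np.asarray(potentials, dtype=float)
    p_low = float(np.percentile(p, p_low_pct))
    p_high = float(np.percentile(p, p_high_pct))
    if p_high == p_low:
        return np.full_like(p, np.nan), p_low, p_high
    norm = 5.0 * (p - p_low) / (p_high - p_low)
    return np.clip(norm, 0.0, 5.0), p_low, p_high


def apply_clahe(
    image: np.ndarray, clip: float = 2.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit raster.

    Tile grid follows the (8, 8) convention; the clip limit is expressed on
    the conventional scale where 1.0 means no limiting beyond the uniform
    histogram and is mapped onto the [0, 1] clip fraction used by
    scikit-image. Display enhancement only; non-invertible by design.
    """
    img = np.asarray(image, dtype=np.uint8)
    kernel = (
        max(img.shape[0] // tiles[0], 1),
        max(img.shape[1] // tiles[1], 1),
    )
    eq = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=min(clip / 100.0, 1.0)
    )
    return (eq * 255.0).round().astype(np.uint8)


def voltage_to_image(
    potentials: np.ndarray,
    spec: ReconstructionSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode recorded potentials into an 8-bit raster.

    Percentile scale to 0-5 V -> multiply by 51 -> clip to [0, 255] -> reshape
    row-major -> CLAHE. Returns (clahe_image, pre_clahe_image); the pre-CLAHE
    raster is the round-trip-faithful product. The caller must supply exactly
    ``rows*cols`` samples (no silent resizing). Degenerate (constant) input
    produces a constant mid-gray raster with a warning.
    """
    spec = spec or ReconstructionSpec()
    p = np.asarray(potentials, dtype=float)
    rows, cols = spec.out_shape
    if p.size != rows * cols:
        raise OpticalError(
            f"got {p.size} samples for a {rows}x{cols} reconstruction; "
            "truncate or pad explicitly"
        )
    norm, p_low, p_high = percentile_normalize(p, spec.p_low_pct, spec.p_high_pct)
    if p_high == p_low:
        warnings.warn("degenerate (constant) potentials: emitting mid-gray raster")
        pre = np.full((rows, cols), 128, dtype=np.uint8)
        return pre.copy(), pre
    intens = np.clip(norm * DEFAULT_DIVISOR, 0.0, 255.0)
    pre = intens.round().astype(np.uint8).reshape(rows, cols)
    return apply_clahe(pre, spec.clahe_clip, spec.clahe_tiles), pre


def response_statistics(
    recording: Recording,
    input_channel: str,
    output_channels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-channel mean, SD and Pearson correlation with the stimulus-input
    channel (table layout: one row per output channel).

    Zero-variance channels get a missing correlation rather than an error.
    """
    x = recording.channel(input_channel)
    if output_channels is None:
        output_channels = [
            l for l in recording.channel_labels if l != input_channel
        ]
    rows = []
    x_sd = float(np.std(x))
    for label in output_channels:
        y = recording.channel(label)
        if len(y) != len(x):
            raise OpticalError("input and output channels must be time-aligned")
        sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
        if sd == 0.0 or x_sd == 0.0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        unit = recording.units_per_channel[recording.channel_labels.index(label)]
        rows.append(
            {"channel": label, "mean": float(np.mean(y)), "std": sd,
             "corr_with_input": r, "unit": unit}
        )
    return pd.DataFrame(rows, columns=["channel", "mean", "std", "corr_with_input", "unit"])


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)
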