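"""Electrode-grid geometry and instantaneous sEMG images.

An HD-sEMG electrode array samples the spatial potential distribution over
a muscle region.  At every sampling instant the per-channel voltages can be
arranged on the grid and linearly mapped to grayscale intensities, turning
a multichannel time series into a sequence of small images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "ElectrodeGrid",
    "IntensityMap",
    "Recording",
    "SemgImage",
    "to_image",
    "image_stack",
    "difference_image",
    "difference_stack",
    "to_vector",
    "gray_to_rgb",
    "jet_colour",
    "save_png",
    "save_hdf5",
]


class DimensionError(ValueError):
    """Shape or length mismatch between a frame/image and its grid."""


class RangeError(ValueError):
    """Voltage outside the intensity-map range with clipping disabled."""


def _default_channel_map(rows: int, cols: int) -> np.ndarray:
    """Row-major layout: channel 0 -> (0, 0), ascending along columns first."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    return np.stack([r, c], axis=1)


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry and channel -> (row, col) layout of an electrode array.

    Parameters
    ----------
    rows, cols:
        Grid dimensions; ``rows * cols`` must equal the channel count.
    row_pitch, col_pitch:
        Inter-electrode distances in millimetres (metadata only).
    channel_map:
        ``(n_channels, 2)`` integer array mapping channel index to
        ``(row, col)``.  Must be a bijection onto the grid.  Defaults to
        row-major order, which matches stacked 2x8 acquisition modules.
    """

    rows: int
    cols: int
    row_pitch: float = 10.05
    col_pitch: float = 7.5
    channel_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        cmap = self.channel_map
        if cmap is None:
            cmap = _default_channel_map(self.rows, self.cols)
        cmap = np.asarray(cmap, dtype=np.intp)
        if cmap.shape != (self.rows * self.cols, 2):
            raise DimensionError(
                f"channel_map must have shape ({self.rows * self.cols}, 2), "
                f"got {cmap.shape}"
            )
        flat = cmap[:, 0] * self.cols + cmap[:, 1]
        if (
            cmap[:, 0].min() < 0
            or cmap[:, 0].max() >= self.rows
            or cmap[:, 1].min() < 0
            or cmap[:, 1].max() >= self.cols
            or len(np.unique(flat)) != len(flat)
        ):
            raise ValueError("channel_map must be a bijection onto the grid")
        object.__setattr__(self, "channel_map", cmap)

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def scatter(self, frame: np.ndarray) -> np.ndarray:
        """Arrange a channel vector (or channels-first array) on the grid.

        ``frame`` of shape ``(n_channels, ...)`` becomes ``(rows, cols, ...)``.
        """
        frame = np.asarray(frame)
        if frame.shape[0] != self.n_channels:
            raise DimensionError(
                f"expected {self.n_channels} channels, got {frame.shape[0]}"
            )
        out = np.empty((self.rows, self.cols) + frame.shape[1:], dtype=frame.dtype)
        out[self.channel_map[:, 0], self.channel_map[:, 1]] = frame
        return out

    def gather(self, image: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`scatter`: grid array back to channel order."""
        image = np.asarray(image)
        if image.shape[:2] != self.shape:
            raise DimensionError(
                f"expected leading shape {self.shape}, got {image.shape[:2]}"
            )
        return image[self.channel_map[:, 0], self.channel_map[:, 1]]


@dataclass(frozen=True)
class IntensityMap:
    """Affine voltage -> intensity map; default [-2.5 mV, 2.5 mV] -> [0, 1]."""

    vmin: float = -2.5
    vmax: float = 2.5
    clip: bool = True

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be strictly less than vmax")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        out = (values - self.vmin) / (self.vmax - self.vmin)
        if self.clip:
            return np.clip(out, 0.0, 1.0)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise RangeError(
                f"voltage outside [{self.vmin}, {self.vmax}] mV with clip disabled"
            )
        return out

    def invert(self, intensities: np.ndarray) -> np.ndarray:
        intensities = np.asarray(intensities, dtype=np.float64)
        return intensities * (self.vmax - self.vmin) + self.vmin


@dataclass
class Recording:
    """A channels x frames signal matrix in mV with metadata labels."""

    signals: np.ndarray
    fs: float
    subject: int = 0
    gesture: int = 0
    trial: int = 0
    session: int = 0
    rectified: bool = False

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise DimensionError("signals must be a 2-D channels x frames matrix")
        if self.signals.shape[1] < 1:
            raise ValueError("recording must contain at least one frame")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.rectified and self.signals.size and self.signals.min() < 0:
            raise ValueError("rectified recording contains negative values")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]

    def replace(self, **kwargs) -> "Recording":
        params = dict(
            signals=self.signals,
            fs=self.fs,
            subject=self.subject,
            gesture=self.gesture,
            trial=self.trial,
            session=self.session,
            rectified=self.rectified,
        )
        params.update(kwargs)
        return Recording(**params)


@dataclass
class SemgImage:
    """A rows x cols intensity image for one sampling instant, values in [0, 1]."""

    pixels: np.ndarray
    grid: ElectrodeGrid
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != self.grid.shape:
            raise DimensionError(
                f"pixel shape {self.pixels.shape} does not match grid {self.grid.shape}"
            )
        if self.pixels.size and (self.pixels.min() < 0.0 or self.pixels.max() > 1.0):
            raise RangeError("pixel intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def to_image(
    frame: np.ndarray,
    grid: ElectrodeGrid,
    imap: IntensityMap | None = None,
    frame_index: int = 0,
) -> SemgImage:
    """Map one instantaneous channel vector (mV) to a grayscale image.

    Each channel's voltage is placed at its grid position and linearly
    transformed to an intensity in ``[0, 1]``.
    """
    imap = imap or IntensityMap()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise DimensionError("frame must be a 1-D channel vector")
    if frame.shape[0] != grid.n_channels:
        raise DimensionError(
            f"frame has {frame.shape[0]} channels, grid expects {grid.n_channels}"
        )
    return SemgImage(imap.apply(grid.scatter(frame)), grid, frame_index)


def image_stack(
    rec: Recording, grid: ElectrodeGrid, imap: IntensityMap | None = None
) -> np.ndarray:
    """All frames of a recording as a ``(n_frames, rows, cols)`` intensity array."""
    imap = imap or IntensityMap()
    if rec.n_channels != grid.n_channels:
        raise DimensionError(
            f"recording has {rec.n_channels} channels, grid expects {grid.n_channels}"
        )
    grid_signals = grid.scatter(rec.signals)  # (rows, cols, T)
    return np.ascontiguousarray(np.moveaxis(imap.apply(grid_signals), -1, 0))


def difference_image(img_t: SemgImage, img_prev: SemgImage) -> np.ndarray:
    """Signed pixel-wise change between two consecutive images, in [-1, 1]."""
    if img_t.pixels.shape != img_prev.pixels.shape:
        raise DimensionError("difference requires images of identical shape")
    if img_t.frame_index != img_prev.frame_index + 1:
        raise ValueError("images must be temporally consecutive")
    return img_t.pixels - img_prev.pixels


def difference_stack(images: np.ndarray) -> np.ndarray:
    """Frame-to-frame differences of a ``(T, rows, cols)`` stack: T-1 images."""
    images = np.asarray(images)
    if images.shape[0] < 2:
        raise ValueError("need at least two frames to form difference images")
    return np.diff(images, axis=0)


def to_vector(frame: np.ndarray) -> np.ndarray:
    """A raw instantaneous channel vector as a feature vector (identity order)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise DimensionError("frame must be a 1-D channel vector")
    if frame.size == 0:
        raise ValueError("empty frame")
    return frame.copy()


def gray_to_rgb(img: SemgImage) -> np.ndarray:
    """Replicate a grayscale image into three identical channels."""
    return np.repeat(img.pixels[..., None], 3, axis=-1)


# Piecewise-linear jet colour map (classic MATLAB/matplotlib "jet"):
# each channel ramps 0 -> 1 -> 0 over staggered quarters of the input range.
def _jet_channel(x: np.ndarray, centre: float) -> np.ndarray:
    return np.clip(1.5 - 4.0 * np.abs(x - centre), 0.0, 1.0)


def jet_colour(img: SemgImage) -> np.ndarray:
    """Apply the jet colour scheme pixel-wise, producing an RGB image in [0, 1].

    Intensity 0 maps to dark blue, 0.5 to green, 1 to dark red.
    """
    x = img.pixels
    return np.stack(
        [_jet_channel(x, 0.75), _jet_channel(x, 0.5), _jet_channel(x, 0.25)],
        axis=-1,
    )


def save_png(img: SemgImage, path, upscale: int = 1) -> None:
    """Export an image as an 8-bit PNG (quantized; for inspection only)."""
    from PIL import Image

    arr = np.round(img.pixels * 255.0).astype(np.uint8)
    if upscale > 1:
        arr = np.kron(arr, np.ones((upscale, upscale), dtype=np.uint8))
    Image.fromarray(arr, mode="L").save(path)


def save_hdf5(images: Iterable[SemgImage] | np.ndarray, path) -> None:
    """Export a float image stack to HDF5 (lossless)."""
    import h5py

    if not isinstance(images, np.ndarray):
        images = np.stack([im.pixels for im in images])
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images)
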