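"""Calibrated image input/output.

A dataset is a START image (the timepoint right after the spheroid is embedded
in the matrix, before any migration) plus an ordered list of later timepoints.
Every image carries its own μm-per-pixel calibration; all images of a dataset
share the same calibration, but may differ in shape (each timepoint is analyzed
independently).

Coordinate convention: arrays are row-major with 0-based indices; ``(x, y)`` in
any report means ``(column, row)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from ._util import boundary_mask

__all__ = [
    "CalibratedImage",
    "TimeSeriesDataset",
    "load_image",
    "load_dataset",
    "write_image",
    "write_mask_image",
    "write_overlay",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_ACCEPTED_SUFFIXES = _TIFF_SUFFIXES | {".png"}


@dataclass
class CalibratedImage:
    """A single-channel 2D intensity grid with physical pixel calibration.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (any integer or float
        dtype; at least 2 rows and 2 columns).
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    timepoint_label
        Free-text timepoint name, e.g. ``"START"`` or ``"24h"``.
    bit_depth
        Sample depth of the source data (8 or 16).
    """

    pixels: np.ndarray
    pixel_size_um: float
    timepoint_label: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image must be 2D with at least 2 rows and 2 columns")
        if not float(self.pixel_size_um) > 0:
            raise ValueError("pixel_size_um must be > 0")
        self.pixel_size_um = float(self.pixel_size_um)
        vals = self.pixels
        if not np.isfinite(np.asarray(vals, dtype=np.float64)).all():
            raise ValueError("intensities must be finite")
        if np.asarray(vals, dtype=np.float64).min() < 0:
            raise ValueError("intensities must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class TimeSeriesDataset:
    """One START image plus zero or more later timepoints, same calibration."""

    start: CalibratedImage
    followups: list[CalibratedImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        for img in self.followups:
            if img.pixel_size_um != self.start.pixel_size_um:
                raise ValueError("all images in a dataset must share pixel_size_um")

    @property
    def images(self) -> list[CalibratedImage]:
        """All images, START first."""
        return [self.start, *self.followups]


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    # fall back on value range
    return 8 if arr.max(initial=0) <= 255 else 16


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return tifffile.imread(path)
    return iio.imread(path)


def _to_single_channel(arr: np.ndarray) -> np.ndarray:
    """Squeeze a decoded raster down to one 2D channel.

    Multi-channel input is accepted only when exactly one channel carries any
    signal (common for single-stain exports saved as RGB).
    """
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError(f"not a 2D grayscale image (got shape {arr.shape})")
    # channel axis: trailing for RGB(A)-style, leading for planar stacks
    axis = 2 if arr.shape[2] <= 4 else 0
    if axis == 0 and arr.shape[0] > 4:
        raise ValueError(f"not a 2D grayscale image (got shape {arr.shape})")
    channels = np.moveaxis(arr, axis, 0)
    informative = [c for c in channels if np.any(c)]
    if len(informative) == 1:
        return informative[0]
    raise ValueError(
        "not single-channel: "
        f"{len(informative)} of {len(channels)} channels carry signal"
    )


def load_image(
    path: str | Path,
    pixel_size_um: float,
    timepoint_label: str | None = None,
) -> CalibratedImage:
    """Load a TIFF or PNG as a :class:`CalibratedImage`.

    Intensities are preserved bit-exactly from the source.  The timepoint
    label defaults to the file stem.
    """
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED_SUFFIXES:
        raise ValueError(f"unsupported format '{path.suffix}' (TIFF/PNG only)")
    if not path.is_file():
        raise FileNotFoundError(path)
    arr = _to_single_channel(_read_raster(path))
    if arr.size == 0:
        raise ValueError("zero-sized image")
    return CalibratedImage(
        pixels=arr,
        pixel_size_um=pixel_size_um,
        timepoint_label=timepoint_label if timepoint_label is not None else path.stem,
        bit_depth=_bit_depth_of(arr),
    )


def load_dataset(
    start_path: str | Path,
    followup_paths: Sequence[str | Path],
    pixel_size_um: float,
    labels: Sequence[str] | None = None,
) -> TimeSeriesDataset:
    """Assemble a :class:`TimeSeriesDataset` from files.

    ``labels``, when given, overrides the file-stem timepoint labels and must
    provide one entry per image (START first).
    """
    start_path = Path(start_path)
    followup_paths = [Path(p) for p in followup_paths]
    resolved_start = start_path.resolve()
    for p in followup_paths:
        if p.resolve() == resolved_start:
            raise ValueError("START duplicated in followup list")
    n = 1 + len(followup_paths)
    if labels is not None and len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    start = load_image(
        start_path, pixel_size_um, labels[0] if labels else None
    )
    followups = [
        load_image(p, pixel_size_um, labels[i + 1] if labels else None)
        for i, p in enumerate(followup_paths)
    ]
    return TimeSeriesDataset(start=start, followups=followups)


def write_image(array: np.ndarray, path: str | Path) -> None:
    """Write a 2D or RGB array as TIFF or PNG, chosen by suffix."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, array)
    else:
        iio.imwrite(path, array)


def write_mask_image(grid: np.ndarray, path: str | Path) -> None:
    """Export a boolean mask as an 8-bit binary raster (0/255)."""
    write_image(np.where(np.asarray(grid, bool), 255, 0).astype(np.uint8), path)


def to_display_gray(image: CalibratedImage) -> np.ndarray:
    """Convert intensities to 8-bit for display, scaling by the bit-depth range."""
    if image.bit_depth == 8:
        return image.pixels.astype(np.uint8)
    scale = 255.0 / (2**image.bit_depth - 1)
    return np.round(np.asarray(image.pixels, np.float64) * scale).astype(np.uint8)


def write_overlay(image: CalibratedImage, mask, objects, path: str | Path) -> np.ndarray:
    """Write an RGB overlay: grayscale base, mask boundary in red, detected
    object pixels in green.  Returns the RGB array that was written.

    ``mask`` is a :class:`~spheroidquant.mask_generation.SpheroidMask` (or any
    object with a boolean ``grid``); ``objects`` an iterable of detected
    objects with ``pixels`` arrays of (row, col) coordinates.  Inputs are
    never mutated.
    """
    grid = np.asarray(mask.grid, bool)
    if grid.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    base = to_display_gray(image)
    rgb = np.stack([base, base, base], axis=-1)
    bnd = boundary_mask(grid)
    rgb[bnd] = (255, 0, 0)
    for obj in objects:
        rows, cols = obj.pixels[:, 0], obj.pixels[:, 1]
        rgb[rows, cols] = (0, 255, 0)
    write_image(rgb, path)
    return rgb
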