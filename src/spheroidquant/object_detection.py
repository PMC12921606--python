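"""Detection of invading objects outside the spheroid-core mask.

Candidate objects are the extended maxima (EMax) of the image: connected
regions of local maxima whose prominence over the surrounding saddle level is
at least ``h``, with ``h`` expressed as a *dynamic* — a fraction of the
observed image intensity range.  Because the criterion is a local contrast,
the detection is robust to smooth, non-constant background.  Components that
touch the core mask are attributed to the core and dropped whole; remaining
objects large enough to contain a disk of the expected artifact radius
(bubbles, debris) are flagged and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage.morphology import local_maxima, reconstruction

from ._util import SQUARE3, disk_element
from .image_io import CalibratedImage
from .mask_generation import SpheroidMask

__all__ = [
    "EMaxParams",
    "DetectedObject",
    "extended_maxima",
    "objects_outside_mask",
    "exclude_artifacts",
    "detect",
]

#: relative slack so that a peak whose prominence equals h exactly is retained
_H_SLACK = 1e-9


@dataclass(frozen=True)
class EMaxParams:
    """Detection parameters.

    dynamic
        Prominence criterion as a fraction of the image intensity range,
        in (0, 1].  Default 0.001.
    artifact_radius_um
        Objects that can contain a disk of this radius are excluded as
        artifacts; 0 disables the exclusion.
    """

    dynamic: float = 0.001
    artifact_radius_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.dynamic <= 1:
            raise ValueError("dynamic must be in (0, 1]")
        if self.artifact_radius_um < 0:
            raise ValueError("artifact_radius_um must be >= 0")


@dataclass
class DetectedObject:
    """One labeled connected region outside the mask.

    ``pixels`` is an (N, 2) array of (row, col) coordinates.  Geometry and
    shape fields are filled by :mod:`spheroidquant.measurement`.
    ``centroid_xy`` is (column, row) per the package coordinate convention.
    """

    label: int
    pixels: np.ndarray
    area_px: int = 0
    centroid_xy: tuple[float, float] = (0.0, 0.0)
    area_um2: float | None = None
    perimeter_um: float | None = None
    circularity: float | None = None
    roundness: float | None = None
    solidity: float | None = None
    distance_um: float | None = None
    excluded_as_artifact: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)
        if self.pixels.shape[0] == 0:
            raise ValueError("object pixel set must be non-empty")
        self.area_px = int(self.pixels.shape[0])
        r, c = self.pixels[:, 0].mean(), self.pixels[:, 1].mean()
        self.centroid_xy = (float(c), float(r))

    @property
    def centroid_rc(self) -> tuple[float, float]:
        return (self.centroid_xy[1], self.centroid_xy[0])

    def crop(self, pad: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean crop of the object with optional padding; returns
        (crop, (row_offset, col_offset))."""
        r0, c0 = self.pixels.min(axis=0) - pad
        r1, c1 = self.pixels.max(axis=0) + pad
        out = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        out[self.pixels[:, 0] - r0, self.pixels[:, 1] - c0] = True
        return out, (int(r0), int(c0))


def extended_maxima(image: CalibratedImage | np.ndarray, dynamic: float) -> np.ndarray:
    """Extended-maxima label grid at the given dynamic.

    ``h = dynamic × (max − min)`` of the raw image (observed range, so the
    same dynamic is portable across 8- and 16-bit data).  The components are
    the regional maxima of the h-maxima transform (morphological
    reconstruction of ``image − h`` under ``image``), 8-connected.  A peak
    whose prominence equals ``h`` exactly is retained.  A flat image yields
    zero components, and a "component" covering the whole image is discarded
    (no localized maximum exists).
    """
    if not 0 < dynamic <= 1:
        raise ValueError("dynamic must be in (0, 1]")
    pixels = image.pixels if isinstance(image, CalibratedImage) else image
    img = np.asarray(pixels, dtype=np.float64)
    rng = float(img.max() - img.min())
    out_dtype = np.int32
    if rng == 0.0:
        return np.zeros(img.shape, dtype=out_dtype)
    h_eff = dynamic * rng * (1.0 - _H_SLACK)
    rec = reconstruction(img - h_eff, img, method="dilation", footprint=SQUARE3)
    peaks = local_maxima(rec, connectivity=2, allow_borders=True)
    if peaks.all():
        return np.zeros(img.shape, dtype=out_dtype)
    return _skmeasure.label(peaks, connectivity=2).astype(out_dtype)


def objects_outside_mask(
    label_grid: np.ndarray, mask: SpheroidMask
) -> list[DetectedObject]:
    """Keep the components lying entirely outside the mask.

    A component with *any* pixel inside the mask is attributed to the core
    and dropped whole (clipping would corrupt shape descriptors).  Survivors
    are relabeled 1..k in original label order.
    """
    label_grid = np.asarray(label_grid)
    if label_grid.shape != mask.grid.shape:
        raise ValueError("label grid and mask shapes differ")
    inside = np.unique(label_grid[mask.grid])
    objects: list[DetectedObject] = []
    slices = ndimage.find_objects(label_grid)
    next_label = 1
    for lab, sl in enumerate(slices, start=1):
        if sl is None or lab in inside:
            continue
        rows, cols = np.nonzero(label_grid[sl] == lab)
        coords = np.column_stack([rows + sl[0].start, cols + sl[1].start])
        objects.append(DetectedObject(label=next_label, pixels=coords))
        next_label += 1
    return objects


def _can_contain_disk(obj: DetectedObject, radius_px: int) -> bool:
    crop, _ = obj.crop(pad=0)
    selem = disk_element(radius_px)
    eroded = ndimage.binary_erosion(crop, structure=selem, border_value=0)
    return bool(eroded.any())


def exclude_artifacts(
    objects: Sequence[DetectedObject],
    artifact_radius_um: float,
    pixel_size_um: float,
) -> list[DetectedObject]:
    """Flag objects that can contain a disk of the given radius as artifacts.

    The disk is the digital structuring element {dr² + dc² ≤ r²} with
    ``r = round(artifact_radius_um / pixel_size_um)``, at least 1 px; a radius
    of 0 μm disables the exclusion entirely.  Flags are set in place;
    flagged objects stay in the detailed table but are dropped from counts
    and summaries downstream.
    """
    objects = list(objects)
    if artifact_radius_um < 0:
        raise ValueError("artifact_radius_um must be >= 0")
    if artifact_radius_um == 0:
        for obj in objects:
            obj.excluded_as_artifact = False
        return objects
    r_px = max(1, round(artifact_radius_um / pixel_size_um))
    for obj in objects:
        obj.excluded_as_artifact = _can_contain_disk(obj, r_px)
    return objects


def detect(
    image: CalibratedImage, mask: SpheroidMask, params: EMaxParams
) -> list[DetectedObject]:
    """Full detection: extended maxima → outside-mask filter → artifact flags.

    Deterministic for fixed inputs.  Adding a constant to all intensities
    does not change the result (``h`` scales with the shift-invariant range).
    """
    if image.shape != mask.grid.shape:
        raise ValueError("image and mask shapes differ")
    labels = extended_maxima(image, params.dynamic)
    objects = objects_outside_mask(labels, mask)
    return exclude_artifacts(objects, params.artifact_radius_um, image.pixel_size_um)


def kept(objects: Iterable[DetectedObject]) -> list[DetectedObject]:
    """Objects not flagged as artifacts (the ones that enter summaries)."""
    return [o for o in objects if not o.excluded_as_artifact]
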