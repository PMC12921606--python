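"""Per-object geometry, boundary distances, and the per-image summary.

Conventions follow the ImageJ particle-analysis tradition: perimeters are
traced along 8-connected boundaries through pixel centers (axial step 1,
diagonal step √2); circularity is 4πA/P² capped at 1; roundness is 4A/(πL²)
with L the major axis of the moment-matched ellipse; solidity is the area
over the filled convex-hull area.  The mask perimeter is measured on a
*smoothed* copy of the mask (morphological opening then closing with a small
disk) so that it is not inflated by protrusions narrower than ``detail_um``;
areas and boundary distances always use the raw mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure as _skmeasure

from ._util import CROSS, boundary_mask, disk_element
from .mask_generation import SpheroidMask
from .object_detection import DetectedObject

__all__ = [
    "SummaryRecord",
    "smooth_mask",
    "mask_perimeter",
    "distance_to_boundary",
    "shape_descriptors",
    "measure_objects",
    "summarize",
]

#: default smoothing scale (μm): only details larger than this survive in the
#: perimeter mask; midpoint of the sensible 10–20 μm window for 5× images
DEFAULT_DETAIL_UM = 15.0

_SQRT2 = math.sqrt(2.0)

# Moore neighborhood in clockwise order starting at West (image rows grow
# downward, so W -> NW -> N -> ... is clockwise on screen)
_MOORE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
)
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


@dataclass
class SummaryRecord:
    """Per-image roll-up of the invasion measurements.

    Distances are absent (None) when no objects were kept; the per-perimeter
    object count is objects per *millimetre* of smoothed mask perimeter and
    absent when the perimeter is zero.
    """

    timepoint_label: str
    mode: str
    mask_area_um2: float
    mask_perimeter_um: float
    n_objects: int
    n_objects_per_mm: float | None
    total_object_area_um2: float
    mean_distance_um: float | None
    median_distance_um: float | None
    n_excluded_artifacts: int
    emax_dynamic: float
    artifact_radius_um: float
    detail_um: float
    threshold_used: float | None


def smooth_mask(
    mask: SpheroidMask, detail_um: float = DEFAULT_DETAIL_UM,
    pixel_size_um: float | None = None,
) -> SpheroidMask:
    """Morphological opening then closing with a disk of radius
    ``round(detail_um / 2 / pixel_size_um)`` px (at least 1), removing
    protrusions and indentations narrower than ``detail_um``.

    Used only for perimeter computation; idempotent; an empty mask passes
    through unchanged.
    """
    if detail_um <= 0:
        raise ValueError("detail_um must be > 0")
    px = pixel_size_um if pixel_size_um is not None else mask.pixel_size_um
    if not mask.grid.any():
        return replace(mask, grid=mask.grid.copy())
    selem = disk_element(max(1, round(detail_um / 2.0 / px)))
    opened = ndimage.binary_opening(mask.grid, structure=selem)
    closed = ndimage.binary_closing(opened, structure=selem)
    return replace(mask, grid=closed)


def _trace_length(region: np.ndarray) -> float:
    """Closed-contour length of a single 8-connected component, Moore-traced
    through pixel centers (axial 1, diagonal √2).  Isolated pixels trace to 0.
    """
    rows, cols = np.nonzero(region)
    if rows.size <= 1:
        return 0.0
    pad = np.pad(region, 1)
    start = (int(rows[0]) + 1, int(cols[0]) + 1)
    cur = start
    back = 0  # West of the raster-first pixel is guaranteed background
    length = 0.0
    first_move = None
    while True:
        for k in range(1, 9):
            j = (back + k) % 8
            nxt = (cur[0] + _MOORE[j][0], cur[1] + _MOORE[j][1])
            if pad[nxt]:
                break
        else:
            return 0.0  # isolated pixel
        move = (cur, j)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        length += 1.0 if j % 2 == 0 else _SQRT2
        prev_checked = (
            cur[0] + _MOORE[(back + k - 1) % 8][0],
            cur[1] + _MOORE[(back + k - 1) % 8][1],
        )
        cur = nxt
        back = _MOORE_INDEX[(prev_checked[0] - cur[0], prev_checked[1] - cur[1])]
    return length


def _grid_perimeter_px(grid: np.ndarray) -> float:
    """Traced perimeter of a boolean grid in pixel units: outer contours of
    every 8-connected component plus contours of enclosed holes."""
    grid = np.asarray(grid, bool)
    total = 0.0
    labels = _skmeasure.label(grid, connectivity=2)
    for sl_lab, sl in zip(
        range(1, labels.max() + 1), ndimage.find_objects(labels)
    ):
        total += _trace_length(labels[sl] == sl_lab)
    # holes: background components (4-connected) not touching the border
    padded_bg = np.pad(~grid, 1, constant_values=True)
    bg_labels = _skmeasure.label(padded_bg, connectivity=1)
    border_label = bg_labels[0, 0]
    for lab, sl in zip(
        range(1, bg_labels.max() + 1), ndimage.find_objects(bg_labels)
    ):
        if lab == border_label or sl is None:
            continue
        total += _trace_length(bg_labels[sl] == lab)
    return total


def mask_perimeter(mask: SpheroidMask, pixel_size_um: float | None = None) -> float:
    """Perimeter of the given mask in μm (sum over components and holes).

    Pass the *smoothed* mask for the summary-table perimeter.  An empty mask
    measures 0, as does a single pixel (no steps to trace; degenerate).
    """
    px = pixel_size_um if pixel_size_um is not None else mask.pixel_size_um
    return _grid_perimeter_px(mask.grid) * px


def _boundary_tree(mask: SpheroidMask) -> cKDTree:
    bnd = boundary_mask(mask.grid)
    coords = np.column_stack(np.nonzero(bnd))
    if coords.shape[0] == 0:
        raise ValueError("no boundary: mask is empty")
    return cKDTree(coords)


def distance_to_boundary(
    obj: DetectedObject,
    mask: SpheroidMask,
    pixel_size_um: float | None = None,
    reference: str = "centroid",
    _tree: cKDTree | None = None,
) -> float:
    """Euclidean distance (μm) from an object to the nearest mask-boundary
    pixel.

    Boundary pixels are mask pixels with at least one 4-connected background
    neighbor (the image border counts as background).  ``reference`` selects
    the object-side reference point: its centroid (default) or its nearest
    own pixel (``"edge"``).
    """
    px = pixel_size_um if pixel_size_um is not None else mask.pixel_size_um
    tree = _tree if _tree is not None else _boundary_tree(mask)
    if reference == "centroid":
        d, _ = tree.query(np.asarray(obj.centroid_rc, np.float64))
        return float(d) * px
    if reference == "edge":
        d, _ = tree.query(obj.pixels.astype(np.float64))
        return float(np.min(d)) * px
    raise ValueError("reference must be 'centroid' or 'edge'")


def shape_descriptors(
    obj: DetectedObject, pixel_size_um: float = 1.0
) -> tuple[float, float, float]:
    """(circularity, roundness, solidity) of an object's pixel set.

    circularity = 4πA/P² with the traced perimeter, capped at 1.0 (digital
    contours of near-circular blobs otherwise overshoot); roundness =
    4A/(πL²) with L the moment-ellipse major axis; solidity = A over the
    filled convex-hull area.  Degenerate objects whose perimeter or major
    axis is zero (e.g. a single pixel) report 1.0 by convention.  All three
    are unitless and independent of ``pixel_size_um``.
    """
    crop, _ = obj.crop(pad=1)
    area = float(obj.area_px)
    perim = _grid_perimeter_px(crop)
    circularity = 1.0 if perim == 0 else min(1.0, 4.0 * math.pi * area / perim**2)
    props = _skmeasure.regionprops(crop.astype(np.uint8))[0]
    major = props.axis_major_length
    roundness = 1.0 if major == 0 else min(1.0, 4.0 * area / (math.pi * major**2))
    solidity = min(1.0, float(props.solidity))
    return circularity, roundness, solidity


def measure_objects(
    objects: Sequence[DetectedObject],
    mask: SpheroidMask,
    pixel_size_um: float,
    distance_from: str = "centroid",
) -> list[DetectedObject]:
    """Fill the geometry, shape, and distance fields of detected objects
    in place (returns the same list for chaining)."""
    objects = list(objects)
    tree = _boundary_tree(mask) if mask.grid.any() else None
    for obj in objects:
        obj.area_um2 = obj.area_px * pixel_size_um**2
        crop, _ = obj.crop(pad=1)
        obj.perimeter_um = _grid_perimeter_px(crop) * pixel_size_um
        obj.circularity, obj.roundness, obj.solidity = shape_descriptors(obj)
        if tree is not None:
            obj.distance_um = distance_to_boundary(
                obj, mask, pixel_size_um, reference=distance_from, _tree=tree
            )
    return objects


def summarize(
    mask: SpheroidMask,
    objects: Sequence[DetectedObject],
    pixel_size_um: float,
    detail_um: float = DEFAULT_DETAIL_UM,
    timepoint_label: str = "",
    emax_dynamic: float = float("nan"),
    artifact_radius_um: float = 0.0,
) -> SummaryRecord:
    """Build the per-image summary row.

    ``objects`` is the full detection list; artifact-flagged entries are
    counted in ``n_excluded_artifacts`` and excluded from every other figure.
    Distance fields must already be filled (see :func:`measure_objects`).
    """
    kept = [o for o in objects if not o.excluded_as_artifact]
    perimeter_um = mask_perimeter(smooth_mask(mask, detail_um, pixel_size_um),
                                  pixel_size_um)
    n = len(kept)
    distances = [o.distance_um for o in kept if o.distance_um is not None]
    per_mm = n / (perimeter_um / 1000.0) if perimeter_um > 0 else None
    return SummaryRecord(
        timepoint_label=timepoint_label,
        mode=mask.mode,
        mask_area_um2=mask.area_px * pixel_size_um**2,
        mask_perimeter_um=perimeter_um,
        n_objects=n,
        n_objects_per_mm=per_mm,
        total_object_area_um2=float(sum(o.area_px for o in kept)) * pixel_size_um**2,
        mean_distance_um=float(np.mean(distances)) if distances else None,
        median_distance_um=float(np.median(distances)) if distances else None,
        n_excluded_artifacts=len(objects) - n,
        emax_dynamic=emax_dynamic,
        artifact_radius_um=artifact_radius_um,
        detail_um=detail_um,
        threshold_used=mask.threshold_used,
    )
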