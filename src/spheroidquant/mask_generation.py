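"""Spheroid-core mask computation.

Two strategies cover the two phenotypes seen in matrix-embedded spheroids:

* **compact** — the spheroid keeps a sharp boundary throughout the experiment,
  so every timepoint is thresholded independently (minimum cross-entropy, or a
  user override).  No information is carried over from START.
* **disintegrating** — the core loses its boundary after embedding.  The START
  image is thresholded, its mask area recorded, and at later timepoints a mask
  of the *same area* is placed on the highest-intensity pixels.  Everything
  outside that area is treated as invading material.

``auto_select_mode`` chooses between the two by checking whether the
independently-thresholded core area shrinks at any later timepoint, the
signature of rapid disintegration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from skimage import measure as _skmeasure

from .image_io import CalibratedImage, TimeSeriesDataset

__all__ = [
    "SpheroidMask",
    "mce_threshold",
    "segment_compact",
    "fixed_area_mask",
    "largest_component",
    "auto_select_mode",
    "build_masks",
]

logger = logging.getLogger(__name__)

COMPACT = "compact"
DISINTEGRATING = "disintegrating"
AUTO = "auto"

#: fractional shrinkage of the per-image core area (vs START) that flags
#: disintegration in automatic mode selection
DEFAULT_SHRINK_TOL = 0.05


@dataclass
class SpheroidMask:
    """Binary mask of the compact spheroid core, with provenance.

    ``threshold_used`` is set when the mask came from thresholding;
    ``target_area_px`` when it came from the fixed-area placement.
    """

    grid: np.ndarray
    pixel_size_um: float
    mode: str
    threshold_used: float | None = None
    target_area_px: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


def mce_threshold(image: CalibratedImage | np.ndarray) -> float:
    """Minimum cross-entropy (Li) threshold of an image histogram.

    Exhaustively minimizes the Li & Lee cross-entropy objective

    .. math:: \\eta(t) = -\\sum_{g \\le t} g\\,h(g)\\,\\ln\\mu_0(t)
                        -\\sum_{g > t} g\\,h(g)\\,\\ln\\mu_1(t)

    (the :math:`\\sum g\\,h(g)\\ln g` term is independent of *t* and dropped)
    over every distinct intensity level that leaves both classes non-empty.
    Foreground is strictly greater than the returned threshold; ties are
    broken toward the smallest level.

    Raises ``ValueError`` on a constant image.
    """
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    vals, counts = np.unique(pixels, return_counts=True)
    if vals.size < 2:
        raise ValueError("no contrast; cannot threshold")
    vals = vals.astype(np.float64)
    w = counts.astype(np.float64)
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(vals * w)
    tot_w, tot_m = cum_w[-1], cum_m[-1]
    # candidate t = vals[i] for i in 0..k-2 (background <= t, foreground > t)
    m0 = cum_m[:-1]
    m1 = tot_m - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / cum_w[:-1]
        mu1 = m1 / (tot_w - cum_w[:-1])
        term0 = np.where(m0 > 0, -m0 * np.log(mu0), 0.0)
        term1 = np.where(m1 > 0, -m1 * np.log(mu1), 0.0)
    eta = term0 + term1
    return float(vals[int(np.argmin(eta))])


def segment_compact(
    image: CalibratedImage, threshold_override: float | None = None
) -> SpheroidMask:
    """Threshold one image independently ("compact"-mode segmentation).

    Uses :func:`mce_threshold` unless ``threshold_override`` is given.  An
    override above the image maximum legally yields an empty mask.
    """
    t = float(threshold_override) if threshold_override is not None else mce_threshold(image)
    grid = np.asarray(image.pixels, np.float64) > t
    if not grid.any():
        logger.warning(
            "threshold %g yields an empty mask for %r", t, image.timepoint_label
        )
    return SpheroidMask(
        grid=grid, pixel_size_um=image.pixel_size_um, mode=COMPACT, threshold_used=t
    )


def fixed_area_mask(image: CalibratedImage, target_area_px: int) -> SpheroidMask:
    """Mask covering exactly the ``target_area_px`` highest-intensity pixels.

    All pixels strictly above the cut intensity are included; pixels *at* the
    cut intensity are included in raster-scan order (top-left first) until the
    target is reached, so the area is exact and the result reproducible.
    """
    target_area_px = int(target_area_px)
    n = image.pixels.size
    if not 0 <= target_area_px <= n:
        raise ValueError(f"target_area_px {target_area_px} outside [0, {n}]")
    grid = np.zeros(n, dtype=bool)
    if target_area_px > 0:
        flat = np.asarray(image.pixels, np.float64).ravel()
        # stable sort keeps ties in raster order
        order = np.argsort(-flat, kind="stable")
        grid[order[:target_area_px]] = True
    return SpheroidMask(
        grid=grid.reshape(image.shape),
        pixel_size_um=image.pixel_size_um,
        mode=DISINTEGRATING,
        target_area_px=target_area_px,
    )


def largest_component(mask: SpheroidMask) -> SpheroidMask:
    """Retain only the largest 8-connected component of the mask.

    Detached bright particles are thereby treated as separate from the core.
    Ties are broken toward the component containing the raster-earliest pixel;
    an empty mask is returned unchanged.  Idempotent.
    """
    labels = _skmeasure.label(mask.grid, connectivity=2)
    n = labels.max()
    if n == 0:
        return replace(mask, grid=mask.grid.copy())
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    candidates = np.flatnonzero(areas == areas.max())
    if candidates.size == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        first = np.flatnonzero(np.isin(flat, candidates))[0]
        keep = flat[first]
    return replace(mask, grid=labels == keep)


def auto_select_mode(
    dataset: TimeSeriesDataset, shrink_tol: float = DEFAULT_SHRINK_TOL
) -> str:
    """Choose between compact and disintegrating mask strategies.

    Each image is thresholded independently (MCE) and reduced to its largest
    component.  If any later timepoint's core area falls below
    ``(1 - shrink_tol)`` of the START area — the symptom of rapid
    disintegration — the disintegrating strategy is selected; otherwise
    compact.  With no followups the answer is compact.
    """
    if not dataset.followups:
        return COMPACT
    areas = [
        largest_component(segment_compact(img)).area_px for img in dataset.images
    ]
    start_area = areas[0]
    logger.info(
        "auto mode selection: per-image largest-component areas (px) = %s", areas
    )
    if any(a < (1.0 - shrink_tol) * start_area for a in areas[1:]):
        logger.info("auto mode selection -> %s", DISINTEGRATING)
        return DISINTEGRATING
    logger.info("auto mode selection -> %s", COMPACT)
    return COMPACT


def build_masks(
    dataset: TimeSeriesDataset,
    mode: str = AUTO,
    keep_largest: bool = True,
    threshold_overrides: Mapping[str, float] | None = None,
    shrink_tol: float = DEFAULT_SHRINK_TOL,
) -> list[SpheroidMask]:
    """Compute one core mask per image (START first).

    ``threshold_overrides`` maps timepoint labels to manual thresholds (the
    non-interactive counterpart of the manual mask-adjustment loop; in
    disintegrating mode only the START override has an effect, since followup
    masks are placed by area, not threshold).

    In disintegrating mode with ``keep_largest`` on, the fixed-area property
    of followup masks is intentionally broken: detached bright particles are
    dropped from the core and hence counted as invading material.
    """
    overrides = dict(threshold_overrides or {})
    if mode == AUTO:
        mode = auto_select_mode(dataset, shrink_tol=shrink_tol)
    if mode not in (COMPACT, DISINTEGRATING):
        raise ValueError(f"unknown mode {mode!r}")

    images = dataset.images
    if mode == COMPACT:
        masks = [
            segment_compact(img, overrides.get(img.timepoint_label)) for img in images
        ]
    else:
        start_mask = segment_compact(
            images[0], overrides.get(images[0].timepoint_label)
        )
        target = start_mask.area_px
        start_mask = replace(start_mask, mode=DISINTEGRATING)
        masks = [start_mask] + [fixed_area_mask(img, target) for img in images[1:]]
    if keep_largest:
        masks = [largest_component(m) for m in masks]
    return masks
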