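"""Shared fixtures and independent brute-force oracles.

Every oracle here re-derives the quantity it checks by a route independent of
the package implementation: naive iterative flooding instead of the hybrid
reconstruction algorithm, pure-Python plateau BFS instead of vectorized
regional maxima, exhaustive disk placement instead of erosion, and plain
minimum loops instead of KD-trees.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import ndimage

from spheroidquant.image_io import CalibratedImage

_H_SLACK = 1e-9  # same prominence-equality convention as the implementation


# ---------------------------------------------------------------------------
# minimum cross-entropy oracle


def mce_objective(pixels: np.ndarray, t: float) -> float:
    """Li cross-entropy objective (constant term dropped) for threshold t;
    +inf when a class is empty."""
    flat = np.asarray(pixels, np.float64).ravel()
    bg, fg = flat[flat <= t], flat[flat > t]
    if bg.size == 0 or fg.size == 0:
        return math.inf
    s = 0.0
    if bg.sum() > 0:
        s -= bg.sum() * math.log(bg.mean())
    if fg.sum() > 0:
        s -= fg.sum() * math.log(fg.mean())
    return s


def mce_bruteforce(pixels: np.ndarray, levels=range(256)) -> int:
    """Exhaustive minimization over candidate levels; ties -> smallest."""
    best_t, best = None, math.inf
    for t in levels:
        e = mce_objective(pixels, t)
        if e < best:
            best, best_t = e, t
    assert best_t is not None
    return best_t


# ---------------------------------------------------------------------------
# extended-maxima oracle: naive flooding + plateau BFS


def reconstruct_bruteforce(seed: np.ndarray, ceiling: np.ndarray) -> np.ndarray:
    """Morphological reconstruction by dilation via naive iteration to a
    fixed point (8-connected)."""
    footprint = np.ones((3, 3))
    cur = seed.copy()
    while True:
        nxt = np.minimum(ndimage.grey_dilation(cur, footprint=footprint), ceiling)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def regional_maxima_bruteforce(arr: np.ndarray) -> np.ndarray:
    """Boolean regional-maxima map via pure-Python BFS over equal-value
    plateaus: a plateau is a maximum iff no member pixel has a greater
    8-neighbor."""
    h, w = arr.shape
    visited = np.zeros((h, w), bool)
    out = np.zeros((h, w), bool)
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r0 in range(h):
        for c0 in range(w):
            if visited[r0, c0]:
                continue
            v = arr[r0, c0]
            stack = [(r0, c0)]
            visited[r0, c0] = True
            plateau = []
            is_max = True
            while stack:
                r, c = stack.pop()
                plateau.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if arr[rr, cc] > v:
                        is_max = False
                    elif arr[rr, cc] == v and not visited[rr, cc]:
                        visited[rr, cc] = True
                        stack.append((rr, cc))
            if is_max:
                for r, c in plateau:
                    out[r, c] = True
    return out


def emax_bruteforce(pixels: np.ndarray, dynamic: float) -> list[frozenset]:
    """Extended-maxima component pixel sets via the naive flood route."""
    img = np.asarray(pixels, np.float64)
    rng = img.max() - img.min()
    if rng == 0:
        return []
    h_eff = dynamic * rng * (1.0 - _H_SLACK)
    rec = reconstruct_bruteforce(img - h_eff, img)
    peaks = regional_maxima_bruteforce(rec)
    if peaks.all():
        return []
    lab, n = ndimage.label(peaks, structure=np.ones((3, 3)))
    return [
        frozenset(zip(*np.nonzero(lab == i))) for i in range(1, n + 1)
    ]


def label_grid_components(label_grid: np.ndarray) -> list[frozenset]:
    out = []
    for i in range(1, int(label_grid.max()) + 1):
        coords = np.nonzero(label_grid == i)
        if coords[0].size:
            out.append(frozenset(zip(*coords)))
    return out


# ---------------------------------------------------------------------------
# artifact containment oracle


def can_contain_disk_bruteforce(pixel_set: np.ndarray, radius_px: int) -> bool:
    """Place the digital disk at every object pixel and test containment."""
    pixels = {tuple(p) for p in np.asarray(pixel_set).reshape(-1, 2)}
    r = int(radius_px)
    offsets = [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ]
    for (pr, pc) in pixels:
        if all((pr + dr, pc + dc) in pixels for dr, dc in offsets):
            return True
    return False


# ---------------------------------------------------------------------------
# boundary distance oracle


def distance_bruteforce(point_rc, grid: np.ndarray) -> float:
    """Min Euclidean distance (px) from a point to any boundary pixel of the
    mask; boundary = mask pixel with a 4-neighbor outside the mask (image
    border counts as outside)."""
    h, w = grid.shape
    best = math.inf
    pr, pc = point_rc
    for r in range(h):
        for c in range(w):
            if not grid[r, c]:
                continue
            on_boundary = False
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not grid[rr, cc]:
                    on_boundary = True
                    break
            if on_boundary:
                best = min(best, math.hypot(r - pr, c - pc))
    return best


# ---------------------------------------------------------------------------
# random test-image helpers


def random_blob(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """A random connected blob: thresholded smoothed noise, largest
    component."""
    noise = ndimage.gaussian_filter(rng.normal(size=(size, size)), 3.0)
    grid = noise > np.quantile(noise, 0.7)
    lab, n = ndimage.label(grid, structure=np.ones((3, 3)))
    if n == 0:
        grid = np.zeros((size, size), bool)
        grid[size // 2, size // 2] = True
        return grid
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    return lab == areas.argmax()


def bumpy_image(rng: np.random.Generator, size: int = 64, n_bumps: int | None = None):
    """A smooth test image: ramp background plus 1-6 Gaussian bumps of random
    position, width and height."""
    if n_bumps is None:
        n_bumps = int(rng.integers(1, 7))
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    img = 10.0 + 0.3 * cc + 0.1 * rr
    for _ in range(n_bumps):
        r0, c0 = rng.uniform(5, size - 5, 2)
        sig = rng.uniform(1.5, 4.0)
        amp = rng.uniform(20.0, 120.0)
        img += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig * sig))
    return img


def as_image(pixels: np.ndarray, pixel_size_um: float = 1.0, label: str = "t") -> CalibratedImage:
    return CalibratedImage(
        pixels=pixels, pixel_size_um=pixel_size_um, timepoint_label=label,
        bit_depth=8 if np.asarray(pixels).dtype == np.uint8 else 16,
    )


@pytest.fixture(scope="session")
def presets():
    from spheroidquant.synthetic_fixtures import scenario_presets

    return scenario_presets()


@pytest.fixture(scope="session")
def disintegrating_run(presets):
    """Rendered disintegrating preset with masks built in auto mode (shared
    across tests; everything downstream is deterministic)."""
    from spheroidquant.mask_generation import build_masks
    from spheroidquant.synthetic_fixtures import render_fixture

    dataset, truth = render_fixture(presets["disintegrating_invasion"])
    masks = build_masks(dataset, mode="auto", keep_largest=True)
    return dataset, truth, masks
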