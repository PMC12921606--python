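"""Small shared morphology helpers (no dependencies on other package modules)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: 4-connected structuring element (von Neumann neighborhood).
CROSS = ndimage.generate_binary_structure(2, 1)
#: 8-connected structuring element (Moore neighborhood).
SQUARE3 = ndimage.generate_binary_structure(2, 2)


def disk_element(radius_px: int) -> np.ndarray:
    """Digital disk { (dr, dc) : dr² + dc² <= r² } as a boolean array.

    ``radius_px`` must be >= 0; radius 0 yields the single-pixel element.
    """
    r = int(radius_px)
    if r < 0:
        raise ValueError("radius_px must be >= 0")
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * r


def boundary_mask(grid: np.ndarray) -> np.ndarray:
    """Boundary pixels of a boolean grid: foreground pixels with at least one
    4-connected background neighbor.  Pixels on the image edge count as
    boundary (the outside is treated as background)."""
    grid = np.asarray(grid, dtype=bool)
    if not grid.any():
        return np.zeros_like(grid)
    interior = ndimage.binary_erosion(grid, structure=CROSS, border_value=0)
    return grid & ~interior
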