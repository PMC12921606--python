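# spheroidquant

Quantification of growth and matrix invasion of 3D multicellular spheroids
from 2D fluorescence time-series images.

## The problem

Spheroids grown from tumor cell lines and embedded in extracellular matrix
(collagen, Matrigel) are a standard in-vitro model of invasion. A
fluorescently labeled spheroid is imaged at low magnification right after
embedding (the **START** timepoint, before any migration has occurred) and at
later intervals. Two things are of interest:

* **growth** — the increase of the compact spheroid-core area, and
* **expansion** — the number, area, and spread of objects (single cells or
  detached cell clusters) that appear in the matrix *outside* the core,
  regardless of whether the underlying process is invasion, proliferation, or
  both.

`spheroidquant` turns one START image plus later timepoints (single-channel
8/16-bit TIFF or PNG, with a μm-per-pixel calibration) into per-object and
per-timepoint tables, binary masks, and overlay images.

## The method

1. **Core mask.** Two strategies, selectable or chosen automatically:
   * *compact* — every timepoint is segmented independently by minimum
     cross-entropy (Li) thresholding of the histogram, exhaustively
     minimizing η(t) = −Σ_{g≤t} g·h(g)·ln μ₀ − Σ_{g>t} g·h(g)·ln μ₁
     (foreground strictly above t). Suitable when the spheroid keeps a
     sharp boundary.
   * *disintegrating* — the START image is thresholded, its mask area A is
     recorded, and at each later timepoint a mask of exactly area A is placed
     on the A highest-intensity pixels (deterministic raster-order tie
     breaking at the cut intensity). Suitable when the core boundary is
     rapidly lost; the assumption is that invading single cells are dimmer
     than the core.
   * *auto* — if the independently thresholded, largest-component core area
     at any later timepoint falls below 95 % of the START area (a sign of
     disintegration), the disintegrating strategy is used.
   Optionally (default on) only the largest 8-connected mask component is
   kept, so detached bright particles count as invading material.
2. **Object detection.** Invading objects are the *extended maxima* (EMax) of
   the image: 8-connected regions whose peak rises at least
   h = dynamic × (image intensity range) above the surrounding saddle level —
   a local contrast criterion that tolerates non-constant background. Any
   component touching the mask is attributed to the core and dropped whole.
3. **Artifact exclusion.** A detected object that can fully contain a disk of
   a user-given radius (a bubble or debris, larger than any cell) is flagged
   and excluded from all summary figures, but kept in the detailed table.
4. **Measurements.** Per object: position, area, traced perimeter, shape
   descriptors (circularity 4πA/P², roundness 4A/(πL²), solidity A/A_hull),
   and the Euclidean distance from its centroid (or nearest pixel, with
   `--distance-from edge`) to the nearest mask-boundary pixel. Per image:
   mask area and perimeter, object count (total and per mm of mask
   perimeter), total object area, and mean/median object distances. The
   perimeter is measured on a *smoothed* mask (opening+closing with a disk,
   default detail scale 15 μm) so thin protrusions do not inflate it; areas
   and distances always use the raw mask.

Coordinates are row-major and 0-based; `(x, y)` in every table means
`(column, row)`.

## Worked example

No microscope needed — the package ships a synthetic-scenario generator with
planted ground truth:

```
spheroidquant fixtures --preset disintegrating_invasion --out demo/fix
spheroidquant run --start demo/fix/START.tif --followups demo/fix/24h.tif \
    --pixel-size 2.0 --mode auto --emax-dynamic 0.001 --out demo/out
```

The run log records the automatic mode choice:

```
mode = disintegrating (requested: auto)
[START] mask area = 20533 px, threshold = 10165, target_area_px = None
[START] n_objects = 0, n_excluded_artifacts = 0
[24h] mask area = 11145 px, threshold = n/a, target_area_px = 20533
[24h] n_objects = 80, n_excluded_artifacts = 0
```

and `demo/out/summary.csv` contains one row per timepoint:

```
timepoint_label,mode,mask_area_um2,mask_perimeter_um,n_objects,n_objects_per_mm,total_object_area_um2,mean_distance_um,median_distance_um,...
START,disintegrating,82132,1064.43,0,0,0,,,...
24h,disintegrating,44580,779.98,80,102.567,18456,94.8287,81.2765,...
```

Reading: at START the whole signal is the compact core (area 82 132 μm²,
no objects outside). By 24 h the core has fragmented — the retained largest
component is down to 44 580 μm² — and 80 objects sit in the matrix
(the 20 planted invading cells plus 60 detached core fragments), about
103 objects per mm of mask perimeter, at a mean distance of 94.8 μm from the
core boundary. `24h_objects.csv` lists each object with position, shape
descriptors, and distance; `*_overlay.png` shows the mask boundary in red and
detected objects in green for visual verification. To mimic the interactive
mask-verification loop, re-run with `--threshold 24h=12000`-style overrides
(or `--dry-run-masks` for a fast masks-only pass) until the overlay matches.

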