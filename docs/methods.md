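# Methods

## Scope and model

`spheroidquant` analyzes one spheroid per image, one image per timepoint,
single channel. The model of the assay is deliberately simple: a single
bright, roughly convex core; dimmer punctate objects appearing outside it
over time; optionally large bright artifacts; smoothly varying background.
All decisions below follow from that model.

## Mask generation

**Minimum cross-entropy threshold.** The compact-mode segmentation minimizes
the Li & Lee cross-entropy criterion over the image histogram. The
implementation is an exhaustive, vectorized minimization over every distinct
intensity level that leaves both classes non-empty (the `Σ g·h(g)·ln g` term
is constant in *t* and dropped; `0·ln 0 := 0`). Exhaustive search rather than
the usual fixed-point iteration guarantees the global minimum and a total
ordering: ties break toward the smallest level. Foreground is *strictly*
greater than the threshold.

**Fixed-area mask (disintegrating strategy).** The START threshold defines a
target area A; later masks cover exactly the A brightest pixels. At the cut
intensity, pixels are admitted in raster-scan order (top-left first), which
makes the mask a pure function of the image: exact area, bit-reproducible.
The START mask area is recorded *before* largest-component retention, so the
area target reflects the full thresholded START signal; retention is then
applied to every mask, deliberately breaking the fixed-area property at later
timepoints when bright material has detached (that material becomes
"invading").

**Automatic mode choice.** All followups are inspected (not just the first):
each image is MCE-thresholded and reduced to its largest 8-connected
component; if any followup area is below `(1 − shrink_tol)` × START area the
disintegrating strategy is chosen. `shrink_tol` defaults to 0.05 — small
enough to catch genuine fragmentation (which halves the area in the bundled
scenario) while ignoring segmentation jitter of a stable or growing core
(well under 5 % in practice). The per-image areas and the decision are
logged.

**Connectivity.** 8-connectivity everywhere (component labeling, EMax,
boundary tracing); holes in a mask are 4-connected background, the dual
convention.

## Extended maxima

`h = dynamic × (max − min)` of the *observed* image range, not the bit-depth
range, so the same dynamic transfers between 8- and 16-bit exports. The
components are the regional-maximum plateaus of the h-maxima transform
(grayscale reconstruction by dilation of `image − h` under `image`). The
prominence criterion is inclusive (≥ h): the reconstruction is run with
`h·(1 − 1e−9)` so a peak whose prominence equals h exactly is kept — without
the slack, floating-point reconstruction drops the boundary case (e.g. a
lone peak at `dynamic = 1`, whose prominence is exactly the range). A flat
image yields no components, and a maxima region covering the whole image is
discarded as non-localized. Merged neighboring cells are reported as one
object by design; no watershed splitting is attempted, and no attempt is made
to recover the full fluorescent footprint of an object — the maxima region is
the object.

## Artifact exclusion

An object is an artifact iff the erosion of its pixel set by the digital disk
`{(dr,dc): dr²+dc² ≤ r²}`, `r = round(radius_um / pixel_size_um)` (minimum
1 px), is non-empty — exactly "can contain a disk of that radius". Radius
0 μm disables the test. Flagged objects stay in the per-object table with
`excluded_as_artifact=True` and are removed from every summary figure,
including total object area.

## Measurements

**Perimeter.** Moore-neighbor boundary tracing through pixel centers, axial
steps 1 and diagonal steps √2, summed over every component's outer contour
plus every hole contour. A single pixel traces to 0 (documented degenerate
case). This chain-length convention overestimates an ideal circle by ~5 %
(measured: +4.9 % on a radius-50 digital disk), which is why the mask is
smoothed first and why circularity is capped.

**Smoothing.** Opening then closing with a digital disk of radius
`round(detail_um / 2 / pixel_size_um)` px (min 1). `detail_um` defaults to
15 μm — the midpoint of the 10–20 μm band that separates cell-scale
protrusions from core-scale features at this magnification. The smoothed mask
is used *only* for the perimeter (and the per-mm object normalization);
inside/outside decisions, areas, and distances use the raw mask, so smoothing
can never move an object across the boundary.

**Distances.** Boundary pixels are mask pixels with a 4-connected background
neighbor (image border counts as background). The distance is the Euclidean
distance from the object's centroid to the nearest boundary pixel (KD-tree;
verified against a brute-force scan to 1e−9 px). Centroid reference is the
default because a single per-object position is reported; `--distance-from
edge` switches to the nearest-own-pixel convention for users who prefer gap
distance.

**Shape descriptors.** circularity = 4πA/P² (traced perimeter, capped at
1.0), roundness = 4A/(πL²) with L the moment-ellipse major axis, solidity =
A over the *filled convex hull* area (pixel count of the convex image, which
is exactly 1 for convex pixel sets; a polygon hull through pixel centers
would exceed 1 on digital shapes). Degenerate objects with zero perimeter or
axis report 1.0 by convention.

**Per-perimeter normalization** is objects per millimetre of smoothed mask
perimeter; the unit is part of the column name (`n_objects_per_mm`).

## Synthetic scenarios

The generator renders: background base + linear ramp (columns) + Gaussian
noise (i.i.d., seeded per timepoint); a core as an edge-blurred disk
(σ = 2 μm); invaders as isotropic Gaussian spots (σ = 6 μm ≈ a cell radius,
peak 350 counts — the "signal"); the disintegration phenotype as a shrunken
core plus 60 detached bright fragments (radius 16 μm) on three staggered
rings; optionally one saturated bubble. Noise σ is 3 % of signal
(10.5 counts) and the ramp 20 % of signal (70 counts).

Amplitudes are set so the detection regime matches real widefield data,
where the core dominates the intensity range: with the core at 62 000 counts
on the 16-bit scale, `h` at the recommended dynamic 0.001 is ≈ 62 counts ≈
6 noise σ — far above noise prominences (which rarely exceed ~3σ, since a
flood from any noise peak quickly reaches higher ground) yet far below the
350-count invader amplitude. The fragment load is chosen so the followup's
bright footprint exceeds the START mask area; the fixed-area cut therefore
falls inside the bright class and the retained core boundary tracks the true
(shrunken) core radius to ~1 px, making planted center-to-boundary distances
recoverable.

What the generator does *not* emulate: optics (PSF, vignetting), Poisson
photon statistics (a Poisson option exists but is off by default so oracle
tests stay exact), irregular core shapes, and object motion between
timepoints. Passing tests therefore demonstrate algorithmic correctness
under the stated model, not robustness to every property of real
microscopy data.

Problem sizes used throughout the suite — 384×384 px scenarios, 64×64 oracle
images, 100–200 random cases per brute-force comparison — keep the full test
run and the acceptance script in the tens of seconds while exercising every
code path at sizes where the oracles are exact.

## Numerical and design choices

* Foreground is `> t`, never `≥ t`; all tie rules (fixed-area raster fill,
  largest-component raster-earliest, MCE smallest level) are total orders,
  so every mask and table is bit-reproducible; CSV floats are written with
  6 significant digits.
* The pipeline is seed-free; the only randomness in the package is the
  fixture generator's seeded noise.
* Calibration always comes from the explicit `--pixel-size`/config value.
* Interactive threshold verification is replaced by per-image `--threshold
  LABEL=VALUE` overrides plus always-written overlays; `--dry-run-masks`
  recomputes masks/overlays only.
* An empty mask is legal after an above-maximum override (the caller is
  warned); a constant image is a hard error for thresholding.

## Known limitations

* One spheroid per image; no ROI cropping of neighboring debris fields
  beyond artifact exclusion.
* The EMax object is a maxima region, not a full segmentation, so object
  areas underestimate true fluorescent footprints.
* The disintegrating strategy assumes invading cells are dimmer than the
  core; a followup whose bright content falls below the START mask area will
  see its fixed-area mask spill into background (mitigated by
  largest-component retention).
* The traced-perimeter convention has a known ~5 % upward bias on smooth
  round outlines; comparisons should use a single convention throughout,
  which the package enforces.
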