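"""Synthetic spheroid time series with planted ground truth.

The generator emulates the imaging regime of low-magnification widefield
fluorescence of a labeled spheroid embedded in matrix: a bright, compact core
dominating the intensity range; much dimmer single cells (rendered as
isotropic Gaussian spots) that appear outside the core at later timepoints; an
optional disintegration phenotype in which the core shrinks while shedding
bright detached fragments; optionally a large saturated "bubble" artifact; a
non-constant background (linear ramp); and additive, seeded Gaussian noise.

Amplitudes are chosen so that the recommended detection dynamic works the way
it does on real data: with the core near the top of the 16-bit scale, the
prominence threshold h = dynamic × range at dynamic 0.001 sits about six noise
standard deviations above the floor, so single-cell spots (peak amplitude
"signal" = 350 counts, noise σ = 3 % of that) are detected without false
positives from noise.  The noise is i.i.d. per pixel — there is no optics
simulation (PSF, vignetting), so passing tests demonstrate algorithmic
correctness, not robustness to every microscope artifact.

Geometry is in pixel units (row, col); sizes and distances are in μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import CalibratedImage, TimeSeriesDataset

__all__ = [
    "GaussianSpot",
    "DiskArtifact",
    "Fragmentation",
    "FixtureSpec",
    "TimepointTruth",
    "GroundTruth",
    "render_fixture",
    "scenario_presets",
]

_GOLDEN_ANGLE = 2.399963229728653


@dataclass(frozen=True)
class GaussianSpot:
    """A planted invading cell: isotropic Gaussian intensity bump."""

    center_rc: tuple[float, float]
    peak: float
    sigma_um: float
    timepoint: int


@dataclass(frozen=True)
class DiskArtifact:
    """A planted large bright disk (bubble/debris)."""

    center_rc: tuple[float, float]
    radius_um: float
    intensity: float
    timepoint: int


@dataclass(frozen=True)
class Fragmentation:
    """Disintegration phenotype: detached bright core fragments placed on
    staggered rings around the (shrunken) core at every followup timepoint."""

    count: int = 60
    radius_um: float = 16.0
    intensity: float = 49600.0
    ring_radii_um: tuple[float, ...] = (152.0, 184.0, 216.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of a rendered time series; the seed and the fields
    below determine the output bit-exactly."""

    image_shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 2.0
    timepoint_labels: tuple[str, ...] = ("START", "24h")
    core_center_rc: tuple[float, float] = (192.0, 192.0)
    core_radius_um: tuple[float, ...] = (160.0, 160.0)
    core_intensity: float = 62000.0
    core_edge_sigma_um: float = 2.0
    invaders: tuple[GaussianSpot, ...] = ()
    artifacts: tuple[DiskArtifact, ...] = ()
    background_level: float = 500.0
    background_ramp: float = 70.0
    noise_sigma: float = 10.5
    fragmentation: Fragmentation | None = None
    seed: int = 42
    bit_depth: int = 16


@dataclass
class TimepointTruth:
    """Planted truth for one timepoint."""

    label: str
    core_center_rc: tuple[float, float]
    core_radius_px: float
    core_pixels: np.ndarray
    invader_centers: np.ndarray  # (k, 2) rows/cols
    invader_distances_um: np.ndarray  # (k,) center-to-core-boundary
    fragment_pixels: np.ndarray
    artifact_pixels: np.ndarray


@dataclass
class GroundTruth:
    timepoints: list[TimepointTruth] = field(default_factory=list)


def _radius_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1])


def _soft_disk(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    sigma_px: float,
) -> np.ndarray:
    """Unit-height disk with a Gaussian-smoothed edge."""
    hard = (_radius_grid(shape, center) <= radius_px).astype(np.float64)
    if sigma_px > 0:
        return ndimage.gaussian_filter(hard, sigma_px)
    return hard


def fragment_centers(
    frag: Fragmentation, core_center_rc: tuple[float, float], pixel_size_um: float
) -> list[tuple[float, float]]:
    """Deterministic staggered-ring placement of fragment centers (px)."""
    rings = frag.ring_radii_um
    per_ring = [frag.count // len(rings)] * len(rings)
    for i in range(frag.count - sum(per_ring)):
        per_ring[i] += 1
    centers = []
    for i, (r_um, n) in enumerate(zip(rings, per_ring)):
        r_px = r_um / pixel_size_um
        offset = (i + 0.5) * math.pi / max(n, 1)
        for k in range(n):
            a = offset + 2.0 * math.pi * k / n
            centers.append(
                (
                    core_center_rc[0] + r_px * math.sin(a),
                    core_center_rc[1] + r_px * math.cos(a),
                )
            )
    return centers


def render_fixture(spec: FixtureSpec) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Render the time series described by ``spec`` and its ground truth.

    The START image contains the core only (no invaders — no migration can
    have happened yet); followups add growth/shrinkage, invaders, fragments,
    and artifacts per the spec.  Raises ``ValueError`` if a planted invader
    center lies closer than 3σ to its timepoint's core disk.
    """
    n_t = len(spec.timepoint_labels)
    if len(spec.core_radius_um) != n_t:
        raise ValueError("core_radius_um must give one radius per timepoint")
    px = spec.pixel_size_um
    shape = spec.image_shape
    sigma_edge_px = spec.core_edge_sigma_um / px
    max_val = float(2**spec.bit_depth - 1)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16

    for spot in spec.invaders:
        if spot.timepoint == 0:
            raise ValueError("invaders may not be planted at START")
        r_core = spec.core_radius_um[spot.timepoint] / px
        d = math.hypot(
            spot.center_rc[0] - spec.core_center_rc[0],
            spot.center_rc[1] - spec.core_center_rc[1],
        )
        if d < r_core + 3.0 * spot.sigma_um / px:
            raise ValueError(
                f"invader at {spot.center_rc} overlaps the core "
                f"(center distance {d:.1f} px < core {r_core:.1f} px + 3σ)"
            )

    radius_from_core = _radius_grid(shape, spec.core_center_rc)
    images: list[CalibratedImage] = []
    truth = GroundTruth()
    cols = np.arange(shape[1], dtype=np.float64)
    ramp = spec.background_ramp * (cols / (shape[1] - 1))

    for t, label in enumerate(spec.timepoint_labels):
        r_core_px = spec.core_radius_um[t] / px
        field_ = np.full(shape, spec.background_level, dtype=np.float64) + ramp
        field_ += spec.core_intensity * _soft_disk(
            shape, spec.core_center_rc, r_core_px, sigma_edge_px
        )
        frag_pixels = np.zeros(shape, dtype=bool)
        if spec.fragmentation is not None and t > 0:
            frag = spec.fragmentation
            fr_px = frag.radius_um / px
            for c in fragment_centers(frag, spec.core_center_rc, px):
                field_ += frag.intensity * _soft_disk(shape, c, fr_px, sigma_edge_px)
                frag_pixels |= _radius_grid(shape, c) <= fr_px
        inv_centers, inv_dists = [], []
        for spot in spec.invaders:
            if spot.timepoint != t:
                continue
            sig = spot.sigma_um / px
            d2 = _radius_grid(shape, spot.center_rc) ** 2
            field_ += spot.peak * np.exp(-d2 / (2.0 * sig * sig))
            inv_centers.append(spot.center_rc)
            d = math.hypot(
                spot.center_rc[0] - spec.core_center_rc[0],
                spot.center_rc[1] - spec.core_center_rc[1],
            )
            inv_dists.append((d - r_core_px) * px)
        art_pixels = np.zeros(shape, dtype=bool)
        for art in spec.artifacts:
            if art.timepoint != t:
                continue
            ar_px = art.radius_um / px
            field_ += art.intensity * _soft_disk(shape, art.center_rc, ar_px, sigma_edge_px)
            art_pixels |= _radius_grid(shape, art.center_rc) <= ar_px
        if spec.noise_sigma > 0:
            rng = np.random.default_rng([spec.seed, t])
            field_ = field_ + rng.normal(0.0, spec.noise_sigma, size=shape)
        pixels = np.rint(np.clip(field_, 0.0, max_val)).astype(dtype)
        images.append(
            CalibratedImage(
                pixels=pixels,
                pixel_size_um=px,
                timepoint_label=label,
                bit_depth=spec.bit_depth,
            )
        )
        truth.timepoints.append(
            TimepointTruth(
                label=label,
                core_center_rc=spec.core_center_rc,
                core_radius_px=r_core_px,
                core_pixels=radius_from_core <= r_core_px,
                invader_centers=np.asarray(inv_centers, np.float64).reshape(-1, 2),
                invader_distances_um=np.asarray(inv_dists, np.float64),
                fragment_pixels=frag_pixels,
                artifact_pixels=art_pixels,
            )
        )
    dataset = TimeSeriesDataset(start=images[0], followups=images[1:])
    return dataset, truth


def _spiral_invaders(
    n: int,
    r0_px: float,
    r1_px: float,
    center: tuple[float, float],
    timepoint: int,
    peak: float = 350.0,
    sigma_um: float = 6.0,
    angle0: float = 0.0,
) -> tuple[GaussianSpot, ...]:
    """Golden-angle spiral placement: deterministic, well-separated spots."""
    radii = np.linspace(r0_px, r1_px, n)
    spots = []
    for i in range(n):
        a = angle0 + i * _GOLDEN_ANGLE
        spots.append(
            GaussianSpot(
                center_rc=(
                    center[0] + radii[i] * math.sin(a),
                    center[1] + radii[i] * math.cos(a),
                ),
                peak=peak,
                sigma_um=sigma_um,
                timepoint=timepoint,
            )
        )
    return tuple(spots)


def scenario_presets() -> dict[str, FixtureSpec]:
    """Named fixture scenarios mirroring the phenotypes the assay must
    distinguish.

    ``compact_growth``
        A compactly growing spheroid (sharp boundary throughout, core area
        increasing), with a few late invaders.
    ``disintegrating_invasion``
        A rapidly invading spheroid: the core shrinks by 24 h while shedding
        bright detached fragments, and 20 single cells appear in the matrix.
    ``suppressed_invasion``
        The same spheroid under an invasion-suppressing treatment: fewer
        invaders that have traveled less far.
    ``artifact_bubble``
        ``disintegrating_invasion`` plus one large saturated bubble, for
        exercising artifact exclusion.
    """
    center = (192.0, 192.0)
    compact = FixtureSpec(
        timepoint_labels=("START", "24h", "48h"),
        core_radius_um=(160.0, 192.0, 224.0),
        invaders=(
            _spiral_invaders(5, 135.0, 165.0, center, timepoint=1)
            + _spiral_invaders(8, 140.0, 175.0, center, timepoint=2, angle0=1.1)
        ),
        seed=11,
    )
    disintegrating = FixtureSpec(
        timepoint_labels=("START", "24h"),
        core_radius_um=(160.0, 120.0),
        invaders=_spiral_invaders(20, 126.0, 176.0, center, timepoint=1),
        fragmentation=Fragmentation(),
        seed=42,
    )
    suppressed = replace(
        disintegrating,
        invaders=_spiral_invaders(6, 124.0, 140.0, center, timepoint=1),
    )
    bubble = replace(
        disintegrating,
        artifacts=(
            DiskArtifact(
                center_rc=(48.0, 48.0), radius_um=40.0, intensity=66000.0, timepoint=1
            ),
        ),
    )
    return {
        "compact_growth": compact,
        "disintegrating_invasion": disintegrating,
        "suppressed_invasion": suppressed,
        "artifact_bubble": bubble,
    }
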