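"""Microscopy-side shape morphometrics on binary masks.

For cross-method comparison with the cytometric descriptors, hyphal elements
segmented from micrographs are measured with the classical binary-image
statistics:

* roughness = perimeter² / (4π · area) — 1 for a disk, grows with boundary
  irregularity (the "hairiness" of a pellet's annular region);
* fullness = area / convex area — 1 for convex shapes, drops as the element
  becomes ragged or branched.

Area is the foreground pixel count times the pixel area.  The perimeter is
the length of the sub-pixel boundary polygon (marching-squares contour at
level 0.5), not a pixel-edge count, so a rasterized disk has roughness ≈ 1.
The convex area is the hull of the foreground *pixel corners* (centers
± 0.5 px); because the union of pixel squares is contained in that hull,
fullness ≤ 1 holds for every mask, single pixels included.

The microscopy classification mirrors the cytometric classes via area
thresholds plus two topology cues: small clumps contain skeleton loops
(entangled mycelium), hyphae do not; pellets additionally need a detected
dark core of sufficient area (graylevel input required for core detection —
a pure binary mask never reports a core).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, morphology

from .errors import ValidationError
from .types import MorphClass


@dataclass
class BinaryMask:
    """A segmented element: boolean pixel grid plus spatial calibration."""

    pixels: np.ndarray
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be a 2-D boolean grid")
        if not self.um_per_px > 0:
            raise ValidationError("um_per_px must be positive")


@dataclass(frozen=True)
class ImageMetrics:
    """Shape statistics of one element (areas in μm², lengths in μm)."""

    area: float
    perimeter: float
    convex_area: float
    roughness: float
    fullness: float
    has_core: bool
    core_area: Optional[float]
    skeleton_has_loop: bool


def boundary_perimeter(pixels: np.ndarray, smoothing: int = 2) -> float:
    """Total length of the sub-pixel boundary polygon(s), in pixels.

    Marching-squares contours at level 0.5 on the zero-padded mask, with
    ``smoothing`` rounds of B-spline corner cutting: the raw staircase
    contour overestimates the geometric perimeter of smooth shapes by ~5%,
    and two subdivision rounds bring a rasterized disk within a few percent
    of its true circumference while leaving polygonal shapes essentially
    unchanged.  Interior hole boundaries count toward the perimeter.
    """
    padded = np.pad(pixels.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        for _ in range(smoothing):
            contour = measure.subdivide_polygon(contour, degree=2, preserve_ends=False)
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total


def convex_hull_area(pixels: np.ndarray) -> float:
    """Area of the convex hull of the foreground pixel corners, in px²."""
    rows, cols = np.nonzero(pixels)
    if rows.size == 0:
        raise ValidationError("empty mask")
    # boundary pixels suffice for the hull and keep the point set small
    # (scipy erosion: outside the image counts as background, so border
    # pixels are never treated as interior)
    interior = ndimage.binary_erosion(pixels)
    boundary = pixels & ~interior
    if not boundary.any():
        boundary = pixels
    rows, cols = np.nonzero(boundary)
    pts = np.column_stack([rows, cols]).astype(float)
    corners = np.concatenate(
        [pts + [dr, dc] for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)]
    )
    try:
        return float(ConvexHull(corners).volume)  # 2-D hull "volume" is area
    except QhullError as exc:  # pragma: no cover - corners are never collinear
        raise ValidationError(f"convex hull failed: {exc}") from exc


def skeleton_has_loop(pixels: np.ndarray) -> bool:
    """True iff the topological skeleton of the mask contains a cycle."""
    skel = morphology.skeletonize(pixels)
    if not skel.any():
        return False
    n_components = measure.label(skel, connectivity=2).max()
    euler = measure.euler_number(skel, connectivity=2)
    return (n_components - euler) > 0  # components - euler = number of holes


def detect_dark_core(
    pixels: np.ndarray, graylevel: np.ndarray, core_threshold: float
) -> Optional[np.ndarray]:
    """Largest interior dark region of a graylevel element, or None.

    The core is the largest connected region inside the (eroded) mask whose
    intensity is below ``core_threshold``.  The binarization threshold is
    exposed because illumination and contrast shift it between sessions.
    """
    interior = morphology.erosion(pixels, morphology.disk(2))
    dark = interior & (np.asarray(graylevel, float) < core_threshold)
    if not dark.any():
        return None
    labels = measure.label(dark, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def measure_element(
    mask: BinaryMask,
    graylevel: np.ndarray | None = None,
    core_threshold: float = 0.25,
) -> ImageMetrics:
    """Shape metrics of one connected element.

    ``graylevel`` enables dark-core detection (pellet identification); on a
    pure binary mask ``has_core`` is always False.
    """
    px = mask.pixels
    if not px.any():
        raise ValidationError("empty mask")
    if measure.label(px, connectivity=2).max() != 1:
        raise ValidationError("mask must contain exactly one connected element")

    upp = mask.um_per_px
    n_fg = int(px.sum())
    area = n_fg * upp**2
    perimeter = boundary_perimeter(px) * upp
    convex_area = convex_hull_area(px) * upp**2

    core_area: Optional[float] = None
    has_core = False
    if graylevel is not None:
        core = detect_dark_core(px, graylevel, core_threshold)
        if core is not None:
            has_core = True
            core_area = float(core.sum()) * upp**2

    return ImageMetrics(
        area=area,
        perimeter=perimeter,
        convex_area=convex_area,
        roughness=perimeter**2 / (4.0 * np.pi * area),
        fullness=area / convex_area,
        has_core=has_core,
        core_area=core_area,
        skeleton_has_loop=skeleton_has_loop(px),
    )


# Table of microscopy class limits (μm²)
HYPHAE_AREA_MIN = 100.0
SMALL_CLUMP_AREA_MIN = 1000.0
LARGE_CLUMP_AREA_MIN = 3500.0
PELLET_AREA_MIN = 7500.0
PELLET_CORE_AREA_MIN = 7000.0


def classify_microscopy(
    metrics: ImageMetrics, core_area: float | None = None
) -> MorphClass:
    """Microscopy-side morphological classification by area and topology.

    Pellet: area > 7500 μm², a detected core, core area > 7000 μm².
    Large clump: area > 3500 μm², not a pellet.  In the 1000–3500 μm²
    band the skeleton-loop criterion separates small clumps (loop) from
    hyphae (no loop); hyphae extend down to 100 μm².  Total function —
    anything else is unclassified.
    """
    if core_area is None:
        core_area = metrics.core_area
    area = metrics.area
    has_core = metrics.has_core or core_area is not None
    if area > PELLET_AREA_MIN and has_core and (core_area or 0.0) > PELLET_CORE_AREA_MIN:
        return MorphClass.PELLET
    if area > LARGE_CLUMP_AREA_MIN:
        return MorphClass.LARGE_CLUMP
    if SMALL_CLUMP_AREA_MIN < area <= LARGE_CLUMP_AREA_MIN and metrics.skeleton_has_loop:
        return MorphClass.SMALL_CLUMP
    if HYPHAE_AREA_MIN < area <= LARGE_CLUMP_AREA_MIN and not metrics.skeleton_has_loop:
        return MorphClass.HYPHAE
    return MorphClass.UNCLASSIFIED
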