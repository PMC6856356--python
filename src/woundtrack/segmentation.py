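"""Per-cell segmentation into surface and contour masks.

Cells are segmented by seeded active contours: a small rectangular core around
a manually supplied seed point is expanded by Chan-Vese evolution until it
reaches the cell boundary.  The filled region is the *surface* mask; the
*contour* mask is the boundary band of a stated thickness.  A cruder
whole-image threshold variant is provided for dense scenes where individual
seeding is impractical (components may then be multi-cell clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.segmentation import morphological_chan_vese

from woundtrack.errors import (
    DegenerateContourError,
    ParameterError,
    SegmentationFailure,
)

logger = logging.getLogger(__name__)

#: objects smaller than this many pixels are treated as false detections
DEFAULT_MIN_AREA_PX = 50


@dataclass
class CellMask:
    """Binary pixel mask for one segmented cell (or cluster).

    Parameters
    ----------
    pixels :
        Boolean array, True inside the cell.
    kind :
        ``"surface"`` (all pixels inside the outline) or ``"contour"``
        (boundary band only).
    pixel_size :
        Physical pixel size in µm/px; used to report the area in µm².
    """

    pixels: np.ndarray
    kind: str = "surface"
    cell_id: int = 0
    frame: int = 0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.kind not in ("surface", "contour"):
            raise ParameterError(f"unknown mask kind: {self.kind!r}")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    def centroid(self) -> tuple[float, float]:
        """Centroid as (x, y) in pixel coordinates."""
        rows, cols = np.nonzero(self.pixels)
        if rows.size == 0:
            raise SegmentationFailure("cannot take centroid of empty mask")
        return float(cols.mean()), float(rows.mean())

    def centroid_um(self) -> tuple[float, float]:
        x, y = self.centroid()
        return x * self.pixel_size, y * self.pixel_size


@dataclass
class SeedSpec:
    """Manually selected cell seed: a point expanded into a square core.

    ``core_halfwidth`` is the number of pixels the point is expanded in each
    direction (−x, +x, −y, +y), conventionally between 5 and 15.
    """

    point: tuple[float, float]  # (x, y) in px
    core_halfwidth: int = 5

    def __post_init__(self) -> None:
        if self.core_halfwidth < 1:
            raise ParameterError("core_halfwidth must be >= 1")


def _initial_level_set(shape: tuple[int, int], seed: SeedSpec) -> np.ndarray:
    x, y = seed.point
    col, row = int(round(x)), int(round(y))
    h = seed.core_halfwidth
    if not (0 <= row < shape[0] and 0 <= col < shape[1]):
        raise ParameterError(f"seed point {seed.point} outside image {shape}")
    if row - h < 0 or row + h >= shape[0] or col - h < 0 or col + h >= shape[1]:
        raise ParameterError("seed core rectangle extends outside the image")
    ls = np.zeros(shape, dtype=np.int8)
    ls[row - h : row + h + 1, col - h : col + h + 1] = 1
    return ls


def grow_cell(
    image: np.ndarray,
    seed: SeedSpec,
    max_iterations: int = 200,
    smoothing: int = 1,
    stable_iterations: int = 5,
    pixel_size: float = 1.0,
    cell_id: int = 0,
    frame: int = 0,
) -> CellMask:
    """Grow a surface mask from a seed by Chan-Vese active-contour evolution.

    The evolution runs on a contrast-normalized copy of the image, so the
    result is invariant to uniform intensity scaling.  It stops early once the
    level set is unchanged for ``stable_iterations`` consecutive iterations.
    The returned region is the 4-connected component containing the seed with
    interior holes filled.

    Raises
    ------
    SegmentationFailure
        If the image is constant, or the evolution leaves the seed outside
        the foreground, or the grown region has no boundary (floods the
        whole frame).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("grow_cell expects a single-channel 2D frame")
    ptp = float(np.ptp(image))
    if ptp == 0.0:
        raise SegmentationFailure("constant image: no boundary to evolve to")
    norm = (image - image.min()) / ptp

    ls = _initial_level_set(image.shape, seed)
    unchanged = 0
    for _ in range(max_iterations):
        new_ls = morphological_chan_vese(
            norm, num_iter=1, init_level_set=ls, smoothing=smoothing
        )
        if np.array_equal(new_ls, ls):
            unchanged += 1
            if unchanged >= stable_iterations:
                break
        else:
            unchanged = 0
        ls = new_ls

    fg = ls.astype(bool)
    col, row = int(round(seed.point[0])), int(round(seed.point[1]))
    if not fg[row, col]:
        raise SegmentationFailure("evolution collapsed away from the seed")
    labels = sk_label(fg, connectivity=1)
    region = labels == labels[row, col]
    region = ndi.binary_fill_holes(region)
    if region.sum() >= 0.95 * region.size:
        raise SegmentationFailure("region flooded the frame: no cell boundary")
    return CellMask(region, kind="surface", cell_id=cell_id, frame=frame,
                    pixel_size=pixel_size)


def contour_of(surface: CellMask, thickness_px: int = 1) -> CellMask:
    """Boundary band of a surface mask: surface minus its erosion.

    Raises :class:`DegenerateContourError` when the erosion empties the mask,
    i.e. the requested thickness meets or exceeds the mask inradius.
    """
    if thickness_px < 1:
        raise ParameterError("thickness_px must be >= 1")
    if surface.kind != "surface":
        raise ParameterError("contour_of expects a surface mask")
    if surface.area_px == 0:
        raise ParameterError("surface mask is empty")
    eroded = ndi.binary_erosion(surface.pixels, iterations=thickness_px)
    if not eroded.any():
        raise DegenerateContourError(
            f"thickness {thickness_px} px >= inradius of mask"
        )
    band = surface.pixels & ~eroded
    return CellMask(band, kind="contour", cell_id=surface.cell_id,
                    frame=surface.frame, pixel_size=surface.pixel_size)


def filter_small(
    masks: list[CellMask], min_area_px: int = DEFAULT_MIN_AREA_PX
) -> list[CellMask]:
    """Drop masks whose pixel area is strictly below ``min_area_px``.

    Objects exactly at the threshold are kept.  Order is preserved and every
    exclusion is logged with the cell id and area.
    """
    kept = []
    for m in masks:
        if m.area_px < min_area_px:
            logger.info(
                "excluded object %s (frame %s): area %d px < %d px",
                m.cell_id, m.frame, m.area_px, min_area_px,
            )
        else:
            kept.append(m)
    if len(kept) < len(masks):
        logger.warning("size filter removed %d of %d objects (< %d px)",
                       len(masks) - len(kept), len(masks), min_area_px)
    return kept


def threshold_segment(
    image: np.ndarray,
    threshold: float,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    pixel_size: float = 1.0,
    frame: int = 0,
    connectivity: int = 1,
    fill_holes: bool = True,
) -> list[CellMask]:
    """Whole-image intensity-threshold segmentation.

    Returns connected components of ``image >= threshold`` after the small
    object filter.  Holes are filled by default so a supra-threshold membrane
    rim yields the full cell footprint.  Components may be multi-cell
    clusters; this is intentional for dense recruitment scenes.
    """
    image = np.asarray(image)
    fg = image >= threshold
    if fill_holes:
        fg = ndi.binary_fill_holes(fg)
    labels = sk_label(fg, connectivity=connectivity)
    masks = [
        CellMask(labels == i, kind="surface", cell_id=i, frame=frame,
                 pixel_size=pixel_size)
        for i in range(1, labels.max() + 1)
    ]
    masks = filter_small(masks, min_area_px)
    if not masks:
        logger.warning("threshold %s yielded no components >= %d px",
                       threshold, min_area_px)
    return masks
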