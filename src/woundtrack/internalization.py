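"""Receptor-internalization scoring by gray-level co-occurrence contrast.

A receptor that internalizes redistributes from a smooth plasma-membrane rim
into intracellular puncta.  That change in texture is captured by the contrast
of a gray-level co-occurrence matrix (GLCM) computed over the surface-segmented
cell:

    C = Σ_{i,j} |i − j|² p(i, j)

where p(i, j) is the joint frequency of quantized gray levels i and j at a
fixed pixel offset.  Smooth membranous signal keeps mass near the diagonal
(C small); punctate/vesicular signal puts mass off-diagonal (C large).

Intensities are quantized over the masked region's own min..max, which makes
the score invariant to affine intensity transforms (detector gain and offset).
Only pixel pairs with *both* ends inside the mask are accumulated, so the
score reflects intracellular heterogeneity rather than the cell/background
edge; a zero-fill variant is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from shapely.geometry import LineString, Point

from woundtrack.errors import DataError, NormalizationError, ParameterError
from woundtrack.segmentation import CellMask

logger = logging.getLogger(__name__)

DEFAULT_N_LEVELS = 8
DEFAULT_OFFSET = (0, 1)  # (dy, dx): right neighbor


@dataclass
class CoocMatrix:
    """Normalized gray-level co-occurrence matrix over a masked region."""

    p: np.ndarray
    n_levels: int
    offset: tuple[int, int]
    symmetric: bool
    quantization_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.n_levels, self.n_levels):
            raise ParameterError("co-occurrence matrix shape mismatch")
        if (self.p < 0).any():
            raise ParameterError("co-occurrence frequencies must be >= 0")
        total = self.p.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ParameterError("co-occurrence matrix must sum to 1")


@dataclass
class ContrastResult:
    """Raw and (optionally) normalized contrast for one cell."""

    cell_id: int
    raw_contrast: float
    normalized_contrast: float | None = None
    normalization_mode: str = "none"
    reference_value: float | None = None


def quantize(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    quantization_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Linearly quantize masked intensities to ``n_levels`` gray levels.

    Returns the integer level image (valid inside the mask) and the intensity
    range used.  A constant region maps to level 0 by convention.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    if vals.size == 0:
        raise DataError("empty mask")
    if quantization_range is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = map(float, quantization_range)
    levels = np.zeros(image.shape, dtype=np.intp)
    if hi > lo:
        scaled = (image - lo) / (hi - lo) * n_levels
        levels = np.clip(np.floor(scaled), 0, n_levels - 1).astype(np.intp)
    return levels, (lo, hi)


def cooc_matrix(
    image: np.ndarray,
    mask: CellMask | np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    symmetric: bool = False,
    quantization_range: tuple[float, float] | None = None,
    zero_fill: bool = False,
) -> CoocMatrix:
    """Co-occurrence matrix of a masked cell region.

    Pairs are accumulated for the displacement ``offset = (dy, dx)``; by
    default only pairs with both pixels inside the mask count.  With
    ``zero_fill=True`` out-of-mask pixels are treated as zero intensity
    instead (introducing cell-edge pairs), provided for sensitivity analysis.

    Raises :class:`DataError` if no valid pixel pair exists at the offset.
    """
    pixels = mask.pixels if isinstance(mask, CellMask) else np.asarray(mask, bool)
    image = np.asarray(image, dtype=float)
    if image.shape != pixels.shape:
        raise ParameterError("image and mask shapes differ")
    if zero_fill:
        work = np.where(pixels, image, 0.0)
        levels, qrange = quantize(work, np.ones_like(pixels), n_levels,
                                  quantization_range)
        pair_mask = np.ones_like(pixels)
    else:
        levels, qrange = quantize(image, pixels, n_levels, quantization_range)
        pair_mask = pixels

    dy, dx = offset
    h, w = image.shape
    # source window such that (r+dy, c+dx) stays in bounds
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    if r0 >= r1 or c0 >= c1:
        raise DataError("offset larger than image")
    src_ok = pair_mask[r0:r1, c0:c1]
    dst_ok = pair_mask[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    both = src_ok & dst_ok
    i = levels[r0:r1, c0:c1][both]
    j = levels[r0 + dy : r1 + dy, c0 + dx : c1 + dx][both]
    if i.size == 0:
        raise DataError("no valid in-mask pixel pair at the stated offset")
    counts = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    return CoocMatrix(counts / counts.sum(), n_levels, offset, symmetric, qrange)


def contrast(m: CoocMatrix) -> float:
    """GLCM contrast C = Σ |i − j|² p(i, j).  Dimensionless, in [0, (N−1)²]."""
    idx = np.arange(m.n_levels)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float((diff2 * m.p).sum())


def cell_contrast(image: np.ndarray, mask: CellMask | np.ndarray,
                  **cooc_kwargs) -> float:
    """Convenience: contrast of a masked cell in one call."""
    return contrast(cooc_matrix(image, mask, **cooc_kwargs))


def quality_gate(
    image: np.ndarray,
    mask: CellMask | np.ndarray,
    saturation_value: float | None = None,
    max_saturated_frac: float = 0.01,
    min_distinct_levels: int = 4,
    n_levels: int = DEFAULT_N_LEVELS,
) -> tuple[bool, str | None]:
    """Configurable stand-in for the manual exclusion of unreliable cells.

    Rejects cells that are overly bright (more than ``max_saturated_frac`` of
    pixels at the saturation value) or overly dim (masked intensities occupy
    fewer than ``min_distinct_levels`` of the ``n_levels`` quantization bins).
    Returns ``(ok, reason)``; rejections are logged by the pipeline.
    """
    pixels = mask.pixels if isinstance(mask, CellMask) else np.asarray(mask, bool)
    image = np.asarray(image)
    vals = image[pixels]
    if vals.size == 0:
        return False, "empty mask"
    if saturation_value is None:
        saturation_value = (
            np.iinfo(image.dtype).max if np.issubdtype(image.dtype, np.integer)
            else None
        )
    if saturation_value is not None:
        frac = float((vals >= saturation_value).mean())
        if frac > max_saturated_frac:
            return False, f"saturated ({frac:.1%} of pixels)"
    levels, _ = quantize(image, pixels, n_levels)
    if np.unique(levels[pixels]).size < min_distinct_levels:
        return False, f"dynamic range < {min_distinct_levels} levels"
    return True, None


def normalize_contrast(
    values: list[ContrastResult],
    mode: str,
    reference_cells: list[ContrastResult] | None = None,
) -> list[ContrastResult]:
    """Normalize raw contrasts to a stated reference.

    ``cht_mean`` divides by the mean raw contrast of reference cells
    (non-mobilized cells in the CHT of the same movie); ``movie_max`` divides
    by the maximum raw contrast over the movie; ``none`` passes through.
    """
    if mode == "none":
        return [
            ContrastResult(v.cell_id, v.raw_contrast, v.raw_contrast,
                           "none", 1.0)
            for v in values
        ]
    if mode == "cht_mean":
        if not reference_cells:
            raise NormalizationError("cht_mean mode requires reference cells")
        ref = float(np.mean([r.raw_contrast for r in reference_cells]))
    elif mode == "movie_max":
        if not values:
            return []
        ref = float(max(v.raw_contrast for v in values))
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise NormalizationError(f"zero normalization divisor in mode {mode!r}")
    return [
        ContrastResult(v.cell_id, v.raw_contrast, v.raw_contrast / ref,
                       mode, ref)
        for v in values
    ]


# ---------------------------------------------------------------------------
# gradient profiling against the wound margin
# ---------------------------------------------------------------------------

def as_polyline(margin) -> LineString:
    if isinstance(margin, LineString):
        return margin
    return LineString(np.asarray(margin, dtype=float))


def distances_to_margin(points: np.ndarray, margin) -> np.ndarray:
    """Min Euclidean distance (µm) from each (x, y) point to the margin polyline."""
    line = as_polyline(margin)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([line.distance(Point(p)) for p in pts])


def gradient_profile(
    centroids: np.ndarray,
    contrasts: np.ndarray,
    wound_margin,
    bin_width_um: float = 25.0,
    max_distance_um: float | None = None,
) -> pd.DataFrame:
    """Binned mean ± SEM of normalized contrast vs distance from the margin.

    Each cell (or clustered-cell component) is assigned the minimum distance
    from its centroid to the wound-margin polyline, then binned at
    ``bin_width_um``.  SEM is across cells within a bin and reported only
    for n ≥ 2.  Returns columns bin_lo, bin_hi, distance_um (bin center),
    mean, sem, n.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    d = distances_to_margin(centroids, wound_margin)
    if d.size == 0:
        raise DataError("gradient_profile needs at least one cell")
    top = max_distance_um if max_distance_um is not None else d.max()
    n_bins = max(1, int(np.ceil((top + 1e-9) / bin_width_um)))
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = contrasts[idx == b]
        if (idx == b).sum() == 0:
            continue
        sem = float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size >= 2 else np.nan
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "distance_um": 0.5 * (edges[b] + edges[b + 1]),
            "mean": float(sel.mean()), "sem": sem, "n": int(sel.size),
        })
    return pd.DataFrame(rows)


def fit_decay_length(
    distances: np.ndarray, values: np.ndarray, l0: float = 100.0
) -> tuple[float, float]:
    """Fit values ≈ A·exp(−d/L); returns (L, A).

    Used to read a decay length off a contrast-vs-distance profile.
    """
    distances = np.asarray(distances, float)
    values = np.asarray(values, float)
    ok = np.isfinite(distances) & np.isfinite(values)
    if ok.sum() < 3:
        raise DataError("need >= 3 points to fit a decay length")

    def model(d, a, ell):
        return a * np.exp(-d / ell)

    popt, _ = curve_fit(model, distances[ok], values[ok],
                        p0=[values[ok].max(), l0],
                        bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=10000)
    return float(popt[1]), float(popt[0])


# ---------------------------------------------------------------------------
# ratiometric and uptake metrics
# ---------------------------------------------------------------------------

def membrane_ratio(gfp_image: np.ndarray, cfp_image: np.ndarray,
                   contour: CellMask | np.ndarray) -> float:
    """Expression-normalized membrane receptor level.

    Ratio of mean receptor-GFP to mean control membrane-CFP on the contour
    mask, divided by the same ratio over the whole (unmasked) image.  The
    double ratio cancels expression-level differences between embryos: a cell
    whose receptor is uniformly scaled scores 1.0 regardless of the scale.
    """
    pixels = contour.pixels if isinstance(contour, CellMask) else np.asarray(contour, bool)
    gfp = np.asarray(gfp_image, float)
    cfp = np.asarray(cfp_image, float)
    if not pixels.any():
        raise ParameterError("contour mask is empty")
    cfp_masked = cfp[pixels].mean()
    cfp_global = cfp.mean()
    gfp_global = gfp.mean()
    if cfp_masked == 0 or cfp_global == 0 or gfp_global == 0:
        raise NormalizationError("zero denominator in membrane ratio")
    masked_ratio = gfp[pixels].mean() / cfp_masked
    global_ratio = gfp_global / cfp_global
    return float(masked_ratio / global_ratio)


def uptake_score(
    gfp_mask: CellMask | np.ndarray,
    mcherry_image: np.ndarray,
    transplant_roi,
) -> float:
    """Chemokine uptake: mean ligand-mCherry inside the cell mask, normalized
    to the mean mCherry of a transplant reference window (150×150 px by
    convention) to absorb expression variation across embryos.

    ``transplant_roi`` is either a boolean mask or ``(row0, col0, height,
    width)`` in pixels.
    """
    pixels = gfp_mask.pixels if isinstance(gfp_mask, CellMask) else np.asarray(gfp_mask, bool)
    img = np.asarray(mcherry_image, float)
    if not pixels.any():
        raise ParameterError("GFP mask is empty")
    if isinstance(transplant_roi, np.ndarray) and transplant_roi.dtype == bool:
        roi_vals = img[transplant_roi]
    else:
        r0, c0, h, w = transplant_roi
        roi_vals = img[r0 : r0 + h, c0 : c0 + w].ravel()
    if roi_vals.size == 0:
        raise ParameterError("transplant ROI is empty")
    ref = float(roi_vals.mean())
    if ref == 0:
        raise NormalizationError("transplant ROI mean intensity is zero")
    return float(img[pixels].mean() / ref)
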