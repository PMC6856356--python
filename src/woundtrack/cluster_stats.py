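"""Wound recruitment counts and neutrophil cluster sizes.

Recruitment is counted as the number of cell centroids inside an axis-aligned
200 × 200 µm square centered on the wound.  Cluster size is the mean area of
segmented objects after dropping surfaces below 60 µm² (segmentation
artefacts), averaged across all retained object-frame observations in a
stated time window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.measure import find_contours, label as sk_label

from woundtrack.errors import ParameterError, WoundtrackError

logger = logging.getLogger(__name__)

RECRUITMENT_HALFWIDTH_UM = 100.0  # 200x200 um square
MIN_CLUSTER_AREA_UM2 = 60.0


def recruitment_count(
    centroids: pd.DataFrame,
    wound_center: tuple[float, float],
    half_width_um: float = RECRUITMENT_HALFWIDTH_UM,
) -> pd.Series:
    """Centroids inside the square around the wound, per frame.

    ``centroids`` needs columns frame, x_um, y_um.  Square membership is
    closed: a centroid exactly on the boundary counts.
    """
    cx, cy = wound_center
    df = centroids.copy()
    inside = (
        (df["x_um"] - cx).abs() <= half_width_um
    ) & ((df["y_um"] - cy).abs() <= half_width_um)
    counts = df[inside].groupby("frame").size()
    all_frames = df["frame"].unique()
    return counts.reindex(sorted(all_frames), fill_value=0).rename("count")


def cluster_size(
    records: pd.DataFrame,
    min_area_um2: float = MIN_CLUSTER_AREA_UM2,
    window: tuple[float, float] | None = None,
    time_col: str = "frame",
    per_frame_mean: bool = False,
) -> float | None:
    """Mean object area (µm²) for a cohort over a time window.

    Areas strictly below ``min_area_um2`` are dropped (objects exactly at the
    threshold are kept).  By default the mean runs across all retained
    object-frame observations; ``per_frame_mean=True`` first averages within
    each frame.  Returns None (with a warning) if nothing is retained.
    """
    df = records.copy()
    if window is not None:
        lo, hi = window
        df = df[(df[time_col] >= lo) & (df[time_col] <= hi)]
        if df.empty:
            logger.warning("cluster_size: window %s has no data", window)
            return None
    dropped = df[df["area_um2"] < min_area_um2]
    for _, row in dropped.iterrows():
        logger.info("cluster_size: dropped object area %.1f um2 < %.1f um2",
                    row["area_um2"], min_area_um2)
    df = df[df["area_um2"] >= min_area_um2]
    if df.empty:
        logger.warning("cluster_size: nothing retained above %.1f um2",
                       min_area_um2)
        return None
    if per_frame_mean:
        return float(df.groupby(time_col)["area_um2"].mean().mean())
    return float(df["area_um2"].mean())


def owa_from_time_projection(
    frames: np.ndarray,
    threshold: float,
    min_area_px: int = 50,
    pixel_size: float = 1.0,
) -> Polygon:
    """Candidate owa polygon from a maximum-intensity time projection.

    High-density neutrophil areas persist across frames and stand out in the
    projection; the largest connected supra-threshold component's outline is
    returned as a polygon in µm.  The result is a *candidate* — the final owa
    remains user-editable.

    Raises :class:`WoundtrackError` if no component reaches ``min_area_px``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ParameterError("expected a (T, H, W) frame stack")
    proj = frames.max(axis=0)
    labels = sk_label(proj >= threshold, connectivity=1)
    if labels.max() == 0:
        raise WoundtrackError("time projection has no supra-threshold pixels")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area_px:
        raise WoundtrackError(
            f"largest component {sizes[best - 1]} px below the "
            f"{min_area_px} px area floor"
        )
    component = labels == best
    contours = find_contours(component.astype(float), 0.5)
    outline = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y) in um
    xy = np.column_stack([outline[:, 1], outline[:, 0]]) * pixel_size
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly
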