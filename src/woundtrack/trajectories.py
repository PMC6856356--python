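"""Track ingestion, forward/reverse classification and motility statistics.

All geometry is referenced to the *occupied wound area* (owa), the polygon
covered by the neutrophil cluster at the wound.  For each consecutive pair of
track points the module derives an instantaneous speed v_t (µm/min), the
distance d_t from the step's start point to the nearest owa-perimeter point
(0 inside the owa), and the approach-angle cosine cos θ_t between the step
displacement and the vector from the start point to that nearest perimeter
point (+1 toward the owa, −1 away).

Tracks are classified against the owa:

* ``forward_intersecting`` — started outside, entered the owa; the forward
  segment runs from the first point to the last point before first entry
  (in-owa points are excluded from forward statistics).
* ``reverse`` — left the owa after residing there; the reverse segment runs
  from the last in-owa point to the track end.  A track can contribute both
  a forward and a reverse segment.
* ``forward_nonintersecting`` / ``away_nonintersecting`` — never intersected;
  split by whether the end point is closer to the owa than the start.

Net reverse traffic = (# reverse segments) / (# owa-intersecting forward
tracks); non-intersecting tracks are excluded from both counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points

from woundtrack.errors import DataError, ParameterError

logger = logging.getLogger(__name__)

MIN_TRACK_POINTS = 3  # duration threshold: exclude short-lived tracks
STRAIGHTNESS_ZONE_UM = 50.0
STRAIGHTNESS_MIN_PATH_UM = 10.0
COSINE_ZONE_UM = 50.0

#: classifier categories
FORWARD_INTERSECTING = "forward_intersecting"
REVERSE = "reverse"
FORWARD_NONINTERSECTING = "forward_nonintersecting"
AWAY_NONINTERSECTING = "away_nonintersecting"
UNCLASSIFIED_INSIDE = "unclassified_inside"

#: generator ground-truth label -> classifier category
LABEL_TO_CATEGORY = {
    "forward_intersecting": FORWARD_INTERSECTING,
    "forward_then_reverse": REVERSE,
    "nonintersecting_toward": FORWARD_NONINTERSECTING,
    "nonintersecting_away": AWAY_NONINTERSECTING,
}


@dataclass
class Track:
    """Ordered (t, x, y) samples for one cell, in seconds and µm."""

    track_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise DataError(f"track {self.track_id}: ragged columns")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.x)) \
                or not np.all(np.isfinite(self.y)):
            raise DataError(f"track {self.track_id}: non-finite coordinates")
        if len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise DataError(f"track {self.track_id}: non-monotone time")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TrackClassification:
    track_id: int
    category: str
    forward_segment: tuple[int, int] | None = None  # inclusive point indices
    reverse_segment: tuple[int, int] | None = None
    intersected: bool = False


def owa_from_vertices(vertices) -> Polygon:
    """Build the owa polygon from an ordered vertex list (µm)."""
    poly = Polygon(np.asarray(vertices, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ParameterError("owa polygon must be simple with positive area")
    return poly


def load_tracks(
    source,
    min_duration: int = MIN_TRACK_POINTS,
    fin_polygon: Polygon | None = None,
) -> list[Track]:
    """Load tracks from a spot-export CSV (track_id, t_s, x_um, y_um).

    Points outside the fin polygon (when given) are dropped first — movement
    in the CHT is excluded — then tracks shorter than ``min_duration`` time
    points are removed.  The three-point default excludes short-lived tracks.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        try:
            df = pd.read_csv(source)
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise DataError(f"cannot parse tracks CSV {source}: {exc}") from exc
    required = {"track_id", "t_s", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise DataError(
            f"tracks table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    bad = df[["t_s", "x_um", "y_um"]].apply(
        lambda c: ~np.isfinite(pd.to_numeric(c, errors="coerce"))
    )
    if bad.to_numpy().any():
        line = int(bad.any(axis=1).idxmax()) + 2  # 1-based incl. header
        raise DataError(f"malformed row near line {line} of tracks table")

    tracks: list[Track] = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(float)
        x = g["x_um"].to_numpy(float)
        y = g["y_um"].to_numpy(float)
        if fin_polygon is not None:
            keep = np.array(
                [fin_polygon.covers(Point(px, py)) for px, py in zip(x, y)]
            )
            t, x, y = t[keep], x[keep], y[keep]
        if len(t) < min_duration:
            logger.info("track %s excluded: %d < %d time points",
                        tid, len(t), min_duration)
            continue
        tracks.append(Track(tid, t, x, y))
    return tracks


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _inside(owa: Polygon, p) -> bool:
    # boundary counts as inside (closed polygon)
    return owa.covers(Point(p))


def distance_to_owa(owa: Polygon, p) -> float:
    """Distance to the nearest owa-perimeter point; 0 for points inside."""
    pt = Point(p)
    if owa.covers(pt):
        return 0.0
    return float(owa.exterior.distance(pt))


def nearest_perimeter_point(owa: Polygon, p) -> np.ndarray:
    q = nearest_points(owa.exterior, Point(p))[0]
    return np.array([q.x, q.y])


def classify_track(track: Track, owa: Polygon) -> TrackClassification:
    """Classify one track against the owa.

    Points on the polygon boundary count as inside.  A track entirely inside
    the owa that never exits is reported ``unclassified_inside``.
    """
    pts = track.points
    inside = np.array([_inside(owa, p) for p in pts])
    if inside.any():
        first_in = int(np.argmax(inside))
        last_in = int(len(inside) - 1 - np.argmax(inside[::-1]))
        forward = (0, first_in - 1) if first_in > 0 else None
        reverse = (last_in, len(pts) - 1) if last_in < len(pts) - 1 else None
        if forward is None and reverse is None:
            return TrackClassification(track.track_id, UNCLASSIFIED_INSIDE,
                                       intersected=True)
        category = REVERSE if reverse is not None else FORWARD_INTERSECTING
        return TrackClassification(track.track_id, category, forward, reverse,
                                   intersected=True)
    d_start = distance_to_owa(owa, pts[0])
    d_end = distance_to_owa(owa, pts[-1])
    category = FORWARD_NONINTERSECTING if d_end < d_start \
        else AWAY_NONINTERSECTING
    return TrackClassification(track.track_id, category, intersected=False)


def step_records(
    track: Track,
    owa: Polygon,
    classification: TrackClassification | None = None,
) -> pd.DataFrame:
    """Per-step derived quantities for one track.

    One row per consecutive point pair, indexed by the step's start point:
    v_um_min, d_um, cos_theta (NaN when the start is inside the owa or the
    displacement is zero), inside_owa, and the phase implied by the forward/
    reverse segments of the classification.
    """
    if len(track) < 2:
        raise DataError("step_records needs >= 2 points")
    if classification is None:
        classification = classify_track(track, owa)
    pts = track.points
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise DataError(f"track {track.track_id}: non-positive time step")
    disp = np.diff(pts, axis=0)
    step_len = np.hypot(disp[:, 0], disp[:, 1])
    v = step_len / dt * 60.0  # µm/min

    n = len(pts) - 1
    d = np.empty(n)
    cos_theta = np.full(n, np.nan)
    inside = np.zeros(n, dtype=bool)
    for i in range(n):
        p0 = pts[i]
        if _inside(owa, p0):
            inside[i] = True
            d[i] = 0.0
            continue
        d[i] = distance_to_owa(owa, p0)
        if step_len[i] == 0:
            continue
        to_owa = nearest_perimeter_point(owa, p0) - p0
        norm = np.hypot(*to_owa)
        if norm == 0:
            continue
        cos_theta[i] = float(np.dot(disp[i], to_owa) / (step_len[i] * norm))
    cos_theta = np.clip(cos_theta, -1.0, 1.0)

    phase = np.full(n, "unclassified", dtype=object)
    if classification.forward_segment is not None:
        a, b = classification.forward_segment
        phase[a : b] = "forward"  # steps whose start AND end lie in segment
    if classification.reverse_segment is not None:
        a, b = classification.reverse_segment
        phase[a : b] = "reverse"

    return pd.DataFrame({
        "track_id": track.track_id,
        "t_s": track.t[:-1],
        "v_um_min": v,
        "d_um": d,
        "cos_theta": cos_theta,
        "inside_owa": inside,
        "phase": phase,
        "category": classification.category,
    })


def cohort_steps(
    tracks: list[Track], owa: Polygon,
    classifications: list[TrackClassification] | None = None,
) -> pd.DataFrame:
    """Concatenated step records for a track cohort."""
    if classifications is None:
        classifications = [classify_track(tr, owa) for tr in tracks]
    frames = [step_records(tr, owa, cl)
              for tr, cl in zip(tracks, classifications)]
    if not frames:
        return pd.DataFrame(columns=["track_id", "t_s", "v_um_min", "d_um",
                                     "cos_theta", "inside_owa", "phase",
                                     "category"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# binned profiles
# ---------------------------------------------------------------------------

def _binned_profile(df: pd.DataFrame, value_col: str, bin_col: str,
                    bin_edges: np.ndarray, aggregation: str) -> pd.DataFrame:
    edges = np.asarray(bin_edges, dtype=float)
    work = df[[bin_col, value_col, "track_id"]].dropna(subset=[bin_col, value_col])
    idx = np.digitize(work[bin_col].to_numpy(), edges) - 1
    work = work.assign(_bin=idx)
    work = work[(idx >= 0) & (idx < len(edges) - 1)]
    if aggregation == "per_cell":
        work = (work.groupby(["_bin", "track_id"], as_index=False)[value_col]
                .mean())
    elif aggregation != "per_step":
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    rows = []
    for b, g in work.groupby("_bin"):
        vals = g[value_col].to_numpy()
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 \
            else np.nan
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "bin_center": 0.5 * (edges[b] + edges[b + 1]),
            "mean": float(vals.mean()), "sem": sem, "n": int(vals.size),
        })
    return pd.DataFrame(rows).sort_values("bin_lo").reset_index(drop=True) \
        if rows else pd.DataFrame(
            columns=["bin_lo", "bin_hi", "bin_center", "mean", "sem", "n"])


def _scope_filter(steps: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "all":
        return steps
    if scope == "forward_all":
        # forward segments of intersecting tracks plus every step of
        # toward-moving non-intersecting tracks
        return steps[(steps["phase"] == "forward")
                     | (steps["category"] == FORWARD_NONINTERSECTING)]
    if scope == "reverse":
        return steps[steps["phase"] == "reverse"]
    raise ParameterError(f"unknown scope {scope!r}")


def speed_vs_distance(
    steps: pd.DataFrame,
    bin_edges=None,
    scope: str = "forward_all",
    aggregation: str = "per_step",
) -> pd.DataFrame:
    """Mean ± SEM of instantaneous speed per distance-from-owa bin.

    ``aggregation='per_cell'`` first averages within each track per bin
    (error bars then span cells rather than cell steps).  Default bins are
    25 µm wide.
    """
    work = _scope_filter(steps, scope)
    if work.empty:
        logger.warning("speed_vs_distance: no steps in scope %r", scope)
        return _binned_profile(work, "v_um_min", "d_um", [0, 1], "per_step")
    if bin_edges is None:
        top = float(np.ceil(work["d_um"].max() / 25.0)) * 25.0 or 25.0
        bin_edges = np.arange(0.0, top + 25.0, 25.0)
    return _binned_profile(work, "v_um_min", "d_um", bin_edges, aggregation)


def speed_vs_cosine(
    steps: pd.DataFrame,
    bin_edges=None,
    zone_um: float = COSINE_ZONE_UM,
    scope: str = "forward_all",
    aggregation: str = "per_step",
) -> pd.DataFrame:
    """Mean ± SEM of speed per cos θ bin within a zone near the owa.

    Only steps starting within (0, zone_um] of the owa perimeter and with a
    defined cos θ are used.  Default bins are 0.25 wide over [−1, 1].
    """
    if bin_edges is None:
        bin_edges = np.linspace(-1.0, 1.0, 9)
    work = _scope_filter(steps, scope)
    work = work[(work["d_um"] > 0) & (work["d_um"] <= zone_um)
                & work["cos_theta"].notna()]
    if work.empty:
        logger.warning("speed_vs_cosine: no steps with defined cos theta "
                       "within %s um", zone_um)
    # make the top bin closed so cos=1 lands in the last bin
    edges = np.asarray(bin_edges, dtype=float).copy()
    edges[-1] = np.nextafter(edges[-1], np.inf)
    prof = _binned_profile(work, "v_um_min", "cos_theta", edges, aggregation)
    if not prof.empty:
        prof["bin_hi"] = np.minimum(prof["bin_hi"], 1.0)
        prof["bin_center"] = 0.5 * (prof["bin_lo"] + prof["bin_hi"])
    return prof


# ---------------------------------------------------------------------------
# track-level statistics
# ---------------------------------------------------------------------------

@dataclass
class StraightnessResult:
    track_id: int
    straightness: float | None
    excluded_reason: str | None = None


def straightness(
    track: Track,
    owa: Polygon,
    zone_um: float = STRAIGHTNESS_ZONE_UM,
    min_path_um: float = STRAIGHTNESS_MIN_PATH_UM,
) -> StraightnessResult:
    """Track straightness S = net displacement / cumulative path length.

    Restricted to points within ``zone_um`` of the owa (in-owa points count
    as distance 0), in temporal order.  1 = direct migration, 0 = closed
    wandering.  Tracks whose restricted cumulative path is below
    ``min_path_um`` are excluded as insufficient movement, as are tracks with
    fewer than two in-zone points.
    """
    pts = track.points
    d = np.array([distance_to_owa(owa, p) for p in pts])
    zone = pts[d <= zone_um]
    if len(zone) < 2:
        return StraightnessResult(track.track_id, None, "fewer than 2 points in zone")
    seg = np.diff(zone, axis=0)
    path = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if path < min_path_um:
        return StraightnessResult(track.track_id, None,
                                  f"path {path:.2f} um < {min_path_um} um")
    net = float(np.hypot(*(zone[-1] - zone[0])))
    return StraightnessResult(track.track_id, net / path)


def net_reverse_traffic(
    classifications: list[TrackClassification],
) -> float | None:
    """Reverse segments over owa-intersecting forward tracks.

    The denominator counts tracks with a forward segment that intersected the
    owa (tracks that also produced a reverse segment still count); the
    numerator counts reverse segments.  Non-intersecting tracks are excluded
    from both.  Returns None (with a warning) when no forward-intersecting
    track exists.
    """
    n_forward = sum(
        1 for c in classifications
        if c.intersected and c.forward_segment is not None
    )
    n_reverse = sum(1 for c in classifications if c.reverse_segment is not None)
    if n_forward == 0:
        logger.warning("net reverse traffic undefined: no forward-"
                       "intersecting tracks")
        return None
    return n_reverse / n_forward


def speed_within_owa(steps: pd.DataFrame, group_col: str | None = None):
    """Mean ± SEM of speed over steps starting inside the owa.

    With ``group_col`` (e.g. a larva/cohort column) returns one row per
    group; otherwise a single (mean, sem, n) tuple.  Returns None when no
    in-owa step exists.
    """
    inside = steps[steps["inside_owa"]]
    if inside.empty:
        logger.warning("speed_within_owa: no steps inside the owa")
        return None
    if group_col is None:
        vals = inside["v_um_min"].to_numpy()
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 \
            else np.nan
        return float(vals.mean()), sem, int(vals.size)
    out = inside.groupby(group_col)["v_um_min"].agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size"
    )
    return out.reset_index()


def cohort_summary(
    classifications: list[TrackClassification],
    straightness_results: list[StraightnessResult] | None = None,
) -> dict:
    """Counts per category, net reverse traffic and straightness quantiles."""
    counts: dict[str, int] = {}
    for c in classifications:
        counts[c.category] = counts.get(c.category, 0) + 1
    nrt = net_reverse_traffic(classifications)
    summary = {
        "n_tracks": len(classifications),
        "category_counts": counts,
        "n_forward_intersecting": sum(
            1 for c in classifications
            if c.intersected and c.forward_segment is not None
        ),
        "n_reverse_segments": sum(
            1 for c in classifications if c.reverse_segment is not None
        ),
        "net_reverse_traffic": nrt,
    }
    if straightness_results is not None:
        vals = [r.straightness for r in straightness_results
                if r.straightness is not None]
        summary["n_straightness_included"] = len(vals)
        summary["n_straightness_excluded"] = len(straightness_results) - len(vals)
        if vals:
            q = np.quantile(vals, [0.25, 0.5, 0.75])
            summary["straightness_quartiles"] = [float(v) for v in q]
    return summary
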