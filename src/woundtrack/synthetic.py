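"""Synthetic fluorescence scenes and trajectories with known ground truth.

Two kinds of phantom are generated:

* **Cell phantoms** — a single cell whose total fluorescence is split between
  a smoothly shaded membrane ring and a set of interior Gaussian puncta
  according to a *vesicular fraction* in [0, 1].  The integrated cell flux is
  independent of the split, so downstream contrast comparisons measure
  texture, not brightness.  A fraction of 0 emulates a membrane-resident
  receptor, a fraction of 1 a fully internalized (vesicular) one.
* **Gradient scenes** — many cells placed at varying distances from a wound
  margin, with the true vesicular fraction decaying as exp(−d/λ), emulating
  ligand-driven internalization within ~200 µm of a wound.

Trajectories are biased persistent random walks: the heading is drawn from a
von Mises distribution centered on the previous heading (persistence) or, when
within a bias range of the occupied wound area (owa), on the direction to the
nearest owa-perimeter point with concentration κ.  Walkers that reach the owa
dwell there and, with probability ``p_reverse``, leave again and perform an
unbiased walk — giving ground-truth forward/reverse labels for the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points

from woundtrack.errors import ParameterError, PlacementError

#: ground-truth track labels
FORWARD_INTERSECTING = "forward_intersecting"
FORWARD_THEN_REVERSE = "forward_then_reverse"
NONINTERSECTING_TOWARD = "nonintersecting_toward"
NONINTERSECTING_AWAY = "nonintersecting_away"


# ---------------------------------------------------------------------------
# phantom images
# ---------------------------------------------------------------------------

@dataclass
class ScenePhantomParams:
    """Parameters of a single-cell fluorescence phantom.

    Total cell flux is fixed; a constant ``cytosol_fraction`` of it forms a
    diffuse interior pool and ``vesicular_fraction`` sets how the remaining
    receptor pool is split between interior puncta (internalized) and the
    membrane ring (surface-resident).  ``noise_model`` is ``("none",)``,
    ``("gaussian", sigma_frac_of_peak)`` or ``("poisson", scale)``.
    """

    image_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.5  # µm/px
    cell_radius: float = 5.0  # µm
    membrane_thickness: float = 0.75  # µm
    vesicle_count: int = 12
    vesicle_sigma: float = 0.3  # µm
    vesicular_fraction: float = 0.0
    cytosol_fraction: float = 0.25  # diffuse cytosolic pool, vf-independent
    total_flux: float = 5e5  # integrated cell counts
    background_level: float = 100.0
    noise_model: tuple = ("poisson", 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vesicular_fraction <= 1.0:
            raise ParameterError("vesicular_fraction must be in [0, 1]")
        if not 0.0 <= self.cytosol_fraction < 1.0:
            raise ParameterError("cytosol_fraction must be in [0, 1)")
        if self.cell_radius <= 0 or self.membrane_thickness <= 0:
            raise ParameterError("cell geometry must be positive")
        if self.noise_model[0] not in ("none", "gaussian", "poisson"):
            raise ParameterError(f"unknown noise model {self.noise_model[0]!r}")


def _apply_noise(image: np.ndarray, noise_model: tuple,
                 rng: np.random.Generator) -> np.ndarray:
    kind = noise_model[0]
    if kind == "none":
        return image
    if kind == "gaussian":
        sigma = noise_model[1] * image.max()
        return image + rng.normal(0.0, sigma, image.shape)
    # poisson: scale counts, draw, scale back
    scale = noise_model[1]
    return rng.poisson(np.maximum(image * scale, 0)).astype(float) / scale


def render_cell_image(
    params: ScenePhantomParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one centered cell phantom.

    Returns ``(image, surface_mask, contour_mask)`` where the image is 16-bit
    unsigned (clipped at saturation), the surface mask marks all pixels inside
    the cell outline and the contour mask the membrane ring band.
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_shape
    r_px = params.cell_radius / params.pixel_size
    mt_px = params.membrane_thickness / params.pixel_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if r_px + 2 > min(h, w) / 2.0:
        raise ParameterError(
            f"cell radius {params.cell_radius} µm does not fit in "
            f"{params.image_shape} at {params.pixel_size} µm/px"
        )

    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - cy, cc - cx)
    surface = dist <= r_px
    contour = surface & (dist >= r_px - mt_px)

    # membrane ring: Gaussian radial profile centered mid-ring, shaded
    # gently into the cytosol so the membrane phenotype is genuinely smooth
    ring_center = r_px - mt_px / 2.0
    ring_sigma = 2.0 * mt_px
    membrane = np.exp(-((dist - ring_center) ** 2) / (2 * ring_sigma**2))
    membrane[~surface] = 0.0
    membrane /= membrane.sum()

    # vesicles: Gaussian puncta in the eroded interior (one membrane
    # thickness inside the ring).  The number of active puncta grows with the
    # vesicular fraction at roughly constant per-punctum flux — internalizing
    # receptor accumulates in more endosomes, not brighter ones — which keeps
    # the contrast score increasing over the whole fraction range.  Centers
    # follow a jittered golden-angle spiral so puncta stay well separated.
    vesicles = np.zeros((h, w))
    vf = params.vesicular_fraction
    max_center_r = r_px - 2.0 * mt_px
    n_active = 0
    if vf > 0 and params.vesicle_count > 0 and max_center_r > 0:
        n_active = max(1, int(round(vf * params.vesicle_count)))
        sig_px = params.vesicle_sigma / params.pixel_size
        k = np.arange(params.vesicle_count)
        rad = max_center_r * np.sqrt((k + 0.5) / params.vesicle_count)
        rad = np.clip(rad + rng.normal(0.0, 0.3, params.vesicle_count),
                      0, max_center_r)
        ang = k * 2.399963229728653 + rng.uniform(0, 2 * np.pi)  # golden angle
        for r_i, a_i in zip(rad[:n_active], ang[:n_active]):
            vy, vx = cy + r_i * np.sin(a_i), cx + r_i * np.cos(a_i)
            vesicles += np.exp(
                -((rr - vy) ** 2 + (cc - vx) ** 2) / (2 * sig_px**2)
            )
        vesicles[~surface] = 0.0
        vesicles /= vesicles.sum()

    if vf > 0 and vesicles.sum() == 0:
        raise ParameterError(
            "vesicular_fraction > 0 but no room for vesicles inside the ring"
        )

    # diffuse cytosolic pool (blurred disk): keeps the whole footprint above
    # background at any vesicular fraction, as in real cells
    cytosol = ndi.gaussian_filter(surface.astype(float), 2.0)
    cytosol[~surface] = 0.0
    cytosol /= cytosol.sum()

    cf = params.cytosol_fraction
    cell = params.total_flux * (
        cf * cytosol + (1 - cf) * ((1 - vf) * membrane + vf * vesicles)
    )

    image = cell + params.background_level
    image = _apply_noise(image, params.noise_model, rng)
    image = np.clip(np.round(image), 0, np.iinfo(np.uint16).max)
    return image.astype(np.uint16), surface, contour


@dataclass
class GradientSceneParams:
    """Scene of many cells with internalization decaying away from a margin.

    The per-cell true vesicular fraction is exp(−distance/decay_length).
    The wound margin defaults to a straight vertical polyline at x = 0.
    """

    image_shape: tuple[int, int] = (640, 640)  # 320 µm field at 0.5 µm/px
    wound_margin: np.ndarray | None = None  # polyline (x, y) µm
    decay_length: float = 200.0  # µm
    n_cells: int = 40
    max_distance: float = 300.0  # µm
    min_separation: float | None = None  # µm between cell centers
    max_retries: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ParameterError("decay_length must be > 0")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.wound_margin is None:
            # straight margin along the left edge; height filled in (µm)
            # by render_gradient_scene from the image shape and pixel size
            self.wound_margin = None
        else:
            self.wound_margin = np.asarray(self.wound_margin, dtype=float)


def true_vesicular_fraction(distance_um, decay_length: float = 200.0):
    """Ground-truth internalization: exp(−d/λ)."""
    return np.exp(-np.asarray(distance_um, dtype=float) / decay_length)


def render_gradient_scene(
    params: GradientSceneParams, phantom: ScenePhantomParams
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Render a multi-cell gradient scene.

    Cells are placed at rejection-sampled positions with distance to the
    margin in [0, max_distance] and pairwise center separation of at least
    ``min_separation`` (default 2·radius + 4 µm).  Returns the 16-bit image,
    a ground-truth table (cell_id, x_um, y_um, distance_um,
    vesicular_fraction) and an integer label image of the true surface masks.
    """
    from shapely.geometry import LineString

    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_shape
    px = phantom.pixel_size
    r_um = phantom.cell_radius
    sep = params.min_separation or (2 * r_um + 4.0)
    margin_xy = params.wound_margin
    if margin_xy is None:
        margin_xy = np.array([[0.0, 0.0], [0.0, h * px]])
    margin = LineString(margin_xy)

    # patch large enough for the whole cell, and a placement margin so the
    # patch never leaves the frame
    patch_px = int(np.ceil(2 * (r_um / px + 3)))
    if patch_px % 2 == 0:
        patch_px += 1
    edge = (patch_px // 2 + 1) * px

    centers: list[tuple[float, float]] = []
    dists: list[float] = []
    tries = 0
    while len(centers) < params.n_cells:
        if tries >= params.max_retries:
            raise PlacementError(
                f"placed only {len(centers)}/{params.n_cells} cells after "
                f"{params.max_retries} retries"
            )
        tries += 1
        x = rng.uniform(edge, w * px - edge)
        y = rng.uniform(edge, h * px - edge)
        d = margin.distance(Point(x, y))
        if d > params.max_distance:
            continue
        if any(math.hypot(x - cx, y - cy) < sep for cx, cy in centers):
            continue
        centers.append((x, y))
        dists.append(d)

    image = np.full((h, w), float(phantom.background_level))
    labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    for i, ((x, y), d) in enumerate(zip(centers, dists), start=1):
        vf = float(true_vesicular_fraction(d, params.decay_length))
        cell_params = replace(
            phantom,
            image_shape=(patch_px, patch_px),
            vesicular_fraction=vf,
            background_level=0.0,
            noise_model=("none",),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        patch, surf, _ = render_cell_image(cell_params)
        row0 = int(round(y / px)) - patch_px // 2
        col0 = int(round(x / px)) - patch_px // 2
        image[row0 : row0 + patch_px, col0 : col0 + patch_px] += patch.astype(float)
        lab_view = labels[row0 : row0 + patch_px, col0 : col0 + patch_px]
        lab_view[surf] = i
        rows.append({"cell_id": i, "x_um": x, "y_um": y, "distance_um": d,
                     "vesicular_fraction": vf})

    image = _apply_noise(image, phantom.noise_model, rng)
    image = np.clip(np.round(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return image, pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class WalkerParams:
    """Biased persistent-random-walk parameters.

    Speeds are in µm/min, the frame interval ``dt`` in seconds (30 s matches
    typical confocal time-lapse acquisition).  ``persistence`` in [0, 1) sets
    directional correlation between successive steps; ``bias_strength`` is the
    von Mises concentration κ toward the nearest owa-perimeter point, applied
    while the walker is within ``bias_range`` of the owa.  On entering the owa
    a walker dwells ``dwell_frames`` frames and then leaves with probability
    ``p_reverse`` (walking unbiased thereafter) or stays confined inside.
    ``speed_cosine_coupling`` optionally modulates speed as
    v = v₀·(1 + a·cos θ) with θ the approach angle to the owa.
    """

    n_tracks: int = 50
    n_frames: int = 240  # 2 h at 30 s/frame
    dt: float = 30.0  # s
    mean_speed: float = 8.0  # µm/min
    speed_sd: float = 2.0
    persistence: float = 0.5
    bias_strength: float = 3.0  # κ
    bias_range: float = 200.0  # µm
    dwell_frames: int = 10
    p_reverse: float = 0.3
    speed_cosine_coupling: float = 0.0
    fin_polygon: Polygon | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ParameterError("speeds must be >= 0")
        if not 0.0 <= self.p_reverse <= 1.0:
            raise ParameterError("p_reverse must be in [0, 1]")
        if not 0.0 <= self.persistence < 1.0:
            raise ParameterError("persistence must be in [0, 1)")
        if self.bias_strength < 0:
            raise ParameterError("bias_strength (kappa) must be >= 0")
        if self.fin_polygon is None:
            self.fin_polygon = Polygon(
                [(0, 0), (400, 0), (400, 300), (0, 300)]
            )
        if self.fin_polygon.is_empty or self.fin_polygon.area <= 0:
            raise ParameterError("fin_polygon must have positive area")


@dataclass
class SimTrack:
    """One simulated trajectory with its ground-truth label."""

    track_id: int
    t: np.ndarray  # s
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    label: str


def _persistence_kappa(p: float) -> float:
    # monotone map [0,1) -> [0,inf); p=0 gives a uniform heading
    return 2.0 * p / (1.0 - p)


def _reflect(pt: np.ndarray, fin: Polygon) -> np.ndarray:
    """Mirror a point that left the fin about the nearest boundary point."""
    q = nearest_points(fin.exterior, Point(pt))[0]
    mirrored = 2.0 * np.array([q.x, q.y]) - pt
    if fin.covers(Point(mirrored)):
        return mirrored
    return np.array([q.x, q.y])


def simulate_tracks(params: WalkerParams, owa: Polygon) -> list[SimTrack]:
    """Simulate labeled neutrophil-like trajectories around an owa polygon.

    Every emitted track carries a ground-truth label derived from its realized
    geometry with the same inside-test the classifier uses (boundary counts as
    inside): tracks with a point in the owa are ``forward_intersecting`` or,
    if points exist after the last in-owa point, ``forward_then_reverse``;
    non-intersecting tracks are ``nonintersecting_toward`` when they end
    strictly closer to the owa than they started, else ``nonintersecting_away``.
    """
    fin = params.fin_polygon
    if not fin.covers(owa):
        raise ParameterError("owa must lie inside the fin polygon")
    rng = np.random.default_rng(params.rng_seed)
    kappa_p = _persistence_kappa(params.persistence)
    step_min = params.dt / 60.0  # minutes per frame
    ring = owa.exterior
    minx, miny, maxx, maxy = fin.bounds

    def sample_start() -> np.ndarray:
        while True:
            p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
            if fin.covers(Point(p)) and not owa.covers(Point(p)):
                return p

    tracks: list[SimTrack] = []
    times = np.arange(params.n_frames) * params.dt
    for tid in range(params.n_tracks):
        pos = sample_start()
        heading = rng.uniform(-np.pi, np.pi)
        pts = [pos.copy()]
        state = "walking"
        will_reverse = rng.uniform() < params.p_reverse
        dwell_left = 0
        centroid = np.array([owa.centroid.x, owa.centroid.y])
        for _ in range(params.n_frames - 1):
            here = Point(pos)
            inside = owa.covers(here)
            if state == "walking" and inside:
                state = "dwelling"
                dwell_left = params.dwell_frames

            if state == "dwelling":
                dwell_left -= 1
                if dwell_left <= 0:
                    state = "egress" if will_reverse else "resident"
                pts.append(pos.copy())
                continue

            if state == "resident":
                # confined unbiased motion inside the owa (stays clustered)
                heading = rng.uniform(-np.pi, np.pi)
                v = max(rng.normal(params.mean_speed, params.speed_sd), 0.0)
                cand = pos + v * step_min * np.array(
                    [np.cos(heading), np.sin(heading)]
                )
                if owa.covers(Point(cand)):
                    pos = cand
                pts.append(pos.copy())
                continue

            v = max(rng.normal(params.mean_speed, params.speed_sd), 0.0)

            if state == "egress":
                # active exit: step outward through the nearest boundary
                # point until outside the owa, then walk unbiased
                q = nearest_points(ring, Point(pos))[0]
                out_vec = np.array([q.x, q.y]) - pos
                if np.hypot(*out_vec) < 1e-9:
                    out_vec = pos - centroid
                heading = math.atan2(out_vec[1], out_vec[0])
                step = max(v, params.mean_speed) * step_min
                cand = pos + step * np.array(
                    [np.cos(heading), np.sin(heading)]
                )
                if not fin.covers(Point(cand)):
                    cand = _reflect(cand, fin)
                pos = cand
                if not owa.covers(Point(pos)):
                    state = "reversing"
                pts.append(pos.copy())
                continue

            # walking (biased toward owa) or reversing (unbiased walk; the
            # occupied cluster area acts as an obstacle after dispersal)
            target = nearest_points(ring, here)[0]
            to_owa = np.array([target.x - pos[0], target.y - pos[1]])
            dist = np.hypot(*to_owa)
            if (state == "walking" and not inside and dist > 0
                    and dist <= params.bias_range and params.bias_strength > 0):
                mu = math.atan2(to_owa[1], to_owa[0])
                heading = rng.vonmises(mu, params.bias_strength)
            else:
                heading = rng.vonmises(heading, kappa_p) if kappa_p > 0 \
                    else rng.uniform(-np.pi, np.pi)
            a = params.speed_cosine_coupling
            if a != 0.0 and dist > 0:
                cos_theta = math.cos(heading - math.atan2(to_owa[1], to_owa[0]))
                v = max(v * (1.0 + a * cos_theta), 0.0)
            cand = pos + v * step_min * np.array(
                [np.cos(heading), np.sin(heading)]
            )
            if not fin.covers(Point(cand)):
                cand = _reflect(cand, fin)
            if state == "reversing" and owa.covers(Point(cand)):
                q = nearest_points(ring, Point(cand))[0]
                mirrored = 2.0 * np.array([q.x, q.y]) - cand
                if fin.covers(Point(mirrored)) and not owa.covers(Point(mirrored)):
                    cand = mirrored
                else:
                    cand = pos  # stay put rather than re-enter the cluster
            pos = cand
            pts.append(pos.copy())

        xy = np.array(pts)
        label = _ground_truth_label(xy, owa)
        tracks.append(SimTrack(tid, times.copy(), xy[:, 0], xy[:, 1], label))
    return tracks


def _ground_truth_label(xy: np.ndarray, owa: Polygon) -> str:
    inside = np.array([owa.covers(Point(p)) for p in xy])
    if inside.any():
        last_in = int(np.nonzero(inside)[0][-1])
        if last_in < len(xy) - 1:
            return FORWARD_THEN_REVERSE
        return FORWARD_INTERSECTING
    d0 = owa.exterior.distance(Point(xy[0]))
    d1 = owa.exterior.distance(Point(xy[-1]))
    return NONINTERSECTING_TOWARD if d1 < d0 else NONINTERSECTING_AWAY


def tracks_to_dataframe(tracks: list[SimTrack]) -> pd.DataFrame:
    """Long-format table with header track_id, t_s, x_um, y_um, label."""
    frames = [
        pd.DataFrame({
            "track_id": tr.track_id, "t_s": tr.t,
            "x_um": tr.x, "y_um": tr.y, "label": tr.label,
        })
        for tr in tracks
    ]
    if not frames:
        return pd.DataFrame(columns=["track_id", "t_s", "x_um", "y_um", "label"])
    return pd.concat(frames, ignore_index=True)
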