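"""End-to-end runs composing the analysis stages.

Each ``run_*`` function takes a validated config (see
:mod:`woundtrack.config`), writes its outputs under ``outdir`` and returns
the paths it wrote.  A manifest JSON carrying the config hash and the
effective parameters makes every run self-describing; given the same config
and seed the data outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from woundtrack import cluster_stats, internalization, segmentation, synthetic
from woundtrack import trajectories as traj
from woundtrack.config import config_hash
from woundtrack.errors import ConfigError
from woundtrack.io import (
    ensure_dir,
    read_polygon_csv,
    read_seeds_csv,
    read_tiff,
    write_masks_manifest,
    write_polygon_csv,
    write_tiff,
    write_tracks_csv,
)

logger = logging.getLogger(__name__)


def _manifest(outdir: Path, cfg: dict, stage: str, outputs: dict) -> None:
    payload = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "config": cfg,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str)
    )


def _phantom_params(cfg: dict, seed: int) -> synthetic.ScenePhantomParams:
    s = cfg["scene"]
    return synthetic.ScenePhantomParams(
        pixel_size=cfg["pixel_size"],
        cell_radius=s["cell_radius"],
        membrane_thickness=s["membrane_thickness"],
        vesicle_count=s["vesicle_count"],
        vesicle_sigma=s["vesicle_sigma"],
        cytosol_fraction=s["cytosol_fraction"],
        total_flux=s["total_flux"],
        background_level=s["background_level"],
        noise_model=tuple(s["noise"]),
        rng_seed=seed,
    )


def run_simulate(cfg: dict, outdir=None) -> dict:
    """Write a gradient phantom scene and a labeled simulated track set."""
    outdir = ensure_dir(outdir or cfg["outdir"])
    seed = cfg["seed"]
    s = cfg["scene"]
    scene_params = synthetic.GradientSceneParams(
        image_shape=tuple(s["image_shape"]),
        decay_length=s["decay_length"],
        n_cells=s["n_cells"],
        max_distance=s["max_distance"],
        rng_seed=seed,
    )
    image, table, labels = synthetic.render_gradient_scene(
        scene_params, _phantom_params(cfg, seed)
    )
    w = cfg["walkers"]
    owa = Polygon(w["owa_polygon"])
    walk_params = synthetic.WalkerParams(
        n_tracks=w["n_tracks"], n_frames=w["n_frames"], dt=w["dt"],
        mean_speed=w["mean_speed"], speed_sd=w["speed_sd"],
        persistence=w["persistence"], bias_strength=w["bias_strength"],
        bias_range=w["bias_range"], dwell_frames=w["dwell_frames"],
        p_reverse=w["p_reverse"],
        speed_cosine_coupling=w["speed_cosine_coupling"],
        fin_polygon=Polygon(w["fin_polygon"]), rng_seed=seed,
    )
    tracks = synthetic.simulate_tracks(walk_params, owa)

    outputs = {
        "scene": outdir / "scene.tiff",
        "scene_labels": outdir / "scene_labels.tiff",
        "scene_truth": outdir / "scene_truth.csv",
        "tracks": outdir / "tracks.csv",
        "polygons": outdir / "polygons.csv",
    }
    write_tiff(outputs["scene"], image)
    write_tiff(outputs["scene_labels"], labels)
    table.to_csv(outputs["scene_truth"], index=False)
    write_tracks_csv(outputs["tracks"], synthetic.tracks_to_dataframe(tracks))
    write_polygon_csv(outputs["polygons"],
                      {"owa": owa, "fin": walk_params.fin_polygon})
    _manifest(outdir, cfg, "simulate", outputs)
    return outputs


def run_segment(cfg: dict, outdir=None) -> dict:
    """Segment frames into cell masks: seeded Chan-Vese or threshold mode."""
    outdir = ensure_dir(outdir or cfg["outdir"])
    seg = cfg["segmentation"]
    image_path = seg["images"] or (outdir / "scene.tiff")
    image = read_tiff(image_path)
    frames = image if image.ndim == 3 else image[None]
    px = cfg["pixel_size"]
    masks = []
    if seg["seeds"] is not None:
        seeds = read_seeds_csv(seg["seeds"])
        for _, row in seeds.iterrows():
            frame_idx = int(row["frame"])
            spec = segmentation.SeedSpec((row["x_px"], row["y_px"]),
                                         seg["core_halfwidth"])
            m = segmentation.grow_cell(
                frames[frame_idx], spec, max_iterations=seg["max_iterations"],
                pixel_size=px, cell_id=int(row["cell_id"]), frame=frame_idx,
            )
            masks.append(m)
        masks = segmentation.filter_small(masks, seg["min_area_px"])
    else:
        threshold = seg["threshold"]
        if threshold is None:
            threshold = 2.5 * float(np.median(frames))
            logger.info("no seeds/threshold configured; using 2.5x the "
                        "median intensity (%.1f) as threshold", threshold)
        for i, frame in enumerate(frames):
            masks.extend(segmentation.threshold_segment(
                frame, threshold, seg["min_area_px"], pixel_size=px, frame=i,
            ))
    label_stack = np.zeros(frames.shape, dtype=np.int32)
    for m in masks:
        label_stack[m.frame][m.pixels] = m.cell_id
    outputs = {
        "labels": outdir / "masks_labels.tiff",
        "manifest_csv": outdir / "masks.csv",
    }
    write_tiff(outputs["labels"], label_stack)
    write_masks_manifest(outputs["manifest_csv"], masks)
    _manifest(outdir, cfg, "segment", outputs)
    return outputs


def run_internalization(cfg: dict, outdir=None) -> dict:
    """Score per-cell contrast on a scene and profile it against the margin."""
    outdir = ensure_dir(outdir or cfg["outdir"])
    icfg = cfg["internalization"]
    seg = cfg["segmentation"]
    image_path = seg["images"] or (outdir / "scene.tiff")
    image = read_tiff(image_path)
    if image.ndim == 3:
        image = image[0]
    px = cfg["pixel_size"]
    threshold = seg["threshold"]
    if threshold is None:
        # robust default: background-dominated images have median ~ background
        threshold = 2.5 * float(np.median(image))
    masks = segmentation.threshold_segment(image, threshold,
                                           seg["min_area_px"], pixel_size=px)
    results, centroids = [], []
    for m in masks:
        ok, reason = internalization.quality_gate(
            image, m,
            max_saturated_frac=icfg["max_saturated_frac"],
            min_distinct_levels=icfg["min_distinct_levels"],
            n_levels=icfg["n_levels"],
        )
        if not ok:
            logger.warning("excluded cell %d: %s", m.cell_id, reason)
            continue
        c = internalization.cell_contrast(
            image, m, n_levels=icfg["n_levels"],
            offset=tuple(icfg["offset"]), symmetric=icfg["symmetric"],
            zero_fill=icfg["zero_fill"],
        )
        results.append(internalization.ContrastResult(m.cell_id, c))
        centroids.append(m.centroid_um())
    normalized = internalization.normalize_contrast(
        results, icfg["normalization"]
    ) if results else []

    margin = np.array([[0.0, 0.0], [0.0, image.shape[0] * px]])
    rows = []
    for res, cen in zip(normalized, centroids):
        d = internalization.distances_to_margin([cen], margin)[0]
        rows.append({
            "cell_id": res.cell_id, "raw_contrast": res.raw_contrast,
            "normalization_mode": res.normalization_mode,
            "reference_value": res.reference_value,
            "normalized_contrast": res.normalized_contrast,
            "distance_um": d, "x_um": cen[0], "y_um": cen[1],
        })
    cells_df = pd.DataFrame(rows)
    outputs = {"cells": outdir / "contrast_cells.csv",
               "profile": outdir / "contrast_profile.csv"}
    cells_df.to_csv(outputs["cells"], index=False)
    if not cells_df.empty:
        profile = internalization.gradient_profile(
            cells_df[["x_um", "y_um"]].to_numpy(),
            cells_df["normalized_contrast"].to_numpy(),
            margin, bin_width_um=icfg["bin_width_um"],
        )
    else:
        logger.warning("no cells segmented; writing empty contrast outputs")
        profile = pd.DataFrame(
            columns=["bin_lo", "bin_hi", "distance_um", "mean", "sem", "n"])
    profile.to_csv(outputs["profile"], index=False)
    _manifest(outdir, cfg, "internalization", outputs)
    return outputs


def run_trajectories(cfg: dict, outdir=None) -> dict:
    """Classify tracks, derive step statistics, profiles and the summary."""
    outdir = ensure_dir(outdir or cfg["outdir"])
    tcfg = cfg["trajectories"]
    tracks_path = tcfg["tracks"] or (outdir / "tracks.csv")
    if not Path(tracks_path).exists():
        raise ConfigError(f"tracks file not found: {tracks_path}")
    polygons = {}
    poly_path = tcfg["owa"] or (outdir / "polygons.csv")
    if Path(str(poly_path)).exists():
        polygons = read_polygon_csv(poly_path)
    elif tcfg["owa"] is None:
        raise ConfigError(f"owa polygon file not found: {poly_path}")
    owa = polygons.get("owa")
    if owa is None:
        raise ConfigError(f"no 'owa' polygon in {poly_path}")
    fin = polygons.get("fin")

    df = pd.read_csv(tracks_path)
    if tcfg["time_window_s"] is not None:
        lo, hi = tcfg["time_window_s"]
        df = df[(df["t_s"] >= lo) & (df["t_s"] <= hi)]
    tracks = traj.load_tracks(df, min_duration=tcfg["min_duration"],
                              fin_polygon=fin)
    classifications = [traj.classify_track(tr, owa) for tr in tracks]
    steps = traj.cohort_steps(tracks, owa, classifications)
    svd = traj.speed_vs_distance(
        steps,
        bin_edges=None if steps.empty else np.arange(
            0.0, steps["d_um"].max() + tcfg["distance_bin_um"],
            tcfg["distance_bin_um"]),
        aggregation=tcfg["aggregation"],
    )
    svc = traj.speed_vs_cosine(
        steps, bin_edges=np.linspace(-1, 1, tcfg["cosine_bins"] + 1),
        zone_um=tcfg["cosine_zone_um"], aggregation=tcfg["aggregation"],
    )
    straightness_results = [
        traj.straightness(tr, owa, tcfg["straightness_zone_um"],
                          tcfg["straightness_min_path_um"])
        for tr in tracks
    ]
    for r in straightness_results:
        if r.straightness is None:
            logger.info("straightness excluded track %s: %s",
                        r.track_id, r.excluded_reason)
    summary = traj.cohort_summary(classifications, straightness_results)
    if summary["net_reverse_traffic"] is None:
        summary["net_reverse_traffic"] = "missing"

    outputs = {
        "steps": outdir / "steps.csv",
        "classifications": outdir / "classifications.csv",
        "speed_vs_distance": outdir / "speed_vs_distance.csv",
        "speed_vs_cosine": outdir / "speed_vs_cosine.csv",
        "straightness": outdir / "straightness.csv",
        "summary": outdir / "cohort_summary.json",
    }
    steps.to_csv(outputs["steps"], index=False)
    pd.DataFrame([{
        "track_id": c.track_id, "category": c.category,
        "forward_start": c.forward_segment[0] if c.forward_segment else "",
        "forward_end": c.forward_segment[1] if c.forward_segment else "",
        "reverse_start": c.reverse_segment[0] if c.reverse_segment else "",
        "reverse_end": c.reverse_segment[1] if c.reverse_segment else "",
    } for c in classifications]).to_csv(outputs["classifications"], index=False)
    svd.to_csv(outputs["speed_vs_distance"], index=False)
    svc.to_csv(outputs["speed_vs_cosine"], index=False)
    pd.DataFrame([{
        "track_id": r.track_id, "straightness": r.straightness,
        "excluded_reason": r.excluded_reason or "",
    } for r in straightness_results]).to_csv(outputs["straightness"], index=False)
    Path(outputs["summary"]).write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    _manifest(outdir, cfg, "trajectories", outputs)
    return outputs


def run_clusters(cfg: dict, outdir=None) -> dict:
    """Recruitment counts and cluster-size summary from a masks manifest."""
    outdir = ensure_dir(outdir or cfg["outdir"])
    ccfg = cfg["clusters"]
    masks_path = outdir / "masks.csv"
    labels_path = outdir / "masks_labels.tiff"
    if not masks_path.exists():
        raise ConfigError(f"masks manifest not found: {masks_path}")
    records = pd.read_csv(masks_path)
    px = cfg["pixel_size"]
    centroid_rows = []
    if labels_path.exists():
        labels = read_tiff(labels_path)
        if labels.ndim == 2:
            labels = labels[None]
        for f, frame in enumerate(labels):
            for cid in np.unique(frame)[np.unique(frame) > 0]:
                rows_, cols_ = np.nonzero(frame == cid)
                centroid_rows.append({
                    "frame": f, "cell_id": int(cid),
                    "x_um": cols_.mean() * px, "y_um": rows_.mean() * px,
                })
    centroids = pd.DataFrame(centroid_rows,
                             columns=["frame", "cell_id", "x_um", "y_um"])
    center = ccfg["wound_center"]
    if center is None:
        h = read_tiff(outdir / "scene.tiff").shape[0] * px \
            if (outdir / "scene.tiff").exists() else 0.0
        center = (0.0, h / 2.0)
    counts = cluster_stats.recruitment_count(
        centroids, tuple(center), ccfg["recruitment_half_width_um"]
    ) if not centroids.empty else pd.Series(dtype=int, name="count")
    mean_area = cluster_stats.cluster_size(
        records.rename(columns={"frame": "frame"}),
        min_area_um2=ccfg["min_area_um2"],
        window=tuple(ccfg["window"]) if ccfg["window"] else None,
    )
    outputs = {"counts": outdir / "recruitment_counts.csv",
               "summary": outdir / "cluster_summary.json"}
    counts.rename_axis("frame").reset_index().to_csv(outputs["counts"],
                                                     index=False)
    Path(outputs["summary"]).write_text(json.dumps({
        "mean_cluster_area_um2": mean_area if mean_area is not None else "missing",
        "min_area_um2": ccfg["min_area_um2"],
        "n_objects": int((records["area_um2"] >= ccfg["min_area_um2"]).sum()),
    }, indent=2, sort_keys=True))
    _manifest(outdir, cfg, "clusters", outputs)
    return outputs


def run_all(cfg: dict, outdir=None) -> dict:
    """simulate → segment → internalization → trajectories → clusters."""
    outdir = ensure_dir(outdir or cfg["outdir"])
    outputs = {}
    outputs.update(run_simulate(cfg, outdir))
    outputs.update(run_segment(cfg, outdir))
    outputs.update(run_internalization(cfg, outdir))
    outputs.update(run_trajectories(cfg, outdir))
    outputs.update(run_clusters(cfg, outdir))
    return outputs
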