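"""Readers/writers for the pipeline's on-disk formats.

Images travel as multi-page 16-bit TIFF (tifffile), tabular data as CSV
(pandas), polygons as vertex CSVs with columns name,vertex_index,x_um,y_um.
TIFF writes omit timestamps so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from woundtrack.errors import DataError

TRACK_COLUMNS = ["track_id", "t_s", "x_um", "y_um"]


def write_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image), datetime=False,
                     software=False)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_tracks_csv(path, df: pd.DataFrame) -> None:
    cols = [c for c in TRACK_COLUMNS + ["label"] if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def write_polygon_csv(path, polygons: dict[str, Polygon]) -> None:
    rows = []
    for name, poly in polygons.items():
        xs, ys = poly.exterior.coords.xy
        for i, (x, y) in enumerate(zip(xs[:-1], ys[:-1])):
            rows.append({"name": name, "vertex_index": i,
                         "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_polygon_csv(path) -> dict[str, Polygon]:
    df = pd.read_csv(path)
    required = {"name", "vertex_index", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise DataError(f"polygon CSV needs columns {sorted(required)}")
    out = {}
    for name, g in df.groupby("name"):
        g = g.sort_values("vertex_index")
        out[name] = Polygon(g[["x_um", "y_um"]].to_numpy())
    return out


def read_seeds_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "cell_id", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise DataError(f"seeds CSV needs columns {sorted(required)}")
    return df


def write_masks_manifest(path, masks) -> None:
    rows = [{"cell_id": m.cell_id, "frame": m.frame, "kind": m.kind,
             "area_px": m.area_px, "area_um2": m.area_um2} for m in masks]
    pd.DataFrame(
        rows, columns=["cell_id", "frame", "kind", "area_px", "area_um2"]
    ).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
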