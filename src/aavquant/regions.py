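"""Region-of-interest gating of cell coordinates.

Sections are reconstructed as coordinate scatters and gated with named
polygons (cortex, striatum, hippocampus) — the open equivalent of drawing
freehand ROIs on the plotted NeuN+ scatter and reapplying the saved ROI to
every channel.  Polygons are consumed from files rather than drawn
interactively; membership is point-in-polygon with boundary points counted
inside, so a cell on a saved ROI edge is never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .quantify import CellRecord, SectionStats, cells_to_frame, section_stats


@dataclass
class RoiPolygon:
    """Closed planar polygon in well-frame um naming a brain region."""

    region: str
    vertices: list[tuple[float, float]]
    section_id: int = 0

    def __post_init__(self) -> None:
        verts = list(self.vertices)
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]  # stored implicitly closed
        if len(verts) < 3:
            raise ValueError(f"polygon {self.region!r} needs >= 3 distinct vertices")
        self.vertices = [(float(x), float(y)) for x, y in verts]
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"polygon {self.region!r} is self-intersecting or degenerate")
        self._poly = poly

    @property
    def polygon(self) -> Polygon:
        return self._poly

    @classmethod
    def from_shapely(cls, region: str, poly: Polygon, section_id: int = 0) -> "RoiPolygon":
        return cls(region=region, vertices=list(poly.exterior.coords), section_id=section_id)


def point_in_polygon(x_um: float, y_um: float, poly: RoiPolygon | Polygon) -> bool:
    """Membership test with on-boundary points counted inside."""
    p = poly.polygon if isinstance(poly, RoiPolygon) else poly
    return bool(p.covers(Point(float(x_um), float(y_um))))


def points_in_polygon(xs: np.ndarray, ys: np.ndarray, poly: RoiPolygon | Polygon) -> np.ndarray:
    """Vectorised membership for coordinate arrays (boundary inclusive)."""
    p = poly.polygon if isinstance(poly, RoiPolygon) else poly
    pts = shapely.points(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float))
    return shapely.covers(p, pts)


def gate_region(cells: list[CellRecord] | pd.DataFrame, poly: RoiPolygon) -> list[CellRecord]:
    """Cells whose coordinates fall inside the ROI.

    Membership depends only on (x, y), so applying a saved ROI to the
    Hoechst-, NeuN- or GFP-derived scatter of the same section gives
    consistent per-cell membership.
    """
    if isinstance(cells, pd.DataFrame):
        cells = [
            CellRecord(int(r.cell_id), int(r.section_id), float(r.x_um), float(r.y_um),
                       bool(r.is_neun), bool(r.is_gfp))
            for r in cells.itertuples()
        ]
    if not cells:
        return []
    xs = np.array([c.x_um for c in cells])
    ys = np.array([c.y_um for c in cells])
    keep = points_in_polygon(xs, ys, poly)
    return [c for c, k in zip(cells, keep) if k]


@dataclass
class RegionStats(SectionStats):
    region: str = ""


def region_stats(
    cells: list[CellRecord] | pd.DataFrame, polygons: list[RoiPolygon]
) -> list[RegionStats]:
    """Per-region percentages on the polygon-gated subsets.

    An empty region yields a row with n_cells=0 and missing percentages
    rather than an error.
    """
    names = [p.region for p in polygons]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique per section")
    out = []
    for poly in polygons:
        subset = gate_region(cells, poly)
        if subset:
            s = section_stats(subset)
            out.append(
                RegionStats(
                    section_id=s.section_id,
                    n_cells=s.n_cells,
                    pct_neun=s.pct_neun,
                    pct_gfp=s.pct_gfp,
                    pct_neun_gfp=s.pct_neun_gfp,
                    pct_both_of_all=s.pct_both_of_all,
                    region=poly.region,
                )
            )
        else:
            out.append(
                RegionStats(
                    section_id=poly.section_id,
                    n_cells=0,
                    pct_neun=float("nan"),
                    pct_gfp=float("nan"),
                    pct_neun_gfp=float("nan"),
                    pct_both_of_all=float("nan"),
                    region=poly.region,
                )
            )
    return out


def region_stats_frame(stats: list[RegionStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "section_id": s.section_id,
                "region": s.region,
                "n_cells": s.n_cells,
                "pct_neun": s.pct_neun,
                "pct_gfp": s.pct_gfp,
                "pct_neun_gfp": s.pct_neun_gfp,
                "pct_both_of_all": s.pct_both_of_all,
            }
            for s in stats
        ]
    )


# ---------------------------------------------------------------------------
# ROI file formats: CSV (region,vertex_index,x_um,y_um) and GeoJSON.


def write_rois_csv(polys: list[RoiPolygon], path: str) -> None:
    rows = []
    for poly in polys:
        for i, (x, y) in enumerate(poly.vertices):
            rows.append({"region": poly.region, "vertex_index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=["region", "vertex_index", "x_um", "y_um"]).to_csv(path, index=False)


def read_rois_csv(path: str, section_id: int = 0) -> list[RoiPolygon]:
    df = pd.read_csv(path)
    polys = []
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("vertex_index")
        polys.append(
            RoiPolygon(
                region=str(region),
                vertices=list(zip(grp["x_um"].astype(float), grp["y_um"].astype(float))),
                section_id=section_id,
            )
        )
    return polys


def write_rois_geojson(polys: list[RoiPolygon], path: str) -> None:
    features = []
    for poly in polys:
        ring = [[x, y] for x, y in poly.vertices] + [[poly.vertices[0][0], poly.vertices[0][1]]]
        features.append(
            {
                "type": "Feature",
                "properties": {"region": poly.region, "section_id": poly.section_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_rois_geojson(path: str) -> list[RoiPolygon]:
    with open(path) as fh:
        data = json.load(fh)
    polys = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        ring = feat["geometry"]["coordinates"][0]
        polys.append(
            RoiPolygon(
                region=str(props.get("region", "roi")),
                vertices=[(float(x), float(y)) for x, y in ring],
                section_id=int(props.get("section_id", 0)),
            )
        )
    return polys


def plot_scatter(cells: list[CellRecord] | pd.DataFrame, ax=None, markers_only: str | None = "neun"):
    """Render the cell scatter used as the template for drawing ROIs.

    By default only NeuN+ cells are shown, which delineates grey-matter
    boundaries better than the all-nuclei scatter.  Returns the axis.
    """
    import matplotlib.pyplot as plt

    df = cells_to_frame(cells) if not isinstance(cells, pd.DataFrame) else cells
    if markers_only == "neun":
        df = df[df["is_neun"]]
    elif markers_only == "gfp":
        df = df[df["is_gfp"]]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["x_um"], df["y_um"], s=2, linewidths=0)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return ax
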