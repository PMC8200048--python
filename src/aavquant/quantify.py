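"""Co-localisation of gated marker detections onto nuclei and per-section
percentages.

Positivity rules reflect the stains: the reporter is NLS-tagged, so a
nucleus is GFP+ only when a gated GFP object covers at least half of the
nucleus mask; NeuN stains the soma including the nucleus, so a nucleus is
NeuN+ when a gated NeuN object contains the nucleus centroid.  Each marker
object can claim at most one nucleus (nearest centroid wins), so one
merged marker blob spanning two nuclei never double-counts.

Percentages (denominators differ by design):
  pct_neun       = 100 * NeuN+ / Hoechst+
  pct_gfp        = 100 * GFP+ / Hoechst+
  pct_neun_gfp   = 100 * (NeuN+ and GFP+) / NeuN+
  pct_both_of_all= 100 * (NeuN+ and GFP+) / Hoechst+
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segment import DetectedObject

GFP_COVERAGE_FRACTION = 0.5


@dataclass
class CellRecord:
    cell_id: int
    section_id: int
    x_um: float
    y_um: float
    is_neun: bool
    is_gfp: bool


@dataclass
class SectionStats:
    section_id: int
    n_cells: int
    pct_neun: float
    pct_gfp: float
    pct_neun_gfp: float  # GFP+ among NeuN+ (NaN when no NeuN+ cells)
    pct_both_of_all: float  # NeuN+/GFP+ among all Hoechst+ cells


def _mask_overlap(a: DetectedObject, b: DetectedObject) -> int:
    """Pixel overlap of two masks stored as (offset, bool array)."""
    ar0, ac0 = a.mask_offset
    br0, bc0 = b.mask_offset
    ah, aw = a.mask.shape
    bh, bw = b.mask.shape
    r0, r1 = max(ar0, br0), min(ar0 + ah, br0 + bh)
    c0, c1 = max(ac0, bc0), min(ac0 + aw, bc0 + bw)
    if r0 >= r1 or c0 >= c1:
        return 0
    sub_a = a.mask[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    sub_b = b.mask[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    return int((sub_a & sub_b).sum())


def _centroid_in_mask(x_um: float, y_um: float, obj: DetectedObject, pixel_size_um: float,
                      origin_um: tuple[float, float]) -> bool:
    col = int((x_um - origin_um[0]) / pixel_size_um)
    row = int((y_um - origin_um[1]) / pixel_size_um)
    r0, c0 = obj.mask_offset
    rr, cc = row - r0, col - c0
    if 0 <= rr < obj.mask.shape[0] and 0 <= cc < obj.mask.shape[1]:
        return bool(obj.mask[rr, cc])
    return False


def assign_markers(
    nuclei: list[DetectedObject],
    neun_objects: list[DetectedObject],
    gfp_objects: list[DetectedObject],
    pixel_size_um: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
    section_id: int = 0,
    search_radius_um: float = 15.0,
) -> list[CellRecord]:
    """Build per-cell records from nuclei and gated marker detections.

    All inputs must share the same well frame (same mosaic).  A marker
    object is matched against nearby nuclei (within ``search_radius_um`` of
    its centroid); among the nuclei satisfying the positivity rule, the one
    with the nearest centroid is claimed and the others stay unclaimed.
    """
    records = [
        CellRecord(
            cell_id=n.object_id,
            section_id=section_id,
            x_um=n.x_um,
            y_um=n.y_um,
            is_neun=False,
            is_gfp=False,
        )
        for n in nuclei
    ]
    if not nuclei:
        return records
    centroids = np.array([[n.x_um, n.y_um] for n in nuclei])
    tree = cKDTree(centroids)

    def nearby(obj: DetectedObject) -> list[int]:
        return sorted(
            tree.query_ball_point([obj.x_um, obj.y_um], search_radius_um),
            key=lambda i: (math.hypot(nuclei[i].x_um - obj.x_um, nuclei[i].y_um - obj.y_um), i),
        )

    for obj in neun_objects:
        for i in nearby(obj):
            if _centroid_in_mask(nuclei[i].x_um, nuclei[i].y_um, obj, pixel_size_um, origin_um):
                records[i].is_neun = True
                break  # nearest centroid wins; one nucleus per marker object

    for obj in gfp_objects:
        obj_px = obj.n_pixels
        if obj_px == 0:
            continue
        for i in nearby(obj):
            nuc = nuclei[i]
            if nuc.n_pixels == 0:
                continue
            if _mask_overlap(obj, nuc) >= GFP_COVERAGE_FRACTION * nuc.n_pixels:
                records[i].is_gfp = True
                break
    return records


def section_stats(cells: list[CellRecord] | pd.DataFrame, section_id: int | None = None) -> SectionStats:
    """Per-section percentages; raises on an empty cell list.

    ``pct_neun_gfp`` is NaN (reported as missing) when no NeuN+ cells exist.
    """
    df = cells_to_frame(cells) if not isinstance(cells, pd.DataFrame) else cells
    n = len(df)
    if n == 0:
        raise ValueError("section_stats requires at least one cell")
    if section_id is None:
        section_id = int(df["section_id"].iloc[0])
    n_neun = int(df["is_neun"].sum())
    n_gfp = int(df["is_gfp"].sum())
    n_both = int((df["is_neun"] & df["is_gfp"]).sum())
    return SectionStats(
        section_id=section_id,
        n_cells=n,
        pct_neun=100.0 * n_neun / n,
        pct_gfp=100.0 * n_gfp / n,
        pct_neun_gfp=(100.0 * n_both / n_neun) if n_neun > 0 else float("nan"),
        pct_both_of_all=100.0 * n_both / n,
    )


CELL_COLUMNS = ["cell_id", "section_id", "x_um", "y_um", "is_neun", "is_gfp"]


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "section_id": c.section_id,
                "x_um": c.x_um,
                "y_um": c.y_um,
                "is_neun": c.is_neun,
                "is_gfp": c.is_gfp,
            }
            for c in cells
        ],
        columns=CELL_COLUMNS,
    )
    return df.astype({"cell_id": int, "section_id": int, "x_um": float, "y_um": float,
                      "is_neun": bool, "is_gfp": bool}) if len(df) else df


def export_cells(cells: list[CellRecord] | pd.DataFrame, path: str) -> None:
    """Write per-cell records as CSV (flags as 0/1); round-trips exactly."""
    df = cells_to_frame(cells) if not isinstance(cells, pd.DataFrame) else cells.copy()
    if len(df):
        df["is_neun"] = df["is_neun"].astype(int)
        df["is_gfp"] = df["is_gfp"].astype(int)
        df["x_um"] = df["x_um"].map(lambda v: repr(float(v)))
        df["y_um"] = df["y_um"].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False, columns=CELL_COLUMNS)


def import_cells(path: str) -> list[CellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        CellRecord(
            cell_id=int(r.cell_id),
            section_id=int(r.section_id),
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            is_neun=bool(int(r.is_neun)),
            is_gfp=bool(int(r.is_gfp)),
        )
        for r in df.itertuples()
    ]


def stats_frame(stats: list[SectionStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "section_id": s.section_id,
                "n_cells": s.n_cells,
                "pct_neun": s.pct_neun,
                "pct_gfp": s.pct_gfp,
                "pct_neun_gfp": s.pct_neun_gfp,
                "pct_both_of_all": s.pct_both_of_all,
            }
            for s in stats
        ]
    )


def export_stats(stats: list[SectionStats], path: str) -> None:
    """Per-section stats CSV with percentages at 1 decimal place."""
    df = stats_frame(stats)
    for col in ("pct_neun", "pct_gfp", "pct_neun_gfp", "pct_both_of_all"):
        df[col] = df[col].round(1)
    df.to_csv(path, index=False)
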