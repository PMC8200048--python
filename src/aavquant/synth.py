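"""Synthetic coronal-section generator with per-cell ground truth.

Emulates high-content acquisition of a stained mouse brain section: a
stylized section geometry (ellipse body with polygonal sub-regions labelled
cortex / striatum / hippocampus / other) is populated with nuclei at tissue
density; each nucleus is a Hoechst object, neurons additionally carry a
somatic NeuN signal, and transduced cells a nuclear GFP signal (the reporter
is NLS-tagged, so GFP is confined to nuclei).  The field is imaged as a grid
of overlapping tiles, each a z-stack of optical slices with axial intensity
falloff and Poisson-Gaussian sensor noise.  High-intensity debris speckles
in the marker channels and a dim nuclear autofluorescence floor in the GFP
channel give the downstream morphology gate something real to reject.

Ground truth (cell coordinates, region labels, neuron / transduced flags)
is returned alongside the pixel data so every downstream stage can be
scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon, box

from .imgio import CHANNELS, Mosaic, MultiChannelStack, TileLayout, TilePosition, stitch

REGIONS = ("cortex", "striatum", "hippocampus", "other")

_FLAT = 0  # flat-top profile (nuclei, somata): plateau with soft rim
_GAUSS = 1  # sharp Gaussian profile (debris speckles)

_OBJ_DTYPE = np.dtype(
    [
        ("x", "f8"),
        ("y", "f8"),
        ("radius", "f8"),  # plateau radius for _FLAT, sigma for _GAUSS
        ("amp", "f8"),  # peak amplitude in counts above background
        ("z0", "f8"),  # axial position of best focus, um
        ("sigma_z", "f8"),
        ("kind", "i4"),
    ]
)


@dataclass(frozen=True)
class SectionGeometry:
    """Named stylized section shape: disjoint region polygons in um.

    Polygons live in the well frame (x right, y down, origin at the mosaic
    top-left) and jointly tile an elliptical section body.
    """

    name: str
    regions: dict[str, Polygon]

    @property
    def bounds_um(self) -> tuple[float, float, float, float]:
        geoms = list(self.regions.values())
        b = shapely.unary_union(geoms).bounds
        return b

    @property
    def width_um(self) -> float:
        b = self.bounds_um
        return b[2] + b[0]  # symmetric margin

    @property
    def height_um(self) -> float:
        b = self.bounds_um
        return b[3] + b[1]

    def scaled(self, factor: float) -> "SectionGeometry":
        """Scale all regions about the section centre, preserving the margin."""
        b = self.bounds_um
        cx, cy = (b[0] + b[2]) / 2, (b[1] + b[3]) / 2
        regions = {
            name: shapely.affinity.scale(poly, factor, factor, origin=(cx, cy))
            for name, poly in self.regions.items()
        }
        return SectionGeometry(name=f"{self.name}*{factor:.3f}", regions=regions)


def coronal_geometry(scale: float = 1.0, margin_um: float = 20.0) -> SectionGeometry:
    """Stylized coronal section: ellipse split into dorsal cortex, a lateral
    striatum and hippocampus, and a central 'other' strip.

    ``scale=1`` gives a 1200 x 900 um hemisection-sized ellipse (~0.85 mm^2),
    sized so that ~2000 nuclei give a realistic ~2400 nuclei/mm^2 packing
    for a 25 um section.
    """
    a, b = 600.0 * scale, 450.0 * scale
    cx, cy = margin_um + a, margin_um + b
    ellipse = shapely.affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=48), a, b)
    big = 10.0 * (a + b)
    # dorsal cap (y below cy - 0.15 b since y grows downward)
    cortex = ellipse.intersection(box(cx - big, cy - big, cx + big, cy - 0.15 * b))
    ventral = box(cx - big, cy - 0.15 * b, cx + big, cy + big)
    striatum = ellipse.intersection(ventral).intersection(box(cx - big, cy - big, cx - 0.10 * a, cy + big))
    hippocampus = ellipse.intersection(ventral).intersection(box(cx + 0.10 * a, cy - big, cx + big, cy + big))
    other = ellipse.intersection(ventral).intersection(box(cx - 0.10 * a, cy - big, cx + 0.10 * a, cy + big))
    return SectionGeometry(
        name=f"coronal(scale={scale:g})",
        regions={"cortex": cortex, "striatum": striatum, "hippocampus": hippocampus, "other": other},
    )


def _as_region_map(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        out = dict(value)
    else:
        out = {r: float(value) for r in REGIONS}
    for r, v in out.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}[{r}] must be in [0, 1], got {v}")
    return out


@dataclass
class SectionSpec:
    """Stated world for one synthetic section.

    Imaging geometry follows the acquisition protocol being emulated: stacks
    of 19 optical slices 1.2 um apart, tiles captured with 10% overlap.
    ``pixel_size_um`` defaults to 0.3 (40x water-immersion class) and is
    configurable.
    """

    geometry: SectionGeometry = field(default_factory=coronal_geometry)
    n_nuclei: int = 2000
    neuron_fraction_by_region: dict[str, float] | float = 0.4
    transduction_fraction_by_region: dict[str, float] | float = 0.14
    # optional per-region transduction probability for neurons specifically;
    # non-neuron probability is then solved so the overall regional fraction
    # still matches transduction_fraction_by_region
    neuron_transduction_by_region: dict[str, float] | float | None = None
    nucleus_radius_um: tuple[float, float] = (3.5, 0.4)  # mean, sd
    soma_radius_um: float = 4.6
    snr: float | dict[str, float] = 10.0
    debris_rate: float = 40.0  # speckles per mm^2 per marker channel
    gfp_autofluorescence: float = 0.12  # median floor, fraction of full GFP amplitude
    gfp_autofluorescence_sigma: float = 0.4  # lognormal sigma of the floor
    pixel_size_um: float = 0.3
    n_z: int = 19
    z_step_um: float = 1.2
    tile_size_px: int = 256
    overlap_fraction: float = 0.1
    background_counts: float = 100.0
    read_noise_counts: float = 3.0
    touching_fraction: float = 0.03  # nuclei deliberately placed as touching pairs

    def validate(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        if self.nucleus_radius_um[0] <= 0:
            raise ValueError("nucleus_radius_um mean must be > 0")
        if self.debris_rate < 0:
            raise ValueError("debris_rate must be >= 0")
        if not (0.0 <= self.touching_fraction <= 0.5):
            raise ValueError("touching_fraction must be in [0, 0.5]")
        _as_region_map(self.neuron_fraction_by_region, "neuron_fraction_by_region")
        _as_region_map(self.transduction_fraction_by_region, "transduction_fraction_by_region")
        if self.neuron_transduction_by_region is not None:
            _as_region_map(self.neuron_transduction_by_region, "neuron_transduction_by_region")
        for r, poly in self.geometry.regions.items():
            if not poly.is_valid:
                raise ValueError(f"geometry region {r!r} is not a valid (non-self-intersecting) polygon")
        snr = self.snr if isinstance(self.snr, dict) else {c: self.snr for c in CHANNELS}
        for c, v in snr.items():
            if v <= 0:
                raise ValueError(f"snr[{c}] must be > 0")

    def snr_for(self, channel: str) -> float:
        if isinstance(self.snr, dict):
            return float(self.snr[channel])
        return float(self.snr)


@dataclass
class GroundTruth:
    """Per-cell truth rows plus per-object debris rows."""

    cells: pd.DataFrame  # cell_id, x_um, y_um, region, is_neuron, is_transduced
    debris: pd.DataFrame  # object_id, channel, x_um, y_um, size_um, amplitude

    def neuron_fraction(self) -> float:
        return float(self.cells["is_neuron"].mean()) if len(self.cells) else float("nan")

    def transduced_fraction(self) -> float:
        return float(self.cells["is_transduced"].mean()) if len(self.cells) else float("nan")


TRUTH_COLUMNS = ["cell_id", "x_um", "y_um", "region", "is_neuron", "is_transduced"]


def write_truth(truth: GroundTruth, path: str) -> None:
    df = truth.cells.copy()
    df["is_neuron"] = df["is_neuron"].astype(int)
    df["is_transduced"] = df["is_transduced"].astype(int)
    df.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_neuron"] = df["is_neuron"].astype(bool)
    df["is_transduced"] = df["is_transduced"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Scene construction (all randomness except sensor noise lives here)


@dataclass
class Scene:
    truth: GroundTruth
    objects: dict[str, np.ndarray]  # per channel, _OBJ_DTYPE records
    layout: TileLayout
    width_px: int
    height_px: int


def _place_in_region(
    poly: Polygon, n: int, min_dist: float, touch_dist: float, n_touching: int, rng: np.random.Generator
) -> np.ndarray:
    """Blue-noise-ish placement: rejection sampling with a minimum centre
    distance, plus ``n_touching`` deliberately touching partners to exercise
    object splitting downstream."""
    if n == 0:
        return np.empty((0, 2))
    inner = poly.buffer(-1.0)
    if inner.is_empty:
        inner = poly
    minx, miny, maxx, maxy = inner.bounds
    pts: list[tuple[float, float]] = []
    n_primary = n - n_touching
    attempts = 0
    max_attempts = 300 * n + 1000
    arr = np.empty((0, 2))
    while len(pts) < n_primary and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not inner.covers(Point(x, y)):
            continue
        ok = True
        # linear scan is fine at region scale; positions are appended rarely
        for px, py in pts[-64:]:
            if (px - x) ** 2 + (py - y) ** 2 < min_dist**2:
                ok = False
                break
        if ok and len(pts) > 64:
            d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
            if d2.min() < min_dist**2:
                ok = False
        if ok:
            pts.append((x, y))
            if len(pts) % 64 == 0:
                arr = np.asarray(pts)
    # touching partners: offset an existing point by touch_dist
    placed = list(pts)
    for i in range(n_touching):
        if not placed:
            break
        base = placed[rng.integers(0, len(placed))]
        for _ in range(20):
            theta = rng.uniform(0, 2 * math.pi)
            x = base[0] + touch_dist * math.cos(theta)
            y = base[1] + touch_dist * math.sin(theta)
            if inner.covers(Point(x, y)):
                pts.append((x, y))
                break
        else:
            # fall back to an ordinary point so the region count is exact
            while True:
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if inner.covers(Point(x, y)):
                    pts.append((x, y))
                    break
    # top up if rejection sampling ran out of attempts (very dense specs)
    while len(pts) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if inner.covers(Point(x, y)):
            pts.append((x, y))
    return np.asarray(pts[:n], dtype=float)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``weights``."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts


def _make_layout(spec: SectionSpec) -> tuple[TileLayout, int, int]:
    b = spec.geometry.bounds_um
    width_um = b[2] + b[0]
    height_um = b[3] + b[1]
    px = spec.pixel_size_um
    width_px = int(math.ceil(width_um / px))
    height_px = int(math.ceil(height_um / px))
    stride = int(round(spec.tile_size_px * (1.0 - spec.overlap_fraction)))
    n_cols = max(1, int(math.ceil((width_px - spec.tile_size_px) / stride)) + 1)
    n_rows = max(1, int(math.ceil((height_px - spec.tile_size_px) / stride)) + 1)
    tiles = [
        TilePosition(row=r, col=c, x_um=c * stride * px, y_um=r * stride * px)
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    layout = TileLayout(
        tiles=tiles,
        tile_size_px=spec.tile_size_px,
        overlap_fraction=spec.overlap_fraction,
        pixel_size_um=px,
    )
    mosaic_w = stride * (n_cols - 1) + spec.tile_size_px
    mosaic_h = stride * (n_rows - 1) + spec.tile_size_px
    return layout, mosaic_w, mosaic_h


def build_scene(spec: SectionSpec, seed: int) -> Scene:
    """Draw the ground truth and all object rendering attributes.

    All placement / identity randomness is consumed here in a fixed order,
    so equal (spec, seed) gives bit-identical scenes; per-tile sensor noise
    uses separate child streams keyed on the tile grid position.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EC710]))
    neuron_f = _as_region_map(spec.neuron_fraction_by_region, "neuron_fraction_by_region")
    trans_f = _as_region_map(spec.transduction_fraction_by_region, "transduction_fraction_by_region")
    neuron_trans = (
        _as_region_map(spec.neuron_transduction_by_region, "neuron_transduction_by_region")
        if spec.neuron_transduction_by_region is not None
        else None
    )
    region_names = list(spec.geometry.regions)
    areas = np.array([spec.geometry.regions[r].area for r in region_names])
    counts = _largest_remainder(spec.n_nuclei, areas)
    r_mean, r_sd = spec.nucleus_radius_um
    min_dist = 1.5 * r_mean
    touch_dist = 1.9 * r_mean

    rows = []
    cell_id = 0
    for r_name, n_r in zip(region_names, counts):
        n_touch = int(round(spec.touching_fraction * n_r))
        xy = _place_in_region(spec.geometry.regions[r_name], n_r, min_dist, touch_dist, n_touch, rng)
        f_n = neuron_f.get(r_name, 0.0)
        f_t = trans_f.get(r_name, 0.0)
        is_neuron = rng.random(n_r) < f_n
        if neuron_trans is not None:
            u = neuron_trans.get(r_name, f_t)
            v = (f_t - f_n * u) / (1.0 - f_n) if f_n < 1.0 else u
            v = min(max(v, 0.0), 1.0)
            p = np.where(is_neuron, u, v)
        else:
            p = np.full(n_r, f_t)
        is_trans = rng.random(n_r) < p
        radii = np.clip(rng.normal(r_mean, r_sd, n_r), 2.2, None)
        for i in range(n_r):
            rows.append(
                {
                    "cell_id": cell_id,
                    "x_um": xy[i, 0],
                    "y_um": xy[i, 1],
                    "region": r_name,
                    "is_neuron": bool(is_neuron[i]),
                    "is_transduced": bool(is_trans[i]),
                    "radius_um": float(radii[i]),
                }
            )
            cell_id += 1
    cells = pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "region", "is_neuron", "is_transduced", "radius_um"]
    )
    if len(cells) == 0:
        cells = cells.astype({"cell_id": int, "x_um": float, "y_um": float, "region": str,
                              "is_neuron": bool, "is_transduced": bool, "radius_um": float})

    layout, mosaic_w, mosaic_h = _make_layout(spec)
    depth = (spec.n_z - 1) * spec.z_step_um
    n = len(cells)
    z0 = rng.uniform(0.25 * depth, 0.75 * depth, n) if spec.n_z > 1 else np.zeros(n)
    B = spec.background_counts

    # per-channel amplitude factors: Hoechst is stoichiometric (tight),
    # antibody staining and reporter expression vary more
    amp_hoechst = spec.snr_for("hoechst") * B * np.exp(rng.normal(0.0, 0.1, n))
    amp_neun = spec.snr_for("neun") * B * np.exp(rng.normal(0.0, 0.15, n))
    amp_gfp_bright = spec.snr_for("gfp") * B * np.exp(rng.normal(0.0, 0.2, n))
    amp_gfp_auto = (
        spec.snr_for("gfp") * B * spec.gfp_autofluorescence
        * np.exp(rng.normal(0.0, spec.gfp_autofluorescence_sigma, n))
    )

    sigma_z_cell = 3.0  # um, axial falloff scale for in-tissue objects
    objects: dict[str, list[np.ndarray]] = {c: [] for c in CHANNELS}
    if n:
        x = cells["x_um"].to_numpy()
        y = cells["y_um"].to_numpy()
        radii = cells["radius_um"].to_numpy()
        is_neuron = cells["is_neuron"].to_numpy()
        is_trans = cells["is_transduced"].to_numpy()

        hoechst = np.zeros(n, dtype=_OBJ_DTYPE)
        hoechst["x"], hoechst["y"], hoechst["radius"] = x, y, radii
        hoechst["amp"], hoechst["z0"] = amp_hoechst, z0
        hoechst["sigma_z"], hoechst["kind"] = sigma_z_cell, _FLAT
        objects["hoechst"].append(hoechst)

        # NeuN is a neuronal *nuclear* antigen with weaker cytoplasmic
        # staining: render a bright nuclear core plus a dimmer somatic
        # plateau, so adjacent neurons keep an intensity saddle between
        # their cores that object splitting can exploit
        idx_n = np.flatnonzero(is_neuron)
        core = np.zeros(len(idx_n), dtype=_OBJ_DTYPE)
        core["x"], core["y"] = x[idx_n], y[idx_n]
        core["radius"] = 1.15 * radii[idx_n]  # nucleus plus perinuclear rim
        core["amp"], core["z0"] = amp_neun[idx_n], z0[idx_n]
        core["sigma_z"], core["kind"] = sigma_z_cell, _FLAT
        soma = core.copy()
        # soma size does not track the nucleus-size draw: small-nucleus
        # neurons still have full-sized somata
        soma["radius"] = spec.soma_radius_um
        soma["amp"] = 0.55 * amp_neun[idx_n]
        objects["neun"].append(core)
        objects["neun"].append(soma)

        # every nucleus has a dim autofluorescence floor in GFP; transduced
        # nuclei get the full reporter amplitude
        gfp = np.zeros(n, dtype=_OBJ_DTYPE)
        gfp["x"], gfp["y"] = x, y
        gfp["radius"] = 0.95 * radii
        gfp["amp"] = np.where(is_trans, amp_gfp_bright, amp_gfp_auto)
        gfp["z0"], gfp["sigma_z"], gfp["kind"] = z0, sigma_z_cell, _FLAT
        objects["gfp"].append(gfp)

    # debris speckles in the marker channels
    bounds = spec.geometry.bounds_um
    bbox_area_mm2 = (mosaic_w * spec.pixel_size_um) * (mosaic_h * spec.pixel_size_um) / 1e6
    debris_rows = []
    debris_id = 0
    for channel in ("neun", "gfp"):
        n_d = rng.poisson(spec.debris_rate * bbox_area_mm2)
        if n_d == 0:
            continue
        d = np.zeros(n_d, dtype=_OBJ_DTYPE)
        d["x"] = rng.uniform(0.0, mosaic_w * spec.pixel_size_um, n_d)
        d["y"] = rng.uniform(0.0, mosaic_h * spec.pixel_size_um, n_d)
        d["radius"] = rng.uniform(0.7, 2.8, n_d)  # Gaussian sigma, um
        d["amp"] = spec.snr_for(channel) * B * rng.uniform(1.5, 3.0, n_d)
        d["z0"] = rng.uniform(0.0, depth if depth > 0 else 1.0, n_d) if spec.n_z > 1 else 0.0
        d["sigma_z"], d["kind"] = 1.5, _GAUSS
        objects[channel].append(d)
        for i in range(n_d):
            debris_rows.append(
                {
                    "object_id": debris_id,
                    "channel": channel,
                    "x_um": float(d["x"][i]),
                    "y_um": float(d["y"][i]),
                    "size_um": float(d["radius"][i]),
                    "amplitude": float(d["amp"][i]),
                }
            )
            debris_id += 1
    debris = pd.DataFrame(debris_rows, columns=["object_id", "channel", "x_um", "y_um", "size_um", "amplitude"])

    packed = {
        c: (np.concatenate(parts) if parts else np.zeros(0, dtype=_OBJ_DTYPE)) for c, parts in objects.items()
    }
    truth = GroundTruth(cells=cells, debris=debris)
    return Scene(truth=truth, objects=packed, layout=layout, width_px=mosaic_w, height_px=mosaic_h)


# ---------------------------------------------------------------------------
# Rendering


def _render_tile(scene: Scene, spec: SectionSpec, row: int, col: int, seed: int) -> MultiChannelStack:
    px = spec.pixel_size_um
    size = spec.tile_size_px
    stride = scene.layout.stride_px
    x0_um, y0_um = col * stride * px, row * stride * px
    zs = np.arange(spec.n_z, dtype=np.float64) * spec.z_step_um
    B = spec.background_counts
    channels: dict[str, np.ndarray] = {}
    for ci, channel in enumerate(CHANNELS):
        # objects occlude rather than add (stained bodies sit side by side,
        # they are not transparent emitters), so same-channel signal is
        # composited by per-pixel maximum; this also keeps an intensity
        # saddle between touching nuclei for the splitting step to find
        sig = np.zeros((spec.n_z, size, size), dtype=np.float64)
        objs = scene.objects[channel]
        if len(objs):
            # pad by the object's own footprint so boundary objects render
            pad = np.where(objs["kind"] == _FLAT, 1.8 * objs["radius"], 3.5 * objs["radius"])
            sel = (
                (objs["x"] + pad >= x0_um)
                & (objs["x"] - pad <= x0_um + size * px)
                & (objs["y"] + pad >= y0_um)
                & (objs["y"] - pad <= y0_um + size * px)
            )
            for o, p in zip(objs[sel], pad[sel]):
                cx = (o["x"] - x0_um) / px
                cy = (o["y"] - y0_um) / px
                rp = p / px
                xlo, xhi = max(0, int(cx - rp)), min(size, int(cx + rp) + 2)
                ylo, yhi = max(0, int(cy - rp)), min(size, int(cy + rp) + 2)
                if xlo >= xhi or ylo >= yhi:
                    continue
                yy, xx = np.ogrid[ylo:yhi, xlo:xhi]
                r2 = ((xx + 0.5 - cx) * px) ** 2 + ((yy + 0.5 - cy) * px) ** 2
                if o["kind"] == _FLAT:
                    # flat plateau with a steep rim at ~0.8 of the nominal
                    # radius (chromatin boundary), near-zero beyond it
                    core = 0.8 * o["radius"]
                    patch = o["amp"] / (1.0 + (r2 / core**2) ** 4)
                else:
                    patch = o["amp"] * np.exp(-r2 / (2.0 * o["radius"] ** 2))
                fz = np.exp(-((zs - o["z0"]) ** 2) / (2.0 * o["sigma_z"] ** 2))
                block = sig[:, ylo:yhi, xlo:xhi]
                np.maximum(block, patch[None, :, :] * fz[:, None, None], out=block)
        vol = sig + B
        # Poisson-Gaussian sensor model, normal approximation of the shot
        # noise (counts are >= 100 everywhere, where the approximation is
        # excellent and ~4x faster than exact Poisson draws)
        tile_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7015E, row, col, ci]))
        noisy = tile_rng.normal(vol, np.sqrt(vol + spec.read_noise_counts**2))
        channels[channel] = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)
    return MultiChannelStack(channels=channels, pixel_size_um=px, z_step_um=spec.z_step_um)


def generate_section(
    spec: SectionSpec, seed: int
) -> tuple[dict[tuple[int, int], MultiChannelStack], TileLayout, GroundTruth]:
    """Generate all tiles of one section plus its ground truth.

    Identical (spec, seed) gives bit-identical pixel data and truth tables.
    For large specs prefer :func:`generate_section_mosaic`, which streams
    tiles through maximum projection without retaining the stacks.
    """
    scene = build_scene(spec, seed)
    tiles = {
        (t.row, t.col): _render_tile(scene, spec, t.row, t.col, seed) for t in scene.layout.tiles
    }
    return tiles, scene.layout, scene.truth


def generate_section_mosaic(spec: SectionSpec, seed: int) -> tuple[Mosaic, TileLayout, GroundTruth]:
    """Generate a section and return the stitched maximum-projection mosaic.

    Equivalent to generate_section -> max_project each tile -> stitch, but
    tiles are discarded as soon as they are projected.
    """
    from .imgio import max_project

    scene = build_scene(spec, seed)
    projections = {}
    for t in scene.layout.tiles:
        stack = _render_tile(scene, spec, t.row, t.col, seed)
        projections[(t.row, t.col)] = max_project(stack)
    mosaic = stitch(projections, scene.layout)
    return mosaic, scene.layout, scene.truth


def section_seed(seed: int, index: int) -> int:
    """Deterministic per-section seed for a series; stays below 2**31."""
    return int((int(seed) * 1000003 + 7919 * (index + 1)) % (2**31))


def generate_brain_series(
    spec: SectionSpec, n_sections: int, seed: int, scale_range: tuple[float, float] = (0.85, 1.0)
) -> list[tuple[SectionSpec, int, GroundTruth]]:
    """Plan a series of sections sampled along the anterior-posterior axis.

    Geometry scales smoothly (small at the poles, largest mid-brain) to
    mimic sampling every Nth section through the whole brain.  Returns a
    (section spec, derived seed, truth) triple per section; pixel data are
    rendered lazily by the caller with :func:`generate_section_mosaic` so a
    whole series never has to be held in memory.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    lo, hi = scale_range
    out = []
    for i in range(n_sections):
        frac = (i + 0.5) / n_sections
        s = lo + (hi - lo) * math.sin(math.pi * frac)
        sec_spec = replace(spec, geometry=spec.geometry.scaled(s))
        s_seed = section_seed(seed, i)
        scene = build_scene(sec_spec, s_seed)
        out.append((sec_spec, s_seed, scene.truth))
    return out
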