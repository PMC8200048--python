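"""Nucleus and marker-cell detection on stitched maximum projections.

The detector re-specifies the published parameterisation of a proprietary
HCS "find nuclei" / "find cells" step as an open algorithm with the same
knobs and the same monotone roles:

1. Gaussian smoothing (default 3 px).
2. Global robust threshold: background + CT x (99.9th percentile - background),
   where CT is the *common threshold* fraction.
3. Connected components, then a per-object *individual threshold*:
   background + IT x (object peak - background).
4. Marker-controlled watershed splitting: candidate intensity maxima are
   kept when separated by at least (20 / SC) um, so a larger *splitting
   coefficient* SC splits more aggressively and SC = 0 disables splitting.
5. Filters: area strictly greater than the printed minimum; a contrast
   quality bound; objects touching the mosaic border are discarded.

Contrast is (object mean - local background mean) / (object mean + local
background mean) on the smoothed image, with local background taken from an
annulus around the object excluding any detected foreground.  The published
criteria print a contrast *limit* without stating its direction; here the
default direction ``"below"`` treats the limit as a minimum distinctness
(objects with contrast below the limit are excluded), which is the reading
under which the printed values keep genuine nuclei.  The opposite reading
is available as ``contrast_direction="above"``.

Printed parameter presets: nuclei (CT 0.35, area > 15 um^2, SC 7, IT 0.4,
contrast 0.06), NeuN (CT 0.1, area > 30 um^2, SC 4, IT 0.4, contrast 0.1),
GFP (CT 0.1, area > 14 um^2, SC 7, IT 0.4, contrast 0.18).  The relaxed GFP
reanalysis keeps the same detection parameters; relaxation happens in the
downstream morphology gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from .imgio import Mosaic, TileLayout

SPLIT_SEPARATION_CONSTANT_UM = 20.0  # min maxima separation = const / SC


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma_px: float = 3.0
    common_threshold: float = 0.35  # CT: global threshold fraction
    individual_threshold: float = 0.4  # IT: per-object re-threshold fraction
    min_area_um2: float = 15.0  # strict: area must exceed this
    splitting_coefficient: float = 7.0  # SC: 0 disables splitting
    contrast_limit: float = 0.06
    contrast_direction: str = "below"  # "below": exclude low-contrast objects

    def validate(self) -> None:
        if not (0.0 <= self.common_threshold <= 1.0):
            raise ValueError("common_threshold must be in [0, 1]")
        if not (0.0 <= self.individual_threshold <= 1.0):
            raise ValueError("individual_threshold must be in [0, 1]")
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be > 0")
        if self.splitting_coefficient < 0:
            raise ValueError("splitting_coefficient must be >= 0")
        if not (0.0 <= self.contrast_limit <= 1.0):
            raise ValueError("contrast_limit must be in [0, 1]")
        if self.contrast_direction not in ("below", "above"):
            raise ValueError("contrast_direction must be 'below' or 'above'")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")


#: Printed parameter sets for the three detection channels.  ``gfp_relaxed``
#: shares the gfp detection parameters; the relaxation is applied in gating.
PRESETS: dict[str, SegmentationParams] = {
    "nuclei": SegmentationParams(
        common_threshold=0.35, min_area_um2=15.0, splitting_coefficient=7.0,
        individual_threshold=0.4, contrast_limit=0.06,
    ),
    "neun": SegmentationParams(
        common_threshold=0.1, min_area_um2=30.0, splitting_coefficient=4.0,
        individual_threshold=0.4, contrast_limit=0.1,
    ),
    "gfp": SegmentationParams(
        common_threshold=0.1, min_area_um2=14.0, splitting_coefficient=7.0,
        individual_threshold=0.4, contrast_limit=0.18,
    ),
}
PRESETS["gfp_relaxed"] = PRESETS["gfp"]


def load_presets(path: str) -> dict[str, SegmentationParams]:
    """Read named parameter presets from a key-value config file.

    Format: one ``preset.key = value`` per line, ``#`` comments.  Unlisted
    keys default to the printed values above.
    """
    raw: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = (s.strip() for s in line.split("=", 1))
            preset, param = key.split(".", 1)
            raw.setdefault(preset, {})[param] = value
    out = {}
    for preset, kv in raw.items():
        base = PRESETS.get(preset, SegmentationParams())
        fields = {}
        for k, v in kv.items():
            fields[k] = v if k == "contrast_direction" else float(v)
        out[preset] = replace(base, **fields)
        out[preset].validate()
    return out


@dataclass
class DetectedObject:
    """One segmented nucleus or marker-cell candidate."""

    object_id: int
    channel: str
    x_um: float
    y_um: float
    area_um2: float
    mean_intensity: float
    peak_intensity: float
    contrast: float
    roundness: float
    # mask as (row0, col0, bool array) in mosaic pixel coordinates
    mask_offset: tuple[int, int] = (0, 0)
    mask: np.ndarray | None = None
    tile_id: int | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum()) if self.mask is not None else 0


def smooth(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing; sigma 0 returns the input unchanged."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    img = np.asarray(image, dtype=np.float64)
    if sigma_px == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma_px, mode="nearest")


def _select_maxima(
    values: np.ndarray, mask: np.ndarray, min_sep_px: int, threshold_abs: float | None = None
) -> np.ndarray:
    """Local maxima kept when pairwise (Euclidean) separation >= min_sep_px.

    Candidate maxima (connected plateau regions collapsed to their
    centroid) are accepted greedily in decreasing height order, enforcing
    the separation criterion with exact Euclidean distances.
    """
    local_max = (values == ndimage.maximum_filter(values, size=5)) & mask
    if threshold_abs is not None:
        local_max &= values >= threshold_abs
    # a flat plateau is one maximum, not many: collapse connected plateau
    # pixels to their centroid before enforcing the separation criterion
    lbl, n = ndimage.label(local_max, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.empty((0, 2), dtype=int)
    centroids = ndimage.center_of_mass(local_max, lbl, range(1, n + 1))
    cands = np.array([[int(round(r)), int(round(c))] for r, c in centroids])
    # snap any centroid that fell off the mask (concave plateaus) back on
    for k, (r, c) in enumerate(cands):
        if not mask[r, c]:
            rows, cols = np.nonzero(lbl == k + 1)
            j = np.argmin((rows - r) ** 2 + (cols - c) ** 2)
            cands[k] = (rows[j], cols[j])
    heights = values[cands[:, 0], cands[:, 1]]
    order = np.argsort(-heights, kind="stable")
    kept: list[np.ndarray] = []
    for ci in order:
        c = cands[ci]
        if all(np.hypot(*(c - k)) >= min_sep_px for k in kept):
            kept.append(c)
    return np.array(kept)


def _detect(
    image: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
    channel: str,
    origin_um: tuple[float, float] = (0.0, 0.0),
    tile_id: int | None = None,
) -> list[DetectedObject]:
    params.validate()
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    im = smooth(image, params.smoothing_sigma_px)
    bg = float(np.median(im))
    hi = float(np.percentile(im, 99.9))
    if hi - bg <= 1e-12:
        return []  # blank / zero-variance image: nothing to find
    global_thr = bg + params.common_threshold * (hi - bg)
    fg = im > global_thr
    if not fg.any():
        return []
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    slices = ndimage.find_objects(labels)
    px_area = pixel_size_um**2
    sc = params.splitting_coefficient
    min_sep_px = (
        max(1, int(round((SPLIT_SEPARATION_CONSTANT_UM / sc) / pixel_size_um))) if sc > 0 else None
    )
    h, w = im.shape
    objects: list[DetectedObject] = []
    oid = 0
    annulus_struct = ndimage.generate_binary_structure(2, 2)
    for comp_index, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        # work on a padded bounding box so dilation for the annulus fits
        pad = 6
        r0 = max(0, sl[0].start - pad)
        r1 = min(h, sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(w, sl[1].stop + pad)
        patch = im[r0:r1, c0:c1]
        comp_mask = labels[r0:r1, c0:c1] == comp_index
        any_fg = fg[r0:r1, c0:c1]
        # split the component into candidate cells FIRST (intensity maxima
        # satisfying the separation criterion), so that the individual
        # re-threshold can use each cell's own peak: in confluent tissue a
        # single bright cell must not raise the bar for a whole chain of
        # touching cells
        cell_regions: list[np.ndarray]
        if min_sep_px is not None:
            coords = _select_maxima(np.where(comp_mask, patch, 0.0), comp_mask, min_sep_px)
            if len(coords) > 1:
                markers = np.zeros(comp_mask.shape, dtype=int)
                for mi, (rr, cc) in enumerate(coords, start=1):
                    markers[rr, cc] = mi
                ws = watershed(-patch, markers=markers, mask=comp_mask)
                cell_regions = [ws == mi for mi in range(1, len(coords) + 1)]
            else:
                cell_regions = [comp_mask]
        else:
            cell_regions = [comp_mask]
        sub_masks: list[np.ndarray] = []
        for region in cell_regions:
            if not region.any():
                continue
            own_peak = float(patch[region].max())
            indiv_thr = bg + params.individual_threshold * (own_peak - bg)
            core = region & (patch >= indiv_thr)
            if not core.any():
                continue
            # keep the fragment holding the cell's peak; other islands are
            # shards at the watershed boundary
            frags, _n = ndimage.label(core, structure=np.ones((3, 3), dtype=int))
            pr, pc = np.unravel_index(np.argmax(np.where(region, patch, -np.inf)), patch.shape)
            frag = frags == frags[pr, pc]
            if not frag.any():
                continue
            if min_sep_px is not None:
                # secondary shape-based split: equal-intensity cells fused
                # without a usable saddle still show two lobes in the
                # distance transform of the core mask
                edt = ndimage.distance_transform_edt(frag)
                edt_coords = _select_maxima(edt, frag, min_sep_px, threshold_abs=2.0)
                if len(edt_coords) > 1:
                    markers = np.zeros(frag.shape, dtype=int)
                    for mi, (rr, cc) in enumerate(edt_coords, start=1):
                        markers[rr, cc] = mi
                    ws = watershed(-edt, markers=markers, mask=frag)
                    sub_masks.extend(ws == mi for mi in range(1, len(edt_coords) + 1))
                else:
                    sub_masks.append(frag)
            else:
                sub_masks.append(frag)
        for sub in sub_masks:
                npx = int(sub.sum())
                if npx == 0:
                    continue
                area = npx * px_area
                if not (area > params.min_area_um2):
                    continue
                rows, cols = np.nonzero(sub)
                # discard border-touching objects (partial-area artifacts)
                if (
                    (rows.min() + r0 == 0)
                    or (cols.min() + c0 == 0)
                    or (rows.max() + r0 == h - 1)
                    or (cols.max() + c0 == w - 1)
                ):
                    continue
                obj_mean = float(patch[sub].mean())
                obj_peak = float(patch[sub].max())
                annulus = ndimage.binary_dilation(sub, annulus_struct, iterations=5) & ~any_fg
                if annulus.any():
                    local_bg = float(np.median(patch[annulus]))
                else:
                    local_bg = bg
                denom = obj_mean + local_bg
                contrast = (obj_mean - local_bg) / denom if denom > 0 else 0.0
                if params.contrast_direction == "below":
                    if contrast < params.contrast_limit:
                        continue
                else:
                    if contrast >= params.contrast_limit:
                        continue
                # moments-based roundness 4A/(pi * major_axis^2): exactly 1
                # for a disk, robust to rasterisation unlike perimeter-based
                if npx > 1:
                    cov = np.cov(np.vstack([rows, cols]).astype(float))
                    major = 4.0 * math.sqrt(max(np.linalg.eigvalsh(cov).max(), 1e-12))
                    roundness = min(1.0, 4.0 * npx / (math.pi * major**2))
                else:
                    roundness = 1.0
                cy = rows.mean() + r0
                cx = cols.mean() + c0
                objects.append(
                    DetectedObject(
                        object_id=oid,
                        channel=channel,
                        x_um=origin_um[0] + (cx + 0.5) * pixel_size_um,
                        y_um=origin_um[1] + (cy + 0.5) * pixel_size_um,
                        area_um2=area,
                        mean_intensity=obj_mean,
                        peak_intensity=obj_peak,
                        contrast=contrast,
                        roundness=roundness,
                        mask_offset=(rows.min() + r0, cols.min() + c0),
                        mask=sub[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1].copy(),
                        tile_id=tile_id,
                    )
                )
                oid += 1
    return objects


def find_nuclei(
    hoechst: Mosaic | np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float | None = None,
    tile_id: int | None = None,
) -> list[DetectedObject]:
    """Detect cell nuclei on a Hoechst maximum-projection mosaic."""
    params = params if params is not None else PRESETS["nuclei"]
    if isinstance(hoechst, Mosaic):
        return _detect(hoechst.channels["hoechst"], params, hoechst.pixel_size_um,
                       "hoechst", hoechst.origin_um, tile_id)
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required when passing a bare array")
    return _detect(hoechst, params, pixel_size_um, "hoechst", (0.0, 0.0), tile_id)


def find_marker_cells(
    marker: Mosaic | np.ndarray,
    channel: str,
    params: SegmentationParams | None = None,
    pixel_size_um: float | None = None,
    tile_id: int | None = None,
) -> list[DetectedObject]:
    """Detect marker-positive cell candidates (NeuN somata or GFP nuclei)."""
    if params is None:
        params = PRESETS.get(channel)
        if params is None:
            raise ValueError(f"no default preset for channel {channel!r}")
    if isinstance(marker, Mosaic):
        return _detect(marker.channels[channel], params, marker.pixel_size_um,
                       channel, marker.origin_um, tile_id)
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required when passing a bare array")
    return _detect(marker, params, pixel_size_um, channel, (0.0, 0.0), tile_id)


def dedup_overlap(
    objects: list[DetectedObject],
    layout: TileLayout | None = None,
    radius_um: float = 3.5,
) -> list[DetectedObject]:
    """Merge duplicate detections of one cell seen by two overlapping tiles.

    Pairs of same-channel objects from *different* tiles closer than
    ``radius_um`` are merged, keeping the larger-area member.  Pairs are
    processed in increasing distance order; ties break on object identity,
    so the result is deterministic and matches a brute-force all-pairs merge.
    Objects from a single mosaic (``tile_id`` None everywhere) are returned
    unchanged unless they carry distinct tile ids.
    """
    alive = list(objects)
    if len(alive) < 2:
        return alive
    pts = np.array([[o.x_um, o.y_um] for o in alive])
    tree = cKDTree(pts)
    pairs = []
    for i, j in sorted(tree.query_pairs(radius_um)):
        a, b = alive[i], alive[j]
        if a.channel != b.channel:
            continue
        if a.tile_id is None or b.tile_id is None or a.tile_id == b.tile_id:
            continue
        d = math.hypot(a.x_um - b.x_um, a.y_um - b.y_um)
        pairs.append((d, i, j))
    pairs.sort()
    removed: set[int] = set()
    for _, i, j in pairs:
        if i in removed or j in removed:
            continue
        a, b = alive[i], alive[j]
        # keep the larger area; on a tie keep the lower object identity
        if (a.area_um2, -i) >= (b.area_um2, -j):
            removed.add(j)
        else:
            removed.add(i)
    return [o for k, o in enumerate(alive) if k not in removed]
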