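"""Detection: thresholds, area/contrast filters, splitting, deduplication."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from aavquant import (
    PRESETS,
    dedup_overlap,
    find_marker_cells,
    find_nuclei,
    smooth,
)
from aavquant.imgio import Mosaic, max_project
from aavquant.pipeline import match_detections
from aavquant.segment import DetectedObject, load_presets
from aavquant.synth import generate_section
from conftest import small_spec

PX = 0.5  # um per pixel used by the synthetic fixtures


def disk_image(area_um2, px=PX, amp=1000.0, bg=100.0, size=80):
    """Hard disk of an exact pixel count matching the requested area."""
    n_px = int(round(area_um2 / px**2))
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - size / 2) ** 2 + (xx - size / 2) ** 2
    order = np.argsort(r2.ravel(), kind="stable")[:n_px]
    img = np.full((size, size), bg)
    img.ravel()[order] += amp
    return img


def flat_top_pair(dist_um, radius_um=3.5, px=PX, amp=1000.0, bg=100.0, size=120):
    """Two nuclei rendered the way the generator draws them (max composite)."""
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for cx in (size / 2 - dist_um / 2 / px, size / 2 + dist_um / 2 / px):
        r2 = ((xx - cx) * px) ** 2 + ((yy - size / 2) * px) ** 2
        core = 0.8 * radius_um
        img = np.maximum(img, amp / (1.0 + (r2 / core**2) ** 4))
    return img + bg


def no_smoothing(preset):
    return dataclasses.replace(preset, smoothing_sigma_px=0.0)


class TestSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((30, 30), 42.0)
        np.testing.assert_allclose(smooth(img, 3.0), img)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20))
        np.testing.assert_array_equal(smooth(img, 0.0), img)

    def test_single_bright_pixel_mass_conserved(self):
        # discrete Gaussian oracle: peak drops, total mass is conserved on
        # the interior (kernel support well inside the image)
        img = np.zeros((41, 41))
        img[20, 20] = 1000.0
        out = smooth(img, 3.0)
        assert out[20, 20] < 1000.0
        assert abs(out.sum() - 1000.0) / 1000.0 < 1e-3

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros((5, 5)), -1.0)


class TestFindNuclei:
    def test_blank_image_returns_empty(self):
        assert find_nuclei(np.zeros((50, 50)), pixel_size_um=PX) == []
        assert find_nuclei(np.full((50, 50), 7.0), pixel_size_um=PX) == []

    def test_area_filter_is_strict(self):
        # printed criterion: area > 15 um^2; a 12 um^2 nucleus is excluded
        params = no_smoothing(PRESETS["nuclei"])
        assert find_nuclei(disk_image(12.0), params, pixel_size_um=PX) == []
        kept = find_nuclei(disk_image(20.0), params, pixel_size_um=PX)
        assert len(kept) == 1
        assert kept[0].area_um2 == pytest.approx(20.0, abs=2 * PX**2)

    def test_recall_and_precision_on_synthetic_section(self, section):
        mosaic, _, truth = section
        objs = find_nuclei(mosaic)
        xy = truth.cells[["x_um", "y_um"]].to_numpy()
        matched = match_detections(objs, xy, radius_um=3.5)
        tp = int((matched >= 0).sum())
        assert tp / len(xy) >= 0.95  # recall
        assert tp / len(objs) >= 0.95  # precision

    def test_mask_pixels_exceed_individual_threshold(self, section):
        mosaic, _, _ = section
        params = PRESETS["nuclei"]
        im = smooth(mosaic.channels["hoechst"], params.smoothing_sigma_px)
        bg = float(np.median(im))
        for obj in find_nuclei(mosaic)[:50]:
            r0, c0 = obj.mask_offset
            h, w = obj.mask.shape
            patch = im[r0 : r0 + h, c0 : c0 + w]
            own_threshold = bg + params.individual_threshold * (obj.peak_intensity - bg)
            assert patch[obj.mask].min() >= own_threshold - 1e-6

    def test_raising_thresholds_never_increases_count(self, section):
        mosaic, _, _ = section
        base = PRESETS["nuclei"]
        n_base = len(find_nuclei(mosaic, base))
        for min_area in (20.0, 30.0, 50.0):
            n = len(find_nuclei(mosaic, dataclasses.replace(base, min_area_um2=min_area)))
            assert n <= n_base
            n_base_area = n
        n_base = len(find_nuclei(mosaic, base))
        last = n_base
        for ct in (0.45, 0.55):
            n = len(find_nuclei(mosaic, dataclasses.replace(base, common_threshold=ct)))
            assert n <= last
            last = n

    def test_splitting_coefficient_controls_object_splitting(self):
        # two nuclei two radii apart: split at SC=7, merged at SC=0
        img = flat_top_pair(dist_um=7.0)
        at_sc7 = find_nuclei(img, PRESETS["nuclei"], pixel_size_um=PX)
        at_sc0 = find_nuclei(
            img, dataclasses.replace(PRESETS["nuclei"], splitting_coefficient=0.0), pixel_size_um=PX
        )
        assert len(at_sc7) == 2
        assert len(at_sc0) == 1


class TestFindMarkerCells:
    def test_neun_area_filter(self):
        # printed NeuN criterion: area > 30 um^2
        params = no_smoothing(PRESETS["neun"])
        assert find_marker_cells(disk_image(25.0), "neun", params, pixel_size_um=PX) == []
        assert len(find_marker_cells(disk_image(40.0), "neun", params, pixel_size_um=PX)) == 1

    def test_gfp_area_filter(self):
        # printed GFP criterion: area > 14 um^2 -> a 20 um^2 candidate stays
        params = no_smoothing(PRESETS["gfp"])
        kept = find_marker_cells(disk_image(20.0), "gfp", params, pixel_size_um=PX)
        assert len(kept) == 1

    def test_blank_marker_channel(self):
        assert find_marker_cells(np.zeros((40, 40)), "gfp", pixel_size_um=PX) == []


class TestDedupOverlap:
    def obj(self, oid, x, y, area=40.0, tile_id=0, channel="hoechst"):
        return DetectedObject(
            object_id=oid, channel=channel, x_um=x, y_um=y, area_um2=area,
            mean_intensity=1.0, peak_intensity=1.0, contrast=0.5, roundness=1.0,
            tile_id=tile_id,
        )

    def test_duplicate_pair_merged_keeping_larger(self):
        a = self.obj(0, 10.0, 10.0, area=50.0, tile_id=0)
        b = self.obj(1, 10.8, 10.2, area=30.0, tile_id=1)
        out = dedup_overlap([a, b], radius_um=3.5)
        assert out == [a]

    def test_distinct_objects_both_retained(self):
        a = self.obj(0, 10.0, 10.0, tile_id=0)
        b = self.obj(1, 40.0, 10.0, tile_id=1)
        assert len(dedup_overlap([a, b], radius_um=3.5)) == 2

    def test_same_tile_pairs_not_merged(self):
        a = self.obj(0, 10.0, 10.0, tile_id=0)
        b = self.obj(1, 11.0, 10.0, tile_id=0)
        assert len(dedup_overlap([a, b], radius_um=3.5)) == 2

    def test_matches_brute_force_merge(self):
        # O(n^2) oracle with the same deterministic pair ordering
        rng = np.random.default_rng(5)
        objs = []
        for i in range(120):
            x, y = rng.uniform(0, 80, 2)
            objs.append(
                self.obj(i, x, y, area=float(rng.uniform(20, 60)), tile_id=int(rng.integers(0, 4)))
            )
        radius = 4.0

        def brute_force(objects):
            alive = list(objects)
            pairs = []
            for i in range(len(alive)):
                for j in range(i + 1, len(alive)):
                    a, b = alive[i], alive[j]
                    if a.channel != b.channel or a.tile_id == b.tile_id:
                        continue
                    d = math.hypot(a.x_um - b.x_um, a.y_um - b.y_um)
                    if d < radius:
                        pairs.append((d, i, j))
            pairs.sort()
            removed = set()
            for _, i, j in pairs:
                if i in removed or j in removed:
                    continue
                a, b = alive[i], alive[j]
                if (a.area_um2, -i) >= (b.area_um2, -j):
                    removed.add(j)
                else:
                    removed.add(i)
            return [o for k, o in enumerate(alive) if k not in removed]

        fast = dedup_overlap(objs, radius_um=radius)
        slow = brute_force(objs)
        assert [o.object_id for o in fast] == [o.object_id for o in slow]

    def test_nucleus_in_overlap_zone_counted_once(self):
        # per-tile detection sees seam nuclei twice; dedup keeps exactly one
        spec = small_spec(n_nuclei=120, debris_rate=0.0)
        tiles, layout, truth = generate_section(spec, seed=4)
        objects = []
        next_id = 0
        for (row, col), stack in tiles.items():
            proj = max_project(stack)
            pos = layout.position(row, col)
            tile_mosaic = Mosaic(
                channels=proj, pixel_size_um=spec.pixel_size_um, origin_um=(pos.x_um, pos.y_um)
            )
            for obj in find_nuclei(tile_mosaic, tile_id=row * 100 + col):
                obj = dataclasses.replace(obj, object_id=next_id)
                next_id += 1
                objects.append(obj)
        deduped = dedup_overlap(objects, layout, radius_um=3.5)
        # no remaining cross-tile near-duplicates
        pts = np.array([[o.x_um, o.y_um] for o in deduped])
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(3.5):
            assert deduped[i].tile_id == deduped[j].tile_id
        # every truth nucleus matched by at most one detection
        xy = truth.cells[["x_um", "y_um"]].to_numpy()
        matched = match_detections(deduped, xy, radius_um=3.5)
        counts = np.bincount(matched[matched >= 0])
        assert counts.max() == 1


class TestPresets:
    def test_printed_parameter_values(self):
        nuc, neun, gfp = PRESETS["nuclei"], PRESETS["neun"], PRESETS["gfp"]
        assert (nuc.common_threshold, nuc.min_area_um2, nuc.splitting_coefficient,
                nuc.individual_threshold, nuc.contrast_limit) == (0.35, 15.0, 7.0, 0.4, 0.06)
        assert (neun.common_threshold, neun.min_area_um2, neun.splitting_coefficient,
                neun.individual_threshold, neun.contrast_limit) == (0.1, 30.0, 4.0, 0.4, 0.1)
        assert (gfp.common_threshold, gfp.min_area_um2, gfp.splitting_coefficient,
                gfp.individual_threshold, gfp.contrast_limit) == (0.1, 14.0, 7.0, 0.4, 0.18)
        assert PRESETS["gfp_relaxed"] == gfp

    def test_preset_file_round_trip(self, tmp_path):
        path = tmp_path / "presets.cfg"
        path.write_text(
            "nuclei.common_threshold = 0.4   # tweak\n"
            "custom.min_area_um2 = 25\n"
            "custom.contrast_direction = above\n"
        )
        presets = load_presets(str(path))
        assert presets["nuclei"].common_threshold == 0.4
        assert presets["nuclei"].min_area_um2 == 15.0
        assert presets["custom"].min_area_um2 == 25.0
        assert presets["custom"].contrast_direction == "above"
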