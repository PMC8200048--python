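"""End-to-end composition: synthesis -> segmentation -> gating -> per-cell
records -> section and region statistics.

The stages are plain functions over in-memory objects; :func:`run_pipeline`
is the file-based wrapper that writes the CSV outputs and a log of every
preset and threshold used.  Researcher labelling of gate training examples
is replaced by :func:`auto_label`, which matches detections against the
generator's ground truth — the synthetic analogue of a human calling each
detection true or false.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import gating, synth
from .gating import DEFAULT_STRINGENCY, RELAXED_STRINGENCY, GateModel
from .imgio import Mosaic
from .quantify import (
    CellRecord,
    SectionStats,
    assign_markers,
    export_cells,
    section_stats,
    stats_frame,
)
from .regions import RoiPolygon, region_stats, region_stats_frame
from .segment import PRESETS, DetectedObject, SegmentationParams, find_marker_cells, find_nuclei
from .synth import GroundTruth, SectionSpec


@dataclass
class PipelineConfig:
    """Run configuration: parameter presets, gate stringencies and seeds."""

    spec: SectionSpec = field(default_factory=SectionSpec)
    n_sections: int = 8
    seed: int = 1
    presets: dict[str, SegmentationParams] = field(default_factory=lambda: dict(PRESETS))
    stringency: float = DEFAULT_STRINGENCY
    relaxed_stringency: float = RELAXED_STRINGENCY
    use_relaxed_gfp: bool = False
    n_labels_per_class: int = 50
    match_radius_um: float = 4.0
    alpha: float = 0.05

    def config_hash(self) -> str:
        text = repr(
            (
                sorted((k, repr(v)) for k, v in self.presets.items()),
                self.stringency,
                self.relaxed_stringency,
                self.use_relaxed_gfp,
                self.n_sections,
                self.seed,
                self.n_labels_per_class,
                self.match_radius_um,
                self.alpha,
                repr(self.spec),
            )
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class SectionResult:
    section_id: int
    truth: GroundTruth
    cells: list[CellRecord]
    stats: SectionStats
    nuclei: list[DetectedObject]
    neun_gated: list[DetectedObject]
    gfp_gated: list[DetectedObject]
    geometry: synth.SectionGeometry


def detect_all(
    mosaic: Mosaic, presets: dict[str, SegmentationParams]
) -> dict[str, list[DetectedObject]]:
    """Run the three detection channels on one stitched mosaic."""
    return {
        "hoechst": find_nuclei(mosaic, presets["nuclei"]),
        "neun": find_marker_cells(mosaic, "neun", presets["neun"]),
        "gfp": find_marker_cells(mosaic, "gfp", presets["gfp"]),
    }


def match_detections(
    objects: list[DetectedObject], truth_xy: np.ndarray, radius_um: float
) -> np.ndarray:
    """Greedy nearest-centroid matching of detections to truth positions.

    Returns per-detection truth indices (-1 for unmatched).  Each truth
    position is claimed at most once, nearest pair first.
    """
    matched = np.full(len(objects), -1, dtype=int)
    if len(objects) == 0 or len(truth_xy) == 0:
        return matched
    det_xy = np.array([[o.x_um, o.y_um] for o in objects])
    tree = cKDTree(truth_xy)
    dists, idxs = tree.query(det_xy, k=1, distance_upper_bound=radius_um)
    order = np.argsort(dists)
    claimed: set[int] = set()
    for di in order:
        if not np.isfinite(dists[di]):
            break
        ti = int(idxs[di])
        if ti in claimed:
            # fall back to the next unclaimed truth cell in range
            cands = tree.query_ball_point(det_xy[di], radius_um)
            cands = sorted(
                (c for c in cands if c not in claimed),
                key=lambda c: float(np.hypot(*(truth_xy[c] - det_xy[di]))),
            )
            if not cands:
                continue
            ti = cands[0]
        matched[di] = ti
        claimed.add(ti)
    return matched


def auto_label(
    objects: list[DetectedObject],
    truth: GroundTruth,
    channel: str,
    radius_um: float = 4.0,
) -> np.ndarray:
    """Label detections true/false from ground truth (synthetic researcher).

    A NeuN detection is true when it matches a neuron's nucleus position; a
    GFP detection when it matches a transduced cell.  Everything unmatched
    (debris, autofluorescence picked up around non-transduced nuclei) is
    false.
    """
    cells = truth.cells
    if channel == "neun":
        pos = cells[cells["is_neuron"]]
    elif channel == "gfp":
        pos = cells[cells["is_transduced"]]
    else:
        raise ValueError(f"no truth labels for channel {channel!r}")
    xy = pos[["x_um", "y_um"]].to_numpy(dtype=float)
    matched = match_detections(objects, xy, radius_um)
    return matched >= 0


def train_gates(
    mosaic: Mosaic,
    detections: dict[str, list[DetectedObject]],
    truth: GroundTruth,
    seed: int,
    n_per_class: int = 50,
    match_radius_um: float = 4.0,
) -> dict[str, GateModel]:
    """Train the NeuN and GFP morphology gates on one labelled section."""
    models: dict[str, GateModel] = {}
    for channel in ("neun", "gfp"):
        objs = detections[channel]
        labels = auto_label(objs, truth, channel, match_radius_um)
        X = np.array([gating.extract_features(o, mosaic).values for o in objs])
        channel_tag = sum(channel.encode())  # stable across processes
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), channel_tag]))
        keep = []
        for cls in (True, False):
            idx = np.flatnonzero(labels == cls)
            if len(idx) > n_per_class:
                idx = rng.choice(idx, size=n_per_class, replace=False)
            keep.extend(idx.tolist())
        keep = sorted(keep)
        models[channel] = gating.train_gate((X[keep], labels[keep]), seed=seed)
    return models


def analyze_section(
    mosaic: Mosaic,
    config: PipelineConfig,
    gates: dict[str, GateModel],
    section_id: int = 0,
) -> tuple[list[CellRecord], dict[str, list[DetectedObject]]]:
    """Segment, gate and co-localise one stitched section mosaic."""
    detections = detect_all(mosaic, config.presets)
    gfp_stringency = config.relaxed_stringency if config.use_relaxed_gfp else config.stringency
    neun_gated = gating.apply_gate(detections["neun"], gates["neun"], mosaic, config.stringency)
    gfp_gated = gating.apply_gate(detections["gfp"], gates["gfp"], mosaic, gfp_stringency)
    cells = assign_markers(
        detections["hoechst"],
        neun_gated,
        gfp_gated,
        pixel_size_um=mosaic.pixel_size_um,
        origin_um=mosaic.origin_um,
        section_id=section_id,
    )
    detections = dict(detections)
    detections["neun_gated"] = neun_gated
    detections["gfp_gated"] = gfp_gated
    return cells, detections


def run_series(
    config: PipelineConfig,
    gates: dict[str, GateModel] | None = None,
) -> tuple[list[SectionResult], dict[str, GateModel]]:
    """Generate and analyse a whole synthetic brain series.

    Gates are trained on the first section's detections against its ground
    truth unless pre-trained models are supplied (e.g. to analyse a
    non-permissive control series with gates trained on a permissive brain).
    """
    plan = synth.generate_brain_series(config.spec, config.n_sections, config.seed)
    results: list[SectionResult] = []
    for i, (sec_spec, sec_seed, _truth) in enumerate(plan):
        mosaic, _layout, truth = synth.generate_section_mosaic(sec_spec, sec_seed)
        if gates is None:
            detections = detect_all(mosaic, config.presets)
            gates = train_gates(
                mosaic, detections, truth, seed=config.seed,
                n_per_class=config.n_labels_per_class, match_radius_um=config.match_radius_um,
            )
        cells, detections = analyze_section(mosaic, config, gates, section_id=i)
        stats = section_stats(cells, section_id=i)
        results.append(
            SectionResult(
                section_id=i,
                truth=truth,
                cells=cells,
                stats=stats,
                nuclei=detections["hoechst"],
                neun_gated=detections["neun_gated"],
                gfp_gated=detections["gfp_gated"],
                geometry=sec_spec.geometry,
            )
        )
    return results, gates


def series_region_stats(results: list[SectionResult]) -> pd.DataFrame:
    """Per-section, per-region statistics gated with the generator polygons.

    Stands in for ROIs drawn on the NeuN+ scatter: the generator's region
    polygons are reapplied to every section's cell coordinates.
    """
    frames = []
    for res in results:
        polys = [
            RoiPolygon.from_shapely(name, poly, section_id=res.section_id)
            for name, poly in res.geometry.regions.items()
            if name != "other"
        ]
        frames.append(region_stats_frame(region_stats(res.cells, polys)))
    return pd.concat(frames, ignore_index=True)


def _write_with_hash(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: PipelineConfig,
    outdir: str,
    gates: dict[str, GateModel] | None = None,
    with_regions: bool = True,
) -> dict[str, str]:
    """File-based end-to-end run; returns the paths written.

    Outputs: per-section cell CSVs, a section stats CSV, a region stats
    CSV, saved gate models and a log recording every preset and threshold.
    Identical config and seed give byte-identical outputs.
    """
    os.makedirs(outdir, exist_ok=True)
    chash = config.config_hash()
    results, gates = run_series(config, gates=gates)
    paths: dict[str, str] = {}
    for res in results:
        p = os.path.join(outdir, f"cells_section{res.section_id:02d}.csv")
        export_cells(res.cells, p)
        paths[f"cells_{res.section_id}"] = p
        t = os.path.join(outdir, f"truth_section{res.section_id:02d}.csv")
        synth.write_truth(res.truth, t)
        paths[f"truth_{res.section_id}"] = t
    sdf = stats_frame([r.stats for r in results]).round(1)
    stats_path = os.path.join(outdir, "section_stats.csv")
    _write_with_hash(sdf, stats_path, chash)
    paths["section_stats"] = stats_path
    if with_regions:
        rdf = series_region_stats(results).round(1)
        rpath = os.path.join(outdir, "region_stats.csv")
        _write_with_hash(rdf, rpath, chash)
        paths["region_stats"] = rpath
    for channel, model in gates.items():
        gpath = os.path.join(outdir, f"gate_{channel}.txt")
        model.save(gpath)
        paths[f"gate_{channel}"] = gpath
    log_path = os.path.join(outdir, "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write(f"config_hash = {chash}\n")
        fh.write(f"seed = {config.seed}\nn_sections = {config.n_sections}\n")
        fh.write(f"stringency = {config.stringency}\n")
        fh.write(f"relaxed_stringency = {config.relaxed_stringency}\n")
        fh.write(f"use_relaxed_gfp = {config.use_relaxed_gfp}\n")
        for name, p in sorted(config.presets.items()):
            fh.write(f"preset.{name} = {p}\n")
    paths["log"] = log_path
    return paths
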