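"""Shared fixtures: one small synthetic section reused across the suite.

The section is generated once per session at a reduced scale (250 nuclei,
0.5 um pixels, 5 optical slices) so the whole suite stays fast while still
exercising tiling, stitching, detection, gating and assignment end to end.
"""

import pytest

from aavquant import (
    PRESETS,
    PipelineConfig,
    SectionSpec,
    coronal_geometry,
    generate_section_mosaic,
)
from aavquant.pipeline import detect_all, train_gates


def small_spec(**overrides) -> SectionSpec:
    base = dict(
        geometry=coronal_geometry(scale=0.35),
        n_nuclei=250,
        pixel_size_um=0.5,
        n_z=5,
    )
    base.update(overrides)
    return SectionSpec(**base)


@pytest.fixture(scope="session")
def section():
    """(mosaic, layout, truth) for the canonical small test section."""
    return generate_section_mosaic(small_spec(), seed=1)


@pytest.fixture(scope="session")
def detections(section):
    mosaic, _layout, _truth = section
    return detect_all(mosaic, PRESETS)


@pytest.fixture(scope="session")
def gates(section, detections):
    mosaic, _layout, truth = section
    return train_gates(mosaic, detections, truth, seed=1)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(spec=small_spec(), n_sections=2, seed=1)
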