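"""Per-region statistics by polygon gating of cell coordinates.

Analyses a short synthetic brain series with a cortex-enriched neuron
fraction (60% cortex vs 40% elsewhere), then reapplies the section's region
polygons to the per-cell coordinate table — the scripted equivalent of
drawing freehand ROIs on the NeuN+ scatter and reapplying them to every
channel.
"""

from aavquant import PipelineConfig, SectionSpec, coronal_geometry, run_series
from aavquant.pipeline import series_region_stats

spec = SectionSpec(
    geometry=coronal_geometry(scale=0.5),
    n_nuclei=500,
    neuron_fraction_by_region={"cortex": 0.60, "striatum": 0.40, "hippocampus": 0.40, "other": 0.40},
    transduction_fraction_by_region=0.15,
    pixel_size_um=0.5,
    n_z=5,
)
config = PipelineConfig(spec=spec, n_sections=3, seed=2)
results, gates = run_series(config)

rdf = series_region_stats(results)
print(rdf.round(1).to_string(index=False))

print("\nmean per region across sections:")
summary = rdf.groupby("region")[["pct_neun", "pct_gfp", "pct_neun_gfp"]].mean().round(1)
print(summary.to_string())
print("\ncortex recovers the enriched ~60% neuron fraction, striatum and"
      "\nhippocampus the ~40% baseline; transduction is uniform at ~15%.")
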