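"""Generate one synthetic coronal section and inspect its ground truth.

Builds a small stylized section (ellipse split into cortex / striatum /
hippocampus / other), renders the three fluorescence channels as overlapping
tiles of z-stacks, and prints what the generator knows to be true — the
reference every downstream stage is scored against.
"""

from aavquant import SectionSpec, coronal_geometry, generate_section, max_project

spec = SectionSpec(
    geometry=coronal_geometry(scale=0.35),
    n_nuclei=250,
    neuron_fraction_by_region=0.4,  # brain-wide neuron fraction
    transduction_fraction_by_region=0.14,  # permissive-strain transduction
    pixel_size_um=0.5,
    n_z=5,
)
tiles, layout, truth = generate_section(spec, seed=1)

print(f"tiles: {len(tiles)} ({layout.n_rows} x {layout.n_cols} grid, "
      f"{spec.tile_size_px} px, {layout.overlap_fraction:.0%} overlap)")
stack = next(iter(tiles.values()))
print(f"each tile: {stack.n_z} optical slices of {stack.shape_yx} px, channels {list(stack.channels)}")
proj = max_project(stack)
print(f"max projection of one tile: hoechst intensity {proj['hoechst'].min()}..{proj['hoechst'].max()}")

cells = truth.cells
print(f"\nground truth: {len(cells)} nuclei, {len(truth.debris)} debris speckles")
print(f"  neurons: {cells.is_neuron.sum()} ({100 * cells.is_neuron.mean():.1f}% — binomial draw at 40%)")
print(f"  transduced: {cells.is_transduced.sum()} ({100 * cells.is_transduced.mean():.1f}% — drawn at 14%)")
print("\nper-region cell counts (proportional to region area):")
print(cells.groupby("region").size().to_string())
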