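# Methods

This note documents the models, algorithms and numerical choices behind
`aavquant`, in the spirit of a software methods section: what is computed,
under which assumptions, and what a passing test does and does not
establish.

## 1. Imaging model and the synthetic-section generator

### Stated world

The generator emulates the acquisition protocol of a high-content screen
of stained coronal brain sections:

| parameter | default | rationale |
|---|---|---|
| section geometry | 1200 × 900 µm ellipse split into cortex (dorsal cap), striatum, hippocampus (ventro-lateral), other (central strip) | stylized, not an atlas: the pipeline only consumes region-labelled point sets, and the original ROIs were freehand |
| nuclei per section | 2000 | ≈2400 nuclei/mm², a realistic packing for a 25 µm section |
| nucleus radius | N(3.5, 0.4) µm, min 2.2 | mouse brain nuclei ≈ 7 µm diameter |
| soma radius (NeuN) | 4.6 µm, independent of the nucleus draw | ≈9 µm somata; small-nucleus neurons still have full-sized somata |
| z geometry | 19 slices × 1.2 µm | the emulated protocol |
| tiles | 256 px, 10% overlap | the emulated protocol |
| pixel size | 0.3 µm/px | 40× water-immersion class; never printed, therefore configurable |
| SNR | 10 (signal/background of means) | clean immunofluorescence |
| background | 100 counts + read noise σ=3 | 16-bit sCMOS scale |
| debris | 40 speckles/mm² per marker channel, σ 0.7–2.8 µm, 1.5–3× signal | gives the gate something to reject |
| GFP autofluorescence | every nucleus carries a dim GFP floor, lognormal(median 0.12× reporter, σ=0.4) | the substrate of the relaxed-gating background |
| neuron/transduction fractions | per-region maps; cells drawn independently per cell | binomial ground truth |

Per-channel amplitude spreads are lognormal with σ = 0.10 (Hoechst — a
stoichiometric DNA dye), 0.15 (NeuN antibody) and 0.20 (GFP expression).

### Rendering

Nuclei, somata and GFP-positive nuclei are flat-top profiles
`amp / (1 + (r²/core²)⁴)` with `core = 0.8 × radius` (plateau with a steep
rim at the chromatin/membrane boundary); debris are sharp Gaussians.
Same-channel objects are composited by **per-pixel maximum**, not
addition: stained bodies occlude one another rather than summing like
transparent emitters, which preserves an intensity saddle between touching
cells — the physical feature object splitting relies on.  NeuN is rendered
as a bright nuclear core (1.15× nucleus radius — NeuN is a neuronal
*nuclear* antigen with perinuclear signal) plus a 0.55× cytoplasmic
plateau out to the soma radius, so adjacent neurons keep deep saddles
between their cores.

Each object has one axial focus position z₀ (uniform in the middle half of
the stack) with Gaussian falloff (σ_z = 3 µm; 1.5 µm for debris); maximum
projection recovers approximately the in-focus amplitude.  Sensor noise is
Poisson–Gaussian; the Poisson term uses its Gaussian approximation
`N(µ, µ)` (counts are ≥100 everywhere, where the approximation is
excellent and several times faster).  All placement randomness is consumed
by one seeded stream in fixed order; per-tile noise uses child streams
keyed by `(seed, row, col, channel)`, so identical `(spec, seed)` is
bit-identical, tile by tile.

Nucleus placement is rejection sampling inside each region polygon (shrunk
0.5–1 µm so stored region labels are reproduced exactly by
point-in-polygon) with a minimum centre distance of 1.5× the mean radius,
plus a deliberate 3% of touching pairs (1.9× radius apart) to exercise
splitting.  Series generation scales the geometry smoothly (0.85–1.0,
sinusoidal along the series) to mimic anterior–posterior sampling, with a
deterministic derived seed per section.

### What the generator does *not* model

No PSF or optical blur beyond the analysis-side smoothing, no vignetting
or flatfield structure, no tile registration error (offsets are exact), no
anatomically accurate region shapes, no glial marker channels, no
z-dependent scattering.  A green recovery test therefore establishes that
the analysis chain is unbiased *under this world*; it cannot certify
performance on real tissue with mounting artifacts or antibody-dependent
staining quality.

## 2. Detection

The proprietary "method C" of the emulated software is unpublished; only
its parameter names and values are.  The re-specification keeps each
parameter's monotone role:

1. Gaussian smoothing, default σ = 3 px.
2. Global threshold `bg + CT·(P99.9 − bg)` with `bg` the image median —
   robust to the foreground fraction.  Blank (zero-variance) images return
   an empty list.
3. Connected components of the thresholded mask.
4. **Splitting before re-thresholding.** Candidate maxima of the smoothed
   component are kept when pairwise separation ≥ `20/SC` µm (SC = 0
   disables splitting); if several survive, a marker-controlled watershed
   on inverted intensity partitions the component.  Maxima selection
   collapses connected plateau pixels to a single candidate and enforces
   the separation criterion with exact Euclidean distances (a square
   suppression footprint systematically over-suppresses near-threshold
   pairs).  The 20 µm constant maps the printed SC values to minimum
   separations of 2.9 µm (SC 7) and 5 µm (SC 4), consistent with nuclear
   vs somatic object scales.
5. **Individual threshold per object**: `bg + IT·(own peak − bg)`, using
   each watershed region's own peak.  Ordering matters: applying IT per
   connected component would let one bright cell raise the bar for every
   cell it touches in confluent tissue; the per-object contract is the
   point of having IT at all.  The fragment containing the object's peak
   is kept.
6. A secondary shape-based split: if the core mask still holds ≥2 maxima
   of its Euclidean distance transform at the separation criterion
   (≥2 px deep), the fused mask is divided by watershed on the inverted
   distance transform.  This resolves equal-intensity pairs that have no
   usable intensity saddle.
7. Filters: area strictly greater than the printed minimum (`area >
   15 µm²` is exclusive); border-touching objects discarded (partial-area
   artifacts); a contrast bound.

**Contrast** is `(object mean − local background) / (object mean + local
background)` on the smoothed image, with local background the median of a
5-px annulus excluding all detected foreground (falling back to the global
background for fully embedded objects).  The published criteria print a
contrast limit without stating its direction.  Read as "exclude objects at
or above the limit", the printed values (0.06 for nuclei) would reject
every genuine nucleus under any annulus-based contrast definition; read as
a minimum distinctness — exclude objects *below* the limit — they pass
real objects and reject flat junk.  The default is therefore the
minimum-distinctness reading; `contrast_direction="above"` selects the
opposite.

Roundness is the moments-based `4A/(π·major_axis²)` (exactly 1 for a
disk, unbiased on rasters, unlike perimeter-based circularity at small
radii).

`dedup_overlap` merges same-channel detections from different tiles closer
than one mean nucleus radius, keeping the larger area; pairs are processed
in increasing distance order with deterministic tie-breaks, so the fast
KD-tree implementation is exactly equivalent to the O(n²) reference merge.
It applies to per-tile detection workflows; the default pipeline stitches
first and detects once.

## 3. Gating

Features per detection: area, roundness, width/length ratio, mean / peak /
sd of intensity, contrast, radial slope (centre-half vs rim mean — near
zero for flat-top nuclei, near one for speckles) and texture energy
(normalised mean squared Sobel gradient).  The gate is an L2-regularised
logistic regression on standardised features (C = 20; at the default C = 1
the shrunken weights let bright debris leak through — held-out accuracy
rises from ~0.84 to ≥0.97 across generator seeds).  The fit is
deterministic given the seed.

Stringency is the probability threshold: default 0.5; the relaxed preset
uses 0.05.  Gating at stringency s keeps `score ≥ s`, so the gated set
shrinks monotonically in s, +∞ passes nothing and −∞ everything.  Training
examples come from CSV label tables (or, on synthetic data,
`auto_label`, which matches detections to ground-truth marker cells by
greedy nearest-centroid within 4 µm — the synthetic stand-in for
researcher clicks).  Labelled example count defaults to 50 per class, an
arbitrary but documented choice; both classes must be present.

On zero-transduction fixtures the relaxed gate admits the bright tail of
the autofluorescence floor (~1–2% of cells at the default world),
reproducing the qualitative background signature that justifies the
stringent criteria; the default gate keeps ≥98% of true objects on
debris-free data.

## 4. Co-localisation and statistics

A GFP object marks a nucleus GFP+ when it covers ≥50% of the nucleus mask
(nuclear-localised reporter); a NeuN object marks a nucleus NeuN+ when it
contains the nucleus centroid (somatic/nuclear stain).  Each marker object
claims at most one nucleus — the eligible nucleus with the nearest
centroid — so one merged marker blob never double-counts.  Percentages per
section: `pct_neun` and `pct_gfp` over all Hoechst+ cells, `pct_neun_gfp`
over NeuN+ cells (NaN when none), plus `pct_both_of_all` over all cells,
since both denominators are in use in the field.  CSV exports round
percentages to 1 decimal; in-memory values are full precision.

## 5. Regions

ROIs are consumed from CSV (`region,vertex_index,x_um,y_um`) or GeoJSON;
polygons must be simple with ≥3 vertices.  Membership is point-in-polygon
with boundary points counted inside (cells on a saved ROI edge are never
dropped; generator regions are disjoint so no double-counting arises) and
depends only on coordinates, so a saved ROI reapplied to any channel's
scatter yields identical per-cell membership.  Geometry is delegated to
shapely (`covers`); the test suite checks exact agreement with an
independent winding-number implementation on 10⁴ random cases.  A plotting
helper renders the NeuN+ scatter used as the template for drawing ROIs
externally; interactive drawing is out of scope.

## 6. qPCR / VGCn

The standard curve is an OLS fit of mean replicate Cq against log₁₀ input
copies; ≥3 dilution points spanning ≥2 logs are required, replicates are
averaged before fitting (standard practice for triplicate plates).
Efficiency is `100·(10^(−1/slope) − 1)`; 100% iff slope = −log₂10 =
−3.321928.  A non-negative slope flags the curve rather than raising, but
quantification against such a curve raises.  Unknowns:
`copies = 10^((Cq − intercept)/slope)` per 10 ng template; mean Cq at or
beyond the no-signal cutoff (default 40, the cycling limit) reports zero
copies with a flag.  Per-genome conversion divides by 1667 genomes per
10 ng (6.0 pg per diploid mouse genome) — the constant is configurable
because the original per-genome axis never states it.

The Grubbs screen is two-sided, single-outlier, no iterative removal:
`G = max|x−x̄|/s` against `((n−1)/√n)·√(t²/(n−2+t²))` with
`t = t₁₋α/(2n), n−2`; it requires n ≥ 3 and s > 0 and is invariant to
affine rescaling.  Regression is OLS with the slope's two-sided t-test
p-value (delegated to `scipy.stats.linregress`; the tests verify it
against explicit normal equations).

## 7. Scaling of tests and acceptance runs

Unit tests use 250-nucleus sections at 0.5 µm/px with 5 optical slices;
`scripts/acceptance.py` uses full-scale cell numbers (2000/section, 8 or 4
sections per series) at the same reduced imaging scale.  The reductions
(0.5 vs 0.3 µm/px; 5 vs 19 slices) keep the suite around a minute and the
acceptance script around two minutes on one CPU and were chosen a priori
as resolution/depth reductions that leave per-object sampling adequate
(nucleus diameter ≈ 14 px; axial falloff still exercised); cell counts and
composition fractions are never scaled.

## 8. Known limitations

- Recovery of `pct_neun` carries a small negative bias (≈1–2 points at
  40–60% neurons) from tight cell pairs below the splitting separation
  criterion; this is inherent to the one-nucleus-per-marker-object rule
  plus watershed resolution, and the acceptance tolerance (±3 points)
  absorbs it.
- Detection operates on maximum projections, not slice-wise 3D linking;
  within-stack duplication is handled entirely by projection.
- The gate is linear; strongly non-convex class boundaries (e.g. "bright
  AND flat") are only approximated, which is why a mild regularisation
  (C = 20) matters.
- Monotonicity of detection counts in CT and min-area holds empirically on
  the fixtures and is asserted there, but watershed reconfiguration under
  threshold changes can in principle produce local exceptions.
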