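# Methods

This note documents the models, conventions and reconstructed
parameters behind phenoglyph: what each stage computes, which choices
were genuinely open, and what the synthetic fixtures do and do not
establish.

## Glyph encoding

A glyph lives in a unit bounding box centred on its anchor. The main
ellipse semi-axes are `0.25 × scaled length` and `0.25 × scaled width`;
this constant guarantees containment even when a maximal protrusion
(whose height can equal the main semi-major axis) or maximal spikes are
drawn. The registry holds 21 elements; exactly 8 are proportional-fill
(the three ellipse area fills, the border fill, the spikes fraction and
the three organelles). The registry composition beyond the 15 elements
shown in the published example panel (perinuclear dimensions and fill,
main/perinuclear colour, border fill, sub-circle count) is a
reconstruction consistent with the printed counts; it is fixed, not
user-extensible, so specs validate against a stable vocabulary.

Conventions chosen where the visual language leaves freedom:

- **Border fill** is *arc-length* proportional, starting at 12 o'clock
  and running clockwise. On an eccentric ellipse an angular sweep would
  over-weight the flat ends; arc length is what the eye integrates.
  Arc-length parameterization uses trapezoidal quadrature of the
  ellipse speed on a 4096-point grid; rendered arc length tracks the
  bound value to well under 1%.
- **Area fill** places symbols on a fixed hexagonal lattice (spacing
  `max(a,b)/5`, sites kept inside 90% of the boundary), filled bottom-up;
  the number of placed sites is `round(value × lattice size)`. The
  lattice is deterministic — no RNG anywhere in rendering.
- **Spikes** tile a contiguous clockwise arc covering `fraction` of the
  perimeter at a pitch of 1/24 perimeter; spike height is
  `height × 0.25 × minor semi-axis` (salient without dominating).
- **Sub-circles** pack centre-first, then on concentric rings with ring
  capacities 6·j, first slot at 12 o'clock; the common radius is 0.45 of
  the ring spacing, which guarantees non-overlap, and is clamped with a
  warning for absurd counts.
- **Protrusion** is a half-ellipse on top of the cell whose major
  dimension is `value × main major dimension`; its height is fixed at
  half its own major dimension (only the major dimension is an encoding
  channel).
- **Organelles** (line, ellipse, rectangle) sit at three fixed slots in
  the lower cytoplasm and fill bottom-up with *height* proportional to
  the value; for the ellipse organelle the filled area is therefore the
  circular segment below the chord (area equals half the disc exactly at
  value 0.5).
- **Colour-bound elements** map the value through a perceptually uniform
  sequential colour map (viridis by default, overridable per binding);
  most elements are deliberately colour independent.
- **Membrane process** (named in the source material but never
  described) is rendered as a stalk on the glyph's right side with
  length proportional to the value, ending in a small knob; this is a
  reconstruction.

Scaling: dimensional columns are scaled jointly —
`v' = (v − min_all)/range_all × 0.9 + 0.1` over the pooled values — so
the pooled minimum maps to 0.1 (objects never vanish) and aspect ratios
are preserved up to one affine map. Other columns are min-max scaled to
[0, 1]. Degenerate zero-range inputs map to the interval midpoint (0.55
and 0.5 respectively) rather than erroring: a flat column should render
as a mid-sized object, not crash a figure. Re-scaling an already scaled
table is rejected; pre-scaled user input outside the domain is clipped
with a logged warning.

Coordinate layout rescales given xy (typically the first two PCs) onto
the canvas with a margin and chooses the glyph size so the median
nearest-neighbour distance is at least 1.5 glyph widths — the published
material shows PC-space glyph panels but does not specify a size rule.

## Image feature extraction

Pixels are 0-based, row-major, with float intensities in native range.

- **Nuclei**: Gaussian smoothing (σ = 2 px), Otsu threshold refined to
  the midpoint of the foreground/background medians (Otsu's split is
  sensitive to class imbalance; the median midpoint puts the boundary on
  the half-maximum contour of a step edge), hole filling, then a
  watershed on the negated distance transform seeded at peaks ≥ 7 px
  apart to split touching nuclei. Objects under 25 px are dropped.
- **Cells**: seeded watershed growing one cell per nucleus on the
  inverted smoothed cell channel. The foreground mask uses a locally
  adaptive threshold: a pixel is foreground where the lightly smoothed
  (σ = 1 px) intensity exceeds both 0.45 × the local plateau (grey
  dilation, radius 2 px) and a global floor of 0.5 × Otsu. The
  half-plateau rule lands the boundary of a step-edged object on the
  step midline *regardless of the object's brightness*, which keeps dim
  protrusive peripheries (≳ half the core intensity) without inflating
  bright cells; the floor keeps noise out. Every cell contains its seed
  nucleus by construction.
- **Morphology**: length/width are the major/minor axis lengths of the
  second-moment ellipse; area is pixel count × (pixel size)²; the form
  factor is 4πA/P² with the perimeter estimated by the 4-direction
  Crofton formula (a pixel-edge perimeter would push a digital disc's
  form factor to ≈ 0.79; Crofton keeps it within ~1% of 1).
- **Neighbour fraction**: the border is the 8-connectivity erosion
  residue; NF is the fraction of border pixels whose 8-neighbourhood
  contains a different positive label.
- **Core/protrusion split**: threshold = 0.7 × mean intensity over the
  cell mask; the core is the largest 8-connected component above
  threshold, the protrusion is the remainder. If nothing clears the
  threshold the whole cell becomes the core (logged); this can only
  happen for pathological flat inputs.
- **SER textures** (the proprietary originals are unpublished; this is
  the package's reconstruction, stated in full in
  `TextureEngine.ser`): single-scale (σ = 2 px) scale-normalized
  Gaussian derivatives; with Hessian eigenvalues l1 ≤ l2 of σ²H, an
  anisotropy factor |l1−l2|/(|l1|+|l2|) separates blob-like (spot,
  hole, from the trace) from line-like (ridge, valley) responses;
  saddle is the geometric mean of opposed curvatures; edge is σ|∇I|;
  bright/dark are one-sided deviations from the region mean. The small
  DC leakage of truncated derivative kernels is cancelled exactly by
  subtracting `region mean × (kernel response to an all-ones image)`,
  so constant regions score identically zero.
- **Gabor textures**: 4 orientations × 2 wavelengths (4 and 8 px),
  mean squared response magnitude over the region, with the region mean
  subtracted before filtering (the kernels are not DC-free). By
  linearity the subtraction is applied analytically, so the whole-image
  responses can be cached and reused across regions without
  approximation.
- **Haralick**: intensities min-max quantized to 32 levels within the
  region; GLCM at distance 1 pooled over the four directions, symmetric,
  normalized after dropping a sentinel level that marks out-of-region
  pixels (so only within-region pairs contribute — this is why the GLCM
  is built with an extra level rather than on a bounding box). Reported
  statistics: angular second moment, contrast, correlation, entropy
  (natural log). Pooling over directions weights each direction by its
  pair count; per-direction normalization would weight them equally —
  the pooled convention is asserted in the tests.
- **Ruffliness**: SER edge averaged over a membrane band (3 px
  morphological erosion residue; a cell thinner than the band uses the
  whole cell, logged) divided by the cell form factor. Texture features
  require ≥ 25 px of region; smaller regions raise an error and the
  affected cell is dropped with a log message (cell-level fault
  isolation).
- **QC**: cells are removed if the mask touches the image border, if
  the cell area is below 100 px², or if the mean nuclear intensity
  exceeds the per-image median + 3 × MAD (the original mitotic cut was
  manual per cell line; a robust per-image default replaces it). With a
  degenerate MAD of zero the mitotic rule is inert rather than flagging
  everything. All thresholds are config-exposed (`RunConfig`).

The 52-feature schema is: cell {length, width, area, form factor} +
nucleus {length, width, area, form factor} + NF + protrusion area +
relative protrusion area + ruffliness + 20 nuclear-channel texture
features (nucleus region) + 20 cell-channel texture features (core
region). The exact published composition is not printed anywhere; this
schema is the reconstruction consistent with every stated count.

## Profile analysis

The 20-column texture block of each region is compressed to the score
on its first principal component ("texture index"), computed on the
scaled block; the sign is fixed so the index correlates positively with
the mean texture magnitude (PCA signs are arbitrary). Profiles are then
z-scored per feature (sample sd, ddof = 1) and clustered with Euclidean
distance and average linkage (UPGMA) via scipy's linkage, whose merge
ordering is deterministic under ties; the flat cut uses maxclust.
Whether the original analysis z-scored before or after the texture
compression is not stated; this package scales the block, compresses,
assembles the 9-feature profile, and z-scores that. 2-D layout
coordinates are the scores on the first two PCs with the
largest-|loading| positive sign convention. Glyphs of cluster averages
are rendered from the *plot-scaled* (0.1–1 / 0–1) features, never from
z-scores.

## Synthetic fixtures

The image generator renders elliptical cells with hard intensity
plateaus (bright concentric core, dimmer periphery as the planted
protrusion), optional speckle (30% multiplicative noise) or grating
(wavelength 6 px, 30% modulation) texture in the core, a uniform
nucleus plateau, and additive Gaussian pixel noise (sd 1 by default,
i.e. ~1% of the plateau). Overlapping blueprints must be flagged
`touching`; contested pixels go to the nearest cell centre in
normalized ellipse distance. Ground truth (masks, relative protrusion
areas, NF from mask adjacency) is returned alongside the pixels. All
generators are pure functions of their spec, seed included
(`numpy.random.default_rng`, a counter-based PCG64).

The default 5-cell demo image staggers the nuclear plateaus over
90–110 so the per-image mitotic MAD cut has a meaningful scale; with
five near-identical nuclei the MAD degenerates and the cut would flag
noise.

The archetype table generator draws Gaussian samples (clipped to
feature domains) around five archetype means over the nine plotted
features — a round/high-NF archetype, a ruffly/textured/protrusive one,
a spread/smooth one, an intermediate highly textured one and a compact
smooth one — with 20 samples per archetype by default; the means and
sds mirror the qualitative cluster descriptions of the motivating study
at plausible scales (lengths in μm, fractions in [0, 1]). Texture
indices can be expanded into 20-column blocks (index × fixed positive
loadings + noise) so the compression stage is exercised end to end.

What passing tests show — and don't. Synthetic cells have piecewise-
constant intensities, smooth elliptical outlines, no illumination
gradients, no out-of-focus light, and noise far below real microscopy
levels. Segmentation recovering planted objects at ≥ 95% Jaccard on
noise-free fixtures validates the geometry of the chain, not its
robustness on real images; archetype recovery at ARI ≥ 0.9 validates
the analysis plumbing, not the biological separability of real cell
lines. The watershed boundary between *touching equal-intensity* cells
is arbitrary within the flat contact zone, so touching cells are
excluded from the Jaccard assertions (their NF is still meaningful).

## Problem sizes

The test suite and the acceptance script run the full extraction on
256 × 256 two-channel images with five planted cells, cluster 100-sample
archetype tables over 20 seeds, and check UPGMA/PCA against brute-force
oracles at n ≤ 8 / n ≤ 50 — sizes chosen so the whole suite completes
in well under a minute while every stage still runs end to end.

## Known limitations

- The SER definitions, the 52-feature schema, the registry composition
  beyond the published example panel, and the membrane-process glyph are
  reconstructions (flagged above); parameter choices (σ = 2 px, 32 GLCM
  levels, 3 px membrane band, QC cut-offs) are common defaults, all
  config-exposed.
- No illumination correction, no 3-D stacks, no plate/well management.
- Rendering is static SVG/PNG; no interactivity or occlusion-aware
  layout (overlap control is a size heuristic).
- `k` (number of flat clusters) is a user choice; the package does not
  select it.
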