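# phenoglyph

Glyph-based visualization of high-content imaging data. Instead of
heatmaps or bar charts, each cell (or cell population) is drawn as a
small cell-like pictogram: ellipses for the cell body, nucleus and
perinuclear region, a half-ellipse for protrusions, spikes for membrane
ruffling, and *proportionally filled* outlines (border arcs, symbol
fills, organelle shapes) for fraction-valued features such as the
neighbour fraction or a texture index. Up to 21 variables can be
encoded per glyph, 8 of them through proportional filling. The result
reads like a cartoon of the phenotype, so morphological differences
between samples can be seen rather than decoded.

The package is aimed at people doing image-based profiling (high-content
screening, cell morphology studies) and provides the full chain:

- **Rendering** (`phenoglyph.render`, `phenoglyph.geometry`): scaled
  feature rows + a glyph spec → resolution-independent scenes, exported
  as SVG or PNG, with an automatic legend and grid or coordinate (e.g.
  PC-space) layouts.
- **Feature extraction** (`phenoglyph.images`): two-channel fluorescence
  images (nuclear + cell-body stain) → a 52-feature per-cell table:
  cell/nucleus length, width, area and form factor (4πA/P²), neighbour
  fraction NF (fraction of the cell border in contact with other
  cells), protrusion area from the 70%-of-mean-intensity core split,
  ruffliness (membrane SER-edge texture / form factor), and 20 texture
  features (8 SER + 8 Gabor + 4 Haralick) per region-channel pair.
- **Profile analysis** (`phenoglyph.profiles`): texture blocks are
  compressed to a one-dimensional *texture index* (first principal
  component of the scaled block), profiles are z-scored, clustered with
  Euclidean distance and average linkage (UPGMA), and projected on the
  first two PCs for glyph placement.
- **Synthetic fixtures** (`phenoglyph.synthetic`): seeded generators
  for ground-truth images (ellipsoidal cells with intensity plateaus,
  textures, touching neighbours) and for feature tables drawn around
  five morphological archetypes, so every stage is testable without
  external data.

Two scalings coexist, on purpose: for *plotting*, dimensional features
(lengths and widths) are scaled jointly to [0.1, 1] — pooled minimum to
0.1, pooled maximum to 1.0 — so aspect ratios survive and no object
vanishes, while all other features are min-max scaled to [0, 1]; for
*clustering and PCA* the assembled profiles are z-scored per feature.

## Worked example

The bundled demo generates a synthetic two-channel image with five
planted cells (one touching pair, one cell with a dim protrusive
periphery, two textured cells), extracts the per-cell table, and renders
a 15-variable glyph panel plus a PC-space layout of the five archetype
means:

```
$ phenoglyph demo --out-dir demo_out --seed 7
wrote demo files to demo_out
```

`demo_out/demo_features.csv` then contains one row per surviving cell
and 52 feature columns; a few of them:

```
         cell_length  cell_width  cell_area  cell_form_factor  neighbour_fraction  relative_protrusion_area
cell_id
1             60.378      41.893     1838.0             0.635               0.216                     0.004
2             45.491      45.084     1610.0             0.970               0.000                     0.122
3             51.941      40.038     1633.0             0.958               0.000                     0.176
4             50.462      30.318     1116.0             0.695               0.312                     0.000
5             51.976      33.553     1369.0             0.910               0.000                     0.243
```

Cells 1 and 4 are the touching pair: both have non-zero neighbour
fraction (the fractions differ because the shared border is divided by
each cell's own perimeter). Cell 5 was planted with a dim peripheral
plateau covering a quarter of its area and the 70% rule recovers a
relative protrusion area of 0.24. Form factors near 1 are round cells;
the elongated protrusive cell scores 0.64.

To render glyphs from your own table:

```
$ phenoglyph plot --table features.csv --spec glyphs.yml --out figure.svg \
      --dimensional cell_length --dimensional cell_width
```

where `glyphs.yml` maps feature names to element names, e.g.

```yaml
cell_length: main-ellipse-length
cell_width: main-ellipse-width
neighbour_fraction: main-ellipse-border-fill
cell_texture_index: main-ellipse-area-fill
relative_protrusion_area: protrusion
```

`phenoglyph extract` runs the image pipeline from TIFF/PNG channels and
`phenoglyph analyze` computes texture indices, clusters and PC
coordinates from a feature CSV.

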