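# puzzlecell

3D morphometry of polylobate **puzzle sclereids** — the interlocking stone
cells of nut shells — and hyperspectral Raman unmixing of their developing
cell walls.

During shell development these cells transform from small isodiametric
blobs into large cells with many interlocking lobes. `puzzlecell` provides
the descriptors that quantify that transformation on labeled 3D
segmentation volumes, the spectroscopy tools that characterize the wall
chemistry driving it, the statistics to compare developmental stages, and
a phantom generator with known ground truth so the whole pipeline can be
validated without access to microscopy data. It is aimed at plant-anatomy
and biomechanics groups working with SBF-SEM / confocal 3D segmentations
and confocal Raman maps.

## What it computes

For each cell of a labeled volume (axis order `(z, y, x)`, per-axis
spacing in µm):

* **volume** `V` and **surface area** `S` (marching-cubes isosurface,
  anisotropic spacing);
* **solidity** `V / V_hull` — 1 for convex cells, decreasing as lobes
  form;
* **LES**, the largest empty sphere
  `d_LES = 2·max_{v∈cell} min_{w∉cell} ‖v − w‖`, a proxy for the maximal
  turgor-induced wall stress, plus an isometric no-lobe baseline
  `c·V^{1/3}` extrapolated from a reference stage;
* **lobe count** — endpoints of a pruned geodesic centreline tree
  (prominence-filtered maxima of the geodesic distance field from the
  inscribed-sphere center);
* **contact areas** with each neighbour, fragmented into connected
  patches by intercellular space;
* **wall thickness** maps (largest-inscribed-sphere local thickness) and
  the mask of above-average "loops" of thickening.

For hyperspectral Raman cubes `(y, x, wavenumber)`: cosmic-ray despiking,
band-integral imaging (e.g. the CH-stretch window 2831–3009 cm⁻¹),
non-negative matrix factorization into endmember spectra and abundance
maps, cosine assignment of endmembers to a reference library, sparse
non-negative fitting by orthogonal matching pursuit, and sub-sample
marker-band localization (the ~850 cm⁻¹ pectin band shifts with the
degree of esterification: 856 cm⁻¹ for 10–34%, 853 cm⁻¹ for >85%).

Stage comparison uses a Kruskal–Wallis ANOVA on ranks with Dunn's
all-pairs post hoc (tie-corrected, Bonferroni-adjusted).

## Worked example

Generate a 12-lobe phantom and measure it:

```python
from puzzlecell import synthcell, morphometry, skeleton

spec = synthcell.LobedCellSpec(
    base_radii=(10, 10, 10),   # µm ellipsoid semi-axes
    n_lobes=12, bump_amplitude=0.35,
    spacing=(0.5, 0.5, 0.5),   # µm per voxel
    seed=7,
)
vol, truth = synthcell.make_lobed_cell(spec)

v = morphometry.cell_volume(vol, 1)
s = morphometry.cell_surface_area(vol, 1)
hull, sol = morphometry.solidity(vol, 1)
les, _ = morphometry.largest_empty_sphere(vol, 1)
k = skeleton.count_lobes(vol, 1)
print(f"volume        {v:9.1f} um^3 (analytic {truth['analytic_volume']:.1f})")
print(f"surface area  {s:9.1f} um^2")
print(f"solidity      {sol:9.3f}")
print(f"LES diameter  {les:9.2f} um")
print(f"lobe count    {k:9d} (ground truth {truth['n_lobes']})")
```

prints

```
volume           4814.1 um^3 (analytic 4816.2)
surface area     1562.8 um^2
solidity          0.756
LES diameter      20.02 um
lobe count           11 (ground truth 12)
```

The voxelized volume agrees with the analytic radius-field quadrature to
0.05%; solidity is well below 1 because the hull bridges the indentations
between lobes; the LES stays pinned at the 20 µm core diameter no matter
how much volume the lobes add — which is exactly why lobed growth keeps
wall stress low; and the skeleton recovers 11 of the 12 seeded lobes (two
jittered lobes merged, within the ±2 band the recovery experiments use).

## Command-line pipeline

```sh
puzzlecell all --config pipeline.yaml --seed 1 --output-dir out/
```

runs synth → measure → skeleton → raman → stats from one YAML config:
phantom label stacks and a hyperspectral cube with truth JSON, a per-cell
descriptor CSV (border-touching cells excluded), skeleton node/edge CSVs,
endmember/abundance/OMP reports, and per-stage summary and Dunn pairwise
tables. One global seed fixes every output byte; `manifest.json` records
the config hash and derived seeds.

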