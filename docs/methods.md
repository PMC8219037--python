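# Methods

`puzzlecell` implements the quantitative core of a 3D study of polylobate
("puzzle") sclereids — the interlocking stone cells that make nut shells
tough — together with the hyperspectral Raman analysis of their developing
walls. Because serial block-face SEM segmentations are rarely shared, the
package ships a phantom generator whose ground truth exercises every
descriptor; all empirical statements below are what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinate and voxel conventions

All volumes are `(z, y, x)` indexed, 0-based, with per-axis physical
spacing `(sz, sy, sx)` in µm. A voxel occupies the closed unit cell of its
grid position; the center of voxel `i` lies at `(i + 0.5)·s`. Anisotropic
spacing is handled by sampling-weighted distance transforms and
per-orientation face areas — nothing is resampled to an isotropic grid.

## Phantoms

**Lobed single cells** are star-convex shapes
`r(u) = r_ellipsoid(u)·(1 + A·Σₖ gₖ(u))`, where the `gₖ` are unit-height
von Mises–Fisher bumps `exp(κ(cos θₖ − 1))` centred on K directions placed
quasi-uniformly on the sphere (Fibonacci lattice) and jittered by the seed
(angular sd 0.15 of the mean lobe pitch). Defaults: amplitude `A = 0.35`
(a mature lobe protrudes ~35% of the local radius), sharpness `κ = 50`.
κ was chosen so that adjacent lobes of a 12-lobe cell remain geometrically
separable — the construction is meant to make lobe-count recovery
well-posed, not to reproduce walnut geometry in detail. Truth records
carry K, the jittered directions, and an analytic volume from lat–long
quadrature of `r³/3`.

**Tissues** are Voronoi partitions of rejection-sampled seed points (minimum
separation `max(2·wall_thickness, 0.15·domain)`). Walls become background
where the two nearest-seed distances differ by less than `wall_thickness`
(equivalent to eroding each region by half the wall). Intercellular space
(ICS) is carved per interface as `ceil(6·f)` periodic stripes along a
seeded in-plane direction with area coverage `f = ics_fraction`: `f = 0`
leaves interfaces intact, `f = 1` opens them completely, and intermediate
values fragment each contact into more, smaller patches — the hallmark of
ICS invasion. The truth adjacency lists each Voronoi pair with its
zero-wall interface area and whether it remains in contact.

**Hyperspectral cubes** mix reference spectra under smooth Gaussian-blob
abundance maps, with multiplicative Gaussian noise (shot noise scales with
intensity; relative sd is the single knob) and seeded single-sample cosmic
rays of 20–100× the local intensity, floored at 2% of the cube maximum so
a spike in a dark pixel is still a detector-scale event. The built-in
reference library holds Gaussian-band approximations of cellulose (378,
1095, 1380 cm⁻¹ plus the CH-stretch envelope), a xylan-like hemicellulose,
and two pectins whose ~850 cm⁻¹ marker encodes the degree of methyl
esterification (856 cm⁻¹ for 10–34%, 853 cm⁻¹ for >85%); the ester C=O
band at 1740 cm⁻¹ strengthens with esterification.

What the phantoms do *not* emulate: SBF-SEM texture and segmentation
noise, mechanically grown (as opposed to constructed) lobes, curved or
non-planar cell interfaces, Raman baselines and fluorescence. Passing
tests therefore demonstrate correctness of the measurement pipeline on
known geometry, not robustness to every artefact of real micrographs.

## Shape descriptors

* **Volume** — voxel count × voxel volume.
* **Surface area** — marching cubes at level 0.5 on the binary mask after
  Gaussian smoothing with σ = 0.7 voxels. Binary marching cubes
  overestimates curved areas by ~9%; the smoothed field recovers the
  digital sphere's area to ~1%. The cost is rounded sharp edges (a perfect
  cube loses ~12%), acceptable because cell surfaces are curved at voxel
  scale. If smoothing leaves no 0.5-crossing (single voxels, 1-voxel
  bars), the raw binary field is used. The voxel-face area is retained as
  an internal upper bound.
* **Solidity** — cell volume over convex-hull volume. The hull volume is
  the mean of the hull over surface-voxel corner points (overestimates by
  a half-voxel shell) and over surface-voxel centers (underestimates by
  the same at first order); the bias cancels, leaving a quadratically
  vanishing error. Values marginally above 1 (convex digital solids) are
  clipped to 1.
* **LES (largest empty sphere)** — diameter = 2 × max over cell voxels of
  the anisotropic Euclidean distance from the voxel center to the nearest
  non-cell voxel center (exterior padded as background). Ties resolve to
  the lexicographically smallest `(z, y, x)`. Reported as a diameter in µm.
* **No-lobe LES baseline** — isometric extrapolation: fit
  `c = mean(les / volume^{1/3})` on a reference stage and predict
  `c·V^{1/3}`. The functional form is a package choice; isometric scaling
  is the natural null model for "same volume, no lobes".
* **Contact areas** — shared faces between 6-adjacent voxels of different
  non-background labels, weighted by the physical face area of their
  orientation. Patches are connected components of interface faces, two
  faces being connected when their voxel pairs are 26-adjacent (or equal)
  on both sides, so faces meeting only at an edge stay in one patch.
* **Wall thickness** — largest-inscribed-sphere local thickness: EDT
  followed by a sphere-coverage sweep in descending radius order, minus
  one voxel pitch to convert center-to-center distances into
  surface-to-surface thickness (an n-voxel slab reports exactly `n·s`).
  The above-average mask (`thickness > mean` strictly) visualizes "loops"
  of wall thickening.

Whole-volume measurement excludes cells touching the border, whose
descriptors would be truncated.

## Lobe counting

The centreline is a geodesic tree, not a thinning skeleton: parallel
topology-preserving thinning collapses a lobed ball to a point, so
endpoints of a thinned skeleton cannot count lobes of blob-like cells.
Instead: (1) smooth the mask (closing then opening with a discrete ball,
default radius 2 voxels) so segmentation artefacts do not spawn tips;
(2) root the tree at the EDT maximum (the inscribed-sphere center);
(3) compute the geodesic distance field G over the 26-connected voxel
graph; (4) take as branch tips the local maxima of G whose topographic
prominence — height above the saddle joining them to a higher maximum,
found by a union-find persistence sweep — exceeds a threshold; (5) trace
predecessor paths from each tip to the root. Terminal branches shorter
than `min_branch_len` are then pruned (never disconnecting the tree).

`min_branch_len` doubles as the prominence threshold and defaults to
0.25 × LES radius: a main lobe protrudes by a sizeable fraction of the
core radius, surface roughness by a voxel or two. Endpoint counts are
floored at 2, the conventional score for isodiametric cells (a bare path
— bar, sphere axis — has two ends). Elongated cells (bars, L-tubes)
reduce to their full centreline path with 2 endpoints, exactly as a
thinning skeleton would.

## Raman unmixing

* **Despiking** — per-pixel spectral median filter (window 5, so two
  adjacent spiked bands cannot mask each other); samples whose residual
  exceeds 8 robust sd are replaced by the local median. The robust scale
  is `1.4826·MAD` floored at 2% of the pixel's peak intensity: sharp real
  bands leave median residuals up to ~10% of the peak at 2 cm⁻¹ sampling,
  well below 8 × 2%, while cosmic rays are tens of times local intensity.
  The operation is idempotent.
* **Band integrals** — per-pixel trapezoid over a wavenumber window,
  optionally after subtracting the linear chord between the window ends.
* **NMF** — multiplicative updates on the Frobenius loss over the
  (pixels × bands) matrix, seeded uniform init, objective recorded per
  iteration (non-increasing by construction). Endmembers are normalized
  to unit maximum with the scale folded into the abundances. `k` defaults
  to 6 in the pipeline config. All `k` endmembers are reported with their
  library assignment; selecting "relevant" components is left to the user.
* **Endmember assignment** — greedy maximum cosine similarity against the
  reference library (resampled to the cube axis by linear interpolation);
  all-zero endmembers are flagged unassigned.
* **OMP** — greedy selection of the library atom with the largest positive
  correlation to the residual, full non-negative least-squares refit of
  all selected coefficients each round, stopping at `max_atoms`, at a
  residual-norm fraction below `residual_tol`, or when no positive
  correlation remains. Coefficients are concentrations, hence the
  non-negativity constraint.
* **Marker-band localization** — windowed argmax refined by three-point
  parabolic interpolation, resolving the 853 vs 856 cm⁻¹ esterification
  markers at 1–2 cm⁻¹ sampling; flat windows return a no-peak flag.

## Statistics

Stage comparison uses the Kruskal–Wallis one-way ANOVA on ranks
(tie-corrected, chi-square p, df = g−1; all-identical input is defined as
H = 0, p = 1) followed by Dunn's all-pairs z with the standard tie term
`T = Σ(t³−t)/(12(N−1))`. Both unadjusted and Bonferroni-adjusted p-values
are reported and the significance flag uses the adjusted column —
conservative and reproducible. The chi-square approximation suggests group
sizes of at least 5. Stage summaries report n, mean, sd, median, quartiles
and the 1.5·IQR whisker bounds used in box plots.

## Pipeline and determinism

The `puzzlecell` CLI (`synth`, `measure`, `skeleton`, `raman`, `stats`,
`all`) is a thin layer over the library driven by one YAML config. Every
random stage receives a seed derived deterministically from the global
seed (SeedSequence over a CRC of the stage tag), so one seed fixes every
output byte; each run writes a manifest with the config echo, its SHA-256,
derived seeds and the package version.

## Problem sizes

The shipped tests and the acceptance script run phantoms of roughly
60–100³ voxels (single cells), 36–60³ tissues with 8–10 cells, 16×16×1401
hyperspectral cubes, 20 seeds per lobe-count recovery condition and 2000
null simulations for the type-I-error calibration — sizes chosen so the
whole suite completes in a few minutes on one core while every property
is still exercised at meaningful resolution.

## Known limitations

* Lobe counting assumes lobes protrude from a single dominant core; cells
  with several comparable cores (dumbbells) may attribute branches to the
  larger core only.
* The half-voxel-averaged hull slightly misestimates hulls of very
  anisotropic voxels; solidity comparisons should use similar spacing
  across groups.
* Wall-thickness subtraction of one voxel pitch assumes the thin axis is
  sampled at (or near) the smallest spacing component.
* The stripe model of ICS fragments interfaces deterministically; real ICS
  fronts are irregular and can isolate islands the stripe model cannot.
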