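"""Synthetic phantoms with known ground truth.

Walnut-shell sclereids develop from small isodiametric cells into large
polylobate "3D puzzle" cells.  This module generates stand-ins for the two
kinds of raw data such a study produces — SBF-SEM-style labeled cell volumes
and confocal-Raman hyperspectral cubes — with the generating parameters
returned as ground truth, so every downstream descriptor can be validated
against a known answer.

Single cells are star-convex radial-bump shapes: an ellipsoid whose radius
field carries K angular bumps placed quasi-uniformly on the sphere
(Fibonacci lattice) and jittered by the seed.  Tissues are Voronoi
partitions of seeded points, with walls carved as background where two
regions meet and intercellular space (ICS) opened as seeded stripes across
a controllable fraction of each interface.  Hyperspectral cubes mix
reference spectra under smooth abundance maps with multiplicative noise and
cosmic-ray spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .voxelio import HyperspectralCube, LabeledVolume, Spectrum


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class LobedCellSpec:
    """Parameters of one star-convex lobed cell phantom.

    ``bump_amplitude`` is the bump height as a fraction of the local
    ellipsoid radius (0–1); ``bump_sharpness`` is the concentration κ of
    the von Mises–Fisher-shaped angular profile exp(κ(cosθ − 1)).
    """

    base_radii: tuple[float, float, float] = (10.0, 10.0, 10.0)
    n_lobes: int = 0
    bump_amplitude: float = 0.35
    bump_sharpness: float = 50.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.base_radii):
            raise ValueError("base_radii must be positive")
        if not (0 <= self.bump_amplitude < 1):
            raise ValueError("bump_amplitude must be in [0, 1)")
        if self.n_lobes < 0:
            raise ValueError("n_lobes must be >= 0")


@dataclass
class TissueSpec:
    """Parameters of a multi-cell Voronoi tissue phantom."""

    n_cells: int = 10
    domain_size: tuple[float, float, float] = (40.0, 40.0, 40.0)
    wall_thickness: float = 0.0
    ics_fraction: float = 0.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be >= 0")
        if not (0 <= self.ics_fraction <= 1):
            raise ValueError("ics_fraction must be in [0, 1]")


@dataclass
class CubeSpec:
    """Parameters of a synthetic hyperspectral cube.

    ``abundance_model`` maps endmember name → list of Gaussian blobs
    ``(cy, cx, width_px, height)`` defining its smooth spatial weight map.
    ``noise_sd`` is the relative sd of multiplicative Gaussian noise;
    ``n_spikes`` single-pixel single-band cosmic-ray spikes of 20–100×
    local intensity are added at seeded positions.
    """

    shape: tuple[int, int] = (32, 32)
    abundance_model: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    n_spikes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")


# ---------------------------------------------------------------------------
# lobed single cells
# ---------------------------------------------------------------------------

def fibonacci_sphere(k: int) -> np.ndarray:
    """K quasi-uniform unit directions on the sphere (Fibonacci lattice)."""
    if k == 0:
        return np.zeros((0, 3))
    i = np.arange(k, dtype=float) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([z, r * np.sin(phi), r * np.cos(phi)])  # (z, y, x)


def _jitter_directions(dirs: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Perturb unit directions by Gaussian noise of angular scale sigma (rad)."""
    if len(dirs) == 0:
        return dirs
    noisy = dirs + sigma * rng.standard_normal(dirs.shape)
    return noisy / np.linalg.norm(noisy, axis=1, keepdims=True)


def _radius_field(units: np.ndarray, spec: LobedCellSpec, dirs: np.ndarray) -> np.ndarray:
    """Star-convex radius r(u) for an array of unit directions (N, 3)."""
    rz, ry, rx = spec.base_radii
    inv = np.sqrt(
        (units[:, 0] / rz) ** 2 + (units[:, 1] / ry) ** 2 + (units[:, 2] / rx) ** 2
    )
    r_ell = 1.0 / np.maximum(inv, 1e-12)
    if len(dirs):
        cosang = units @ dirs.T  # (N, K)
        bumps = np.exp(spec.bump_sharpness * (cosang - 1.0)).sum(axis=1)
        r_ell = r_ell * (1.0 + spec.bump_amplitude * bumps)
    return r_ell


def _analytic_volume(spec: LobedCellSpec, dirs: np.ndarray, n_theta: int = 240) -> float:
    """V = (1/3) ∮ r(u)³ dΩ by lat–long quadrature on the direction sphere."""
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = (np.arange(2 * n_theta) + 0.5) * 2 * math.pi / (2 * n_theta)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    units = np.column_stack(
        [np.cos(tt).ravel(), (np.sin(tt) * np.sin(pp)).ravel(), (np.sin(tt) * np.cos(pp)).ravel()]
    )
    r = _radius_field(units, spec, dirs)
    dOmega = (math.pi / n_theta) * (2 * math.pi / (2 * n_theta)) * np.sin(tt).ravel()
    return float((r**3 * dOmega).sum() / 3.0)


def make_lobed_cell(spec: LobedCellSpec) -> tuple[LabeledVolume, dict]:
    """Voxelize one star-convex lobed cell; label 1 on background 0.

    The grid is auto-sized so the perturbed radius fits with a one-voxel
    background margin; a cell still touching the boundary is an error
    (descriptors would be truncated).

    Returns the volume and a truth record with the lobe count, the jittered
    bump directions, and an analytic volume estimate from quadrature of the
    radius field.
    """
    rng = np.random.default_rng(spec.seed)
    dirs = fibonacci_sphere(spec.n_lobes)
    if spec.n_lobes:
        # jitter scale: a fraction of the mean angular pitch between lobes
        pitch = math.sqrt(4.0 * math.pi / spec.n_lobes)
        dirs = _jitter_directions(dirs, rng, 0.15 * pitch)

    # probe the radius field for the grid extent
    probe = fibonacci_sphere(2000) if spec.n_lobes else fibonacci_sphere(200)
    r_max = float(_radius_field(probe, spec, dirs).max()) * 1.02

    spacing = np.asarray(spec.spacing, dtype=float)
    half = np.ceil(r_max / spacing).astype(int) + 2
    shape = 2 * half + 1
    center = (shape / 2.0) * spacing  # physical center of the grid

    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing[0] - center[0],
        (np.arange(shape[1]) + 0.5) * spacing[1] - center[1],
        (np.arange(shape[2]) + 0.5) * spacing[2] - center[2],
        indexing="ij",
    )
    offs = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    norms = np.linalg.norm(offs, axis=1)
    units = offs / np.maximum(norms, 1e-12)[:, None]
    r = _radius_field(units, spec, dirs)
    inside = (norms <= r).reshape(tuple(shape))
    inside.flat[np.argmin(norms)] = True  # center voxel always inside

    labels = inside.astype(np.uint16)
    border = (
        labels[0].any() or labels[-1].any()
        or labels[:, 0].any() or labels[:, -1].any()
        or labels[:, :, 0].any() or labels[:, :, -1].any()
    )
    if border:
        raise ValueError("generated cell touches the grid boundary")

    truth = {
        "n_lobes": spec.n_lobes,
        "bump_directions": dirs,
        "analytic_volume": _analytic_volume(spec, dirs),
        "seed": spec.seed,
    }
    return LabeledVolume(labels, spec.spacing), truth


# ---------------------------------------------------------------------------
# tissues
# ---------------------------------------------------------------------------

def _place_seeds(spec: TissueSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform seed points with a minimum pairwise separation (rejection)."""
    domain = np.asarray(spec.domain_size, dtype=float)
    min_sep = max(2.0 * spec.wall_thickness, 0.15 * float(domain.min()))
    pts: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform(0, 1, 3) * domain
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == spec.n_cells:
                return np.array(pts)
    raise ValueError(
        f"could not place {spec.n_cells} seeds with separation {min_sep:.2f} µm "
        f"in domain {tuple(domain)}"
    )


def tissue_seed_points(spec: TissueSpec) -> np.ndarray:
    """The (n_cells, 3) seed points a given TissueSpec will use, in µm.

    Deterministic in ``spec.seed`` and identical to the placement inside
    :func:`make_tissue`, so geometric ground truth (e.g. bisector-plane
    interface areas) can be derived analytically.
    """
    return _place_seeds(spec, np.random.default_rng(spec.seed))


def make_tissue(spec: TissueSpec) -> tuple[LabeledVolume, list[dict]]:
    """Voronoi tissue phantom with walls and seeded intercellular space.

    Walls: voxels whose two nearest seeds are closer than ``wall_thickness``
    apart in distance (equivalent to eroding each region by half the wall
    thickness) become background.  ICS: across each Voronoi interface,
    ``ceil(6·ics_fraction)`` background stripes are opened along a seeded
    in-plane direction with total area coverage ``ics_fraction``; at
    fraction 1 the whole interface opens, at 0 nothing does.

    Returns the volume and a truth adjacency list of dicts with keys
    ``label_a``, ``label_b``, ``planned_area`` (µm², zero-wall Voronoi
    interface area) and ``in_contact``.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = _place_seeds(spec, rng)
    spacing = np.asarray(spec.spacing, dtype=float)
    domain = np.asarray(spec.domain_size, dtype=float)
    shape = np.maximum(np.round(domain / spacing).astype(int), 1)

    zc = (np.arange(shape[0]) + 0.5) * spacing[0]
    yc = (np.arange(shape[1]) + 0.5) * spacing[1]
    xc = (np.arange(shape[2]) + 0.5) * spacing[2]
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    pos = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)

    d2 = ((pos[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1)
    d = np.sqrt(d2)
    nearest = order[:, 0]
    d1 = d[np.arange(len(pos)), nearest]
    if spec.n_cells > 1:
        second = order[:, 1]
        dgap = d[np.arange(len(pos)), second] - d1
    else:
        second = nearest
        dgap = np.full(len(pos), np.inf)

    labels = (nearest + 1).astype(np.int32)
    labels[dgap < spec.wall_thickness] = 0

    face_areas = np.array(
        [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
    )
    # planned interface areas from the zero-wall partition
    nearest_grid = nearest.reshape(tuple(shape))
    pair_area: dict[tuple[int, int], float] = {}
    for axis in range(3):
        a = np.moveaxis(nearest_grid, axis, 0)[:-1]
        b = np.moveaxis(nearest_grid, axis, 0)[1:]
        diff = a != b
        la, lb = a[diff], b[diff]
        lo, hi = np.minimum(la, lb), np.maximum(la, lb)
        uniq, counts = np.unique(np.column_stack([lo, hi]), axis=0, return_counts=True)
        for (i, j), c in zip(uniq, counts):
            k = (int(i), int(j))
            pair_area[k] = pair_area.get(k, 0.0) + float(c) * face_areas[axis]

    # ICS stripes
    frac = spec.ics_fraction
    gap = max(spec.wall_thickness, 3.0 * float(spacing.max()))
    if frac > 0:
        pair_idx = np.minimum(nearest, second), np.maximum(nearest, second)
        for (i, j) in sorted(pair_area):
            prng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77, i, j]))
            sel = (pair_idx[0] == i) & (pair_idx[1] == j) & (dgap < gap)
            if not sel.any():
                continue
            if frac >= 1.0:
                labels[sel] = 0
                continue
            normal = seeds[j] - seeds[i]
            normal /= np.linalg.norm(normal)
            t = prng.standard_normal(3)
            t -= (t @ normal) * normal
            t /= np.linalg.norm(t)
            s = pos[sel] @ t
            smin, smax = s.min(), s.max()
            extent = max(smax - smin, 1e-9)
            n_stripes = int(math.ceil(6 * frac))
            period = extent / n_stripes * (1 + 1e-9)
            phase = prng.uniform(0, period)
            in_stripe = ((s - smin + phase) % period) < frac * period
            idx = np.flatnonzero(sel)[in_stripe]
            labels[idx] = 0

    labels = labels.reshape(tuple(shape))
    present = np.unique(labels)
    missing = [k + 1 for k in range(spec.n_cells) if (k + 1) not in present]
    if missing:
        raise ValueError(f"spec produced empty cells: labels {missing}")

    in_contact_possible = spec.wall_thickness == 0 and frac < 1
    truth = [
        {
            "label_a": i + 1,
            "label_b": j + 1,
            "planned_area": area,
            "in_contact": in_contact_possible,
        }
        for (i, j), area in sorted(pair_area.items())
    ]
    return LabeledVolume(labels.astype(np.int32), spec.spacing), truth


# ---------------------------------------------------------------------------
# spectra and cubes
# ---------------------------------------------------------------------------

def make_reference_spectrum(name: str, bands, axis) -> Spectrum:
    """Sum of Gaussian peaks ``(center cm⁻¹, width(sigma) cm⁻¹, height)``."""
    axis = np.asarray(axis, dtype=float)
    y = np.zeros_like(axis)
    for center, width, height in bands:
        if not (axis.min() <= center <= axis.max()):
            raise ValueError(f"band center {center} outside axis range for {name!r}")
        y += height * np.exp(-((axis - center) ** 2) / (2.0 * width**2))
    return Spectrum(axis, y)


#: Gaussian band tables (center cm⁻¹, sigma cm⁻¹, height) for the reference
#: compounds: cellulose (378, 1095, 1380 cm⁻¹ plus the CH-stretch envelope),
#: hemicellulose (xylan-like), and pectins whose ~850 cm⁻¹ marker band shifts
#: with the degree of methyl esterification (856 cm⁻¹ for 10–34%, 853 cm⁻¹
#: for >85%; the ester C=O at 1740 cm⁻¹ strengthens with esterification).
REFERENCE_BANDS = {
    "cellulose": [
        (378.0, 6.0, 0.45),
        (1095.0, 8.0, 1.0),
        (1120.0, 8.0, 0.55),
        (1380.0, 9.0, 0.6),
        (2897.0, 30.0, 0.9),
    ],
    "hemicellulose": [
        (494.0, 8.0, 0.5),
        (898.0, 7.0, 0.6),
        (1094.0, 10.0, 0.5),
        (1460.0, 12.0, 0.45),
        (2920.0, 32.0, 0.8),
    ],
    "pectin_de_10_34": [
        (856.0, 6.0, 1.0),
        (1078.0, 10.0, 0.4),
        (1608.0, 12.0, 0.5),
        (1740.0, 9.0, 0.15),
        (2945.0, 32.0, 0.6),
    ],
    "pectin_de_85": [
        (853.0, 6.0, 1.0),
        (1078.0, 10.0, 0.4),
        (1740.0, 9.0, 0.6),
        (2945.0, 32.0, 0.7),
    ],
}

REFERENCE_METADATA = {
    "cellulose": {"class": "cellulose"},
    "hemicellulose": {"class": "hemicellulose"},
    "pectin_de_10_34": {"class": "pectin", "esterification": "10-34%"},
    "pectin_de_85": {"class": "pectin", "esterification": ">85%"},
}


def default_axis(lo: float = 300.0, hi: float = 3100.0, step: float = 2.0) -> np.ndarray:
    """Default Raman shift axis in cm⁻¹ (~300–3100, 2 cm⁻¹ sampling)."""
    return np.arange(lo, hi + step / 2, step)


def default_reference_library(axis=None):
    """Reference library of cell-wall polysaccharide spectra on one axis."""
    from .ramanunmix import ReferenceLibrary

    if axis is None:
        axis = default_axis()
    entries = [
        (name, make_reference_spectrum(name, bands, axis), REFERENCE_METADATA[name])
        for name, bands in REFERENCE_BANDS.items()
    ]
    return ReferenceLibrary(entries)


def _blob_map(shape, blobs) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    m = np.zeros(shape, dtype=float)
    for cy, cx, width, height in blobs:
        m += height * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * width**2)))
    return m


def make_hyperspectral_cube(spec: CubeSpec, library) -> tuple[HyperspectralCube, dict]:
    """Mix library spectra under blob abundance maps; add noise and spikes.

    cube(y, x, :) = Σ_e abundance_e(y, x) · spectrum_e, times multiplicative
    Gaussian noise (1 + noise_sd·N), clipped at zero, plus ``n_spikes``
    single-sample additive cosmic-ray spikes of 20–100× local intensity.
    """
    rng = np.random.default_rng(spec.seed)
    missing = [n for n in spec.abundance_model if n not in library.names]
    if missing:
        raise KeyError(f"endmembers not in library: {missing}")

    axis = library.wavenumbers
    names = list(spec.abundance_model)
    maps = np.stack([_blob_map(spec.shape, spec.abundance_model[n]) for n in names])
    spectra = np.stack([library.spectrum(n).intensities for n in names])
    cube = np.einsum("eyx,eb->yxb", maps, spectra)

    if spec.noise_sd > 0:
        cube = cube * (1.0 + spec.noise_sd * rng.standard_normal(cube.shape))
        cube = np.clip(cube, 0.0, None)

    spikes = []
    # cosmic rays are detector events: their size does not track a dim band,
    # so floor the reference intensity at 2% of the cube's global maximum
    floor = max(0.02 * float(cube.max()), 1e-6)
    for _ in range(spec.n_spikes):
        y = int(rng.integers(0, spec.shape[0]))
        x = int(rng.integers(0, spec.shape[1]))
        b = int(rng.integers(0, axis.size))
        mag = float(rng.uniform(20.0, 100.0)) * max(cube[y, x, b], floor)
        cube[y, x, b] += mag
        spikes.append((y, x, b, mag))

    truth = {
        "endmember_names": names,
        "abundances": {n: maps[i] for i, n in enumerate(names)},
        "spikes": spikes,
    }
    return HyperspectralCube(cube, axis), truth
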