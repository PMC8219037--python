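"""Readers and writers for the formats the pipeline touches.

Label stacks and hyperspectral cubes travel as multipage TIFF (one page per
z-slice or spectral band), spectra and descriptor tables as CSV, and meshes
as PLY/STL.  Everything in the package uses (z, y, x) axis order, 0-based
indexing, and per-axis physical spacing ``(sz, sy, sx)`` in micrometres.
A voxel occupies the closed unit cell of its grid position; the physical
coordinate of the voxel center at index ``i`` is ``(i + 0.5) * s`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
import trimesh


class FormatError(ValueError):
    """Raised when a file does not satisfy the expected on-disk contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """A 3D grid of integer cell labels with physical voxel spacing.

    Parameters
    ----------
    labels
        Integer array of shape ``(nz, ny, nx)``.  Each non-background value
        denotes one cell's voxel set.
    spacing
        Voxel pitch ``(sz, sy, sx)`` in µm; all components positive.
    background_label
        Value meaning "not a cell" (intercellular space or exterior).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    background_label: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must have an integer dtype")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (sz, sy, sx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def cell_labels(self) -> np.ndarray:
        """Sorted distinct non-background labels present in the volume."""
        values = np.unique(self.labels)
        return values[values != self.background_label]

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one cell; raises KeyError if the label is absent."""
        m = self.labels == label
        if not m.any():
            raise KeyError(f"label {label} not present in volume")
        return m


@dataclass
class Spectrum:
    """A single spectrum: wavenumber axis (cm⁻¹) plus intensities (counts).

    The axis is normalized to strictly ascending order on construction;
    a descending axis is accepted and flipped together with the intensities.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValueError("wavenumbers and intensities must be 1D of equal length")
        d = np.diff(w)
        if w.size > 1 and np.all(d < 0):
            w, y = w[::-1].copy(), y[::-1].copy()
        elif w.size > 1 and not np.all(d > 0):
            raise ValueError("wavenumber axis must be strictly monotonic")
        self.wavenumbers, self.intensities = w, y

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class HyperspectralCube:
    """(y, x, band) intensity grid with a shared wavenumber axis."""

    cube: np.ndarray
    wavenumbers: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        w = np.asarray(self.wavenumbers, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must be 3D (y, x, band)")
        if self.cube.shape[2] != w.size:
            raise FormatError(
                f"cube has {self.cube.shape[2]} bands but wavenumber axis has {w.size}"
            )
        d = np.diff(w)
        if w.size > 1 and np.all(d < 0):
            w = w[::-1].copy()
            self.cube = self.cube[:, :, ::-1].copy()
        elif w.size > 1 and not np.all(d > 0):
            raise ValueError("wavenumber axis must be strictly monotonic")
        self.wavenumbers = w
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    def pixel(self, y: int, x: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.cube[y, x, :])


# ---------------------------------------------------------------------------
# label stacks
# ---------------------------------------------------------------------------

def read_label_stack(path, spacing) -> LabeledVolume:
    """Read a multipage TIFF whose pages are z-slices of a label volume."""
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"ragged page shapes in {path}: {sorted(shapes)}")
        arr = tif.asarray()
    if arr.ndim == 2:  # single page
        arr = arr[None, ...]
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"label stack must have integer pixel type, got {arr.dtype}")
    return LabeledVolume(arr, spacing)


def write_label_stack(vol: LabeledVolume, path) -> None:
    """Write a label volume as multipage TIFF, one page per z-slice.

    16-bit container by default, auto-promoted to 32-bit when labels exceed
    65535 — never silently truncated.
    """
    labels = vol.labels
    top = int(labels.max()) if labels.size else 0
    if top <= np.iinfo(np.uint16).max:
        out = labels.astype(np.uint16)
    elif top <= np.iinfo(np.uint32).max:
        out = labels.astype(np.uint32)
    else:
        raise FormatError(f"label {top} exceeds the 32-bit container")
    tifffile.imwrite(path, out)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh(vertices, faces, path) -> None:
    """Write a triangular mesh as PLY or STL, chosen by file extension."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise ValueError("refusing to write an empty mesh")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise ValueError("faces index vertices out of range")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(str(path))


def read_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PLY/STL mesh back as (vertices, faces)."""
    mesh = trimesh.load_mesh(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# spectra, cubes, tables
# ---------------------------------------------------------------------------

_WN_COL = "wavenumber_cm1"


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column (wavenumber, intensity) CSV into a Spectrum."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("spectrum CSV needs two numeric columns")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {_WN_COL: spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False, float_format="%.17g")


def read_cube(path_tiff, path_wavenumbers, pixel_spacing=(1.0, 1.0)) -> HyperspectralCube:
    """Read a band-sequential TIFF cube plus its wavenumber sidecar CSV.

    TIFF pages are spectral bands in sidecar row order; a page-count /
    sidecar-length mismatch is a format error.
    """
    arr = tifffile.imread(path_tiff)
    if arr.ndim == 2:
        arr = arr[None, ...]
    w = pd.read_csv(path_wavenumbers).iloc[:, 0].to_numpy(float)
    if arr.shape[0] != w.size:
        raise FormatError(
            f"cube has {arr.shape[0]} pages but sidecar lists {w.size} wavenumbers"
        )
    return HyperspectralCube(np.moveaxis(arr, 0, 2), w, pixel_spacing)


def write_cube(cube: HyperspectralCube, path_tiff, path_wavenumbers) -> None:
    tifffile.imwrite(path_tiff, np.moveaxis(cube.cube, 2, 0).astype(np.float64))
    pd.DataFrame({_WN_COL: cube.wavenumbers}).to_csv(
        path_wavenumbers, index=False, float_format="%.17g"
    )


def write_records_csv(records, path) -> None:
    """Write per-cell descriptor records (dataclasses or dicts) as CSV."""
    from dataclasses import asdict, is_dataclass

    rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
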