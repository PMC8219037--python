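import numpy as np
import pytest
from scipy import ndimage

from conftest import random_label_volume
from oracles import (
    brute_force_contact_faces,
    brute_force_les,
    brute_force_patch_count,
    facet_divergence_hull_volume,
)
from puzzlecell import morphometry, synthcell
from puzzlecell.morphometry import CellShapeRecord
from puzzlecell.voxelio import LabeledVolume


def cube_volume(n=10, spacing=(1.0, 1.0, 1.0), pad=2):
    labels = np.zeros((n + 2 * pad,) * 3, dtype=np.uint8)
    labels[pad:-pad, pad:-pad, pad:-pad] = 1
    return LabeledVolume(labels, spacing)


class TestVolume:
    @pytest.mark.parametrize(
        "spacing,expected",
        [((1.0, 1.0, 1.0), 1000.0), ((0.1, 0.1, 0.1), 1.0)],
    )
    def test_cube_volume_scales_with_spacing(self, spacing, expected):
        vol = cube_volume(10, spacing)
        assert morphometry.cell_volume(vol, 1) == pytest.approx(expected)

    def test_sphere_volume_analytic(self):
        spec = synthcell.LobedCellSpec(base_radii=(5.0, 5.0, 5.0), n_lobes=0,
                                       bump_amplitude=0.0, spacing=(0.2, 0.2, 0.2))
        vol, _ = synthcell.make_lobed_cell(spec)
        assert morphometry.cell_volume(vol, 1) == pytest.approx(523.6, rel=0.02)

    def test_absent_label_rejected(self):
        with pytest.raises(KeyError):
            morphometry.cell_volume(cube_volume(), 7)


class TestSurfaceArea:
    def test_sphere_area_analytic(self, sphere_volume):
        vol, _ = sphere_volume
        area = morphometry.cell_surface_area(vol, 1)
        assert area == pytest.approx(4 * np.pi * 100, rel=0.03)

    def test_cube_area_bounded_by_voxel_faces(self):
        vol = cube_volume(10)
        mesh_area = morphometry.cell_surface_area(vol, 1)
        face_area = morphometry.voxel_face_area(vol, 1)
        assert face_area == pytest.approx(600.0)
        # isosurfacing rounds the sharp edges, so the mesh area sits below
        # the analytic 600 µm² and always below the voxel-face bound
        assert mesh_area < face_area
        assert mesh_area == pytest.approx(600.0, rel=0.13)

    def test_single_voxel_area_positive_below_bound(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = 1
        vol = LabeledVolume(labels, (1.0, 1.0, 1.0))
        area = morphometry.cell_surface_area(vol, 1)
        assert 0 < area < 6.0

    def test_mesh_below_voxel_faces_on_random_volumes(self):
        for seed in range(5):
            vol = random_label_volume(seed)
            for label in vol.cell_labels():
                assert morphometry.cell_surface_area(vol, int(label)) <= \
                    morphometry.voxel_face_area(vol, int(label))


class TestSolidity:
    def test_solid_cube_exactly_one(self):
        _, sol = morphometry.solidity(cube_volume(10), 1)
        assert sol == 1.0

    def test_cross_hull_matches_divergence_oracle(self):
        """3-armed orthogonal cross: hull volume against an independent
        facet-divergence computation."""
        labels = np.zeros((15, 15, 15), dtype=np.uint8)
        labels[2:13, 7, 7] = 1
        labels[7, 2:13, 7] = 1
        labels[7, 7, 2:13] = 1
        vol = LabeledVolume(labels, (1.0, 1.0, 1.0))
        hull_vol, sol = morphometry.solidity(vol, 1)
        oracle = 0.5 * (
            facet_divergence_hull_volume(
                morphometry.surface_voxel_corners(vol.mask(1), vol.spacing)
            )
            + facet_divergence_hull_volume(
                morphometry.surface_voxel_centers(vol.mask(1), vol.spacing)
            )
        )
        assert hull_vol == pytest.approx(oracle, rel=1e-9)
        assert sol == pytest.approx(31.0 / hull_vol, rel=1e-9)

    def test_lobed_phantom_loses_solidity(self, lobed_volume):
        vol, _ = lobed_volume
        _, sol = morphometry.solidity(vol, 1)
        assert sol < 0.8

    def test_coplanar_voxels_rejected(self):
        labels = np.zeros((3, 5, 5), dtype=np.uint8)
        labels[1, 1:4, 1:4] = 1  # a flat plate one voxel thick is still 3D
        flat = np.zeros((1, 5, 5), dtype=np.uint8)
        flat[0, 1:4, 1:4] = 1
        # degenerate: all surface voxel centers coplanar
        vol = LabeledVolume(flat, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            morphometry.solidity(vol, 1)

    def test_discretization_error_vanishes_with_resolution(self):
        """The volume/hull ratio of a digitized ball approaches 1 (a convex
        shape's true solidity) as the grid gets finer."""
        errors = []
        for spacing in (0.5, 0.25):
            spec = synthcell.LobedCellSpec(base_radii=(5.0, 5.0, 5.0), n_lobes=0,
                                           bump_amplitude=0.0,
                                           spacing=(spacing,) * 3)
            vol, _ = synthcell.make_lobed_cell(spec)
            hull_vol, _ = morphometry.solidity(vol, 1)
            errors.append(abs(morphometry.cell_volume(vol, 1) / hull_vol - 1.0))
        assert errors[0] >= errors[1]
        assert errors[1] < 0.04


class TestLargestEmptySphere:
    def test_matches_brute_force_on_random_volumes(self):
        for seed in range(6):
            vol = random_label_volume(seed)
            for label in vol.cell_labels():
                les, _ = morphometry.largest_empty_sphere(vol, int(label))
                oracle = brute_force_les(vol.labels, int(label), vol.spacing)
                assert les == pytest.approx(oracle, abs=1e-9)

    def test_digital_ball_diameter(self):
        r = 8
        n = 2 * r + 5
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        labels = ((zz**2 + yy**2 + xx**2) <= r * r).astype(np.uint8)
        vol = LabeledVolume(labels, (1.0, 1.0, 1.0))
        les, center = morphometry.largest_empty_sphere(vol, 1)
        assert les == pytest.approx(2 * r, abs=1.0)

    def test_thin_bar_limited_by_width(self):
        labels = np.zeros((3, 3, 24), dtype=np.uint8)
        labels[1, 1, 2:22] = 1
        vol = LabeledVolume(labels, (1.0, 1.0, 1.0))
        les, _ = morphometry.largest_empty_sphere(vol, 1)
        assert les == pytest.approx(2.0, abs=0.01)  # 2 × 1-voxel distance

    def test_bounded_by_equivalent_sphere(self):
        for seed in range(4):
            vol = random_label_volume(seed)
            voxel_diag = np.linalg.norm(vol.spacing)
            for label in vol.cell_labels():
                les, _ = morphometry.largest_empty_sphere(vol, int(label))
                v = morphometry.cell_volume(vol, int(label))
                assert les <= (6 * v / np.pi) ** (1 / 3) + 2 * voxel_diag

    def test_monotone_under_growth(self):
        """Adding voxels never decreases volume, hull volume, or LES."""
        vol = random_label_volume(3, n_blobs=1)
        les0, _ = morphometry.largest_empty_sphere(vol, 1)
        v0 = morphometry.cell_volume(vol, 1)
        h0, _ = morphometry.solidity(vol, 1)
        grown = ndimage.binary_dilation(vol.labels == 1).astype(np.uint8)
        gvol = LabeledVolume(grown, vol.spacing)
        les1, _ = morphometry.largest_empty_sphere(gvol, 1)
        assert morphometry.cell_volume(gvol, 1) >= v0
        assert morphometry.solidity(gvol, 1)[0] >= h0
        assert les1 >= les0


class TestLESBaseline:
    def _records(self, volumes, les):
        return [
            CellShapeRecord(label=i, volume=v, surface_area=0, hull_volume=v,
                            solidity=1, les_diameter=d, les_center=(0, 0, 0))
            for i, (v, d) in enumerate(zip(volumes, les))
        ]

    def test_fixed_point_at_reference_volume(self):
        recs = self._records([100.0, 100.0], [5.0, 5.0])
        assert morphometry.les_baseline(recs, 100.0) == pytest.approx(5.0)

    def test_thirteen_fold_volume_cube_root_scaling(self):
        """13× the reference volume predicts 13^(1/3) ≈ 2.351× the LES."""
        recs = self._records([100.0], [5.0])
        predicted = morphometry.les_baseline(recs, 1300.0)
        assert predicted == pytest.approx(5.0 * 13 ** (1 / 3), rel=1e-12)

    def test_lobed_cell_falls_below_baseline(self):
        """A lobed cell of equal volume has a smaller LES than the no-lobe
        isometric extrapolation predicts."""
        ref_spec = synthcell.LobedCellSpec(base_radii=(5.0, 5.0, 5.0), n_lobes=0,
                                           bump_amplitude=0.0, spacing=(0.4, 0.4, 0.4))
        ref_vol, _ = synthcell.make_lobed_cell(ref_spec)
        ref_rec = self._records(
            [morphometry.cell_volume(ref_vol, 1)],
            [morphometry.largest_empty_sphere(ref_vol, 1)[0]],
        )
        lobed_spec = synthcell.LobedCellSpec(base_radii=(10.0, 10.0, 10.0), n_lobes=10,
                                             bump_amplitude=0.35, spacing=(0.5, 0.5, 0.5),
                                             seed=2)
        lobed_vol, _ = synthcell.make_lobed_cell(lobed_spec)
        v = morphometry.cell_volume(lobed_vol, 1)
        les, _ = morphometry.largest_empty_sphere(lobed_vol, 1)
        assert les < morphometry.les_baseline(ref_rec, v)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            morphometry.les_baseline([], 100.0)


class TestContactAreas:
    def two_cubes(self, gap=0, window=False):
        labels = np.zeros((6, 6, 10), dtype=np.uint8)
        labels[1:5, 1:5, 1:5] = 1
        labels[1:5, 1:5, 5 + gap : 9 + gap] = 2
        if window:
            labels[2:4, 2:4, 4:6] = 0  # punch the central 2×2 faces out
        return LabeledVolume(labels, (1.0, 1.0, 1.0))

    def test_full_face_contact(self):
        table = morphometry.contact_areas(self.two_cubes())
        assert len(table) == 1
        assert table.loc[0, "area"] == 16.0
        assert table.loc[0, "n_patches"] == 1

    def test_windowed_face_is_one_ring_patch(self):
        table = morphometry.contact_areas(self.two_cubes(window=True))
        assert table.loc[0, "area"] == 12.0
        assert table.loc[0, "n_patches"] == 1  # the ring stays connected

    def test_gap_breaks_contact(self):
        labels = self.two_cubes().labels.copy()
        labels[:, :, 5] = np.where(labels[:, :, 5] == 2, 0, labels[:, :, 5])
        table = morphometry.contact_areas(LabeledVolume(labels, (1, 1, 1)))
        assert len(table) == 0

    def test_matches_brute_force_enumeration(self):
        for seed in range(6):
            vol = random_label_volume(seed)
            table = morphometry.contact_areas(vol)
            oracle = brute_force_contact_faces(vol.labels)
            assert len(table) == len(oracle)
            for row in table.itertuples():
                faces = oracle[(row.label_a, row.label_b)]
                assert row.area == pytest.approx(len(faces))
                assert row.n_patches == brute_force_patch_count(faces)

    def test_anisotropic_face_areas(self):
        vol = self.two_cubes()
        aniso = LabeledVolume(vol.labels, (2.0, 3.0, 1.0))
        table = morphometry.contact_areas(aniso)
        assert table.loc[0, "area"] == pytest.approx(16 * 2.0 * 3.0)

    def test_contact_bounded_by_voxel_face_area(self):
        for seed in range(4):
            vol = random_label_volume(seed)
            table = morphometry.contact_areas(vol)
            for label in vol.cell_labels():
                rows = table[(table.label_a == label) | (table.label_b == label)]
                assert rows["area"].sum() <= morphometry.voxel_face_area(vol, int(label))


class TestNeighbourCount:
    def test_rubiks_cube_center_has_six(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        lab = 1
        for z in range(3):
            for y in range(3):
                for x in range(3):
                    labels[2 * z : 2 * z + 2, 2 * y : 2 * y + 2, 2 * x : 2 * x + 2] = lab
                    lab += 1
        vol = LabeledVolume(labels, (1.0, 1.0, 1.0))
        table = morphometry.contact_areas(vol)
        assert morphometry.neighbour_count(table, 14) == 6  # center cell

    def test_isolated_cells_have_zero(self):
        spec = synthcell.TissueSpec(n_cells=5, domain_size=(18.0, 18.0, 18.0),
                                    wall_thickness=0.0, ics_fraction=1.0,
                                    spacing=(0.5, 0.5, 0.5), seed=1)
        vol, _ = synthcell.make_tissue(spec)
        table = morphometry.contact_areas(vol)
        for label in vol.cell_labels():
            assert morphometry.neighbour_count(table, int(label)) == 0

    def test_matches_voronoi_truth_degree(self):
        spec = synthcell.TissueSpec(n_cells=8, domain_size=(24.0, 24.0, 24.0),
                                    wall_thickness=0.0, ics_fraction=0.0,
                                    spacing=(0.5, 0.5, 0.5), seed=7)
        vol, truth = synthcell.make_tissue(spec)
        table = morphometry.contact_areas(vol)
        for label in vol.cell_labels():
            degree = sum(
                1 for t in truth
                if t["in_contact"] and label in (t["label_a"], t["label_b"])
            )
            assert morphometry.neighbour_count(table, int(label)) == degree


class TestWallThickness:
    def test_uniform_slab(self):
        slab = np.zeros((9, 16, 16), dtype=bool)
        slab[2:7] = True
        tmap = morphometry.wall_thickness_map(slab, (0.2, 0.2, 0.2))
        interior = tmap.values[4, 4:12, 4:12]
        np.testing.assert_allclose(interior, 1.0, atol=0.2)  # ±1 voxel
        assert tmap.mean == pytest.approx(1.0, abs=0.2)

    def test_hollow_sphere_shell(self):
        n = 33
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        r = np.sqrt(zz**2 + yy**2 + xx**2)
        shell = (r >= 9) & (r <= 12)  # wall ~3 voxels
        tmap = morphometry.wall_thickness_map(shell, (1.0, 1.0, 1.0))
        assert tmap.mean == pytest.approx(3.0, abs=1.0)

    def test_bimodal_slabs_recovered(self):
        bim = np.zeros((16, 10, 30), dtype=bool)
        bim[5:10, :, 0:15] = True  # 5 voxels thick
        bim[3:12, :, 15:30] = True  # 9 voxels thick
        tmap = morphometry.wall_thickness_map(bim, (1.0, 1.0, 1.0))
        thin = tmap.values[7, 5, 2:10]
        thick = tmap.values[7, 5, 20:28]
        np.testing.assert_allclose(thin, 5.0, atol=1.0)
        np.testing.assert_allclose(thick, 9.0, atol=1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morphometry.wall_thickness_map(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestThicknessExcess:
    def test_uniform_slab_gives_empty_mask(self):
        slab = np.zeros((9, 12, 12), dtype=bool)
        slab[3:6] = True
        tmap = morphometry.wall_thickness_map(slab, (1.0, 1.0, 1.0))
        # every interior voxel equals the mean; nothing is strictly above it
        ex = morphometry.thickness_excess_mask(tmap)
        assert ex[4, 4:8, 4:8].sum() == 0

    def test_bimodal_mask_selects_thick_slab(self):
        bim = np.zeros((16, 10, 30), dtype=bool)
        bim[5:10, :, 0:15] = True
        bim[3:12, :, 15:30] = True
        tmap = morphometry.wall_thickness_map(bim, (1.0, 1.0, 1.0))
        ex = morphometry.thickness_excess_mask(tmap)
        assert ex[7, 5, 20]  # thick plateau above the mean
        assert not ex[7, 5, 5]  # thin plateau below it

    def test_embedded_annulus_forms_single_loop(self):
        """A thicker ring embedded in a thin plate shows up as one
        connected 'loop' in the excess mask."""
        plate = np.zeros((13, 40, 40), dtype=bool)
        plate[5:8] = True  # 3 voxels thick
        yy, xx = np.meshgrid(np.arange(40) - 19.5, np.arange(40) - 19.5, indexing="ij")
        ring = (np.sqrt(yy**2 + xx**2) >= 10) & (np.sqrt(yy**2 + xx**2) <= 14)
        for z in (3, 4, 8, 9):  # thicken the plate to 7 voxels on the ring
            plate[z, ring] = True
        tmap = morphometry.wall_thickness_map(plate, (1.0, 1.0, 1.0))
        ex = morphometry.thickness_excess_mask(tmap)
        lab, n = ndimage.label(ex, structure=np.ones((3, 3, 3)))
        assert n == 1
        # the loop encircles the plate center: it is hollow in the middle
        assert not ex[:, 18:22, 18:22].any()


class TestRotationRobustness:
    def test_descriptors_invariant_under_axis_permutation(self, lobed_volume):
        vol, _ = lobed_volume
        rotated = LabeledVolume(
            np.rot90(vol.labels, k=1, axes=(1, 2)).copy(), vol.spacing
        )
        v1 = morphometry.cell_volume(vol, 1)
        v2 = morphometry.cell_volume(rotated, 1)
        assert v1 == v2
        s1 = morphometry.cell_surface_area(vol, 1)
        s2 = morphometry.cell_surface_area(rotated, 1)
        assert s1 == pytest.approx(s2, rel=1e-5)  # float32 isosurface field
        les1, _ = morphometry.largest_empty_sphere(vol, 1)
        les2, _ = morphometry.largest_empty_sphere(rotated, 1)
        assert les1 == pytest.approx(les2, abs=1e-9)
        h1, sol1 = morphometry.solidity(vol, 1)
        h2, sol2 = morphometry.solidity(rotated, 1)
        assert h1 == pytest.approx(h2, rel=1e-9)

    def test_arbitrary_rotation_within_discretization_tolerance(self):
        """The same continuous phantom voxelized after a 30° tilt keeps its
        descriptors within 5%."""
        base = synthcell.LobedCellSpec(base_radii=(6.0, 8.0, 10.0), n_lobes=0,
                                       bump_amplitude=0.0, spacing=(0.4, 0.4, 0.4))
        vol, _ = synthcell.make_lobed_cell(base)
        mask = vol.mask(1).astype(float)
        rot = ndimage.rotate(mask, 30, axes=(1, 2), order=1, cval=0.0)
        rvol = LabeledVolume((rot > 0.5).astype(np.uint8), vol.spacing)
        assert morphometry.cell_volume(rvol, 1) == pytest.approx(
            morphometry.cell_volume(vol, 1), rel=0.05
        )
        assert morphometry.cell_surface_area(rvol, 1) == pytest.approx(
            morphometry.cell_surface_area(vol, 1), rel=0.05
        )
        assert morphometry.largest_empty_sphere(rvol, 1)[0] == pytest.approx(
            morphometry.largest_empty_sphere(vol, 1)[0], rel=0.05
        )


class TestMeasureCells:
    def test_border_cells_excluded(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[0:3, 0:3, 0:3] = 1  # touches border
        labels[3:6, 3:6, 3:6] = 2  # interior
        vol = LabeledVolume(labels, (1.0, 1.0, 1.0))
        recs = morphometry.measure_cells(vol)
        assert [r.label for r in recs] == [2]
        recs_all = morphometry.measure_cells(vol, exclude_border=False)
        assert [r.label for r in recs_all] == [1, 2]

    def test_record_invariants_on_tissue(self):
        spec = synthcell.TissueSpec(n_cells=8, domain_size=(24.0, 24.0, 24.0),
                                    wall_thickness=0.0, ics_fraction=0.2,
                                    spacing=(0.5, 0.5, 0.5), seed=9)
        vol, _ = synthcell.make_tissue(spec)
        voxel_diag = np.linalg.norm(vol.spacing)
        # Voronoi regions of a small tissue all reach the domain border, so
        # measure everything rather than only interior cells here
        recs = morphometry.measure_cells(vol, exclude_border=False)
        assert recs
        for r in recs:
            assert 0 < r.solidity <= 1
            assert r.les_diameter <= (6 * r.volume / np.pi) ** (1 / 3) + 2 * voxel_diag
            assert r.total_contact_area <= morphometry.voxel_face_area(vol, r.label)
            assert r.n_contact_patches >= r.n_neighbours
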