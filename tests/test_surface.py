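"""Voxel surface construction and feature-field evaluation."""

import numpy as np
import pytest
from scipy import ndimage

from zernpatch import (
    Atom,
    ParameterizedStructure,
    assign_hbond,
    build_grid,
    compute_electrostatics,
    compute_mhp,
    compute_visibility,
    extract_ppi_surface,
    extract_surface,
)
from zernpatch.surface import VoxelGrid, fibonacci_sphere

from conftest import make_surface_from_indices


def synthetic_structure(positions, radius=1.7, charge=0.0, logp=0.0, hbond="none"):
    """ParameterizedStructure with per-atom parameters given directly."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            residue_name="ALA",
            chain_id="A",
            residue_seq=i + 1,
            position=tuple(p),
            element="C",
        )
        for i, p in enumerate(positions)
    ]

    def vec(v):
        return np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)

    return ParameterizedStructure(
        atoms=atoms,
        radius=vec(radius),
        partial_charge=vec(charge),
        atomic_logp=vec(logp),
        hbond_class=[hbond] * n if isinstance(hbond, str) else list(hbond),
    )


def ball_grid(radius_vox: int, spacing: float = 0.6) -> VoxelGrid:
    n = 2 * radius_vox + 5
    c = n // 2
    ax = np.arange(n)
    d2 = (
        (ax[:, None, None] - c) ** 2
        + (ax[None, :, None] - c) ** 2
        + (ax[None, None, :] - c) ** 2
    )
    return VoxelGrid(
        origin=np.zeros(3), spacing=spacing, protein=d2 <= radius_vox**2
    )


class TestBuildGrid:
    def test_single_atom_volume_matches_sphere(self):
        st = synthetic_structure([[0, 0, 0]], radius=1.7)
        grid = build_grid(st, spacing=0.6, probe=1.4)
        count = grid.protein.sum()
        expected = 4 / 3 * np.pi * (1.7 / 0.6) ** 3
        assert abs(count - expected) / expected < 0.15

    def test_far_apart_atoms_give_two_components(self):
        st = synthetic_structure([[0, 0, 0], [50, 0, 0]], radius=1.7)
        grid = build_grid(st)
        _, n_comp = ndimage.label(grid.protein)
        assert n_comp == 2

    def test_probe_inaccessible_cavity_is_protein(self):
        # dense shell of atoms around an empty center: probe cannot enter
        dirs = fibonacci_sphere(300)
        st = synthetic_structure(5.0 * dirs, radius=1.7)
        grid = build_grid(st)
        center_idx = grid.index_of(np.zeros(3))
        assert grid.protein[tuple(center_idx)]

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            build_grid(synthetic_structure(np.empty((0, 3))))


class TestExtractSurface:
    def test_solid_ball_yields_spherical_shell(self):
        r_vox = 6
        grid = ball_grid(r_vox)
        surf = extract_surface(grid)
        center = (np.array(grid.dims) // 2) * grid.spacing
        radii = np.linalg.norm(surf.points - center, axis=1)
        r = r_vox * grid.spacing
        assert np.all(np.abs(radii - r) <= grid.spacing * np.sqrt(3))
        # shell is one connected component
        mask = np.zeros(grid.dims, dtype=bool)
        mask[tuple(surf.voxel_index.T)] = True
        _, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n_comp == 1

    def test_single_voxel_is_its_own_surface(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        grid = VoxelGrid(origin=np.zeros(3), spacing=0.6, protein=mask)
        surf = extract_surface(grid)
        assert len(surf) == 1

    def test_hollow_shell_has_inner_and_outer_boundary(self):
        grid = ball_grid(6)
        inner = ball_grid(3).protein
        pad = (np.array(grid.dims) - np.array(inner.shape)) // 2
        hollow = grid.protein.copy()
        sl = tuple(slice(p, p + s) for p, s in zip(pad, inner.shape))
        hollow[sl] &= ~inner
        grid2 = VoxelGrid(origin=np.zeros(3), spacing=0.6, protein=hollow)
        surf = extract_surface(grid2)
        center = (np.array(grid2.dims) // 2) * grid2.spacing
        radii = np.linalg.norm(surf.points - center, axis=1)
        assert (radii < 2.5).any()  # inner wall
        assert (radii > 3.0).any()  # outer wall

    def test_degenerate_grids_rejected(self):
        full = VoxelGrid(np.zeros(3), 0.6, np.ones((4, 4, 4), dtype=bool))
        empty = VoxelGrid(np.zeros(3), 0.6, np.zeros((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            extract_surface(full)
        with pytest.raises(ValueError):
            extract_surface(empty)


class TestInterfaceExtraction:
    def test_cutoff_is_strict(self):
        st = synthetic_structure([[0, 0, 0]])
        grid = build_grid(st)
        surf = extract_surface(grid)
        # place one partner atom 4.9 Å from the closest surface point
        p0 = surf.points[np.argmax(surf.points[:, 0])]
        partner_in = synthetic_structure([p0 + [4.9, 0, 0]])
        ppi = extract_ppi_surface(surf, partner_in, cutoff=5.0)
        assert len(ppi) >= 1
        d = np.linalg.norm(ppi.points - (p0 + [4.9, 0, 0]), axis=1)
        assert d.min() < 5.0

    def test_no_interface_beyond_cutoff(self):
        st = synthetic_structure([[0, 0, 0]])
        grid = build_grid(st)
        surf = extract_surface(grid)
        far = surf.points[:, 0].max()
        partner_out = synthetic_structure([[far + 5.1, 0, 0]])
        with pytest.raises(ValueError, match="no interface"):
            extract_ppi_surface(surf, partner_out, cutoff=5.0)

    def test_translated_copy_has_no_interface(self):
        st = synthetic_structure([[0, 0, 0], [3, 0, 0]])
        grid = build_grid(st)
        surf = extract_surface(grid)
        shifted = synthetic_structure([[100, 0, 0], [103, 0, 0]])
        with pytest.raises(ValueError, match="no interface"):
            extract_ppi_surface(surf, shifted)


class TestHydrophobicField:
    def test_single_atom_field_is_its_logp(self):
        st = synthetic_structure([[0, 0, 0]], logp=0.5)
        grid = build_grid(st)
        surf = extract_surface(grid)
        compute_mhp(surf, st)
        np.testing.assert_allclose(surf.mhp, 0.5, atol=1e-12)

    def test_symmetric_opposite_atoms_cancel(self):
        st = synthetic_structure([[-2, 0, 0], [2, 0, 0]], logp=[1.0, -1.0])
        surf = make_surface_from_indices([[0, 0, 0]])
        surf.points = np.array([[0.0, 5.0, 0.0]])  # equidistant from both atoms
        compute_mhp(surf, st)
        assert surf.mhp[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_atom_case_matches_direct_evaluation(self):
        # independent scalar evaluation of the weighted-average definition
        st = synthetic_structure([[3, 0, 0], [0, 5, 0]], logp=[1.0, 0.0])
        surf = make_surface_from_indices([[0, 0, 0]])
        surf.points = np.array([[0.0, 0.0, 0.0]])
        compute_mhp(surf, st)
        w1 = 1.0 / (1.0 + np.exp(3.0 - 4.0))
        w2 = 1.0 / (1.0 + np.exp(5.0 - 4.0))
        expected = (1.0 * w1 + 0.0 * w2) / (w1 + w2)
        assert surf.mhp[0] == pytest.approx(expected, abs=1e-12)

    def test_field_is_convex_combination_of_logp(self):
        rng = np.random.default_rng(0)
        logp = rng.uniform(-2, 3, size=8)
        st = synthetic_structure(rng.uniform(-5, 5, size=(8, 3)), logp=logp)
        grid = build_grid(st)
        surf = extract_surface(grid)
        compute_mhp(surf, st)
        assert surf.mhp.min() >= logp.min() - 1e-9
        assert surf.mhp.max() <= logp.max() + 1e-9


class TestHbondField:
    @pytest.mark.parametrize(
        "hbond,expected",
        [("donor", 1), ("acceptor", -1), ("none", 0), ("dual", 0)],
    )
    def test_nearest_atom_class_maps_to_value(self, hbond, expected):
        st = synthetic_structure([[0, 0, 0]], hbond=hbond)
        grid = build_grid(st)
        surf = extract_surface(grid)
        assign_hbond(surf, st)
        assert set(np.unique(surf.hbond)) == {expected}

    def test_ties_broken_by_lowest_serial(self):
        st = synthetic_structure(
            [[-2, 0, 0], [2, 0, 0]], hbond=["donor", "acceptor"]
        )
        surf = make_surface_from_indices([[0, 0, 0]])
        surf.points = np.array([[0.0, 0.0, 0.0]])  # exactly equidistant
        assign_hbond(surf, st)
        assert surf.hbond[0] == 1  # serial 1 is the donor


class TestVisibility:
    def test_isolated_voxel_fully_exposed(self):
        surf = make_surface_from_indices([[0, 0, 0]])
        compute_visibility(surf)
        assert surf.visibility[0] == 1.0

    def test_inner_wall_of_closed_shell_fully_buried(self):
        grid = ball_grid(9)
        inner = ball_grid(4).protein
        pad = (np.array(grid.dims) - np.array(inner.shape)) // 2
        hollow = grid.protein.copy()
        sl = tuple(slice(p, p + s) for p, s in zip(pad, inner.shape))
        hollow[sl] &= ~inner
        grid2 = VoxelGrid(origin=np.zeros(3), spacing=0.6, protein=hollow)
        surf = extract_surface(grid2)
        center = (np.array(grid2.dims) // 2) * grid2.spacing
        radii = np.linalg.norm(surf.points - center, axis=1)
        innermost = int(np.argmin(radii))
        compute_visibility(surf, point_indices=[innermost])
        assert surf.visibility[innermost] == 0.0

    def test_flat_slab_face_sees_half_the_sky(self):
        mask = np.zeros((60, 60, 10), dtype=bool)
        mask[:, :, 1:5] = True  # 4-voxel-thick slab
        grid = VoxelGrid(origin=np.zeros(3), spacing=0.6, protein=mask)
        surf = extract_surface(grid)
        target = np.flatnonzero(
            (surf.voxel_index[:, 0] == 30)
            & (surf.voxel_index[:, 1] == 30)
            & (surf.voxel_index[:, 2] == 4)  # top face center
        )[0]
        compute_visibility(surf, point_indices=[target])
        assert surf.visibility[target] == pytest.approx(0.5, abs=0.05)

    def test_approaching_wall_monotonically_blocks(self):
        vis = []
        for gap in (18, 10, 4):  # voxels of free space between the slabs
            mask = np.zeros((44, 44, 30), dtype=bool)
            mask[2:42, 2:42, 1:4] = True
            mask[2:42, 2:42, 4 + gap : 7 + gap] = True
            grid = VoxelGrid(origin=np.zeros(3), spacing=0.6, protein=mask)
            surf = extract_surface(grid)
            target = np.flatnonzero(
                (surf.voxel_index[:, 0] == 22)
                & (surf.voxel_index[:, 1] == 22)
                & (surf.voxel_index[:, 2] == 3)  # lower slab, facing the wall
            )[0]
            compute_visibility(surf, point_indices=[target])
            vis.append(surf.visibility[target])
        assert vis[0] > vis[1] > vis[2]

    def test_invalid_ray_count_rejected(self):
        surf = make_surface_from_indices([[0, 0, 0]])
        with pytest.raises(ValueError):
            compute_visibility(surf, n_rays=0)


class TestElectrostatics:
    def test_coulomb_ratio_follows_distance_dependent_dielectric(self):
        st = synthetic_structure([[0, 0, 0]], charge=1.0)
        surf = make_surface_from_indices([[0, 0, 0], [1, 0, 0]])
        surf.points = np.array([[2.0, 0, 0], [4.0, 0, 0]])
        compute_electrostatics(surf, st, backend="coulomb")
        # φ ∝ 1/(4 r²): ratio φ(2)/φ(4) = 16/4 = 4
        assert surf.electrostatic[0] / surf.electrostatic[1] == pytest.approx(4.0)

    def test_zero_charges_give_zero_potential(self):
        st = synthetic_structure([[0, 0, 0], [3, 0, 0]], charge=0.0)
        grid = build_grid(st)
        surf = extract_surface(grid)
        compute_electrostatics(surf, st)
        np.testing.assert_array_equal(surf.electrostatic, 0.0)

    def test_constant_dx_map_interpolates_to_constant(self, tmp_path):
        from gridData import Grid

        surf = make_surface_from_indices([[0, 0, 0], [1, 1, 1]])
        g = Grid(
            np.full((8, 8, 8), 2.5),
            origin=surf.points.min(0) - 2.0,
            delta=[1.0, 1.0, 1.0],
        )
        path = tmp_path / "const.dx"
        g.export(str(path), file_format="dx")
        compute_electrostatics(surf, backend="dx_map", map_path=path)
        np.testing.assert_allclose(surf.electrostatic, 2.5, atol=1e-9)

    def test_dx_map_requires_path_and_coverage(self, tmp_path):
        surf = make_surface_from_indices([[0, 0, 0]])
        with pytest.raises(ValueError, match="map_path"):
            compute_electrostatics(surf, backend="dx_map")


def test_fields_invariant_under_axis_aligned_rotation():
    """90° rotations are exact on the grid: field multisets must agree."""
    rng = np.random.default_rng(3)
    pos = rng.uniform(-4, 4, size=(10, 3))
    logp = rng.uniform(-1, 1, size=10)
    charge = rng.uniform(-0.5, 0.5, size=10)
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])

    def fields(positions):
        st = synthetic_structure(positions, logp=logp, charge=charge)
        grid = build_grid(st)
        surf = extract_surface(grid)
        compute_mhp(surf, st)
        compute_electrostatics(surf, st)
        assign_hbond(surf, st)
        compute_visibility(surf)
        return surf

    a = fields(pos)
    b = fields(pos @ Rz.T)
    assert len(a) == len(b)
    np.testing.assert_allclose(np.sort(a.mhp), np.sort(b.mhp), atol=1e-9)
    np.testing.assert_allclose(
        np.sort(a.electrostatic), np.sort(b.electrostatic), atol=1e-9
    )
    # ray directions are a fixed global lattice, not 90°-symmetric, so
    # visibility is invariant only up to direction-sampling noise
    dv = np.sort(a.visibility) - np.sort(b.visibility)
    assert np.abs(dv).max() <= 0.05
    assert np.abs(dv).mean() <= 0.01
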