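"""Membrane/nuclear distances, shell volumes and normalized profiles."""

import numpy as np
import pytest

import granuleloc as g
from granuleloc.spatial_enrichment import densify_polylines


def _cube_annotation(side=30.0, spacing=(1.0, 1.0, 1.0), membrane_face=True):
    """Cubic embryo of the given side (µm) with an optional membrane on the
    x=0 face only."""
    nz = int(side / spacing[0]) + 1
    square = np.array([[0.0, 0.0], [0.0, side], [side, side], [side, 0.0]])
    outline = {z: square for z in range(nz)}
    membranes = {}
    if membrane_face:
        membranes = {z: [np.array([[0.0, 0.0], [side, 0.0]])] for z in range(nz)}
    return g.EmbryoAnnotation(
        spacing=spacing, outline=outline, membranes=membranes, included_slices=(0, nz - 1)
    )


class TestMembraneDistance:
    def test_molecule_on_membrane_vertex_is_zero(self):
        ann = _cube_annotation()
        d, _ = g.membrane_distance(np.array([[15.0, 0.0, 0.0]]), ann)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_center_of_cube_with_single_face_membrane(self):
        """Membrane on one face only: the center is 15 µm away."""
        ann = _cube_annotation(side=30.0)
        d, _ = g.membrane_distance(np.array([[15.0, 15.0, 15.0]]), ann)
        assert d[0] == pytest.approx(15.0, abs=1e-6)

    def test_matches_bruteforce_nearest_point(self, desk_geometry, rng):
        cfg, ann = desk_geometry
        mols = g.sample_molecules(g.desk_config(seed=5, n_molecules=100))
        d, _ = g.membrane_distance(mols.positions, ann)
        cloud = densify_polylines(ann)
        kept = ann.slice_in_range(np.round(mols.positions[:, 0] / cfg.spacing[0]).astype(int))
        brute = np.array(
            [np.min(np.linalg.norm(cloud - p, axis=1)) for p in mols.positions[kept]]
        )
        assert np.allclose(d, brute, atol=1e-6)

    def test_excluded_slices_dropped_and_counted(self):
        ann = _cube_annotation()
        ann.included_slices = (5, 25)
        mols = np.array([[1.0, 15.0, 15.0], [15.0, 15.0, 15.0]])
        d, n_dropped = g.membrane_distance(mols, ann)
        assert len(d) == 1 and n_dropped == 1

    def test_no_membrane_annotation_errors(self):
        ann = _cube_annotation(membrane_face=False)
        ann.outline = {}
        with pytest.raises(ValueError):
            g.membrane_distance(np.array([[1.0, 1.0, 1.0]]), ann)


def _spherical_nucleus_annotation(radius=5.0, spacing=(0.2, 0.2, 0.2), extent=16.0):
    shape = tuple(int(extent / s) + 1 for s in spacing)
    c = extent / 2
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing[0],
        np.arange(shape[1]) * spacing[1],
        np.arange(shape[2]) * spacing[2],
        indexing="ij",
    )
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    square = np.array([[0.2, 0.2], [0.2, extent - 0.2], [extent - 0.2, extent - 0.2], [extent - 0.2, 0.2]])
    outline = {z: square for z in range(shape[0])}
    return (
        g.EmbryoAnnotation(
            spacing=spacing,
            outline=outline,
            nuclear_mask=mask,
            included_slices=(0, shape[0] - 1),
        ),
        c,
    )


class TestNuclearDistance:
    def test_centroid_of_spherical_nucleus(self):
        ann, c = _spherical_nucleus_annotation(radius=5.0)
        d, _ = g.nuclear_distance(np.array([[c, c, c]]), ann)
        assert d[0] == pytest.approx(-5.0, abs=0.3)

    def test_boundary_molecule_is_zero(self):
        ann, c = _spherical_nucleus_annotation(radius=5.0)
        d, _ = g.nuclear_distance(np.array([[c, c, c + 5.0]]), ann)
        half_diag = 0.5 * np.linalg.norm(ann.spacing)
        assert abs(d[0]) <= half_diag + 1e-9

    def test_sign_convention_inside_negative(self):
        ann, c = _spherical_nucleus_annotation(radius=5.0)
        d, _ = g.nuclear_distance(np.array([[c, c, c + 2.0], [c, c, c + 7.0]]), ann)
        assert d[0] < 0 < d[1]

    def test_matches_bruteforce_over_boundary_voxels(self, rng):
        ann, c = _spherical_nucleus_annotation(radius=4.0, spacing=(0.4, 0.4, 0.4))
        from scipy import ndimage

        mask = ann.nuclear_mask
        surface = mask & ~ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1), border_value=0)
        surf_um = np.argwhere(surface) * np.array(ann.spacing)
        mols = rng.uniform(2.0, 14.0, (50, 3))
        d, _ = g.nuclear_distance(mols, ann)
        brute_abs = np.array([np.min(np.linalg.norm(surf_um - p, axis=1)) for p in mols])
        voxel_diag = np.linalg.norm(ann.spacing)
        assert np.all(np.abs(np.abs(d) - brute_abs) <= voxel_diag)

    def test_molecule_outside_outline_excluded(self):
        ann, c = _spherical_nucleus_annotation(radius=5.0)
        d, n_dropped = g.nuclear_distance(np.array([[c, 0.05, 0.05]]), ann)
        assert len(d) == 0 and n_dropped == 1


class TestShellVolumes:
    def test_spherical_embryo_concentric_ratio(self):
        """Bins [0,10) vs [10,20) µm from the surface of a 20 µm sphere
        have the analytic 7:1 volume ratio."""
        cfg = g.SimulationConfig(half_axes=(20.0, 20.0, 20.0), spacing=(0.25, 0.25, 0.25), n_nuclei=0)
        ann = g.make_geometry(cfg)
        vols = g.shell_volumes(ann, np.array([0.0, 10.0, 20.0]), "membrane", shape=cfg.shape)
        assert vols[1] > 0
        ratio = vols[0] / vols[1]
        assert ratio == pytest.approx(7.0, rel=0.02)

    def test_bin_beyond_embryo_has_zero_volume(self, desk_geometry):
        cfg, ann = desk_geometry
        vols = g.shell_volumes(ann, np.array([0.0, 10.0, 50.0, 100.0]), "membrane", shape=cfg.shape)
        assert vols[-1] == 0.0

    def test_voxel_size_convergence(self):
        vols = {}
        for i, sp in enumerate([(0.4, 0.4, 0.4), (0.2, 0.2, 0.2)]):
            cfg = g.SimulationConfig(half_axes=(10.0, 10.0, 10.0), spacing=sp, n_nuclei=0)
            ann = g.make_geometry(cfg)
            vols[i] = g.shell_volumes(ann, np.array([0.0, 5.0, 10.0]), "membrane", shape=cfg.shape)
        assert np.all(np.abs(vols[1] - vols[0]) / vols[0] < 0.02)


class TestRadialProfile:
    def test_all_molecules_in_first_bin_closed_form(self):
        edges = np.array([0.0, 10.0, 20.0])
        volumes = np.array([300.0, 700.0])
        prof = g.radial_profile(np.full(50, 2.0), volumes, edges)
        assert prof.normalized[0] == pytest.approx(1000.0 / 300.0)
        assert prof.normalized[1] == 0.0

    def test_duplication_invariance(self, rng):
        edges = np.array([0.0, 5.0, 10.0, 15.0])
        volumes = np.array([100.0, 200.0, 50.0])
        d = rng.uniform(0, 15, 200)
        a = g.radial_profile(d, volumes, edges).normalized
        b = g.radial_profile(np.concatenate([d, d]), volumes, edges).normalized
        assert np.allclose(a, b)

    def test_volume_weighted_mean_is_one(self, rng):
        for _ in range(10):
            edges = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
            volumes = rng.uniform(10, 500, 4)
            d = rng.uniform(0, 12, 300)
            prof = g.radial_profile(d, volumes, edges)
            weighted = np.nansum(prof.normalized * prof.shell_volumes) / prof.shell_volumes.sum()
            assert weighted == pytest.approx(1.0, abs=1e-12)

    def test_normalization_invariants_hold_for_arbitrary_inputs(self):
        """Property: for any distances and positive volumes, the
        volume-weighted mean of the normalized profile is exactly 1 and
        the profile is invariant under count duplication."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        edges = np.array([0.0, 2.0, 5.0, 9.0])

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            dists=st.lists(st.floats(0.0, 8.99), min_size=1, max_size=60),
            vols=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=3),
        )
        def check(dists, vols):
            volumes = np.array(vols)
            prof = g.radial_profile(np.array(dists), volumes, edges)
            weighted = np.nansum(prof.normalized * volumes) / volumes.sum()
            assert weighted == pytest.approx(1.0, abs=1e-9)
            doubled = g.radial_profile(np.repeat(dists, 2), volumes, edges)
            assert np.allclose(doubled.normalized, prof.normalized, equal_nan=True)

        check()

    def test_zero_volume_bin_reported_missing(self):
        edges = np.array([0.0, 5.0, 10.0])
        prof = g.radial_profile(np.array([2.0, 3.0]), np.array([100.0, 0.0]), edges)
        assert np.isnan(prof.normalized[1])

    def test_all_zero_volumes_error(self):
        with pytest.raises(ValueError):
            g.radial_profile(np.array([1.0]), np.array([0.0, 0.0]), np.array([0.0, 1.0, 2.0]))


class TestUniformNull:
    def test_uniform_profile_near_one_and_rootn_shrink(self, desk_geometry):
        """Uniform placement scores ~1 per bin, with the max deviation
        shrinking roughly as n^{-1/2}."""
        cfg, ann = desk_geometry
        vols = g.shell_volumes(ann, np.arange(0.0, 9.0, 3.0), "membrane", shape=cfg.shape)
        devs = {}
        for n in (1_000, 10_000, 100_000):
            mols = g.sample_molecules(g.desk_config(seed=17, n_molecules=n))
            d, _ = g.membrane_distance(mols.positions, ann)
            prof = g.radial_profile(d, vols, np.arange(0.0, 9.0, 3.0))
            devs[n] = np.nanmax(np.abs(prof.normalized - 1.0))
        assert devs[1_000] > devs[100_000]
        assert devs[100_000] < 0.05

    def test_membrane_enrichment_ratio_recovered(self):
        """Generated in-shell:out density ratio ρ is measured within 10%."""
        edges = np.array([0.0, 3.0, 20.0])
        for rho in (1.0, 2.0, 4.0):
            cfg = g.desk_config(
                seed=23,
                n_molecules=10_000,
                model=g.MoleculeModel(kind="membrane_enriched", rho=rho, shell_width=3.0),
            )
            ann = g.make_geometry(cfg)
            mols = g.sample_molecules(cfg, ann)
            d, _ = g.membrane_distance(mols.positions, ann)
            vols = g.shell_volumes(ann, edges, "membrane", shape=cfg.shape)
            prof = g.radial_profile(d, vols, edges)
            measured = prof.normalized[0] / prof.normalized[1]
            assert measured == pytest.approx(rho, rel=0.10)
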