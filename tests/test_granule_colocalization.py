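"""Granule blob detection, cluster hulls and 3D overlap statistics."""

import numpy as np
import pytest

import granuleloc as g
from granuleloc.granule_colocalization import (
    ClusterVolume,
    _dist_point_to_hull,
    sphere_hull_overlap,
)

SPACING = (0.2, 0.1, 0.1)


def _sphere_stack(centers, radius, shape=(60, 120, 120), amplitude=120.0, background=10.0, snr=None, seed=0):
    rng = np.random.default_rng(seed)
    vox = np.full(shape, background)
    dz, dy, dx = SPACING
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * dz, np.arange(shape[1]) * dy, np.arange(shape[2]) * dx, indexing="ij"
    )
    for c in np.atleast_2d(centers):
        vox += amplitude * (((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius**2)
    if snr is not None:
        sigma = amplitude / snr
        vox = vox + rng.normal(0, sigma, shape)
    return g.ImageStack(np.clip(vox, 0, None), SPACING)


class TestDetectGranules:
    def test_blank_image_gives_no_granules(self):
        stack = g.ImageStack(np.full((20, 40, 40), 7.0), SPACING)
        assert g.detect_granules(stack, threshold=0.05) == []

    def test_single_sphere_recovered(self):
        center = np.array([6.0, 6.0, 6.0])
        stack = _sphere_stack(center, radius=1.0, snr=10)
        granules = g.detect_granules(stack, threshold=0.1)
        assert len(granules) == 1
        gr = granules[0]
        assert np.all(np.abs(np.array(gr.center) - center) <= np.array(SPACING) * 2)
        assert gr.radius == pytest.approx(1.0, rel=0.3)

    def test_two_separated_spheres(self):
        centers = np.array([[6.0, 6.0, 2.5], [6.0, 6.0, 10.5]])
        stack = _sphere_stack(centers, radius=0.8, snr=10)
        granules = g.detect_granules(stack, threshold=0.1)
        assert len(granules) == 2

    def test_empty_scale_range_rejected(self):
        stack = g.ImageStack(np.zeros((20, 40, 40)), SPACING)
        with pytest.raises(ValueError, match="scale range"):
            g.detect_granules(stack, scale_range=(1.0, 0.5), threshold=0.1)


class TestClusterHull:
    def test_regular_tetrahedron_volume(self):
        """Edge-2 regular tetrahedron has volume 2³/(6√2) ≈ 0.9428 µm³."""
        a = 2.0
        pts = (
            np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
            * a
            / (2 * np.sqrt(2))
        )
        vol = g.cluster_hull(pts)
        assert not vol.degenerate
        assert vol.volume == pytest.approx(a**3 / (6 * np.sqrt(2)), rel=1e-9)

    def test_two_point_cluster_falls_back_to_balls(self):
        vol = g.cluster_hull(np.array([[0, 0, 0], [0, 0, 0.4]]), eps=0.75)
        assert vol.degenerate
        assert vol.ball_radius == pytest.approx(0.375)

    def test_coplanar_points_fall_back(self):
        pts = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 1], [0, 0.5, 0.5]], dtype=float)
        assert g.cluster_hull(pts).degenerate

    def test_hull_volume_matches_facet_enumeration(self, rng):
        """Brute-force oracle: every point triple whose plane has all other
        points on one side is a hull facet; summing signed tetrahedra from
        the centroid gives the hull volume."""
        pts = rng.random((12, 3)) * 4
        centroid = pts.mean(axis=0)
        vol_brute = 0.0
        n = len(pts)
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
                    if np.linalg.norm(normal) < 1e-12:
                        continue
                    side = (pts - pts[i]) @ normal
                    if np.all(side <= 1e-9) or np.all(side >= -1e-9):
                        vol_brute += abs((pts[i] - centroid) @ np.cross(pts[j] - centroid, pts[k] - centroid)) / 6
        assert g.cluster_hull(pts).volume == pytest.approx(vol_brute, rel=1e-6)


class TestSphereHullOverlap:
    def test_cluster_inside_granule_overlaps(self, rng):
        pts = rng.normal([5, 5, 5], 0.2, (6, 3))
        vol = g.cluster_hull(pts)
        assert sphere_hull_overlap(vol, g.Granule((5, 5, 5), 2.0, 1.0))

    def test_distant_granule_no_overlap(self, rng):
        pts = rng.normal([5, 5, 5], 0.2, (6, 3))
        vol = g.cluster_hull(pts)
        # surface gap of ~5 µm
        assert not sphere_hull_overlap(vol, g.Granule((5, 5, 12), 1.0, 1.0))

    def test_agrees_with_dense_sampling_oracle(self, rng):
        """Exact sphere-hull test vs rejection-sampled hull points on 100
        random configurations (borderline cases within sampling resolution
        are skipped)."""
        n_checked = 0
        for _ in range(100):
            pts = rng.uniform(0, 4, (int(rng.integers(4, 12)), 3))
            vol = g.cluster_hull(pts)
            if vol.degenerate:
                continue
            center = rng.uniform(-1, 5, 3)
            radius = float(rng.uniform(0.3, 1.5))
            d = _dist_point_to_hull(center, vol)
            if abs(d - radius) < 0.02:
                continue  # borderline beyond oracle resolution
            # oracle: sample points inside the hull, test sphere membership
            eqs = vol.hull.equations
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            samples = lo + (hi - lo) * rng.random((100_000, 3))
            inside = np.all(samples @ eqs[:, :3].T + eqs[:, 3] <= 0, axis=1)
            hull_pts = np.vstack([samples[inside], pts])
            oracle = bool(np.any(np.linalg.norm(hull_pts - center, axis=1) <= radius))
            assert sphere_hull_overlap(vol, g.Granule(tuple(center), radius, 1.0)) == oracle
            n_checked += 1
        assert n_checked >= 60

    def test_pct_monotone_under_radius_inflation(self, rng):
        pts = [rng.normal(c, 0.2, (5, 3)) for c in rng.uniform(1, 9, (8, 3))]
        mols = np.vstack(pts)
        cs = g.dbscan_cluster(mols, eps=0.75, min_pts=2)
        centers = rng.uniform(1, 9, (6, 3))
        pcts = []
        for scale in (0.3, 0.8, 1.5, 3.0):
            granules = [g.Granule(tuple(c), scale, 1.0) for c in centers]
            pcts.append(g.colocalize(cs, granules).pct_clusters_on_granules)
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))

    def test_subsampled_cluster_detected_no_more_often(self, rng):
        """Containment monotonicity: a subset of a cluster's points can
        never overlap a granule that the full cluster misses."""
        for _ in range(20):
            pts = rng.uniform(0, 3, (10, 3))
            sub = pts[rng.choice(10, 5, replace=False)]
            granule = g.Granule(tuple(rng.uniform(-1, 4, 3)), float(rng.uniform(0.2, 1.0)), 1.0)
            full = sphere_hull_overlap(g.cluster_hull(pts), granule)
            subset = sphere_hull_overlap(g.cluster_hull(sub), granule)
            assert full or not subset


class TestColocalize:
    def test_counts_and_percentages_consistent(self, rng):
        cl = [rng.normal(c, 0.15, (4, 3)) for c in [[2, 2, 2], [2, 2, 8], [8, 8, 8]]]
        cs = g.dbscan_cluster(np.vstack(cl), eps=0.75, min_pts=2)
        granules = [g.Granule((2, 2, 2), 1.0, 1.0), g.Granule((20, 20, 20), 1.0, 1.0)]
        stats = g.colocalize(cs, granules)
        assert stats.n_clusters == 3 and stats.n_granules == 2
        assert stats.n_overlapping_clusters == 1
        assert stats.pct_clusters_on_granules == pytest.approx(100 / 3)
        assert stats.n_granules_with_cluster == 1
        assert stats.pct_granules_with_cluster == pytest.approx(50.0)

    def test_seeded_association_fraction_recovered(self):
        """Clusters seeded on granules at fraction f=0.6 are measured
        within the binomial 95% CI."""
        cfg = g.desk_config(
            seed=31,
            n_molecules=200,
            model=g.MoleculeModel(
                kind="granule_associated",
                n_clusters=40,
                cluster_size=5,
                cluster_sigma=0.15,
                n_granules=30,  # >= f·C so each seeded cluster gets its own granule
                granule_radius=0.8,
                association_fraction=0.6,
            ),
        )
        truth = g.sample_molecules(cfg)
        cs = g.dbscan_cluster(truth.positions, eps=0.75, min_pts=2)
        granules = [
            g.Granule((r.z_um, r.y_um, r.x_um), r.radius_um, 1.0)
            for r in truth.granules.itertuples()
        ]
        stats = g.colocalize(cs, granules)
        ci_half = 1.96 * np.sqrt(0.6 * 0.4 / 40) * 100
        assert abs(stats.pct_clusters_on_granules - 60.0) <= ci_half


class TestColocCompare:
    def _stats(self, pcts):
        return [
            g.ColocStats(10, 10, int(p / 10), p, 5, 50.0) for p in pcts
        ]

    def test_identical_distributions_not_significant(self, rng):
        a = self._stats(rng.normal(50, 5, 10))
        out = g.coloc_compare({"20C": a, "30C": a})
        assert out["welch_p"] > 0.5

    def test_shifted_distributions_significant(self, rng):
        a = self._stats(rng.normal(30, 5, 10))
        b = self._stats(rng.normal(60, 5, 10))
        out = g.coloc_compare({"20C": a, "30C": b})
        assert out["welch_p"] < 0.001

    def test_empty_condition_errors(self):
        with pytest.raises(ValueError):
            g.coloc_compare({"a": [], "b": self._stats([1, 2])})

    def test_single_embryo_condition_omits_p(self):
        out = g.coloc_compare({"a": self._stats([50.0]), "b": self._stats([60.0, 70.0])})
        assert "welch_p" not in out
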