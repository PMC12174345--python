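"""Patch surfaces, boundary-corrected RDF against independent geometric
oracles, distance-context profiles, and the heterogeneity resampling."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Point

import poremap as pm
from poremap.spatial import DEFAULT_CONTEXT_BINS_A, _annulus_patch_areas


class TestPatchSurface:
    def test_single_point_disk_area(self):
        patch = pm.compute_patch_surface(pm.ParticleSet([[10, 10]]), 5.0, "convex")
        assert patch.area == pytest.approx(math.pi * 25, rel=0.01)

    def test_collinear_capsule_area(self):
        """Three collinear points spaced s, dilated by R, form a stadium
        of area pi R^2 + 4 s R (closed form)."""
        s, R = 6.0, 5.0
        pts = pm.ParticleSet([[10, 10], [10 + s, 10], [10 + 2 * s, 10]])
        patch = pm.compute_patch_surface(pts, R, "convex")
        assert patch.area == pytest.approx(math.pi * R * R + 4 * s * R, rel=0.01)

    def test_concave_at_most_convex(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 40)
            pts = pm.ParticleSet(rng.uniform(0, 60, (n, 2)))
            concave = pm.compute_patch_surface(pts, 3.0, "concave")
            convex = pm.compute_patch_surface(pts, 3.0, "convex")
            assert concave.area <= convex.area * 1.001

    def test_particles_inside_patch(self, glassy300):
        patch = pm.compute_patch_surface(glassy300, 5.0, "concave")
        assert patch.mode == "concave"
        assert patch.contains(glassy300.positions).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pm.compute_patch_surface(pm.ParticleSet(np.empty((0, 2))), 5.0)
        with pytest.raises(ValueError):
            pm.compute_patch_surface(pm.ParticleSet([[0, 0]]), -1.0)


class TestRDF:
    def test_two_point_support(self):
        d = 7.3
        ps = pm.ParticleSet([[30, 30], [30 + d, 30]])
        patch = pm.compute_patch_surface(ps, 15.0, "convex")
        rdf = pm.compute_rdf(ps, patch, dr=0.5, r_max=15.0)
        nz = np.nonzero(rdf.g)[0]
        assert len(nz) == 1
        assert abs(rdf.r[nz[0]] - d) <= 0.25

    def test_brute_force_equivalence(self):
        """Library g(r) matches a from-scratch double loop whose ring∩patch
        areas come from exact shapely geometry instead of the raster."""
        rng = np.random.default_rng(4)
        ps = pm.ParticleSet(rng.uniform(0, 40, (60, 2)))
        patch = pm.compute_patch_surface(ps, 3.0, "convex")
        dr, r_max = 1.0, 12.0
        rdf = pm.compute_rdf(ps, patch, dr=dr, r_max=r_max)

        edges = np.arange(0, r_max + dr / 2, dr)
        rho = ps.n / patch.area
        g_ref = np.zeros(len(edges) - 1)
        n_ref = np.zeros(len(edges) - 1)
        for i in range(ps.n):
            center = Point(ps.positions[i])
            for k in range(len(edges) - 1):
                ring = center.buffer(edges[k + 1], quad_segs=64).difference(
                    center.buffer(edges[k], quad_segs=64)
                )
                area = ring.intersection(patch.polygon).area
                if area <= 0:
                    continue
                cnt = 0
                for j in range(ps.n):
                    if j == i:
                        continue
                    dij = math.hypot(*(ps.positions[j] - ps.positions[i]))
                    if edges[k] <= dij < edges[k + 1]:
                        cnt += 1
                g_ref[k] += cnt / area
                n_ref[k] += 1
        g_ref = np.where(n_ref > 0, g_ref / np.maximum(n_ref, 1) / rho, 0.0)
        np.testing.assert_allclose(rdf.g, g_ref, rtol=0.12, atol=0.05)

    def test_boundary_correction_removes_edge_bias(
        self, poisson_rdf_corrected, poisson_rdf_full_ring
    ):
        """On a CSR pattern the ring∩patch normalization keeps mean g at 1
        where full-ring normalization is biased low by edge losses."""
        sel = (poisson_rdf_corrected.r >= 10) & (poisson_rdf_corrected.r <= 40)
        err_corrected = abs(poisson_rdf_corrected.g[sel].mean() - 1.0)
        err_full = abs(poisson_rdf_full_ring.g[sel].mean() - 1.0)
        assert err_corrected < err_full

    def test_effective_area_bounded_by_full_ring(self, poisson_rdf_corrected):
        # raster counting scatters by about a pixel row per annulus, so the
        # bound carries a two-pixel absolute slack (0.5 nm^2 at 0.5 nm/px)
        full = 2 * math.pi * poisson_rdf_corrected.r * poisson_rdf_corrected.dr
        assert np.all(poisson_rdf_corrected.effective_area <= full + 0.5)

    def test_interior_particle_sees_full_rings(self):
        """Deep inside the patch the ring∩patch area equals the full ring:
        per-bin within raster tolerance once rings span many pixels, and
        exactly in cumulative area."""
        ps = pm.ParticleSet([[50, 50]])
        patch = pm.compute_patch_surface(ps, 30.0, "convex")
        edges = np.arange(0.0, 11.0, 1.0)
        areas = _annulus_patch_areas(ps.positions, patch, edges)
        centers = edges[:-1] + 0.5
        full = 2 * math.pi * centers * 1.0
        sel = centers >= 2.0
        np.testing.assert_allclose(areas[0][sel], full[sel], rtol=0.1)
        assert areas[0].sum() == pytest.approx(math.pi * 10.0**2, rel=0.01)

    def test_glassy_second_shell(self, glassy_rdf):
        """Dense glassy packings show a second coordination shell near
        twice the contact spacing."""
        r, g = glassy_rdf.r, glassy_rdf.g
        sel = (r >= 9.5) & (r <= 12.5)
        idx = np.where(sel)[0]
        has_local_max = any(
            g[k] > g[k - 1] and g[k] >= g[k + 1] and g[k] > 1.0
            for k in idx[1:-1]
        )
        assert has_local_max

    def test_degenerate_input_rejected(self, glassy300):
        patch = pm.compute_patch_surface(glassy300, 5.0)
        with pytest.raises(ValueError):
            pm.compute_rdf(pm.ParticleSet([[0, 0]]), patch)
        with pytest.raises(ValueError):
            pm.compute_rdf(glassy300, patch, dr=-0.1)


class TestShellOccurrences:
    def test_single_pair(self):
        ps = pm.ParticleSet([[0, 0], [5.2, 0]])
        prof = pm.shell_occurrences(ps)
        expect = {"<50": 0.0, "[50,56)": 1.0, "[56,62)": 0.0,
                  "[62,68)": 0.0, "[68,80)": 0.0, "[80,86)": 0.0}
        assert prof.as_dict() == expect
        # the three lipid-separated classes are each one lipid layer (6 A) wide
        widths = np.diff(DEFAULT_CONTEXT_BINS_A)[:3]
        assert tuple(widths) == (6.0, 6.0, 6.0)

    def test_counting_conservation(self):
        """Class occurrences plus the beyond-range remainder account for
        every neighbour pair exactly (brute-force pair count)."""
        rng = np.random.default_rng(2)
        ps = pm.ParticleSet(rng.uniform(0, 30, (40, 2)))
        prof = pm.shell_occurrences(ps)
        d = ps.pairwise_distances()
        within = 2 * np.count_nonzero(d < 8.6) / ps.n
        beyond = 2 * np.count_nonzero(d >= 8.6) / ps.n
        assert prof.occurrences.sum() == pytest.approx(within)
        assert within + beyond == pytest.approx(ps.n - 1)

    def test_unsorted_bins_rejected(self):
        ps = pm.ParticleSet([[0, 0], [5, 0]])
        with pytest.raises(ValueError):
            pm.shell_occurrences(ps, class_bins_a=(56, 50))


class TestPatchHeterogeneity:
    def test_interior_lattice_is_homogeneous(self):
        """On a perfect lattice, patches centered on interior particles
        all see the same neighbourhood: per-patch SD is zero."""
        xx, yy = np.meshgrid(np.arange(20) * 6.0, np.arange(20) * 6.0)
        ps = pm.ParticleSet(np.column_stack([xx.ravel(), yy.ravel()]))
        interior = np.where(
            (ps.positions[:, 0] >= 18) & (ps.positions[:, 0] <= 96)
            & (ps.positions[:, 1] >= 18) & (ps.positions[:, 1] <= 96)
        )[0]
        ens = pm.patch_heterogeneity(ps, n_repeats=30, seed=1, candidates=interior)
        assert np.all(ens.sd < 1e-12)

    def test_determinism(self, glassy300):
        a = pm.patch_heterogeneity(glassy300, n_repeats=20, seed=9)
        b = pm.patch_heterogeneity(glassy300, n_repeats=20, seed=9)
        np.testing.assert_array_equal(a.profiles, b.profiles)

    def test_ensemble_consistent_with_whole_structure(self, glassy300):
        """Local-patch means stay within 2 SD of the whole-structure
        profile on a statistically homogeneous glassy assembly."""
        ens = pm.patch_heterogeneity(glassy300, n_repeats=100, seed=5)
        whole = pm.shell_occurrences(glassy300)
        sd = np.maximum(ens.sd, 1e-9)
        assert np.all(np.abs(ens.mean - whole.occurrences) <= 2 * sd)

    def test_small_structures_sample_without_replacement(self):
        rng = np.random.default_rng(0)
        ps = pm.ParticleSet(rng.uniform(0, 50, (37, 2)))
        ens = pm.patch_heterogeneity(ps, n_repeats=100, seed=0)
        assert len(ens.profiles) == 37
        assert len(set(ens.centers.tolist())) == 37

    def test_bad_arguments_rejected(self, glassy300):
        with pytest.raises(ValueError):
            pm.patch_heterogeneity(glassy300, patch_radius=-1)
        with pytest.raises(ValueError):
            pm.patch_heterogeneity(glassy300, n_repeats=0)
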