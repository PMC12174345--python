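"""Generator contracts: hard-core packings, uniformity of the Poisson
control, topography rendering signatures, and template geometry."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import chisquare

import poremap as pm
from poremap.synthetic import PackingError


class TestPatterns:
    def test_empty_pattern(self):
        cfg = pm.GeneratorConfig(kind="poisson", n_particles=0)
        ps = pm.generate_pattern(cfg, pm.Region(50, 50))
        assert ps.n == 0

    def test_two_particle_hard_core(self):
        cfg = pm.GeneratorConfig(kind="glassy", n_particles=2, spacing=5.5, jitter=0.0, seed=0)
        ps = pm.generate_pattern(cfg, pm.Region(200, 200))
        assert pdist(ps.positions).min() >= 5.5

    def test_glassy_mean_nn_spacing(self, glassy300):
        """Dense glassy packing has mean NN distance near the contact
        distance (pore diameter + lipid annulus), verified brute-force."""
        d = np.linalg.norm(
            glassy300.positions[:, None, :] - glassy300.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert 5.2 <= nn.mean() <= 5.9

    @pytest.mark.parametrize("kind", ["glassy", "filament", "dense"])
    @pytest.mark.parametrize("seed", [0, 11])
    def test_hard_core_respected(self, kind, seed):
        cfg = pm.GeneratorConfig(kind=kind, n_particles=60, spacing=5.5, jitter=0.3, seed=seed)
        ps = pm.generate_pattern(cfg, pm.Region(90, 90))
        assert ps.n == 60
        assert pdist(ps.positions).min() >= 5.5 - 0.3 - 1e-9

    @pytest.mark.parametrize("kind", ["glassy", "poisson", "filament", "dense"])
    def test_determinism(self, kind):
        cfg = pm.GeneratorConfig(kind=kind, n_particles=40, seed=5)
        a = pm.generate_pattern(cfg, pm.Region(80, 80))
        b = pm.generate_pattern(cfg, pm.Region(80, 80))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_poisson_quadrat_uniformity(self, poisson2000):
        """CSR control passes a chi-square test on 10x10 quadrat counts."""
        counts, _, _ = np.histogram2d(
            poisson2000.positions[:, 0], poisson2000.positions[:, 1],
            bins=10, range=[[0, 300], [0, 300]],
        )
        stat, p = chisquare(counts.ravel())
        assert p > 0.01

    def test_infeasible_density_raises(self):
        cfg = pm.GeneratorConfig(kind="glassy", n_particles=100, spacing=5.5, seed=0)
        with pytest.raises(PackingError):
            pm.generate_pattern(cfg, pm.Region(20, 20))

    def test_dense_pattern_is_aggregated(self):
        cfg = pm.GeneratorConfig(kind="dense", n_particles=80, spacing=5.0, seed=2)
        ps = pm.generate_pattern(cfg, pm.Region(150, 150))
        centroid = ps.positions.mean(axis=0)
        spread = np.linalg.norm(ps.positions - centroid, axis=1).max()
        assert spread < 40  # compact aggregate, not spread over the region

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            pm.GeneratorConfig(kind="hexagonal")
        with pytest.raises(ValueError):
            pm.GeneratorConfig(spacing=-1)


class TestTopographyRendering:
    def test_flat_membrane_without_particles(self):
        ps = pm.ParticleSet(np.empty((0, 2)), region=pm.Region(20, 20))
        img = pm.render_topography(ps, noise_sd=0.0)
        assert np.allclose(img.heights, img.heights.flat[0])

    def test_single_pore_depression_width(self):
        """A rendered pore reads back as a ~4.5 nm wide depression at
        half depth, the topographic signature of the open channel."""
        ps = pm.ParticleSet([[10.0, 10.0]], region=pm.Region(20, 20))
        img = pm.render_topography(ps, pixel_size=0.25, noise_sd=0.0)
        s, h = pm.extract_profile(img, (2, 10), (18, 10))
        assert h.min() < -1.0  # a real depression
        width = pm.full_width_at_half_depth(s, h)
        assert abs(width - 4.5) <= 0.25

    def test_nanobead_renders_as_peak(self):
        """With a bound nanobead the pore signature flips from a hole to
        a protrusion above the membrane baseline."""
        ps = pm.ParticleSet([[10.0, 10.0]], region=pm.Region(20, 20))
        img = pm.render_topography(ps, pixel_size=0.25, noise_sd=0.0, bead_fraction=1.0)
        s, h = pm.extract_profile(img, (2, 10), (18, 10))
        baseline = np.median(np.concatenate([h[:10], h[-10:]]))
        assert h.max() > baseline + 1.0
        assert h.min() >= baseline - 1e-9  # no hole left

    def test_coarse_pixels_rejected(self):
        ps = pm.ParticleSet([[10.0, 10.0]], region=pm.Region(20, 20))
        with pytest.raises(ValueError, match="coarse"):
            pm.render_topography(ps, pixel_size=2.0)

    def test_render_determinism(self):
        ps = pm.ParticleSet([[5, 5], [12, 13]], region=pm.Region(20, 20))
        a = pm.render_topography(ps, noise_sd=0.1, bead_fraction=0.5, seed=9)
        b = pm.render_topography(ps, noise_sd=0.1, bead_fraction=0.5, seed=9)
        np.testing.assert_array_equal(a.heights, b.heights)


class TestTemplates:
    def test_protein_only_template(self):
        tpl = pm.generate_template(n_first_shell_per_leaflet=0, fill=False)
        assert tpl.n_lipids == 0
        assert len(tpl.protein_beads) > 0

    def test_default_first_shell_counts(self, default_template):
        """~20 lipids per leaflet in direct contact with the protein."""
        for leaf in ("cytosolic", "IMS"):
            n = int((default_template.first_shell & (default_template.leaflet == leaf)).sum())
            assert n == 20

    def test_template_determinism(self):
        a = pm.generate_template(seed=4)
        b = pm.generate_template(seed=4)
        np.testing.assert_array_equal(a.lipid_beads, b.lipid_beads)
        np.testing.assert_array_equal(a.species, b.species)

    def test_lipids_inside_cylinder(self, default_template):
        r = np.hypot(default_template.lipid_beads[:, 0], default_template.lipid_beads[:, 1])
        assert r.max() <= default_template.cylinder_radius + 1e-9

    def test_leaflets_partition_lipids(self, default_template):
        leaf = default_template.leaflet
        assert np.all((leaf == "cytosolic") | (leaf == "IMS"))
        assert 0 < int((leaf == "cytosolic").sum()) < default_template.n_lipids

    def test_geometric_overflow_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            pm.generate_template(n_first_shell_per_leaflet=200)
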