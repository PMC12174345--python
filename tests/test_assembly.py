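"""Assembly builder: rotation optimization against the exhaustive grid
oracle, lipid pruning semantics, first-shell counts, contact classes,
and occupancy/enrichment maps."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

import poremap as pm
from poremap.assembly import total_clash_score
from poremap import assembly as A


def rotate(beads, angle):
    c, s = math.cos(angle), math.sin(angle)
    out = beads.copy()
    out[:, 0] = c * beads[:, 0] - s * beads[:, 1]
    out[:, 1] = s * beads[:, 0] + c * beads[:, 1]
    return out


class TestBuild:
    def test_single_site_zero_clash(self, default_template):
        ps = pm.ParticleSet([[20, 20]], region=pm.Region(40, 40))
        model = pm.build_assembly(ps, [default_template], seed=1)
        assert model.n_sites == 1
        assert total_clash_score(model) == 0

    def test_two_site_rotations_match_joint_oracle(self, default_template):
        """The chosen pair of rotations reaches the global minimum of the
        clash score over the full angle x angle grid."""
        tpl = default_template
        n_rot = 32
        ps = pm.ParticleSet([[20, 20], [24, 20]], region=pm.Region(44, 40))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pm.build_assembly(ps, [tpl], n_rotations=n_rot, seed=2)
        achieved = total_clash_score(model)
        angles = np.arange(n_rot) * 2 * math.pi / n_rot
        best = None
        for a1 in angles:
            t1 = cKDTree(rotate(tpl.protein_beads, a1) + np.array([20, 20, 0]))
            for a2 in angles:
                p2 = rotate(tpl.protein_beads, a2) + np.array([24, 20, 0])
                sc = int(t1.query_ball_point(p2, model.clash_cutoff,
                                             return_length=True).sum())
                best = sc if best is None else min(best, sc)
        assert achieved == best

    def test_close_sites_warn_and_flag(self, default_template):
        ps = pm.ParticleSet([[20, 20], [23.5, 20]], region=pm.Region(43, 40))
        with pytest.warns(UserWarning, match="hard core"):
            model = pm.build_assembly(ps, [default_template], seed=0)
        assert (0, 1) in model.clashing_sites

    def test_determinism(self, default_template):
        ps = pm.ParticleSet([[10, 10], [16, 10], [13, 15]], region=pm.Region(26, 25))
        m1 = pm.build_assembly(ps, [default_template], seed=4)
        m2 = pm.build_assembly(ps, [default_template], seed=4)
        for a, b in zip(m1.instances, m2.instances):
            assert a.angle == b.angle
            np.testing.assert_array_equal(a.lipids, b.lipids)

    def test_invalid_inputs(self, default_template):
        ps = pm.ParticleSet([[5, 5]])
        with pytest.raises(ValueError):
            pm.build_assembly(ps, [])
        with pytest.raises(ValueError):
            pm.build_assembly(ps, [default_template], n_rotations=0)


class TestPruning:
    def test_disjoint_cylinders_prune_nothing(self, default_template):
        ps = pm.ParticleSet([[20, 20], [32, 20]], region=pm.Region(52, 40))
        model = pm.build_assembly(ps, [default_template], seed=3)
        pm.prune_overlapping_lipids(model)
        assert model.n_lipids_pruned == 0

    def test_pruned_count_matches_brute_force(self, default_template):
        """Pruned beads are exactly those violating the cutoff against
        other instances' proteins or earlier retained lipids (re-derived
        here with plain distance scans)."""
        ps = pm.ParticleSet([[20, 20], [26, 20]], region=pm.Region(46, 40))
        model = pm.build_assembly(ps, [default_template], seed=3)
        cutoff = A.DEFAULT_OVERLAP_CUTOFF_NM
        inst0, inst1 = model.instances

        def min_dist(points, others):
            if not len(points) or not len(others):
                return np.full(len(points), np.inf)
            return np.array(
                [np.linalg.norm(others - p, axis=1).min() for p in points]
            )

        # instance 0 lipids yield only to instance 1's protein
        drop0 = min_dist(inst0.lipids, inst1.protein) <= cutoff
        kept0 = inst0.lipids[~drop0]
        # instance 1 lipids yield to instance 0's protein and retained lipids
        drop1 = (min_dist(inst1.lipids, inst0.protein) <= cutoff) | (
            min_dist(inst1.lipids, kept0) <= cutoff
        )
        expected_pruned = int(drop0.sum() + drop1.sum())

        pm.prune_overlapping_lipids(model)
        assert model.n_lipids_pruned == expected_pruned
        assert pm.count_inter_instance_clashes(model, cutoff) == 0

    def test_idempotent_and_conserving(self, default_template):
        ps = pm.ParticleSet([[20, 20], [26, 20], [23, 25]], region=pm.Region(46, 45))
        model = pm.build_assembly(ps, [default_template], seed=6)
        n0 = model.n_lipids_initial
        pm.prune_overlapping_lipids(model)
        assert model.n_lipids_retained + model.n_lipids_pruned == n0
        retained_once = model.n_lipids_retained
        pm.prune_overlapping_lipids(model)
        assert model.n_lipids_retained == retained_once
        assert model.n_lipids_retained + model.n_lipids_pruned == n0


class TestFirstShell:
    def test_isolated_template_counts(self, default_template):
        ps = pm.ParticleSet([[20, 20]], region=pm.Region(40, 40))
        model = pm.build_assembly(ps, [default_template], seed=1)
        counts = pm.first_shell_lipids(model)
        assert counts[0] == {"cytosolic": 20, "IMS": 20}

    def test_zero_cutoff_zero_counts(self, default_template):
        ps = pm.ParticleSet([[20, 20]], region=pm.Region(40, 40))
        model = pm.build_assembly(ps, [default_template], seed=1)
        counts = pm.first_shell_lipids(model, shell_cutoff=0.0)
        assert counts[0] == {"cytosolic": 0, "IMS": 0}

    def test_matches_brute_force_scan(self, default_template):
        ps = pm.ParticleSet([[20, 20], [26.5, 20]], region=pm.Region(46, 40))
        model = pm.build_assembly(ps, [default_template], seed=2)
        pm.prune_overlapping_lipids(model)
        cutoff = A.DEFAULT_SHELL_CUTOFF_NM
        counts = pm.first_shell_lipids(model, cutoff)
        for k, inst in enumerate(model.instances):
            lip = inst.lipids[inst.retained]
            leaf = inst.leaflet[inst.retained]
            near = np.array(
                [np.linalg.norm(inst.protein - p, axis=1).min() <= cutoff for p in lip]
            )
            for leaflet in ("cytosolic", "IMS"):
                assert counts[k][leaflet] == int((near & (leaf == leaflet)).sum())


class TestContacts:
    def test_distance_class_assignment(self, default_template):
        """A 5.8 nm pair falls in the [56,62) A lipid-separated class; the
        classifier shares its boundaries with the distance-context module."""
        ps = pm.ParticleSet([[20, 20], [25.8, 20]], region=pm.Region(46, 40))
        model = pm.build_assembly(ps, [default_template], seed=1)
        pm.prune_overlapping_lipids(model)
        contacts = pm.classify_contacts(model)
        assert len(contacts) == 1
        assert contacts[0].label == "[56,62)"
        assert contacts[0].distance_a == pytest.approx(58.0)
        # lipids fill the inter-protein corridor at this separation
        assert contacts[0].mediation == "lipid-bridged"

    def test_direct_contact_class(self, default_template):
        ps = pm.ParticleSet([[20, 20], [25.1, 20]], region=pm.Region(46, 40))
        model = pm.build_assembly(ps, [default_template], seed=1)
        contacts = pm.classify_contacts(model)
        assert contacts[0].mediation == "direct"
        assert contacts[0].label == "[50,56)"


class TestOccupancy:
    def test_uniform_beads_near_unit_enrichment(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 15, (100_000, 2))
        omap = pm.compute_occupancy_map(
            xy, np.full(len(xy), "PC"), grid_resolution=1.0, extent=(0, 0, 15, 15)
        )
        e = omap.enrichment("PC")[omap.occupied]
        assert np.mean((e >= 0.9) & (e <= 1.1)) >= 0.95

    def test_quadrant_confined_species_enrichment(self):
        """A species confined to one quadrant of the occupied region is
        4-fold enriched there (closed-form area ratio)."""
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 20, (40_000, 2))
        confined = rng.uniform(0, 10, (10_000, 2))
        pos = np.vstack([bg, confined])
        species = np.array(["BG"] * len(bg) + ["X"] * len(confined))
        omap = pm.compute_occupancy_map(pos, species, grid_resolution=1.0,
                                        extent=(0, 0, 20, 20))
        quadrant = omap.enrichment("X")[:10, :10]
        assert quadrant.mean() == pytest.approx(4.0, rel=0.02)
        # conventional fold cutoffs select nested regions
        assert omap.enriched_region("X", 1.8).sum() <= omap.enriched_region("X", 1.2).sum()

    def test_counts_conserved_and_mean_enrichment_unity(self, default_template):
        ps = pm.ParticleSet([[10, 10], [16, 10]], region=pm.Region(26, 20))
        model = pm.build_assembly(ps, [default_template], seed=5)
        pm.prune_overlapping_lipids(model)
        pos, species, leaflet, _ = model.lipid_table()
        omap = pm.compute_occupancy_map(pos, species, grid_resolution=0.2)
        total = sum(h.sum() for h in omap.counts.values())
        assert total == len(pos)
        for s in omap.species:
            e = omap.enrichment(s)[omap.occupied]
            assert e.mean() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pm.compute_occupancy_map(np.empty((0, 2)), np.empty(0))
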