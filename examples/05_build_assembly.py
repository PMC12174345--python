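"""Build a coarse-grained protein-lipid assembly model at measured pore
coordinates, prune overlapping lipids, and map lipid enrichment.

Each site receives a disc-and-shell template (barrel-like protein ring,
~20 first-shell lipids per leaflet inside a 5 nm cylinder); in-plane
rotations are chosen to minimize inter-protein bead clashes; lipids of
later-placed instances yield to earlier ones.  Pair contacts are then
classified by distance and by whether lipids occupy the inter-protein
corridor.
"""

import numpy as np

import poremap as pm

particles = pm.generate_pattern(
    pm.GeneratorConfig(kind="glassy", n_particles=25, spacing=5.5, jitter=0.3, seed=4),
    pm.Region(42, 42),
)
template = pm.generate_template(seed=0)
model = pm.build_assembly(particles, [template], n_rotations=64, seed=4)
pm.prune_overlapping_lipids(model)
print(f"placed {model.n_sites} instances; lipids: {model.n_lipids_initial} initial, "
      f"{model.n_lipids_pruned} pruned, {model.n_lipids_retained} retained")
print(f"residual inter-instance bead clashes: "
      f"{pm.count_inter_instance_clashes(model, model.clash_cutoff)}")

shells = pm.first_shell_lipids(model)
mean_cyto = np.mean([c["cytosolic"] for c in shells.values()])
print(f"mean first-shell lipids per instance (cytosolic leaflet): {mean_cyto:.1f} "
      "(~20 for an isolated protein; fewer when pores share their annulus)")

contacts = pm.classify_contacts(model)
kinds = {}
for c in contacts:
    kinds[c.mediation] = kinds.get(c.mediation, 0) + 1
print(f"pair contacts within 8.6 nm: {len(contacts)} -> {kinds}")

pos, species, leaflet, _ = model.lipid_table()
sel = leaflet == "cytosolic"
omap = pm.compute_occupancy_map(pos[sel], species[sel], grid_resolution=0.2)
for s in omap.species:
    frac = omap.enriched_region(s, 1.2).sum() / max(omap.occupied.sum(), 1)
    print(f"{s}: {100 * frac:.0f}% of occupied cells above 1.2-fold enrichment")
print("\nEnrichment = local density / species mean over the occupied region;")
print("1.2- and 1.8-fold are the conventional display cutoffs.")
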