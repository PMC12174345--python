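"""Boundary-corrected radial distribution function and distance-context
profile of a dense glassy assembly.

g(r) is normalized per particle by the intersection of each ring with
the dilated-hull patch surface, so edge particles need not be discarded.
The distance-context classes translate center-to-center distances into
interaction types: clashing (<50 A), direct contact [50,56), successive
lipid-separated shells (6 A apart), and bridged/row contexts.
"""

import numpy as np

import poremap as pm

particles = pm.generate_pattern(
    pm.GeneratorConfig(kind="glassy", n_particles=300, spacing=5.5, jitter=0.3, seed=1),
    pm.Region(120, 120),
)
patch = pm.compute_patch_surface(particles, dilation_radius=5.0, mode="concave")
print(f"patch surface: {patch.area:.0f} nm^2 ({patch.mode} hull), "
      f"density rho = {particles.n / patch.area * 1e6:.0f} pores/um^2")

rdf = pm.compute_rdf(particles, patch, dr=0.2, r_max=20.0)
print(f"first g(r) peak at {pm.first_peak(rdf):.1f} nm "
      "(pore diameter 4.5 nm + ~1 nm lipid annulus)")

profile = pm.shell_occurrences(particles, patch)
print("\nmean neighbours per protein, by distance context (A):")
for label, value in profile.as_dict().items():
    print(f"  {label:9s} {value:5.2f}")

ensemble = pm.patch_heterogeneity(particles, patch_radius=15.0, integral_max=10.0,
                                  n_repeats=100, seed=1)
print("\nlocal 15-nm patches (100 resamples), mean +- SD per context:")
for label, m, s in zip(ensemble.labels, ensemble.mean, ensemble.sd):
    print(f"  {label:9s} {m:5.2f} +- {s:4.2f}")
print("\nSD across patches quantifies within-structure heterogeneity.")
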