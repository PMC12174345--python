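"""Generate the four synthetic membrane regimes and summarize their
short-range order.

The glassy packing emulates dense honeycomb assemblies of 4.5 nm pores
separated by a ~1 nm lipid annulus; filaments emulate chain-like
assemblies a few molecules wide; dense aggregates are compact disordered
islands; the Poisson pattern is the complete-spatial-randomness control.
"""

import numpy as np
from scipy.spatial import cKDTree

import poremap as pm

region = pm.Region(120.0, 120.0)
for kind in ("glassy", "filament", "dense", "poisson"):
    cfg = pm.GeneratorConfig(kind=kind, n_particles=150, seed=1)
    ps = pm.generate_pattern(cfg, region)
    nn = cKDTree(ps.positions).query(ps.positions, k=2)[0][:, 1]
    print(f"{kind:9s} n={ps.n}  mean NN = {nn.mean():5.2f} nm  min NN = {nn.min():5.2f} nm")

print()
print("Hard-core regimes never fall below spacing - jitter (~5.2 nm), while")
print("the Poisson control shows unconstrained spacings down to near zero.")
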