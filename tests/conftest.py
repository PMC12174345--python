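import numpy as np
import pytest

import poremap as pm

GLASSY_REGION = pm.Region(120.0, 120.0)


@pytest.fixture(scope="session")
def glassy300():
    """Dense glassy packing at the honeycomb spacing (4.5 nm pore + 1 nm
    lipid annulus), the canonical dense-assembly fixture."""
    cfg = pm.GeneratorConfig(
        kind="glassy", n_particles=300, spacing=5.5, jitter=0.3, seed=1
    )
    return pm.generate_pattern(cfg, GLASSY_REGION)


@pytest.fixture(scope="session")
def glassy_rdf(glassy300):
    patch = pm.compute_patch_surface(glassy300, 5.0, "concave")
    return pm.compute_rdf(glassy300, patch, dr=0.2, r_max=20.0)


@pytest.fixture(scope="session")
def poisson2000():
    cfg = pm.GeneratorConfig(kind="poisson", n_particles=2000, seed=3)
    return pm.generate_pattern(cfg, pm.Region(300.0, 300.0))


@pytest.fixture(scope="session")
def poisson_patch(poisson2000):
    # dilation ~ pore radius: hugs the pattern without inflating S_patch
    return pm.compute_patch_surface(poisson2000, 2.5, "convex")


@pytest.fixture(scope="session")
def poisson_rdf_corrected(poisson2000, poisson_patch):
    return pm.compute_rdf(poisson2000, poisson_patch, dr=0.2, r_max=40.0)


@pytest.fixture(scope="session")
def poisson_rdf_full_ring(poisson2000, poisson_patch):
    return pm.compute_rdf(
        poisson2000, poisson_patch, dr=0.2, r_max=40.0, edge_correction="full_ring"
    )


@pytest.fixture(scope="session")
def default_template():
    return pm.generate_template(seed=0)


def pore_grid(n_side: int = 5, spacing: float = 8.0, margin: float = 8.0):
    """Regular grid of pore centers with generous separation."""
    xs = np.array(
        [
            (margin + spacing * i, margin + spacing * j)
            for i in range(n_side)
            for j in range(n_side)
        ],
        dtype=float,
    )
    side = 2 * margin + spacing * (n_side - 1)
    return pm.ParticleSet(xs, region=pm.Region(side, side))
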