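"""Synthetic membrane generators.

Emulates the three kinds of input the analyses consume:

* planar point patterns of pore centers — glassy (disordered, hard-core
  "honeycomb"-like) packings, filament chains, dense aggregates, and
  Poisson controls;
* AFM-like topography images rendering each pore as a ~4.5 nm depression
  (or, for nanobead-labelled proteins, a protrusion) on a noisy membrane;
* coarse-grained disc-and-shell protein+lipid templates with ~20
  first-shell lipids per leaflet inside a 5 nm cylinder.

The glassy generator is random sequential adsorption (RSA) with a hard
core at the nominal spacing, followed by a single bounded jitter pass, so
the minimum pairwise distance never drops below ``spacing - jitter``.
This reproduces the amorphous, non-crystalline crowding seen in dense
membrane-protein assemblies; it is a model of the *statistics* of those
assemblies, not of their formation kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .particles import ParticleSet, Region
from .topography import TopographyImage

__all__ = [
    "GeneratorConfig",
    "Template",
    "PackingError",
    "PORE_DIAMETER_NM",
    "DEFAULT_SPACING_NM",
    "generate_pattern",
    "render_topography",
    "generate_template",
]

#: AFM pore diameter of the channel (nm).
PORE_DIAMETER_NM = 4.5
#: Most probable center-to-center spacing: pore diameter + 1 nm lipid annulus.
DEFAULT_SPACING_NM = 5.5


class PackingError(RuntimeError):
    """Requested density is infeasible for the hard-core constraint."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic point pattern.

    ``spacing`` is the hard-core center-to-center distance (nm); the
    default 5.5 nm = 4.5 nm pore + 1.0 nm lipid annulus.  ``jitter``
    bounds the post-packing displacement of each particle, so glassy
    patterns keep all pairs at >= spacing - jitter.
    """

    kind: str = "glassy"  # glassy | filament | dense | poisson
    n_particles: int = 300
    spacing: float = DEFAULT_SPACING_NM
    jitter: float = 0.3
    n_chains: int | None = None  # filament kind; default n_particles // 12
    persistence: float = 0.9  # filament heading correlation in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("glassy", "filament", "dense", "poisson"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if not (0 <= self.persistence < 1):
            raise ValueError("persistence must be in [0, 1)")


def generate_pattern(config: GeneratorConfig, region: Region) -> ParticleSet:
    """Draw a point pattern of pore centers inside ``region``.

    Returns the ground-truth positions (used downstream to benchmark the
    detector).  Raises :class:`PackingError` when the requested hard-core
    density cannot be packed after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    if n == 0:
        return ParticleSet(np.empty((0, 2)), condition=config.kind, region=region)

    if config.kind == "poisson":
        pos = rng.uniform([0, 0], [region.width, region.height], size=(n, 2))
    elif config.kind == "glassy":
        pos = _rsa(rng, n, config.spacing, 0.0, 0.0, region.width, region.height)
        pos = _cohesion_relax(rng, pos, config.spacing, region)
        pos = _jitter_pass(rng, pos, config.jitter, region)
    elif config.kind == "dense":
        # one compact disk-shaped aggregate: RSA at a feasible packing
        # fraction, then cohesion compaction toward contact
        r_disk = (config.spacing / 2) * math.sqrt(n / 0.45) + config.spacing
        cx, cy = region.width / 2, region.height / 2
        if r_disk > min(cx, cy):
            raise PackingError("aggregate does not fit in region")
        pos = _rsa(
            rng, n, config.spacing,
            cx - r_disk, cy - r_disk, cx + r_disk, cy + r_disk,
            disk=(cx, cy, r_disk),
        )
        pos = _cohesion_relax(rng, pos, config.spacing, region)
        pos = _jitter_pass(rng, pos, config.jitter, region)
    else:  # filament
        pos = _filaments(rng, config, region)
        pos = _jitter_pass(rng, pos, config.jitter, region)

    return ParticleSet(pos, condition=config.kind, region=region)


def _rsa(rng, n, spacing, x0, y0, x1, y1, disk=None, max_attempts_per_point=2000):
    """Random sequential adsorption with hard core ``spacing``."""
    pts: list[np.ndarray] = []
    arr = np.empty((0, 2))
    attempts = 0
    budget = max(max_attempts_per_point * n, 20000)
    while len(pts) < n:
        if attempts >= budget:
            raise PackingError(
                f"could not pack {n} particles at spacing {spacing} nm "
                f"(placed {len(pts)} after {attempts} attempts)"
            )
        m = min(512, budget - attempts)
        cand = rng.uniform([x0, y0], [x1, y1], size=(m, 2))
        attempts += m
        if disk is not None:
            cx, cy, r = disk
            cand = cand[(cand[:, 0] - cx) ** 2 + (cand[:, 1] - cy) ** 2 <= r * r]
        for p in cand:
            if len(pts) >= n:
                break
            if arr.size:
                d2 = np.sum((arr - p) ** 2, axis=1)
                if d2.min() < spacing * spacing:
                    continue
            pts.append(p)
            arr = np.asarray(pts)
    return np.asarray(pts)


def _cohesion_relax(rng, pos, spacing, region, n_iter=40, step_frac=0.15):
    """Compact an RSA packing toward contact while keeping the hard core.

    Dense protein-lipid assemblies are cohesive (lipids act as mortar
    between pores), so after adsorption each particle takes small steps
    toward the centroid of its neighbours, with moves rejected whenever
    they would violate the hard-core spacing or leave the region.  This
    pulls typical nearest-neighbour distances down toward the contact
    distance without ever breaking the spacing constraint, producing the
    glass-like short-range order of a crowded, amorphous assembly.
    """
    n = len(pos)
    if n < 3:
        return pos
    pos = pos.copy()
    reach = 2.0 * spacing
    s2 = spacing * spacing
    step = step_frac * spacing
    for _ in range(n_iter):
        order = rng.permutation(n)
        for i in order:
            delta = pos - pos[i]
            d2 = np.einsum("ij,ij->i", delta, delta)
            d2[i] = np.inf
            near = d2 < reach * reach
            if not near.any():
                continue
            pull = delta[near].mean(axis=0)
            norm = math.hypot(*pull)
            if norm < 1e-12:
                continue
            newp = pos[i] + pull / norm * min(step, norm)
            if not (0 <= newp[0] <= region.width and 0 <= newp[1] <= region.height):
                continue
            nd2 = np.einsum("ij,ij->i", pos - newp, pos - newp)
            nd2[i] = np.inf
            if nd2.min() >= s2:
                pos[i] = newp
    return pos


def _jitter_pass(rng, pos, jitter, region):
    """Displace each point by at most jitter/2 (preserves >= spacing - jitter)."""
    if jitter <= 0 or len(pos) == 0:
        return pos
    theta = rng.uniform(0, 2 * math.pi, len(pos))
    rad = rng.uniform(0, jitter / 2, len(pos))
    out = pos + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    out[:, 0] = np.clip(out[:, 0], 0, region.width)
    out[:, 1] = np.clip(out[:, 1], 0, region.height)
    return out


def _filaments(rng, config: GeneratorConfig, region: Region) -> np.ndarray:
    """Correlated random walks: chains of particles at the hard-core spacing."""
    n = config.n_particles
    n_chains = config.n_chains or max(1, n // 12)
    sigma = (1.0 - config.persistence) * math.pi / 2  # heading change SD (rad)
    spacing = config.spacing
    pts: list[np.ndarray] = []
    arr = np.empty((0, 2))

    def clashes(p):
        if not len(pts):
            return False
        return np.min(np.sum((arr - p) ** 2, axis=1)) < spacing * spacing

    attempts = 0
    budget = 500 * n + 20000
    chain = 0
    while len(pts) < n and attempts < budget:
        chain += 1
        # new chain seed
        for _ in range(200):
            attempts += 1
            start = rng.uniform([0, 0], [region.width, region.height])
            if not clashes(start):
                break
        else:
            continue
        pts.append(start)
        arr = np.asarray(pts)
        heading = rng.uniform(0, 2 * math.pi)
        per_chain = max(2, int(round(n / n_chains)))
        placed = 1
        while placed < per_chain and len(pts) < n:
            attempts += 1
            if attempts >= budget:
                break
            heading += rng.normal(0, sigma)
            nxt = pts[-1] + spacing * np.array([math.cos(heading), math.sin(heading)])
            if not region.contains(nxt)[0] or clashes(nxt):
                break  # chain ends at boundary or clash
            pts.append(nxt)
            arr = np.asarray(pts)
            placed += 1
    if len(pts) < n:
        raise PackingError(f"filament generator placed only {len(pts)}/{n} particles")
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# Topography rendering
# ---------------------------------------------------------------------------

def render_topography(
    particles: ParticleSet,
    pore_diameter: float = PORE_DIAMETER_NM,
    pore_depth: float = 1.4,
    pixel_size: float = 0.5,
    noise_sd: float = 0.05,
    bead_fraction: float = 0.0,
    seed: int = 0,
    region: Region | None = None,
    bead_diameter: float = 5.0,
    bead_offset: float = 1.5,
) -> TopographyImage:
    """Render particles as pores (depressions) on a flat noisy membrane.

    Each pore is an inverted Gaussian of full width at half maximum equal
    to ``pore_diameter``.  A random ``bead_fraction`` subset is instead
    rendered as the spherical cap of a ``bead_diameter`` nanobead whose
    center sits ``bead_offset`` above the membrane plane — the protrusion
    signature of nanobead-labelled protein.
    """
    if not 0 <= bead_fraction <= 1:
        raise ValueError("bead_fraction must be in [0, 1]")
    if pixel_size > pore_diameter / 4:
        raise ValueError(
            f"pixel_size {pixel_size} nm too coarse to resolve a "
            f"{pore_diameter} nm pore (need <= diameter/4)"
        )
    region = region or particles.region
    if region is None:
        raise ValueError("no region: pass region= or use particles with one")
    rng = np.random.default_rng(seed)
    nc = max(4, int(round(region.width / pixel_size)))
    nr = max(4, int(round(region.height / pixel_size)))
    heights = np.zeros((nr, nc))

    # pixel-center world coordinates
    cols = (np.arange(nc) + 0.5) * pixel_size
    rows_y = (nr - np.arange(nr) - 0.5) * pixel_size

    n = particles.n
    is_bead = np.zeros(n, dtype=bool)
    if n and bead_fraction > 0:
        k = int(round(bead_fraction * n))
        is_bead[rng.choice(n, size=k, replace=False)] = True

    sigma = pore_diameter / (2 * math.sqrt(2 * math.log(2)))  # FWHM -> sd
    bead_r = bead_diameter / 2
    for (x, y), bead in zip(particles.positions, is_bead):
        if bead:
            half = bead_r
        else:
            half = 3 * sigma
        c0 = max(0, int((x - half) / pixel_size) - 1)
        c1 = min(nc, int((x + half) / pixel_size) + 2)
        r0 = max(0, int((region.height - y - half) / pixel_size) - 1)
        r1 = min(nr, int((region.height - y + half) / pixel_size) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = cols[c0:c1] - x
        dy = rows_y[r0:r1] - y
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        if bead:
            cap = np.zeros_like(d2)
            inside = d2 < bead_r * bead_r
            cap[inside] = bead_offset + np.sqrt(bead_r * bead_r - d2[inside])
            heights[r0:r1, c0:c1] = np.maximum(heights[r0:r1, c0:c1], cap)
        else:
            heights[r0:r1, c0:c1] -= pore_depth * np.exp(-d2 / (2 * sigma * sigma))

    if noise_sd > 0:
        heights += rng.normal(0, noise_sd, heights.shape)
    return TopographyImage(heights, pixel_size, {"condition": particles.condition})


# ---------------------------------------------------------------------------
# Coarse-grained disc-and-shell templates
# ---------------------------------------------------------------------------

SPECIES = ("PC", "PE", "CHOL")


@dataclass
class Template:
    """Coarse-grained protein + annular-lipid template.

    Protein beads form a barrel-like ring (19 strand columns, outer
    diameter 4.5 nm); lipid beads fill a cylinder of ``cylinder_radius``
    around the protein axis, one set per leaflet (cytosolic / IMS), with
    the innermost ring tagged as the first lipid shell.  Coordinates in
    nm, protein axis through the origin along z.
    """

    protein_beads: np.ndarray  # (M, 3)
    lipid_beads: np.ndarray  # (K, 3)
    species: np.ndarray  # (K,) str
    leaflet: np.ndarray  # (K,) str: cytosolic | IMS
    first_shell: np.ndarray  # (K,) bool
    cylinder_radius: float = 5.0

    def __post_init__(self) -> None:
        self.protein_beads = np.asarray(self.protein_beads, float).reshape(-1, 3)
        self.lipid_beads = np.asarray(self.lipid_beads, float).reshape(-1, 3)
        self.species = np.asarray(self.species)
        self.leaflet = np.asarray(self.leaflet)
        self.first_shell = np.asarray(self.first_shell, bool)
        if self.lipid_beads.size:
            r = np.hypot(self.lipid_beads[:, 0], self.lipid_beads[:, 1])
            if r.max() > self.cylinder_radius + 1e-9:
                raise ValueError("lipid beads outside cylinder radius")
        leaflets = set(self.leaflet.tolist())
        if self.lipid_beads.size and not leaflets <= {"cytosolic", "IMS"}:
            raise ValueError(f"bad leaflet tags {leaflets}")

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_beads)


#: protein ring geometry (nm): 19 strand columns, bead centers at r=2.0,
#: 5 z-levels spanning the barrel height; outer surface ~4.5 nm diameter.
_N_STRANDS = 19
_PROTEIN_RADIUS = 2.0
_Z_LEVELS = np.linspace(-1.7, 1.7, 5)
_LEAFLET_Z = {"cytosolic": 1.0, "IMS": -1.0}
_FIRST_SHELL_RADIUS = 2.6
_FILL_MIN_RADIUS = 3.3
_LIPID_MIN_DIST = 0.75


def generate_template(
    n_first_shell_per_leaflet: int = 20,
    cylinder_radius: float = 5.0,
    species_weights: dict[str, float] | None = None,
    seed: int = 0,
    fill: bool = True,
) -> Template:
    """Build a disc-and-shell template.

    Exactly ``n_first_shell_per_leaflet`` lipids per leaflet are placed on
    the annulus in direct contact with the protein wall and tagged
    first-shell; with ``fill=True`` the rest of the cylinder is packed
    with additional lipids at a realistic areal density.  Species are
    drawn from ``species_weights`` (default PC/PE/CHOL = 0.6/0.3/0.1).
    """
    if n_first_shell_per_leaflet < 0:
        raise ValueError("n_first_shell_per_leaflet must be >= 0")
    weights = species_weights or {"PC": 0.6, "PE": 0.3, "CHOL": 0.1}
    wsum = sum(weights.values())
    if not math.isclose(wsum, 1.0, abs_tol=1e-6):
        raise ValueError("species weights must sum to 1")
    if n_first_shell_per_leaflet > 0:
        ring_capacity = math.floor(2 * math.pi * _FIRST_SHELL_RADIUS / _LIPID_MIN_DIST)
        if n_first_shell_per_leaflet > ring_capacity:
            raise ValueError(
                f"{n_first_shell_per_leaflet} first-shell lipids do not fit on the "
                f"contact annulus (capacity {ring_capacity})"
            )
    if cylinder_radius < _FIRST_SHELL_RADIUS and n_first_shell_per_leaflet > 0:
        raise ValueError("cylinder_radius too small for a first lipid shell")

    rng = np.random.default_rng(seed)
    ang = np.arange(_N_STRANDS) * 2 * math.pi / _N_STRANDS
    ring = np.column_stack([np.cos(ang), np.sin(ang)]) * _PROTEIN_RADIUS
    protein = np.concatenate(
        [np.column_stack([ring, np.full(_N_STRANDS, z)]) for z in _Z_LEVELS]
    )

    beads, leaflet, shell = [], [], []
    for leaf, z in _LEAFLET_Z.items():
        # first shell: even angular placement with a small jitter
        m = n_first_shell_per_leaflet
        if m:
            a = np.arange(m) * 2 * math.pi / m + rng.uniform(0, 2 * math.pi)
            a += rng.normal(0, 0.3 / m, m)
            xy = np.column_stack([np.cos(a), np.sin(a)]) * _FIRST_SHELL_RADIUS
            for p in xy:
                beads.append([p[0], p[1], z])
                leaflet.append(leaf)
                shell.append(True)
        if fill and cylinder_radius > _FILL_MIN_RADIUS:
            area = math.pi * (cylinder_radius**2 - _FILL_MIN_RADIUS**2)
            n_fill = int(area / 0.64)  # ~0.64 nm^2 per lipid
            placed = []
            attempts = 0
            while len(placed) < n_fill and attempts < 400 * n_fill:
                attempts += 1
                r = math.sqrt(rng.uniform(_FILL_MIN_RADIUS**2, cylinder_radius**2))
                t = rng.uniform(0, 2 * math.pi)
                p = np.array([r * math.cos(t), r * math.sin(t)])
                if placed:
                    d2 = np.sum((np.asarray(placed) - p) ** 2, axis=1)
                    if d2.min() < _LIPID_MIN_DIST**2:
                        continue
                placed.append(p)
            for p in placed:
                beads.append([p[0], p[1], z])
                leaflet.append(leaf)
                shell.append(False)

    beads_arr = np.asarray(beads).reshape(-1, 3)
    k = len(beads_arr)
    names = np.array(list(weights), dtype=object)
    probs = np.array([weights[s] for s in names], dtype=float)
    probs /= probs.sum()
    species = names[rng.choice(len(names), size=k, p=probs)] if k else np.empty(0, object)
    return Template(
        protein,
        beads_arr,
        species.astype(str) if k else np.empty(0, "U8"),
        np.asarray(leaflet, dtype="U16") if k else np.empty(0, "U16"),
        np.asarray(shell, bool) if k else np.empty(0, bool),
        cylinder_radius,
    )
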