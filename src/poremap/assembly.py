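"""Protein-lipid assembly models at measured pore coordinates.

Given the planar pore centers measured on a membrane and a pool of
coarse-grained protein+annulus templates, the builder places one
template per site, choosing for each site the in-plane rotation (over a
uniform angle grid, greedily in placement order) that minimizes the
clash score against already-placed instances; the clash score is the
number of inter-instance protein-bead pairs closer than the clash
cutoff.  Overlapping lipids from later instances are then sequentially
removed, yielding a stereochemical model from which pairwise contact
classes, first-shell lipid counts and per-species occupancy/enrichment
maps are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .particles import ParticleSet
from .spatial import DEFAULT_CONTEXT_BINS_A
from .synthetic import PORE_DIAMETER_NM, Template

__all__ = [
    "PlacedInstance",
    "AssemblyModel",
    "ContactClass",
    "OccupancyMap",
    "build_assembly",
    "prune_overlapping_lipids",
    "count_inter_instance_clashes",
    "first_shell_lipids",
    "classify_contacts",
    "compute_occupancy_map",
    "DEFAULT_CLASH_CUTOFF_NM",
    "DEFAULT_OVERLAP_CUTOFF_NM",
    "DEFAULT_SHELL_CUTOFF_NM",
]

#: one coarse-grained bead diameter (nm); pairs closer than this clash
DEFAULT_CLASH_CUTOFF_NM = 0.47
DEFAULT_OVERLAP_CUTOFF_NM = 0.47
#: lipid beads within this distance of a protein bead are first-shell
DEFAULT_SHELL_CUTOFF_NM = 0.8


def _rot2(xyz: np.ndarray, angle: float) -> np.ndarray:
    """Rotate beads about the membrane normal (z) through the origin."""
    c, s = math.cos(angle), math.sin(angle)
    out = xyz.copy()
    out[:, 0] = c * xyz[:, 0] - s * xyz[:, 1]
    out[:, 1] = s * xyz[:, 0] + c * xyz[:, 1]
    return out


@dataclass
class PlacedInstance:
    site_id: int
    template_index: int
    angle: float  # rad, about the channel axis
    translation: np.ndarray  # (x, y) nm
    protein: np.ndarray  # (M, 3) nm, world frame
    lipids: np.ndarray  # (K, 3) nm, world frame
    species: np.ndarray
    leaflet: np.ndarray
    first_shell_tag: np.ndarray
    retained: np.ndarray  # (K,) bool, False once pruned

    @property
    def retained_lipids(self) -> np.ndarray:
        return self.lipids[self.retained]


@dataclass
class AssemblyModel:
    instances: list[PlacedInstance]
    clash_cutoff: float
    pruned_log: list[tuple[int, int, str]] = field(default_factory=list)
    clashing_sites: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.instances)

    def centers(self) -> np.ndarray:
        return np.asarray([inst.translation for inst in self.instances]).reshape(-1, 2)

    def pairwise_center_distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.centers()))

    @property
    def n_lipids_initial(self) -> int:
        return sum(len(i.lipids) for i in self.instances)

    @property
    def n_lipids_retained(self) -> int:
        return sum(int(i.retained.sum()) for i in self.instances)

    @property
    def n_lipids_pruned(self) -> int:
        return len(self.pruned_log)

    def lipid_table(self, retained_only: bool = True):
        """(positions, species, leaflet, instance ids) of lipid beads."""
        pos, spc, leaf, inst = [], [], [], []
        for k, i in enumerate(self.instances):
            keep = i.retained if retained_only else np.ones(len(i.lipids), bool)
            pos.append(i.lipids[keep])
            spc.append(i.species[keep])
            leaf.append(i.leaflet[keep])
            inst.append(np.full(int(keep.sum()), k))
        if not pos:
            return (np.empty((0, 3)), np.empty(0, "U8"), np.empty(0, "U16"), np.empty(0, int))
        return (
            np.concatenate(pos),
            np.concatenate(spc),
            np.concatenate(leaf),
            np.concatenate(inst),
        )


def build_assembly(
    particles: ParticleSet,
    templates: list[Template],
    n_rotations: int = 64,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF_NM,
    seed: int = 0,
    refine_sweeps: int = 2,
) -> AssemblyModel:
    """Place one randomly drawn template per site with clash-minimizing
    in-plane rotations.

    Sites are processed in input order; for each, all ``n_rotations``
    grid angles are scored against already-placed protein beads and the
    lowest-scoring angle wins (ties broken by the smallest angle).  Up to
    ``refine_sweeps`` additional passes re-optimize every site's angle
    against the full set of neighbours, so pair configurations reach the
    grid optimum rather than a greedy artefact.  Sites closer than the
    protein hard-core diameter are flagged (and warned about): their
    residual protein-protein clashes are physical "clashing class"
    contacts, not builder failures.
    """
    if not templates:
        raise ValueError("need at least one template")
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng(seed)
    centers = particles.positions
    n = len(centers)
    angles = np.arange(n_rotations) * 2 * math.pi / n_rotations

    draws = rng.integers(0, len(templates), size=n)
    instances: list[PlacedInstance] = []

    def score(prot_world: np.ndarray, others: cKDTree | None) -> int:
        if others is None:
            return 0
        return int(others.query_ball_point(prot_world, clash_cutoff, return_length=True).sum())

    # greedy placement
    placed_protein: list[np.ndarray] = []
    for site in range(n):
        tpl = templates[draws[site]]
        shift = np.array([centers[site, 0], centers[site, 1], 0.0])
        tree = cKDTree(np.concatenate(placed_protein)) if placed_protein else None
        best_angle, best_score = angles[0], None
        for a in angles:
            sc = score(_rot2(tpl.protein_beads, a) + shift, tree)
            if best_score is None or sc < best_score:
                best_angle, best_score = a, sc
            if best_score == 0:
                break
        prot = _rot2(tpl.protein_beads, best_angle) + shift
        lip = _rot2(tpl.lipid_beads, best_angle) + shift if tpl.lipid_beads.size else tpl.lipid_beads.copy()
        instances.append(
            PlacedInstance(
                site, int(draws[site]), float(best_angle), centers[site].copy(),
                prot, lip, tpl.species.copy(), tpl.leaflet.copy(),
                tpl.first_shell.copy(), np.ones(len(tpl.lipid_beads), bool),
            )
        )
        placed_protein.append(prot)

    # refinement: re-optimize each site's angle against all other instances
    for _ in range(max(0, refine_sweeps)):
        improved = False
        for site in range(n):
            others = [inst.protein for k, inst in enumerate(instances) if k != site]
            tree = cKDTree(np.concatenate(others)) if others else None
            tpl = templates[draws[site]]
            shift = np.array([centers[site, 0], centers[site, 1], 0.0])
            cur = instances[site]
            best_angle, best_score = cur.angle, score(cur.protein, tree)
            for a in angles:
                sc = score(_rot2(tpl.protein_beads, a) + shift, tree)
                if sc < best_score or (sc == best_score and a < best_angle):
                    best_angle, best_score = float(a), sc
            if not math.isclose(best_angle, cur.angle):
                improved = True
                _reorient(cur, tpl, best_angle, shift)
        if not improved:
            break

    if refine_sweeps > 0:
        _pairwise_polish(instances, templates, draws, centers, angles, clash_cutoff)

    model = AssemblyModel(instances, clash_cutoff)
    hard_core = PORE_DIAMETER_NM
    if n > 1:
        d = model.pairwise_center_distances()
        iu = np.triu_indices(n, 1)
        for i, j in zip(*iu):
            if d[i, j] < hard_core:
                model.clashing_sites.append((int(i), int(j)))
        if model.clashing_sites:
            warnings.warn(
                f"{len(model.clashing_sites)} site pair(s) closer than the "
                f"{hard_core} nm protein hard core; residual protein-protein "
                "clashes flagged as clashing-class contacts",
                stacklevel=2,
            )
    return model


def _reorient(inst: PlacedInstance, tpl: Template, angle: float, shift: np.ndarray) -> None:
    inst.angle = float(angle)
    inst.protein = _rot2(tpl.protein_beads, angle) + shift
    if tpl.lipid_beads.size:
        inst.lipids = _rot2(tpl.lipid_beads, angle) + shift


def _pairwise_polish(instances, templates, draws, centers, angles, clash_cutoff,
                     max_sweeps: int = 3) -> None:
    """Joint exhaustive rotation search over interacting site pairs.

    Single-site best-response sweeps can stall in a local optimum of the
    joint clash landscape; for every pair of sites close enough to
    interact, this searches the full angle x angle grid (others fixed)
    and keeps any strict improvement.  For a two-site assembly this is
    exactly the global grid optimum.  Deterministic: scans pairs in
    order, ties resolved toward the smallest (angle_i, angle_j).
    """
    from scipy.spatial.distance import cdist

    n = len(instances)
    if n < 2:
        return
    # interaction reach in the membrane plane
    reach = max(
        float(np.hypot(t.protein_beads[:, 0], t.protein_beads[:, 1]).max())
        for t in templates
    ) * 2.0 + clash_cutoff + 1e-9
    rot_cache: dict[int, np.ndarray] = {}
    for t_idx in set(draws.tolist()):
        beads = templates[t_idx].protein_beads
        rot_cache[t_idx] = np.stack([_rot2(beads, a) for a in angles])

    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(centers[j] - centers[i])) >= reach:
                    continue
                ti, tj = draws[i], draws[j]
                si = np.array([centers[i, 0], centers[i, 1], 0.0])
                sj = np.array([centers[j, 0], centers[j, 1], 0.0])
                ri = rot_cache[ti] + si  # (A, M, 3)
                rj = rot_cache[tj] + sj
                others = [
                    inst.protein for k, inst in enumerate(instances) if k not in (i, j)
                ]
                tree = cKDTree(np.concatenate(others)) if others else None

                def unary(rot_world):
                    if tree is None:
                        return np.zeros(len(rot_world), int)
                    return np.array([
                        int(tree.query_ball_point(r, clash_cutoff, return_length=True).sum())
                        for r in rot_world
                    ])

                ui = unary(ri)
                uj = unary(rj)
                nA = len(angles)
                cross = np.empty((nA, nA), int)
                flat_j = rj.reshape(-1, 3)
                mj = rj.shape[1]
                for a in range(nA):
                    d = cdist(ri[a], flat_j)
                    hits = (d <= clash_cutoff).sum(axis=0)  # per flattened j bead
                    cross[a] = hits.reshape(nA, mj).sum(axis=1)
                total = cross + ui[:, None] + uj[None, :]
                a_best, b_best = np.unravel_index(np.argmin(total), total.shape)
                cur_ai = int(np.argmin(np.abs(angles - instances[i].angle)))
                cur_aj = int(np.argmin(np.abs(angles - instances[j].angle)))
                if total[a_best, b_best] < total[cur_ai, cur_aj]:
                    improved = True
                    _reorient(instances[i], templates[ti], float(angles[a_best]), si)
                    _reorient(instances[j], templates[tj], float(angles[b_best]), sj)
        if not improved:
            break


def total_clash_score(model: AssemblyModel) -> int:
    """Number of inter-instance protein-bead pairs below the clash cutoff."""
    total = 0
    for i in range(model.n_sites):
        for j in range(i + 1, model.n_sites):
            ti = cKDTree(model.instances[i].protein)
            total += int(
                ti.query_ball_point(
                    model.instances[j].protein, model.clash_cutoff, return_length=True
                ).sum()
            )
    return total


def prune_overlapping_lipids(
    model: AssemblyModel, overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF_NM
) -> AssemblyModel:
    """Sequentially remove overlapping lipid beads (in place; returns model).

    Iterating over instances in placement order, a lipid bead is removed
    if it lies within ``overlap_cutoff`` of any *other* instance's
    protein beads (proteins are fixed; lipids yield), or of a retained
    lipid bead of an earlier-placed instance (earlier instances win).
    The removal log records every pruned bead; pruning is idempotent.
    """
    protein_all = (
        np.concatenate([inst.protein for inst in model.instances])
        if model.instances else np.empty((0, 3))
    )
    protein_owner = np.concatenate(
        [np.full(len(inst.protein), k) for k, inst in enumerate(model.instances)]
    ) if model.instances else np.empty(0, int)
    prot_tree = cKDTree(protein_all) if len(protein_all) else None

    retained_pts: list[np.ndarray] = []  # lipids retained from earlier instances
    earlier_tree = None
    for k, inst in enumerate(model.instances):
        if inst.lipids.size:
            drop = np.zeros(len(inst.lipids), bool)
            if prot_tree is not None:
                neigh = prot_tree.query_ball_point(inst.lipids, overlap_cutoff)
                for b, idx in enumerate(neigh):
                    if any(protein_owner[i] != k for i in idx):
                        drop[b] = True
            if earlier_tree is not None:
                hits = earlier_tree.query_ball_point(
                    inst.lipids, overlap_cutoff, return_length=True
                )
                drop |= hits > 0
            newly = drop & inst.retained
            for b in np.nonzero(newly)[0]:
                model.pruned_log.append((k, int(b), "overlap"))
            inst.retained &= ~drop
            if inst.retained.any():
                retained_pts.append(inst.lipids[inst.retained])
        if retained_pts:
            earlier_tree = cKDTree(np.concatenate(retained_pts))
    return model


def count_inter_instance_clashes(
    model: AssemblyModel, cutoff: float, include_protein_pairs: bool = True
) -> int:
    """Residual inter-instance bead pairs (retained beads) below cutoff."""
    beads, owner = [], []
    for k, inst in enumerate(model.instances):
        pts = [inst.protein] if include_protein_pairs else []
        pts.append(inst.retained_lipids)
        for p in pts:
            if len(p):
                beads.append(p)
                owner.append(np.full(len(p), k))
    if not beads:
        return 0
    beads = np.concatenate(beads)
    owner = np.concatenate(owner)
    tree = cKDTree(beads)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if not len(pairs):
        return 0
    return int(np.count_nonzero(owner[pairs[:, 0]] != owner[pairs[:, 1]]))


def first_shell_lipids(
    model: AssemblyModel, shell_cutoff: float = DEFAULT_SHELL_CUTOFF_NM
) -> dict[int, dict[str, int]]:
    """Retained lipids in direct contact with each instance's protein wall.

    A lipid bead belongs to the first shell of its own instance when it
    lies within ``shell_cutoff`` of any protein bead of that instance;
    counts are split by leaflet tag.
    """
    out: dict[int, dict[str, int]] = {}
    for k, inst in enumerate(model.instances):
        counts = {"cytosolic": 0, "IMS": 0}
        if inst.lipids.size and shell_cutoff > 0:
            tree = cKDTree(inst.protein)
            near = tree.query_ball_point(
                inst.lipids[inst.retained], shell_cutoff, return_length=True
            ) > 0
            leaf = inst.leaflet[inst.retained]
            for l in ("cytosolic", "IMS"):
                counts[l] = int(np.count_nonzero(near & (leaf == l)))
        out[k] = counts
    return out


# ---------------------------------------------------------------------------
# Contact classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactClass:
    pair: tuple[int, int]
    distance_a: float  # center distance, Angstrom
    label: str  # distance-context class
    mediation: str  # direct | lipid-bridged | mixed


def classify_contacts(
    model: AssemblyModel,
    class_bins_a: tuple = DEFAULT_CONTEXT_BINS_A,
    direct_cutoff_a: float = 53.0,
    corridor_width_nm: float = PORE_DIAMETER_NM,
) -> list[ContactClass]:
    """Classify neighbouring site pairs by center distance and mediation.

    The class label comes from the same distance boundaries used by the
    distance-context profiles (single source of truth).  Mediation:
    pairs closer than ``direct_cutoff_a`` are direct protein-protein
    contacts; otherwise the pair is lipid-bridged when retained lipid
    beads occupy the rectangular corridor (width = one protein diameter)
    between the two centers, and mixed when none do.
    """
    edges = np.asarray(class_bins_a, float)
    labels = [f"<{edges[0]:g}"] + [
        f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])
    ]
    r_max_nm = edges[-1] / 10.0
    lip_pos, _, _, lip_owner = model.lipid_table(retained_only=True)
    out: list[ContactClass] = []
    centers = model.centers()
    for i in range(model.n_sites):
        for j in range(i + 1, model.n_sites):
            d_nm = float(np.hypot(*(centers[j] - centers[i])))
            if d_nm >= r_max_nm:
                continue
            d_a = d_nm * 10.0
            k = int(np.searchsorted(edges, d_a, side="right"))
            label = labels[k]
            if d_a < direct_cutoff_a:
                mediation = "direct"
            else:
                n_bridge = _corridor_count(
                    lip_pos, lip_owner, centers[i], centers[j], corridor_width_nm, (i, j)
                )
                mediation = "lipid-bridged" if n_bridge > 0 else "mixed"
            out.append(ContactClass((i, j), d_a, label, mediation))
    return out


def _corridor_count(lip_pos, lip_owner, a, b, width, pair):
    """Lipid beads inside the rectangle between centers a and b."""
    if not len(lip_pos):
        return 0
    ab = b - a
    L = np.hypot(*ab)
    if L == 0:
        return 0
    u = ab / L
    rel = lip_pos[:, :2] - a
    t = rel @ u
    perp = np.abs(rel @ np.array([-u[1], u[0]]))
    inside = (t > 0) & (t < L) & (perp <= width / 2)
    return int(np.count_nonzero(inside))


# ---------------------------------------------------------------------------
# Occupancy / enrichment maps
# ---------------------------------------------------------------------------


@dataclass
class OccupancyMap:
    """Per-species bead counts on a fine grid with enrichment ratios.

    ``enrichment[s] = counts[s] / mean_density[s]`` where the species
    mean density is its total count divided by the number of occupied
    cells (cells holding at least one bead of any species), so the mean
    enrichment of each species over the occupied region is exactly 1.
    """

    counts: dict[str, np.ndarray]
    resolution: float  # nm per cell
    origin: tuple[float, float]
    occupied: np.ndarray  # bool grid

    @property
    def species(self) -> list[str]:
        return list(self.counts)

    def mean_density(self, species: str) -> float:
        n_occ = int(self.occupied.sum())
        return float(self.counts[species].sum()) / n_occ if n_occ else 0.0

    def enrichment(self, species: str) -> np.ndarray:
        mu = self.mean_density(species)
        out = np.zeros_like(self.counts[species], dtype=float)
        if mu > 0:
            out[self.occupied] = self.counts[species][self.occupied] / mu
        return out

    def enriched_region(self, species: str, fold: float = 1.2) -> np.ndarray:
        """Boolean grid of cells at or above a fold-enrichment cutoff
        (conventional cutoffs: 1.2 and 1.8)."""
        return self.enrichment(species) >= fold


DEFAULT_ENRICHMENT_CUTOFFS = (1.2, 1.8)


def compute_occupancy_map(
    positions: np.ndarray,
    species: np.ndarray,
    grid_resolution: float = 0.2,
    extent: tuple[float, float, float, float] | None = None,
) -> OccupancyMap:
    """Bin bead positions per species on a fine grid (default 2 A), with
    no Gaussian averaging.

    ``extent`` is (x0, y0, x1, y1) in nm; by default the bead bounding
    box.  Species with zero beads are skipped with a warning.
    """
    positions = np.asarray(positions, float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("need at least one bead")
    xy = positions[:, :2]
    species = np.asarray(species)
    if extent is None:
        x0, y0 = xy.min(axis=0)
        x1, y1 = xy.max(axis=0)
    else:
        x0, y0, x1, y1 = extent
    nx = max(1, int(math.ceil((x1 - x0) / grid_resolution)))
    ny = max(1, int(math.ceil((y1 - y0) / grid_resolution)))
    xedges = x0 + np.arange(nx + 1) * grid_resolution
    yedges = y0 + np.arange(ny + 1) * grid_resolution

    counts: dict[str, np.ndarray] = {}
    for s in dict.fromkeys(species.tolist()):  # preserve first-seen order
        sel = species == s
        if not np.any(sel):
            warnings.warn(f"species {s!r} has no beads; skipped", stacklevel=2)
            continue
        h, _, _ = np.histogram2d(xy[sel, 0], xy[sel, 1], bins=[xedges, yedges])
        counts[str(s)] = h  # (nx, ny), x along rows
    if not counts:
        raise ValueError("no species with beads")
    occupied = np.zeros((nx, ny), bool)
    for h in counts.values():
        occupied |= h > 0
    return OccupancyMap(counts, grid_resolution, (x0, y0), occupied)
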