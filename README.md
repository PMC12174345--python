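# poremap

Quantitative analysis of membrane-protein supramolecular organization
from AFM data, built around the mitochondrial outer-membrane channel
VDAC1: a ~4.5 nm β-barrel pore that crowds into dense, glass-like
("honeycomb") protein–lipid assemblies, filament chains, or compact
aggregates depending on the lipid environment. The package is for
structural biologists and biophysicists who have planar pore
coordinates or topography images and want the statistics that
characterize such assemblies — plus a synthetic-membrane generator so
every stage can be exercised and validated without instrument data.

## What it computes

**Boundary-corrected radial distribution function.** For N pore centers
P_i inside a patch surface S_patch (the concave or convex hull of all
positions dilated by a radius), with global density ρ = N / S_patch:

    g(r) = (1/N) Σ_i  N_i(r, dr) / (ρ · |S_ring(r, dr) ∩ S_patch|)

where N_i(r, dr) counts neighbours of particle i in the annulus
[r − dr/2, r + dr/2) and S_ring = 2πr·dr. Normalizing each annulus by
its intersection with the patch (measured on a 0.5 nm raster) corrects
edge effects without discarding boundary particles — essential for the
small, irregular patches these assemblies form.

**Distance-context profiles.** Neighbour counts per protein in the six
center-to-center classes <50, [50,56), [56,62), [62,68), [68,80),
[80,86) Å — clashing, direct contact, three successive lipid-separated
shells (6 Å apart, one lipid layer each), and bridged/row contexts —
plus a resampling analysis over 15 nm local patches (100 repeats) that
quantifies within-structure heterogeneity.

**Cluster statistics.** Monomer/cluster partition as connected
components of the ε-distance graph (DBSCAN, min samples 2, ε = 5.3 nm
by default), reporting n, f_mono, cluster count, f_clust = 1 − f_mono,
and cluster-size mean ± SEM.

**Pore detection.** Normalized (Pearson) cross-correlation of an
inverted-pore template against topography images, greedy non-maximum
suppression, sub-pixel centroid refinement, and three stringency tiers
yielding nested confidence sets.

**Assembly models.** Coarse-grained disc-and-shell protein+lipid
templates (~20 first-shell lipids per leaflet inside a 5 nm cylinder)
placed at measured coordinates with clash-minimizing in-plane rotations,
sequential removal of overlapping lipids, contact classification
(direct / lipid-bridged / mixed), and per-species lipid occupancy grids
(2 Å bins, no smoothing) with 1.2- / 1.8-fold enrichment cutoffs.

**Composition bookkeeping.** Mass and molar fractions for reference
bilayer compositions and the lipid:protein mass-to-molar ratio
conversion (3:1 w/w ≈ 140:1 molar for a ~34.8 kDa channel).

## Worked example

```sh
python examples/03_rdf_and_contexts.py
```

```
patch surface: 14992 nm^2 (concave hull), density rho = 20010 pores/um^2
first g(r) peak at 5.7 nm (pore diameter 4.5 nm + ~1 nm lipid annulus)

mean neighbours per protein, by distance context (A):
  <50        0.00
  [50,56)    0.39
  [56,62)    1.29
  [62,68)    0.57
  [68,80)    1.28
  [80,86)    0.71

local 15-nm patches (100 resamples), mean +- SD per context:
  <50        0.00 +- 0.00
  [50,56)    0.31 +- 0.21
  [56,62)    1.03 +- 0.33
  [62,68)    0.44 +- 0.23
  [68,80)    0.92 +- 0.32
  [80,86)    0.47 +- 0.23
```

The fixture is a dense glassy packing of 300 pores (hard-core spacing
5.5 nm = 4.5 nm pore + 1.0 nm annulus) in a 120 × 120 nm field. The
first g(r) maximum sits at the contact distance; the context profile
shows no clashing pairs (the hard core forbids them), a dominant
lipid-separated shell, and patch-to-patch scatter quantifying the
heterogeneity of the assembly. The other example scripts cover pattern
generation, detection on rendered topographies, cluster tables across
packing regimes, assembly building with enrichment maps, and the
composition tables.

A thin CLI mirrors the library (`poremap simulate|render|detect|rdf|
contexts|cluster|build-assembly|occupancy|composition|run`).

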