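# Methods

This note documents the models, conventions, parameter choices and
known limitations of the package. Units are nm for lengths (distance
class boundaries are quoted in Å, as is conventional for molecular
contacts), nm² for areas, Da for masses.

## Coordinate conventions

World coordinates put the origin at the lower-left corner of the
analysis region, x right, y up, in nm. Images are row-major with row 0
at the top; pixel centers sit at half-integer offsets
(x = (col + ½)·px). `TopographyImage.world_to_pixel` /
`pixel_to_world` are the single source of truth for the mapping, and
round-trip exactly (tested). Particle tables round-trip through CSV
(`id, x_nm, y_nm, tier, condition`), topographies through 32-bit float
TIFF or plain-text matrices, templates and models through PDB (Å;
species in the residue name, leaflet in the chain id, first-shell flag
in the B-factor).

## Synthetic membrane generator

The generator defines the study conditions for all tests; it emulates
the *statistics* of the assemblies, not their formation kinetics.

* **Glassy ("honeycomb") packings** — random sequential adsorption
  (RSA) with a hard core at the nominal spacing (default 5.5 nm =
  4.5 nm pore diameter + 1.0 nm lipid annulus), followed by a cohesion
  relaxation: each particle repeatedly steps (≤ 0.15 × spacing, 40
  sweeps) toward the centroid of its neighbours within 2 × spacing,
  rejecting any move that violates the hard core or leaves the region.
  The relaxation models the cohesive, lipid-mediated attraction that
  holds these assemblies together and pulls typical nearest-neighbour
  distances down toward contact (mean NN ≈ 5.8 nm for the default
  fixture) while keeping the pattern amorphous. A final jitter pass
  displaces each particle by at most jitter/2, so the minimum pairwise
  distance never falls below spacing − jitter. Default fixture: n =
  300 in 120 × 120 nm (≈ 90% of RSA saturation — dense but reliably
  feasible for any seed; ≈ 2 × 10⁴ pores/µm²). The real surface
  density of reconstituted membranes is not published; the region size
  is therefore a free parameter chosen to make the packing
  contact-dominated, and is documented wherever it matters.
* **Filaments** — correlated random walks: chains of particles at the
  hard-core spacing whose heading diffuses with SD
  (1 − persistence)·π/2 per step; chains terminate at boundaries or
  clashes. Default persistence 0.9 gives gently curving strands a few
  molecules long, with the same hard core as above.
* **Dense aggregates** — RSA confined to a central disk sized for a
  0.45 packing fraction, then the same cohesion compaction; produces a
  single compact amorphous island.
* **Poisson control** — uniform i.i.d. positions (no hard core), the
  complete-spatial-randomness reference for the RDF.

All generators are deterministic given (config, seed); identical calls
are bit-identical.

**Topography rendering.** Membrane = constant height plus i.i.d.
Gaussian noise. Each pore is an inverted Gaussian of FWHM =
pore_diameter (default 4.5 nm) and depth 1.4 nm — this matches the
smooth AFM depression of an open pore without modelling tip
convolution, which is out of scope. A `bead_fraction` subset is
instead rendered as the spherical cap of a 5 nm nanobead whose center
sits 1.5 nm above the membrane plane (peak ≈ 4 nm), converting the
depression into a protrusion — the orientation signature of
nanobead-labelled protein. SNR is defined as pore depth / noise SD.

**Templates.** The protein is a barrel-like ring of 95 beads (19
strand columns at radius 2.0 nm, five z-levels over ±1.7 nm; outer
surface ≈ 4.5 nm diameter). Exactly `n_first_shell_per_leaflet`
(default 20) lipids per leaflet sit on the contact annulus at radius
2.6 nm; the rest of the 5 nm cylinder is RSA-filled at ~0.64 nm² per
lipid with a 0.75 nm minimum separation. Species (PC/PE/CHOL, default
weights 0.6/0.3/0.1) are drawn per bead; leaflets are tagged
cytosolic/IMS at z = ±1.0 nm.

## Pore detection

Correlation is Pearson-normalized over the template footprint
(zero-mean template; local image mean and variance from uniform
filters), computed with wrap boundary handling so detection is exactly
equivariant under integer cyclic shifts. Candidates are 3 × 3 local
maxima above the loosest threshold; greedy non-maximum suppression
keeps the best-scoring candidate within `min_separation` (default
4.0 nm), ties broken lexicographically by (row, col) so outputs are
deterministic. Sub-pixel centers come from the centroid of the
(min-subtracted) 3 × 3 correlation neighbourhood. The three stringency
tiers are correlation thresholds (defaults 0.8 / 0.6 / 0.45); a
detection's tier is the most stringent threshold it passes, so tier
sets are nested by construction. The published stringency settings are
not quantified, so the thresholds are configuration values; only the
nesting structure (n₁ ≤ n₂ ≤ n₃) is asserted, not particular counts.

## Patch surface and RDF

S_patch is the union of disks of the dilation radius centered on a
hull of the positions: convex, or concave via an alpha shape (union of
Delaunay triangles with circumradius ≤ α, α = 2 × dilation radius)
with a convex fallback when the alpha complex is empty, degenerate, or
disconnected. Areas — both S_patch and every per-particle annulus
intersection — are measured by counting raster pixels at 0.5 nm/px,
which is robust for arbitrarily concave patches; pixel centers are
offset half a pixel from the hull vertices so grid-aligned inputs do
not place centers exactly on polygon boundaries. Closed-form checks
(disk, stadium) agree to < 1%; per-annulus areas carry a
one-to-two-pixel discretization scatter, which is the tolerance used
wherever they are compared to 2πr·dr.

g(r) bins pair distances at dr = 0.2 nm by default — fine enough to
resolve the 6 Å sub-structure of lipid-separated shells. Each
particle's annulus count is normalized by its own ring∩patch area;
bins where that area is zero are excluded from the average for that
bin (the particle cannot host neighbours there); when all areas are
positive this reduces to the plain (1/N)Σ form. Self-pairs are
excluded at the particle level (each pore contributes one center).
The dilation radius is not published; guidance: ~5 nm for dense
assemblies (t7-style fixtures), but for sparse patterns a dilation of
roughly half the mean nearest-neighbour spacing (e.g. 2.5 nm for the
n = 2000 CSR control in 300 × 300 nm) — a large rim on a sparse
pattern inflates S_patch and biases g upward by the rim fraction.
`first_peak` reports the first local maximum past 1 nm whose g exceeds
half the global maximum (guards against shot-noise bumps in
near-empty bins).

**Distance contexts.** Occurrences are mean neighbour counts per
reference protein within each class — the discrete equivalent of
integrating ρ·g(r) over each shell; whether to normalize per protein
or report structure totals is a switch (`normalize`), per-protein
being the default. The heterogeneity resampling centers a 15 nm patch
on a randomly chosen protein, computes occurrences within the
restricted subset up to `integral_max` (10 nm default; 50 nm
recommended for sparse conditions), repeats 100 times (every protein
at most once when the structure holds fewer than 100), and reports
per-repeat profiles with mean and SD.

## Clustering

DBSCAN (scikit-learn) on coordinates with min_samples = 2, which for
this setting is exactly connected components of the ε-distance graph:
a pair at ≤ ε is a dimer cluster, singletons are monomers. ε defaults
to 5.3 nm; 5.6 nm — the direct-contact distance used when describing
the assemblies — can be passed instead (both values appear in the
source literature; 5.3 is the clustering default there). Labels are
canonicalized by each cluster's lexicographically smallest member
coordinate, so they are independent of input order. f_clust is
computed as 1.0 − f_mono, making the partition identity exact in
floating point. Cluster-size dispersion is reported as both SD and
SEM; SEM is the display default (published ± values are consistent
with SEM). An independent union-find oracle over brute-force pair
distances verifies the partition on hundreds of random instances.

## Assembly builder

Sites are processed in input order; each receives a template drawn
uniformly (seeded). The clash score is the count of inter-instance
protein-bead pairs below the clash cutoff (default 0.47 nm ≈ one
coarse-grained bead diameter) — a count, not an energy, since only
"clashes" are defined. Rotation search: greedy per-site minimization
over a uniform angle grid (default 64), ties to the smallest angle;
then best-response sweeps; then a pairwise polish that exhaustively
searches the joint angle × angle grid for every interacting pair
(others fixed), which for a two-site assembly equals the global grid
optimum and is oracle-tested as such. Sites closer than the 4.5 nm
protein hard core are flagged and warned about — their residual
protein–protein clashes are physical "clashing class" contacts, not
builder failures.

**Lipid pruning** is sequential with earlier-placed instances winning:
a lipid bead is removed when within the overlap cutoff of any *other*
instance's protein beads (proteins are fixed; lipids yield) or of a
retained lipid of an earlier instance. This leaves zero inter-instance
bead pairs below the cutoff (protein–protein pairs excepted, see
above), conserves beads (retained + pruned = initial, logged), and is
idempotent.

**Contacts.** Pair classes come from the same Å boundaries as the
distance-context profiles (single source of truth). Mediation: pairs
under 53 Å are direct; otherwise "lipid-bridged" when retained lipid
beads occupy the rectangular corridor of width one protein diameter
between the centers, "mixed" when none do. The corridor definition is
a convention of this package (the distinction is not defined
geometrically in the source literature) and is flagged as such.

**Occupancy maps** bin beads per species on a 2 Å grid per leaflet
with no smoothing. The occupied region is the union over species of
nonzero cells; a species' mean density is its total count over the
occupied-cell count, so enrichment (local/mean) averages exactly 1
over the occupied region and a species confined to a quarter of it is
4-fold enriched — both used as closed-form checks. 1.2- and 1.8-fold
are the conventional display cutoffs. Maps are 2-D per leaflet (the
analysis surface of top-view density figures); no volumetric
rendering.

## Composition tools

Fractions are percentages of totals; display rounding to 1 decimal,
raw values retained. The bundled SM2 table is internally inconsistent
as printed (per-species counts sum to 1120 against a printed total of
1100; the cardiolipin row's count cannot be reconciled with its
printed molar fraction); per-row masses and the printed totals are
trusted and `consistency_report()` flags the rest rather than
resolving it. The ~140:1 molar ratio for a 3:1 (w/w) reconstitution
follows under a mean lipid mass of 745 Da and a protein mass of
~34.8 kDa (His-tagged channel); the protein mass behind the published
ratio is not printed, so this is a documented assumption.

## What the synthetic data does and does not show

The generators reproduce hard-core spacing, amorphous short-range
order, chain anisotropy, aggregation, and CSR — the features the
statistics consume. They do not reproduce tip convolution, scanner
drift, long-range height gradients, pore-shape heterogeneity, or the
true (unpublished) surface densities of reconstituted membranes.
Passing tests therefore validate the estimators and their edge
corrections, not instrument-specific artefact handling, which is
explicitly out of scope. Problem sizes used in tests (n = 300 dense
fixture, n = 2000 CSR control, 25-pore detection images, 30-site
assemblies) are chosen as the smallest at which the statistics are
stable; all scale linearly or near-linearly if increased.

## Numerical choices, at a glance

| quantity | default | rationale |
|---|---|---|
| pore diameter | 4.5 nm | AFM signature of the open channel |
| hard-core spacing | 5.5 nm | pore + 1.0 nm lipid annulus; most probable inter-pore distance |
| RDF bin width dr | 0.2 nm | resolves 6 Å shell sub-structure |
| raster resolution | 0.5 nm/px | patch/annulus areas to ~1% |
| DBSCAN ε | 5.3 nm | direct-contact clustering radius (5.6 nm variant available) |
| detection thresholds | 0.8/0.6/0.45 | stringency tiers (configuration values) |
| min separation (NMS) | 4.0 nm | just under one pore diameter |
| clash/overlap cutoff | 0.47 nm | one coarse-grained bead diameter |
| first-shell cutoff | 0.8 nm | bead contact distance at the protein wall |
| rotation grid | 64 angles | 5.6° resolution, exhaustively polishable for pairs |
| occupancy grid | 2 Å | published map resolution, no smoothing |
| enrichment cutoffs | 1.2 / 1.8 | conventional display levels |
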