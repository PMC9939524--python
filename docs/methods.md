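# Methods

`zernpatch` quantifies the similarity of protein–protein interaction (PPI)
interfaces without aligning the structures.  The receptor's molecular
surface is voxelized, the interface region is cut out, covered with
overlapping circular patches, and each patch is summarized by
rotation-invariant 3D Zernike descriptors of its shape and of four
physicochemical fields.  Two interfaces are compared by putting their
patches in one-to-one correspondence and averaging per-pair distances into
a single interface score (0 = identical).

## Surface model

The solvent-excluded volume is rasterized on a cubic grid (spacing
`grid_spacing` = 0.6 Å) with a water probe (`probe_radius` = 1.4 Å):
voxels farther than *r*<sub>atom</sub> + *r*<sub>probe</sub> from every
heavy atom are probe-accessible; the accessible region connected to the
box boundary is flood-filled and dilated back by the probe radius, and
everything else — atom interiors, reentrant volume, probe-inaccessible
cavities — is protein.  Surface points are protein voxels with a solvent
voxel among their 26 neighbors.  Two numerical details matter:

* the probe dilation threshold is *r*<sub>probe</sub> + Δ/2 (Δ = grid
  spacing), compensating the systematic half-voxel underestimate of
  center-to-center distances relative to the true distance to the
  accessible region; without it a 1.7 Å atom rasterizes ~30 % too fat
  (validated against the analytic sphere volume);
* the grid origin is snapped to the global lattice of multiples of Δ, so
  voxelization commutes exactly with axis-aligned 90° rotations.

Hydrogens are parsed but excluded from every distance computation.

## Canonical frame

Before voxelization the complex is moved into a canonical frame: the
principal axes of a ramp-weighted covariance of the heavy-atom
coordinates (receptor and partner jointly), with the sign of the first
two axes fixed by the weighted third moment and the third axis completing
a right-handed system.  The ramp weight (1 … 2 over the atom sequence) is
itself invariant under rigid motion and breaks spatial symmetries that
would leave the axes degenerate.  Consequently any rigid transform of the
input lands in the *same* frame and the entire pipeline — surface, seeds,
patch counts, descriptors — is independent of the deposited pose; the
interface score between a complex and a rigidly moved copy of itself is
zero to machine precision.  This matters because greedy seed packing (see
below) is chaotically sensitive to the voxelization: re-voxelizing in a
rotated grid relocates seed sites by 2–3 Å and would otherwise leak a
spurious 0.2–0.4 into the score.  Seed coordinates are mapped back to the
input frame before being reported, so hotspot queries and hub-training
superpositions work in the caller's coordinates.  The external-map
electrostatics backend (`dx_map`) skips canonicalization because the map
is defined in input coordinates.

## Feature fields

Evaluated on surface points (interface-only where noted):

* **Electrostatic potential** — default screened Coulomb,
  φ<sub>i</sub> = Σ<sub>j</sub> q<sub>j</sub>/(ε(r)·r) with ε(r) = 4r and
  r clamped at 1 Å, on a kT/e-like scale; alternatively trilinear
  interpolation of an OpenDX map from a Poisson–Boltzmann solver.  The
  pipeline only requires a consistent field; per-patch rescaling (below)
  removes the absolute scale.
* **Hydrophobicity** — the molecular hydrophobic field
  MHP<sub>i</sub> = Σ<sub>j</sub> f<sub>j</sub>w<sub>ij</sub> / Σ<sub>j</sub>w<sub>ij</sub>,
  w<sub>ij</sub> = 1/(1 + exp(r<sub>ij</sub> − 4)), a distance-weighted
  convex combination of per-atom logP contributions f<sub>j</sub> from the
  bundled Crippen-style table (an open substitute for proprietary atomic
  logP parameterizations; any consistent per-atom scale serves).
* **Hydrogen-bond character** — +1 / −1 / 0 by the class of the nearest
  heavy atom (donor / acceptor / other; ties by lowest serial).  Atoms
  with both characters (Ser OG, His ring N, …) are classed `dual` and map
  to 0: the ±1 scheme has no slot for them and 0 is the symmetric choice.
* **Visibility** — the fraction of 512 Fibonacci-lattice rays from the
  point that escape to `ray_length` = 20 Å; 1 fully exposed, 0 fully
  buried; a local-curvature proxy.  A ray is blocked when a sample (taken
  every grid spacing) passes within `block_tol` = 0.3 Å of the protein
  *interior*, i.e. protein voxels behind the one-voxel surface shell.
  The shell itself does not block: the evaluated point sits at a voxel
  center half a voxel inside the true boundary, so shell-blocking would
  occlude grazing rays and a flat wall would see ~0.34 of the sky instead
  of the correct half; interior blocking reproduces all three anchor
  values (isolated voxel → 1, closed cavity → 0, slab face → 0.5 ± 0.02).
  Ray directions form a fixed global lattice, so visibility is invariant
  under rotation only up to direction-sampling noise (≲ 0.05 per point).
* Fields are evaluated on the full surface except visibility, which is
  evaluated on interface points only (its rays still test the full
  protein volume).

## Interface, patches, patch positions

The interface is the set of surface points strictly closer than
`interface_cutoff` = 5 Å to a heavy atom of the binding partner.  Seed
points are selected greedily — points scanned outward from the interface
centroid, accepted when more than `seed_separation` = 5 Å from every
accepted seed — and each seed's patch collects interface points within
`patch_radius` = 10 Å; patches overlap and jointly cover the interface.
Each seed's approximate patch position (APP) is a histogram (1 Å bins, 50
bins, overflow in the last) of geodesic distances to the other seeds on
the 26-neighbor interface voxel graph (Euclidean fallback across
disconnected components), normalized to unit sum so interfaces with
different seed counts remain comparable.

## Zernike descriptors

Each patch is translated so its seed is at the origin, scaled by
1/(`patch_radius` × 1.25) so points lie within radius 0.8 of the unit
ball, and splatted (nearest voxel, collisions averaged) onto a 64³ grid —
once per feature: occupancy 1 for shape; the field value for the others.
Electrostatics and hydrophobicity are divided by the patch's maximum
absolute value (floored at ε) so that all inputs lie in [−1, 1];
hydrogen-bond and visibility already do.  The function is expanded in the
Canterakis–Zernike basis Z<sub>nlm</sub> = R<sub>nl</sub>(r)Y<sub>lm</sub>(θ,φ)
up to order n = 15; the radial polynomials are evaluated through the
numerically stable Jacobi form
R<sub>nl</sub>(r) = √(2n+3) r<sup>l</sup> P<sub>k</sub><sup>(0, l+½)</sup>(2r²−1),
k = (n−l)/2 (orthonormal on [0,1] with weight r²), with real spherical
harmonics internally.  The descriptor is the vector of m-norms
F<sub>nl</sub> = √(Σ<sub>m</sub> Ω<sub>nlm</sub>²) — 72 values at order 15
— identical in the real and complex bases and invariant under rotation up
to re-voxelization error (≤ 1e-6 relative for exact 90° grid rotations,
≤ 2 % for arbitrary rotations at 64³).  The basis sampled at in-ball
voxel centers (~1 GB at 64³, order 15) is cached per process, making a
five-feature patch a single matrix product.

## Matching and the interface score

The patch distance between patches a, b is
pDist = Σ<sub>i</sub> w<sub>i</sub>‖F<sub>a,i</sub> − F<sub>b,i</sub>‖₂
over the five features, with trained weights (1.0, 0.1, 1.0, 0.3, 1.6)
for shape, electrostatics, visibility, H-bond, hydrophobicity.  APPD is
the L2 distance between APP histograms.  Matching minimizes
PatchScore = w<sub>P</sub>·avg(pDist) + w<sub>R</sub>·RMSD + w<sub>A</sub>·avg(APPD),
weights (0.7, 0.9, 1.7), by a forward auction with ε-scaling
(ε₀ = max cost/(n+1), scale 5, final ε < 1/n; bid ties to the lowest
index; rectangular problems padded square with indifferent dummy rows,
keeping the ε·n optimality guarantee).  Because the RMSD term is global
while the auction needs per-pair costs, matching iterates: assign on
w<sub>P</sub>·pDist + w<sub>A</sub>·APPD, Kabsch-superpose the matched
seeds, add w<sub>R</sub>·(per-pair deviation under the current
superposition) to the cost, re-assign until stable (≤ 10 rounds).  One or
two seed pairs cannot usefully constrain a rotation and are scored as
RMSD 0, flagged degenerate.  The smaller patch set always bids; equal
sizes are ordered by a canonical byte key of the descriptors, so the
procedure is exactly symmetric in its arguments.

The final interface score is
k<sub>P</sub>·avg(pDist) + k<sub>R</sub>·avg(dev) + k<sub>A</sub>·avg(APPD) + k<sub>S</sub>·SD
with weights (0.6, 0.1, 0.2, 0.1) and SD = |n<sub>A</sub> − n<sub>B</sub>|/max(n<sub>A</sub>, n<sub>B</sub>);
the RMSD slot uses the average of per-pair post-superposition deviations,
consistent with reading every slot as a matched-pair average.  Candidate
ranking against multiple references uses per-reference Z-scores
(population standard deviation) averaged across references, ascending.

## Weight training

Training runs on a hub dataset: proteins that bind several partners
through the same interface.  Patch pairs from two partners of a hub are
labeled corresponding when their seeds, superposed via the hub, are
within 5 Å; partner pairs with fewer than five labels are discarded and a
hub needs two retained partners.  Three grid-search stages over
0.0–2.0 step 0.1 (ties → lexicographically smallest vector; a
coordinate-descent mode trades exhaustiveness for speed):

1. feature weights — maximize the fraction of query patches whose
   minimum-pDist counterpart is labeled (queries without any labeled
   counterpart are excluded from the denominator; a query with several
   labels succeeds if its argmin is any of them).  The 21⁵ grid is
   evaluated as one chunked matrix product over precomputed per-feature
   distance tensors;
2. patch-score weights — maximize auction recovery of labeled pairs
   (denominator: all labeled pairs by default; the matched-pair
   denominator is available as an option);
3. interface-score weights — minimize the mean retrieval midrank of
   co-hub partners over all 21⁴ combinations, reusing four per-pair
   match terms computed once.  Midranks (ties share rank) prevent the
   all-zero weight vector from trivially ranking everything first.

## Synthetic fixtures

The generators build poly-alanine pseudo-proteins (5 heavy atoms per
residue, standard naming so the bundled parameter table applies) as
sphere clusters, helical spirals or slabs, with chain B lowered by
bisection until the closest heavy-atom approach equals the requested gap
(default 3 Å < the 5 Å interface cutoff).  The same spec and seed yield
byte-identical PDB output.  The hub-dataset generator uses rectangular
6×(3+h)-residue slabs — anisotropy keeps the canonical frame stable
between copies — whose partners are jittered copies (σ = 0.1 Å) of one
base slab against a fixed hub, giving known correspondences under the
identity alignment.  The designated signal feature carries an independent
uniform value per residue fixed across a hub's partners; the other scalar
channels are re-randomized per partner, so only the signal feature
identifies corresponding patches.

What the fixtures emulate is the *surface statistics* the method
consumes: a contiguous interface with room for several patch seeds and
controllable per-atom fields.  They are not physical proteins — no
side-chain chemistry, no realistic charge distribution, no
Poisson–Boltzmann electrostatics — so passing tests demonstrate the
correctness and invariances of the machinery, not biological accuracy on
real complexes.  Two fixture-scale caveats carry over to real data:
greedy seed packing relocates seed sites by a few Å under any
perturbation of the surface (conformational change, crystal-form
differences), which bounds how sharply correspondences can be recovered;
and the score's SD term makes interfaces of different patch counts
dissimilar regardless of local field agreement.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: toy complexes of 60–150 atoms (voxel grids ≲ 100³), interface
surfaces of a few thousand points, 4–22 patches per interface; the metric
suite uses 20 fixtures, the training suite a 2-hub × 3-partner dataset
(~17–22 patches per partner, ≥ 40 labeled pairs per partner pair).
Auction optimality is checked on 500 random instances up to 6×6 against
exhaustive permutation.  These sizes were chosen so a full run completes
in minutes on a single core while every code path — including the 21⁵
exhaustive stage-1 search — is exercised at full grid resolution
(0.6 Å, 64³ Zernike grids, order 15).

## Known limitations

* Voxel geodesics overestimate true surface geodesics by up to the usual
  26-neighbor metric error (~8 %); histograms use 1 Å bins, which absorbs
  most of it.
* The screened-Coulomb backend is a stand-in on an arbitrary scale; for
  publication-grade electrostatics supply an OpenDX map.
* The auction is ε-optimal, not exact: assignments can differ from the
  Hungarian optimum by up to ε·n in cost (ε < 1/n), which is negligible
  against typical patch-distance scales but not zero.
* Patch counts, and hence SD, depend on the greedy seed packing; two
  interfaces of identical area can differ by ±1–2 seeds.
* Non-standard residues and ligands (HETATM) are excluded at parse time;
  parameter lookups for unknown (residue, atom) pairs fall back to
  neutral defaults with a warning count.
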