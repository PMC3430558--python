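# Methods

## Problem and model

Flexible macromolecules (hinge proteins, multi-domain enzymes, motor
proteins) change shape as part of their function. Rigid-body shape
comparison scores two conformers of the same molecule as different
shapes, because Euclidean (chord) distances between surface points
shrink when the molecule articulates. The *inner distance* between two
surface points — the length of the shortest path connecting them that
stays inside the molecular volume — is nearly unchanged by
articulation: a path through a hinge follows the bent axis rather than
the chord. The package's central object, the **inner-distance shape
signature (IDSS)**, is the probability density of inner distances
between all pairs of uniformly sampled surface landmarks, stored as a
128-bin histogram. Comparing two molecules reduces to comparing two
PDFs with the Minkowski L1 norm, mapped to a similarity

    s(a, b) = 1 − ‖a − b‖₁ / 2  ∈  [0, 1],

since two PDFs are at most 2 apart in L1. Retrieval quality over a
database with conformational group labels is summarized by
group-averaged precision-recall curves and their trapezoidal AUC, and
the whole database is embedded for navigation by classical
multidimensional scaling (MDS) of the pairwise 1 − s matrix.

## Pipeline and parameters

1. **Volume model.** One PDB chain is read (waters always excluded,
   HETATM excluded by default; Bondi vdW radii H 1.20, C 1.70, N 1.55,
   O 1.52, S 1.80, P 1.80, default 1.70 Å). The solvent-excluded
   (Connolly) volume is approximated on a uniform lattice by a
   morphological closing: mark voxels within `radius + probe` of any
   atom, erode by `probe` via a Euclidean distance transform, keep the
   largest 26-connected component. Defaults `h = 1.0 Å`,
   `probe = 1.4 Å` (a water-sized probe), lattice capped at 96³ with
   automatic `h` rescaling. The closing converges to the analytic
   solvent-excluded volume as `h → 0`; at 1 Å it reproduces analytic
   sphere volumes to within a few percent. The union with the on-lattice
   vdW set is enforced after erosion so that the closing is always a
   superset of the probe-0 volume.
2. **Surface and landmarks.** Surface voxels are occupied voxels with
   an unoccupied 6-neighbor. `n = 128` landmarks (8128 pairs) are
   spread over them by Lloyd relaxation (assign surface voxels to the
   nearest site by ambient Euclidean distance, move each site to the
   surface voxel nearest its cluster centroid, at most 20 rounds,
   seeded initialization). 128 landmarks keep the histogram's sampling
   noise below the between-shape distances we need to resolve while a
   full descriptor stays under a second of compute for desk-scale
   solids; the count is configurable.
3. **Inner distances.** Paths run through the full occupied volume
   (interior included) on the 26-neighbor graph with Euclidean edge
   weights h, h√2, h√3; one Dijkstra sweep per landmark. The
   26-connectivity metrication error overestimates straight-line
   distances by at most ~8% (worst direction), which slightly stretches
   inner distances relative to chords even on convex solids.
4. **Signature.** The 8128 values are histogrammed into `B = 128` bins
   over `[0, d_max]` and normalized to sum 1. Default range mode is
   `per_shape_max` (`d_max` = largest observed inner distance), which
   makes the signature scale-invariant; `fixed_range` (caller-supplied
   `d_max`) is provided for size-sensitive databases.

## Baseline descriptors

- **D2** — chord-length PDF over the same Lloyd landmarks.
- **SD** — chord-length PDF over 10 000 uniform random surface voxel
  pairs (seeded); the random-pair variant of the shape-distribution
  idea, converging to the dense chord distribution.
- **GD** — shortest-path PDF restricted to the surface-voxel subgraph
  (geodesics along the shell rather than through the volume); raises if
  the subgraph disconnects a landmark pair.
- **SHD** — rotation-invariant spherical-harmonic shell energies:
  binary occupancy sampled on 32 concentric spheres about the occupancy
  centroid using a 64-point Gauss–Legendre × 128-point uniform
  longitude grid, per-degree energies ‖f_l‖ for l ≤ 16, concatenated
  and L2-normalized. The quadrature is exact for the band limit, so a
  constant shell (fully interior to a ball) has zero l ≥ 1 energy to
  machine precision. Exact invariance holds for symmetry operations
  that map the sampling grid onto itself (polar 90° rotations, axis
  flips); arbitrary rotations are stable only up to resampling error.
- **SAH** — solid-angle concavity histogram: for every surface voxel,
  the occupied fraction of a radius-4-voxel ball centered there
  (≈ local solid angle: 1/2 on flat patches, lower on spikes, higher in
  pockets), histogrammed over [0, 1].

D2 vs SD keeps the two chord-based variants distinct: D2 uses the
deterministic Lloyd landmark set, SD uses seeded random pairs.

## Synthetic study shapes

Real conformer families (flexible-molecule benchmarks) are emulated by
articulated capsules: a tube of length L and radius r hinged at its
midpoint, each arm deflected by half the bend angle, so the bent tube
is the same solid as the straight one up to the elbow overlap (volume
preserved within ~10% at 60°). Spheres and dumbbells (two lobes plus a
cylindrical neck) serve as rigid distractors. A seed draws a uniform
random 3D orientation before voxelization, so replicate conformers are
not lattice-aligned copies.

The retrieval benchmark is 4 families × 5 conformers (bend angles 0°
to 90°) plus 10 distractors treated as singleton groups. All four
families share tube radius 3 and differ only in length (48, 34, 24,
17): family identity is then a purely global property. This matters for
what the benchmark can show — with per-family radii, a local curvature
descriptor (SAH) can identify families from a rigid local feature and
the benchmark stops probing deformation-invariant *global* shape
retrieval, which is its purpose. On the final design the inner-distance
signature reaches mean AUC ≈ 0.7 and every rigid baseline stays at or
below ≈ 0.6 across replicate seeds.

What the generator does **not** emulate: atomic-scale surface texture,
cavities and tunnels, side-chain-level flexibility, non-hinge (shear or
twist) motions, and crystallographic noise. Passing tests therefore
demonstrate the geometric mechanism of deformation invariance, not
retrieval performance on real protein databases.

## Evaluation protocol

Every database member queries all others (self excluded); ties break
lexicographically by id. Precision is recorded at each relevant
retrieval (recall j/R, R = group size − 1), linearly interpolated onto
the 20-level recall grid {0.05, …, 1.0}, averaged within each group,
then across groups (unweighted). Singleton groups are excluded as
queries with a warning but remain in the rankings as distractors. AUC
prepends the recall→0 value by constant extrapolation and integrates by
trapezoid, so a precision-1 curve integrates to exactly 1. For random
rankings the interpolated average is biased above the relevant-item
fraction at low recall; the tail (recall ≥ 0.5) approaches the
fraction, which is how the null model is validated.

## Navigation maps

Classical (Torgerson) MDS on D = 1 − S: double-center −½ J D² J, take
the top-d eigenpairs with positive eigenvalues (d ∈ {2, 3}), zero-pad
with a warning if fewer exist. Each axis's sign is fixed so its
largest-magnitude coordinate is positive, making the embedding
deterministic and order-independent. The reported stress is
√(Σ(d̂ᵢⱼ−dᵢⱼ)²/Σdᵢⱼ²); because classical MDS nests solutions, adding an
axis never increases it. Classical scaling was chosen over iterative
stress majorization for determinism; for the small indexed databases
this package targets, the eigendecomposition is exact and instant.
Group colors come from a fixed 20-color qualitative palette in group
order.

## Numerical choices and degenerate inputs

- Histograms divide integer counts by the pair count: sums are 1 to
  1e-9 by construction; an empty distance set or a `fixed_range`
  smaller than the largest observed value is an error.
- Lloyd site collisions (two centroids mapping to one voxel) are
  resolved by keeping the earlier site and moving the duplicate to the
  nearest free surface voxel; sites are returned in lattice order so a
  fixed seed gives a canonical set.
- A single-voxel grid yields a graph with no edges; descriptor
  construction requires ≥ 2 landmarks and says so.
- Disconnected occupancy is rejected at graph construction; the
  voxelizer prevents it by keeping the largest component.
- Distance matrices for MDS must be symmetric, non-negative,
  zero-diagonal (checked to 1e-10).

## Known limitations

- The worked protein-pair comparisons require the four RCSB entries
  (1aon, 1irk, 1j5n, 1lwm); the corresponding check fails with an
  explanatory message when the files are not present under
  `tests/data/pdb/`, and the original work does not state the lattice
  resolution, probe radius or landmark count behind its printed scores,
  so only the ordering and rough magnitudes are expected to reproduce.
- 26-connectivity metrication stretches inner distances up to ~8%
  direction-dependently; on convex solids IDSS and D2 therefore differ
  by a systematic few-percent scale factor rather than coinciding.
- At 128 bins, histogram sampling noise between two independent
  landmark draws of the *same* shape is ~0.2 in L1; distances below
  that are not meaningful at the default landmark count.
- Bends up to 90° leave chord distributions of slender tubes closer to
  the straight tube than to a volume-matched ball, so the chord (D2)
  descriptor, while clearly worse at ranking (AUC), does not confuse a
  90°-bent rod with a sphere outright; outright confusion appears only
  at hairpin-like bends.
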