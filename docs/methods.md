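# Methods

This note documents the models, numerical choices and limitations behind
`conjmap`. Units are nm for lengths, nm² for areas, kT (or kJ/mol with
k_B = 0.0083145 kJ mol⁻¹ K⁻¹) for free energies.

## Conjugate model and residue-wise minimum distances

A conjugate is two covalently linked subunits (distal / proximal, in the
ubiquitin-dimer convention: the distal moiety contributes its C-terminus to
the linkage). Each residue has exactly one *backbone site* — the Cα atom in
atomistic structures, the backbone bead in coarse-grained ones — so every
descriptor is identical across resolutions. The analysis range defaults to
residues 1–72 per subunit (the flexible ubiquitin tail 73–76 is excluded
from descriptors but kept for SASA); with two 72-residue ranges the RMD
vector has 144 entries: per distal backbone site the minimum Euclidean
distance to the proximal backbone sites, then the symmetric proximal
block. Distances are plain Euclidean by default; a minimum-image mode
exists for trajectories where the conjugate might straddle the periodic
box, but a covalently linked pair in a well-set-up run does not, so the
default avoids silently remapping broken molecules. The two blocks share
their global minimum (both equal the closest inter-subunit backbone
contact), which the tests use as a structural sanity check.

## Sketch-map

Sigmoid transform: F(r) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a}, with
F(0) = 0, F(σ) = 1/2, F → 1. Defaults σ = 5.9 (on the nm scale of raw RMD
vectors — no whitening or rescaling is applied to the descriptors),
A = 12, B = 4 in high dimension and a = 2, b = 4 in the map. The steeper
high-dimensional transform compresses distances far beyond σ and ignores
those far below it, focusing the embedding on the intermediate range where
conformational basins separate.

Landmark selection mixes seeded uniform picks with greedy farthest-point
("minmax") selection: ⌈γN⌉ random landmarks first, the remainder each
maximizing its minimum distance to the set so far; γ = 0 starts from the
globally most distant pair so the map's extremes are always represented.
The exact staging of the random/minmax mix in the original sketch-map
implementations is not uniquely documented; this rule is our documented
interpretation, chosen for determinism and simplicity. Landmark weights
count the input rows nearest to each landmark; they enter the stress as
w_i·w_j and can be disabled (`use_weights=False`).

The stress χ² = Σ_{i<j} w_i w_j [F_hd(R_ij) − F_ld(r_ij)]² is minimized
over the 2N landmark coordinates by L-BFGS with the analytic gradient,
initialized from classical (Torgerson) MDS of the F_hd-transformed
distances rescaled to the σ scale (MDS of values in [0, 1) would otherwise
start the map in the flat region of F_ld). Optional seeded restarts
perturb the initialization; the best result is kept, and the returned
stress is never above the initialization's. Convergence tolerance is a
relative stress change of 10⁻⁶ (`tol`), `max_iter` 1000; hitting the
iteration cap returns the best configuration with `converged=False`
rather than raising. Stress is invariant under rotation, translation and
reflection of the map, so coordinates are reproducible only up to a rigid
motion across library versions — but bit-identical for identical inputs
and seeds.

Out-of-sample placement minimizes the same mismatch against the fixed
landmarks: a vectorized scan over a grid covering the padded landmark
bounding box (spacing 1% of the box by default) followed by gradient
descent with per-point backtracking. The placement objective is non-convex;
the grid stage exists precisely to avoid local traps, and duplicated input
rows are solved once and scattered back, which both guarantees identical
placements for identical frames and makes low-entropy ensembles cheap.

## Free-energy landscapes

Projected points are histogrammed (default 100×100 over the padded
bounding box; a `bin_width` option produces square bins, which matters for
strongly anisotropic maps where per-axis bin counts would slice basins
thinner along one axis); the density is Boltzmann-inverted F = −kT ln p
and shifted so the lowest populated bin is zero. Local minima are
populated bins strictly below all populated 8-neighbors; flat plateaus
(exactly tied values, which happens with tied counts) are counted once at
their centroid bin. Bins with fewer than 2 samples (configurable) are
treated as unpopulated before minima detection to suppress single-sample
noise minima. Basin representatives: per minimum the nearest projected
frame plus n_random frames drawn uniformly (seeded) within a radius; the
default 4 minima × (1 + 10) frames mirrors the conventional selection of
CG structures for atomistic re-simulation.

## Landscape comparison

EMD between two normalized 2D histograms is computed as an exact
transportation LP (HiGHS) over the *populated* bins only, with Euclidean
ground distance between bin centers — so the cost of the solve scales with
the occupied area, not the grid. Oversized supports can be coarsened by
bin aggregation (logged); entropic approximations are deliberately not
used for reported values. With a metric ground distance EMD is a metric
(identity, symmetry, triangle inequality are property-tested), so the
pairwise matrix embeds meaningfully with classical MDS; the arrangement is
centered and sign-fixed (first system non-negative on each axis) for
determinism. Max-normalization divides by the largest off-diagonal entry,
making the most dissimilar pair exactly 1.0; an all-zero matrix skips
normalization with a warning. Comparison operates on projected densities,
not on FES values.

## SASA and interface analysis

Shrake–Rupley with a deterministic Fibonacci sphere lattice (960 points
per sphere by default; single-sphere areas are then exact to well under
1%, two-sphere overlaps to ~0.1%). Probe radius defaults: 0.14 nm
(atomistic), 0.21 nm (coarse-grained); radii come from a Bondi-style
element table atomistically and a uniform 0.23 nm bead radius for CG, all
overridable — bead-specific CG radii are configuration, not fixed truth.
Polarity: N/O (with attached H, inferred from PDB ordering) polar, C/S
apolar; CG beads by name-prefix class.

The interface area uses the same-frame isolated subunit as reference:
SA_interface = SASA_distal + SASA_proximal − SASA_conjugate, computed
per-particle as (isolated − in-conjugate) burial. Because the identical
point lattice is used in both evaluations and removing particles can only
uncover points, per-particle burial is non-negative *exactly*, the
apolar/polar split partitions SA_interface exactly, and the per-residue
ΔSASA profile sums to SA_interface per frame — accounting identities the
tests assert at 10⁻⁹ nm². (A clamp for tiny negative totals exists for
configurations where differing lattices are supplied externally.) ΔSASA
error bars are the standard deviation of per-run means over independent
runs. Patch accessibility divides a patch's SASA in the conjugate by its
SASA in the reference monomer — by default the same-frame isolated
subunit, optionally a user-supplied per-residue table (e.g. from a
monomer simulation); fractions are averaged over frames and clipped to
[0, 1]. Shipped patch definitions (Ile44: {8, 44, 68, 70}; Ile36:
{36, 71}; Phe4: {2, 4, 14}; TEK box: {6, 11, 12, 14, 34}) follow common
literature usage and are editable configuration — residue 73+ members are
excluded along with the tail.

## Synthetic ensembles

The generator emulates what a long CG simulation of a two-domain conjugate
delivers to this analysis: frames drawn from a small set of conformational
basins with prescribed occupancies. Subunits are compact self-avoiding
backbone-site chains (bond 0.38 nm, minimum site separation 0.35 nm,
centroid-biased growth giving sublinear radius-of-gyration scaling);
basins are rigid poses of the proximal subunit docked at contact distance
(0.4 nm clearance) along distinct directions with distinct rotations, with
isotropic Gaussian site noise of 0.05 nm by default — the scale of CG
backbone jitter within a basin. Frames exceeding an optional linker-length
cap are resampled; ground-truth basin labels are emitted alongside so
tests never re-infer them.

What the generator does *not* emulate: transition paths between basins
(frames are i.i.d. mixture draws, so landscapes have empty gaps rather
than saddles), internal subunit flexibility beyond isotropic jitter,
time correlation, and force-field physics. Passing tests therefore
demonstrate the correctness of the analysis chain on its stated
assumptions, not the realism of any particular ensemble.

### Parameter-recovery experiments

Two experiments anchor the end-to-end tests and the acceptance script.

*Occupancy recovery.* A 0.7/0.3 two-basin ensemble at 10⁵ frames, run
through the full chain, must yield two FES minima whose depth difference is
−kT ln(3/7) within 3σ of binomial counting error. This experiment uses
rigid (zero-noise) basins: with positional noise, each basin's peak height
acquires a factor from the local Jacobian of the descriptor-to-map
transform — a property of the embedding geometry, not of the occupancies —
so the clean test of the Boltzmann-inversion arithmetic holds the ensemble
rigid, where every basin concentrates in a single bin and bin mass equals
occupancy exactly. The landmark count for this experiment is 50 (two
distinct descriptor vectors exist; more landmarks are redundant).

*Minima counting.* A 0.5/0.3/0.2 three-basin ensemble at 10⁵ frames with
the default 0.05 nm noise must produce exactly three detected minima. Here
the histogram uses square bins of one tenth of the occupied x-span, wide
enough that a basin's noise cloud does not fragment, and 150 landmarks —
desk-scale analysis defaults for a 10⁵-frame single-system map (the
library default of N = 2000 landmarks targets multi-system campaigns).

## Pipeline

`run_pipeline` pools the RMDs of all configured systems, fits one shared
map (landmarks from the pool, as a multi-system comparison requires common
coordinates), projects each system, builds densities on a common extent,
and reports minima, basin frames, the normalized EMD matrix with its MDS
arrangement, and interface statistics. Every stochastic stage requires an
explicit seed at validation time; reports are JSON with sorted keys so
identical configurations reproduce byte-identical payloads, and a
provenance file records versions, seeds, parameters and input hashes.
Sampling-plan bookkeeping (`SimulationPlan`) multiplies conformations ×
replicas × duration exactly and rounds only at display (2 significant
figures).

## Known limitations

- Sketch-map stress is non-convex; different seeds can reach different
  (near-degenerate) embeddings. Restarts mitigate but do not eliminate
  this.
- Out-of-sample placement quality degrades for points far outside the
  landmark hull (the grid covers the padded landmark bounding box only).
- Exact EMD on densely populated large grids is expensive; coarsening
  trades resolution for tractability and is logged when applied.
- FES depths from histograms are resolution-dependent wherever basin
  widths differ; depth *differences* equal occupancy log-ratios only when
  bins are commensurate with basins (see parameter-recovery notes above).
- The SASA polarity assignment for hydrogens relies on PDB atom ordering;
  explicit per-particle polarity tables override it.
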