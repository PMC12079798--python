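# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what its synthetic tests do and do not demonstrate.

## Dual-parameter Vietoris–Rips filtrations

The structural input is an alpha-carbon cloud: one point per residue with
a chain label and an author residue number (angstrom coordinates).  Author
numbering is used as-is; numbering gaps are respected, so residue distance
is |r₁ − r₂| on the numbers themselves, not on list positions.  Between
chains the residue distance is the constant R_inter = R + 1, where R is
the largest within-chain residue distance in the cloud (for a two-chain
Fc-type construct with 206 residues per chain, R = 205 and R_inter = 206).

For each ρ = 1 … R_inter the dissimilarity between two atoms is their
Euclidean distance when their residue distance is ≤ ρ and a sentinel M
otherwise.  M must exceed every scale at which persistence is computed so
that forbidden pairs never enter any complex; the default is the
persistence cutoff + 10 Å (any value strictly above the cutoff is
equivalent — the pad only fixes a reproducible choice).  Matrices for
successive ρ are built incrementally by unmasking newly admissible pairs;
a from-scratch path exists and the two are compared element-wise in
regression tests at 1.0001 × 10⁻¹⁰.

Because admissible pairs only grow with ρ, the filtrations are nested in
ρ for every ε, and ρ = R_inter is the classical Vietoris–Rips filtration
on Euclidean distances.

## Persistent homology

No dedicated persistent-homology library is part of this package's
dependency set; the computation is authored here, twice, by design:

* **Production engine** (`rips_barcode`): dimension 0 by a union-find
  sweep over edges in filtration order; dimensions ≥ 1 by boundary-matrix
  column reduction over GF(2) with the twist/clearing optimization,
  processed top-down, columns stored as arbitrary-precision integer
  bitsets.  Simplices are ordered by (filtration value, vertex tuple),
  which makes ties deterministic and the output independent of input
  point order.
* **Oracle** (`brute_force_barcode`): explicit enumeration of all
  simplices up to one dimension above the requested one and classical
  left-to-right reduction of the full dense boundary matrix.  Limited to
  15 points; it exists solely as an independent cross-check and is held
  to multiset equality with the engine on randomized instances.

Conventions shared by both: coefficients in the two-element field; every
class alive at the cutoff gets death = cutoff (including the everlasting
component in dimension 0, so dimension-0 curves are well defined);
zero-length bars [b, b) are empty intervals and are discarded.  The
full-scale cutoff convention is max(grid) + 0.001 Å.

## Gaussian Betti vectors

The Betti number β_k(ε) counts bars with b ≤ ε < d.  Its smooth surrogate
centers an isotropic bivariate Gaussian of scale σ at each diagram point
(b, d) and integrates the sum over the same region {x ≤ ε < y}, giving
per unit-weight bar Φ((ε − b)/σ)·Φ((d − ε)/σ) ∈ [0, 1].  This closed form
is verified against numerical double integration in the tests.  Gaussians
are not truncated or renormalized near the diagonal or at zero.  A
nonnegative weight w(b, d) may scale each bar's term (w ≡ 1 default;
birth-, death-, and lifetime-based weights are accepted as callables).
As σ → 0 the vector converges to the Betti vector away from bar
endpoints; smoothing strictly reduces total variation.

The multi-dimension summary concatenates the dimension-0, 1, 2 vectors,
each divided by its own bar count so differently scaled curves are
comparable; an empty diagram contributes a zero block (0/0 := 0, the only
choice continuous in the empty limit).

## Grid selection and matrix assembly

The shared ε grid is chosen from data: classical dimension-1 barcodes of
a sample of frames; floor the minimal birth and ceil the maximal death to
integers; extend both ends by 4σ_max (σ_max = 0.5 Å by default, giving
the 2 Å buffer); clamp the lower end at one grid spacing.  Fc-scale
inputs with births flooring to 3 Å and deaths ceiling to 28 Å yield the
1–30 Å window.  The default spacing is 0.1 Å (291 rows over 1–30 Å):
fine enough to resolve observed bar lengths while keeping matrices small;
row count is a configurable choice, not part of the method.

Each CROCKER column is computed from its own filtration — smoothing acts
only along ε, never across ρ, and no persistence is tracked across ρ.
GCCD differencing keeps the first column and subtracts successive ones;
cumulative summation inverts it exactly (pure floating-point telescoping,
tested at 1.0001 × 10⁻¹⁰ alongside the identity that the summed GCCD
columns equal the independently computed full-cloud vector).  Saved CSV
matrices round to ten decimal places; rows are ε ascending, columns ρ
ascending.

## Classification protocol

Per frame, the flattened (ε-major) GCCD matrix — or a spatial-only
Gaussian Betti summary — is one feature vector.  k-NN uses Euclidean
distances with an odd k; distance ties break by (trajectory_id,
frame_index) so predictions are reproducible (the hand-rolled vote is
cross-checked against scikit-learn's classifier in tests).  For a 4 + 4
trajectory study, each of the 16 test splits holds out one trajectory per
class; hyperparameters (σ, k) are selected inside the 3 + 3 training set
by the 9 leave-one-trajectory-pair-out validation splits, maximizing mean
validation accuracy with ties going to the smallest σ then the smallest
k (bias toward less smoothing).  Test frames never reach the search.
The σ grid default is {0.125, 0.25, 0.5} Å — its maximum pinned by the
4σ_max grid buffer — and the k grid default is {15, 25, 35, 45}; both
are user-configurable, and the synthetic studies here use small odd k
values matched to their frame counts.  MDS embeddings use the metric
variant on precomputed summary distances (classical initialization); PCA
reports explained-variance ratios.

## Synthetic fixtures: what they emulate, and what not

The generators produce multi-chain clouds with planted, analytically
known topology:

* **Chain loop**: n points on a circle, one chain, zig-zag residue
  numbering (odd residues up one side, even down the other) so every
  spatially adjacent pair differs by ≤ 2 in residue number; for a planted
  gap g ≥ 3 the top residue is shifted so exactly one polygon edge
  requires residue distance g.  Distinct residue numbers make closure at
  residue distance 1 impossible (that graph is a path), so g = 1 is
  accepted but realizes the earliest achievable closure, g = 2.  Exact
  gap localization holds when the analysis window stays below the
  polygon's second-chord scale (above it, transient chord cycles at large
  ε can deposit mass in earlier columns); tests and the acceptance script
  use such windows.
* **Two-chain ring**: 2n points on a circle split into two
  consecutively numbered arcs.  Within-chain complexes are clique
  complexes of path powers — contractible at every scale — so all
  within-chain GCCD columns are exactly zero and the ring's mass sits
  solely in the inter-chain column, with no window restriction.
* **Labeled studies**: two conditions whose ring edge lengths differ by
  `class_effect` Å, several trajectories per condition (each with an
  independent starting-structure jitter), frames differing by i.i.d.
  isotropic Gaussian coordinate noise.  Defaults (4 trajectories per
  class, ~10 frames, 12-point clouds, 0.05–0.06 Å noise) keep the full
  16-split evaluation fast while exercising every stage of the protocol.

These fixtures are topological test objects: they have no bond-length,
steric, or secondary-structure realism, and their class signal is a
single global scale difference.  Passing tests therefore demonstrate the
correctness of the machinery — filtration construction, persistence,
vectorization, differencing, split hygiene — not classification power on
real MD ensembles, whose feature differences are subtler and
higher-dimensional.

## Degenerate inputs and edge cases

Empty atom selections, mismatched trajectory rosters (reported with the
offending frame index), even k, σ ≤ 0, ρ outside [1, R_inter], and a
sentinel M at or below the cutoff all raise typed errors.  Altloc atoms
keep the blank or 'A' conformer with the highest occupancy (deterministic
tie-break); insertion codes are assumed absent in analyzed ranges.  A
cloud too small to carry any cycle yields empty barcodes, zero vectors,
and an all-zero GCCD matrix rather than an error; automatic grid
selection on such a sample is an error, since no scale information
exists.

## Known limitations

The persistence engine is pure Python/NumPy and comfortable up to a few
dozen points per cloud across hundreds of filtrations; full-size antibody
domains (hundreds of residues × R_inter filtrations) are beyond its
intended scale, and a compiled persistent-homology backend would slot in
behind `rips_barcode` without changing any contract.  Cycle
representatives are deliberately out of scope (representative choice is
software-dependent); only barcodes are consumed downstream.
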