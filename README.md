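# gccd — Gaussian CROCKER column differences

Topological summaries of multi-chain biomolecular structures that combine
**spatial** and **sequential** information, with a downstream k-nearest-neighbor
classification protocol for molecular-dynamics conformations.

## The problem

Persistent homology of an alpha-carbon point cloud quantifies loops and
tunnels (dimension-1 features) across all spatial scales at once, but it is
blind to the protein's sequence: a loop closed by residues adjacent in the
chain and a loop closed across two chains of a dimer look the same.  For
multi-chain proteins such as antibody Fc domains — where glycosylated and
aglycosylated simulations are nearly indistinguishable by standard
descriptors — that sequential context carries the signal.

## The method

For a cloud of alpha carbons with chain labels and author residue numbers,
define the *residue distance* between two atoms as |r₁ − r₂| within a chain
and a fixed sentinel value R_inter = R + 1 between chains (R the largest
within-chain residue distance).  For each residue distance ρ = 1 … R_inter,
a dissimilarity matrix

d_ρ(a₁, a₂) = ‖x₁ − x₂‖ if the residue distance ≤ ρ, else M (a large value)

defines a Vietoris–Rips filtration; ρ = R_inter recovers the classical
filtration on Euclidean distances alone.  Each filtration's dimension-k
barcode {[bᵢ, dᵢ)} is smoothed into a **Gaussian Betti vector** on a shared
regular ε grid,

g_σ(ε) = Σᵢ w(bᵢ, dᵢ) · Φ((ε − bᵢ)/σ) · Φ((dᵢ − ε)/σ),

the mass of isotropic Gaussians centered at the diagram points over the
region {x ≤ ε < y} counted by the Betti number β_k(ε) (default weight
w ≡ 1).  Stacking these vectors column-by-column over ρ gives the
**Gaussian CROCKER matrix**; differencing successive columns gives the
**GCCD matrix**, which localizes every class of cycles at the residue
distance where it first emerges.  Cumulative sums invert the differencing
exactly, and the row-wise sum of all GCCD columns is the classical
Gaussian Betti vector of the full cloud.

Flattened GCCD matrices are features for k-NN classification with
trajectory-level train/test splits (one trajectory per class held out;
16 splits for a 4 + 4 study) and a nested 9-fold leave-one-trajectory-pair-out
grid search over (σ, k).

Persistent homology is computed in-package over GF(2) (union-find for
dimension 0, twist/clearing boundary reduction for dimensions ≥ 1) and is
cross-checked against an independent brute-force simplex-enumeration oracle.

## Worked example

```python
import numpy as np
from gccd import (EpsilonGrid, make_two_chain_ring, gaussian_crocker,
                  gccd_from_crocker, rips_barcode)
from gccd.filtration import euclidean_matrix

# two chains forming one ring: the loop needs inter-chain connections
ring = make_two_chain_ring(n_per_chain=8, radius=2.0)

bc = rips_barcode(euclidean_matrix(ring), {1}, cutoff=4.001)[1]
print("full-cloud dimension-1 barcode:", bc.bars)

grid = EpsilonGrid.regular(0.1, 4.0, 0.1)
G = gccd_from_crocker(gaussian_crocker(ring, grid, sigma=0.25))
print("GCCD column masses (rho = 1..8):", np.round(np.abs(G.values).sum(axis=0), 3))
```

prints

```
full-cloud dimension-1 barcode: [[0.78036129 3.69551813]]
GCCD column masses (rho = 1..8): [ 0.     0.     0.     0.     0.     0.     0.    29.065]
```

The 16-point ring has a single loop born at the polygon edge length
(0.78 Å) that survives until the triangle-fill scale (3.70 Å).  Every
within-chain GCCD column is exactly zero — each chain alone is an arc with
no cycles at any scale — and the loop's entire Gaussian mass sits in the
final, inter-chain column (ρ = 8 = R_inter), which is precisely the
sequential localization the matrix is designed to expose.

A command-line interface mirrors the library
(`gccd fixtures | grid | crocker | gccd | classify | embed`); see
`gccd --help`.

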