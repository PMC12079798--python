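"""Dual-parameter dissimilarity matrices for Vietoris-Rips filtrations.

For each residue distance rho, the dissimilarity between two alpha carbons
is their Euclidean distance if their residue distance is at most rho, and
a large sentinel M otherwise.  Residue distance is the absolute difference
of author residue numbers within a chain, and a fixed value R_inter = R + 1
between chains (R being the largest within-chain residue distance), so that
rho = R_inter recovers the classical Vietoris-Rips filtration on Euclidean
distances alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError
from .structure_io import AlphaCarbonCloud, AlphaCarbonRecord

DEFAULT_M_PAD = 10.0  # angstroms beyond the persistence cutoff


@dataclass(frozen=True)
class ResidueDistanceScheme:
    """Largest within-chain residue distance R, and R_inter = R + 1."""

    max_within: int

    def __post_init__(self):
        if self.max_within < 1:
            raise ParameterError("max_within must be >= 1")

    @property
    def inter_chain_value(self) -> int:
        return self.max_within + 1

    @classmethod
    def from_cloud(cls, cloud: AlphaCarbonCloud) -> "ResidueDistanceScheme":
        """R = max over chains of (last - first author residue number)."""
        r = 0
        for cid in cloud.chain_order:
            res = cloud.residue_numbers[cloud.chain_ids == cid]
            r = max(r, int(res.max() - res.min()))
        if cloud.n_chains == 1 and r < 1:
            raise ParameterError("cloud has a single residue; no residue distances")
        return cls(max_within=max(r, 1))


@dataclass
class DissimilarityMatrix:
    """Square symmetric matrix of Euclidean distances / sentinel M values."""

    values: np.ndarray
    rho: int
    M: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ParameterError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ParameterError("dissimilarity matrix must have zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def residue_distance(
    a: AlphaCarbonRecord, b: AlphaCarbonRecord, scheme: ResidueDistanceScheme
) -> int:
    """|r_a - r_b| within a chain; scheme.inter_chain_value across chains."""
    if a.chain_id == b.chain_id:
        return abs(a.residue_number - b.residue_number)
    return scheme.inter_chain_value


def residue_distance_matrix(
    cloud: AlphaCarbonCloud, scheme: ResidueDistanceScheme
) -> np.ndarray:
    """Integer matrix of pairwise residue distances for a whole cloud."""
    res = cloud.residue_numbers
    rd = np.abs(res[:, None] - res[None, :])
    same = cloud.chain_ids[:, None] == cloud.chain_ids[None, :]
    rd = np.where(same, rd, scheme.inter_chain_value)
    np.fill_diagonal(rd, 0)
    return rd.astype(int)


def euclidean_matrix(cloud: AlphaCarbonCloud) -> np.ndarray:
    return squareform(pdist(cloud.coords))


def choose_M(epsilon_max: float, pad: float = DEFAULT_M_PAD) -> float:
    """Sentinel strictly beyond the largest scale at which PH is computed."""
    if epsilon_max <= 0:
        raise ParameterError("epsilon_max must be positive")
    if pad <= 0:
        raise ParameterError("pad must be positive")
    return epsilon_max + pad


def build_dissimilarity(
    cloud: AlphaCarbonCloud,
    rho: int,
    M: float,
    scheme: ResidueDistanceScheme,
) -> DissimilarityMatrix:
    """Euclidean distances where residue distance <= rho, else sentinel M."""
    if not 1 <= rho <= scheme.inter_chain_value:
        raise ParameterError(
            f"rho must lie in [1, {scheme.inter_chain_value}], got {rho}"
        )
    euc = euclidean_matrix(cloud)
    if M <= euc.max():
        raise ParameterError(
            "M must exceed every admissible Euclidean distance "
            "(connections at dissimilarity M must be effectively forbidden)"
        )
    rd = residue_distance_matrix(cloud, scheme)
    values = np.where(rd <= rho, euc, M)
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(values=values, rho=rho, M=M)


def iter_dissimilarities(
    cloud: AlphaCarbonCloud,
    M: float,
    scheme: ResidueDistanceScheme,
):
    """Yield (rho, DissimilarityMatrix) for rho = 1 .. R_inter, incrementally.

    The Euclidean and residue-distance matrices are computed once; each step
    unmasks the pairs newly admissible at that rho.  Identical to calling
    :func:`build_dissimilarity` per rho.
    """
    euc = euclidean_matrix(cloud)
    if M <= euc.max():
        raise ParameterError("M must exceed every admissible Euclidean distance")
    rd = residue_distance_matrix(cloud, scheme)
    values = np.full_like(euc, M)
    np.fill_diagonal(values, 0.0)
    for rho in range(1, scheme.inter_chain_value + 1):
        newly = rd == rho
        values[newly] = euc[newly]
        yield rho, DissimilarityMatrix(values=values.copy(), rho=rho, M=M)
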