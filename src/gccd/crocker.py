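"""Gaussian CROCKER matrices over (epsilon, rho) and their column differences.

A Gaussian CROCKER matrix has one column per residue distance
rho = 1 .. R_inter; column rho is the Gaussian Betti vector of the
Vietoris-Rips barcode of the rho-restricted dissimilarity matrix,
evaluated on a shared regular epsilon grid.  Smoothing acts only along
epsilon; residue distances are discrete and each column's persistence is
computed from its own filtration.  Differencing successive columns gives
the GCCD matrix, which localizes each class of cycles at the residue
distance where it first emerges; cumulative sums invert the differencing
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError
from .filtration import (
    DissimilarityMatrix,
    ResidueDistanceScheme,
    build_dissimilarity,
    choose_M,
    euclidean_matrix,
    iter_dissimilarities,
)
from .homology import Barcode, rips_barcode
from .structure_io import AlphaCarbonCloud
from .vectorize import SAVE_DECIMALS, EpsilonGrid, gaussian_betti_vector

DEFAULT_SPACING = 0.1  # angstroms between epsilon grid rows
CAP_MARGIN = 0.001     # added to max(grid) to form the death cap


@dataclass
class GaussianCrockerMatrix:
    grid: EpsilonGrid
    rhos: np.ndarray
    sigma: float
    dimension: int
    values: np.ndarray  # shape (len(grid), len(rhos))

    def __post_init__(self):
        self.rhos = np.asarray(self.rhos, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid), len(self.rhos)):
            raise ParameterError("values must be (len(grid), len(rhos))")
        self.values = v


@dataclass
class GCCDMatrix:
    grid: EpsilonGrid
    rhos: np.ndarray
    sigma: float
    dimension: int
    values: np.ndarray

    def __post_init__(self):
        self.rhos = np.asarray(self.rhos, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid), len(self.rhos)):
            raise ParameterError("values must be (len(grid), len(rhos))")
        self.values = v

    def flatten(self) -> np.ndarray:
        """Row-major (epsilon-major) flattening, the classification feature."""
        return self.values.ravel(order="C")


def default_cap(grid: EpsilonGrid) -> float:
    return float(grid.values[-1]) + CAP_MARGIN


def select_epsilon_grid(
    sample_clouds: Iterable[AlphaCarbonCloud],
    sigma_max: float,
    spacing: float = DEFAULT_SPACING,
    dim: int = 1,
) -> EpsilonGrid:
    """Choose the shared epsilon grid from sample full-cloud barcodes.

    Computes classical (all connections allowed) Vietoris-Rips barcodes of
    the sample clouds, floors the minimum birth and ceils the maximum
    death to integers, extends both ends by a buffer of 4 * sigma_max, and
    clamps the lower end at >= spacing.  Returns the regular grid.
    """
    if sigma_max <= 0 or spacing <= 0:
        raise ParameterError("sigma_max and spacing must be positive")
    births, deaths = [], []
    n_clouds = 0
    for cloud in sample_clouds:
        n_clouds += 1
        euc = euclidean_matrix(cloud)
        cutoff = float(euc.max()) * 1.001 + 1.0
        bc = rips_barcode(euc, dims={dim}, cutoff=cutoff)[dim]
        if bc.n_bars:
            births.append(bc.bars[:, 0].min())
            deaths.append(bc.bars[:, 1].max())
    if n_clouds == 0:
        raise SelectionError("sample is empty")
    if not births:
        raise SelectionError("all sample barcodes are empty; cannot choose a grid")
    buffer = 4.0 * sigma_max
    lo = math.floor(min(births)) - buffer
    hi = math.ceil(max(deaths)) + buffer
    lo = max(lo, spacing)
    if hi <= lo:
        raise SelectionError("degenerate grid range")
    return EpsilonGrid.regular(lo, hi, spacing)


def rho_barcodes(
    cloud: AlphaCarbonCloud,
    scheme: ResidueDistanceScheme,
    M: float,
    cutoff: float,
    dim: int = 1,
    incremental: bool = True,
) -> list[Barcode]:
    """Dimension-``dim`` barcode for every rho = 1 .. R_inter.

    ``incremental`` reuses one progressively unmasked dissimilarity matrix
    (the persistence of each column is still computed independently);
    ``incremental=False`` rebuilds each matrix from scratch.  The two
    paths are interchangeable and are compared in regression tests.
    """
    if cutoff >= M:
        raise ParameterError("cutoff must stay below the sentinel M")
    out = []
    if incremental:
        for _rho, dm in iter_dissimilarities(cloud, M, scheme):
            out.append(rips_barcode(dm, dims={dim}, cutoff=cutoff)[dim])
    else:
        for rho in range(1, scheme.inter_chain_value + 1):
            dm = build_dissimilarity(cloud, rho, M, scheme)
            out.append(rips_barcode(dm, dims={dim}, cutoff=cutoff)[dim])
    return out


def crocker_from_barcodes(
    barcodes: list[Barcode],
    grid: EpsilonGrid,
    sigma: float,
) -> GaussianCrockerMatrix:
    cols = [gaussian_betti_vector(bc, grid, sigma).values for bc in barcodes]
    return GaussianCrockerMatrix(
        grid=grid,
        rhos=np.arange(1, len(barcodes) + 1),
        sigma=sigma,
        dimension=barcodes[0].dimension if barcodes else 1,
        values=np.column_stack(cols),
    )


def gaussian_crocker(
    cloud: AlphaCarbonCloud,
    grid: EpsilonGrid,
    sigma: float,
    dim: int = 1,
    scheme: Optional[ResidueDistanceScheme] = None,
    M: Optional[float] = None,
    cutoff: Optional[float] = None,
    incremental: bool = True,
) -> GaussianCrockerMatrix:
    """Assemble the Gaussian CROCKER matrix of one conformation."""
    scheme = scheme or ResidueDistanceScheme.from_cloud(cloud)
    cutoff = default_cap(grid) if cutoff is None else cutoff
    if cutoff < grid.values[-1]:
        raise ParameterError("cutoff must reach the top of the grid")
    M = choose_M(cutoff) if M is None else M
    barcodes = rho_barcodes(cloud, scheme, M, cutoff, dim=dim, incremental=incremental)
    return crocker_from_barcodes(barcodes, grid, sigma)


def gccd_from_crocker(C: GaussianCrockerMatrix) -> GCCDMatrix:
    """Successive column differences; the first column is kept as is."""
    diff = np.empty_like(C.values)
    diff[:, 0] = C.values[:, 0]
    diff[:, 1:] = np.diff(C.values, axis=1)
    return GCCDMatrix(
        grid=C.grid, rhos=C.rhos, sigma=C.sigma, dimension=C.dimension, values=diff
    )


def crocker_from_gccd(G: GCCDMatrix) -> GaussianCrockerMatrix:
    """Exact inverse of :func:`gccd_from_crocker` (cumulative row sums)."""
    return GaussianCrockerMatrix(
        grid=G.grid,
        rhos=G.rhos,
        sigma=G.sigma,
        dimension=G.dimension,
        values=np.cumsum(G.values, axis=1),
    )


def gccd_matrix(cloud: AlphaCarbonCloud, grid: EpsilonGrid, sigma: float, **kw) -> GCCDMatrix:
    """Convenience: Gaussian CROCKER then column differencing."""
    return gccd_from_crocker(gaussian_crocker(cloud, grid, sigma, **kw))


def matrix_to_frame(mat) -> pd.DataFrame:
    """Rows = epsilon ascending, columns = rho ascending, 10-decimal rounding."""
    df = pd.DataFrame(
        np.round(mat.values, SAVE_DECIMALS),
        index=np.round(mat.grid.values, SAVE_DECIMALS),
        columns=mat.rhos,
    )
    df.index.name = "epsilon"
    return df


def write_matrix_csv(mat, path) -> None:
    matrix_to_frame(mat).to_csv(path)


def write_matrix_npz(mat, path, source: str = "") -> None:
    """Compact binary container with metadata."""
    np.savez_compressed(
        path,
        values=np.round(mat.values, SAVE_DECIMALS),
        grid=mat.grid.values,
        spacing=mat.grid.spacing,
        rhos=mat.rhos,
        sigma=mat.sigma,
        dimension=mat.dimension,
        source=np.array(source),
    )


def read_matrix_csv(path, sigma: float, dimension: int = 1, kind: str = "gccd"):
    df = pd.read_csv(path, index_col=0)
    grid_vals = df.index.to_numpy(dtype=float)
    spacing = float(grid_vals[1] - grid_vals[0]) if len(grid_vals) > 1 else 1.0
    grid = EpsilonGrid(values=grid_vals, spacing=spacing)
    cls = GCCDMatrix if kind == "gccd" else GaussianCrockerMatrix
    return cls(
        grid=grid,
        rhos=df.columns.to_numpy(dtype=int),
        sigma=sigma,
        dimension=dimension,
        values=df.to_numpy(dtype=float),
    )
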