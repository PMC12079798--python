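"""Betti curves, Betti vectors, and (weighted) Gaussian Betti vectors.

The Betti number at scale epsilon counts bars [b, d) with b <= epsilon < d
(equivalently, persistence-diagram points with x <= epsilon < y).  Its
smooth surrogate, the Gaussian Betti number, replaces each counted point
by an isotropic bivariate Gaussian of scale sigma centered at (b, d) and
integrates the sum of Gaussians over the same region {x <= epsilon < y}:
each unit-weight bar contributes

    Phi((epsilon - b) / sigma) * Phi((d - epsilon) / sigma)

where Phi is the standard normal CDF, a value in [0, 1].  A weight
function w(b, d) >= 0 may scale each bar's contribution, which reduces to
the plain Gaussian Betti number at w = 1.  Gaussians are neither truncated
nor renormalized near the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import ParameterError
from .homology import Barcode

SAVE_DECIMALS = 10  # decimal places kept when writing results

WeightFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]


def unit_weight(birth: np.ndarray, death: np.ndarray) -> np.ndarray:
    """The default weight, w(b, d) = 1 for every bar."""
    return np.ones_like(np.asarray(birth, dtype=float))


def lifetime_weight(birth: np.ndarray, death: np.ndarray) -> np.ndarray:
    """w(b, d) = d - b: emphasize persistent classes."""
    return np.asarray(death, dtype=float) - np.asarray(birth, dtype=float)


@dataclass(frozen=True)
class EpsilonGrid:
    """Strictly increasing, regularly spaced scale values (angstroms)."""

    values: np.ndarray
    spacing: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise ParameterError("grid must be a nonempty 1-D array")
        if v[0] < 0:
            raise ParameterError("grid values must be nonnegative")
        if len(v) > 1:
            steps = np.diff(v)
            if np.any(steps <= 0) or not np.allclose(steps, self.spacing, rtol=1e-6):
                raise ParameterError("grid must increase with regular spacing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def regular(cls, lo: float, hi: float, spacing: float) -> "EpsilonGrid":
        if spacing <= 0 or hi <= lo:
            raise ParameterError("need spacing > 0 and hi > lo")
        n = int(round((hi - lo) / spacing)) + 1
        return cls(values=lo + spacing * np.arange(n), spacing=spacing)


@dataclass
class GaussianBettiVector:
    grid: EpsilonGrid
    sigma: float
    dimension: int
    values: np.ndarray
    n_bars: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),) or np.any(v < -1e-12):
            raise ParameterError("values must be nonnegative, one per grid point")
        self.values = v


def betti_number(barcode: Barcode, epsilon: float) -> int:
    """Count of bars alive at epsilon: birth <= epsilon < death."""
    if barcode.n_bars == 0:
        return 0
    b, d = barcode.bars[:, 0], barcode.bars[:, 1]
    return int(np.count_nonzero((b <= epsilon) & (epsilon < d)))


def betti_vector(barcode: Barcode, grid: EpsilonGrid) -> np.ndarray:
    eps = grid.values
    if barcode.n_bars == 0:
        return np.zeros(len(eps))
    b, d = barcode.bars[:, 0], barcode.bars[:, 1]
    alive = (b[None, :] <= eps[:, None]) & (eps[:, None] < d[None, :])
    return alive.sum(axis=1).astype(float)


def _contributions(
    barcode: Barcode,
    epsilon: np.ndarray,
    sigma: float,
    weight: Optional[WeightFunction],
) -> np.ndarray:
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    eps = np.atleast_1d(np.asarray(epsilon, dtype=float))
    if barcode.n_bars == 0:
        return np.zeros(len(eps))
    b, d = barcode.bars[:, 0], barcode.bars[:, 1]
    w = unit_weight(b, d) if weight is None else np.asarray(weight(b, d), dtype=float)
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    mass = ndtr((eps[:, None] - b[None, :]) / sigma) * ndtr(
        (d[None, :] - eps[:, None]) / sigma
    )
    return mass @ w


def gaussian_betti_number(
    barcode: Barcode,
    epsilon: float,
    sigma: float,
    weight: Optional[WeightFunction] = None,
) -> float:
    """Weighted Gaussian mass over {x <= epsilon < y}, summed over bars."""
    return float(_contributions(barcode, np.array([epsilon]), sigma, weight)[0])


def gaussian_betti_vector(
    barcode: Barcode,
    grid: EpsilonGrid,
    sigma: float,
    weight: Optional[WeightFunction] = None,
) -> GaussianBettiVector:
    values = _contributions(barcode, grid.values, sigma, weight)
    return GaussianBettiVector(
        grid=grid,
        sigma=sigma,
        dimension=barcode.dimension,
        values=values,
        n_bars=barcode.n_bars,
    )


def normalized_multidim_vector(
    barcodes: Mapping[int, Barcode],
    grid: EpsilonGrid,
    sigma: float,
) -> np.ndarray:
    """Concatenated per-dimension Gaussian Betti vectors, dims 0, 1, 2.

    Each dimension's vector is divided by its own bar count so curves of
    different scales are comparable; an empty diagram contributes a zero
    block (0/0 defined as 0).
    """
    blocks = []
    for dim in (0, 1, 2):
        if dim not in barcodes:
            raise ParameterError(f"barcode for dimension {dim} missing")
        bc = barcodes[dim]
        if bc.n_bars == 0:
            blocks.append(np.zeros(len(grid)))
        else:
            vec = gaussian_betti_vector(bc, grid, sigma)
            blocks.append(vec.values / bc.n_bars)
    return np.concatenate(blocks)


def vector_to_frame(vec: GaussianBettiVector) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epsilon": np.round(vec.grid.values, SAVE_DECIMALS),
            "value": np.round(vec.values, SAVE_DECIMALS),
        }
    )


def write_vector(vec: GaussianBettiVector, path) -> None:
    vector_to_frame(vec).to_csv(path, index=False)
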