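"""Vietoris-Rips persistent homology over the two-element field.

Two independently written computation routes are provided:

* :func:`rips_barcode` — the production path.  Dimension 0 uses a
  union-find sweep over edges; dimensions >= 1 use boundary-matrix column
  reduction with the twist/clearing optimization, processing dimensions
  top-down and storing GF(2) columns as arbitrary-precision integer
  bitsets.

* :func:`brute_force_barcode` — a small-instance oracle: explicit
  enumeration of every simplex up to one dimension above the requested
  one, followed by classical left-to-right reduction of the full dense
  boundary matrix over GF(2).

Both apply the same death-capping rule: any class still alive at the
cutoff scale is assigned death = cutoff, and zero-length bars
(birth = death) are empty intervals [b, b) and are discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import ParameterError, SizeError
from .filtration import DissimilarityMatrix

BRUTE_FORCE_MAX_POINTS = 15


@dataclass(frozen=True)
class Bar:
    """Half-open persistence interval [birth, death), angstroms."""

    birth: float
    death: float

    def __post_init__(self):
        if not 0 <= self.birth < self.death:
            raise ValueError(f"need 0 <= birth < death, got [{self.birth}, {self.death})")

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


@dataclass
class Barcode:
    """Multiset of bars for one homology dimension of one filtration."""

    dimension: int
    bars: np.ndarray  # shape (m, 2): birth, death
    cap: float

    def __post_init__(self):
        b = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        if b.size:
            if np.any(b[:, 0] < 0) or np.any(b[:, 0] >= b[:, 1]):
                raise ValueError("bars must satisfy 0 <= birth < death")
            if np.any(b[:, 1] > self.cap + 1e-12):
                raise ValueError("no death may exceed the cap")
        # canonical multiset order
        order = np.lexsort((b[:, 1], b[:, 0])) if b.size else []
        self.bars = b[order] if b.size else b

    @property
    def n_bars(self) -> int:
        return self.bars.shape[0]

    def __len__(self) -> int:
        return self.n_bars

    def __iter__(self):
        return (Bar(float(b), float(d)) for b, d in self.bars)

    @classmethod
    def from_pairs(cls, dimension: int, pairs: Iterable[tuple[float, float]], cap: float):
        arr = np.array(
            [(b, d) for b, d in pairs if d > b], dtype=float
        ).reshape(-1, 2)
        return cls(dimension=dimension, bars=arr, cap=cap)

    def equals(self, other: "Barcode", tol: float = 1e-9) -> bool:
        """Multiset equality of bars within tolerance (canonical order)."""
        if self.n_bars != other.n_bars:
            return False
        if self.n_bars == 0:
            return True
        return bool(np.allclose(self.bars, other.bars, atol=tol, rtol=0))


def barcodes_to_frame(barcodes: Mapping[int, Barcode]) -> pd.DataFrame:
    """Serialize barcodes as (dimension, birth, death) rows."""
    rows = [
        (dim, float(b), float(d))
        for dim, bc in sorted(barcodes.items())
        for b, d in bc.bars
    ]
    return pd.DataFrame(rows, columns=["dimension", "birth", "death"])


def barcodes_from_frame(df: pd.DataFrame, cap: float) -> dict[int, Barcode]:
    out = {}
    for dim, grp in df.groupby("dimension"):
        out[int(dim)] = Barcode(int(dim), grp[["birth", "death"]].to_numpy(), cap)
    return out


def _as_matrix(D: Union[DissimilarityMatrix, np.ndarray], cutoff: float) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        if cutoff >= D.M:
            raise ParameterError("cutoff must stay below the sentinel M")
        return D.values
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ParameterError("distance matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ParameterError("distance matrix must have zero diagonal")
    return arr


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[max(ra, rb)] = min(ra, rb)
        return True


def _sorted_edges(D: np.ndarray, cutoff: float):
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = D[iu, ju]
    keep = w <= cutoff
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    return [((int(i), int(j)), float(f)) for i, j, f in zip(iu[order], ju[order], w[order])]


def _enumerate_simplices(D: np.ndarray, cutoff: float, maxdim: int):
    """Simplices of each dimension 1..maxdim with filtration values <= cutoff.

    Returns dict dim -> list of (vertex_tuple, value), each list sorted by
    (value, vertex tuple) so that the per-dimension order is a filtration
    order with deterministic tie-breaking.
    """
    n = D.shape[0]
    adj = (D <= cutoff) & ~np.eye(n, dtype=bool)
    nbrs = [frozenset(np.nonzero(adj[i])[0].tolist()) for i in range(n)]
    simplices: dict[int, list] = {1: _sorted_edges(D, cutoff)}
    prev = [(s, f) for s, f in simplices[1]]
    for d in range(2, maxdim + 1):
        cur = []
        for verts, f in prev:
            common = nbrs[verts[0]]
            for v in verts[1:]:
                common = common & nbrs[v]
            top = verts[-1]
            for v in sorted(common):
                if v <= top:
                    continue
                fv = max(f, max(float(D[u, v]) for u in verts))
                if fv <= cutoff:
                    cur.append((verts + (v,), fv))
        cur.sort(key=lambda t: (t[1], t[0]))
        simplices[d] = cur
        prev = cur
    return simplices


def _reduce_boundary(columns, rows, skip: frozenset):
    """Twist-style GF(2) reduction of one boundary matrix.

    ``columns``/``rows`` are (vertex_tuple, value) lists in filtration
    order.  Columns whose simplex is in ``skip`` are cleared (known
    positive from the reduction one dimension up).  Returns
    (pairs, paired_rows, positive_columns): pairs as (birth, death),
    paired_rows the set of row simplices killed here, positive_columns
    the column simplices whose reduced column is zero (cleared included).
    """
    row_index = {s: i for i, (s, _) in enumerate(rows)}
    row_f = [f for _, f in rows]
    low_to_col: dict[int, int] = {}
    pairs: list[tuple[float, float]] = []
    paired_rows: set = set()
    positive: list = []
    for verts, f in columns:
        if verts in skip:
            positive.append((verts, f))
            continue
        col = 0
        for omit in range(len(verts)):
            face = verts[:omit] + verts[omit + 1:]
            col |= 1 << row_index[face]
        while col:
            piv = col.bit_length() - 1
            other = low_to_col.get(piv)
            if other is None:
                break
            col ^= other
        if col:
            piv = col.bit_length() - 1
            low_to_col[piv] = col
            paired_rows.add(rows[piv][0])
            pairs.append((row_f[piv], f))
        else:
            positive.append((verts, f))
    return pairs, paired_rows, positive


def rips_barcode(
    D: Union[DissimilarityMatrix, np.ndarray],
    dims: Iterable[int],
    cutoff: float,
) -> dict[int, Barcode]:
    """Vietoris-Rips barcodes for the requested homology dimensions.

    Any class still alive at ``cutoff`` receives death = cutoff; bars of
    zero length are discarded.  For a :class:`DissimilarityMatrix` the
    cutoff must stay below the sentinel M, so forbidden pairs never enter
    the complex.
    """
    dims = sorted(set(int(d) for d in dims))
    if not dims or dims[0] < 0:
        raise ParameterError("dims must be a nonempty set of nonnegative integers")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    arr = _as_matrix(D, cutoff)
    n = arr.shape[0]
    maxdim = dims[-1]
    simplices = _enumerate_simplices(arr, cutoff, maxdim + 1)
    edges = simplices[1]

    # dimension 0 + positivity of edges via union-find
    uf = _UnionFind(n)
    deaths0: list[float] = []
    positive_edges: list = []
    for verts, f in edges:
        if uf.union(*verts):
            deaths0.append(f)
        else:
            positive_edges.append((verts, f))
    out: dict[int, Barcode] = {}
    if 0 in dims:
        n_alive = n - len(deaths0)
        pairs0 = [(0.0, d) for d in deaths0] + [(0.0, cutoff)] * n_alive
        out[0] = Barcode.from_pairs(0, pairs0, cap=cutoff)

    # dimensions >= 1: reduce boundary matrices top-down with clearing
    paired: dict[int, set] = {}       # dim -> simplices killed (paired as births)
    positive: dict[int, list] = {1: positive_edges}
    pairs_by_dim: dict[int, list] = {}
    for k in range(maxdim, 0, -1):
        cols = simplices[k + 1]
        rows = simplices[k]
        skip = frozenset(paired.get(k + 1, ()))
        pairs, paired_rows, pos_cols = _reduce_boundary(cols, rows, skip)
        pairs_by_dim[k] = pairs
        paired[k] = paired_rows
        if k + 1 <= maxdim:
            positive[k + 1] = pos_cols

    for k in dims:
        if k == 0:
            continue
        pairs = list(pairs_by_dim.get(k, []))
        killed = paired.get(k, set())
        for verts, f in positive.get(k, []):
            if verts not in killed:
                pairs.append((f, cutoff))
        out[k] = Barcode.from_pairs(k, pairs, cap=cutoff)
    return out


def brute_force_barcode(
    D: Union[DissimilarityMatrix, np.ndarray],
    dim: int,
    cutoff: float,
) -> Barcode:
    """Oracle barcode by full dense GF(2) boundary-matrix reduction.

    Enumerates every simplex up to dimension ``dim + 1`` with filtration
    value <= cutoff, orders them globally by (value, dimension, vertices),
    and reduces the complete boundary matrix column by column.  Limited to
    small point sets.
    """
    if dim < 0:
        raise ParameterError("dim must be nonnegative")
    arr = _as_matrix(D, cutoff)
    n = arr.shape[0]
    if n > BRUTE_FORCE_MAX_POINTS:
        raise SizeError(
            f"brute-force oracle limited to {BRUTE_FORCE_MAX_POINTS} points, got {n}"
        )
    # global simplex list: (value, dim, vertices)
    entries: list[tuple[float, int, tuple]] = [(0.0, 0, (i,)) for i in range(n)]
    for d in range(1, dim + 2):
        for verts in itertools.combinations(range(n), d + 1):
            f = max(arr[u, v] for u, v in itertools.combinations(verts, 2))
            if f <= cutoff:
                entries.append((float(f), d, verts))
    entries.sort()
    m = len(entries)
    index = {verts: j for j, (_, _, verts) in enumerate(entries)}
    # dense boundary matrix over GF(2)
    R = np.zeros((m, m), dtype=bool)
    for j, (_, d, verts) in enumerate(entries):
        if d == 0:
            continue
        for omit in range(len(verts)):
            face = verts[:omit] + verts[omit + 1:]
            R[index[face], j] = True
    lows = np.full(m, -1, dtype=int)
    owner = np.full(m, -1, dtype=int)  # pivot row -> column owning it
    for j in range(m):
        while R[:, j].any():
            low = int(np.nonzero(R[:, j])[0][-1])
            if owner[low] < 0:
                lows[j] = low
                owner[low] = j
                break
            R[:, j] ^= R[:, owner[low]]
    pairs: list[tuple[float, float]] = []
    for j in range(m):
        if lows[j] >= 0:
            i = lows[j]
            if entries[i][1] == dim:
                pairs.append((entries[i][0], entries[j][0]))
    # essential classes: zero columns never used as a pivot row
    for j in range(m):
        if entries[j][1] != dim:
            continue
        if lows[j] < 0 and not R[:, j].any() and owner[j] < 0:
            pairs.append((entries[j][0], cutoff))
    return Barcode.from_pairs(dim, pairs, cap=cutoff)
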