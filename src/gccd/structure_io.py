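"""Parse structures and trajectories into validated alpha-carbon clouds.

The only structural information the downstream topology needs is, per
residue: a chain label, an author residue number, and the 3-D position of
the alpha carbon (in angstroms).  This module reads that information from
PDB and mmCIF files (via gemmi, with optional biological-assembly
expansion) and from the package's plain per-frame CSV table
(columns ``frame, chain, residue, x, y, z``), and writes the CSV table
back out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import EmptySelectionError, FormatError, RosterMismatchError

TABLE_COLUMNS = ["frame", "chain", "residue", "x", "y", "z"]


@dataclass(frozen=True)
class AlphaCarbonRecord:
    """One alpha carbon: chain label, author residue number, position (A)."""

    chain_id: str
    residue_number: int
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        if self.residue_number < 0:
            raise ValueError("residue_number must be nonnegative")
        object.__setattr__(self, "position", pos)


@dataclass
class AlphaCarbonCloud:
    """One conformation's alpha carbons with chain and residue labels.

    Stored columnar: ``chain_ids`` (str array), ``residue_numbers`` (int
    array) and ``coords`` (n x 3 float array, angstroms), in chain order
    then residue order.  Within each chain residue numbers are strictly
    increasing and no (chain, residue) pair repeats.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    coords: np.ndarray
    residue_range: Optional[tuple[int, int]] = None

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if self.residue_numbers.shape != (n,) or self.coords.shape != (n, 3):
            raise ValueError("chain_ids, residue_numbers, coords must agree in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.residue_numbers < 0):
            raise ValueError("residue numbers must be nonnegative")
        seen_chains: list[str] = []
        for cid in self.chain_ids:
            if cid not in seen_chains:
                seen_chains.append(cid)
        for cid in seen_chains:
            res = self.residue_numbers[self.chain_ids == cid]
            if np.any(np.diff(res) <= 0):
                raise ValueError(
                    f"residue numbers in chain {cid!r} must be strictly increasing"
                )
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if np.any(self.residue_numbers < lo) or np.any(self.residue_numbers > hi):
                raise ValueError("residue numbers outside declared residue_range")
        self._chain_order = seen_chains

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def n_chains(self) -> int:
        return len(self._chain_order)

    @property
    def chain_order(self) -> list[str]:
        return list(self._chain_order)

    @property
    def records(self) -> list[AlphaCarbonRecord]:
        return [
            AlphaCarbonRecord(c, int(r), p)
            for c, r, p in zip(self.chain_ids, self.residue_numbers, self.coords)
        ]

    def roster(self) -> list[tuple[str, int]]:
        return [(str(c), int(r)) for c, r in zip(self.chain_ids, self.residue_numbers)]

    @classmethod
    def from_records(
        cls,
        records: Sequence[AlphaCarbonRecord],
        residue_range: Optional[tuple[int, int]] = None,
    ) -> "AlphaCarbonCloud":
        if not records:
            raise EmptySelectionError("no alpha-carbon records")
        return cls(
            chain_ids=np.array([r.chain_id for r in records], dtype=object),
            residue_numbers=np.array([r.residue_number for r in records], dtype=int),
            coords=np.array([r.position for r in records], dtype=float),
            residue_range=residue_range,
        )

    def select(
        self,
        residue_range: Optional[tuple[int, int]] = None,
        chain_ids: Optional[Sequence[str]] = None,
    ) -> "AlphaCarbonCloud":
        """Restrict to a residue range and/or chain set (idempotent)."""
        mask = np.ones(len(self), dtype=bool)
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
        if chain_ids is not None:
            keep = set(chain_ids)
            mask &= np.array([c in keep for c in self.chain_ids])
        if not mask.any():
            raise EmptySelectionError("selection matched no alpha carbons")
        return AlphaCarbonCloud(
            self.chain_ids[mask],
            self.residue_numbers[mask],
            self.coords[mask],
            residue_range=residue_range,
        )


@dataclass
class TrajectoryFrameSet:
    """Ordered frames of one trajectory sharing a single atom roster."""

    frames: list[AlphaCarbonCloud]
    label: str = "unlabeled"
    trajectory_id: int = 0
    frame_indices: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.frames))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.frame_indices) != len(self.frames):
            raise ValueError("frame_indices must match frames in length")
        if np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame_indices must be strictly increasing")
        if self.frames:
            ref = self.frames[0].roster()
            for idx, frame in zip(self.frame_indices[1:], self.frames[1:]):
                if frame.roster() != ref:
                    raise RosterMismatchError(
                        int(idx), "atom roster differs from first frame"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[AlphaCarbonCloud]:
        return iter(self.frames)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffixes = "".join(path.suffixes).lower()
    if ".cif" in suffixes or ".mmcif" in suffixes:
        return "mmcif"
    if ".csv" in suffixes:
        return "csv"
    return "pdb"


def _read_gemmi(path: Path, fmt: str) -> gemmi.Structure:
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown structure format {fmt!r}")
        st.setup_entities()
        return st
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc


def _model_to_records(model: gemmi.Model) -> list[AlphaCarbonRecord]:
    """Alpha carbons of standard amino acids, chain order then residue order.

    Altloc policy: consider only blank or 'A' conformers; on ties keep the
    highest occupancy (blank preferred over 'A' on an exact tie).
    """
    records = []
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            candidates = [
                a
                for a in residue
                if a.name == "CA" and a.element.name == "C" and a.altloc in ("\x00", "", "A")
            ]
            if not candidates:
                continue
            atom = sorted(
                candidates, key=lambda a: (-a.occ, a.altloc not in ("\x00", ""))
            )[0]
            records.append(
                AlphaCarbonRecord(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
            )
    return records


def read_structure(
    path,
    format: Optional[str] = None,
    assembly: Optional[int] = None,
    residue_range: Optional[tuple[int, int]] = None,
    chain_ids: Optional[Sequence[str]] = None,
) -> AlphaCarbonCloud:
    """Read one conformation's alpha carbons from a PDB/mmCIF file.

    When ``assembly`` is given, the named biological assembly is expanded
    before atom selection (copied chains get numbered names).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    st = _read_gemmi(path, fmt)
    if assembly is not None:
        names = [a.name for a in st.assemblies]
        if str(assembly) not in names:
            raise FormatError(
                f"assembly {assembly!r} not defined in {path.name}; available: {names}"
            )
        st.transform_to_assembly(str(assembly), gemmi.HowToNameCopiedChain.AddNumber)
    if len(st) == 0:
        raise EmptySelectionError(f"{path.name} contains no models")
    records = _model_to_records(st[0])
    if not records:
        raise EmptySelectionError(f"{path.name} contains no standard alpha carbons")
    cloud = AlphaCarbonCloud.from_records(records)
    if residue_range is not None or chain_ids is not None:
        cloud = cloud.select(residue_range=residue_range, chain_ids=chain_ids)
    return cloud


def read_frames(
    path,
    label: str = "unlabeled",
    trajectory_id: int = 0,
    start_frame: int = 0,
    format: Optional[str] = None,
    residue_range: Optional[tuple[int, int]] = None,
) -> TrajectoryFrameSet:
    """Read a trajectory from a CSV table or a multi-model PDB file.

    Frames with index < ``start_frame`` are dropped (the initial portion of
    an MD trajectory is typically discarded as equilibration).  In a
    multi-model file each MODEL is one frame, indexed from 0.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frames, indices = _read_csv_frames(path)
    else:
        st = _read_gemmi(path, fmt)
        frames, indices = [], []
        for i, model in enumerate(st):
            records = _model_to_records(model)
            if not records:
                raise EmptySelectionError(f"model {i} of {path.name} has no alpha carbons")
            frames.append(AlphaCarbonCloud.from_records(records))
            indices.append(i)
    if residue_range is not None:
        frames = [f.select(residue_range=residue_range) for f in frames]
    kept = [(i, f) for i, f in zip(indices, frames) if i >= start_frame]
    if not kept:
        raise EmptySelectionError(f"no frames with index >= {start_frame}")
    indices = [i for i, _ in kept]
    frames = [f for _, f in kept]
    ref = frames[0].roster()
    for i, f in zip(indices[1:], frames[1:]):
        if f.roster() != ref:
            raise RosterMismatchError(i, "atom roster differs from first retained frame")
    return TrajectoryFrameSet(
        frames=frames,
        label=label,
        trajectory_id=trajectory_id,
        frame_indices=np.array(indices),
    )


def _read_csv_frames(path: Path) -> tuple[list[AlphaCarbonCloud], list[int]]:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name} lacks columns {missing}")
    frames, indices = [], []
    for idx, grp in df.groupby("frame", sort=True):
        frames.append(
            AlphaCarbonCloud(
                chain_ids=grp["chain"].astype(str).to_numpy(dtype=object),
                residue_numbers=grp["residue"].to_numpy(dtype=int),
                coords=grp[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
        indices.append(int(idx))
    return frames, indices


def cloud_to_table(cloud: AlphaCarbonCloud, frame: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": frame,
            "chain": cloud.chain_ids.astype(str),
            "residue": cloud.residue_numbers,
            "x": cloud.coords[:, 0],
            "y": cloud.coords[:, 1],
            "z": cloud.coords[:, 2],
        }
    )


def write_cloud(cloud: AlphaCarbonCloud, path, frame: int = 0) -> None:
    """Write one cloud as the package CSV table."""
    cloud_to_table(cloud, frame).to_csv(path, index=False)


def write_frames(frameset: TrajectoryFrameSet, path) -> None:
    """Write a whole trajectory as the package CSV table."""
    tables = [
        cloud_to_table(f, frame=int(i))
        for i, f in zip(frameset.frame_indices, frameset.frames)
    ]
    pd.concat(tables, ignore_index=True).to_csv(path, index=False)
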