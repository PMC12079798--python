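"""Synthetic multi-chain alpha-carbon clouds with planted topology.

These generators are topological test objects, not physical models: they
place points on circles (plus optional isotropic Gaussian coordinate
noise) and assign chain labels and author residue numbers so that each
planted loop becomes admissible at a known residue distance.

* :func:`make_chain_loop` — a single chain on a circle whose residue
  numbering is zig-zagged so that the polygon loop closes exactly at
  residue distance ``gap``.  With distinct residue numbers no cycle can
  close at residue distance 1 (that graph is a path), so the earliest
  achievable closure is 2; ``gap=1`` is accepted and produces it.

* :func:`make_two_chain_ring` — two chains, each an arc of a common
  circle with consecutive numbering, so the large ring exists only once
  inter-chain connections are allowed.  Within-chain complexes are clique
  complexes of path powers, which are contractible at every scale: the
  ring's signal is confined to the final (inter-chain) column exactly.

* :func:`make_labeled_frames` / :func:`make_study` — labeled frame sets
  whose planted ring scales differ between classes by ``class_effect``
  angstroms, emulating two simulation conditions of one molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .structure_io import AlphaCarbonCloud, TrajectoryFrameSet


@dataclass(frozen=True)
class PlantedFeature:
    """What a generator planted: kind, birth scale (A), closure gap."""

    kind: str  # loop | void | inter_chain_loop
    scale: float
    adjacency_gap: int
    chains_involved: tuple[str, ...] = ("A",)

    def __post_init__(self):
        if self.scale <= 0 or self.adjacency_gap < 1:
            raise ParameterError("need scale > 0 and adjacency_gap >= 1")


def polygon_edge_length(n_points: int, radius: float) -> float:
    """Side length of a regular n-gon inscribed in a circle of ``radius``."""
    return 2.0 * radius * np.sin(np.pi / n_points)


def effective_gap(gap: int) -> int:
    """Residue distance at which the planted loop actually closes (>= 2)."""
    return max(int(gap), 2)


def _zigzag_residues(n: int, gap: int) -> np.ndarray:
    """Residue numbers in circle order with max adjacent difference = gap.

    Plain zig-zag (odd ascending, even descending) has max adjacent
    difference 2; for gap >= 3 the top residue is shifted up by gap - 2,
    making the largest step exactly ``gap`` while leaving all other steps
    unchanged (author numbering permits gaps).
    """
    nums = list(range(1, n + 1))
    circle = nums[0::2] + nums[1::2][::-1]
    g = effective_gap(gap)
    if g > 2:
        k = circle.index(n)
        circle[k] = n + (g - 2)
    return np.array(circle, dtype=int)


def make_chain_loop(
    n_points: int,
    radius: float,
    gap: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AlphaCarbonCloud:
    """Single-chain circular loop closing at residue distance ``gap``.

    With ``noise_sd = 0`` the loop's birth scale is the polygon edge
    length; exact residue-distance localization additionally requires the
    analysis window to stay below the polygon's second-chord scale
    (see the planted-feature notes in the package docs).
    """
    if n_points < 4:
        raise ParameterError("n_points must be >= 4")
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if not 1 <= gap <= n_points:
        raise ParameterError(f"gap must lie in [1, {n_points}]")
    angles = 2.0 * np.pi * np.arange(n_points) / n_points
    coords = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_points)]
    )
    residues = _zigzag_residues(n_points, gap)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    order = np.argsort(residues)
    return AlphaCarbonCloud(
        chain_ids=np.array(["A"] * n_points, dtype=object),
        residue_numbers=residues[order],
        coords=coords[order],
    )


def chain_loop_feature(n_points: int, radius: float, gap: int) -> PlantedFeature:
    return PlantedFeature(
        kind="loop",
        scale=polygon_edge_length(n_points, radius),
        adjacency_gap=effective_gap(gap),
        chains_involved=("A",),
    )


def make_two_chain_ring(
    n_per_chain: int,
    radius: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AlphaCarbonCloud:
    """Two chains, each a consecutive-numbered arc of one common circle."""
    if n_per_chain < 2:
        raise ParameterError("n_per_chain must be >= 2")
    if radius <= 0:
        raise ParameterError("radius must be positive")
    n = 2 * n_per_chain
    angles = 2.0 * np.pi * np.arange(n) / n
    coords = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    chains = np.array(["A"] * n_per_chain + ["B"] * n_per_chain, dtype=object)
    residues = np.concatenate(
        [np.arange(1, n_per_chain + 1), np.arange(1, n_per_chain + 1)]
    )
    return AlphaCarbonCloud(chain_ids=chains, residue_numbers=residues, coords=coords)


def two_chain_ring_feature(n_per_chain: int, radius: float) -> PlantedFeature:
    return PlantedFeature(
        kind="inter_chain_loop",
        scale=polygon_edge_length(2 * n_per_chain, radius),
        adjacency_gap=n_per_chain,  # R_inter for consecutive numbering 1..n
        chains_involved=("A", "B"),
    )


def _ring_radius_for_edge(n_total: int, edge: float) -> float:
    return edge / (2.0 * np.sin(np.pi / n_total))


def make_labeled_frames(
    n_frames: int,
    class_effect: float,
    noise_sd: float,
    seed: int,
    n_per_chain: int = 6,
    base_edge: float = 2.0,
    labels: tuple[str, str] = ("glycosylated", "aglycosylated"),
    trajectory_ids: tuple[int, int] = (0, 0),
) -> tuple[TrajectoryFrameSet, TrajectoryFrameSet]:
    """Two labeled frame sets whose planted ring scales differ by class_effect.

    The first class's ring has edge length ``base_edge``; the second's,
    ``base_edge + class_effect``.  Frames within a set differ by i.i.d.
    isotropic Gaussian coordinate noise.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if class_effect < 0 or base_edge + class_effect <= 0:
        raise ParameterError("class_effect must keep the edge length positive")
    rng = np.random.default_rng(seed)
    n_total = 2 * n_per_chain
    out = []
    for which, (label, traj_id) in enumerate(zip(labels, trajectory_ids)):
        edge = base_edge + (class_effect if which == 1 else 0.0)
        base = make_two_chain_ring(n_per_chain, _ring_radius_for_edge(n_total, edge))
        frames = []
        for _ in range(n_frames):
            coords = base.coords
            if noise_sd > 0:
                coords = coords + rng.normal(0.0, noise_sd, coords.shape)
            frames.append(
                AlphaCarbonCloud(base.chain_ids, base.residue_numbers, coords)
            )
        out.append(
            TrajectoryFrameSet(frames=frames, label=label, trajectory_id=traj_id)
        )
    return out[0], out[1]


def make_study(
    n_trajectories: int = 4,
    n_frames: int = 12,
    class_effect: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_per_chain: int = 6,
    base_edge: float = 2.0,
    start_jitter_sd: float | None = None,
) -> list[TrajectoryFrameSet]:
    """A full two-condition study: n_trajectories labeled frame sets per class.

    Trajectories within a class differ by an independent starting-structure
    jitter (one extra noise draw applied to every frame of the trajectory),
    emulating distinct starting conformations of one simulation condition.
    """
    if start_jitter_sd is None:
        start_jitter_sd = noise_sd
    rng = np.random.default_rng(seed)
    framesets = []
    for traj in range(n_trajectories):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        glyco, aglyco = make_labeled_frames(
            n_frames,
            class_effect,
            noise_sd,
            seed=sub_seed,
            n_per_chain=n_per_chain,
            base_edge=base_edge,
            trajectory_ids=(traj, traj),
        )
        for fs in (glyco, aglyco):
            if start_jitter_sd > 0:
                jitter = rng.normal(0.0, start_jitter_sd, fs.frames[0].coords.shape)
                fs.frames = [
                    AlphaCarbonCloud(f.chain_ids, f.residue_numbers, f.coords + jitter)
                    for f in fs.frames
                ]
            framesets.append(fs)
    return framesets
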