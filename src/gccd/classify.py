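"""Downstream protocol: features, k-NN, nested splits, MDS/PCA embeddings.

Each frame of each trajectory is summarized by one flattened vector (a
GCCD matrix, the full-cloud dimension-1 Gaussian Betti vector, or the
concatenated normalized dimension-0/1/2 Gaussian Betti vectors).  Frames
are classified by majority vote among the k nearest training summaries in
Euclidean distance.  Hyperparameters (sigma, k) are chosen by a nested
leave-one-trajectory-pair-out search: each of the 16 train/test splits
holds out one trajectory per class for testing, and within its 3+3
training trajectories all 9 leave-one-pair-out validation splits score
each hyperparameter pair; the best mean validation accuracy wins, ties
going to the smallest sigma then the smallest k.  Test frames never
influence hyperparameter selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .crocker import (
    crocker_from_barcodes,
    default_cap,
    gccd_from_crocker,
    rho_barcodes,
)
from .errors import ParameterError
from .filtration import ResidueDistanceScheme, choose_M, euclidean_matrix
from .homology import Barcode, rips_barcode
from .structure_io import TrajectoryFrameSet
from .vectorize import EpsilonGrid, gaussian_betti_vector, normalized_multidim_vector

SUMMARY_KINDS = ("gccd", "gauss_betti_1d", "gauss_betti_012")
DEFAULT_KS = (15, 25, 35, 45)        # neighbor counts searched over (odd)
DEFAULT_SIGMAS = (0.125, 0.25, 0.5)  # angstroms; max pinned by the 4*sigma buffer


@dataclass
class FeatureTable:
    """Flattened per-frame summaries with trajectory/frame/label metadata."""

    trajectory_ids: np.ndarray
    frame_indices: np.ndarray
    labels: np.ndarray
    X: np.ndarray
    summary_kind: str

    def __post_init__(self):
        self.trajectory_ids = np.asarray(self.trajectory_ids, dtype=int)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.trajectory_ids)
        if not (len(self.frame_indices) == len(self.labels) == self.X.shape[0] == n):
            raise ParameterError("metadata and feature rows must agree in length")
        if self.summary_kind not in SUMMARY_KINDS:
            raise ParameterError(f"summary_kind must be one of {SUMMARY_KINDS}")

    def __len__(self) -> int:
        return len(self.trajectory_ids)

    def trajectories(self) -> list[tuple[str, int]]:
        """Distinct (label, trajectory_id) pairs, in first-seen order."""
        seen: list[tuple[str, int]] = []
        for lab, tid in zip(self.labels, self.trajectory_ids):
            key = (str(lab), int(tid))
            if key not in seen:
                seen.append(key)
        return seen

    def restrict(self, pairs: Sequence[tuple[str, int]]) -> "FeatureTable":
        keep = set((str(l), int(t)) for l, t in pairs)
        mask = np.array(
            [(str(l), int(t)) in keep for l, t in zip(self.labels, self.trajectory_ids)]
        )
        return FeatureTable(
            self.trajectory_ids[mask],
            self.frame_indices[mask],
            self.labels[mask],
            self.X[mask],
            self.summary_kind,
        )


# ---------------------------------------------------------------------------
# feature computation

@dataclass
class StudyBarcodes:
    """Per-frame barcodes precomputed once; vectorization varies with sigma."""

    trajectory_ids: np.ndarray
    frame_indices: np.ndarray
    labels: np.ndarray
    rho_barcodes: list[list[Barcode]]            # per frame, rho = 1..R_inter
    multidim: Optional[list[dict[int, Barcode]]]  # per frame, dims 0/1/2
    cutoff: float


def compute_study_barcodes(
    framesets: Sequence[TrajectoryFrameSet],
    grid: EpsilonGrid,
    scheme: Optional[ResidueDistanceScheme] = None,
    dim: int = 1,
    cutoff: Optional[float] = None,
    M: Optional[float] = None,
    with_multidim: bool = False,
) -> StudyBarcodes:
    """Barcodes for every frame of every trajectory (sigma-independent)."""
    if not framesets:
        raise ParameterError("no frame sets supplied")
    scheme = scheme or ResidueDistanceScheme.from_cloud(framesets[0].frames[0])
    cutoff = default_cap(grid) if cutoff is None else cutoff
    M = choose_M(cutoff) if M is None else M
    tids, fids, labs, rhos, multi = [], [], [], [], []
    for fs in framesets:
        for idx, cloud in zip(fs.frame_indices, fs.frames):
            tids.append(fs.trajectory_id)
            fids.append(int(idx))
            labs.append(fs.label)
            rhos.append(rho_barcodes(cloud, scheme, M, cutoff, dim=dim))
            if with_multidim:
                multi.append(
                    rips_barcode(euclidean_matrix(cloud), dims={0, 1, 2}, cutoff=cutoff)
                )
    return StudyBarcodes(
        trajectory_ids=np.array(tids),
        frame_indices=np.array(fids),
        labels=np.array(labs, dtype=object),
        rho_barcodes=rhos,
        multidim=multi if with_multidim else None,
        cutoff=cutoff,
    )


def feature_table(
    study: StudyBarcodes,
    grid: EpsilonGrid,
    sigma: float,
    summary_kind: str = "gccd",
) -> FeatureTable:
    """Vectorize precomputed barcodes into one summary row per frame."""
    rows = []
    for i in range(len(study.trajectory_ids)):
        if summary_kind == "gccd":
            crocker = crocker_from_barcodes(study.rho_barcodes[i], grid, sigma)
            rows.append(gccd_from_crocker(crocker).flatten())
        elif summary_kind == "gauss_betti_1d":
            # the classical (all-connections) filtration is the last rho column
            full = study.rho_barcodes[i][-1]
            rows.append(gaussian_betti_vector(full, grid, sigma).values)
        elif summary_kind == "gauss_betti_012":
            if study.multidim is None:
                raise ParameterError(
                    "study was computed without multidim barcodes"
                )
            rows.append(normalized_multidim_vector(study.multidim[i], grid, sigma))
        else:
            raise ParameterError(f"unknown summary kind {summary_kind!r}")
    return FeatureTable(
        trajectory_ids=study.trajectory_ids,
        frame_indices=study.frame_indices,
        labels=study.labels,
        X=np.vstack(rows),
        summary_kind=summary_kind,
    )


# ---------------------------------------------------------------------------
# distances and k-NN

def pairwise_distances(table: FeatureTable) -> np.ndarray:
    """Euclidean distances between all pairs of flattened summaries."""
    if len(table) == 0:
        raise ParameterError("empty feature table")
    return cdist(table.X, table.X)


def knn_predict(train: FeatureTable, test: FeatureTable, k: int) -> np.ndarray:
    """Majority label among the k nearest training summaries per test frame.

    Distance ties break by stable (trajectory_id, frame_index) order so
    predictions are reproducible.
    """
    if k % 2 == 0:
        raise ParameterError("k must be odd to avoid majority-vote ties")
    if k > len(train):
        raise ParameterError(f"k={k} exceeds training size {len(train)}")
    if train.X.shape[1] != test.X.shape[1]:
        raise ParameterError("train and test summaries have different lengths")
    classes = sorted(set(str(l) for l in train.labels))
    if len(classes) != 2:
        raise ParameterError("k-NN protocol expects exactly two labels")
    dist = cdist(test.X, train.X)
    preds = []
    for row in dist:
        order = np.lexsort((train.frame_indices, train.trajectory_ids, row))
        top = train.labels[order[:k]]
        votes = np.count_nonzero(top == classes[1])
        preds.append(classes[1] if votes * 2 > k else classes[0])
    return np.array(preds, dtype=object)


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(np.asarray(predicted) == np.asarray(truth)))


# ---------------------------------------------------------------------------
# split schemes and hyperparameter search

def _trajectories_by_label(table: FeatureTable) -> dict[str, list[int]]:
    by_label: dict[str, list[int]] = {}
    for lab, tid in table.trajectories():
        by_label.setdefault(lab, []).append(tid)
    if len(by_label) != 2:
        raise ParameterError("expected exactly two labels")
    return by_label


def validation_splits(train_pairs: Sequence[tuple[str, int]]):
    """Leave one trajectory of each label out of a 3+3 training set."""
    by_label: dict[str, list[int]] = {}
    for lab, tid in train_pairs:
        by_label.setdefault(lab, []).append(tid)
    (la, ids_a), (lb, ids_b) = sorted(by_label.items())
    for ta, tb in itertools.product(sorted(ids_a), sorted(ids_b)):
        held = [(la, ta), (lb, tb)]
        rest = [p for p in train_pairs if p not in held]
        yield rest, held


def grid_search(
    tables_by_sigma: Mapping[float, FeatureTable],
    train_pairs: Sequence[tuple[str, int]],
    ks: Sequence[int] = DEFAULT_KS,
) -> tuple[float, int, pd.DataFrame]:
    """Best (sigma, k) by mean accuracy over the leave-one-pair-out splits.

    Returns the winning pair and the full validation table.  Ties break to
    the smallest sigma, then the smallest k.
    """
    if not tables_by_sigma:
        raise ParameterError("no summaries supplied")
    records = []
    for sigma in sorted(tables_by_sigma):
        table = tables_by_sigma[sigma].restrict(train_pairs)
        for k in sorted(ks):
            accs = []
            for rest, held in validation_splits(train_pairs):
                train = table.restrict(rest)
                valid = table.restrict(held)
                accs.append(accuracy(knn_predict(train, valid, k), valid.labels))
            records.append(
                {"sigma": sigma, "k": k, "mean_validation_accuracy": float(np.mean(accs))}
            )
    results = pd.DataFrame(records)
    best = results.sort_values(
        ["mean_validation_accuracy", "sigma", "k"],
        ascending=[False, True, True],
        kind="stable",
    ).iloc[0]
    return float(best["sigma"]), int(best["k"]), results


def test_splits(table: FeatureTable):
    """All (glyco trajectory, aglyco trajectory) held-out test pairs."""
    by_label = _trajectories_by_label(table)
    (la, ids_a), (lb, ids_b) = sorted(by_label.items())
    all_pairs = [(lab, tid) for lab in (la, lb) for tid in by_label[lab]]
    for ta, tb in itertools.product(sorted(ids_a), sorted(ids_b)):
        held = [(la, ta), (lb, tb)]
        rest = [p for p in all_pairs if p not in held]
        yield rest, held


def evaluate(
    tables_by_sigma: Mapping[float, FeatureTable],
    ks: Sequence[int] = DEFAULT_KS,
) -> pd.DataFrame:
    """Run every train/test split; one row per split plus selected (sigma, k).

    The grand mean of the per-split test accuracies is the study's summary
    number for this feature kind.
    """
    any_table = next(iter(tables_by_sigma.values()))
    rows = []
    for train_pairs, held in test_splits(any_table):
        sigma, k, _ = grid_search(tables_by_sigma, train_pairs, ks)
        table = tables_by_sigma[sigma]
        train = table.restrict(train_pairs)
        test = table.restrict(held)
        acc = accuracy(knn_predict(train, test, k), test.labels)
        rows.append(
            {
                "test_pair": tuple(held),
                "sigma": sigma,
                "k": k,
                "test_accuracy": acc,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_test_accuracy"] = float(df["test_accuracy"].mean())
    return df


# ---------------------------------------------------------------------------
# embeddings

def embed(
    table: FeatureTable,
    method: str = "mds",
    n_components: int = 2,
    seed: int = 0,
):
    """2-D MDS (metric, on precomputed distances) or PCA coordinates.

    PCA additionally returns the explained-variance ratios of the leading
    components.
    """
    if len(table) < n_components + 1:
        raise ParameterError("too few items to embed")
    if method == "mds":
        model = MDS(
            n_components=n_components,
            metric="precomputed",
            metric_mds=True,
            init="classical_mds",
            random_state=seed,
            normalized_stress=False,
        )
        coords = model.fit_transform(pairwise_distances(table))
        return coords, float(model.stress_)
    if method == "pca":
        model = PCA(n_components=n_components, random_state=seed)
        coords = model.fit_transform(table.X)
        return coords, model.explained_variance_ratio_.copy()
    raise ParameterError("method must be 'mds' or 'pca'")
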