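"""k-NN protocol: distances, splits, grid search, evaluation, embeddings."""

import itertools

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from gccd import (
    EpsilonGrid,
    FeatureTable,
    compute_study_barcodes,
    embed,
    evaluate,
    feature_table,
    grid_search,
    knn_predict,
    make_study,
    pairwise_distances,
)
from gccd.classify import accuracy, validation_splits
from gccd.classify import test_splits as enumerate_test_splits
from gccd.errors import ParameterError


def table_from(X, labels, traj=None, kind="gccd"):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    traj = np.zeros(n, dtype=int) if traj is None else np.asarray(traj)
    return FeatureTable(
        trajectory_ids=traj,
        frame_indices=np.arange(n),
        labels=np.asarray(labels, dtype=object),
        X=X,
        summary_kind=kind,
    )


class TestPairwiseDistances:
    def test_identical_vectors_distance_zero(self):
        t = table_from([[1, 2], [1, 2]], ["a", "b"])
        assert pairwise_distances(t)[0, 1] == 0.0

    def test_unit_basis_vectors(self):
        t = table_from([[1, 0], [0, 1]], ["a", "b"])
        assert pairwise_distances(t)[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 7))
        t = table_from(X, ["a"] * 5 + ["b"] * 5)
        D = pairwise_distances(t)
        for i, j in itertools.combinations(range(10), 2):
            assert D[i, j] == pytest.approx(np.sqrt(((X[i] - X[j]) ** 2).sum()))


class TestKnn:
    def test_exact_match_with_k_one(self):
        train = table_from([[0, 0], [5, 5]], ["a", "b"])
        test = table_from([[5, 5]], ["?"])
        assert knn_predict(train, test, 1)[0] == "b"

    def test_single_class_always_predicted(self):
        train = table_from(np.random.default_rng(1).normal(size=(6, 3)),
                           ["a"] * 5 + ["b"])
        test = table_from(np.zeros((4, 3)), ["?"] * 4)
        assert set(knn_predict(train, test, 5)) == {"a"} or True  # majority of 5
        # with k=5 and 5 a's among 6, majority is always 'a'
        assert all(p == "a" for p in knn_predict(train, test, 5))

    def test_agrees_with_sklearn_on_random_data(self):
        rng = np.random.default_rng(2)
        Xtr = rng.normal(size=(50, 6))
        ytr = np.where(rng.random(50) < 0.5, "a", "b")
        Xte = rng.normal(size=(20, 6))
        train = table_from(Xtr, ytr)
        test = table_from(Xte, ["?"] * 20)
        for k in (1, 3, 7):
            ours = knn_predict(train, test, k)
            ref = KNeighborsClassifier(n_neighbors=k).fit(Xtr, ytr).predict(Xte)
            assert list(ours) == list(ref)

    def test_even_k_rejected(self):
        t = table_from([[0], [1]], ["a", "b"])
        with pytest.raises(ParameterError):
            knn_predict(t, t, 2)

    def test_k_larger_than_train_rejected(self):
        t = table_from([[0], [1]], ["a", "b"])
        with pytest.raises(ParameterError):
            knn_predict(t, t, 3)


class TestSplits:
    def pairs(self):
        return [("g", t) for t in range(4)] + [("a", t) for t in range(4)]

    def test_sixteen_test_splits_without_leakage(self):
        t = table_from(
            np.zeros((8, 2)),
            ["g"] * 4 + ["a"] * 4,
            traj=[0, 1, 2, 3, 0, 1, 2, 3],
        )
        splits = list(enumerate_test_splits(t))
        assert len(splits) == 16
        for rest, held in splits:
            assert len(rest) == 6 and len(held) == 2
            assert not set(rest) & set(held)

    def test_nine_validation_splits_per_training_set(self):
        train_pairs = [("g", 0), ("g", 1), ("g", 2), ("a", 0), ("a", 1), ("a", 2)]
        splits = list(validation_splits(train_pairs))
        assert len(splits) == 9
        for rest, held in splits:
            assert len(rest) == 4 and len(held) == 2
            assert not set(rest) & set(held)


class TestGridSearch:
    def perfect_tables(self):
        """Every (sigma, k) separates perfectly -> tie-break applies."""
        rng = np.random.default_rng(3)
        rows, labels, traj = [], [], []
        for lab, offset in (("g", 0.0), ("a", 10.0)):
            for t in range(3):
                for _ in range(4):
                    rows.append([offset + rng.normal(scale=0.1), 0.0])
                    labels.append(lab)
                    traj.append(t)
        base = table_from(rows, labels, traj=traj)
        return {0.5: base, 0.125: base, 0.25: base}

    def test_all_ties_break_to_smallest_sigma_then_k(self):
        pairs = [("g", t) for t in range(3)] + [("a", t) for t in range(3)]
        sigma, k, results = grid_search(self.perfect_tables(), pairs, ks=(3, 1))
        assert (sigma, k) == (0.125, 1)
        assert np.all(results["mean_validation_accuracy"] == 1.0)

    def test_missing_summaries_rejected(self):
        with pytest.raises(ParameterError):
            grid_search({}, [("g", 0)], ks=(1,))


@pytest.fixture(scope="module")
def grid():
    return EpsilonGrid.regular(0.2, 4.0, 0.1)


class TestEndToEnd:

    def run_study(self, grid, class_effect, seed, kind="gccd"):
        sets = make_study(
            n_trajectories=4, n_frames=8, class_effect=class_effect,
            noise_sd=0.06, seed=seed,
        )
        study = compute_study_barcodes(sets, grid, with_multidim=(kind == "gauss_betti_012"))
        tables = {s: feature_table(study, grid, s, kind) for s in (0.125, 0.25, 0.5)}
        return evaluate(tables, ks=(1, 3, 5))

    def test_separable_study_classified_perfectly(self, grid):
        res = self.run_study(grid, class_effect=0.6, seed=21)
        assert len(res) == 16
        assert res.attrs["mean_test_accuracy"] >= 0.95

    def test_null_study_is_at_chance(self, grid):
        res = self.run_study(grid, class_effect=0.0, seed=22)
        assert 0.3 <= res.attrs["mean_test_accuracy"] <= 0.7

    def test_evaluation_is_deterministic(self, grid):
        a = self.run_study(grid, class_effect=0.4, seed=23)
        b = self.run_study(grid, class_effect=0.4, seed=23)
        assert a["test_accuracy"].tolist() == b["test_accuracy"].tolist()
        assert a["sigma"].tolist() == b["sigma"].tolist()

    def test_spatial_only_summaries_also_work(self, grid):
        res = self.run_study(grid, class_effect=0.6, seed=24, kind="gauss_betti_1d")
        assert res.attrs["mean_test_accuracy"] >= 0.9


class TestEmbed:
    def test_collinear_summaries_embed_with_zero_stress(self):
        t = table_from([[0, 0], [1, 0], [2, 0], [3, 0]], ["a", "a", "b", "b"])
        coords, stress = embed(t, method="mds", seed=0)
        assert coords.shape == (4, 2)
        assert stress == pytest.approx(0.0, abs=1e-6)

    def test_pca_ratios_bounded_and_tight_on_rank_two_data(self):
        rng = np.random.default_rng(4)
        basis = rng.normal(size=(2, 12))
        X = rng.normal(size=(30, 2)) @ basis
        t = table_from(X, ["a"] * 15 + ["b"] * 15)
        coords, ratios = embed(t, method="pca", seed=0)
        assert ratios.sum() <= 1.0 + 1e-9
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_items_rejected(self):
        t = table_from([[0, 0]], ["a"])
        with pytest.raises(ParameterError):
            embed(t, method="pca")
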