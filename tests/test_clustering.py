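"""k-medoids, CVI model selection, scaling, relabeling, assignment."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cpetphen.clustering import (
    Assignment,
    ClusterModel,
    CohortChannelScaler,
    DtwKMedoids,
    assign,
    cvi,
    dunn_index,
    fit_sex_models,
    kmedoids_fit,
    relabel_by_fitness,
    select_k,
)
from cpetphen.dtw import dtw_distance


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return D


def exhaustive_best_cost(D, k):
    """Independent brute force over all medoid sets."""
    best = np.inf
    for combo in combinations(range(len(D)), k):
        cost = D[:, combo].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestKMedoids:
    def test_small_instances_match_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            D = random_distance_matrix(rng, 6)
            _, _, cost = kmedoids_fit(D, 2, seed=1)
            assert cost == pytest.approx(exhaustive_best_cost(D, 2))

    def test_pam_near_optimal_on_moderate_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            D = random_distance_matrix(rng, 14)
            # force the iterative path (enumeration disabled)
            _, _, cost = kmedoids_fit(
                D, 3, seed=2, n_restarts=10, exhaustive_threshold=0
            )
            assert cost <= exhaustive_best_cost(D, 3) * 1.05

    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        pts = np.r_[rng.normal(0, 0.3, (10, 2)), rng.normal(8, 0.3, (10, 2))]
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        _, labels, _ = kmedoids_fit(D, 2, seed=0)
        truth = np.r_[np.zeros(10), np.ones(10)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_labels_are_nearest_medoid(self):
        rng = np.random.default_rng(3)
        D = random_distance_matrix(rng, 25)
        medoids, labels, _ = kmedoids_fit(D, 4, seed=0)
        assert np.array_equal(labels, np.argmin(D[:, medoids], axis=1))
        assert len(set(medoids)) == 4

    def test_determinism(self):
        rng = np.random.default_rng(4)
        D = random_distance_matrix(rng, 30)
        a = kmedoids_fit(D, 5, seed=7)
        b = kmedoids_fit(D, 5, seed=7)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_k_validation(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            kmedoids_fit(D, 4, seed=0)
        with pytest.raises(ValueError):
            kmedoids_fit(D, 1, seed=0)


class TestCvi:
    def test_two_tight_far_pairs(self):
        # points 0,1 at distance 0.1; points 2,3 at distance 0.1;
        # cross distance 10
        D = np.array(
            [
                [0.0, 0.1, 10, 10],
                [0.1, 0.0, 10, 10],
                [10, 10, 0.0, 0.1],
                [10, 10, 0.1, 0.0],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        res = cvi(D, labels)
        assert res.silhouette > 0.95
        assert res.dunn == pytest.approx(100.0)  # 10 / 0.1
        assert res.cvi == pytest.approx(res.silhouette * res.dunn)

    def test_degenerate_identical_points(self):
        D = np.zeros((4, 4))
        res_dunn = dunn_index(D, np.array([0, 0, 1, 1]))
        assert np.isinf(res_dunn)

    def test_single_cluster_or_singletons_rejected(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            cvi(D, np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            cvi(D, np.arange(4))

    def test_random_labels_score_below_planted_structure(self):
        rng = np.random.default_rng(5)
        worse = 0
        for _ in range(20):
            pts = np.r_[
                rng.normal(0, 0.5, (8, 2)), rng.normal(6, 0.5, (8, 2))
            ]
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            truth = np.r_[np.zeros(8, int), np.ones(8, int)]
            shuffled = rng.permutation(truth)
            worse += cvi(D, shuffled).cvi < cvi(D, truth).cvi
        assert worse >= 18


class TestSelectK:
    def test_single_candidate(self):
        rng = np.random.default_rng(6)
        D = random_distance_matrix(rng, 12)
        best, table = select_k(D, k_range=[2], seed=0)
        assert best == 2
        assert len(table) == 1

    def test_planted_three_blobs(self):
        rng = np.random.default_rng(7)
        pts = np.concatenate(
            [rng.normal(c, 0.3, (8, 2)) for c in ((0, 0), (6, 0), (0, 6))]
        )
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        best, _ = select_k(D, range(2, 7), seed=0)
        assert best == 3


class TestScaler:
    def test_pooled_moments_are_zero_one_after_transform(self, rng):
        X = [rng.normal(5, 3, size=(int(rng.integers(20, 40)), 3)) for _ in range(6)]
        scaler = CohortChannelScaler().fit(X)
        pooled = np.vstack(scaler.transform(X))
        assert np.allclose(pooled.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(pooled.std(axis=0), 1, atol=1e-12)

    def test_zero_variance_channel_named(self):
        X = [np.ones((10, 2)), np.ones((8, 2))]
        with pytest.raises(ValueError, match="zero-variance"):
            CohortChannelScaler(channels=("HR", "VO2")).fit(X)

    def test_sklearn_params_protocol(self):
        est = DtwKMedoids(n_clusters=3, band=5)
        params = est.get_params()
        assert params["n_clusters"] == 3 and params["band"] == 5
        est.set_params(n_clusters=4)
        assert est.n_clusters == 4


class TestRelabel:
    def test_spec_example_ordering(self):
        order = relabel_by_fitness([20, 35, 15, 28, 24])
        assert order.tolist() == [4, 1, 5, 2, 3]

    def test_ties_keep_original_index_order(self):
        order = relabel_by_fitness([10, 10, 10])
        assert order.tolist() == [1, 2, 3]

    def test_bijection(self, rng):
        for _ in range(10):
            f = rng.normal(size=6)
            order = relabel_by_fitness(f)
            assert sorted(order.tolist()) == [1, 2, 3, 4, 5, 6]


class TestEstimatorAndModels:
    def test_dtw_kmedoids_fit_predict_roundtrip(self, rng):
        series = [
            np.cumsum(rng.normal(size=(15, 2)), axis=0) + off
            for off in (0, 0, 0, 20, 20, 20)
        ]
        est = DtwKMedoids(n_clusters=2, random_state=0).fit(series)
        assert len(est.medoid_indices_) == 2
        assert est.distance_matrix_.shape == (6, 6)
        pred = est.predict(series)
        assert np.array_equal(pred, est.labels_)

    def test_fit_sex_models_and_assignment(self, small_cleaned):
        cleaned, participants, _, truth = small_cleaned
        fits = fit_sex_models(cleaned, participants, k=5, seed=3)
        for sex, fit in fits.items():
            model = fit.model
            stratum_ids = {r.id for r in cleaned if r.sex == sex}
            assert set(model.medoid_ids) <= stratum_ids  # medoid membership
            assert sorted(model.label_order.tolist()) == [1, 2, 3, 4, 5]
            # a medoid assigns to its own phenogroup at distance zero
            by_id = {r.id: r for r in cleaned}
            for raw_idx, mid in enumerate(model.medoid_ids):
                a = assign(model, by_id[mid])
                assert isinstance(a, Assignment)
                assert a.distance_to_medoid == pytest.approx(0.0, abs=1e-9)
                assert a.phenogroup == model.label_order[raw_idx]

    def test_refit_same_seed_is_identical(self, small_cleaned):
        cleaned, participants, _, _ = small_cleaned
        a = fit_sex_models(cleaned, participants, k=5, seed=3)
        b = fit_sex_models(cleaned, participants, k=5, seed=3)
        for sex in a:
            assert a[sex].model.medoid_ids == b[sex].model.medoid_ids
            assert a[sex].assignments == b[sex].assignments

    def test_assignment_is_nearest_medoid(self, small_cleaned):
        cleaned, participants, _, _ = small_cleaned
        fits = fit_sex_models(cleaned, participants, k=5, seed=3)
        model = fits["male"].model
        rec = next(r for r in cleaned if r.sex == "male")
        a = assign(model, rec)
        x = (rec.matrix(model.channels) - model.scaler_mean) / model.scaler_scale
        dists = [dtw_distance(x, m) for m in model.medoids]
        assert a.phenogroup == model.label_order[int(np.argmin(dists))]
        assert a.distance_to_medoid == pytest.approx(min(dists))

    def test_model_json_roundtrip(self, small_cleaned, tmp_path):
        from cpetphen.io import read_model_json, write_model_json

        cleaned, participants, _, _ = small_cleaned
        fits = fit_sex_models(cleaned, participants, k=5, seed=3)
        models = {sex: f.model for sex, f in fits.items()}
        path = tmp_path / "model.json"
        write_model_json(models, path)
        loaded = read_model_json(path)
        for sex in models:
            m0, m1 = models[sex], loaded[sex]
            assert m0.medoid_ids == m1.medoid_ids
            assert np.allclose(m0.scaler_mean, m1.scaler_mean)
            for a, b in zip(m0.medoids, m1.medoids):
                assert np.allclose(a, b)
            assert isinstance(m1, ClusterModel)

    def test_small_stratum_raises(self, small_cleaned):
        cleaned, participants, _, _ = small_cleaned
        males = [r for r in cleaned if r.sex == "male"][:4]
        with pytest.raises(ValueError, match="stratum"):
            fit_sex_models(males, participants, k=5, seed=0)
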