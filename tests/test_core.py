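"""Tests for the iterative SSL engine: pools, pre-labelling, training,
cluster labelling and nearest-cluster classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from harssl.core import (
    ACTIVITY_CLASSES,
    ClusterModel,
    DataPools,
    SSLConfig,
    SSLStream,
    classify,
    classify_batch,
    default_threshold_predicates,
    label_clusters_distance,
    label_clusters_population,
    prelabel,
    train,
)
from harssl.exceptions import ConfigError, InvalidInputError, NotTrainedError
from harssl.synthetic import generate_blobs, isotropic_blob_spec


def make_pools(X, labels=None):
    pools = DataPools()
    for row in X:
        pools.add_unlabeled(row)
    if labels is not None:
        for f, l in labels:
            pools.add_prelabeled(np.asarray(f, dtype=float), l)
    return pools


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": -1},
            {"alpha": 101},
            {"n_clusters": 1},
            {"train_every": 0},
            {"clustering_method": "dbscan"},
            {"labelling_strategy": "centroid"},
            {"prelabel_mode": "magic"},
            {"max_pool_size": 3, "n_clusters": 5},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SSLConfig(**kwargs)

    def test_unknown_mapping_key_rejected(self):
        with pytest.raises(ConfigError):
            SSLConfig.from_mapping({"alhpa": 5})


class TestPrelabel:
    def test_oracle_alpha_zero_never_fires(self, rng):
        cfg = SSLConfig(alpha=0.0)
        assert all(
            prelabel(np.zeros(6), cfg, rng, "sedentary") is None
            for _ in range(200)
        )

    def test_oracle_alpha_hundred_always_fires(self, rng):
        cfg = SSLConfig(alpha=100.0)
        assert all(
            prelabel(np.zeros(6), cfg, rng, "active") == "active"
            for _ in range(200)
        )

    def test_oracle_without_truth_stays_silent(self, rng):
        cfg = SSLConfig(alpha=100.0)
        assert prelabel(np.zeros(6), cfg, rng, None) is None

    def test_oracle_rate_matches_alpha(self):
        cfg = SSLConfig(alpha=10.0, random_seed=5)
        rng = np.random.default_rng(5)
        fired = sum(
            prelabel(np.zeros(6), cfg, rng, "sedentary") is not None
            for _ in range(5000)
        )
        # binomial(5000, 0.1): 5 sd band
        assert abs(fired - 500) < 5 * np.sqrt(5000 * 0.1 * 0.9)

    def test_threshold_mode_requires_thresholds(self, rng):
        cfg = SSLConfig(prelabel_mode="threshold")
        with pytest.raises(ConfigError):
            prelabel(np.zeros(6), cfg, rng)

    def test_threshold_extremes_fire_correct_class(self, rng):
        calib = np.abs(np.random.default_rng(0).normal(size=(500, 6))) + 0.5
        preds = default_threshold_predicates(calib)
        cfg = SSLConfig(
            prelabel_mode="threshold", prelabel_thresholds=preds
        )
        assert prelabel(np.zeros(6), cfg, rng) == "sedentary"
        assert prelabel(np.full(6, 100.0), cfg, rng) == "active"
        # a clearly non-extreme vector stays unlabeled
        mixed = np.array([0.0, 100, 0, 100, 0, 100])
        assert prelabel(mixed, cfg, rng) is None


def brute_force_population(assignments, n_clusters, labels):
    out = []
    for i in range(n_clusters):
        counts = {}
        for a, l in zip(assignments, labels):
            if a == i:
                counts[l] = counts.get(l, 0) + 1
        if not counts:
            out.append(None)
            continue
        best = max(counts.values())
        winners = [c for c, n in counts.items() if n == best]
        out.append(winners[0] if len(winners) == 1 else None)
    return out


class TestPopulationLabelling:
    def test_unique_majority_wins(self):
        # cluster 0: {A:3, B:1} -> A
        labels = label_clusters_population(
            [0, 0, 0, 0], 2, ["A", "A", "A", "B"]
        )
        assert labels == ["A", None]

    def test_tie_stays_unlabeled(self):
        labels = label_clusters_population([0, 0, 0, 0], 1, ["A", "A", "B", "B"])
        assert labels == [None]

    def test_empty_cluster_stays_unlabeled(self):
        assert label_clusters_population([], 3, []) == [None, None, None]

    @given(
        st.integers(2, 8).flatmap(
            lambda k: st.tuples(
                st.just(k),
                st.lists(
                    st.tuples(
                        st.integers(0, k - 1),
                        st.sampled_from(["A", "B", "C"]),
                    ),
                    max_size=60,
                ),
            )
        )
    )
    def test_matches_brute_force_oracle(self, case):
        k, pairs = case
        assignments = [a for a, _ in pairs]
        labels = [l for _, l in pairs]
        assert label_clusters_population(assignments, k, labels) == (
            brute_force_population(assignments, k, labels)
        )


class TestDistanceLabelling:
    def test_nearest_prelabel_wins(self):
        reps = np.zeros((1, 3))
        L = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        assert label_clusters_distance(reps, L, ["A", "B"]) == ["A"]

    def test_empty_lspool_all_unlabeled(self):
        reps = np.zeros((4, 3))
        assert label_clusters_distance(reps, np.empty((0, 3)), []) == [None] * 4

    def test_nonempty_lspool_labels_everything(self, rng):
        reps = rng.normal(size=(20, 3))
        L = rng.normal(size=(5, 3))
        labels = label_clusters_distance(reps, L, list("ABCAB"))
        assert None not in labels

    def test_tie_breaks_to_lowest_episode_index(self):
        reps = np.zeros((1, 2))
        L = np.array([[1.0, 0], [0, 1.0]])  # equidistant
        assert label_clusters_distance(reps, L, ["B", "A"]) == ["B"]

    def test_matches_brute_force_on_random_geometry(self, rng):
        reps = rng.normal(size=(10, 3))
        L = rng.normal(size=(30, 3))
        labels = [f"c{i % 4}" for i in range(30)]
        expected = [
            labels[int(np.argmin([np.linalg.norm(r - l) for l in L]))]
            for r in reps
        ]
        assert label_clusters_distance(reps, L, labels) == expected


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(3)
    reps = rng.normal(size=(20, 3))
    labels = [ACTIVITY_CLASSES[i % 3] if i % 5 else None for i in range(20)]
    return ClusterModel(reps, labels, "kmeans", 1)


class TestClassify:
    def test_exact_representative_hit(self, model):
        pred = classify(model.representatives[7], model)
        assert pred.cluster_index == 7
        assert pred.distance == 0.0
        assert pred.label == model.labels[7]

    def test_unlabeled_cluster_gives_unclassified(self, model):
        pred = classify(model.representatives[0], model)  # labels[0] is None
        assert pred.label is None

    def test_agrees_with_exhaustive_search(self, model):
        rng = np.random.default_rng(11)
        queries = rng.normal(size=(1000, 3), scale=2.0)
        labels, ks, dists = classify_batch(queries, model)
        D = cdist(queries, model.representatives)
        expected_ks = np.argmin(D, axis=1)
        assert np.array_equal(ks, expected_ks)
        assert labels == [model.labels[int(k)] for k in expected_ks]
        np.testing.assert_allclose(dists, D[np.arange(1000), expected_ks])

    def test_untrained_model_rejected(self):
        with pytest.raises(NotTrainedError):
            classify(np.zeros(3), None)


class TestTrain:
    def test_recovers_blob_centers(self):
        spec = isotropic_blob_spec(separation=10, points_per_class=100, seed=1)
        X, labels = generate_blobs(spec)
        pools = make_pools(X, labels=list(zip(X[::10], labels[::10])))
        cfg = SSLConfig(n_clusters=3, use_pca=False, labelling_strategy="distance")
        model = train(pools, cfg, seed=0)
        true_centers = np.vstack([spec.means[c] for c in spec.means])
        D = cdist(model.representatives, true_centers)
        # every generative center matched within 3 sigma / sqrt(n)
        assert np.all(D.min(axis=0) < 3.0 / np.sqrt(100) + 0.5)
        assert sorted(model.labels) == sorted(spec.means)

    def test_deterministic_given_seed(self, default_features):
        X, y = default_features
        pools = make_pools(X[:200], labels=list(zip(X[200:220], y[200:220])))
        cfg = SSLConfig(n_clusters=8)
        m1 = train(pools, cfg, seed=4)
        m2 = train(pools, cfg, seed=4)
        np.testing.assert_array_equal(m1.representatives, m2.representatives)
        assert m1.labels == m2.labels

    def test_every_point_its_own_cluster(self, rng):
        X = rng.normal(size=(6, 6)) * 5
        pools = make_pools(X)
        cfg = SSLConfig(n_clusters=6, use_pca=False)
        model = train(pools, cfg, seed=0)
        D = cdist(X, model.representatives)
        assert np.allclose(np.sort(D.min(axis=1)), 0.0, atol=1e-8)

    def test_count_below_nc_rejected(self, rng):
        pools = make_pools(rng.normal(size=(5, 6)))
        with pytest.raises(InvalidInputError):
            train(pools, SSLConfig(n_clusters=10), seed=0)

    @pytest.mark.parametrize(
        "method", ["gmm_spherical", "gmm_diag", "gmm_full"]
    )
    def test_gmm_backends_train_and_label(self, method):
        X, labels = generate_blobs(
            isotropic_blob_spec(separation=10, points_per_class=60, seed=2)
        )
        pools = make_pools(X, labels=list(zip(X[::15], labels[::15])))
        cfg = SSLConfig(
            n_clusters=3,
            clustering_method=method,
            use_pca=False,
            labelling_strategy="distance",
        )
        model = train(pools, cfg, seed=0)
        assert model.representatives.shape == (3, 6)
        assert None not in model.labels


class TestStream:
    def test_no_model_before_first_training(self, default_features):
        X, y = default_features
        stream = SSLStream(SSLConfig(train_every=100))
        preds = [stream.ingest(X[i], y[i])[0] for i in range(99)]
        assert all(p.label is None for p in preds)
        assert stream.model is None

    def test_pool_conservation(self, default_features):
        X, y = default_features
        stream = SSLStream(SSLConfig())
        for i in range(250):
            stream.ingest(X[i], y[i])
            assert stream.pools.total == i + 1

    def test_training_deferred_until_count_reaches_nc(self, default_features):
        X, y = default_features
        # alpha=100: every episode is pre-labelled, Spool stays empty
        stream = SSLStream(SSLConfig(alpha=100.0, train_every=10, n_clusters=5))
        for i in range(40):
            _, retrained = stream.ingest(X[i], y[i])
            assert not retrained
        assert stream.model is None
        # now let unlabeled episodes accumulate past Nc
        stream.config.alpha = 0.0
        retrained_any = False
        for i in range(40, 60):
            _, retrained = stream.ingest(X[i], y[i])
            retrained_any = retrained_any or retrained
        assert retrained_any and stream.model is not None

    def test_cycle_counter_and_replacement(self, default_features):
        X, y = default_features
        stream = SSLStream(SSLConfig(train_every=50, n_clusters=5))
        for i in range(200):
            stream.ingest(X[i], y[i])
        assert stream.cycle_count == 4
        assert stream.model.cycle_index == 4

    def test_alpha_zero_model_fully_unlabeled(self, default_features):
        X, y = default_features
        for strategy in ("population", "distance"):
            stream = SSLStream(
                SSLConfig(alpha=0.0, labelling_strategy=strategy, train_every=50)
            )
            for i in range(120):
                stream.ingest(X[i], y[i])
            assert stream.model is not None
            assert all(l is None for l in stream.model.labels)

    def test_identical_runs_are_identical(self, default_features):
        X, y = default_features

        def run():
            stream = SSLStream(SSLConfig(random_seed=9, train_every=60))
            return [stream.ingest(X[i], y[i])[0].label for i in range(300)]

        assert run() == run()

    def test_max_pool_size_caps_spool(self, default_features):
        X, y = default_features
        stream = SSLStream(
            SSLConfig(alpha=0.0, max_pool_size=50, n_clusters=5, train_every=30)
        )
        for i in range(200):
            stream.ingest(X[i], y[i])
        assert stream.pools.count == 50
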