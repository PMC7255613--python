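"""Unit tests of the classifier mechanics on small inputs.

Training-quality checks on the full synthetic benchmark (planted-signal
recovery, ablation ordering) live in test_acceptance.py.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from deepsav.model import (
    DeepSAVClassifier,
    NetworkConfig,
    build_network,
    cross_validate,
    median_impute,
    pg_features,
    roc_auc,
)


def _toy_data(n=60, n_pg=0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 1890 + n_pg))
    y = np.arange(n) % 2
    # plant a linear signal in a few columns so fits converge fast
    X[:, 60] += y * 1.0
    return X, y


FAST = dict(filters=4, epochs=2, batch_size=16, early_stopping=False)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_pairs(self):
        # positives 0.9, 0.2; negatives 0.8, 0.1 -> 3 of 4 pairs won
        assert roc_auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]) == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 20), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-9)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = np.r_[np.ones(15), np.zeros(15)].astype(int)
        transformed = np.exp(3 * scores) + 7
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(transformed, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestNetworkConfig:
    def test_defaults_follow_published_architecture(self):
        cfg = NetworkConfig()
        assert (cfg.conv_layers, cfg.filters, cfg.kernel) == (7, 200, 3)
        assert (cfg.max_pool_layers, cfg.residual_links) == (2, 2)
        assert (cfg.dense_layers, cfg.dense_units) == (2, 100)
        assert cfg.dropout == 0.5 and cfg.batch_size == 128

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(dropout=1.0)

    def test_parameter_count_deterministic(self):
        X, y = _toy_data()
        cfg = NetworkConfig(filters=4, epochs=1, early_stopping=False)
        n1 = build_network(cfg).fit(X, y).n_parameters_
        n2 = build_network(cfg).fit(X, y).n_parameters_
        assert n1 == n2


class TestClassifier:
    def test_softmax_outputs_normalised(self):
        X, y = _toy_data()
        clf = DeepSAVClassifier(random_state=0, **FAST).fit(X, y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_scores_in_unit_interval_and_complementary(self):
        X, y = _toy_data(seed=3)
        clf = DeepSAVClassifier(random_state=0, **FAST).fit(X, y)
        s = clf.decision_function(X)
        assert ((0 <= s) & (s <= 1)).all()
        np.testing.assert_allclose(s + clf.predict_proba(X)[:, 0], 1.0, atol=1e-12)

    def test_seeded_determinism(self):
        X, y = _toy_data(seed=1)
        s1 = DeepSAVClassifier(random_state=42, **FAST).fit(X, y).decision_function(X)
        s2 = DeepSAVClassifier(random_state=42, **FAST).fit(X, y).decision_function(X)
        np.testing.assert_array_equal(s1, s2)

    def test_duplicate_windows_get_identical_scores(self):
        X, y = _toy_data(seed=2)
        clf = DeepSAVClassifier(random_state=0, **FAST).fit(X, y)
        X2 = np.vstack([X[:5], X[:5]])
        s = clf.decision_function(X2)
        np.testing.assert_array_equal(s[:5], s[5:])

    def test_single_class_training_rejected(self):
        X, _ = _toy_data()
        with pytest.raises(ValueError):
            DeepSAVClassifier(**FAST).fit(X, np.zeros(len(X)))

    def test_wrong_width_rejected(self):
        X, y = _toy_data()
        clf = DeepSAVClassifier(**FAST)
        with pytest.raises(ValueError):
            clf.fit(X[:, :100], y)

    def test_pg_network_rejects_plain_windows(self):
        X, y = _toy_data(n_pg=18)
        clf = DeepSAVClassifier(n_pg_features=18, random_state=0, **FAST).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict_proba(X[:, :1890])

    def test_plain_network_rejects_pg_input(self):
        X, y = _toy_data()
        clf = DeepSAVClassifier(random_state=0, **FAST).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict_proba(np.hstack([X, np.ones((len(X), 18))]))

    def test_sklearn_clone_and_get_params(self):
        clf = DeepSAVClassifier(filters=8, random_state=5)
        params = clf.get_params()
        assert params["filters"] == 8
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_checkpoint_roundtrip_bit_exact(self, tmp_path):
        X, y = _toy_data(seed=4)
        clf = DeepSAVClassifier(random_state=0, **FAST).fit(X, y)
        path = tmp_path / "model.deepsav"
        clf.save(path)
        loaded = DeepSAVClassifier.load(path)
        np.testing.assert_array_equal(
            clf.decision_function(X), loaded.decision_function(X)
        )
        for k, v in clf.params_.items():
            np.testing.assert_array_equal(v, loaded.params_[k])


class TestCrossValidate:
    def test_minimal_folds(self):
        X, y = _toy_data(n=8)
        res = cross_validate(X, y, k=4, estimator=DeepSAVClassifier(**FAST), seed=0)
        counts = np.bincount(res.fold_assignment)
        assert (counts == 2).all()  # 1 pathogenic + 1 benign per fold
        assert len(res.fold_aucs) == 4

    def test_folds_partition_dataset(self):
        X, y = _toy_data(n=40)
        res = cross_validate(X, y, k=4, estimator=DeepSAVClassifier(**FAST), seed=1)
        assert (res.fold_assignment >= 0).all()
        sizes = np.bincount(res.fold_assignment)
        assert sizes.sum() == 40 and sizes.max() - sizes.min() <= 1

    def test_fold_assignment_seed_stable(self):
        X, y = _toy_data(n=24)
        r1 = cross_validate(X, y, k=4, estimator=DeepSAVClassifier(**FAST), seed=7)
        r2 = cross_validate(X, y, k=4, estimator=DeepSAVClassifier(**FAST), seed=7)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)

    def test_k_exceeding_class_size_rejected(self):
        X, y = _toy_data(n=6)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=4, estimator=DeepSAVClassifier(**FAST))


class TestPGFeatures:
    def test_assembly_shape_and_maf_transform(self):
        maf = np.array([1e-5, 0.1])
        gene_level = np.ones((2, 17))
        side = pg_features(maf, gene_level)
        assert side.shape == (2, 18)
        np.testing.assert_allclose(side[:, 0], -np.log10(maf + 1e-9))

    def test_median_impute_uses_train_medians_only(self):
        train = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        test = np.array([[np.nan, np.nan]])
        tr, te = median_impute(train, test)
        assert not np.isnan(tr).any()
        assert te[0, 0] == 3.0 and te[0, 1] == 5.0

    def test_pg_training_runs(self):
        X, y = _toy_data(n=40, n_pg=18, seed=6)
        clf = DeepSAVClassifier(n_pg_features=18, random_state=0, **FAST).fit(X, y)
        assert clf.decision_function(X).shape == (40,)
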