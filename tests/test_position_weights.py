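"""Encoding, fold assignment, the single-layer trainer and the 9-1 protocol."""

import numpy as np
import pytest

from nucleokey import (
    OligoRecord,
    SyntheticSpec,
    TrainingConfig,
    count_diads,
    cv_position_weights,
    encode,
    encode_pool,
    filter_by_affinity,
    generate_pool,
    make_folds,
    profile_weights_single_class,
    train_single_layer,
)
from nucleokey.oligo_io import LabeledPool, OligoPool


class TestEncode:
    def test_prefix_example(self, p44):
        seq = "CCAA" + "AC" * 73  # L=150; CA and AC are neutral in 4-4
        rec = OligoRecord("a", seq, 1.0)
        fv = encode(rec, p44, label=1, eq1_w=-2.5)
        assert fv.x[0] == 1  # CC
        assert fv.x[1] == 0  # CA
        assert fv.x[2] == -1  # AA
        assert fv.sample_weight == 2.5

    def test_neutral_sequence_all_zero(self, p44):
        rec = OligoRecord("a", "AC" * 75, 0.3)
        fv = encode(rec, p44, label=-1, eq1_w=0.0)
        assert not fv.x.any()

    def test_encoding_consistent_with_count_diads(self, small_synthetic, p44):
        lab = small_synthetic["labeled"]
        X, y, sw = encode_pool(lab, p44)
        assert X.shape == (len(lab), 149)
        assert np.array_equal(y, lab.labels)
        for i in [0, 7, 101]:
            n1, n2 = count_diads(lab.pool.records[i].sequence, p44)
            assert (X[i] == 1).sum() == n1
            assert (X[i] == -1).sum() == n2
            assert sw[i] == pytest.approx(
                abs(lab.pool.records[i].affinity) * abs(n1 - n2)
            )


def _toy_labeled(n, length, rng, labels=None):
    bases = np.array(list("ACGT"))
    if labels is None:
        labels = np.where(rng.random(n) < 0.5, 1, -1)
    records = [
        OligoRecord(
            f"t{i}",
            "".join(bases[rng.integers(0, 4, size=length)]),
            2.0 if labels[i] == 1 else -1.0,
        )
        for i in range(n)
    ]
    return LabeledPool(OligoPool(records, length), np.asarray(labels, dtype=np.int8))


class TestMakeFolds:
    def test_exact_division(self, rng):
        lab = _toy_labeled(100, 10, rng)
        plan = make_folds(lab, K=10, seed=5)
        sizes = np.bincount(plan.assignments)[1:]
        assert sizes.tolist() == [10] * 10

    def test_balanced_remainder(self, rng):
        lab = _toy_labeled(101, 10, rng)
        sizes = np.bincount(make_folds(lab, 10, seed=5).assignments)[1:]
        assert sorted(sizes) == [10] * 9 + [11]

    def test_deterministic_given_seed(self, rng):
        lab = _toy_labeled(57, 10, rng)
        a = make_folds(lab, 10, seed=9).assignments
        b = make_folds(lab, 10, seed=9).assignments
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make_folds(lab, 10, seed=10).assignments)

    def test_stratified_within_one(self, rng):
        labels = np.array([1] * 70 + [-1] * 30)
        lab = _toy_labeled(100, 10, rng, labels=labels)
        plan = make_folds(lab, 10, seed=1)
        for k in range(1, 11):
            fold_labels = labels[plan.assignments == k]
            assert abs((fold_labels == 1).sum() - 7) <= 1

    def test_pool_smaller_than_K(self, rng):
        with pytest.raises(ValueError):
            make_folds(_toy_labeled(5, 10, rng), K=10, seed=0)


class TestTrainSingleLayer:
    def _planted_xy(self, rng, n=400, d=30, pos=10):
        """x[pos] alone determines the label; other features are noise."""
        X = rng.integers(-1, 2, size=(n, d)).astype(np.int8)
        y = np.where(X[:, pos] > 0, 1, -1)
        # avoid degenerate zero column -> force nonzero at planted position
        X[:, pos] = np.where(X[:, pos] == 0, -1, X[:, pos])
        y = np.where(X[:, pos] > 0, 1, -1)
        return X, y

    def test_planted_feature_gets_max_weight(self, rng):
        X, y = self._planted_xy(rng)
        pwv = train_single_layer(X, y, None, TrainingConfig(seed=3))
        assert int(np.argmax(np.abs(pwv.weights))) == 10
        assert pwv.weights[10] > 0

    def test_single_class_rejected(self, rng):
        X = rng.integers(-1, 2, size=(50, 10))
        with pytest.raises(ValueError, match="single_class"):
            train_single_layer(X, np.ones(50), None, TrainingConfig(seed=0))

    def test_duplication_invariance(self, rng):
        X, y = self._planted_xy(rng, n=200)
        cfg = TrainingConfig(seed=4)
        w1 = train_single_layer(X, y, None, cfg).weights
        w2 = train_single_layer(
            np.vstack([X, X]), np.concatenate([y, y]), None, cfg
        ).weights
        np.testing.assert_allclose(w1, w2, atol=1e-8)

    def test_bit_identical_reruns(self, rng):
        X, y = self._planted_xy(rng, n=150)
        sw = rng.random(150)
        cfg = TrainingConfig(seed=11)
        a = train_single_layer(X, y, sw, cfg)
        b = train_single_layer(X, y, sw, cfg)
        assert np.array_equal(a.weights, b.weights) and a.bias == b.bias

    def test_zero_sample_weights_rejected(self, rng):
        X, y = self._planted_xy(rng, n=60)
        with pytest.raises(ValueError, match="zero"):
            train_single_layer(X, y, np.zeros(60), TrainingConfig(seed=0))

    def test_agrees_with_sklearn_logistic(self, small_synthetic, p44):
        """Independent cross-check: an unregularised sklearn logistic fit on
        the same features ranks the same positions at the top."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        lab = small_synthetic["labeled"]
        X, y, _ = encode_pool(lab, p44)
        mine = train_single_layer(
            X, y, None, TrainingConfig(epochs=3000, learning_rate=1.0, seed=0)
        )
        ref = sklearn.LogisticRegression(C=1e6, max_iter=5000, tol=1e-8)
        ref.fit(X, (y > 0).astype(int))
        corr = np.corrcoef(mine.weights, ref.coef_[0])[0, 1]
        assert corr > 0.95
        top_mine = set(np.argsort(-np.abs(mine.weights))[:10])
        top_ref = set(np.argsort(-np.abs(ref.coef_[0]))[:10])
        assert len(top_mine & top_ref) >= 8


class TestCrossValidation:
    def test_confusion_conserves_heldout_sizes(self, small_synthetic, p44):
        lab = small_synthetic["labeled"]
        folds = make_folds(lab, 10, seed=2)
        _, fc = cv_position_weights(lab, p44, folds, TrainingConfig(seed=2))
        for _, row in fc.iterrows():
            held = int((folds.assignments == row["fold"]).sum())
            assert row[["TP", "FP", "TN", "FN"]].sum() == held

    def test_two_fold_toy(self, rng):
        lab = _toy_labeled(4, 10, rng, labels=np.array([1, 1, -1, -1]))
        folds = make_folds(lab, K=2, seed=0)
        _, fc = cv_position_weights(lab, rng_partition(), folds, TrainingConfig(seed=0))
        assert len(fc) == 2
        assert all(fc[["TP", "FP", "TN", "FN"]].sum(axis=1) == 2)

    def test_mean_counts_one_decimal_convention(self, small_synthetic, p44):
        lab = small_synthetic["labeled"]
        folds = make_folds(lab, 10, seed=3)
        _, fc = cv_position_weights(lab, p44, folds, TrainingConfig(seed=3))
        mean_tp = round(float(fc["TP"].mean()), 1)
        assert mean_tp == round(fc["TP"].sum() / 10, 1)

    def test_deterministic_weights(self, small_synthetic, p44):
        lab = small_synthetic["labeled"]
        folds = make_folds(lab, 10, seed=4)
        w1, _ = cv_position_weights(lab, p44, folds, TrainingConfig(seed=4))
        w2, _ = cv_position_weights(lab, p44, folds, TrainingConfig(seed=4))
        assert np.array_equal(w1.weights, w2.weights)


def rng_partition():
    from nucleokey import standard_partitions

    return standard_partitions()[0]


class TestSingleClassProfile:
    def test_regression_recovers_planted_position(self, p44):
        # positive-only subset whose affinity rises with the planted diad class
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        records = []
        for i in range(400):
            seq = list("".join(bases[rng.integers(0, 4, size=50)]))
            bump = 0.0
            if rng.random() < 0.5:
                seq[19:21] = list("CC")  # position 20 carries the signal
                bump = 1.0
            records.append(
                OligoRecord(f"p{i}", "".join(seq), 1.5 + bump + rng.normal(0, 0.1))
            )
        lab = LabeledPool(OligoPool(records, 50), np.ones(400, dtype=np.int8))
        pwv = profile_weights_single_class(lab, "positive", p44)
        assert int(np.argmax(np.abs(pwv.weights))) + 1 == 20

    def test_constant_affinity_gives_flat_weights(self, rng):
        lab = _toy_labeled(100, 30, rng, labels=np.ones(100, dtype=int))
        # overwrite affinities with a constant
        records = [OligoRecord(r.id, r.sequence, 2.0) for r in lab.pool]
        lab = LabeledPool(OligoPool(records, 30), lab.labels)
        pwv = profile_weights_single_class(lab, "positive", rng_partition())
        assert np.max(np.abs(pwv.weights)) < 0.2
        assert pwv.bias == pytest.approx(2.0, abs=0.2)

    def test_empty_subset_rejected(self, rng):
        lab = _toy_labeled(20, 10, rng, labels=np.ones(20, dtype=int))
        with pytest.raises(ValueError):
            profile_weights_single_class(lab, "negative", rng_partition())
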