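"""Key-position-only scoring, classification and the four metrics."""

import math

import numpy as np
import pytest

from nucleokey import (
    ConfusionCounts,
    KeyPositionSet,
    OligoRecord,
    PositionWeightVector,
    SyntheticSpec,
    classify,
    confusion,
    generate_pool,
    metrics,
    score_sequence,
)


def _pwv(weights, bias=0.0):
    return PositionWeightVector(np.asarray(weights, dtype=float), bias, "4-4")


class TestScoreSequence:
    def test_empty_keys_returns_bias(self, p44):
        rec = OligoRecord("a", "ACGT" * 10, 0.0)
        pwv = _pwv(np.ones(39), bias=0.7)
        # an empty key set is representable with k=0
        ks = KeyPositionSet((), 0, "4-4")
        assert score_sequence(rec, pwv, ks, p44) == pytest.approx(0.7)

    def test_all_positive_keys_beat_bias(self, p44):
        rec = OligoRecord("a", "C" * 20, 0.0)  # every diad is CC -> x = +1
        pwv = _pwv(np.full(19, 0.4), bias=-0.1)
        ks = KeyPositionSet((2, 5, 9), 3, "4-4")
        assert score_sequence(rec, pwv, ks, p44) > -0.1

    def test_restricted_equals_masked_full_score(self, p44, rng):
        from nucleokey.diad_profile import diad_codes, sequences_to_codes

        spec = SyntheticSpec(n_sequences=200, seed=77)
        pool, _, _ = generate_pool(spec, p44)
        w = rng.normal(size=149)
        pwv = _pwv(w, bias=0.3)
        keys = tuple(sorted(rng.choice(np.arange(1, 150), 10, replace=False)))
        ks = KeyPositionSet(keys, 10, "4-4")
        masked = np.zeros(149)
        idx = np.array(keys) - 1
        masked[idx] = w[idx]
        table = p44.class_table()
        for rec in pool:
            x = table[diad_codes(sequences_to_codes([rec.sequence]))[0]].astype(float)
            full_masked = float(masked @ x + 0.3)
            assert score_sequence(rec, pwv, ks, p44) == pytest.approx(full_masked)

    def test_key_out_of_range(self, p44):
        rec = OligoRecord("a", "ACGT", 0.0)
        with pytest.raises(ValueError):
            score_sequence(rec, _pwv(np.ones(3)), KeyPositionSet((4,), 1, "x"), p44)


class TestClassify:
    def test_positive_above_threshold(self):
        assert classify(0.7, 0.0) == 1

    def test_boundary_is_negative(self):
        assert classify(0.0, 0.0) == -1

    def test_threshold_sweep_monotone(self, rng):
        scores = rng.normal(size=300)
        counts = [
            sum(classify(s, t) == 1 for s in scores) for t in np.linspace(-3, 3, 25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("inf"))


class TestConfusion:
    def test_perfect_predictions(self):
        labels = [1] * 6 + [-1] * 4
        c = confusion(labels, labels)
        assert (c.TP, c.FP, c.TN, c.FN) == (6, 0, 4, 0)

    def test_inverted_predictions(self):
        labels = np.array([1] * 6 + [-1] * 4)
        c = confusion(-labels, labels)
        assert (c.TP, c.FP, c.TN, c.FN) == (0, 4, 0, 6)

    def test_random_matches_hand_tally(self, rng):
        pred = np.where(rng.random(200) < 0.5, 1, -1)
        lab = np.where(rng.random(200) < 0.5, 1, -1)
        c = confusion(pred, lab)
        tally = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for p, l in zip(pred, lab):
            key = ("T" if p == l else "F") + ("P" if p == 1 else "N")
            tally[key] += 1
        assert (c.TP, c.FP, c.TN, c.FN) == tuple(tally[k] for k in ("TP", "FP", "TN", "FN"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 1], [1])


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((786.3, 367.5, 1763.1, 105.6), (84.3, 88.2, 68.1, 66.6)),
            ((852.6, 301.2, 1678.2, 190.5), (83.7, 81.7, 73.9, 65.1)),
            ((859.8, 294.0, 1673.7, 195.0), (83.8, 81.5, 74.5, 65.3)),
        ],
    )
    def test_reference_rows_one_decimal(self, counts, expected):
        rep = metrics(ConfusionCounts(*counts))
        assert (rep.acc, rep.sen, rep.ppv, rep.mcc) == expected

    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(5, 0, 7, 0))
        assert (rep.acc, rep.sen, rep.ppv, rep.mcc) == (100.0, 100.0, 100.0, 100.0)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            c = rng.random(4) * 100 + 0.5
            scale = float(rng.random() * 9 + 0.1)
            r1 = metrics(ConfusionCounts(*c))
            r2 = metrics(ConfusionCounts(*(c * scale)))
            for v1, v2 in zip(r1.raw, r2.raw):
                assert v1 == pytest.approx(v2)

    def test_label_swap_leaves_acc_mcc(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.random(4) * 50 + 0.5
            a = metrics(ConfusionCounts(tp, fp, tn, fn))
            b = metrics(ConfusionCounts(tn, fn, tp, fp))
            assert a.raw[0] == pytest.approx(b.raw[0])
            assert a.raw[3] == pytest.approx(b.raw[3])

    def test_bounds(self, rng):
        for _ in range(50):
            c = ConfusionCounts(*(rng.random(4) * 100))
            rep = metrics(c)
            for v, lo in zip(rep.raw, (0, 0, 0, -1)):
                if math.isfinite(v):
                    assert lo <= v <= 1

    def test_zero_denominator_flags_nan(self):
        rep = metrics(ConfusionCounts(0, 0, 5, 3))  # no predicted positives
        assert math.isnan(rep.ppv)
        assert math.isfinite(rep.acc)

    def test_mcc_equals_phi_on_small_matrices(self, rng):
        """MCC must equal the Pearson correlation of the binary vectors."""
        for _ in range(30):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 8, size=4))
            if tp + fp + tn + fn == 0:
                continue
            rep = metrics(ConfusionCounts(tp, fp, tn, fn))
            pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            lab = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            if len(set(pred)) < 2 or len(set(lab)) < 2:
                assert math.isnan(rep.raw[3])
                continue
            phi = np.corrcoef(pred, lab)[0, 1]
            assert rep.raw[3] == pytest.approx(phi, abs=1e-12)
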