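"""Size classes, pair construction, logistic fits, CV metrics, smoothing."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

from revscreen import data as bd
from revscreen import training as tr
from revscreen.descriptors import (CompoundDescriptors, DescriptorSet,
                                   PathFingerprint, FP_NBITS)


class TestHeavyAtomClass:
    @pytest.mark.parametrize("n,expected", [
        (8, 10), (10, 10), (11, 11), (35, 35), (59, 59), (60, 60), (66, 60), (1, 10),
    ])
    def test_mapping(self, n, expected):
        assert tr.heavy_atom_class(n) == expected

    def test_total_over_positive_integers(self):
        assert {tr.heavy_atom_class(n) for n in range(1, 200)} == set(tr.SIZE_CLASSES)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tr.heavy_atom_class(0)


def _pair(s3, s2, label, cid="q", tid="t", class_id=25):
    return tr.TrainingPair(cid, tid, s3, s2, label, class_id)


class TestConfusionMetrics:
    def test_perfect_classification(self):
        c = tr.ConfusionCounts(TA=5, TI=5, FA=0, FI=0)
        assert tr.mcc(c) == pytest.approx(1.0)
        assert tr.precision(c) == pytest.approx(1.0)
        assert tr.recall(c) == pytest.approx(1.0)

    def test_perfectly_wrong(self):
        assert tr.mcc(tr.ConfusionCounts(TA=0, TI=0, FA=5, FI=5)) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # (6*3 - 2*1) / sqrt(8*7*5*4) = 16 / sqrt(1120)
        c = tr.ConfusionCounts(TA=6, TI=3, FA=2, FI=1)
        assert tr.mcc(c) == pytest.approx(16 / math.sqrt(1120))
        assert tr.mcc(c) == pytest.approx(0.478, abs=5e-4)

    def test_zero_denominator_convention(self):
        assert tr.mcc(tr.ConfusionCounts(TA=0, TI=5, FA=0, FI=0)) == 0.0

    def test_matches_sklearn_on_random_count_tuples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ta, ti, fa, fi = (int(v) for v in rng.integers(0, 30, size=4))
            if ta + ti + fa + fi == 0:
                continue
            y_true = [1] * ta + [0] * ti + [0] * fa + [1] * fi
            y_pred = [1] * ta + [0] * ti + [1] * fa + [0] * fi
            c = tr.ConfusionCounts(TA=ta, TI=ti, FA=fa, FI=fi)
            assert tr.mcc(c) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)
            assert tr.precision(c) == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0), abs=1e-12)
            assert tr.recall(c) == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0), abs=1e-12)

    def test_confusion_counts_from_probabilities(self):
        c = tr.confusion_counts(np.array([1, 1, 0, 0]),
                                np.array([0.9, 0.3, 0.8, 0.2]))
        assert (c.TA, c.FI, c.FA, c.TI) == (1, 1, 1, 1)


class TestFitLogistic:
    def test_separable_data_orders_positives_first(self):
        rng = np.random.default_rng(2)
        pairs = [_pair(rng.uniform(0, 1), s2, int(s2 > 0.5))
                 for s2 in rng.uniform(0, 1, size=80)]
        # the unpenalized maximum-likelihood fit separates separable data
        coeffs = tr.fit_logistic(pairs, penalty=None)
        probs_pos = [tr.predict_probability_raw(p.score3d, p.score2d, coeffs)
                     for p in pairs if p.label == 1]
        probs_neg = [tr.predict_probability_raw(p.score3d, p.score2d, coeffs)
                     for p in pairs if p.label == 0]
        assert min(probs_pos) > max(probs_neg)

    def test_uninformative_scores_yield_prevalence_intercept(self):
        # all scores zero: c1 = c2 = 0 and C = log(p / (1-p))
        pairs = [_pair(0.0, 0.0, 1)] * 30 + [_pair(0.0, 0.0, 0)] * 70
        c1, c2, C = tr.fit_logistic(pairs)
        assert c1 == pytest.approx(0.0, abs=1e-6)
        assert c2 == pytest.approx(0.0, abs=1e-6)
        assert C == pytest.approx(math.log(0.3 / 0.7), abs=1e-4)

    def test_antisymmetric_data_puts_half_probability_at_centre(self):
        # labels drawn stochastically, then the whole dataset mirrored around
        # (0.5, 0.5) with labels flipped: the (non-separable) MLE inherits the
        # symmetry, so the centre must sit at probability one half
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(150):
            z = rng.normal(0, 1, size=2)
            y = int(rng.random() < 1.0 / (1.0 + np.exp(-(z[0] + z[1]))))
            s = 0.5 + 0.1 * z
            pairs.append(_pair(s[0], s[1], y))
            pairs.append(_pair(1.0 - s[0], 1.0 - s[1], 1 - y))
        coeffs = tr.fit_logistic(pairs)
        assert tr.predict_probability_raw(0.5, 0.5, coeffs) == pytest.approx(
            0.5, abs=1e-3)

    def test_single_label_rejected(self):
        with pytest.raises(tr.DegenerateFitError):
            tr.fit_logistic([_pair(0.1, 0.2, 1), _pair(0.3, 0.4, 1)])

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        pairs = [_pair(*rng.uniform(0, 1, 2), int(rng.random() < 0.4))
                 for _ in range(200)]
        assert tr.fit_logistic(pairs) == tr.fit_logistic(pairs)


class TestCrossValidate:
    def _separable(self, n=200, seed=0):
        # a clear margin around the class boundary keeps every fold's
        # decision threshold on the right side of all held-out points
        rng = np.random.default_rng(seed)
        s2s = [s for s in rng.uniform(0, 1, size=3 * n)
               if abs(s - 0.5) > 0.1][:n]
        return [_pair(rng.uniform(0, 1), s2, int(s2 > 0.5)) for s2 in s2s]

    def test_perfectly_separable_gives_unit_mcc(self):
        for seed in (0, 1, 2):
            m = tr.cross_validate(self._separable(seed=seed), k=10, seed=seed)
            assert m.mcc_cv == pytest.approx(1.0)
            assert m.precision == pytest.approx(1.0)
            assert m.recall == pytest.approx(1.0)

    def test_same_seed_reproduces_metrics(self):
        pairs = self._separable(seed=3)
        a = tr.cross_validate(pairs, seed=9)
        b = tr.cross_validate(pairs, seed=9)
        assert (a.mcc_cv, a.mcc_std, a.precision, a.recall) == \
               (b.mcc_cv, b.mcc_std, b.precision, b.recall)

    def test_requires_both_labels(self):
        with pytest.raises(tr.DegenerateFitError):
            tr.cross_validate([_pair(0.1, 0.2, 1)] * 20, k=10, seed=0)

    def test_requires_k_pairs(self):
        with pytest.raises(ValueError):
            tr.cross_validate(self._separable(n=5), k=10, seed=0)


class TestSmoothing:
    def test_exact_cubic_reproduced(self):
        poly = lambda x: 0.01 * x ** 3 - 0.4 * x ** 2 + 2.0 * x - 7.0
        raw = tr.CoefficientTable({c: (poly(c), 2 * poly(c), -poly(c))
                                   for c in tr.SIZE_CLASSES})
        smoothed = tr.smooth_coefficients(raw)
        for c in tr.SIZE_CLASSES:
            np.testing.assert_allclose(smoothed.coeffs[c], raw.coeffs[c],
                                       atol=1e-9)

    def test_constant_curves_stay_constant(self):
        raw = tr.CoefficientTable({c: (1.5, -2.0, 0.25) for c in tr.SIZE_CLASSES})
        smoothed = tr.smooth_coefficients(raw)
        for c in tr.SIZE_CLASSES:
            np.testing.assert_allclose(smoothed.coeffs[c], (1.5, -2.0, 0.25),
                                       atol=1e-9)

    def test_least_squares_beats_coarse_grid_oracle(self):
        rng = np.random.default_rng(21)
        xs = np.array(tr.SIZE_CLASSES, dtype=float)
        noisy = 0.002 * xs ** 3 - 0.1 * xs ** 2 + rng.normal(0, 5, size=len(xs))
        raw = tr.CoefficientTable({c: (float(v), 0.0, 0.0)
                                   for c, v in zip(tr.SIZE_CLASSES, noisy)})
        fit = np.array([tr.smooth_coefficients(raw).coeffs[c][0]
                        for c in tr.SIZE_CLASSES])
        rss_fit = float(np.sum((fit - noisy) ** 2))
        # brute-force oracle: coarse grid around the generating cubic
        best = np.inf
        for a3 in np.linspace(0.001, 0.003, 5):
            for a2 in np.linspace(-0.15, -0.05, 5):
                for a0 in np.linspace(-20, 20, 9):
                    cand = a3 * xs ** 3 + a2 * xs ** 2 + a0
                    best = min(best, float(np.sum((cand - noisy) ** 2)))
        assert rss_fit <= best + 1e-9

    def test_missing_classes_filled_with_warning(self):
        raw = tr.CoefficientTable({c: (0.1 * c, 1.0, -2.0)
                                   for c in list(tr.SIZE_CLASSES)[5:20]})
        with pytest.warns(UserWarning, match="smoothing over"):
            smoothed = tr.smooth_coefficients(raw)
        assert set(smoothed.coeffs) == set(tr.SIZE_CLASSES)

    def test_table_json_round_trip(self, tmp_path):
        raw = tr.CoefficientTable({c: (0.123456789012345, -1.5, 2.25)
                                   for c in tr.SIZE_CLASSES}, provenance="smoothed")
        path = tmp_path / "coeffs.json"
        raw.save(path)
        loaded = tr.CoefficientTable.load(path)
        assert loaded.provenance == "smoothed"
        assert loaded.coeffs == raw.coeffs


def _toy_descriptors(entries):
    """entries: id -> (es5d rows, on_bits, n_heavy)"""
    ds = DescriptorSet()
    for cid, (rows, on_bits, n_heavy) in entries.items():
        bits = np.zeros(FP_NBITS, dtype=bool)
        bits[list(on_bits)] = True
        ds.add(CompoundDescriptors(cid, np.atleast_2d(np.asarray(rows, float)),
                                   PathFingerprint(bits), n_heavy))
    return ds


class TestBuildTrainingPairs:
    def _universe(self):
        base = np.zeros(18)
        entries = {
            "a1": (base, [1, 2, 3], 25),
            "a2": (base + 0.1, [1, 2, 4], 25),
            "a3": (base + 0.2, [1, 2, 5], 25),
            "dup": (base, [1, 2, 3], 25),           # identical to a1
            **{f"d{i}": (base + 5 + i, [100 + i], 25) for i in range(8)},
        }
        compounds = {cid: bd.CompoundRecord(cid, "X", 25) for cid in entries}
        records = [bd.ActivityRecord(c, "T1", "Ki", 1.0)
                   for c in ("a1", "a2", "a3", "dup")]
        records.append(bd.ActivityRecord("d0", "T1", "IC50", 500.0))
        records.append(bd.ActivityRecord("d1", "T1", "IC50", 50.0))  # gray
        return (bd.BioactivitySet.from_records(compounds, records),
                _toy_descriptors(entries))

    def test_ratio_and_labels(self):
        bset, ds = self._universe()
        pairs = tr.build_training_pairs(bset, ds, class_id=25, ratio=1, seed=0)
        pos = [p for p in pairs if p.label == 1]
        neg = [p for p in pairs if p.label == 0]
        assert len(pos) == 4
        assert len(neg) == 4  # 1 per active; 7 candidates available
        assert all(p.class_id == 25 for p in pairs)

    def test_gray_pairs_never_sampled_as_inactive(self):
        bset, ds = self._universe()
        for seed in range(5):
            pairs = tr.build_training_pairs(bset, ds, class_id=25, ratio=10,
                                            seed=seed)
            assert not any(p.query_id == "d1" and p.label == 0 for p in pairs)

    def test_self_comparison_excluded_unless_duplicate_exists(self):
        bset, ds = self._universe()
        pairs = {p.query_id: p for p in tr.build_training_pairs(
            bset, ds, class_id=25, ratio=1, seed=0) if p.label == 1}
        # a1 has an identical twin (dup) among the actives: scores stay 1
        assert pairs["a1"].score2d == pytest.approx(1.0)
        # a3 has no duplicate: excluding itself, its best match is a2
        assert pairs["a3"].score2d < 1.0

    def test_insufficient_inactive_supply_warns_and_uses_all(self):
        bset, ds = self._universe()
        with pytest.warns(UserWarning, match="inactive candidates"):
            pairs = tr.build_training_pairs(bset, ds, class_id=25, ratio=10,
                                            seed=1)
        neg = [p for p in pairs if p.label == 0]
        assert len(neg) == 7  # 8 decoys minus the gray-zone one

    def test_empty_class_gives_empty_list(self):
        bset, ds = self._universe()
        assert tr.build_training_pairs(bset, ds, class_id=50, seed=0) == []
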