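"""Per-target scoring, probability computation and target ranking."""

import numpy as np
import pytest

from revscreen import data as bd
from revscreen import screening as sc
from revscreen import training as tr
from revscreen.descriptors import (CompoundDescriptors, DescriptorSet,
                                   PathFingerprint, FP_NBITS,
                                   best_pair_similarity, tanimoto)


def _fp(on_bits):
    bits = np.zeros(FP_NBITS, dtype=bool)
    bits[list(on_bits)] = True
    return PathFingerprint(bits)


def _descr(cid, rows, on_bits, n_heavy=25):
    return CompoundDescriptors(cid, np.atleast_2d(np.asarray(rows, float)),
                               _fp(on_bits), n_heavy)


def _universe(entries, actives_by_target):
    ds = DescriptorSet()
    for cid, (rows, bits) in entries.items():
        ds.add(_descr(cid, rows, bits))
    compounds = {cid: bd.CompoundRecord(cid, "X", 25) for cid in entries}
    records = [bd.ActivityRecord(cid, tid, "Ki", 1.0)
               for tid, actives in actives_by_target.items() for cid in actives]
    return ds, bd.BioactivitySet.from_records(compounds, records)


UNIT_COEFFS = tr.CoefficientTable(
    {c: (1.0, 1.0, -1.0) for c in tr.SIZE_CLASSES}, provenance="smoothed")


class TestPredictProbability:
    def test_zero_scores_zero_intercept_gives_half(self):
        coeffs = tr.CoefficientTable({c: (2.0, 3.0, 0.0) for c in tr.SIZE_CLASSES})
        assert sc.predict_probability(0.0, 0.0, coeffs, 25) == pytest.approx(0.5)

    def test_unit_coefficients_at_unit_scores(self):
        # c1 = c2 = 1, C = -1, scores (1, 1): 1 / (1 + e^{-1})
        assert sc.predict_probability(1.0, 1.0, UNIT_COEFFS, 25) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)))

    def test_strictly_increasing_in_score2d(self):
        probs = [sc.predict_probability(0.3, s2, UNIT_COEFFS, 25)
                 for s2 in np.linspace(0, 1, 7)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert all(0 < p < 1 for p in probs)

    def test_missing_class_is_configuration_error(self):
        partial = tr.CoefficientTable({25: (1.0, 1.0, 0.0)})
        with pytest.raises(sc.ConfigurationError):
            sc.predict_probability(0.5, 0.5, partial, 60)


class TestScoreAgainstTarget:
    def test_identical_active_dominates(self):
        rng = np.random.default_rng(0)
        q = _descr("q", rng.normal(size=(3, 18)), [1, 2, 3])
        ds, bset = _universe(
            {"q": (q.es5d, [1, 2, 3]),
             "copy": (q.es5d, [1, 2, 3]),
             "far": (q.es5d + 9.0, [500, 600])},
            {"T": ["copy", "far"]})
        index = sc._TargetIndex(bset, ds)
        tid, actives, es5d, owner, fps = index.entries[0]
        s3, s2, id3, id2 = sc.score_against_target(ds["q"], es5d, owner, fps, actives)
        assert (s3, s2) == (1.0, 1.0)
        assert id3 == "copy" and id2 == "copy"

    def test_equals_exhaustive_max_over_actives(self):
        rng = np.random.default_rng(4)
        entries = {"q": (rng.normal(size=(2, 18)),
                         list(rng.integers(0, FP_NBITS, 30)))}
        actives = []
        for i in range(5):
            entries[f"a{i}"] = (rng.normal(size=(3, 18)),
                                list(rng.integers(0, FP_NBITS, 30)))
            actives.append(f"a{i}")
        ds, bset = _universe(entries, {"T": actives})
        index = sc._TargetIndex(bset, ds)
        _, act, es5d, owner, fps = index.entries[0]
        s3, s2, _, _ = sc.score_against_target(ds["q"], es5d, owner, fps, act)
        brute3 = max(best_pair_similarity(ds["q"].es5d, ds[a].es5d) for a in actives)
        brute2 = max(tanimoto(ds["q"].fingerprint, ds[a].fingerprint)
                     for a in actives)
        assert s3 == pytest.approx(brute3)
        assert s2 == pytest.approx(brute2)

    def test_argmax_actives_can_differ(self):
        base = np.zeros(18)
        ds, bset = _universe(
            {"q": (base, [1, 2, 3, 4]),
             "shape_twin": (base, [900]),          # best in shape only
             "chem_twin": (base + 3.0, [1, 2, 3])},  # best in structure only
            {"T": ["shape_twin", "chem_twin"]})
        _, act, es5d, owner, fps = sc._TargetIndex(bset, ds).entries[0]
        _, _, id3, id2 = sc.score_against_target(ds["q"], es5d, owner, fps, act)
        assert id3 == "shape_twin" and id2 == "chem_twin"


class TestReverseScreen:
    def _planted(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(2, 18))
        entries = {"q": (base, [1, 2, 3, 4, 5])}
        actives_by_target = {}
        # T_hit holds a copy of the query; others hold unrelated actives
        entries["hit"] = (base, [1, 2, 3, 4, 5])
        actives_by_target["T_hit"] = ["hit"]
        for i in range(6):
            entries[f"u{i}"] = (base + 10 + i, [800 + 10 * i, 900 + i])
            actives_by_target[f"T_u{i}"] = [f"u{i}"]
        return _universe(entries, actives_by_target)

    def test_planted_target_ranks_first(self):
        ds, bset = self._planted()
        pred = sc.reverse_screen("q", ds, bset, UNIT_COEFFS)
        assert pred.ranked[0].target_id == "T_hit"
        assert pred.rank_of("T_hit") == 1
        assert len(pred.ranked) == len(bset.targets)

    def test_rank_list_is_permutation_and_deterministic(self):
        ds, bset = self._planted()
        a = sc.reverse_screen("q", ds, bset, UNIT_COEFFS)
        b = sc.reverse_screen("q", ds, bset, UNIT_COEFFS)
        assert [t.target_id for t in a.ranked] == [t.target_id for t in b.ranked]
        assert sorted(t.target_id for t in a.ranked) == sorted(bset.targets)

    def test_tied_targets_ordered_by_target_id(self):
        base = np.zeros(18)
        ds, bset = _universe(
            {"q": (base, [1, 2]),
             "x1": (base + 1, [1, 5]), "x2": (base + 1, [1, 5])},
            {"TB": ["x2"], "TA": ["x1"]})
        pred = sc.reverse_screen("q", ds, bset, UNIT_COEFFS)
        assert [t.target_id for t in pred.ranked] == ["TA", "TB"]
        assert pred.ranked[0].probability == pred.ranked[1].probability

    def test_single_target_is_rank_one(self):
        base = np.zeros(18)
        ds, bset = _universe({"q": (base, [1]), "a": (base + 8, [700])},
                             {"T": ["a"]})
        pred = sc.reverse_screen("q", ds, bset, UNIT_COEFFS)
        assert pred.rank_of("T") == 1

    def test_adding_closer_active_never_lowers_probability(self):
        base = np.zeros(18)
        entries = {"q": (base, [1, 2, 3, 4]), "far": (base + 5, [600])}
        ds1, bset1 = _universe(entries, {"T": ["far"]})
        p1 = sc.reverse_screen("q", ds1, bset1, UNIT_COEFFS).ranked[0].probability
        entries["near"] = (base + 0.5, [1, 2, 3])
        ds2, bset2 = _universe(entries, {"T": ["far", "near"]})
        p2 = sc.reverse_screen("q", ds2, bset2, UNIT_COEFFS).ranked[0].probability
        assert p2 >= p1

    def test_probability_invariant_to_active_scan_order(self):
        rng = np.random.default_rng(12)
        entries = {"q": (rng.normal(size=(2, 18)),
                         list(rng.integers(0, FP_NBITS, 20)))}
        actives = []
        for i in range(6):
            entries[f"a{i}"] = (rng.normal(size=(2, 18)),
                                list(rng.integers(0, FP_NBITS, 20)))
            actives.append(f"a{i}")
        ds, bset_fwd = _universe(entries, {"T": actives})
        _, bset_rev = _universe(entries, {"T": actives[::-1]})
        p_fwd = sc.reverse_screen("q", ds, bset_fwd, UNIT_COEFFS).ranked[0]
        p_rev = sc.reverse_screen("q", ds, bset_rev, UNIT_COEFFS).ranked[0]
        assert p_fwd.probability == pytest.approx(p_rev.probability)

    def test_similarity_floor_prunes_tail_but_keeps_top_ranks(self):
        ds, bset = self._planted()
        full = sc.reverse_screen("q", ds, bset, UNIT_COEFFS)
        pruned = sc.reverse_screen("q", ds, bset, UNIT_COEFFS,
                                   min_score2d=0.5, min_score3d=0.5)
        assert len(pruned.ranked) < len(full.ranked)
        top = [t.target_id for t in full.ranked[:len(pruned.ranked)]]
        assert [t.target_id for t in pruned.ranked] == top

    def test_batch_records_per_query_errors_and_continues(self):
        base = np.zeros(18)
        ds, bset = _universe({"q": (base, [1]), "a": (base, [1])}, {"T": ["a"]})
        predictions, errors = sc.screen_all(["q", "ghost"], ds, bset, UNIT_COEFFS)
        assert set(predictions) == {"q"}
        assert set(errors) == {"ghost"}

    def test_results_tsv_round_trip(self, tmp_path):
        ds, bset = self._planted()
        pred = {"q": sc.reverse_screen("q", ds, bset, UNIT_COEFFS)}
        path = tmp_path / "results.tsv"
        sc.write_results_tsv(pred, path)
        loaded = sc.read_results_tsv(path)
        assert [t.target_id for t in loaded["q"].ranked] == \
               [t.target_id for t in pred["q"].ranked]
        assert loaded["q"].ranked[0].probability == pytest.approx(
            pred["q"].ranked[0].probability)
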