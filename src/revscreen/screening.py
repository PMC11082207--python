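"""Reverse screening: rank candidate protein targets for one query compound.

For every screened target the query is compared to all of the target's known
actives; the best shape similarity (3D-Score) and best fingerprint Tanimoto
(2D-Score) — which may come from different actives — enter the logistic
equation with the smoothed coefficients of the query's heavy-atom class, and
targets are ranked by the resulting probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import data as bd
from .descriptors import ES5D_DIM, DescriptorSet
from .training import CoefficientTable, heavy_atom_class, predict_probability_raw


class ConfigurationError(KeyError):
    pass


@dataclass(frozen=True)
class TargetScore:
    target_id: str
    score3d: float
    score2d: float
    probability: float
    best_3d_active_id: str
    best_2d_active_id: str


@dataclass
class RankedPrediction:
    query_id: str
    ranked: list[TargetScore]
    _rank_of: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._rank_of:
            self._rank_of = {t.target_id: i + 1 for i, t in enumerate(self.ranked)}

    def rank_of(self, target_id: str) -> int:
        """1-based rank of a screened target."""
        return self._rank_of[target_id]


class _TargetIndex:
    """Per-target stacked descriptor arrays for vectorized scoring."""

    def __init__(self, bset: bd.BioactivitySet, descriptors: DescriptorSet):
        self.entries: list[tuple[str, list[str], np.ndarray, np.ndarray, np.ndarray]] = []
        for tid in bset.target_ids:
            actives = [a for a in bset.targets[tid] if a in descriptors]
            if not actives:
                continue
            mats, owner = [], []
            for i, a in enumerate(actives):
                m = descriptors[a].es5d
                mats.append(m)
                owner.extend([i] * m.shape[0])
            es5d = np.vstack(mats)
            fps = np.stack([descriptors[a].fingerprint.bits for a in actives])
            self.entries.append((tid, actives, es5d,
                                 np.asarray(owner, dtype=int), fps))


def score_against_target(query, actives_es5d: np.ndarray, owner: np.ndarray,
                         actives_fps: np.ndarray, active_ids: list[str]
                         ) -> tuple[float, float, str, str]:
    """Best shape and structure similarity of a query against one target.

    Returns (score3d, score2d, best_3d_active_id, best_2d_active_id); the
    two argmax actives can differ.  Ties resolve to the first active in list
    order (deterministic).
    """
    d = cdist(query.es5d, actives_es5d, metric="cityblock").min(axis=0)
    # best (smallest) conformer-pair distance per active
    per_active_d = np.full(len(active_ids), np.inf)
    np.minimum.at(per_active_d, owner, d)
    i3 = int(np.argmin(per_active_d))
    score3d = 1.0 / (1.0 + float(per_active_d[i3]) / ES5D_DIM)

    q = query.fingerprint.bits
    inter = (actives_fps & q).sum(axis=1)
    union = (actives_fps | q).sum(axis=1)
    tanis = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    i2 = int(np.argmax(tanis))
    return score3d, float(tanis[i2]), active_ids[i3], active_ids[i2]


def predict_probability(score3d: float, score2d: float,
                        coeffs: CoefficientTable, n_heavy: int) -> float:
    """Probability of activity from the query's size-class coefficients."""
    try:
        triple = coeffs.for_heavy_atoms(n_heavy)
    except KeyError as exc:
        raise ConfigurationError(
            f"no coefficients for size class {heavy_atom_class(n_heavy)}") from exc
    return predict_probability_raw(score3d, score2d, triple)


def reverse_screen(query_id: str, descriptors: DescriptorSet,
                   screening_set: bd.BioactivitySet, coeffs: CoefficientTable,
                   min_score2d: float = 0.0, min_score3d: float = 0.0,
                   _index: _TargetIndex | None = None) -> RankedPrediction:
    """Score one query against every screened target and rank by probability.

    Ties in probability break by descending 2D-Score, then descending
    3D-Score, then lexicographic target id, so ranks are deterministic.

    ``min_score2d`` / ``min_score3d`` are an optional similarity floor
    (performance knob): targets whose best scores fall below both floors are
    dropped from the list.  Because the logistic probability is monotone in
    the scores under positive coefficients, the floor only prunes the tail
    and never changes top-of-list ranks.
    """
    index = _index if _index is not None else _TargetIndex(screening_set, descriptors)
    query = descriptors[query_id]
    scores: list[TargetScore] = []
    for tid, actives, es5d, owner, fps in index.entries:
        s3, s2, id3, id2 = score_against_target(query, es5d, owner, fps, actives)
        if s2 < min_score2d and s3 < min_score3d:
            continue
        prob = predict_probability(s3, s2, coeffs, query.n_heavy)
        scores.append(TargetScore(tid, s3, s2, prob, id3, id2))
    scores.sort(key=lambda t: (-t.probability, -t.score2d, -t.score3d, t.target_id))
    return RankedPrediction(query_id=query_id, ranked=scores)


def screen_all(query_ids: list[str], descriptors: DescriptorSet,
               screening_set: bd.BioactivitySet, coeffs: CoefficientTable,
               min_score2d: float = 0.0, min_score3d: float = 0.0,
               on_error: str = "record") -> tuple[dict[str, RankedPrediction], dict[str, str]]:
    """Screen a batch of queries; per-query failures are recorded and the
    batch continues.  Returns (predictions, error messages by query id)."""
    index = _TargetIndex(screening_set, descriptors)
    predictions: dict[str, RankedPrediction] = {}
    errors: dict[str, str] = {}
    for qid in query_ids:
        try:
            predictions[qid] = reverse_screen(qid, descriptors, screening_set,
                                              coeffs, min_score2d=min_score2d,
                                              min_score3d=min_score3d,
                                              _index=index)
        except Exception as exc:  # noqa: BLE001 — batch robustness contract
            if on_error == "raise":
                raise
            errors[qid] = str(exc)
    return predictions, errors


def write_results_tsv(predictions: dict[str, RankedPrediction], path,
                      top: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\trank\ttarget_id\tprobability\tscore3d\tscore2d\t"
                 "best_3d_active_id\tbest_2d_active_id\n")
        for qid in sorted(predictions):
            for i, t in enumerate(predictions[qid].ranked[:top], start=1):
                fh.write(f"{qid}\t{i}\t{t.target_id}\t{t.probability:.17g}\t"
                         f"{t.score3d:.17g}\t{t.score2d:.17g}\t"
                         f"{t.best_3d_active_id}\t{t.best_2d_active_id}\n")


def read_results_tsv(path) -> dict[str, RankedPrediction]:
    rows: dict[str, list[TargetScore]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            qid, _rank, tid, prob, s3, s2, id3, id2 = line.rstrip("\n").split("\t")
            rows.setdefault(qid, []).append(TargetScore(
                tid, float(s3), float(s2), float(prob), id3, id2))
    return {qid: RankedPrediction(qid, scores) for qid, scores in rows.items()}
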