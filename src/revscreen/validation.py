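"""Predictive-ability assessment for reverse screening.

The unit of evaluation is one query compound with a set of experimentally
known targets.  After screening, the *best rank* is the minimum rank of any
known target in the query's ranked prediction list, and the headline metric
is success@rank: the percentage of queries whose best rank is within a
cutoff.  Success curves can be stratified by the query's heavy-atom class,
by the amount of bioactivity knowledge on the target (number of known
actives) and by the chemical diversity of that knowledge (number of Murcko
or Oprea scaffolds among the actives).  A *distinct* test subset keeps only
queries whose Murcko AND Oprea scaffolds never occur in the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import data as bd
from .chemspace import murcko_scaffold, oprea_scaffold
from .screening import RankedPrediction
from .training import heavy_atom_class

DEFAULT_KNOWLEDGE_BINS = ((1, 10), (11, 100), (101, 1000), (1001, None))
DEFAULT_DIVERSITY_BINS = ((1, 10), (11, 50), (51, 500), (501, None))


@dataclass(frozen=True)
class EvaluationRecord:
    query_id: str
    known_targets: frozenset[str]
    best_rank: int
    best_target: str  # the known target achieving the best rank

    @property
    def n_known(self) -> int:
        return len(self.known_targets)


@dataclass
class SuccessCurve:
    cutoffs: tuple[int, ...]
    success: tuple[float, ...]  # percentages in [0, 100]
    n_records: int

    def at(self, cutoff: int) -> float:
        return self.success[self.cutoffs.index(cutoff)]


def evaluate_ranks(predictions: dict[str, RankedPrediction],
                   truth: dict[str, set[str]]) -> list[EvaluationRecord]:
    """Best (minimum) rank over each query's known targets.

    Known targets absent from the screen are ignored; a query with no
    findable target is dropped (the evaluation design guarantees every known
    target is screened, so this is defensive only)."""
    records = []
    for qid in sorted(predictions):
        pred = predictions[qid]
        findable = sorted(t for t in truth.get(qid, ()) if t in pred._rank_of)
        if not findable:
            continue
        ranks = {t: pred.rank_of(t) for t in findable}
        best_target = min(ranks, key=lambda t: (ranks[t], t))
        records.append(EvaluationRecord(qid, frozenset(findable),
                                        ranks[best_target], best_target))
    return records


def success_at_rank(records: list[EvaluationRecord],
                    cutoffs=(1, 5, 15, 100)) -> SuccessCurve:
    """success(c) = 100 · |{best_rank ≤ c}| / |records|."""
    if not records:
        raise ValueError("no evaluation records")
    ranks = np.array([r.best_rank for r in records])
    succ = tuple(100.0 * float(np.mean(ranks <= c)) for c in cutoffs)
    return SuccessCurve(tuple(cutoffs), succ, len(records))


def success_by_size_class(records: list[EvaluationRecord],
                          heavy_atoms: dict[str, int],
                          cutoffs=(1, 5, 15, 100)) -> dict[int, SuccessCurve]:
    """Success curves partitioned by the query's heavy-atom class."""
    parts: dict[int, list[EvaluationRecord]] = {}
    for r in records:
        parts.setdefault(heavy_atom_class(heavy_atoms[r.query_id]), []).append(r)
    return {c: success_at_rank(rs, cutoffs) for c, rs in sorted(parts.items())}


def _validate_bins(bins) -> list[tuple[int, float]]:
    norm = [(lo, np.inf if hi is None else hi) for lo, hi in bins]
    norm.sort()
    for (lo1, hi1), (lo2, _hi2) in zip(norm, norm[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping bins: ({lo1},{hi1}) and ({lo2},...)")
    return norm


def _assign_bin(value: int, bins) -> tuple[int, float] | None:
    for lo, hi in bins:
        if lo <= value <= hi:
            return (lo, hi)
    return None


def stratify_by_target_knowledge(records: list[EvaluationRecord],
                                 screening_set: bd.BioactivitySet,
                                 bins=DEFAULT_KNOWLEDGE_BINS,
                                 cutoffs=(1, 5, 15, 100)) -> dict[tuple, SuccessCurve]:
    """Success curves binned by the number of known actives of the target.

    Each record is assigned by its best-ranked known target's active count;
    bins must not overlap; empty bins are omitted.
    """
    bins = _validate_bins(bins)
    counts = {tid: len(acts) for tid, acts in screening_set.targets.items()}
    parts: dict[tuple, list[EvaluationRecord]] = {}
    for r in records:
        b = _assign_bin(counts.get(r.best_target, 0), bins)
        if b is not None:
            parts.setdefault(b, []).append(r)
    return {b: success_at_rank(rs, cutoffs) for b, rs in sorted(parts.items())}


def target_scaffold_counts(screening_set: bd.BioactivitySet,
                           kind: str = "murcko") -> dict[str, int]:
    """Number of distinct (non-empty) scaffolds among each target's actives."""
    fn = {"murcko": murcko_scaffold, "oprea": oprea_scaffold}[kind]
    cache: dict[str, str] = {}
    out: dict[str, int] = {}
    for tid, actives in screening_set.targets.items():
        scaffolds = set()
        for cid in actives:
            smi = screening_set.compounds[cid].smiles_standardized
            if smi not in cache:
                cache[smi] = fn(smi)
            if cache[smi]:
                scaffolds.add(cache[smi])
        out[tid] = len(scaffolds)
    return out


def stratify_by_scaffold_diversity(records: list[EvaluationRecord],
                                   screening_set: bd.BioactivitySet,
                                   scaffold_kind: str = "murcko",
                                   bins=DEFAULT_DIVERSITY_BINS,
                                   cutoffs=(1, 5, 15, 100)) -> dict[tuple, SuccessCurve]:
    """Success curves binned by scaffold diversity of the target's actives."""
    bins = _validate_bins(bins)
    counts = target_scaffold_counts(screening_set, scaffold_kind)
    parts: dict[tuple, list[EvaluationRecord]] = {}
    for r in records:
        b = _assign_bin(counts.get(r.best_target, 0), bins)
        if b is not None:
            parts.setdefault(b, []).append(r)
    return {b: success_at_rank(rs, cutoffs) for b, rs in sorted(parts.items())}


def build_distinct_test_set(test_smiles: dict[str, str],
                            train_smiles: dict[str, str]) -> list[str]:
    """Test compounds whose Murcko AND Oprea scaffolds are both novel.

    A compound is *distinct* when neither its Murcko scaffold nor its Oprea
    scaffold occurs in any training compound (conjunction of the two
    definitions)."""
    train_murcko = {murcko_scaffold(s) for s in train_smiles.values()}
    train_oprea = {oprea_scaffold(s) for s in train_smiles.values()}
    out = []
    for cid in sorted(test_smiles):
        smi = test_smiles[cid]
        if murcko_scaffold(smi) not in train_murcko and \
                oprea_scaffold(smi) not in train_oprea:
            out.append(cid)
    return out


def enrichment_factor(success_pct: float, cutoff: int, n_targets: int) -> float:
    """EF(c) = observed success fraction over the random expectation c/N."""
    if not 1 <= cutoff <= n_targets:
        raise ValueError(f"cutoff must be in [1, {n_targets}], got {cutoff}")
    return (success_pct / 100.0) / (cutoff / n_targets)
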