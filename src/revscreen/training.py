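"""Size-stratified logistic models on similarity features.

Training examples are (query, target) pairs described by two features: the
*3D-Score* (best conformer-pair Manhattan shape similarity between the query
and the target's known actives) and the *2D-Score* (best fingerprint
Tanimoto).  The label is 1 when the query is active on the target.  Because
the informativeness of the two features varies with molecular size, queries
are stratified into 51 heavy-atom classes (≤10, 11…59 one class each, ≥60)
and one binary logistic model

    Probability = 1 / (1 + exp(-c1·3D-Score - c2·2D-Score - C))

is fitted per class by plain (penalty-free) maximum likelihood.  The final
coefficients used for prediction are smoothed across classes by a
third-degree polynomial in the class id, which removes class-to-class
training noise.

Negatives mix measured inactives (≥ 100 µM) with *alleged inactives* —
compounds never reported active on the target under consideration — sampled
per target at 10 negatives per active.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import data as bd
from .descriptors import DescriptorSet, best_pair_similarity, tanimoto

SIZE_CLASSES: tuple[int, ...] = tuple(range(10, 61))  # 51 classes


class DegenerateFitError(ValueError):
    pass


def heavy_atom_class(n: int) -> int:
    """Map a heavy-atom count to its size class: ≤10 → 10, 11–59 → n, ≥60 → 60."""
    if n < 1:
        raise ValueError(f"heavy-atom count must be ≥ 1, got {n}")
    return min(max(n, 10), 60)


@dataclass(frozen=True)
class TrainingPair:
    query_id: str
    target_id: str
    score3d: float
    score2d: float
    label: int
    class_id: int


@dataclass(frozen=True)
class ConfusionCounts:
    TA: int  # actives with Probability > 0.5
    TI: int  # inactives with Probability ≤ 0.5
    FA: int  # inactives with Probability > 0.5
    FI: int  # actives with Probability ≤ 0.5


def confusion_counts(labels: np.ndarray, probabilities: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    labels = np.asarray(labels)
    pred = np.asarray(probabilities) > threshold
    return ConfusionCounts(
        TA=int(np.sum((labels == 1) & pred)),
        TI=int(np.sum((labels == 0) & ~pred)),
        FA=int(np.sum((labels == 0) & pred)),
        FI=int(np.sum((labels == 1) & ~pred)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    denom = math.sqrt(float(c.TA + c.FA) * (c.TA + c.FI) * (c.TI + c.FA) * (c.TI + c.FI))
    if denom == 0:
        return 0.0
    return (c.TA * c.TI - c.FA * c.FI) / denom


def precision(c: ConfusionCounts) -> float:
    return c.TA / (c.TA + c.FA) if (c.TA + c.FA) else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.TA / (c.TA + c.FI) if (c.TA + c.FI) else 0.0


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def similarity_to_actives(query_id: str, target_id: str, bset: bd.BioactivitySet,
                          descriptors: DescriptorSet,
                          exclude_self: bool = True) -> tuple[float, float]:
    """(3D-Score, 2D-Score) of a query against one target's known actives.

    When the query itself is among the target's actives it is excluded from
    its own comparison (a training query must not match itself)."""
    actives = [a for a in bset.targets.get(target_id, ())
               if a in descriptors and not (exclude_self and a == query_id)]
    if not actives:
        return 0.0, 0.0
    q = descriptors[query_id]
    s3 = max(best_pair_similarity(q.es5d, descriptors[a].es5d) for a in actives)
    s2 = max(tanimoto(q.fingerprint, descriptors[a].fingerprint) for a in actives)
    return s3, s2


def build_training_pairs(bset: bd.BioactivitySet, descriptors: DescriptorSet,
                         class_id: int, ratio: int = 10,
                         seed: int = 0) -> list[TrainingPair]:
    """Training pairs for one heavy-atom class.

    Positives: every (active, target) pair whose query falls in the class,
    scored against the target's actives with self-exclusion.  Negatives: per
    target, measured inactives plus alleged inactives of the class (never
    reported active on that target; gray pairs excluded), sampled uniformly
    without replacement, seeded, to ``ratio`` per active.
    """
    rng = np.random.default_rng(seed)
    in_class = {cid for cid in descriptors.ids()
                if heavy_atom_class(descriptors[cid].n_heavy) == class_id}
    pairs: list[TrainingPair] = []
    for tid in bset.target_ids:
        actives = [a for a in bset.targets[tid] if a in in_class]
        if not actives:
            continue
        for qid in actives:
            s3, s2 = similarity_to_actives(qid, tid, bset, descriptors)
            pairs.append(TrainingPair(qid, tid, s3, s2, 1, class_id))
        active_set = set(bset.targets[tid])
        candidates = sorted(
            cid for cid in in_class
            if cid not in active_set
            and bset.labels.get((cid, tid)) != bd.GRAY)
        n_want = ratio * len(actives)
        if len(candidates) < n_want:
            warnings.warn(
                f"target {tid} class {class_id}: only {len(candidates)} inactive "
                f"candidates for {n_want} requested")
            chosen = candidates
        else:
            chosen = sorted(rng.choice(candidates, size=n_want, replace=False))
        for qid in chosen:
            s3, s2 = similarity_to_actives(qid, tid, bset, descriptors,
                                           exclude_self=False)
            pairs.append(TrainingPair(qid, tid, s3, s2, 0, class_id))
    return pairs


def build_all_training_pairs(bset: bd.BioactivitySet, descriptors: DescriptorSet,
                             ratio: int = 10, seed: int = 0
                             ) -> dict[int, list[TrainingPair]]:
    out: dict[int, list[TrainingPair]] = {}
    for class_id in SIZE_CLASSES:
        pairs = build_training_pairs(bset, descriptors, class_id, ratio=ratio,
                                     seed=seed + class_id)
        if pairs:
            out[class_id] = pairs
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _design(pairs: list[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[p.score3d, p.score2d] for p in pairs], dtype=float)
    y = np.array([p.label for p in pairs], dtype=int)
    return X, y


def fit_logistic(pairs: list[TrainingPair],
                 penalty: str | None = "l2") -> tuple[float, float, float]:
    """Binary logistic fit of the label on (3D-Score, 2D-Score).

    Defaults to scikit-learn's standard L2-penalized estimator (C = 1.0,
    intercept unpenalized), which keeps coefficients finite when a size
    class happens to be linearly separable; ``penalty=None`` gives the
    plain maximum-likelihood fit.  Returns (c1, c2, C).
    """
    X, y = _design(pairs)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("training pairs contain a single label")
    model = LogisticRegression(penalty=penalty, solver="lbfgs", tol=1e-8,
                               max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable unpenalized fits stop at max_iter
        model.fit(X, y)
    c1, c2 = (float(v) for v in model.coef_[0])
    return c1, c2, float(model.intercept_[0])


def predict_probability_raw(score3d: float, score2d: float,
                            coeffs: tuple[float, float, float]) -> float:
    c1, c2, C = coeffs
    z = c1 * score3d + c2 * score2d + C
    # clamp to keep the probability strictly inside (0, 1)
    return 1.0 / (1.0 + math.exp(-max(min(z, 700.0), -700.0)))


@dataclass
class CVMetrics:
    mcc_cv: float
    mcc_std: float
    precision: float
    recall: float


def cross_validate(pairs: list[TrainingPair], k: int = 10,
                   seed: int = 0, penalty: str | None = "l2") -> CVMetrics:
    """Row-level shuffled k-fold cross-validation at threshold 0.5.

    Folds are random over rows (no grouping by molecule or target).  A fold
    that ends up single-label triggers one reshuffle; a second failure is an
    error.
    """
    X, y = _design(pairs)
    if len(pairs) < k:
        raise ValueError(f"need at least k={k} pairs, got {len(pairs)}")
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("cross-validation requires both labels")

    def folds_for(rng):
        idx = rng.permutation(len(pairs))
        return np.array_split(idx, k)

    rng = np.random.default_rng(seed)
    folds = folds_for(rng)
    for _ in range(2):
        train_ok = all(len(np.unique(y[np.setdiff1d(np.arange(len(y)), f)])) == 2
                       for f in folds)
        if train_ok:
            break
        folds = folds_for(rng)
    else:
        raise DegenerateFitError("could not form folds with both labels")

    mccs, precs, recs = [], [], []
    for fold in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), fold)
        model = LogisticRegression(penalty=penalty, solver="lbfgs", tol=1e-8,
                                   max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train_idx], y[train_idx])
        prob = model.predict_proba(X[fold])[:, 1]
        c = confusion_counts(y[fold], prob)
        mccs.append(mcc(c))
        precs.append(precision(c))
        recs.append(recall(c))
    return CVMetrics(mcc_cv=float(np.mean(mccs)), mcc_std=float(np.std(mccs)),
                     precision=float(np.mean(precs)), recall=float(np.mean(recs)))


# ---------------------------------------------------------------------------
# Coefficient tables and smoothing
# ---------------------------------------------------------------------------

@dataclass
class CoefficientTable:
    """Per-class (c1, c2, C) triples, raw or polynomial-smoothed."""

    coeffs: dict[int, tuple[float, float, float]]
    provenance: str = "raw"  # or "smoothed"

    def for_heavy_atoms(self, n_heavy: int) -> tuple[float, float, float]:
        class_id = heavy_atom_class(n_heavy)
        if class_id not in self.coeffs:
            raise KeyError(f"no coefficients for size class {class_id}")
        return self.coeffs[class_id]

    def save(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "coeffs": {str(k): list(v) for k, v in sorted(self.coeffs.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CoefficientTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(coeffs={int(k): tuple(v) for k, v in payload["coeffs"].items()},
                   provenance=payload["provenance"])


def fit_all_classes(pairs_by_class: dict[int, list[TrainingPair]]) -> CoefficientTable:
    """Fit one logistic model per size class; degenerate classes are skipped."""
    coeffs: dict[int, tuple[float, float, float]] = {}
    for class_id, pairs in sorted(pairs_by_class.items()):
        try:
            coeffs[class_id] = fit_logistic(pairs)
        except DegenerateFitError:
            warnings.warn(f"size class {class_id}: single-label data, skipped")
    return CoefficientTable(coeffs, provenance="raw")


def smooth_coefficients(raw: CoefficientTable) -> CoefficientTable:
    """Replace each coefficient curve by its degree-3 least-squares polynomial.

    The three curves c1, c2, C as functions of the class id are fitted
    (unweighted) on the classes present and evaluated on all 51 classes, so
    prediction has coefficients even for classes that had no training data.
    Outside the fitted class range the polynomial is held at its value at
    the nearest fitted class: a cubic has no support there and free
    extrapolation can even flip coefficient signs.
    """
    if not raw.coeffs:
        raise ValueError("no raw coefficients to smooth")
    xs = np.array(sorted(raw.coeffs), dtype=float)
    if len(xs) < len(SIZE_CLASSES):
        warnings.warn(f"smoothing over {len(xs)} of {len(SIZE_CLASSES)} classes")
    ys = np.array([raw.coeffs[int(x)] for x in xs])  # (n, 3)
    degree = min(3, len(xs) - 1)
    all_classes = np.clip(np.array(SIZE_CLASSES, dtype=float), xs[0], xs[-1])
    smoothed = np.empty((len(SIZE_CLASSES), 3))
    for j in range(3):
        poly = np.polynomial.Polynomial.fit(xs, ys[:, j], deg=degree)
        smoothed[:, j] = poly(all_classes)
    coeffs = {int(c): tuple(float(v) for v in smoothed[i])
              for i, c in enumerate(SIZE_CLASSES)}
    return CoefficientTable(coeffs, provenance="smoothed")


# ---------------------------------------------------------------------------
# Training-pair TSV I/O
# ---------------------------------------------------------------------------

def write_pairs_tsv(pairs: list[TrainingPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.score3d:.17g}\t{p.score2d:.17g}\t{p.label}\t"
                     f"{p.class_id}\t{p.query_id}\t{p.target_id}\n")


def read_pairs_tsv(path) -> list[TrainingPair]:
    out = []
    with open(path) as fh:
        for line in fh:
            s3, s2, label, class_id, qid, tid = line.rstrip("\n").split("\t")
            out.append(TrainingPair(qid, tid, float(s3), float(s2),
                                    int(label), int(class_id)))
    return out
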