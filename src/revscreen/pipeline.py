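"""End-to-end orchestration: featurize → train → screen → evaluate.

These functions glue the library modules into the reverse-screening
workflow on a labeled bioactivity set, and are what the CLI, the examples
and the synthetic-universe studies drive.  Every stage is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import data as bd
from . import training as tr
from . import validation as vl
from .descriptors import DescriptorSet, featurize
from .fixtures import ExternalTestSet, FixtureSpec, generate_universe
from .screening import RankedPrediction, screen_all


@dataclass
class StudyResult:
    training: bd.BioactivitySet
    test: ExternalTestSet
    descriptors: DescriptorSet          # training compounds
    query_descriptors: DescriptorSet    # held-out compounds
    coeffs_raw: tr.CoefficientTable
    coeffs: tr.CoefficientTable         # smoothed, used for prediction
    predictions: dict[str, RankedPrediction]
    records: list[vl.EvaluationRecord]
    curve: vl.SuccessCurve


def train_models(bset: bd.BioactivitySet, descriptors: DescriptorSet,
                 ratio: int = 10, seed: int = 0
                 ) -> tuple[tr.CoefficientTable, tr.CoefficientTable]:
    """Fit the 51 size-class logistic models and smooth the coefficient
    curves; returns (raw, smoothed) tables."""
    pairs_by_class = tr.build_all_training_pairs(bset, descriptors,
                                                 ratio=ratio, seed=seed)
    raw = tr.fit_all_classes(pairs_by_class)
    return raw, tr.smooth_coefficients(raw)


def run_planted_study(spec: FixtureSpec = FixtureSpec(),
                      n_conformers: int = 3, ratio: int = 10,
                      seed: int | None = None,
                      cutoffs=(1, 5, 15)) -> StudyResult:
    """Full reverse-screening study on a synthetic planted universe.

    Generates the universe, computes descriptors for all training and
    held-out compounds, trains and smooths the size-class models, screens
    every held-out analog against the per-target actives index, and scores
    success@rank against the planted truth.
    """
    if seed is None:
        seed = spec.seed
    training, test = generate_universe(spec, check=spec.n_poor_targets == 0)
    screening_set = bd.build_screening_set(training, species_filter="human")

    train_smiles = {cid: c.smiles_standardized
                    for cid, c in training.compounds.items()}
    query_smiles = test.smiles
    descriptors = featurize(train_smiles, n_conformers=n_conformers,
                            seed=seed, pool_factor=1.0)
    query_descriptors = featurize(query_smiles, n_conformers=n_conformers,
                                  seed=seed, pool_factor=1.0)

    raw, smoothed = train_models(training, descriptors, ratio=ratio, seed=seed)

    merged = DescriptorSet()
    for ds in (descriptors, query_descriptors):
        for cid in ds.ids():
            merged.add(ds[cid])
    predictions, errors = screen_all(sorted(test.compounds), merged,
                                     screening_set, smoothed)
    if errors:
        raise RuntimeError(f"screening failed for {sorted(errors)}")

    records = vl.evaluate_ranks(predictions, test.truth)
    curve = vl.success_at_rank(records, cutoffs)
    return StudyResult(training=training, test=test, descriptors=descriptors,
                       query_descriptors=query_descriptors, coeffs_raw=raw,
                       coeffs=smoothed, predictions=predictions,
                       records=records, curve=curve)
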