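"""Seeded synthetic bioactivity universes with planted similarity structure.

The generator emulates the statistical structure the similarity principle
assumes: each protein target owns an *analog series* — decorated variants of
one core scaffold — whose members are labeled active (≤ 10 µM), while
compounds built from other cores act as decoys, carrying measured-inactive
(≥ 100 µM) or gray-zone (10–100 µM) records in configurable fractions, or no
record at all (alleged inactives).  A few analogs per target are held out as
an external test set with known true targets, guaranteed absent (by
standardized canonical structure) from the training universe.

Everything is a pure function of the spec: the same seed reproduces the
universe bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from . import data as bd
from .descriptors import compute_fingerprint, tanimoto

# Hand-written core scaffolds with two substitution sites.  The first
# N_TARGET_CORES are mutually dissimilar enough that analog series do not
# bleed into each other; the remainder serve as decoy material.
CORE_TEMPLATES: tuple[str, ...] = (
    "O=C(Nc1ccc({0})cc1)c1ccc({1})o1",
    "O=S(=O)(c1ccc({0})cc1)N1CCC({1})CC1",
    "c1cc({0})ccc1-c1nc2cc({1})ccc2[nH]1",
    "c1cc({0})ccc1-c1cc({1})nn1C",
    "O=C(N1CCN(c2ccc({0})cc2)CC1)c1ccc({1})cc1",
    "c1cc({0})ccc1Oc1ccc({1})cn1",
    "c1cc({0})ccc1Cn1cnc2cc({1})ccc21",
    "c1cc({0})ccc1C(=O)N1CCC(c2ccc({1})cc2)CC1",
    "c1cc({0})ccc1-c1nnc(-c2ccc({1})cc2)o1",
    "c1cc({0})ccc1NC(=O)Cc1ccc({1})cc1",
    "c1cc({0})ccc1S(=O)(=O)Nc1ccc({1})cc1",
    "c1cc({0})ccc1-c1ccc2cc({1})ccc2c1",
    "c1cc({0})cc({1})c1N1CCOCC1",
    "c1cc({0})ccc1-c1ncnc({1})c1",
    "c1cc({0})ccc1Cc1c[nH]c2cc({1})ccc12",
    "O=C(Nc1ccc({0})cc1)Nc1ccc({1})cc1",
    "c1cc({0})cc({1})c1N1CCN(C)CC1",
    "O=c1cc(-c2ccc({0})cc2)oc2cc({1})ccc12",
    "c1cc({0})ccc1-c1nc(-c2ccc({1})cc2)cs1",
    "O=C1CC(c2ccc({0})cc2)CN1c1ccc({1})cc1",
    "c1cc({0})ccc1N1CCC2(CCOC2)CC1",
    "CC1(C)CC(=O)c2cc({0})c({1})cc2O1",
    "c1cc({0})ccc1C(=O)c1ccc({1})s1",
    # decoy / reserve cores
    "O=C(NC1CCC({0})CC1)c1ccc({1})cc1",
    "c1cc({0})ccc1CCOc1ccc({1})cc1",
    "c1cc({0})ccc1C1CC1c1ccc({1})cc1",
    "c1cc({0})ccc1-c1ccc2ncccc2c1",
    "c1cc({0})ccc1CN1CCC({1})CC1",
)
N_TARGET_CORES = 23

SUBSTITUENTS: tuple[str, ...] = (
    "[H]", "F", "Cl", "Br", "C", "CC", "OC", "N", "O", "C#N",
    "C(F)(F)F", "CCC", "OCC", "CO", "CN",
)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic bioactivity universe."""

    n_targets: int = 20
    actives_per_target: int = 30
    heldout_per_target: int = 5
    n_decoys: int = 60
    analog_depth: int = 15            # substituents used per site
    fraction_measured_inactive: float = 0.30
    fraction_gray: float = 0.05
    seed: int = 0
    # knowledge-stratification variant: the last n_poor_targets targets get
    # only poor_actives_per_target actives drawn from decoy cores (low
    # similarity to their own held-out analogs)
    n_poor_targets: int = 0
    poor_actives_per_target: int = 2


@dataclass
class ExternalTestSet:
    compounds: dict[str, bd.CompoundRecord] = field(default_factory=dict)
    truth: dict[str, set[str]] = field(default_factory=dict)

    @property
    def smiles(self) -> dict[str, str]:
        return {cid: c.smiles_standardized for cid, c in self.compounds.items()}


def enumerate_analogs(core_template: str, depth: int = 15) -> list[str]:
    """Standardized canonical SMILES of the substituent grid of one core.

    Duplicates arising from symmetric decoration collapse; order is the
    deterministic grid order of first occurrence.  Generated analogs are
    salt-free and neutral by construction, so standardization reduces to
    kekulized canonicalization (identical to the full standardizer's output
    on these structures, which keeps the universe a fixed point of the
    curation pipeline)."""
    from rdkit import Chem

    subs = SUBSTITUENTS[:depth]
    seen = set()
    out = []
    for a, b in product(subs, subs):
        mol = Chem.MolFromSmiles(core_template.format(a, b))
        if mol is None:  # pragma: no cover - templates are validated
            raise GenerationError(f"template produced unparsable analog: "
                                  f"{core_template.format(a, b)!r}")
        Chem.Kekulize(mol, clearAromaticFlags=True)
        smi = Chem.MolToSmiles(mol, kekuleSmiles=True)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_universe(spec: FixtureSpec = FixtureSpec(), check: bool = True
                      ) -> tuple[bd.BioactivitySet, ExternalTestSet]:
    """Build (training universe, external test set) from a spec.

    Each target gets a distinct core and an analog series: ``actives_per_
    target`` training actives (activity log-uniform in (0.001, 10] µM) and
    ``heldout_per_target`` held-out analogs forming the external test set.
    Decoy compounds come from reserve cores; against each target a decoy is
    measured inactive (log-uniform in [100, 10000) µM) with probability
    ``fraction_measured_inactive``, a gray-zone record (10–100 µM) with
    probability ``fraction_gray``, and otherwise carries no record (an
    alleged inactive).  With ``check=True`` the planted truth is asserted:
    every held-out analog of a regular target is closer (by fingerprint
    Tanimoto) to its own target's actives than to any other target's.
    """
    if spec.n_targets < 1 or spec.n_targets > N_TARGET_CORES:
        raise GenerationError(f"n_targets must be in 1..{N_TARGET_CORES}")
    if not 1 <= spec.analog_depth <= len(SUBSTITUENTS):
        raise GenerationError("analog_depth exceeds the substituent list")
    if spec.n_poor_targets > spec.n_targets:
        raise GenerationError("more poor targets than targets")
    rng = np.random.default_rng(spec.seed)

    compounds: dict[str, bd.CompoundRecord] = {}
    records: list[bd.ActivityRecord] = []
    test = ExternalTestSet()
    rich_targets: list[str] = []
    actives_by_target: dict[str, list[str]] = {}

    def add_compound(cid: str, smi: str) -> None:
        compounds[cid] = bd.CompoundRecord(cid, smi, bd.heavy_atom_count(smi))

    # decoy pool from reserve cores (cycled)
    reserve = list(CORE_TEMPLATES[spec.n_targets:]) or [CORE_TEMPLATES[-1]]
    decoy_smiles: list[str] = []
    per_core = int(np.ceil(spec.n_decoys / len(reserve))) if spec.n_decoys else 0
    for tpl in reserve:
        if len(decoy_smiles) >= spec.n_decoys:
            break
        pool = enumerate_analogs(tpl, spec.analog_depth)
        idx = rng.permutation(len(pool))[:per_core]
        decoy_smiles.extend(pool[i] for i in sorted(idx))
    decoy_smiles = decoy_smiles[:spec.n_decoys]
    decoy_ids = [f"DEC{k:03d}" for k in range(len(decoy_smiles))]
    for cid, smi in zip(decoy_ids, decoy_smiles):
        add_compound(cid, smi)

    n_rich = spec.n_targets - spec.n_poor_targets
    poor_pool = list(decoy_smiles)  # poor targets recruit actives from decoys

    for t in range(spec.n_targets):
        tid = f"T{t:02d}"
        series = enumerate_analogs(CORE_TEMPLATES[t], spec.analog_depth)
        is_poor = t >= n_rich
        n_actives = spec.poor_actives_per_target if is_poor else spec.actives_per_target
        n_need = spec.heldout_per_target + (0 if is_poor else n_actives)
        if len(series) < n_need:
            raise GenerationError(
                f"core {t}: grid of {len(series)} analogs cannot supply {n_need}")
        order = rng.permutation(len(series))
        cursor = 0

        active_ids: list[str] = []
        if is_poor:
            if len(poor_pool) < n_actives:
                raise GenerationError("not enough decoys to supply poor-target actives")
            pick = rng.choice(len(poor_pool), size=n_actives, replace=False)
            for j, k in enumerate(sorted(pick)):
                cid = f"{tid}P{j:02d}"
                add_compound(cid, poor_pool[k])
                active_ids.append(cid)
        else:
            rich_targets.append(tid)
            for j in range(n_actives):
                cid = f"{tid}A{j:02d}"
                add_compound(cid, series[order[cursor]])
                cursor += 1
                active_ids.append(cid)
        actives_by_target[tid] = active_ids
        for cid in active_ids:
            records.append(bd.ActivityRecord(
                cid, tid, "Ki", _log_uniform(rng, 0.001, 10.0)))

        for j in range(spec.heldout_per_target):
            cid = f"{tid}H{j}"
            smi = series[order[cursor]]
            cursor += 1
            test.compounds[cid] = bd.CompoundRecord(cid, smi, bd.heavy_atom_count(smi))
            test.truth[cid] = {tid}

        # decoy records against this target
        for cid in decoy_ids:
            u = rng.random()
            if u < spec.fraction_measured_inactive:
                records.append(bd.ActivityRecord(
                    cid, tid, "IC50", _log_uniform(rng, 100.0, 10000.0)))
            elif u < spec.fraction_measured_inactive + spec.fraction_gray:
                records.append(bd.ActivityRecord(
                    cid, tid, "IC50", _log_uniform(rng, 10.0 + 1e-9, 100.0 - 1e-9)))

    training = bd.BioactivitySet.from_records(compounds, records)

    train_structures = {c.smiles_standardized for c in compounds.values()}
    for cid, comp in test.compounds.items():
        if comp.smiles_standardized in train_structures:
            raise GenerationError(f"held-out {cid} leaked into training")

    if check and rich_targets:
        _assert_planted_truth(training, test, rich_targets, actives_by_target)
    return training, test


def _assert_planted_truth(training: bd.BioactivitySet, test: ExternalTestSet,
                          rich_targets: list[str],
                          actives_by_target: dict[str, list[str]]) -> None:
    """Planted-truth invariant: each held-out analog of a regular target is
    strictly more similar (max Tanimoto) to its target's actives than to any
    other target's actives."""
    fps = {cid: compute_fingerprint(c.smiles_standardized)
           for cid, c in training.compounds.items()}
    for qid, comp in test.compounds.items():
        (tid,) = test.truth[qid]
        if tid not in rich_targets:
            continue
        fq = compute_fingerprint(comp.smiles_standardized)
        own = max(tanimoto(fq, fps[a]) for a in actives_by_target[tid])
        for other, acts in actives_by_target.items():
            if other == tid:
                continue
            cross = max(tanimoto(fq, fps[a]) for a in acts)
            if own <= cross:
                raise GenerationError(
                    f"planted truth violated: {qid} prefers {other} "
                    f"({cross:.3f}) over {tid} ({own:.3f})")


# ---------------------------------------------------------------------------
# Flat-file output
# ---------------------------------------------------------------------------

def write_universe(training: bd.BioactivitySet, test: ExternalTestSet,
                   out_dir) -> None:
    """Write the deposit-style TSVs plus a truth file (query → targets)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bd.write_set_tsv(training, out / "training_set.tsv")
    with open(out / "test_set.tsv", "w") as fh:
        for cid in sorted(test.compounds):
            c = test.compounds[cid]
            truth = sorted(test.truth[cid])
            fh.write(f"{c.smiles_standardized}\t{cid}\t{len(truth)}\t"
                     f"{';'.join(truth)}\n")
    with open(out / "truth.tsv", "w") as fh:
        for cid in sorted(test.truth):
            fh.write(f"{cid}\t{';'.join(sorted(test.truth[cid]))}\n")


def read_truth(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            cid, targets = line.rstrip("\n").split("\t")
            out[cid] = set(targets.split(";")) if targets else set()
    return out


# ---------------------------------------------------------------------------
# Descriptor-distribution fixture
# ---------------------------------------------------------------------------

TABLE_STYLE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    # (mu_a, sigma_a, mu_b, sigma_b): heavy overlap ... clean separation
    "heavy_overlap": (93.8, 46.3, 97.7, 41.5),
    "moderate_overlap": (430.9, 118.4, 465.7, 107.2),
    "separated": (10.0, 0.5, 50.0, 0.5),
}


def generate_table1_fixture(params: dict[str, tuple[float, float, float, float]]
                            | None = None, n: int = 10000, seed: int = 0
                            ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Paired Gaussian descriptor samples for exercising the Z-factor across
    overlap regimes.  Returns name → (sample_a, sample_b)."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, (mu_a, sd_a, mu_b, sd_b) in (params or TABLE_STYLE_PARAMS).items():
        out[name] = (rng.normal(mu_a, sd_a, size=n), rng.normal(mu_b, sd_b, size=n))
    return out
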