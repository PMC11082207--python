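"""Bioactivity data model: curation, labeling and flat-file I/O.

Activity records (compound, target, measure, value) are condensed into
per-pair labels with the standard two-threshold rule: a pair is *active* if
any qualifying measurement is ≤ 10 µM, *inactive* if all measurements are
≥ 100 µM, and falls in the *gray area* otherwise (gray pairs train neither
class).  Compounds are kept when they have 5–80 heavy atoms and were tested
in a permitted assay class on a permitted species.

Structures are standardized before any identity comparison: largest organic
fragment (unsalting/desolvation), neutralization where chemically valid,
and a kekulized canonical SMILES.  Overlap removal between an external test
set and the training set is by equality of these standardized canonical
SMILES (stereochemistry-sensitive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

ACTIVE_THRESHOLD_UM = 10.0
INACTIVE_THRESHOLD_UM = 100.0
MIN_HEAVY_ATOMS = 5
MAX_HEAVY_ATOMS = 80

MEASURE_TYPES = frozenset({"IC50", "EC50", "Ki", "KD", "Kic", "Km"})
ASSAY_CLASSES = frozenset({
    "binding", "enzymatic", "generic", "second_messenger",
    "electrophysiology", "transactivation",
})
SPECIES = frozenset({"human", "rat", "mouse"})

ACTIVE, INACTIVE, GRAY = "active", "inactive", "gray"


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    target_id: str
    measure_type: str
    value_uM: float
    assay_class: str = "binding"
    species: str = "human"

    def __post_init__(self):
        if self.value_uM <= 0:
            raise ValueError(f"activity value must be > 0 µM, got {self.value_uM}")
        if self.measure_type not in MEASURE_TYPES:
            raise ValueError(f"unknown measure type {self.measure_type!r}")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles_standardized: str
    heavy_atoms: int


def standardize_structure(raw) -> str:
    """Standardized kekulized canonical SMILES of the largest organic fragment.

    Counter-ions and solvents are dropped, the remaining fragment neutralized
    where chemically valid.  Idempotent: standardizing the output returns it
    unchanged.
    """
    if isinstance(raw, Chem.Mol):
        mol = raw
    else:
        mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise ParseError(f"unparsable structure: {raw!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.LargestFragmentChooser(preferOrganic=True).choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return Chem.MolToSmiles(mol, kekuleSmiles=True)


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable structure: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def classify_activity(records: list[ActivityRecord]) -> str:
    """Label one compound–target pair from all its measurements.

    Any measurement ≤ 10 µM ⇒ active (takes precedence); all ≥ 100 µM ⇒
    inactive; anything else is the gray area.  Order-independent.
    """
    if not records:
        raise ValueError("no activity records for pair")
    values = [r.value_uM for r in records]
    if any(v <= ACTIVE_THRESHOLD_UM for v in values):
        return ACTIVE
    if all(v >= INACTIVE_THRESHOLD_UM for v in values):
        return INACTIVE
    return GRAY


@dataclass
class BioactivitySet:
    """Compounds, per-pair labels and the per-target actives index."""

    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    records: list[ActivityRecord] = field(default_factory=list)
    labels: dict[tuple[str, str], str] = field(default_factory=dict)
    targets: dict[str, list[str]] = field(default_factory=dict)
    target_species: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_records(cls, compounds: dict[str, CompoundRecord],
                     records: list[ActivityRecord],
                     target_species: dict[str, str] | None = None) -> "BioactivitySet":
        by_pair: dict[tuple[str, str], list[ActivityRecord]] = {}
        species: dict[str, str] = dict(target_species or {})
        for r in records:
            by_pair.setdefault((r.compound_id, r.target_id), []).append(r)
            species.setdefault(r.target_id, r.species)
        labels = {pair: classify_activity(rs) for pair, rs in by_pair.items()}
        targets: dict[str, list[str]] = {}
        for (cid, tid), lab in sorted(labels.items()):
            if lab == ACTIVE:
                acts = targets.setdefault(tid, [])
                if cid not in acts:
                    acts.append(cid)
        return cls(compounds=dict(compounds), records=list(records),
                   labels=labels, targets=targets, target_species=species)

    def label(self, compound_id: str, target_id: str) -> str | None:
        return self.labels.get((compound_id, target_id))

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.targets)


def filter_compounds(bset: BioactivitySet) -> tuple[BioactivitySet, dict[str, int]]:
    """Apply the curation filters; returns (filtered set, removal counts).

    Criteria: 5 ≤ heavy atoms ≤ 80 (inclusive), permitted assay class,
    permitted species.  Records failing any criterion are dropped; compounds
    left without records are dropped.
    """
    removed = {"heavy_atoms": 0, "assay_class": 0, "species": 0}
    bad_compounds = set()
    for cid, comp in bset.compounds.items():
        if not MIN_HEAVY_ATOMS <= comp.heavy_atoms <= MAX_HEAVY_ATOMS:
            bad_compounds.add(cid)
    kept_records = []
    for r in bset.records:
        if r.compound_id in bad_compounds:
            removed["heavy_atoms"] += 1
        elif r.assay_class not in ASSAY_CLASSES:
            removed["assay_class"] += 1
        elif r.species not in SPECIES:
            removed["species"] += 1
        else:
            kept_records.append(r)
    kept_ids = {r.compound_id for r in kept_records}
    kept_compounds = {cid: c for cid, c in bset.compounds.items() if cid in kept_ids}
    return (BioactivitySet.from_records(kept_compounds, kept_records,
                                        bset.target_species), removed)


def remove_overlap(test_set: BioactivitySet,
                   training_set: BioactivitySet) -> BioactivitySet:
    """External-set guarantee: drop test compounds whose standardized
    structure occurs in training, and restrict test targets to those present
    in training.  Structures are compared as-is (no re-standardization)."""
    train_smiles = {c.smiles_standardized for c in training_set.compounds.values()}
    train_targets = set(training_set.targets)
    kept_compounds = {cid: c for cid, c in test_set.compounds.items()
                      if c.smiles_standardized not in train_smiles}
    kept_records = [r for r in test_set.records
                    if r.compound_id in kept_compounds and r.target_id in train_targets]
    kept_ids = {r.compound_id for r in kept_records}
    kept_compounds = {cid: c for cid, c in kept_compounds.items() if cid in kept_ids}
    return BioactivitySet.from_records(kept_compounds, kept_records,
                                       test_set.target_species)


def build_screening_set(training_set: BioactivitySet,
                        species_filter: str = "human") -> BioactivitySet:
    """The screening set: active pairs only, on targets of one species."""
    keep_targets = {t for t in training_set.targets
                    if species_filter is None
                    or training_set.target_species.get(t, "human") == species_filter}
    kept_records = [r for r in training_set.records
                    if r.target_id in keep_targets
                    and training_set.labels.get((r.compound_id, r.target_id)) == ACTIVE]
    kept_ids = {r.compound_id for r in kept_records}
    kept_compounds = {cid: c for cid, c in training_set.compounds.items()
                      if cid in kept_ids}
    return BioactivitySet.from_records(kept_compounds, kept_records,
                                       training_set.target_species)


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------

def write_set_tsv(bset: BioactivitySet, path) -> None:
    """Deposit-style flat file: ``smiles<TAB>id<TAB>n_targets<TAB>t1;t2;…``.

    One row per compound; targets are the targets on which the compound is
    labeled active (sorted for determinism).
    """
    by_compound: dict[str, list[str]] = {cid: [] for cid in bset.compounds}
    for (cid, tid), lab in bset.labels.items():
        if lab == ACTIVE and cid in by_compound:
            by_compound[cid].append(tid)
    with open(path, "w") as fh:
        for cid in sorted(by_compound):
            targets = sorted(set(by_compound[cid]))
            smi = bset.compounds[cid].smiles_standardized
            fh.write(f"{smi}\t{cid}\t{len(targets)}\t{';'.join(targets)}\n")


def read_set_tsv(path, target_species: dict[str, str] | None = None) -> BioactivitySet:
    """Read the deposit-style flat file back into a BioactivitySet.

    Every listed target is materialized as one active record (1 µM proxy
    value; the flat file stores labels, not raw measurements)."""
    compounds: dict[str, CompoundRecord] = {}
    records: list[ActivityRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            smi, cid, _n, targets = line.split("\t")
            compounds[cid] = CompoundRecord(cid, smi, heavy_atom_count(smi))
            for tid in targets.split(";") if targets else []:
                records.append(ActivityRecord(cid, tid, "Ki", 1.0))
    return BioactivitySet.from_records(compounds, records, target_species)


def read_activity_csv(path) -> tuple[dict[str, str], list[ActivityRecord]]:
    """Raw activity CSV with columns
    ``compound_id,smiles,target_id,measure_type,value,unit,assay_class,species``.
    Values in nM are converted to µM on read.  Returns (raw smiles by id,
    records)."""
    smiles: dict[str, str] = {}
    records: list[ActivityRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            value = float(row["value"])
            unit = row.get("unit", "uM").strip()
            if unit == "nM":
                value /= 1000.0
            elif unit not in ("uM", "µM"):
                raise ParseError(f"unknown unit {unit!r}")
            smiles[row["compound_id"]] = row["smiles"]
            records.append(ActivityRecord(
                compound_id=row["compound_id"],
                target_id=row["target_id"],
                measure_type=row["measure_type"],
                value_uM=value,
                assay_class=row.get("assay_class", "binding"),
                species=row.get("species", "human"),
            ))
    return smiles, records


def read_sdf(path) -> dict[str, str]:
    """Read structures from an SDF file; returns raw SMILES keyed by the
    molecule name (or a positional id when unnamed)."""
    out: dict[str, str] = {}
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        out[name] = Chem.MolToSmiles(mol)
    return out


def curate(raw_smiles: dict[str, str], records: list[ActivityRecord]) -> tuple[BioactivitySet, dict[str, int]]:
    """Standardize structures, build the labeled set and apply the filters."""
    compounds = {}
    for cid, smi in raw_smiles.items():
        std = standardize_structure(smi)
        compounds[cid] = CompoundRecord(cid, std, heavy_atom_count(std))
    bset = BioactivitySet.from_records(compounds, records)
    return filter_compounds(bset)
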