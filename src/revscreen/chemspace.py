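"""Physicochemical space, distribution overlap, and molecular scaffolds.

Two compound collections (e.g. a training set and an external test set) are
compared in three complementary ways:

* seven physicochemical descriptors per compound (MW, Wildman–Crippen WLOGP,
  Ertl TPSA, rotatable bonds, fraction of sp3 carbons, H-bond acceptors and
  donors);
* the Z-factor overlap statistic per descriptor,
  ``Z = 1 − 3(σ_a + σ_b) / |µ_a − µ_b|`` — at most 1, and strongly negative
  when the two distributions overlap heavily;
* two scaffold abstractions: the Bemis–Murcko wire-like framework (ring
  systems plus linkers, every atom carbon, every bond single) and the more
  abstract Oprea scaffold (the wire frame with linker chains contracted to
  direct ring–ring bonds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

EMPTY_SCAFFOLD = ""


class UndefinedStatisticError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class PhyschemProfile:
    MW: float
    WLOGP: float
    TPSA: float
    n_rotatable_bonds: int
    fCsp3: float
    HBA: int
    HBD: int


def physchem_profile(smiles: str) -> PhyschemProfile:
    """Seven physicochemical descriptors via atomic-contribution methods."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure: {smiles!r}")
    return PhyschemProfile(
        MW=float(Descriptors.MolWt(mol)),
        WLOGP=float(Crippen.MolLogP(mol)),
        TPSA=float(Descriptors.TPSA(mol)),
        n_rotatable_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        fCsp3=float(Descriptors.FractionCSP3(mol)),
        HBA=int(rdMolDescriptors.CalcNumHBA(mol)),
        HBD=int(rdMolDescriptors.CalcNumHBD(mol)),
    )


def z_factor(mu_a: float, sigma_a: float, mu_b: float, sigma_b: float) -> float:
    """Overlap statistic ``1 − 3(σ_a + σ_b) / |µ_a − µ_b|`` (≤ 1)."""
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("standard deviations must be non-negative")
    diff = abs(mu_a - mu_b)
    if diff == 0:
        raise UndefinedStatisticError("Z-factor undefined for equal means")
    return 1.0 - 3.0 * (sigma_a + sigma_b) / diff


@dataclass(frozen=True)
class DescriptorSummary:
    descriptor: str
    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    z: float


def descriptor_summary(samples_a: dict[str, np.ndarray],
                       samples_b: dict[str, np.ndarray]) -> list[DescriptorSummary]:
    """Per-descriptor means, SDs and Z-factor for two profiled sets."""
    out = []
    for name in samples_a:
        a = np.asarray(samples_a[name], dtype=float)
        b = np.asarray(samples_b[name], dtype=float)
        mu_a, sd_a = float(a.mean()), float(a.std())
        mu_b, sd_b = float(b.mean()), float(b.std())
        out.append(DescriptorSummary(name, mu_a, sd_a, mu_b, sd_b,
                                     z_factor(mu_a, sd_a, mu_b, sd_b)))
    return out


def profile_set(smiles_by_id: dict[str, str]) -> dict[str, np.ndarray]:
    """Columns of physicochemical descriptor values over a compound set."""
    profiles = [physchem_profile(s) for _, s in sorted(smiles_by_id.items())]
    return {
        "MW": np.array([p.MW for p in profiles]),
        "WLOGP": np.array([p.WLOGP for p in profiles]),
        "TPSA": np.array([p.TPSA for p in profiles]),
        "n_rotatable_bonds": np.array([p.n_rotatable_bonds for p in profiles], float),
        "fCsp3": np.array([p.fCsp3 for p in profiles]),
        "HBA": np.array([p.HBA for p in profiles], float),
        "HBD": np.array([p.HBD for p in profiles], float),
    }


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------

def _wire_frame(mol: Chem.Mol) -> Chem.Mol:
    """All atoms → carbon, all bonds → single (wire-like abstraction)."""
    rw = Chem.RWMol()
    for _ in range(mol.GetNumAtoms()):
        rw.AddAtom(Chem.Atom(6))
    for b in mol.GetBonds():
        rw.AddBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), Chem.BondType.SINGLE)
    m = rw.GetMol()
    m.UpdatePropertyCache(strict=False)
    Chem.GetSymmSSSR(m)
    return m


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko wire-like framework as a canonical SMILES.

    Side chains are stripped, then every atom is levelled to carbon and every
    bond to a single bond; stripping and levelling iterate to a fixed point
    so the scaffold of a scaffold is itself.  Acyclic molecules yield the
    EMPTY scaffold ''.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure: {smiles!r}")
    prev = None
    for _ in range(8):
        core = MurckoScaffold.GetScaffoldForMol(mol)
        if core.GetNumAtoms() == 0:
            return EMPTY_SCAFFOLD
        mol = _wire_frame(core)
        smi = Chem.MolToSmiles(mol)
        if smi == prev:
            return smi
        prev = smi
    return prev


def _contract_linkers(mol: Chem.Mol) -> Chem.Mol:
    """Drop terminal non-ring atoms, contract degree-2 non-ring linker atoms."""
    changed = True
    while changed:
        changed = False
        mol.UpdatePropertyCache(strict=False)
        Chem.GetSymmSSSR(mol)
        for atom in mol.GetAtoms():
            if atom.IsInRing():
                continue
            deg = atom.GetDegree()
            if deg <= 1:
                rw = Chem.RWMol(mol)
                rw.RemoveAtom(atom.GetIdx())
                mol = rw.GetMol()
                changed = True
                break
            if deg == 2:
                n1, n2 = (n.GetIdx() for n in atom.GetNeighbors())
                rw = Chem.RWMol(mol)
                if rw.GetBondBetweenAtoms(n1, n2) is None:
                    rw.AddBond(n1, n2, Chem.BondType.SINGLE)
                rw.RemoveAtom(atom.GetIdx())
                mol = rw.GetMol()
                changed = True
                break
    return mol


def oprea_scaffold(smiles: str) -> str:
    """Oprea-style ring/linker graph abstraction as a canonical SMILES.

    Computed from the Murcko wire frame by removing residual terminal atoms
    and contracting every chain of non-ring linker atoms to a direct bond
    between the ring atoms it connected, leaving a pure ring-and-junction
    graph.  A function of the Murcko scaffold: compounds sharing a Murcko
    scaffold share an Oprea scaffold.  EMPTY for acyclic molecules.
    """
    core = murcko_scaffold(smiles)
    if core == EMPTY_SCAFFOLD:
        return EMPTY_SCAFFOLD
    mol = _contract_linkers(Chem.MolFromSmiles(core))
    if mol.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    mol.UpdatePropertyCache(strict=False)
    Chem.GetSymmSSSR(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Scaffold bookkeeping
# ---------------------------------------------------------------------------

def mean_molecules_per_scaffold(n_molecules: int, n_scaffolds: int) -> float:
    """Average number of molecules described by one scaffold."""
    if n_scaffolds <= 0:
        raise ValueError("scaffold count must be positive")
    return n_molecules / n_scaffolds


def percentage(part: int, whole: int) -> float:
    if whole <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * part / whole


@dataclass
class ScaffoldOverlapReport:
    kind: str
    n_scaffolds_a: int
    n_scaffolds_b: int
    n_shared: int
    pct_shared_a: float              # shared scaffolds as % of set A scaffolds
    pct_shared_b: float
    mols_per_scaffold_a: float
    mols_per_scaffold_b: float
    n_molecules_exclusive_a: int     # molecules described only by A-exclusive scaffolds
    n_molecules_exclusive_b: int


def scaffold_set_stats(smiles_a: dict[str, str], smiles_b: dict[str, str],
                       kind: str = "murcko") -> ScaffoldOverlapReport:
    """Scaffold counts, shared fractions and per-scaffold molecule averages.

    Acyclic molecules (EMPTY scaffold) are excluded from scaffold counts but
    kept in the molecule totals for the per-scaffold averages."""
    fn = {"murcko": murcko_scaffold, "oprea": oprea_scaffold}[kind]
    sc_a = {cid: fn(s) for cid, s in smiles_a.items()}
    sc_b = {cid: fn(s) for cid, s in smiles_b.items()}
    set_a = {s for s in sc_a.values() if s}
    set_b = {s for s in sc_b.values() if s}
    shared = set_a & set_b
    return ScaffoldOverlapReport(
        kind=kind,
        n_scaffolds_a=len(set_a),
        n_scaffolds_b=len(set_b),
        n_shared=len(shared),
        pct_shared_a=percentage(len(shared), len(set_a)) if set_a else 0.0,
        pct_shared_b=percentage(len(shared), len(set_b)) if set_b else 0.0,
        mols_per_scaffold_a=mean_molecules_per_scaffold(len(sc_a), len(set_a))
        if set_a else float("nan"),
        mols_per_scaffold_b=mean_molecules_per_scaffold(len(sc_b), len(set_b))
        if set_b else float("nan"),
        n_molecules_exclusive_a=sum(1 for s in sc_a.values()
                                    if s and s not in set_b),
        n_molecules_exclusive_b=sum(1 for s in sc_b.values()
                                    if s and s not in set_a),
    )
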