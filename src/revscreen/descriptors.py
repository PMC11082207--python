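"""Conformer shape descriptors and path fingerprints.

A molecule is represented for similarity search by two complementary
descriptors:

* up to 20 *ES5D vectors*, one per 3D conformer: each conformer's atoms are
  embedded in a 5-dimensional space (the three Cartesian coordinates in Å,
  the Gasteiger partial charge and the Wildman–Crippen atomic lipophilicity
  contribution, both scaled to Å-comparable units), six reference centroids
  are placed in that space, and for each centroid the mean, standard
  deviation and (sign-preserving cube root of the) third central moment of
  the atom–centroid distances are recorded — 18 floats per conformer;
* one 1024-bit *path fingerprint* hashing the linear atom paths of the 2D
  structure (paths of 1–6 bonds, i.e. 2–7 atoms).

Shape similarity between two molecules is the Manhattan-based score
``1 / (1 + d/18)`` where ``d`` is the smallest L1 distance over all
conformer pairs; chemical similarity is the Tanimoto coefficient of the
fingerprints.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen
from scipy.spatial.distance import cdist

ES5D_DIM = 18
N_CENTROIDS = 6
FP_NBITS = 1024

#: scaling of the charge dimension, Å per elementary charge (ElectroShape convention)
CHARGE_SCALE = 25.0
#: scaling of the lipophilicity dimension, Å per log-unit of the atomic
#: Wildman–Crippen contribution; chosen so the dimension's per-atom spread is
#: comparable to atomic coordinates (contributions span roughly -1..+1)
LOGP_SCALE = 7.5


class DescriptorError(ValueError):
    """Raised when a structure cannot be featurized."""


# ---------------------------------------------------------------------------
# ES5D
# ---------------------------------------------------------------------------

def _centroids_5d(pts: np.ndarray) -> np.ndarray:
    """Place the six ES5D reference centroids for a (n, 5) point cloud.

    c1 is the barycentre, c2 the point furthest from c1, c3 the point
    furthest from c2.  c4/c5 sit off the molecular plane along the cross
    product of the spatial parts of (c2-c1) and (c3-c1), carrying the extreme
    scaled charges; c6 sits at the barycentre carrying the extreme scaled
    lipophilicity.  Degenerate geometries (single atom, collinear spatial
    arrangement) duplicate the barycentre for the undefined centroids so the
    descriptor is always 18 values.
    """
    c1 = pts.mean(axis=0)
    d1 = np.linalg.norm(pts - c1, axis=1)
    c2 = pts[int(np.argmax(d1))]
    d2 = np.linalg.norm(pts - c2, axis=1)
    c3 = pts[int(np.argmax(d2))]

    a = (c2 - c1)[:3]
    b = (c3 - c1)[:3]
    cross = np.cross(a, b)
    norm = np.linalg.norm(cross)
    if norm < 1e-12:
        c4 = c1.copy()
        c5 = c1.copy()
    else:
        u = cross / norm
        r = np.linalg.norm(a) / 2.0
        q_hi = pts[:, 3].max()
        q_lo = pts[:, 3].min()
        c4 = np.concatenate([c1[:3] + u * r, [q_hi], [c1[4]]])
        c5 = np.concatenate([c1[:3] - u * r, [q_lo], [c1[4]]])
    c6 = c1.copy()
    c6[4] = pts[:, 4].max()
    return np.stack([c1, c2, c3, c4, c5, c6])


def _moments(dists: np.ndarray) -> tuple[float, float, float]:
    mean = float(dists.mean())
    centred = dists - mean
    std = float(np.sqrt(np.mean(centred ** 2)))
    m3 = float(np.mean(centred ** 3))
    return mean, std, float(np.cbrt(m3))


def compute_es5d(
    coords: np.ndarray,
    charges: np.ndarray,
    logp_contribs: np.ndarray,
    charge_scale: float = CHARGE_SCALE,
    logp_scale: float = LOGP_SCALE,
) -> np.ndarray:
    """ES5D vector (18 floats) of one conformer.

    Parameters
    ----------
    coords : (n_atoms, 3) Cartesian coordinates in Å.
    charges : (n_atoms,) partial charges in e.
    logp_contribs : (n_atoms,) atomic lipophilicity contributions.

    Returns the concatenation, over the six centroids, of (mean, standard
    deviation, cube-rooted third central moment) of the atom–centroid
    distances.  Invariant under rigid rotation and translation.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    logp_contribs = np.asarray(logp_contribs, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise DescriptorError("coords must be a non-empty (n, 3) array")
    if charges.shape[0] != coords.shape[0] or logp_contribs.shape[0] != coords.shape[0]:
        raise DescriptorError("charge/lipophilicity annotation missing for some atoms")
    if not (np.isfinite(charges).all() and np.isfinite(logp_contribs).all()):
        raise DescriptorError("non-finite charge or lipophilicity annotation")

    pts = np.column_stack([
        coords,
        charges * charge_scale,
        logp_contribs * logp_scale,
    ])
    out = np.empty(ES5D_DIM)
    for p, c in enumerate(_centroids_5d(pts)):
        d = np.linalg.norm(pts - c, axis=1)
        out[3 * p: 3 * p + 3] = _moments(d)
    return out


def manhattan_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Shape similarity ``M_s = 1 / (1 + d/18)`` for two 18-d ES5D vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != (ES5D_DIM,) or v.shape != (ES5D_DIM,):
        raise DescriptorError(f"ES5D vectors must have length {ES5D_DIM}")
    d = float(np.abs(u - v).sum())
    return 1.0 / (1.0 + d / ES5D_DIM)


def best_pair_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Max Manhattan similarity over all conformer pairs of two molecules.

    ``a`` and ``b`` are (n_conformers, 18) ES5D matrices; the score uses the
    smallest L1 distance over the full conformer-pair grid.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise DescriptorError("empty conformer set")
    if a.shape[1] != ES5D_DIM or b.shape[1] != ES5D_DIM:
        raise DescriptorError(f"ES5D vectors must have length {ES5D_DIM}")
    d = cdist(a, b, metric="cityblock").min()
    return 1.0 / (1.0 + float(d) / ES5D_DIM)


# ---------------------------------------------------------------------------
# Path fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathFingerprint:
    """1024-bit linear-path fingerprint."""

    bits: np.ndarray  # bool, length 1024

    def __post_init__(self):
        arr = np.asarray(self.bits, dtype=bool)
        if arr.shape != (FP_NBITS,):
            raise DescriptorError(f"fingerprint must have {FP_NBITS} bits")
        object.__setattr__(self, "bits", arr)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, s: str) -> "PathFingerprint":
        raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
        return cls(np.unpackbits(raw)[:FP_NBITS].astype(bool))

    def __eq__(self, other) -> bool:
        return isinstance(other, PathFingerprint) and bool((self.bits == other.bits).all())


def compute_fingerprint(mol_or_smiles) -> PathFingerprint:
    """Linear-path fingerprint (paths of 2–7 atoms hashed to 1024 bits)."""
    mol = _as_mol(mol_or_smiles)
    if mol.GetNumHeavyAtoms() < 1:
        raise DescriptorError("structure has no heavy atoms")
    bv = Chem.RDKFingerprint(mol, minPath=1, maxPath=6, fpSize=FP_NBITS,
                             branchedPaths=False)
    bits = np.zeros(FP_NBITS, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return PathFingerprint(bits)


def tanimoto(a: PathFingerprint, b: PathFingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; 0.0 when both sets are empty."""
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Conformers
# ---------------------------------------------------------------------------

@dataclass
class ConformerSet:
    """All-atom conformers of one compound, annotated for ES5D."""

    compound_id: str
    elements: list[str]
    coords: np.ndarray          # (n_conf, n_atoms, 3) in Å
    charges: np.ndarray         # (n_atoms,) Gasteiger, e
    logp_contribs: np.ndarray   # (n_atoms,) Wildman–Crippen atomic contributions
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # i, j, order

    @property
    def count(self) -> int:
        return int(self.coords.shape[0])

    def es5d(self, charge_scale: float = CHARGE_SCALE,
             logp_scale: float = LOGP_SCALE) -> np.ndarray:
        """(n_conf, 18) matrix of ES5D vectors, one row per conformer."""
        return np.stack([
            compute_es5d(self.coords[i], self.charges, self.logp_contribs,
                         charge_scale, logp_scale)
            for i in range(self.count)
        ])


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    mol = Chem.MolFromSmiles(mol_or_smiles)
    if mol is None:
        raise DescriptorError(f"unparsable structure: {mol_or_smiles!r}")
    return mol


def derive_seed(base_seed: int, compound_id: str) -> int:
    """Stable per-compound RNG seed below 2**31."""
    return (int(base_seed) * 1000003 + zlib.crc32(compound_id.encode())) % (2 ** 31 - 1)


def generate_conformers(
    mol_or_smiles,
    compound_id: str = "",
    n_conformers: int = 20,
    seed: int = 0,
    pool_factor: float = 2.0,
) -> ConformerSet:
    """Embed 3D conformers and keep the ``n_conformers`` lowest in energy.

    Distance-geometry embedding (ETKDGv3, seeded) of ``pool_factor *
    n_conformers`` candidates followed by MMFF94 optimisation; conformers are
    ranked by force-field energy and the lowest kept.  Hydrogens are explicit
    (the shape descriptor is all-atom).  Deterministic for a given
    (structure, seed).
    """
    if not 1 <= n_conformers <= 20:
        raise DescriptorError("n_conformers must be in 1..20")
    mol = _as_mol(mol_or_smiles)
    if mol.GetNumHeavyAtoms() < 1:
        raise DescriptorError("structure has no heavy atoms")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    n_pool = max(n_conformers, int(round(pool_factor * n_conformers)))
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_pool, params=params)
    if len(conf_ids) == 0:
        # fall back to unconstrained DG for pathological geometries
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_pool, params=params)
    if len(conf_ids) == 0:
        raise DescriptorError(f"conformer embedding failed for {compound_id!r}")

    energies: list[tuple[float, int]] = []
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=200)
        for cid, (converged, energy) in zip(conf_ids, results):
            energies.append((float(energy) if converged != -1 else np.inf, int(cid)))
    except Exception:  # MMFF typing can fail for exotic atoms
        energies = [(0.0, int(cid)) for cid in conf_ids]
    energies.sort(key=lambda t: (t[0], t[1]))
    keep = [cid for _, cid in energies[:n_conformers]]

    AllChem.ComputeGasteigerCharges(molh)
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()])
    charges = np.nan_to_num(charges, nan=0.0, posinf=0.0, neginf=0.0)
    contribs = np.array([c[0] for c in Crippen.rdMolDescriptors._CalcCrippenContribs(molh)])

    coords = np.stack([
        np.array(molh.GetConformer(cid).GetPositions(), dtype=float) for cid in keep
    ])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              int(b.GetBondTypeAsDouble())) for b in molh.GetBonds()]
    return ConformerSet(
        compound_id=compound_id,
        elements=[a.GetSymbol() for a in molh.GetAtoms()],
        coords=coords,
        charges=charges,
        logp_contribs=contribs,
        bonds=bonds,
    )


# ---------------------------------------------------------------------------
# Multi-MOL2 output
# ---------------------------------------------------------------------------

def write_mol2(conformers: ConformerSet, path) -> None:
    """Write a multi-record TRIPOS MOL2 file, one record per conformer."""
    lines: list[str] = []
    n_atoms = len(conformers.elements)
    n_bonds = len(conformers.bonds)
    for k in range(conformers.count):
        lines.append("@<TRIPOS>MOLECULE")
        lines.append(f"{conformers.compound_id}_conf{k + 1}")
        lines.append(f"{n_atoms} {n_bonds} 0 0 0")
        lines.append("SMALL")
        lines.append("GASTEIGER")
        lines.append("@<TRIPOS>ATOM")
        for i, el in enumerate(conformers.elements):
            x, y, z = conformers.coords[k, i]
            q = conformers.charges[i]
            lines.append(
                f"{i + 1:>7d} {el:<4s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                f"{el:<5s} 1 UNL1 {q:>9.4f}"
            )
        lines.append("@<TRIPOS>BOND")
        for j, (a, b, order) in enumerate(conformers.bonds):
            lines.append(f"{j + 1:>6d} {a + 1:>5d} {b + 1:>5d} {order:>4d}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Descriptor store
# ---------------------------------------------------------------------------

@dataclass
class CompoundDescriptors:
    compound_id: str
    es5d: np.ndarray            # (n_conf, 18)
    fingerprint: PathFingerprint
    n_heavy: int


class DescriptorSet:
    """In-memory store of per-compound descriptors with TSV persistence.

    Cache layout (one row per compound, tab-separated)::

        compound_id  n_heavy  fp_hex  n_conf  v1 v2 ... v(18*n_conf)

    Floats are written with 17 significant digits, which round-trips IEEE-754
    doubles bit-exactly.
    """

    def __init__(self):
        self._store: dict[str, CompoundDescriptors] = {}

    def add(self, d: CompoundDescriptors) -> None:
        self._store[d.compound_id] = d

    def __getitem__(self, compound_id: str) -> CompoundDescriptors:
        return self._store[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._store

    def __len__(self) -> int:
        return len(self._store)

    def ids(self) -> list[str]:
        return sorted(self._store)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for cid in self.ids():
                d = self._store[cid]
                vals = " ".join(f"{v:.17g}" for v in d.es5d.ravel())
                fh.write(f"{cid}\t{d.n_heavy}\t{d.fingerprint.to_hex()}\t"
                         f"{d.es5d.shape[0]}\t{vals}\n")

    @classmethod
    def load(cls, path) -> "DescriptorSet":
        out = cls()
        with open(path) as fh:
            for line in fh:
                cid, n_heavy, fp_hex, n_conf, vals = line.rstrip("\n").split("\t")
                arr = np.array([float(v) for v in vals.split()])
                out.add(CompoundDescriptors(
                    compound_id=cid,
                    es5d=arr.reshape(int(n_conf), ES5D_DIM),
                    fingerprint=PathFingerprint.from_hex(fp_hex),
                    n_heavy=int(n_heavy),
                ))
        return out


def featurize(
    smiles_by_id: dict[str, str],
    n_conformers: int = 20,
    seed: int = 0,
    pool_factor: float = 2.0,
) -> DescriptorSet:
    """Compute ES5D matrices and fingerprints for a batch of compounds.

    Per-compound RNG seeds are derived from ``seed`` and the compound id so
    the result is independent of iteration order.
    """
    out = DescriptorSet()
    for cid in sorted(smiles_by_id):
        smi = smiles_by_id[cid]
        mol = _as_mol(smi)
        cs = generate_conformers(mol, compound_id=cid, n_conformers=n_conformers,
                                 seed=derive_seed(seed, cid), pool_factor=pool_factor)
        out.add(CompoundDescriptors(
            compound_id=cid,
            es5d=cs.es5d(),
            fingerprint=compute_fingerprint(mol),
            n_heavy=mol.GetNumHeavyAtoms(),
        ))
    return out
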