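"""Molecular Quantum Numbers: 42 integer descriptors of the molecular graph.

The MQN system counts atoms, bonds, polarity features and topological
features of a molecule, yielding a 42-dimensional non-negative integer
vector.  Similarity between molecules is measured by the city-block
(Manhattan, L1) distance between their MQN vectors.

Descriptor order (canonical, fixed):

* atom counts: ``c f cl br i s p`` (elements), ``an/cn`` acyclic/cyclic
  nitrogens, ``ao/co`` acyclic/cyclic oxygens, ``hac`` heavy-atom count;
* bond counts on the kekulized graph: ``asb/adb/atb`` acyclic
  single/double/triple, ``csb/cdb/ctb`` cyclic single/double/triple,
  ``rbc`` rotatable bonds;
* polarity counts: ``hba/hbd`` H-bond acceptor/donor atoms, ``hbam/hbdm``
  acceptor/donor sites, ``pos/neg`` formal charges at pH 7.4;
* topology counts: ``asv/adv/atv/aqv`` acyclic mono/di/tri/tetravalent
  nodes, ``cdv/ctv/cqv`` cyclic di/tri/tetravalent nodes, ``r3`` ... ``r9``
  ring-size counts, ``rg10`` rings of ten or more atoms, ``afr/bfr``
  atoms/bonds shared by fused rings.  Ring counts use the smallest set of
  smallest rings (SSSR).

Molecules are ionized at pH 7.4 by a fixed substructure rule table before
descriptor computation (acids deprotonated, aliphatic amines / amidines /
guanidines protonated), so ``pos``/``neg`` reflect physiological charge
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .molio import MoleculeRecord

MQN_NAMES: tuple[str, ...] = (
    # atom counts
    "c", "f", "cl", "br", "i", "s", "p",
    "an", "cn", "ao", "co", "hac",
    # bond counts
    "asb", "adb", "atb", "csb", "cdb", "ctb", "rbc",
    # polarity counts
    "hba", "hbd", "hbam", "hbdm", "pos", "neg",
    # topology counts
    "asv", "adv", "atv", "aqv", "cdv", "ctv", "cqv",
    "r3", "r4", "r5", "r6", "r7", "r8", "r9", "rg10",
    "afr", "bfr",
)

N_MQN = 42

_IDX = {name: i for i, name in enumerate(MQN_NAMES)}


class MQNError(ValueError):
    """Raised when a molecule cannot be described by MQN."""


# --------------------------------------------------------------------------
# Ionization at pH 7.4
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IonizationRule:
    name: str
    smarts: str
    atom_index: int  # index within the SMARTS match of the atom to charge
    charge: int      # +1 protonate, -1 deprotonate


#: Ordered rule table applied at pH 7.4.  Acidic O-H groups with pKa well
#: below 7.4 lose a proton; basic nitrogens with conjugate-acid pKa above
#: 7.4 gain one.  Alcohols, phenols, thiols and amides are untouched.
#: Rules are mutually exclusive per atom: an atom already charged by an
#: earlier rule is never matched again.
IONIZATION_RULES: tuple[IonizationRule, ...] = (
    IonizationRule("carboxylic acid", "[CX3](=O)[OX2H1]", 2, -1),
    IonizationRule("sulfonic acid", "[SX4](=O)(=O)[OX2H1]", 3, -1),
    IonizationRule("sulfinic acid", "[SX3](=O)[OX2H1]", 2, -1),
    IonizationRule("P-oxyacid O-H", "[PX4](=O)[OX2H1]", 2, -1),
    IonizationRule(
        "guanidine",
        "[NX3][CX3](=[NX2;!$(N=C[O,S])])[NX3]", 2, +1,
    ),
    IonizationRule(
        "amidine",
        "[CX3;!$(C([NX3])[NX3])](=[NX2;!$(N=C[O,S])])[NX3]", 1, +1,
    ),
    IonizationRule(
        "aliphatic amine",
        "[NX3;!$([N]=*);!$([N]#*);"
        "!$([N]C=[O,S,N]);!$([N]S(=O)=O);!$([N]c);"
        "!$([N][O,N]);!n]",
        0, +1,
    ),
)


def ionize_ph74(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy with formal charges set per the pH-7.4 rule table.

    The heavy-atom composition is unchanged; only formal charges and
    hydrogen counts move.  Molecules with no ionizable group pass through
    unchanged.
    """
    mol = Chem.Mol(mol)
    touched: set[int] = set()
    for rule in IONIZATION_RULES:
        patt = Chem.MolFromSmarts(rule.smarts)
        for match in mol.GetSubstructMatches(patt):
            idx = match[rule.atom_index]
            if touched & set(match):
                continue
            atom = mol.GetAtomWithIdx(idx)
            if atom.GetFormalCharge() != 0:
                continue
            if rule.charge < 0:
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(True)
            else:
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            touched.update(match)
    Chem.SanitizeMol(mol)
    return mol


# --------------------------------------------------------------------------
# Descriptor computation
# --------------------------------------------------------------------------

def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)


def _is_pyrrole_type_n(atom: Chem.Atom) -> bool:
    # aromatic N donating its lone pair into the ring (pyrrole N-H, N-alkyl)
    return (
        atom.GetIsAromatic()
        and atom.GetSymbol() == "N"
        and atom.GetDegree() + atom.GetTotalNumHs() == 3
        and atom.GetFormalCharge() == 0
    )


def _is_amide_n(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "N":
        return False
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        for bond in nb.GetBonds():
            other = bond.GetOtherAtom(nb)
            if other.GetIdx() == atom.GetIdx():
                continue
            if (
                bond.GetBondType() == Chem.BondType.DOUBLE
                and other.GetSymbol() in ("O", "S")
            ):
                return True
    return False


def _polarity_counts(mol: Chem.Mol) -> tuple[int, int, int, int]:
    """(hba, hbd, hbam, hbdm) on the aromatic-perceived, ionized graph.

    Acceptor atoms: N and O, excluding pyrrole-type N, amide N and
    positively charged atoms.  Donor atoms: N or O bearing at least one
    hydrogen.  Sulfur is neither.  Site counts: donors contribute one site
    per hydrogen; acceptors contribute a lone-pair allowance (neutral O: 2,
    anionic O: 3, N: 1).
    """
    hba = hbd = hbam = hbdm = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        n_h = atom.GetTotalNumHs()
        if n_h > 0:
            hbd += 1
            hbdm += n_h
        if atom.GetFormalCharge() > 0:
            continue
        if sym == "N" and (_is_pyrrole_type_n(atom) or _is_amide_n(atom)):
            continue
        hba += 1
        if sym == "O":
            hbam += 3 if atom.GetFormalCharge() < 0 else 2
        else:
            hbam += 1
    return hba, hbd, hbam, hbdm


def _rotatable_bond_count(mol: Chem.Mol) -> int:
    """Acyclic single bonds between two heavy atoms of heavy-degree >= 2,
    excluding bonds adjacent to a triple bond (linear, rotation unobservable)."""
    triple_atoms = {
        a.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.TRIPLE
        for a in (b.GetBeginAtom(), b.GetEndAtom())
    }
    count = 0
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if _heavy_degree(a) < 2 or _heavy_degree(b) < 2:
            continue
        if a.GetIdx() in triple_atoms or b.GetIdx() in triple_atoms:
            continue
        count += 1
    return count


def compute_mqn(mol: Chem.Mol, ionize: bool = True) -> np.ndarray:
    """Compute the 42 MQN descriptors of one molecule.

    Parameters
    ----------
    mol : rdkit.Chem.Mol
        Parsed molecule.  By default it is first ionized at pH 7.4.
    ionize : bool
        Apply :func:`ionize_ph74` before counting (the package-wide default;
        disable only for diagnostic comparisons on the neutral form).

    Returns
    -------
    numpy.ndarray of shape (42,), dtype int64, in :data:`MQN_NAMES` order.
    """
    if mol is None:
        raise MQNError("cannot compute MQN of None")
    if ionize:
        mol = ionize_ph74(mol)

    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1 and _heavy_degree(atom) > 4:
            raise MQNError(
                f"heavy-atom degree {_heavy_degree(atom)} > 4 at atom "
                f"{atom.GetIdx()} ({atom.GetSymbol()})"
            )

    # polarity block uses the aromatic-perceived graph
    hba, hbd, hbam, hbdm = _polarity_counts(mol)
    rbc = _rotatable_bond_count(mol)

    # bond/ring blocks use the kekulized graph
    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:
        raise MQNError(f"non-kekulizable aromatic system: {exc}") from exc
    Chem.GetSSSR(kek)
    ring_info = kek.GetRingInfo()

    v = np.zeros(N_MQN, dtype=np.int64)

    elem_slot = {"C": "c", "F": "f", "Cl": "cl", "Br": "br", "I": "i",
                 "S": "s", "P": "p"}
    for atom in kek.GetAtoms():
        z = atom.GetAtomicNum()
        if z <= 1:
            continue
        v[_IDX["hac"]] += 1
        sym = atom.GetSymbol()
        in_ring = atom.IsInRing()
        if sym in elem_slot:
            v[_IDX[elem_slot[sym]]] += 1
        elif sym == "N":
            v[_IDX["cn" if in_ring else "an"]] += 1
        elif sym == "O":
            v[_IDX["co" if in_ring else "ao"]] += 1
        deg = _heavy_degree(atom)
        if in_ring:
            if deg in (2, 3, 4):
                v[_IDX[("cdv", "ctv", "cqv")[deg - 2]]] += 1
        else:
            if deg in (1, 2, 3, 4):
                v[_IDX[("asv", "adv", "atv", "aqv")[deg - 1]]] += 1
        q = atom.GetFormalCharge()
        if q > 0:
            v[_IDX["pos"]] += 1
        elif q < 0:
            v[_IDX["neg"]] += 1

    order_slot = {
        Chem.BondType.SINGLE: 0,
        Chem.BondType.DOUBLE: 1,
        Chem.BondType.TRIPLE: 2,
    }
    for bond in kek.GetBonds():
        if bond.GetBeginAtom().GetAtomicNum() <= 1:
            continue
        if bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        slot = order_slot.get(bond.GetBondType())
        if slot is None:
            raise MQNError(
                f"unsupported bond type {bond.GetBondType()} on kekulized graph"
            )
        if bond.IsInRing():
            v[_IDX[("csb", "cdb", "ctb")[slot]]] += 1
        else:
            v[_IDX[("asb", "adb", "atb")[slot]]] += 1

    for ring in ring_info.AtomRings():
        size = len(ring)
        if size >= 10:
            v[_IDX["rg10"]] += 1
        elif size >= 3:
            v[_IDX[f"r{size}"]] += 1

    atom_ring_count = np.zeros(kek.GetNumAtoms(), dtype=int)
    for ring in ring_info.AtomRings():
        for idx in ring:
            atom_ring_count[idx] += 1
    bond_ring_count: dict[int, int] = {}
    for ring in ring_info.BondRings():
        for idx in ring:
            bond_ring_count[idx] = bond_ring_count.get(idx, 0) + 1
    v[_IDX["afr"]] = int((atom_ring_count >= 2).sum())
    v[_IDX["bfr"]] = sum(1 for n in bond_ring_count.values() if n >= 2)

    v[_IDX["rbc"]] = rbc
    v[_IDX["hba"]] = hba
    v[_IDX["hbd"]] = hbd
    v[_IDX["hbam"]] = hbam
    v[_IDX["hbdm"]] = hbdm
    return v


def check_mqn_invariants(mol: Chem.Mol, v: np.ndarray | None = None) -> None:
    """Assert the MQN conservation laws for one molecule.

    Independent quantities are recounted directly on the (ionized,
    kekulized) graph: element totals must match the acyclic/cyclic splits,
    bond-class counts must sum to the number of heavy-heavy bonds, ring
    counts must sum to the circuit rank, and node-class counts must sum to
    the number of non-isolated heavy atoms.  Raises AssertionError on
    violation; useful as a diagnostic on any molecule set.
    """
    ion = ionize_ph74(mol)
    if v is None:
        v = compute_mqn(ion, ionize=False)
    assert v.min() >= 0, "negative descriptor"
    assert np.issubdtype(v.dtype, np.integer), "non-integer descriptor"

    n_n = sum(1 for a in ion.GetAtoms() if a.GetSymbol() == "N")
    n_o = sum(1 for a in ion.GetAtoms() if a.GetSymbol() == "O")
    assert v[_IDX["an"]] + v[_IDX["cn"]] == n_n, "N split broken"
    assert v[_IDX["ao"]] + v[_IDX["co"]] == n_o, "O split broken"

    heavy = [a.GetIdx() for a in ion.GetAtoms() if a.GetAtomicNum() > 1]
    n_bonds = sum(
        1
        for b in ion.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
    )
    bond_total = sum(v[_IDX[k]] for k in ("asb", "adb", "atb", "csb", "cdb", "ctb"))
    assert bond_total == n_bonds, "bond class totals != heavy-heavy bonds"

    n_components = len(Chem.GetMolFrags(ion))
    circuit_rank = n_bonds - len(heavy) + n_components
    ring_total = sum(
        v[_IDX[k]] for k in ("r3", "r4", "r5", "r6", "r7", "r8", "r9", "rg10")
    )
    assert ring_total == circuit_rank, "ring counts != circuit rank"

    n_isolated = sum(
        1 for a in ion.GetAtoms() if a.GetAtomicNum() > 1 and _heavy_degree(a) == 0
    )
    node_total = sum(
        v[_IDX[k]] for k in ("asv", "adv", "atv", "aqv", "cdv", "ctv", "cqv")
    )
    assert node_total == v[_IDX["hac"]] - n_isolated, "node class totals broken"


def mqn_from_smiles(smiles: str, ionize: bool = True) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MQNError(f"unparsable SMILES: {smiles!r}")
    return compute_mqn(mol, ionize=ionize)


def cbd(a: np.ndarray | Sequence[int], b: np.ndarray | Sequence[int]) -> int:
    """City-block (Manhattan) distance between two MQN vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return int(np.abs(a.astype(np.int64) - b.astype(np.int64)).sum())


def cbd_matrix(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """City-block distances from one vector to every row of a matrix."""
    return np.abs(matrix.astype(np.int64) - np.asarray(query, dtype=np.int64)).sum(axis=1)


# --------------------------------------------------------------------------
# Estimator interface
# --------------------------------------------------------------------------

class MQNCalculator(BaseEstimator, TransformerMixin):
    """Stateless transformer turning molecules into 42-column MQN matrices.

    Accepts SMILES strings, RDKit molecules or :class:`MoleculeRecord`
    objects.  ``fit`` records the feature names; ``transform`` returns an
    ``(n, 42)`` int64 array.

    Parameters
    ----------
    ionize : bool, default True
        Apply the pH-7.4 ionization rule table before counting.
    """

    def __init__(self, ionize: bool = True):
        self.ionize = ionize

    def fit(self, X: Iterable = (), y=None) -> "MQNCalculator":
        self.feature_names_ = list(MQN_NAMES)
        self.n_features_out_ = N_MQN
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        rows = [self._one(x) for x in X]
        if not rows:
            return np.zeros((0, N_MQN), dtype=np.int64)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(MQN_NAMES, dtype=object)

    def _one(self, x) -> np.ndarray:
        if isinstance(x, MoleculeRecord):
            return compute_mqn(x.mol, ionize=self.ionize)
        if isinstance(x, Chem.Mol):
            return compute_mqn(x, ionize=self.ionize)
        if isinstance(x, str):
            return mqn_from_smiles(x, ionize=self.ionize)
        raise TypeError(f"cannot compute MQN for {type(x).__name__}")


def mqn_table(
    records: Sequence[MoleculeRecord], ionize: bool = True
) -> tuple[pd.DataFrame, dict[str, str]]:
    """One MQN row per record; per-molecule failures are recorded and skipped.

    Returns (table, errors) where the table has an ``id`` column followed by
    the 42 canonical descriptor columns and errors maps id -> message.
    """
    rows = []
    errors: dict[str, str] = {}
    for rec in records:
        try:
            rows.append([rec.id, *compute_mqn(rec.mol, ionize=ionize)])
        except MQNError as exc:
            errors[rec.id] = str(exc)
    table = pd.DataFrame(rows, columns=["id", *MQN_NAMES])
    return table, errors


def write_mqn_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mqn_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
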