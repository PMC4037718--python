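"""Curated fixture molecules and synthetic library generators.

The curated set holds classic fragrance molecules (monoterpenes, aliphatic
esters and aldehydes, phenolics) whose Hill formulas are documented
checksums, the carvone enantiomer pair, and named non-fragrance-like
molecules (N-heterocycles, thiols, disulfides) that exercise the FL filter.

The two generators stand in for the external fragrance-like database
backgrounds that are not redistributed here:

* :func:`generate_decoys` assembles random CHOS molecules from a fragment
  grammar (alkyl chains and small rings with ether/thioether/carbonyl/
  alcohol decorations), biased so that virtually all outputs pass the FL
  filter — emulating the composition of an FL database subset (HAC 5-21,
  few heteroatoms, at most one donor);
* :func:`generate_analog_family` mutates a seed molecule with small
  structural edit moves (chain homologation/shortening, methyl
  transposition, ring expansion, carbonyl/alcohol swaps), emulating a
  family of close fragrance analogs.

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from rdkit import Chem

from . import fl_filter as _fl
from . import mqn as _mqn
from .lbvs import FragranceFamily
from .molio import MoleculeRecord, record_from_mol, record_from_smiles

#: Hill formulas printed for the classic query compounds; used as the
#: in-package checksum of the curated structures.
CURATED_FORMULAS = {
    "furaneol": "C6H8O3",
    "isoamyl_acetate": "C7H14O2",
    "caprylic_acid": "C8H16O2",
    "vanillin": "C8H8O3",
    "cinnamaldehyde": "C9H8O",
    "limonene": "C10H16",
    "alpha_pinene": "C10H16",
    "camphor": "C10H16O",
    "menthone": "C10H18O",
    "rose_oxide": "C10H18O",
    "menthol": "C10H20O",
    "citronellol": "C10H20O",
    "lauraldehyde": "C12H24O",
}

#: The 13 classic nearest-neighbour query compounds.
QUERY_COMPOUNDS = tuple(CURATED_FORMULAS)

#: Named molecules that the FL criteria exclude (nitrogen heterocycles) or
#: that family curation removes as promiscuous (sulfur volatiles).
NON_FL_EXCLUSIONS = ("pyrazine", "ethyl_anthranilate", "3-ethylpyridine")
PROMISCUOUS_EXAMPLES = ("cyclopentanethiol", "dimethyl_disulfide")


@dataclass
class FixtureSet:
    """Named molecules with ready-made records."""

    molecules: dict[str, str]  # name -> SMILES

    @property
    def records(self) -> list[MoleculeRecord]:
        return [
            record_from_smiles(smi, name) for name, smi in self.molecules.items()
        ]

    def record(self, name: str) -> MoleculeRecord:
        return record_from_smiles(self.molecules[name], name)

    def __len__(self) -> int:
        return len(self.molecules)


def curated_fragrances() -> FixtureSet:
    """Load the packaged curated fragrance set."""
    text = (
        resources.files("flspace").joinpath("data/curated_fragrances.smi").read_text()
    )
    molecules: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split()
        molecules[name] = smiles
    return FixtureSet(molecules)


# --------------------------------------------------------------------------
# Decoy generator (fragment grammar)
# --------------------------------------------------------------------------

def _random_skeleton(rng: random.Random, n_heavy: int) -> Chem.RWMol:
    """Random all-carbon skeleton: optional ring(s) plus a random tree."""
    mol = Chem.RWMol()
    ring_size = 0
    if n_heavy >= 5 and rng.random() < 0.55:
        ring_size = rng.choice((3, 4, 5, 5, 6, 6, 6, 7))
        ring_size = min(ring_size, n_heavy)
        first = [mol.AddAtom(Chem.Atom(6)) for _ in range(ring_size)]
        for i in range(ring_size):
            mol.AddBond(first[i], first[(i + 1) % ring_size], Chem.BondType.SINGLE)
    else:
        mol.AddAtom(Chem.Atom(6))

    while mol.GetNumAtoms() < n_heavy:
        # chain bias: extend the newest atom half of the time
        candidates = [
            a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() < 4
        ]
        if not candidates:
            break
        attach = (
            mol.GetNumAtoms() - 1
            if rng.random() < 0.5 and mol.GetAtomWithIdx(mol.GetNumAtoms() - 1).GetDegree() < 4
            else rng.choice(candidates)
        )
        new = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(attach, new, Chem.BondType.SINGLE)

    # occasional second ring closure between nearby atoms
    if ring_size and mol.GetNumAtoms() >= 8 and rng.random() < 0.2:
        dm = Chem.GetDistanceMatrix(mol)
        pairs = [
            (i, j)
            for i in range(mol.GetNumAtoms())
            for j in range(i + 1, mol.GetNumAtoms())
            if 2 <= dm[i, j] <= 6
            and mol.GetAtomWithIdx(i).GetDegree() < 4
            and mol.GetAtomWithIdx(j).GetDegree() < 4
            and mol.GetBondBetweenAtoms(i, j) is None
        ]
        if pairs:
            i, j = rng.choice(pairs)
            mol.AddBond(i, j, Chem.BondType.SINGLE)
    return mol


def _decorate(rng: random.Random, mol: Chem.RWMol, allow_donor: bool) -> None:
    """Random double bonds and up to three O/S heteroatom substitutions."""
    for _ in range(rng.choice((0, 0, 1, 1, 2))):
        bonds = [
            b
            for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.SINGLE
            and all(
                a.GetDegree() <= 3
                and all(
                    nb.GetBondType() == Chem.BondType.SINGLE for nb in a.GetBonds()
                )
                for a in (b.GetBeginAtom(), b.GetEndAtom())
            )
        ]
        if not bonds:
            break
        rng.choice(bonds).SetBondType(Chem.BondType.DOUBLE)

    n_het = rng.choices((0, 1, 2, 3), weights=(15, 40, 30, 15))[0]
    placed_donor = False
    for _ in range(n_het):
        atoms = [
            a
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6
            and a.GetDegree() <= 2
            and all(nb.GetAtomicNum() == 6 for nb in a.GetNeighbors())
        ]
        if not atoms:
            break
        atom = rng.choice(atoms)
        if (
            atom.GetDegree() == 1
            and atom.GetBonds()[0].GetBondType() == Chem.BondType.SINGLE
            and (placed_donor or not allow_donor)
        ):
            continue  # a second terminal OH/SH would add a donor
        if rng.random() < 0.8:
            atom.SetAtomicNum(8)
            if (
                atom.GetDegree() == 1
                and atom.GetBonds()[0].GetBondType() == Chem.BondType.SINGLE
            ):
                placed_donor = True
        else:
            atom.SetAtomicNum(16)


def generate_decoys(
    n: int,
    seed: int,
    hac_range: tuple[int, int] = (5, 21),
    fl_bias: bool = True,
) -> list[MoleculeRecord]:
    """Generate ``n`` unique random CHOS molecules (ids ``D000001`` ...).

    With ``fl_bias`` every emitted molecule passes the FL filter (donor and
    heteroatom budgets are enforced during assembly, and the few grammar
    outputs that still violate a rule are discarded and regenerated).
    """
    lo, hi = hac_range
    if lo < 1 or hi < lo:
        raise ValueError(f"infeasible hac_range {hac_range}")
    rng = random.Random(seed)
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"decoy generation stalled after {attempts} attempts "
                f"({len(out)}/{n} produced); parameters may be infeasible"
            )
        n_heavy = rng.randint(lo, hi)
        try:
            skel = _random_skeleton(rng, n_heavy)
            _decorate(rng, skel, allow_donor=rng.random() < 0.35)
            mol = skel.GetMol()
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        if fl_bias and not _fl.is_fragrance_like(mol).passed:
            continue
        seen.add(smi)
        out.append(record_from_mol(mol, f"D{len(out) + 1:06d}"))
    return out


# --------------------------------------------------------------------------
# Analog family generator (edit moves)
# --------------------------------------------------------------------------

def _try_move(rng: random.Random, mol: Chem.Mol) -> Chem.Mol | None:
    """Apply one random structural edit move; None when inapplicable."""
    rw = Chem.RWMol(mol)
    move = rng.choice(
        ("append_methyl", "drop_methyl", "transpose_methyl", "expand_ring",
         "carbonyl_to_alcohol", "alcohol_to_carbonyl")
    )

    def terminal_carbons():
        return [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 6
            and a.GetDegree() == 1
            and a.GetBonds()[0].GetBondType() == Chem.BondType.SINGLE
        ]

    if move == "append_methyl":
        sites = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1 and a.GetDegree() < 4
        ]
        if not sites:
            return None
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(rng.choice(sites), new, Chem.BondType.SINGLE)
    elif move == "drop_methyl":
        terms = terminal_carbons()
        if not terms or rw.GetNumAtoms() <= 4:
            return None
        rw.RemoveAtom(rng.choice(terms))
    elif move == "transpose_methyl":
        terms = terminal_carbons()
        if not terms:
            return None
        victim = rng.choice(terms)
        sites = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 6
            and a.GetTotalNumHs() >= 1
            and a.GetDegree() < 4
            and a.GetIdx() != victim
            and rw.GetBondBetweenAtoms(a.GetIdx(), victim) is None
        ]
        if not sites:
            return None
        rw.RemoveAtom(victim)
        sites = [s if s < victim else s - 1 for s in sites]
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(rng.choice(sites), new, Chem.BondType.SINGLE)
    elif move == "expand_ring":
        ring_bonds = [
            b
            for b in rw.GetBonds()
            if b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE
        ]
        if not ring_bonds:
            return None
        bond = rng.choice(ring_bonds)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        rw.RemoveBond(i, j)
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(i, new, Chem.BondType.SINGLE)
        rw.AddBond(new, j, Chem.BondType.SINGLE)
    elif move == "carbonyl_to_alcohol":
        carbonyls = [
            b
            for b in rw.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE
            and {b.GetBeginAtom().GetAtomicNum(), b.GetEndAtom().GetAtomicNum()}
            == {6, 8}
            and not b.IsInRing()
        ]
        if not carbonyls:
            return None
        rng.choice(carbonyls).SetBondType(Chem.BondType.SINGLE)
    else:  # alcohol_to_carbonyl
        hydroxyls = [
            b
            for b in rw.GetBonds()
            if b.GetBondType() == Chem.BondType.SINGLE
            and not b.IsInRing()
            and (
                (b.GetBeginAtom().GetAtomicNum() == 8 and b.GetBeginAtom().GetDegree() == 1)
                or (b.GetEndAtom().GetAtomicNum() == 8 and b.GetEndAtom().GetDegree() == 1)
            )
        ]
        feasible = []
        for b in hydroxyls:
            c = b.GetBeginAtom() if b.GetBeginAtom().GetAtomicNum() == 6 else b.GetEndAtom()
            if c.GetAtomicNum() == 6 and c.GetTotalNumHs() >= 1:
                feasible.append(b)
        if not feasible:
            return None
        rng.choice(feasible).SetBondType(Chem.BondType.DOUBLE)

    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if len(Chem.GetMolFrags(out)) != 1:
        return None
    return out


@dataclass
class AnalogFamily:
    """A seed molecule with generated structural analogs."""

    name: str
    seed: MoleculeRecord
    members: list[MoleculeRecord]
    max_cbd: int

    def as_fragrance_family(self, include_seed: bool = True) -> FragranceFamily:
        members = ([self.seed] if include_seed else []) + self.members
        return FragranceFamily(self.name, members, n_raw=len(members))


def generate_analog_family(
    seed_smiles: str,
    n: int,
    seed: int,
    name: str = "analogs",
    max_moves: int = 2,
) -> AnalogFamily:
    """Generate ``n`` unique FL analogs of a seed molecule by edit moves.

    Each analog is 1..``max_moves`` random moves away from the seed, passes
    the FL filter and differs from the seed; the maximum MQN city-block
    distance to the seed over the family is reported on the result.
    """
    seed_rec = record_from_smiles(seed_smiles, f"{name}:seed")
    if seed_rec is None:
        raise ValueError(f"unparsable seed SMILES: {seed_smiles!r}")
    if not _fl.is_fragrance_like(seed_rec).passed:
        raise ValueError("seed molecule is not fragrance-like")
    rng = random.Random(seed)
    seed_vec = _mqn.compute_mqn(seed_rec.mol)

    seen = {seed_rec.smiles}
    members: list[MoleculeRecord] = []
    max_cbd = 0
    attempts = 0
    max_attempts = 500 * max(n, 1) + 500
    while len(members) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"analog generation stalled ({len(members)}/{n} produced)"
            )
        mol = Chem.Mol(seed_rec.mol)
        for _ in range(rng.randint(1, max_moves)):
            moved = _try_move(rng, mol)
            if moved is not None:
                mol = moved
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        if not _fl.is_fragrance_like(mol).passed:
            continue
        seen.add(smi)
        rec = record_from_mol(mol, f"{name}:{len(members) + 1:03d}")
        members.append(rec)
        max_cbd = max(max_cbd, _mqn.cbd(seed_vec, _mqn.compute_mqn(rec.mol)))
    return AnalogFamily(name, seed_rec, members, max_cbd)
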