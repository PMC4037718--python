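"""Reading, canonicalizing, deduplicating and writing molecule collections.

Molecules are carried through the package as :class:`MoleculeRecord` objects:
an id, a canonical (stereo-aware) SMILES, the Hill formula, the heavy-atom
count and a database-membership bit mask.  Multi-fragment inputs (salts,
mixtures) are reduced to their largest organic fragment before anything else
happens, since the fragrance-like chemical space consists of single neutral
organic molecules.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


@dataclass
class MoleculeRecord:
    """One parsed molecule.

    Attributes
    ----------
    id : str
        Unique identifier within a collection (input id or ``M000001`` style).
    smiles : str
        Canonical isomeric SMILES of the largest organic fragment.
    formula : str
        Hill-order molecular formula (C first, H second, rest alphabetical).
    hac : int
        Heavy-atom count.
    db_mask : int
        Bit field of source-database membership (0 until registered).
    """

    id: str
    smiles: str
    formula: str
    hac: int
    db_mask: int = 0
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
        return self._mol


@dataclass
class ParseReport:
    """Bookkeeping for one read/dedup pass."""

    read: int = 0
    parsed: int = 0
    skipped: int = 0
    deduplicated: int = 0
    skipped_entries: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "read": self.read,
                    "parsed": self.parsed,
                    "skipped": self.skipped,
                    "deduplicated": self.deduplicated,
                    "skipped_entries": self.skipped_entries,
                },
                indent=2,
            )
        )


_ORGANIC = {"C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I", "B"}


def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Return the largest fragment (most heavy atoms; ties by canonical SMILES)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    # prefer fragments containing carbon (the organic component of a salt)
    def key(f: Chem.Mol) -> tuple:
        has_c = any(a.GetSymbol() == "C" for a in f.GetAtoms())
        return (has_c, f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))

    return max(frags, key=key)


def canonical_smiles(mol: Chem.Mol, ignore_stereo: bool = False) -> str:
    return Chem.MolToSmiles(mol, isomericSmiles=not ignore_stereo)


def hill_formula(mol_or_record: Chem.Mol | MoleculeRecord) -> str:
    """Hill-order molecular formula with implicit hydrogens included.

    Carbon first, hydrogen second, remaining elements alphabetical; for
    carbon-free molecules all elements (including H) are alphabetical.
    """
    mol = mol_or_record.mol if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    counts: dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            n_h += 1
        else:
            counts[sym] = counts.get(sym, 0) + 1
        n_h += atom.GetTotalNumHs()
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h

    def fmt(sym: str) -> str:
        n = counts[sym]
        return sym if n == 1 else f"{sym}{n}"

    parts: list[str] = []
    if "C" in counts:
        parts.append(fmt("C"))
        if "H" in counts:
            parts.append(fmt("H"))
        parts.extend(fmt(s) for s in sorted(counts) if s not in ("C", "H"))
    else:
        parts.extend(fmt(s) for s in sorted(counts))
    return "".join(parts)


def record_from_mol(
    mol: Chem.Mol, mol_id: str, ignore_stereo: bool = False
) -> MoleculeRecord:
    mol = largest_fragment(mol)
    smi = canonical_smiles(mol, ignore_stereo=ignore_stereo)
    mol = Chem.MolFromSmiles(smi)
    return MoleculeRecord(
        id=mol_id,
        smiles=smi,
        formula=hill_formula(mol),
        hac=mol.GetNumHeavyAtoms(),
        _mol=mol,
    )


def record_from_smiles(
    smiles: str, mol_id: str, ignore_stereo: bool = False
) -> MoleculeRecord | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return record_from_mol(mol, mol_id, ignore_stereo=ignore_stereo)


def _iter_smiles_lines(path: Path) -> Iterator[tuple[str, str | None]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else None
            yield smiles, mol_id


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    ignore_stereo: bool = False,
) -> tuple[list[MoleculeRecord], ParseReport]:
    """Read a molecule collection from a SMILES file or an SDF.

    Unparsable entries are skipped and counted in the returned
    :class:`ParseReport`; a file with zero parsable records is a fatal error.
    Input order is preserved.  Ids are taken from the input where present,
    otherwise assigned sequentially (``M000001`` ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such molecule file: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".mol") else "smiles-file"
    if fmt not in ("smiles-file", "sdf"):
        raise ValueError(f"unknown format {fmt!r} (expected 'smiles-file' or 'sdf')")

    report = ParseReport()
    records: list[MoleculeRecord] = []
    seen_ids: set[str] = set()
    counter = 0

    def next_id(preferred: str | None) -> str:
        nonlocal counter
        if preferred and preferred not in seen_ids:
            seen_ids.add(preferred)
            return preferred
        while True:
            counter += 1
            cand = f"M{counter:06d}"
            if cand not in seen_ids:
                seen_ids.add(cand)
                return cand

    if fmt == "smiles-file":
        for smiles, mol_id in _iter_smiles_lines(path):
            report.read += 1
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                report.skipped += 1
                report.skipped_entries.append(smiles)
                continue
            records.append(record_from_mol(mol, next_id(mol_id), ignore_stereo))
            report.parsed += 1
    else:
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            report.read += 1
            if mol is None:
                report.skipped += 1
                report.skipped_entries.append(f"sdf entry {i}")
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
            records.append(record_from_mol(mol, next_id(name or None), ignore_stereo))
            report.parsed += 1

    if not records:
        raise ValueError(
            f"no parsable records in {path} "
            f"(read {report.read}, skipped {report.skipped})"
        )
    return records, report


def dedup(
    records: Sequence[MoleculeRecord], report: ParseReport | None = None
) -> list[MoleculeRecord]:
    """Collapse records with identical canonical structures (first kept).

    Stereoisomers are distinct by default: the canonical SMILES is
    stereo-aware, so enantiomer pairs such as (−)- and (+)-carvone survive as
    two records.
    """
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.smiles in seen:
            if report is not None:
                report.deduplicated += 1
            continue
        seen.add(rec.smiles)
        out.append(rec)
    return out


def write_molecules(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as a two-column ``SMILES id`` file."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.id}\n")


def records_from_smiles_list(
    smiles_list: Sequence[str],
    ids: Sequence[str] | None = None,
    ignore_stereo: bool = False,
) -> list[MoleculeRecord]:
    """Convenience constructor used throughout the test and fixture code."""
    out = []
    for i, smi in enumerate(smiles_list):
        mol_id = ids[i] if ids is not None else f"M{i + 1:06d}"
        rec = record_from_smiles(smi, mol_id, ignore_stereo=ignore_stereo)
        if rec is None:
            raise ValueError(f"unparsable SMILES: {smi!r}")
        out.append(rec)
    return out
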