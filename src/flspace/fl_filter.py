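"""Fragrance-likeness: the four-rule FL property filter and property profiles.

A molecule is fragrance-like (FL) when it is small and almost apolar:

* ``HAC``        — heavy-atom count at most 21;
* ``ELEMENTS``   — heavy atoms only carbon, oxygen or sulfur (H always allowed);
* ``HETEROATOMS``— O + S count at most 3;
* ``HBD``        — at most one hydrogen-bond donor atom.

The donor convention is shared with :mod:`flspace.mqn` (N or O bearing a
hydrogen; thiol S-H does not count), so the filter and the descriptors never
disagree.  All four rules are always evaluated, so the verdict lists every
failed rule, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen
from sklearn.base import BaseEstimator, TransformerMixin

from . import mqn as _mqn
from .molio import MoleculeRecord

HAC_MAX = 21
ALLOWED_ELEMENTS = frozenset({"C", "O", "S"})
HETEROATOM_MAX = 3  # O + S
HBD_MAX = 1

RULES = ("HAC", "ELEMENTS", "HETEROATOMS", "HBD")


@dataclass
class FLVerdict:
    passed: bool
    failed_rules: list[str]
    hac: int
    elements: frozenset[str]
    os_count: int
    hbd: int


def is_fragrance_like(
    mol: Chem.Mol | MoleculeRecord | str,
    count_thiol_donor: bool = False,
) -> FLVerdict:
    """Evaluate the four FL rules on one molecule.

    ``count_thiol_donor`` switches the donor convention to also count S-H
    (off by default; the shared convention counts O/N donors only).
    """
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol
    elif isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("unparsable SMILES")
    mol = _mqn.ionize_ph74(mol)

    elements = frozenset(
        a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomicNum() > 1
    )
    hac = mol.GetNumHeavyAtoms()
    os_count = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("O", "S"))
    hbd = sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() > 0
    )
    if count_thiol_donor:
        hbd += sum(
            1 for a in mol.GetAtoms() if a.GetSymbol() == "S" and a.GetTotalNumHs() > 0
        )

    failed = []
    if hac > HAC_MAX:
        failed.append("HAC")
    if not elements <= ALLOWED_ELEMENTS:
        failed.append("ELEMENTS")
    if os_count > HETEROATOM_MAX:
        failed.append("HETEROATOMS")
    if hbd > HBD_MAX:
        failed.append("HBD")
    return FLVerdict(not failed, failed, hac, elements, os_count, hbd)


@dataclass
class FilterReport:
    n_input: int
    n_passed: int
    retention: float | None
    rule_failures: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "retention": self.retention,
            "rule_failures": self.rule_failures,
        }


def filter_database(
    records: Sequence[MoleculeRecord], count_thiol_donor: bool = False
) -> tuple[list[MoleculeRecord], FilterReport]:
    """Apply the FL filter to a collection, preserving input order.

    Returns the FL subset and a report with the retention fraction
    (``None`` for empty input) and per-rule failure counts (a molecule may
    fail several rules, so the counts can sum to more than the number
    rejected).
    """
    subset = []
    failures = {r: 0 for r in RULES}
    for rec in records:
        verdict = is_fragrance_like(rec, count_thiol_donor=count_thiol_donor)
        if verdict.passed:
            subset.append(rec)
        else:
            for rule in verdict.failed_rules:
                failures[rule] += 1
    retention = len(subset) / len(records) if records else None
    return subset, FilterReport(len(records), len(subset), retention, failures)


class FragranceLikeFilter(BaseEstimator, TransformerMixin):
    """Transformer view of the FL filter (keeps passing records only).

    ``transform`` returns the FL subset of the input sequence; the report of
    the last transform is kept on ``report_``.
    """

    def __init__(self, count_thiol_donor: bool = False):
        self.count_thiol_donor = count_thiol_donor

    def fit(self, X=(), y=None) -> "FragranceLikeFilter":
        self.rules_ = RULES
        return self

    def transform(self, X: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
        subset, self.report_ = filter_database(
            X, count_thiol_donor=self.count_thiol_donor
        )
        return subset


# --------------------------------------------------------------------------
# Property profiles (heavy-atom count, heteroatoms, clogP, ring classes)
# --------------------------------------------------------------------------

RING_CLASSES = ("acyclic", "monocyclic", "bicyclic", "polycyclic")

DEFAULT_BINS = {
    "hac": np.arange(0.5, 40.5 + 1, 1.0),
    "heteroatoms": np.arange(-0.5, 10.5 + 1, 1.0),
    "clogp": np.arange(-6.0, 10.5, 0.5),
}


@dataclass
class PropertyProfile:
    """Normalized property histograms in the style of database comparisons."""

    hac: np.ndarray
    hac_bins: np.ndarray
    heteroatoms: np.ndarray
    heteroatom_bins: np.ndarray
    clogp: np.ndarray
    clogp_bins: np.ndarray
    ring_classes: dict[str, float] = field(default_factory=dict)


def ring_class(mol: Chem.Mol) -> str:
    """Topology class from the SSSR ring count: acyclic / mono / bi / polycyclic."""
    mol = Chem.Mol(mol)
    n_rings = len(Chem.GetSSSR(mol))
    if n_rings == 0:
        return "acyclic"
    if n_rings == 1:
        return "monocyclic"
    if n_rings == 2:
        return "bicyclic"
    return "polycyclic"


def property_profile(
    records: Sequence[MoleculeRecord], bins: dict | None = None
) -> PropertyProfile:
    """Four normalized histograms: HAC, heteroatom count, clogP, ring classes.

    clogP is the Wildman-Crippen atom-contribution estimate; the heteroatom
    count includes every non-carbon heavy atom, not just O and S, so the
    profile is meaningful for unfiltered databases too.  Histogram masses
    each sum to one for non-empty input; empty input yields all-zero
    histograms.
    """
    cfg = dict(DEFAULT_BINS)
    if bins:
        cfg.update(bins)

    hacs, het, clogp = [], [], []
    rings = {c: 0 for c in RING_CLASSES}
    for rec in records:
        mol = rec.mol
        hacs.append(mol.GetNumHeavyAtoms())
        het.append(
            sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetSymbol() != "C")
        )
        clogp.append(Crippen.MolLogP(mol))
        rings[ring_class(mol)] += 1

    def hist(values, edges):
        h, _ = np.histogram(values, bins=edges)
        total = h.sum()
        return h / total if total else h.astype(float)

    n = len(records)
    ring_frac = {c: (rings[c] / n if n else 0.0) for c in RING_CLASSES}
    return PropertyProfile(
        hac=hist(hacs, cfg["hac"]),
        hac_bins=np.asarray(cfg["hac"]),
        heteroatoms=hist(het, cfg["heteroatoms"]),
        heteroatom_bins=np.asarray(cfg["heteroatoms"]),
        clogp=hist(clogp, cfg["clogp"]),
        clogp_bins=np.asarray(cfg["clogp"]),
        ring_classes=ring_frac,
    )
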