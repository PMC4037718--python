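"""The four descriptor spaces used for similarity ranking.

* ``MQN``   — the 42 Molecular Quantum Numbers (:mod:`flspace.mqn`);
* ``Sfp``   — Daylight-type path-based substructure fingerprint, linear
  paths up to 7 bonds hashed and folded to 1024 bits;
* ``ECfp4`` — extended-connectivity (circular) fingerprint of bond diameter
  4 (radius 2), folded to 1024 bits;
* ``MW``    — molecular weight in Da of the pH-7.4 ionized form.

Every space is scored with the city-block distance; on binary fingerprints
this equals the Hamming distance, and on MW the absolute difference.
Fingerprint hashing is delegated to the toolkit, so bit patterns are exact
only per toolkit version; tests treat them as regression fixtures.
"""

from __future__ import annotations

import zlib
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from . import mqn as _mqn
from .molio import MoleculeRecord

N_BITS = 1024
SFP_MAX_PATH = 7
ECFP_RADIUS = 2  # bond diameter 4

SPACES = ("MQN", "Sfp", "ECfp4", "MW")

_sfp_gen = rdFingerprintGenerator.GetRDKitFPGenerator(
    minPath=1, maxPath=SFP_MAX_PATH, fpSize=N_BITS
)
_ecfp_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=ECFP_RADIUS, fpSize=N_BITS
)


def _as_mol(x) -> Chem.Mol:
    if isinstance(x, MoleculeRecord):
        return x.mol
    if isinstance(x, Chem.Mol):
        return x
    if isinstance(x, str):
        mol = Chem.MolFromSmiles(x)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {x!r}")
        return mol
    raise TypeError(f"cannot encode {type(x).__name__}")


def encode_sfp(mol) -> np.ndarray:
    """1024-bit path fingerprint (paths of 0..7 bonds) as a uint8 0/1 vector.

    Linear paths of 1..7 bonds are hashed by the toolkit; length-0 paths
    (typed atoms) are hashed on top, Daylight-style, so even a single-atom
    molecule sets at least one bit.
    """
    mol = _as_mol(mol)
    fp = _sfp_gen.GetFingerprint(mol)
    arr = np.zeros(N_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    for atom in mol.GetAtoms():
        key = f"atom:{atom.GetAtomicNum()}:{atom.GetFormalCharge()}:{int(atom.GetIsAromatic())}"
        arr[zlib.crc32(key.encode()) % N_BITS] = 1
    return arr


def encode_ecfp4(mol) -> np.ndarray:
    """1024-bit circular fingerprint of radius 2 as a uint8 0/1 vector."""
    fp = _ecfp_gen.GetFingerprint(_as_mol(mol))
    arr = np.zeros(N_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def encode_mw(mol) -> np.ndarray:
    """Molecular weight (Da) of the ionized form, as a length-1 vector."""
    ion = _mqn.ionize_ph74(_as_mol(mol))
    return np.array([Descriptors.MolWt(ion)])


def encode_mqn(mol) -> np.ndarray:
    return _mqn.compute_mqn(_as_mol(mol))


class DescriptorSpace:
    """A named molecule encoding with its city-block distance.

    Encodings of :class:`MoleculeRecord` and SMILES inputs are memoized per
    (space, canonical SMILES), since screening protocols encode the same
    background molecules against many references.
    """

    def __init__(self, name: str, encode_fn: Callable[[object], np.ndarray]):
        self.name = name
        self._encode = encode_fn
        self._cache: dict[str, np.ndarray] = {}

    def __repr__(self) -> str:
        return f"DescriptorSpace({self.name!r})"

    def encode(self, x) -> np.ndarray:
        key = None
        if isinstance(x, MoleculeRecord):
            key = x.smiles
        elif isinstance(x, str):
            key = x
        if key is not None:
            hit = self._cache.get(key)
            if hit is None:
                hit = self._cache[key] = self._encode(x)
            return hit
        return self._encode(x)

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("vector length mismatch")
        if self.name == "MW":
            return float(abs(a[0] - b[0]))
        return float(np.abs(a.astype(np.int64) - b.astype(np.int64)).sum())

    def distance_matrix(self, query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
        """Distances from one vector to every row (vectorized)."""
        matrix = np.asarray(matrix)
        if self.name == "MW":
            return np.abs(matrix[:, 0] - query[0])
        return np.abs(
            matrix.astype(np.int64) - np.asarray(query, dtype=np.int64)
        ).sum(axis=1)


_SPACES: dict[str, DescriptorSpace] = {
    "MQN": DescriptorSpace("MQN", encode_mqn),
    "Sfp": DescriptorSpace("Sfp", encode_sfp),
    "ECfp4": DescriptorSpace("ECfp4", encode_ecfp4),
    "MW": DescriptorSpace("MW", encode_mw),
}


def get_space(name: str) -> DescriptorSpace:
    try:
        return _SPACES[name] if name in _SPACES else _SPACES[
            {s.lower(): s for s in _SPACES}[name.lower()]
        ]
    except KeyError:
        raise ValueError(f"unknown descriptor space {name!r}; choose from {SPACES}")


def distance(space: str | DescriptorSpace, a: np.ndarray, b: np.ndarray) -> float:
    if isinstance(space, str):
        space = get_space(space)
    return space.distance(a, b)


class FingerprintEncoder(BaseEstimator, TransformerMixin):
    """Transformer encoding molecules into one of the four descriptor spaces."""

    def __init__(self, space: str = "ECfp4"):
        self.space = space

    def fit(self, X=(), y=None) -> "FingerprintEncoder":
        self.space_ = get_space(self.space)
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        space = get_space(self.space)
        rows = [space.encode(x) for x in X]
        if not rows:
            width = 1 if space.name == "MW" else (42 if space.name == "MQN" else N_BITS)
            return np.zeros((0, width))
        return np.vstack(rows)


# -- hex serialization of binary fingerprints -------------------------------

def fp_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def fp_from_hex(hexstr: str, n_bits: int = N_BITS) -> np.ndarray:
    return np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))[:n_bits]
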