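"""Molecular fingerprints and Tanimoto similarity.

Two binary fingerprint families are exposed: hashed circular fingerprints
(ECFP-style; diameter 6 ⇒ radius 3, 2048 bits by default) used as model
descriptors, and the 166 MACCS structural keys used for analog similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .curation import CuratedDataset, StandardizedMolecule

MACCS_LENGTH = 166


class FeatureError(RuntimeError):
    """Fingerprinting failed for a molecule."""


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary feature vector stored as its set-bit indices."""

    kind: str  # "circular" | "maccs"
    length: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.kind not in ("circular", "maccs"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.kind == "maccs" and self.length != MACCS_LENGTH:
            raise ValueError("MACCS fingerprints have exactly 166 keys")
        if any(b < 0 or b >= self.length for b in self.bits):
            raise ValueError("bit index out of range")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        if self.bits:
            arr[sorted(self.bits)] = 1
        return arr


def _as_mol(molecule: StandardizedMolecule | Chem.Mol | str) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, StandardizedMolecule):
        if molecule.has_error:
            raise FeatureError("cannot fingerprint an error-flagged molecule")
        return molecule.mol
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise FeatureError(f"unparseable SMILES: {molecule!r}")
    return mol


def circular_fingerprint(
    molecule: StandardizedMolecule | Chem.Mol | str,
    radius: int = 3,
    length: int = 2048,
) -> BitFingerprint:
    """Hashed circular (Morgan) fingerprint; radius 3 ≡ ECFP6.

    Deterministic for a fixed structure and invariant to the atom ordering of
    the input SMILES, since atom environments are hashed canonically.
    """
    mol = _as_mol(molecule)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    bv = gen.GetFingerprint(mol)
    return BitFingerprint("circular", length, frozenset(bv.GetOnBits()))


def maccs_fingerprint(molecule: StandardizedMolecule | Chem.Mol | str) -> BitFingerprint:
    """166-key MACCS structural-key fingerprint.

    Keys are numbered 1–166 in the public definitions; they are stored here
    0-based (key *k* → index *k*−1).
    """
    mol = _as_mol(molecule)
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    return BitFingerprint(
        "maccs", MACCS_LENGTH, frozenset(b - 1 for b in bv.GetOnBits() if b >= 1)
    )


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| of two bit sets.

    Defined as 0.0 when both fingerprints are empty, keeping the result in
    [0, 1] without a 0/0.
    """
    if a.kind != b.kind or a.length != b.length:
        raise ValueError(
            f"incompatible fingerprints: {a.kind}/{a.length} vs {b.kind}/{b.length}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass(frozen=True)
class FingerprintSpec:
    kind: str = "circular"
    radius: int = 3
    length: int = 2048

    def compute(self, molecule) -> BitFingerprint:
        if self.kind == "circular":
            return circular_fingerprint(molecule, self.radius, self.length)
        if self.kind == "maccs":
            return maccs_fingerprint(molecule)
        raise ValueError(f"unknown fingerprint kind {self.kind!r}")


def featurize_dataset(
    dataset: CuratedDataset, spec: FingerprintSpec = FingerprintSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Fingerprint every curated record into an (n × length) binary matrix.

    Row order follows dataset record order, so the returned label vector is
    aligned by construction.
    """
    if len(dataset) == 0:
        raise ValueError("cannot featurize an empty dataset")
    n = len(dataset)
    length = MACCS_LENGTH if spec.kind == "maccs" else spec.length
    X = np.zeros((n, length), dtype=np.uint8)
    for i, rec in enumerate(dataset.records):
        try:
            fp = spec.compute(rec.molecule)
        except FeatureError as exc:
            raise FeatureError(
                f"record {rec.molecule.inchikey or i}: {exc}"
            ) from exc
        X[i] = fp.to_array()
    y = np.asarray(dataset.labels, dtype=np.int64)
    return X, y


def featurize_molecules(
    molecules: Sequence, spec: FingerprintSpec = FingerprintSpec()
) -> np.ndarray:
    """Fingerprint a plain sequence of molecules (screening-library path)."""
    length = MACCS_LENGTH if spec.kind == "maccs" else spec.length
    X = np.zeros((len(molecules), length), dtype=np.uint8)
    for i, mol in enumerate(molecules):
        X[i] = spec.compute(mol).to_array()
    return X
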