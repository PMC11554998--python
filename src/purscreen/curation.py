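"""Structure standardization, InChIKey deduplication, and activity binarization.

The curation pipeline turns a raw bioactivity export into a modeling-ready
dataset:

1. every structure passes through a fixed standardization workflow
   (parse → strip stereo annotations that carry no information → validate
   charges and valences → remove isotope labels → keep the largest component
   of salts/mixtures → neutralize);
2. reported potencies are converted to the -log10 molar (pEC50) scale;
3. duplicate structures — detected by InChIKey, so salt forms, isotopologues
   and charge states of one parent collapse together — are merged by
   arithmetic averaging of their pEC50 values;
4. a binary active/inactive label is assigned at a molar cutoff
   (active ⇔ potency at least as good as the cutoff).

Every record that is excluded, merged, or modified leaves an entry in the
curation log, so input counts always reconcile:
|inputs| = Σ n_merged over curated records + |excluded records in log|.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .io_formats import UNIT_TO_MOLAR, RawRecord, normalize_unit


class FlagCode(enum.Enum):
    PARSE_FAIL = "PARSE_FAIL"
    ERR_VALENCE = "ERR_VALENCE"
    ERR_CHARGE = "ERR_CHARGE"
    MULTICOMPONENT = "MULTICOMPONENT"
    DUPLICATE = "DUPLICATE"
    CENSORED_ACTIVITY = "CENSORED_ACTIVITY"


#: Flags that exclude a record from the curated dataset (they are still logged).
ERROR_FLAGS = frozenset(
    {FlagCode.PARSE_FAIL, FlagCode.ERR_VALENCE, FlagCode.ERR_CHARGE}
)


@dataclass(frozen=True)
class CurationFlag:
    code: FlagCode
    detail: str = ""


@dataclass
class StandardizedMolecule:
    """A structure after the standardization workflow.

    ``canonical_structure`` is a kekulized canonical SMILES of the neutral,
    isotope-free largest component; it is empty when an error flag fired.
    ``flags`` records every workflow rule that modified or rejected the input.
    """

    canonical_structure: str
    inchikey: str
    flags: tuple[CurationFlag, ...] = ()
    parent_record_ids: tuple[str, ...] = ()
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def has_error(self) -> bool:
        return any(f.code in ERROR_FLAGS for f in self.flags)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            if self.has_error or not self.canonical_structure:
                raise ValueError("error-flagged molecule has no usable structure")
            object.__setattr__(
                self, "_mol", Chem.MolFromSmiles(self.canonical_structure)
            )
        return self._mol


@dataclass(frozen=True)
class CuratedRecord:
    molecule: StandardizedMolecule
    p_activity: float  # -log10 molar
    n_merged: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.p_activity):
            raise ValueError("p_activity must be finite")
        if self.n_merged < 1:
            raise ValueError("n_merged must be >= 1")

    def to_row(self) -> dict:
        return {
            "inchikey": self.molecule.inchikey,
            "canonical_smiles": self.molecule.canonical_structure,
            "p_activity": self.p_activity,
            "n_merged": self.n_merged,
        }


@dataclass
class CuratedDataset:
    """Deduplicated records with binary labels at a stated molar cutoff."""

    records: list[CuratedRecord]
    cutoff_molar: float
    labels: list[int]
    curation_log: list[tuple[str, CurationFlag]]

    def __post_init__(self) -> None:
        keys = [r.molecule.inchikey for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("curated dataset contains duplicate InChIKeys")
        if len(self.labels) != len(self.records):
            raise ValueError("labels length must equal records length")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_active(self) -> int:
        return int(sum(self.labels))

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_row() | {"label": l} for r, l in zip(self.records, self.labels)]
        return pd.DataFrame(
            rows, columns=["inchikey", "canonical_smiles", "p_activity", "n_merged", "label"]
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"record_id": rid, "flag_code": fl.code.value, "detail": fl.detail}
                for rid, fl in self.curation_log
            ],
            columns=["record_id", "flag_code", "detail"],
        )


class EmptyDatasetError(RuntimeError):
    """Raised when curation rejects every input record."""

    def __init__(self, log: list[tuple[str, CurationFlag]]):
        super().__init__(
            f"all {len(log)} input records were rejected during curation"
        )
        self.curation_log = log


def _parse_structure(structure: str) -> Chem.Mol | None:
    """Parse SMILES or a MOL block without sanitizing (validation comes next)."""
    if "\n" in structure and ("V2000" in structure or "V3000" in structure or "M  END" in structure):
        return Chem.MolFromMolBlock(structure, sanitize=False, removeHs=False)
    return Chem.MolFromSmiles(structure, sanitize=False)


def _is_permanent_cation(atom: Chem.Atom) -> bool:
    # quaternary nitrogen / phosphonium: a +1 center with four heavy neighbors
    # and no proton to remove is a real structural feature, not an error
    return (
        atom.GetFormalCharge() == 1
        and atom.GetSymbol() in ("N", "P")
        and atom.GetTotalNumHs() == 0
        and atom.GetDegree() == 4
    )


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_molecule(structure: str) -> StandardizedMolecule:
    """Apply the standardization workflow to one SMILES or MOL block.

    The steps run in a fixed order, once: parse; strip enhanced and unknown
    stereo annotations; validate valences (flag ``ERR_VALENCE``); remove
    isotope labels; downgrade dative bonds; keep the largest component and
    flag ``MULTICOMPONENT``; neutralize protonation-state charges, flagging
    ``ERR_CHARGE`` for residual non-permanent charges.  Unparseable input
    yields a ``PARSE_FAIL`` flag rather than an exception.  The function is
    idempotent: feeding its own output back produces an identical structure
    and no new flags.
    """
    if not structure or not structure.strip():
        return StandardizedMolecule("", "", (CurationFlag(FlagCode.PARSE_FAIL, "empty structure"),))

    flags: list[CurationFlag] = []
    mol = _parse_structure(structure)
    if mol is None:
        return StandardizedMolecule(
            "", "", (CurationFlag(FlagCode.PARSE_FAIL, f"unparseable: {structure[:80]}"),)
        )

    # enhanced stereo groups (AND/OR/ABS blocks) carry no single-structure
    # meaning here; unknown (wavy) bond stereo is likewise dropped
    if mol.GetStereoGroups():
        mol = Chem.RWMol(mol)
        mol.SetStereoGroups([])
        mol = mol.GetMol()
    for bond in mol.GetBonds():
        if bond.GetBondDir() == Chem.BondDir.UNKNOWN:
            bond.SetBondDir(Chem.BondDir.NONE)
        if bond.GetStereo() == Chem.BondStereo.STEREOANY:
            bond.SetStereo(Chem.BondStereo.STEREONONE)

    # dative bonds become plain single bonds so the acceptor keeps its atoms
    for bond in mol.GetBonds():
        if bond.GetBondType() == Chem.BondType.DATIVE:
            bond.SetBondType(Chem.BondType.SINGLE)

    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        return StandardizedMolecule(
            "", "", tuple(flags) + (CurationFlag(FlagCode.ERR_VALENCE, str(exc)),)
        )
    except Exception as exc:  # kekulization failure, bad aromaticity, ...
        return StandardizedMolecule(
            "", "", tuple(flags) + (CurationFlag(FlagCode.PARSE_FAIL, str(exc)),)
        )

    if any(a.GetIsotope() for a in mol.GetAtoms()):
        for atom in mol.GetAtoms():
            atom.SetIsotope(0)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        sizes = sorted(f.GetNumHeavyAtoms() for f in frags)
        flags.append(
            CurationFlag(
                FlagCode.MULTICOMPONENT,
                f"kept largest of {len(frags)} components (heavy-atom counts {sizes})",
            )
        )
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))

    mol = _UNCHARGER.uncharge(mol)
    residual = [
        a for a in mol.GetAtoms() if a.GetFormalCharge() != 0 and not _is_permanent_cation(a)
    ]
    # a permanent cation balanced by a deprotonated site (an inner salt such as
    # a betaine) is fine; anything else that survived the uncharger is suspect
    if residual and Chem.GetFormalCharge(mol) != 0:
        return StandardizedMolecule(
            "",
            "",
            tuple(flags)
            + (
                CurationFlag(
                    FlagCode.ERR_CHARGE,
                    "net charge %+d not removable by neutralization" % Chem.GetFormalCharge(mol),
                ),
            ),
        )

    Chem.SanitizeMol(mol)
    inchikey = Chem.MolToInchiKey(mol)
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    smiles = Chem.MolToSmiles(kek, kekuleSmiles=True)
    return StandardizedMolecule(smiles, inchikey, tuple(flags), _mol=mol)


def to_pactivity(value: float, units: str) -> float:
    """Convert a reported potency to -log10(molar): (100, nM) → 7.0."""
    if not value > 0:
        raise ValueError(f"activity must be positive, got {value}")
    factor = UNIT_TO_MOLAR[normalize_unit(units)]
    return -math.log10(value * factor)


def deduplicate_and_average(
    records: Sequence[tuple[StandardizedMolecule, float]],
) -> tuple[list[CuratedRecord], list[tuple[str, CurationFlag]]]:
    """Merge records sharing an InChIKey, averaging pEC50 arithmetically.

    Returns the merged records (in first-appearance order) and a log with one
    ``DUPLICATE`` entry per absorbed member, recording the member SMILES,
    activities, and input indices of the whole group for inspection.
    """
    groups: dict[str, list[tuple[int, StandardizedMolecule, float]]] = {}
    order: list[str] = []
    for i, (mol, pact) in enumerate(records):
        if not mol.inchikey:
            raise ValueError("deduplication requires an InChIKey on every molecule")
        if mol.inchikey not in groups:
            groups[mol.inchikey] = []
            order.append(mol.inchikey)
        groups[mol.inchikey].append((i, mol, pact))

    curated: list[CuratedRecord] = []
    log: list[tuple[str, CurationFlag]] = []
    for key in order:
        members = groups[key]
        mean_p = sum(p for _, _, p in members) / len(members)
        first = members[0][1]
        parent_ids = tuple(
            rid for _, m, _ in members for rid in (m.parent_record_ids or ("?",))
        )
        merged = StandardizedMolecule(
            first.canonical_structure, first.inchikey, first.flags, parent_ids
        )
        curated.append(CuratedRecord(merged, mean_p, len(members)))
        if len(members) > 1:
            detail = "merged %d records: %s" % (
                len(members),
                "; ".join(
                    f"idx={i} smiles={m.canonical_structure} p={p:.4f}"
                    for i, m, p in members
                ),
            )
            for i, m, _ in members[1:]:
                rid = m.parent_record_ids[0] if m.parent_record_ids else f"index:{i}"
                log.append((rid, CurationFlag(FlagCode.DUPLICATE, detail)))
    return curated, log


def binarize(p_activity: float, cutoff_molar: float) -> int:
    """1 (active) iff potency is at least as good as the cutoff.

    On the pEC50 scale a cutoff of 5 µM is the threshold -log10(5e-6) ≈ 5.301;
    boundary equality counts as active.
    """
    if not cutoff_molar > 0:
        raise ValueError("cutoff_molar must be positive")
    return int(p_activity >= -math.log10(cutoff_molar))


def curate_dataset(
    records: Sequence[RawRecord], cutoff_molar: float = 5e-6
) -> CuratedDataset:
    """Run the full curation pipeline on raw records.

    standardize → drop error-flagged → convert to pEC50 → deduplicate and
    average → binarize.  Records with a censored qualifier (``>``/``<``) or a
    missing activity get a ``CENSORED_ACTIVITY`` log entry and are excluded:
    a censored EC50 has no defined pEC50 to average.
    """
    if not records:
        raise ValueError("curate_dataset requires at least one record")
    log: list[tuple[str, CurationFlag]] = []
    standardized: list[tuple[StandardizedMolecule, float]] = []
    for rec in records:
        mol = standardize_molecule(rec.structure)
        mol.parent_record_ids = (rec.record_id,)
        if mol.has_error:
            for fl in mol.flags:
                log.append((rec.record_id, fl))
            continue
        if rec.activity_value is None or rec.activity_qualifier != "=":
            reason = (
                "missing activity"
                if rec.activity_value is None
                else f"censored qualifier {rec.activity_qualifier!r}"
            )
            log.append((rec.record_id, CurationFlag(FlagCode.CENSORED_ACTIVITY, reason)))
            continue
        for fl in mol.flags:  # informational flags (MULTICOMPONENT)
            log.append((rec.record_id, fl))
        standardized.append((mol, to_pactivity(rec.activity_value, rec.activity_units)))

    if not standardized:
        raise EmptyDatasetError(log)

    curated, dup_log = deduplicate_and_average(standardized)
    log.extend(dup_log)
    labels = [binarize(r.p_activity, cutoff_molar) for r in curated]
    return CuratedDataset(curated, cutoff_molar, labels, log)
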