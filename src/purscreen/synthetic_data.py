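"""Synthetic bioactivity data with the statistical structure the pipeline assumes.

The generator emulates a curated receptor-agonist export: a few hundred
molecules whose potency (EC50) spans nM–mM, where activity is driven by a
planted substructure motif — mirroring how a congeneric agonist series
carries its SAR in a shared scaffold — plus the messiness of real database
exports: duplicate structures re-reported as salt, charge, or isotope
variants with slightly different activities, a minority of malformed
records, and censored ("> 10000") activities.

Molecules are assembled from a small scaffold/fragment vocabulary.  Motif
carriers embed an indole moiety (the default planted motif), so circular
fingerprints can genuinely learn the activity signal; decoys are verified to
be motif-free.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .io_formats import UNIT_TO_MOLAR, RawRecord

#: Planted activity motif: an indole ring system.
DEFAULT_MOTIF_SMARTS = "c1ccc2c(c1)cc[nH]2"

# Scaffold templates; {A} takes a secondary decoration, {R} the primary
# substituent (the motif variant for actives).  Templates use ring-closure
# digits 1-4; fragments use 8-9, so substitution never collides.
_SCAFFOLDS = (
    "c1cc({A})ccc1{R}",
    "c1cc({A})cc({R})c1",
    "C1CC({A})CCC1{R}",
    "c1nc({A})ccc1{R}",
    "O=C(N{A}){R}",
    "c1csc({A})c1{R}",
    "c1ccc({A})cc1O{R}",
    "O=C(O)c1cc({A})ccc1{R}",
    "CC(=O)Nc1cc({A})ccc1{R}",
)

# Secondary decorations (all attach through a carbon).
_DECORATIONS = (
    "C", "CC", "CCC", "C(C)C", "CCO", "CCN", "C(F)(F)F", "COC",
    "CC#N", "CN8CCOCC8", "Cc8ccccc8", "Cc8ccco8", "CCS(=O)(=O)C",
    "CCl", "CO",
)

# Primary substituents for decoys: drawn from the same chemistry, none
# containing the indole motif.
_DECOY_R = (
    "C", "CCC", "CC(C)C", "CCOC", "CCN(C)C", "Cc8ccccc8", "Cc8ccco8",
    "Cc8cccs8", "CC(=O)NC", "CN8CCCC8", "CCOCC", "C(F)(F)F", "CC#N",
    "Cc8ccc(F)cc8",
)

# Primary substituents for actives: indole-bearing variants.
_MOTIF_R = (
    "Cc8cc9ccccc9[nH]8",
    "CCc8cc9ccccc9[nH]8",
    "Cc8cc9ccc(C)cc9[nH]8",
    "Cc8cc9cc(F)ccc9[nH]8",
    "CCc8cc9ccc(OC)cc9[nH]8",
)

_INVALID_STRINGS = ("C1CC(", "c1ccccc", "X#Y!", "C(C)(C)(", "")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic bioactivity generator.

    Defaults mirror a curated agonist dataset of 244 molecules with a
    139/105 active/inactive balance at a 5 µM cutoff: motif carriers draw
    pEC50 ~ N(6.8, 0.45) (tens of nM to ~1 µM) and non-carriers
    N(3.9, 0.45) (tens of µM to ~1 mM), so both classes sit ≳3 SD from the
    5 µM threshold (pEC50 5.30) and the motif is, with rare tail exceptions,
    the activity label.
    """

    n_records: int = 244
    seed: int = 0
    motif_smarts: str = DEFAULT_MOTIF_SMARTS
    p_motif: float = 139 / 244
    p_duplicate: float = 0.06
    p_salt: float = 0.08
    p_charged: float = 0.05
    p_isotope: float = 0.02
    p_invalid: float = 0.03
    p_censored: float = 0.04
    potency_active_mean: float = 6.8
    potency_active_sd: float = 0.45
    potency_inactive_mean: float = 3.9
    potency_inactive_sd: float = 0.45

    def __post_init__(self) -> None:
        for name in (
            "p_motif", "p_duplicate", "p_salt", "p_charged",
            "p_isotope", "p_invalid", "p_censored",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        excl = self.p_salt + self.p_charged + self.p_isotope + self.p_invalid
        if excl > 1.0:
            raise ValueError(
                f"exclusive corruption probabilities sum to {excl:.3f} > 1"
            )
        if not self.potency_active_mean > self.potency_inactive_mean:
            raise ValueError("active potency mean must exceed inactive mean")


def _structure_pool(motif: bool, rng: np.random.Generator) -> list[str]:
    """All scaffold×decoration×substituent combinations, shuffled."""
    primaries = _MOTIF_R if motif else _DECOY_R
    combos = [
        scaffold.format(A=deco, R=primary)
        for scaffold in _SCAFFOLDS
        for deco in _DECORATIONS
        for primary in primaries
    ]
    rng.shuffle(combos)
    return combos


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def _draw_structure(
    pool: list[str], motif_query: Chem.Mol, want_motif: bool
) -> str:
    """Pop candidates until one parses and has the right motif status."""
    while pool:
        smiles = pool.pop()
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        if mol.HasSubstructMatch(motif_query) == want_motif:
            return Chem.MolToSmiles(mol)
    raise RuntimeError("structure vocabulary exhausted; reduce n_records")


def _salt_form(smiles: str, rng: np.random.Generator) -> str:
    salt = rng.choice([".Cl", ".[Na+].[Cl-]", ".OS(=O)(=O)O", ".O"])
    return smiles + salt


def _charged_form(smiles: str, rng: np.random.Generator) -> str:
    """Re-report the molecule as a protonation-state variant.

    Protonates a neutral amine nitrogen (adding a chloride counterion) or
    deprotonates a carboxylic acid (adding sodium); falls back to a salt
    decoration when neither site exists.  Standardization restores the
    neutral parent, so these variants collapse onto the parent InChIKey.
    """
    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if (
            atom.GetSymbol() == "N"
            and not atom.GetIsAromatic()
            and atom.GetFormalCharge() == 0
            and atom.GetTotalNumHs() > 0
        ):
            atom.SetFormalCharge(1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            return Chem.MolToSmiles(rw.GetMol()) + ".[Cl-]"
    acid = Chem.MolFromSmarts("C(=O)[OX2H1]")
    matches = mol.GetSubstructMatches(acid)
    if matches:
        o_idx = matches[0][2]
        rw.GetAtomWithIdx(o_idx).SetFormalCharge(-1)
        rw.GetAtomWithIdx(o_idx).SetNoImplicit(True)
        return Chem.MolToSmiles(rw.GetMol()) + ".[Na+]"
    return _salt_form(smiles, rng)


def _isotope_form(smiles: str) -> str:
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "C":
            atom.SetIsotope(13)
            break
    return Chem.MolToSmiles(mol.GetMol())


def _report_activity(p_activity: float) -> tuple[float, str]:
    """Express a pEC50 as a (value, unit) pair the way databases report it."""
    molar = 10.0 ** (-p_activity)
    if molar < 1e-7:
        unit = "nM"
    elif molar < 1e-4:
        unit = "µM"
    else:
        unit = "mM"
    return molar / UNIT_TO_MOLAR[unit], unit


def generate_bioactivity_dataset(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[RawRecord], pd.DataFrame]:
    """Generate raw bioactivity records plus a ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per record:
    ``record_id, clean_smiles, is_motif, p_activity_true, corruption,
    censored, duplicate_of``.  Records flagged ``corruption='invalid'``
    carry an unparseable structure; duplicates re-report an earlier
    molecule (possibly decorated) with a perturbed activity.
    """
    rng = np.random.default_rng(config.seed)
    motif_query = Chem.MolFromSmarts(config.motif_smarts)
    if motif_query is None:
        raise ValueError(f"bad motif SMARTS: {config.motif_smarts!r}")
    pools = {
        True: _structure_pool(True, rng),
        False: _structure_pool(False, rng),
    }

    records: list[RawRecord] = []
    truth_rows: list[dict] = []
    # previously emitted clean molecules eligible for duplication
    emitted: list[tuple[str, bool, float, str]] = []  # (rid, motif, p, smiles)

    for i in range(config.n_records):
        rid = f"SYN-{i:04d}"
        duplicate_of = ""
        if emitted and rng.random() < config.p_duplicate:
            src_rid, is_motif, p_src, clean = emitted[rng.integers(len(emitted))]
            p_true = p_src + rng.normal(0.0, 0.15)
            duplicate_of = src_rid
        else:
            is_motif = bool(rng.random() < config.p_motif)
            clean = _draw_structure(pools[is_motif], motif_query, is_motif)
            if is_motif:
                p_true = rng.normal(config.potency_active_mean, config.potency_active_sd)
            else:
                p_true = rng.normal(config.potency_inactive_mean, config.potency_inactive_sd)
            emitted.append((rid, is_motif, p_true, clean))

        u = rng.random()
        if u < config.p_invalid:
            corruption = "invalid"
            structure = str(rng.choice(_INVALID_STRINGS))
        elif u < config.p_invalid + config.p_salt:
            corruption = "salt"
            structure = _salt_form(clean, rng)
        elif u < config.p_invalid + config.p_salt + config.p_charged:
            corruption = "charged"
            structure = _charged_form(clean, rng)
        elif u < config.p_invalid + config.p_salt + config.p_charged + config.p_isotope:
            corruption = "isotope"
            structure = _isotope_form(clean)
        else:
            corruption = "none"
            structure = clean

        censored = bool(rng.random() < config.p_censored)
        value, unit = _report_activity(p_true)
        records.append(
            RawRecord(
                record_id=rid,
                structure=structure,
                activity_value=value,
                activity_units=unit,
                activity_qualifier=">" if censored else "=",
                source="synthetic",
            )
        )
        truth_rows.append(
            {
                "record_id": rid,
                "clean_smiles": clean,
                "is_motif": is_motif,
                "p_activity_true": p_true,
                "corruption": corruption,
                "censored": censored,
                "duplicate_of": duplicate_of,
            }
        )

    return records, pd.DataFrame(truth_rows)


def generate_screening_library(
    n_decoys: int,
    n_planted: int,
    motif_smarts: str = DEFAULT_MOTIF_SMARTS,
    seed: int = 0,
) -> tuple[list[RawRecord], list[str]]:
    """A clean screening library: motif-free decoys plus planted actives.

    Returns ``(records, truth)`` where ``truth`` lists the record ids of the
    planted motif carriers.  Planted members are interleaved at random
    positions so rank order cannot leak from file order.
    """
    if n_planted > n_decoys:
        raise ValueError("n_planted must not exceed n_decoys")
    if n_planted == 0:
        warnings.warn("no planted actives: enrichment is undefined for this library")
    rng = np.random.default_rng(seed)
    motif_query = Chem.MolFromSmarts(motif_smarts)
    decoy_pool = _structure_pool(False, rng)
    motif_pool = _structure_pool(True, rng)

    flags = np.zeros(n_decoys + n_planted, dtype=bool)
    flags[rng.choice(len(flags), size=n_planted, replace=False)] = True
    records, truth = [], []
    for i, planted in enumerate(flags):
        rid = f"LIB-{i:04d}"
        pool = motif_pool if planted else decoy_pool
        smiles = _draw_structure(pool, motif_query, bool(planted))
        records.append(RawRecord(record_id=rid, structure=smiles, source="synthetic-library"))
        if planted:
            truth.append(rid)
    return records, truth


def generate_dose_response(
    bottom: float,
    top: float,
    ic50: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "additive",
):
    """Simulate a concentration–response curve from the three-parameter logistic.

    Responses follow bottom + (top − bottom)/(1 + 10**(x − log10 ic50)) with
    Normal(0, noise_sd) noise — the inhibition orientation, so the response
    approaches ``bottom`` as concentration ≫ IC50.  With
    ``noise_model="proportional"`` the noise is constant-CV: the per-point
    standard deviation is ``noise_sd × |model response|`` (so ``noise_sd=0.05``
    is 5% measurement error), the usual heteroscedasticity of fluorescence
    intensity readouts.
    """
    from .assay_analysis import DoseResponse, _logistic3

    if not ic50 > 0:
        raise ValueError("ic50 must be positive (molar)")
    if noise_model not in ("additive", "proportional"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    x = np.log10(conc)
    resp = _logistic3(x, bottom, top, np.log10(ic50))
    if noise_sd > 0:
        sd = noise_sd * np.abs(resp) if noise_model == "proportional" else noise_sd
        resp = resp + rng.normal(0.0, sd, size=resp.shape)
    return DoseResponse(conc, resp)
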