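"""Consensus scoring and screening-library ranking.

The eight trained classifiers are aggregated per molecule into a consensus:
the unweighted mean of the per-model scores, with a majority-vote count
(models scoring ≥ 0.5) recorded alongside so either consensus reading is
available.  Screening libraries pass through the same structure
standardization as the training data before scoring; members that fail
standardization are logged and skipped, never silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import CurationFlag, StandardizedMolecule, standardize_molecule
from .features import FingerprintSpec, featurize_molecules
from .io_formats import RawRecord
from .modeling import ALGORITHM_NAMES, TrainedModel, predict_scores

VOTE_THRESHOLD = 0.5


class EmptyLibraryError(RuntimeError):
    """Every library member failed standardization."""


@dataclass(frozen=True)
class ConsensusScore:
    mean_score: float
    votes_active: int
    per_model_scores: tuple[tuple[str, float], ...]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.per_model_scores)


@dataclass(frozen=True)
class RankedEntry:
    record_id: str
    molecule: StandardizedMolecule
    consensus: ConsensusScore


@dataclass
class RankedLibrary:
    """A screening library ordered by consensus score.

    ``entries`` holds the top-n requested; ``all_entries`` the full ranking.
    Ties in mean score break by ascending InChIKey for a reproducible order.
    """

    entries: list[RankedEntry]
    library_name: str
    all_entries: list[RankedEntry]
    skipped: list[tuple[str, CurationFlag]]

    def to_frame(self, top_only: bool = True) -> pd.DataFrame:
        entries = self.entries if top_only else self.all_entries
        rows = []
        for rank, e in enumerate(entries, start=1):
            row = {
                "rank": rank,
                "record_id": e.record_id,
                "smiles": e.molecule.canonical_structure,
                "inchikey": e.molecule.inchikey,
                "mean_score": e.consensus.mean_score,
                "votes_active": e.consensus.votes_active,
            }
            row.update(e.consensus.scores)
            rows.append(row)
        return pd.DataFrame(rows)


def consensus_score(
    models: Mapping[str, TrainedModel],
    X: np.ndarray,
    require_full_panel: bool = True,
) -> list[ConsensusScore]:
    """Consensus over the model panel for each feature-matrix row.

    mean_score is the unweighted mean of per-model scores; votes_active
    counts models scoring at or above 0.5.
    """
    if require_full_panel:
        missing = [name for name in ALGORITHM_NAMES if name not in models]
        if missing:
            raise ValueError(f"consensus requires the full panel; missing: {missing}")
    if not models:
        raise ValueError("at least one model is required")
    names = [n for n in ALGORITHM_NAMES if n in models] + [
        n for n in models if n not in ALGORITHM_NAMES
    ]
    X = np.asarray(X, dtype=np.float64)
    per_model = {name: predict_scores(models[name], X) for name in names}
    out = []
    for i in range(X.shape[0]):
        scores = tuple((name, float(per_model[name][i])) for name in names)
        values = [s for _, s in scores]
        out.append(
            ConsensusScore(
                mean_score=float(np.mean(values)),
                votes_active=int(sum(s >= VOTE_THRESHOLD for s in values)),
                per_model_scores=scores,
            )
        )
    return out


def screen_library(
    models: Mapping[str, TrainedModel],
    library: Sequence[RawRecord],
    top_n: int,
    fingerprint: FingerprintSpec = FingerprintSpec(),
    library_name: str = "library",
    require_full_panel: bool = True,
) -> RankedLibrary:
    """Standardize, score, and rank a screening library.

    Library members pass through the same standardization as training data so
    model inputs are consistent; unstandardizable members are recorded in
    ``skipped``.  ``top_n`` larger than the library clamps to the full list.
    """
    if not library:
        raise ValueError("library is empty")
    molecules: list[tuple[str, StandardizedMolecule]] = []
    skipped: list[tuple[str, CurationFlag]] = []
    for rec in library:
        mol = standardize_molecule(rec.structure)
        if mol.has_error:
            skipped.extend((rec.record_id, fl) for fl in mol.flags)
            continue
        molecules.append((rec.record_id, mol))
    if not molecules:
        raise EmptyLibraryError(
            f"all {len(library)} members of {library_name!r} failed standardization"
        )
    X = featurize_molecules([m for _, m in molecules], fingerprint)
    consensus = consensus_score(models, X, require_full_panel=require_full_panel)
    entries = [
        RankedEntry(rid, mol, cs) for (rid, mol), cs in zip(molecules, consensus)
    ]
    entries.sort(key=lambda e: (-e.consensus.mean_score, e.molecule.inchikey))
    return RankedLibrary(
        entries=entries[: max(top_n, 0)] if top_n else list(entries),
        library_name=library_name,
        all_entries=entries,
        skipped=skipped,
    )
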