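"""Peptide candidacy and fragment quantifiability filters.

Candidate peptides for enrichment measurement must be uniquely assigned,
confidently identified, leucine-containing, fully cleaved, methionine-free
(oxidation would split the signal) and among the most intense peptides
detected.  Fragment ions are quantifiable only when their abundance is a
sufficient fraction of the parent (precursor) ion signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TypeVar

import pandas as pd

__all__ = [
    "IdentificationRecord",
    "SelectionCriteria",
    "select_candidate_peptides",
    "select_quantifiable_fragments",
    "read_identifications",
]


@dataclass(frozen=True)
class IdentificationRecord:
    """One peptide-spectrum identification as exported by a search/validation
    tool (sequence, protein assignment, probability, MS-signal rank)."""

    peptide_sequence: str
    assigned_proteins: tuple[str, ...]
    probability: float
    intensity_rank: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be within [0, 1]")
        if self.intensity_rank < 1:
            raise ValueError("intensity_rank must be >= 1")

    @property
    def has_methionine(self) -> bool:
        return "M" in self.peptide_sequence


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for candidate-peptide selection.

    Defaults: assigned with probability > 0.95 to a single protein, within
    the top 10 peptides by MS signal, contains leucine, no missed
    cleavage, no methionine.
    """

    min_probability: float = 0.95
    max_intensity_rank: int = 10
    require_leucine: bool = True
    forbid_missed_cleavage: bool = True
    forbid_methionine: bool = True
    require_unique_protein: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_probability <= 1.0:
            raise ValueError("min_probability must be within [0, 1]")
        if self.max_intensity_rank < 1:
            raise ValueError("max_intensity_rank must be >= 1")


def select_candidate_peptides(
    records: Iterable[IdentificationRecord],
    criteria: SelectionCriteria = SelectionCriteria(),
    target_protein: str | None = None,
) -> list[IdentificationRecord]:
    """Filter identification records down to enrichment-assay candidates.

    A record passes only if it satisfies every active criterion; input
    order is preserved.  ``target_protein`` restricts the unique-assignment
    check to that protein; when None, any uniquely assigned record passes.
    """

    def passes(rec: IdentificationRecord) -> bool:
        if criteria.require_leucine and "L" not in rec.peptide_sequence:
            return False
        if rec.intensity_rank > criteria.max_intensity_rank:
            return False
        if not rec.probability > criteria.min_probability:
            return False
        if criteria.require_unique_protein:
            if len(rec.assigned_proteins) != 1:
                return False
            if target_protein is not None and rec.assigned_proteins[0] != target_protein:
                return False
        elif target_protein is not None and target_protein not in rec.assigned_proteins:
            return False
        if criteria.forbid_missed_cleavage and rec.missed_cleavages != 0:
            return False
        if criteria.forbid_methionine and rec.has_methionine:
            return False
        return True

    return [rec for rec in records if passes(rec)]


FragmentKey = TypeVar("FragmentKey")


def select_quantifiable_fragments(
    scan_fragment_intensities: Mapping[FragmentKey, float],
    parent_intensity: float,
    min_fraction: float = 0.10,
) -> list[FragmentKey]:
    """Keep fragments whose intensity is >= ``min_fraction`` of the parent
    ion intensity (boundary inclusive); low-abundance fragments are not
    quantified.  Input order is preserved."""
    if parent_intensity <= 0:
        raise ValueError("parent_intensity must be > 0")
    threshold = min_fraction * parent_intensity
    return [
        frag
        for frag, intensity in scan_fragment_intensities.items()
        if intensity >= threshold
    ]


_COLUMN_ALIASES = {
    "peptide": "peptide_sequence",
    "sequence": "peptide_sequence",
    "peptide_sequence": "peptide_sequence",
    "proteins": "assigned_proteins",
    "protein": "assigned_proteins",
    "assigned_proteins": "assigned_proteins",
    "probability": "probability",
    "intensity_rank": "intensity_rank",
    "rank": "intensity_rank",
    "missed_cleavages": "missed_cleavages",
}


def read_identifications(path: str | Path) -> list[IdentificationRecord]:
    """Read identification records from CSV/TSV.

    Expected columns (aliases accepted): peptide, proteins
    (semicolon-separated), probability (percent or fraction,
    auto-detected), intensity_rank, missed_cleavages.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    frame = frame.rename(
        columns={c: _COLUMN_ALIASES[c.lower()] for c in frame.columns if c.lower() in _COLUMN_ALIASES}
    )
    required = {"peptide_sequence", "assigned_proteins", "probability", "intensity_rank"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"identification table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        probability = float(row.probability)
        if probability > 1.0:  # given as percent
            probability /= 100.0
        proteins = tuple(
            p.strip() for p in str(row.assigned_proteins).split(";") if p.strip()
        )
        records.append(
            IdentificationRecord(
                peptide_sequence=str(row.peptide_sequence),
                assigned_proteins=proteins,
                probability=probability,
                intensity_rank=int(row.intensity_rank),
                missed_cleavages=int(getattr(row, "missed_cleavages", 0)),
            )
        )
    return records
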