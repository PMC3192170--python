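"""Peptide mass chemistry for targeted deuterated-leucine enrichment assays.

Tryptic digestion, monoisotopic precursor and b/y fragment m/z for
unlabeled and deuterium-labeled species, and construction of the targeted
(inclusion) list used to drive the acquisition of product-ion scans.

The label model is d9- or d10-leucine: every labeled leucine residue adds
``deuterium_count`` times the 2H-1H mass difference to the species that
contains it.  Internally the exact per-deuterium shift (1.006277 Da) is
carried; nominal "+9 Da" / "+10 Da" values are a display convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "DEUTERIUM_SHIFT",
    "MassTable",
    "LabelSpec",
    "D9_LEUCINE",
    "D10_LEUCINE",
    "Peptide",
    "FragmentIon",
    "TargetEntry",
    "InvalidSequenceError",
    "digest",
    "monoisotopic_mh",
    "fragment_mz",
    "label_mass_shift",
    "build_target_list",
    "read_fasta",
    "write_target_list",
]

#: Mass of a proton (Da), i.e. the charge carrier of protonated species.
PROTON_MASS = 1.007276
#: Monoisotopic mass of H2O (Da), the peptide-bond condensation remainder.
WATER_MASS = 18.010565
#: Monoisotopic mass difference 2H - 1H (Da): 2.014102 - 1.007825.
DEUTERIUM_SHIFT = 1.006277

STANDARD_RESIDUES = frozenset("GASPVTCLINDQKEMHFRYW")


class InvalidSequenceError(ValueError):
    """A sequence contains a residue code outside the 20 standard ones."""


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise InvalidSequenceError(
            f"non-standard residue code(s) {sorted(bad)} in {sequence!r}"
        )
    return sequence


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses plus the fixed physical constants.

    The default table ships as a plain-text file
    (``enrichms/data/residue_masses.tsv``); an alternative table can be
    loaded with :meth:`from_file`.
    """

    residue_masses: dict[str, float]
    proton: float = PROTON_MASS
    water: float = WATER_MASS
    deuterium_shift: float = DEUTERIUM_SHIFT

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.residue_masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        for code, mass in self.residue_masses.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for residue {code}")

    @classmethod
    def default(cls) -> "MassTable":
        with resources.files("enrichms.data").joinpath(
            "residue_masses.tsv"
        ).open() as handle:
            return cls(_parse_mass_table(handle))

    @classmethod
    def from_file(cls, path: str | Path) -> "MassTable":
        with open(path) as handle:
            return cls(_parse_mass_table(handle))

    def residue_sum(self, sequence: str) -> float:
        _validate_sequence(sequence)
        return sum(self.residue_masses[aa] for aa in sequence)


def _parse_mass_table(handle: Iterable[str]) -> dict[str, float]:
    masses: dict[str, float] = {}
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, value = line.split("\t")
        masses[code] = float(value)
    return masses


_DEFAULT_TABLE: MassTable | None = None


def default_mass_table() -> MassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = MassTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class LabelSpec:
    """A deuterated-leucine label.

    d10-leucine is infused in vivo; transamination exchanges the
    alpha-carbon deuterium so the residue incorporated into protein is
    d9-leucine.  Synthetic-peptide work uses d10 directly.
    """

    name: str
    target_residue: str = "L"
    deuterium_count: int = 9

    def __post_init__(self) -> None:
        if self.deuterium_count not in (9, 10):
            raise ValueError("deuterium_count must be 9 or 10")

    @property
    def per_label_shift(self) -> float:
        """Mass added per labeled residue (Da)."""
        return self.deuterium_count * DEUTERIUM_SHIFT


D9_LEUCINE = LabelSpec("d9-leucine", "L", 9)
D10_LEUCINE = LabelSpec("d10-leucine", "L", 10)

LABELS = {"d9": D9_LEUCINE, "d10": D10_LEUCINE}


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with coordinates in its parent protein (1-based)."""

    sequence: str
    protein_start: int = 1
    protein_end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.protein_end == 0:
            object.__setattr__(
                self, "protein_end", self.protein_start + len(self.sequence) - 1
            )
        if self.protein_end - self.protein_start + 1 != len(self.sequence):
            raise ValueError("protein coordinates inconsistent with sequence length")

    @property
    def leucine_count(self) -> int:
        return self.sequence.count("L")

    def residue_count(self, code: str) -> int:
        return self.sequence.count(code)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series product ion of a peptide.

    ``b_k`` spans the N-terminal k residues, ``y_k`` the C-terminal k.
    ``label_count`` is the number of labeled target residues within the
    fragment's span.
    """

    peptide: Peptide
    series: str
    ordinal: int
    charge: int = 1
    label_count: int = 0
    mz: float = 0.0

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError("series must be 'b' or 'y'")
        if not 1 <= self.ordinal <= len(self.peptide) - 1:
            raise ValueError("fragment ordinal out of range")

    @property
    def span(self) -> str:
        """Residues covered by this fragment."""
        seq = self.peptide.sequence
        return seq[: self.ordinal] if self.series == "b" else seq[-self.ordinal :]

    @property
    def name(self) -> str:
        return f"{self.series}{self.ordinal}"


@dataclass(frozen=True)
class TargetEntry:
    """One row of the targeted inclusion list."""

    peptide: Peptide
    species: str  # "unlabeled" | "labeled"
    label_count: int
    charge: int
    precursor_mz: float
    fragments: tuple[FragmentIon, ...] = field(default_factory=tuple)


def digest(
    protein_sequence: str, max_missed: int = 0, offset: int = 1
) -> list[Peptide]:
    """In-silico tryptic digestion.

    Cleaves C-terminal of K or R except when the next residue is P (Keil
    rule).  Returns peptides with 0..``max_missed`` missed cleavages, with
    1-based protein coordinates.  Zero-missed peptides tile the protein.
    """
    _validate_sequence(protein_sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    n = len(protein_sequence)
    # cleavage sites: index i means a cut between residue i and i+1 (0-based)
    cuts = [
        i
        for i in range(n - 1)
        if protein_sequence[i] in "KR" and protein_sequence[i + 1] != "P"
    ]
    boundaries = [-1] + cuts + [n - 1]
    peptides: list[Peptide] = []
    for i in range(len(boundaries) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(boundaries):
                break
            start, end = boundaries[i] + 1, boundaries[j]
            peptides.append(
                Peptide(
                    sequence=protein_sequence[start : end + 1],
                    protein_start=offset + start,
                    protein_end=offset + end,
                    missed_cleavages=missed,
                )
            )
    return peptides


def monoisotopic_mh(
    sequence: str,
    label_count: int = 0,
    label: LabelSpec = D9_LEUCINE,
    mass_table: MassTable | None = None,
) -> float:
    """Singly protonated monoisotopic mass MH+ (Da) of a peptide.

    ``label_count`` labeled residues each add ``label.per_label_shift``.
    """
    table = mass_table or default_mass_table()
    if label_count < 0:
        raise ValueError("label_count must be >= 0")
    if label_count > sequence.count(label.target_residue):
        raise ValueError(
            f"label_count {label_count} exceeds {label.target_residue} residues "
            f"in {sequence!r}"
        )
    return (
        table.residue_sum(sequence)
        + table.water
        + table.proton
        + label_count * label.per_label_shift
    )


def fragment_mz(
    peptide: Peptide | str,
    series: str,
    ordinal: int,
    charge: int = 1,
    label_count: int = 0,
    label: LabelSpec = D9_LEUCINE,
    mass_table: MassTable | None = None,
) -> float:
    """m/z of a b- or y-series fragment ion.

    b_k = sum(residues 1..k) + z * proton, over z;
    y_k = sum(residues N-k+1..N) + water + z * proton, over z;
    plus ``label_count`` per-label shifts (divided by charge).
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if charge < 1:
        raise ValueError("charge must be >= 1")
    table = mass_table or default_mass_table()
    frag = FragmentIon(peptide, series, ordinal, charge, label_count)
    span = frag.span
    if label_count > span.count(label.target_residue):
        raise ValueError(
            f"label_count {label_count} exceeds {label.target_residue} residues "
            f"in fragment span {span!r}"
        )
    neutral = table.residue_sum(span)
    if series == "y":
        neutral += table.water
    neutral += label_count * label.per_label_shift
    return (neutral + charge * table.proton) / charge


def label_mass_shift(label: LabelSpec, n_labels: int = 1) -> float:
    """Total mass shift (Da) of a species carrying ``n_labels`` labels."""
    if n_labels < 0:
        raise ValueError("n_labels must be >= 0")
    return n_labels * label.per_label_shift


def make_fragment(
    peptide: Peptide | str,
    series: str,
    ordinal: int,
    charge: int = 1,
    label_count: int = 0,
    label: LabelSpec = D9_LEUCINE,
    mass_table: MassTable | None = None,
) -> FragmentIon:
    """Construct a :class:`FragmentIon` with its theoretical m/z filled in."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    mz = fragment_mz(peptide, series, ordinal, charge, label_count, label, mass_table)
    return FragmentIon(peptide, series, ordinal, charge, label_count, mz)


def _all_fragments(
    peptide: Peptide,
    label_count: int,
    label: LabelSpec,
    table: MassTable,
) -> tuple[FragmentIon, ...]:
    """All singly charged b/y fragments that can carry ``label_count`` labels."""
    frags = []
    for series in ("b", "y"):
        for ordinal in range(1, len(peptide)):
            span = (
                peptide.sequence[:ordinal]
                if series == "b"
                else peptide.sequence[-ordinal:]
            )
            if span.count(label.target_residue) < label_count:
                continue
            frags.append(
                make_fragment(peptide, series, ordinal, 1, label_count, label, table)
            )
    return tuple(frags)


def build_target_list(
    peptides: Iterable[Peptide],
    label: LabelSpec = D9_LEUCINE,
    charges: Iterable[int] = (1,),
    max_labels: int = 1,
    mass_table: MassTable | None = None,
) -> list[TargetEntry]:
    """Build the targeted inclusion list for a set of peptides.

    One unlabeled entry per peptide/charge, plus one labeled entry per
    label count 1..min(max_labels, leucine_count).  Peptides without the
    labelable residue yield unlabeled entries only.  Sorted by precursor
    m/z.  ``max_labels`` defaults to 1: the assay quantifies the
    singly-labeled (+9 Da nominal) species.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides supplied")
    table = mass_table or default_mass_table()
    entries: list[TargetEntry] = []
    for pep in peptides:
        n_target = pep.residue_count(label.target_residue)
        for charge in charges:
            for count in range(0, min(max_labels, n_target) + 1):
                mh = monoisotopic_mh(pep.sequence, count, label, table)
                precursor = (mh + (charge - 1) * table.proton) / charge
                entries.append(
                    TargetEntry(
                        peptide=pep,
                        species="unlabeled" if count == 0 else "labeled",
                        label_count=count,
                        charge=charge,
                        precursor_mz=precursor,
                        fragments=_all_fragments(pep, count, label, table),
                    )
                )
    entries.sort(key=lambda e: e.precursor_mz)
    return entries


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from a FASTA file (id -> sequence)."""
    from pyteomics import fasta

    records: dict[str, str] = {}
    with fasta.read(str(path)) as reader:
        for description, sequence in reader:
            identifier = description.split()[0]
            records[identifier] = sequence.upper()
    return records


def write_target_list(entries: Iterable[TargetEntry], path: str | Path) -> None:
    """Write a target list as CSV, one row per fragment ion."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "peptide",
                "protein_start",
                "protein_end",
                "species",
                "label_count",
                "charge",
                "precursor_mz",
                "fragment_series",
                "fragment_ordinal",
                "fragment_mz",
            ]
        )
        for entry in entries:
            for frag in entry.fragments:
                writer.writerow(
                    [
                        entry.peptide.sequence,
                        entry.peptide.protein_start,
                        entry.peptide.protein_end,
                        entry.species,
                        entry.label_count,
                        entry.charge,
                        f"{entry.precursor_mz:.6f}",
                        frag.series,
                        frag.ordinal,
                        f"{frag.mz:.6f}",
                    ]
                )


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used for printed m/z."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
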