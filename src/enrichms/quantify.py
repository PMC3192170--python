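"""End-to-end quantification: from a targeted run to percent enrichment.

For each monitored fragment ion the pipeline extracts a labeled and an
unlabeled product-ion XIC (labeled fragments from scans targeting the
labeled precursor, shifted by the label mass; unlabeled from scans
targeting the unlabeled precursor), detects and integrates the
chromatographic peaks over a shared window (the species co-elute), applies
the fragment-abundance rule (fragments below 10% of the parent-ion signal
are not quantified), and pools the areas into the percent enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import chem, msdata, selection, stats
from .chem import D9_LEUCINE, FragmentIon, LabelSpec, Peptide
from .msdata import Run, detect_peak, extract_product_xic, integrate, union_bounds
from .stats import FragmentAreaPair, PeptideEnrichment, compute_enrichment

__all__ = [
    "QuantifyConfig",
    "QuantifyResult",
    "quantify_peptide",
    "fragment_area_table",
    "linearity_by_fragment",
]


@dataclass(frozen=True)
class QuantifyConfig:
    """Tolerances and options of the quantification pipeline.

    ``fragment_tolerance`` is the product-ion XIC window (+/- Da);
    ``precursor_tolerance`` matches scans to their inclusion-list target;
    ``min_parent_fraction`` is the quantifiability threshold relative to
    the residual parent-ion signal; ``shared_bounds`` integrates labeled
    and unlabeled XICs over the union of their detected peak windows.
    """

    fragment_tolerance: float = 0.5
    precursor_tolerance: float = 1.5
    min_parent_fraction: float = 0.10
    shared_bounds: bool = True
    boundary_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.fragment_tolerance <= 0 or self.precursor_tolerance <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class QuantifyResult:
    peptide: Peptide
    enrichment: PeptideEnrichment | None
    pairs: list[FragmentAreaPair]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (fragment, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def percent_enrichment(self) -> float:
        if self.enrichment is None:
            raise ValueError("no quantifiable fragments; enrichment undefined")
        return self.enrichment.percent_enrichment


def _fragment_ions(
    peptide: Peptide, fragment_names: Sequence[str]
) -> list[FragmentIon]:
    ions = []
    for name in fragment_names:
        series, ordinal = name[0], int(name[1:])
        ions.append(chem.make_fragment(peptide, series, ordinal))
    return ions


def quantify_peptide(
    run: Run,
    peptide: Peptide | str,
    fragment_names: Sequence[str],
    label: LabelSpec = D9_LEUCINE,
    config: QuantifyConfig = QuantifyConfig(),
) -> QuantifyResult:
    """Measure the percent enrichment of one peptide in one run.

    ``fragment_names`` are the monitored product ions (e.g. ``["y6", "y7",
    "y8"]``); only fragments whose span contains the labelable residue can
    carry the label and contribute a labeled/unlabeled pair.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    shift = label.per_label_shift
    precursor_unlabeled = chem.monoisotopic_mh(peptide.sequence, 0, label)
    precursor_labeled = precursor_unlabeled + shift

    result = QuantifyResult(peptide=peptide, enrichment=None, pairs=[])
    fragments = _fragment_ions(peptide, fragment_names)

    # Parent-ion reference signal: residual precursor peak in the unlabeled
    # product-ion scans, evaluated at the chromatographic apex.
    parent_xic = extract_product_xic(
        run,
        precursor_unlabeled,
        precursor_unlabeled,
        tolerance=config.fragment_tolerance,
        precursor_tolerance=config.precursor_tolerance,
    )
    parent_apex_intensity = (
        float(parent_xic.intensities.max()) if len(parent_xic) else 0.0
    )
    apex_index = (
        int(np.argmax(parent_xic.intensities)) if len(parent_xic) else 0
    )

    unlabeled_xics = {}
    for frag in fragments:
        unlabeled_xics[frag.name] = extract_product_xic(
            run,
            precursor_unlabeled,
            frag.mz,
            tolerance=config.fragment_tolerance,
            precursor_tolerance=config.precursor_tolerance,
        )

    # Abundance rule: compare fragment to parent signal at the apex scan.
    if parent_apex_intensity > 0:
        apex_intensities = {
            name: float(xic.intensities[apex_index]) if len(xic) else 0.0
            for name, xic in unlabeled_xics.items()
        }
        quantifiable = set(
            selection.select_quantifiable_fragments(
                apex_intensities,
                parent_apex_intensity,
                min_fraction=config.min_parent_fraction,
            )
        )
    else:
        result.warnings.append(
            "no parent-ion signal found; fragment-abundance rule not applied"
        )
        quantifiable = {f.name for f in fragments}

    for frag in fragments:
        if frag.name not in quantifiable:
            result.skipped.append(
                (frag.name, "below parent-ion abundance threshold")
            )
            continue
        if label.target_residue not in frag.span:
            result.skipped.append(
                (frag.name, f"no {label.target_residue} in fragment span")
            )
            continue
        unlabeled_xic = unlabeled_xics[frag.name]
        labeled_xic = extract_product_xic(
            run,
            precursor_labeled,
            frag.mz + shift,
            tolerance=config.fragment_tolerance,
            precursor_tolerance=config.precursor_tolerance,
        )
        if len(unlabeled_xic) < 3:
            result.skipped.append((frag.name, "no unlabeled scans"))
            continue
        unlabeled_bounds = detect_peak(
            unlabeled_xic, boundary_fraction=config.boundary_fraction
        )
        if not unlabeled_bounds.found:
            result.skipped.append((frag.name, "no unlabeled peak detected"))
            continue
        if len(labeled_xic) < 3:
            labeled_area = 0.0
            result.warnings.append(
                f"{frag.name}: no labeled scans; labeled area set to 0"
            )
            bounds = unlabeled_bounds
            unlabeled_peak = integrate(unlabeled_xic, bounds)
        else:
            labeled_bounds = detect_peak(
                labeled_xic, boundary_fraction=config.boundary_fraction
            )
            if not labeled_bounds.found:
                result.warnings.append(f"{frag.name}: no labeled peak detected")
            if config.shared_bounds:
                bounds = union_bounds(unlabeled_bounds, labeled_bounds)
            else:
                bounds = unlabeled_bounds
            unlabeled_peak = integrate(unlabeled_xic, bounds)
            if labeled_bounds.found or config.shared_bounds:
                labeled_area = integrate(
                    labeled_xic, bounds if config.shared_bounds else labeled_bounds
                ).area
            else:
                labeled_area = 0.0
        result.pairs.append(
            FragmentAreaPair(
                fragment=frag,
                unlabeled_area=unlabeled_peak.area,
                labeled_area=labeled_area,
            )
        )

    if result.pairs:
        result.enrichment = compute_enrichment(result.pairs, peptide)
    else:
        result.warnings.append("no quantifiable fragments for peptide")
    return result


def fragment_area_table(
    runs: Sequence[Run],
    peptide: Peptide | str,
    fragment_names: Sequence[str],
    label: LabelSpec = D9_LEUCINE,
    config: QuantifyConfig = QuantifyConfig(),
):
    """Per-run, per-fragment labeled/unlabeled areas as a pandas DataFrame
    (columns: run, amount, fragment, species, area)."""
    import pandas as pd

    rows = []
    for index, run in enumerate(runs):
        res = quantify_peptide(run, peptide, fragment_names, label, config)
        amount = run.metadata.get("amount")
        for pair in res.pairs:
            name = (
                pair.fragment.name
                if isinstance(pair.fragment, FragmentIon)
                else str(pair.fragment)
            )
            rows.append((index, amount, name, "unlabeled", pair.unlabeled_area))
            rows.append((index, amount, name, "labeled", pair.labeled_area))
    return pd.DataFrame(
        rows, columns=["run", "amount", "fragment", "species", "area"]
    )


def linearity_by_fragment(
    runs: Sequence[Run],
    peptide: Peptide | str,
    fragment_names: Sequence[str],
    label: LabelSpec = D9_LEUCINE,
    config: QuantifyConfig = QuantifyConfig(),
) -> dict[tuple[str, str], stats.LinearityResult]:
    """Signal-linearity regressions of peak area against injected amount.

    Returns one OLS result per (fragment, species) over a series of runs
    carrying an ``amount`` metadata entry.
    """
    table = fragment_area_table(runs, peptide, fragment_names, label, config)
    if table["amount"].isna().any():
        raise ValueError("every run needs an 'amount' metadata entry")
    results: dict[tuple[str, str], stats.LinearityResult] = {}
    for (fragment, species), group in table.groupby(["fragment", "species"]):
        results[(fragment, species)] = stats.linearity_regression(
            group["amount"].to_numpy(), group["area"].to_numpy()
        )
    return results
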