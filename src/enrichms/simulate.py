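"""Synthetic targeted LC-MS/MS runs with known ground-truth enrichment.

The simulator emulates an inclusion-list acquisition on a single peptide:
product-ion scans alternate between the unlabeled and the labeled
precursor target across a Gaussian elution profile shared by both species
(deuterated peptides are assumed to co-elute).  Each scan carries centroid
peaks for the monitored fragment ions plus a residual precursor peak; the
labeled species' fragment intensities are the unlabeled ones scaled by the
configured true enrichment fraction.  Optional noise: multiplicative
lognormal intensity noise (given as a CV), a constant additive baseline,
and Gaussian m/z jitter.  Runs are deterministic under a fixed seed.

Defaults reproduce the reference assay: the y6/y7/y8 ions of IPVGPETLGR
(the 134-143 tryptic peptide of the ATP synthase beta subunit) with a
d9-leucine label and sub-percent enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import chem
from .chem import D9_LEUCINE, D10_LEUCINE, LabelSpec, Peptide
from .msdata import Run, SpectrumScan

__all__ = [
    "SimConfig",
    "simulate_run",
    "simulate_dilution_series",
    "simulate_mixture_series",
    "DEFAULT_DILUTION_AMOUNTS",
    "DEFAULT_MIXTURE_RATIOS",
]

#: Injected amounts (mg muscle protein) of the seven-point linearity series.
DEFAULT_DILUTION_AMOUNTS = (0.2, 0.3, 0.4, 0.5, 0.8, 1.1, 2.3)

#: Eight labeled:unlabeled molar ratios for the synthetic-peptide mixture
#: series, log-spaced to span measured enrichments of roughly 0.009-8.2%.
DEFAULT_MIXTURE_RATIOS = tuple(
    (float(r), 1.0) for r in np.geomspace(9e-5, 8.185e-2, 8)
)


def _default_peptide() -> Peptide:
    return Peptide("IPVGPETLGR", protein_start=134)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration of one simulated run.

    ``true_enrichment`` is a fraction (0.00482 corresponds to 0.482%).
    ``fragment_base_intensities`` maps fragment names (e.g. ``"y6"``) to
    apex intensities at ``amount_scale`` 1; the residual precursor peak has
    ``parent_base_intensity``.  Noise parameters of 0 give a noise-free run.
    """

    peptide: Peptide = field(default_factory=_default_peptide)
    label: LabelSpec = D9_LEUCINE
    true_enrichment: float = 0.00482
    elution_center: float = 12.0  # minutes
    elution_sigma: float = 0.10  # minutes
    elution_halfwidth_sigmas: float = 5.0
    scan_interval: float = 0.01  # minutes between consecutive scans
    fragment_base_intensities: dict[str, float] = field(
        default_factory=lambda: {"y6": 4.0e4, "y7": 9.0e4, "y8": 7.0e4}
    )
    parent_base_intensity: float = 2.0e5
    amount_scale: float = 1.0
    mz_jitter_sd: float = 0.0  # Da
    multiplicative_cv: float = 0.0  # lognormal intensity noise, as a CV
    baseline: float = 0.0  # additive intensity floor on every peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_enrichment < 0:
            raise ValueError("true_enrichment must be >= 0")
        if self.elution_sigma <= 0 or self.scan_interval <= 0:
            raise ValueError("elution_sigma and scan_interval must be > 0")
        if self.amount_scale <= 0:
            raise ValueError("amount_scale must be > 0")

    def fragments(self) -> list[chem.FragmentIon]:
        """Monitored unlabeled fragment ions, from the configured names."""
        frags = []
        for name in self.fragment_base_intensities:
            series, ordinal = name[0], int(name[1:])
            frags.append(chem.make_fragment(self.peptide, series, ordinal))
        return frags


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def simulate_run(config: SimConfig) -> Run:
    """Simulate one targeted run of the configured peptide.

    Scans alternate between the unlabeled and labeled precursor targets at
    ``scan_interval`` cadence over ``elution_center`` +/-
    ``elution_halfwidth_sigmas`` sigma.  Fragment peak intensity at
    retention time t is ``base * amount_scale * exp(-(t-c)^2/(2 sigma^2))``
    times ``true_enrichment`` for the labeled species, with optional noise.
    """
    rng = np.random.default_rng(config.seed)
    pep = config.peptide
    label = config.label
    shift = label.per_label_shift

    mh_unlabeled = chem.monoisotopic_mh(pep.sequence, 0, label)
    mh_labeled = mh_unlabeled + shift
    fragments = config.fragments()
    bases = np.array(
        [config.fragment_base_intensities[f.name] for f in fragments]
    )

    half = config.elution_halfwidth_sigmas * config.elution_sigma
    start = config.elution_center - half
    n_scans = int(round(2 * half / config.scan_interval)) + 1
    scans: list[SpectrumScan] = []
    for k in range(n_scans):
        t = start + k * config.scan_interval
        labeled = k % 2 == 1
        profile = np.exp(
            -((t - config.elution_center) ** 2) / (2 * config.elution_sigma**2)
        )
        species_factor = config.true_enrichment if labeled else 1.0
        intensities = bases * config.amount_scale * profile * species_factor
        intensities = intensities * _lognormal_factor(
            rng, config.multiplicative_cv, len(intensities)
        )
        intensities = intensities + config.baseline
        mzs = np.array(
            [
                f.mz + (shift if labeled and "L" in f.span else 0.0)
                for f in fragments
            ]
        )
        if config.mz_jitter_sd > 0:
            mzs = mzs + rng.normal(0.0, config.mz_jitter_sd, size=len(mzs))
        parent_mz = mh_labeled if labeled else mh_unlabeled
        parent_intensity = (
            config.parent_base_intensity * config.amount_scale * profile
        )
        parent_intensity *= float(
            _lognormal_factor(rng, config.multiplicative_cv, 1)[0]
        )
        peaks = list(zip(mzs.tolist(), intensities.tolist()))
        peaks.append((parent_mz, parent_intensity + config.baseline))
        scans.append(
            SpectrumScan(
                retention_time=t,
                precursor_target_mz=parent_mz,
                peaks=peaks,
            )
        )
    metadata = {
        "peptide": pep.sequence,
        "label": label.name,
        "true_enrichment": config.true_enrichment,
        "amount": config.amount_scale,
        "seed": config.seed,
    }
    return Run(scans=scans, metadata=metadata)


def simulate_dilution_series(
    config: SimConfig, amounts: Sequence[float] = DEFAULT_DILUTION_AMOUNTS
) -> list[Run]:
    """One run per injected amount, with ``amount_scale`` proportional to
    the amount and per-run seeds derived as base seed + index."""
    if any(a <= 0 for a in amounts):
        raise ValueError("amounts must be positive")
    runs = []
    for index, amount in enumerate(amounts):
        run_config = replace(
            config, amount_scale=float(amount), seed=config.seed + index
        )
        run = simulate_run(run_config)
        run.metadata["amount"] = float(amount)
        runs.append(run)
    return runs


def simulate_mixture_series(
    ratios: Sequence[tuple[float, float]] = DEFAULT_MIXTURE_RATIOS,
    base_config: SimConfig | None = None,
) -> list[Run]:
    """Synthetic-peptide mixture series: one run per labeled:unlabeled
    molar ratio, with true enrichment = labeled/unlabeled.  The synthetic
    labeled peptide carries a d10 label."""
    if len(ratios) < 3:
        raise ValueError("at least 3 mixture ratios required")
    if base_config is None:
        base_config = SimConfig(label=D10_LEUCINE)
    runs = []
    for index, (labeled_moles, unlabeled_moles) in enumerate(ratios):
        if unlabeled_moles <= 0:
            raise ValueError("unlabeled_moles must be > 0")
        run_config = replace(
            base_config,
            true_enrichment=labeled_moles / unlabeled_moles,
            seed=base_config.seed + index,
        )
        run = simulate_run(run_config)
        run.metadata["labeled_moles"] = float(labeled_moles)
        run.metadata["unlabeled_moles"] = float(unlabeled_moles)
        runs.append(run)
    return runs
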