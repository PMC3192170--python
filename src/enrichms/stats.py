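"""Peptide enrichment arithmetic and assay validation statistics.

Percent enrichment of a peptide is the area-sum ratio

    enrichment (%) = 100 * sum(labeled fragment areas)
                         / sum(unlabeled fragment areas)

pooled over the quantifiable fragment ions of that peptide.  Validation
statistics cover replicate reproducibility (CV), signal linearity of
fragment peak area against amount injected (OLS with a two-sided test of
the intercept against zero), and the measured-against-predicted enrichment
regression for synthetic-peptide mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .chem import FragmentIon, Peptide

__all__ = [
    "FragmentAreaPair",
    "PeptideEnrichment",
    "ReplicateSummary",
    "LinearityResult",
    "compute_enrichment",
    "replicate_summary",
    "linearity_regression",
    "predicted_enrichment_from_mixture",
    "measured_vs_predicted",
]


@dataclass(frozen=True)
class FragmentAreaPair:
    """Integrated labeled/unlabeled XIC areas for one fragment ion."""

    fragment: FragmentIon | str
    unlabeled_area: float
    labeled_area: float

    def __post_init__(self) -> None:
        if self.unlabeled_area < 0 or self.labeled_area < 0:
            raise ValueError("areas must be >= 0")

    @property
    def ratio_percent(self) -> float:
        """Per-fragment labeled/unlabeled ratio (%) — diagnostic only; the
        peptide value uses the pooled area-sum ratio."""
        if self.unlabeled_area == 0:
            return math.nan
        return 100.0 * self.labeled_area / self.unlabeled_area


@dataclass(frozen=True)
class PeptideEnrichment:
    peptide: Peptide | str
    pairs: tuple[FragmentAreaPair, ...]
    percent_enrichment: float

    def __post_init__(self) -> None:
        if self.percent_enrichment < 0:
            raise ValueError("percent_enrichment must be >= 0")


@dataclass(frozen=True)
class ReplicateSummary:
    values: tuple[float, ...]
    mean: float
    sd: float
    cv: float  # 100 * sd / mean


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    intercept_p: float
    n: int
    exact_fit: bool = False


def compute_enrichment(
    pairs: Sequence[FragmentAreaPair], peptide: Peptide | str | None = None
) -> PeptideEnrichment:
    """Pooled percent enrichment from labeled/unlabeled fragment areas."""
    if not pairs:
        raise ValueError("at least one fragment area pair required")
    unlabeled_total = sum(p.unlabeled_area for p in pairs)
    if unlabeled_total <= 0:
        raise ValueError("undefined enrichment: total unlabeled area is zero")
    labeled_total = sum(p.labeled_area for p in pairs)
    if peptide is None:
        first = pairs[0].fragment
        peptide = first.peptide if isinstance(first, FragmentIon) else ""
    return PeptideEnrichment(
        peptide=peptide,
        pairs=tuple(pairs),
        percent_enrichment=100.0 * labeled_total / unlabeled_total,
    )


def replicate_summary(values: Sequence[float]) -> ReplicateSummary:
    """Mean, sample SD (n-1 denominator) and CV (%) across replicates."""
    if len(values) < 2:
        raise ValueError("replicate summary requires n >= 2")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    sd = float(arr.std(ddof=1))
    return ReplicateSummary(
        values=tuple(float(v) for v in arr),
        mean=mean,
        sd=sd,
        cv=100.0 * sd / mean,
    )


_EXACT_FIT_RTOL = 1e-12


def linearity_regression(
    x: Sequence[float], y: Sequence[float]
) -> LinearityResult:
    """OLS fit y = a + b*x with R^2 and a two-sided t-test of a = 0.

    An (numerically) exact fit has zero residual variance, so the intercept
    standard error degenerates; such fits are flagged ``exact_fit`` and the
    intercept p-value is 0.0 for a nonzero intercept and 1.0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("regression requires n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    scale = max(np.abs(y).max(), 1.0)
    exact = math.sqrt(max(model.ssr, 0.0) / n) <= _EXACT_FIT_RTOL * scale
    if exact:
        r_squared = 1.0
        intercept_p = 0.0 if abs(intercept) > _EXACT_FIT_RTOL * scale else 1.0
    else:
        r_squared = float(model.rsquared)
        intercept_p = float(model.pvalues[0])
    return LinearityResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        intercept_p=intercept_p,
        n=n,
        exact_fit=exact,
    )


def predicted_enrichment_from_mixture(
    labeled_amount: float, unlabeled_amount: float
) -> float:
    """Predicted percent enrichment of a labeled/unlabeled peptide mixture
    from its molar composition: 100 * labeled / unlabeled."""
    if unlabeled_amount <= 0:
        raise ValueError("unlabeled_amount must be > 0")
    if labeled_amount < 0:
        raise ValueError("labeled_amount must be >= 0")
    return 100.0 * labeled_amount / unlabeled_amount


def measured_vs_predicted(
    measured: Sequence[float], predicted: Sequence[float]
) -> LinearityResult:
    """OLS of measured enrichment on predicted enrichment (both %)."""
    if len(measured) != len(predicted):
        raise ValueError("measured and predicted must have equal length")
    return linearity_regression(predicted, measured)


def percent_to_fraction(percent: float) -> float:
    return percent / 100.0


def fraction_to_percent(fraction: float) -> float:
    return fraction * 100.0
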