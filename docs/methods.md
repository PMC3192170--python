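# Methods

## Label model

The assay measures incorporation of deuterated leucine into a target
protein. d10-leucine is infused; transamination through
alpha-ketoisocaproate exchanges the alpha-carbon deuterium, so the residue
that enters protein is d9-leucine. Synthetic peptide standards are made
with d10-leucine directly. A species carrying n labeled leucines is
heavier by n · d · 1.006277 Da, with d = 9 or 10 deuteriums per label.
The exact per-deuterium shift is carried everywhere internally; "+9 Da" /
"+10 Da" are presentation-level roundings. The 0.5 Da product-ion
tolerance absorbs the 0.06 Da difference, so nominal and exact targeting
select the same peaks.

Mass basis: the standard monoisotopic residue masses (shipped as
`enrichms/data/residue_masses.tsv`, overridable via
`MassTable.from_file`), proton 1.007276 Da, water 18.010565 Da. b-ions
are the N-terminal residue sum plus z protons over z; y-ions add water.
Comparisons with one-decimal reported values use round-half-away-from-zero
(`chem.round_half_away`). No ¹³C isotope-envelope modeling is done: the
assay quantifies monoisotopic species, and fragments are singly charged.

## Digestion and target selection

Trypsin specificity is the Keil rule — cleavage C-terminal of K/R except
before P. The inclusion list contains, per peptide and charge, the
unlabeled precursor and labeled precursors for 1..`max_labels` labels;
`max_labels` defaults to 1 because the quantified species is the singly
labeled (+9 Da) one — at sub-percent precursor enrichment, doubly labeled
peptides are rarer by another two orders of magnitude. Candidate peptides
for quantification must contain leucine, rank within the top 10 by MS
signal (the rank is consumed from the identification record, per run, not
recomputed), be assigned to exactly one protein with probability > 0.95,
have no missed cleavage and no methionine (oxidation would split the
signal between modified forms). Identification probabilities are consumed
from a search/validation export, never computed here.

## XIC extraction and integration

Product-ion XICs use an inclusive ±0.5 Da window; each contributing scan
yields one point (0 when no peak matches). Scans are attributed to a
precursor target within ±1.5 Da, a typical targeted isolation width; the
labeled and unlabeled precursors are ~9-10 Da apart, far beyond any
realistic isolation window, so the two species' scans never mix. Peak
detection takes the global maximum as apex and walks outward until the
signal drops below 1% of the apex or a local minimum below 5% of apex is
met (bounds clipped to the XIC range); an all-zero XIC returns a flagged
no-peak result. Integration is the trapezoidal rule on the raw points —
no smoothing, so areas are exactly reproducible and testable against
closed forms. Because deuteration does not shift retention here, labeled
and unlabeled XICs of a fragment are integrated over the union of their
detected windows (configurable off); this removes the asymmetry that
independent boundary detection would introduce at very low labeled
signal. Fragments below 10% of the parent-ion intensity at the
chromatographic apex are excluded (boundary inclusive), mirroring the
practice of not quantifying low-abundance fragments; when no residual
parent signal exists in the scans the rule cannot be evaluated and is
skipped with a warning.

## Enrichment and statistics

Peptide enrichment is the pooled ratio 100 · ΣA_labeled / ΣA_unlabeled
over the quantifiable fragments — the area-sum form, not the mean of
per-fragment ratios (those are exposed as diagnostics). It is undefined
(an error) when the unlabeled area sum is zero. Replicate summaries use
the sample SD (n−1) and CV = 100·SD/mean. Linearity fits are ordinary
least squares with a two-sided t-test of the intercept against zero at
α = 0.05, no multiple-testing correction; numerically exact fits (zero
residual variance) are flagged and given p = 0 for a nonzero intercept,
p = 1 otherwise, rather than dividing by a zero standard error. All
enrichment values are carried in percent, with converters provided.

## Simulator

The simulator emulates an inclusion-list acquisition on one peptide:
scans alternate between the unlabeled and labeled precursor target at a
fixed cadence across a single shared Gaussian elution profile (deuterium
retention effects ignored). Fragment peak intensity at time t is
base · amount_scale · exp(−(t−c)²/2σ²), scaled by the true enrichment
fraction for the labeled species; each scan also carries a residual
precursor peak so the parent-abundance rule can act. Defaults are the
reference assay conditions: peptide IPVGPETLGR (y6/y7/y8 monitored), true
enrichment 0.00482, elution σ = 0.1 min with a ±5σ window, 0.01 min scan
interval (a realistic ion-trap MS/MS cadence), fragment apex intensities
4·10⁴/9·10⁴/7·10⁴ against a 2·10⁵ parent (fragments at 20–45% of parent,
comfortably quantifiable). The dilution series uses the seven amounts
0.2, 0.3, 0.4, 0.5, 0.8, 1.1 and 2.3 (mg muscle protein equivalents); the
mixture series defaults to eight labeled:unlabeled molar ratios log-spaced
over 9·10⁻⁵–8.185·10⁻², spanning measured enrichments of 0.009–8.2% (the
original eight ratios are not published; only their measured range is, so
the spacing is this package's choice).

Noise is multiplicative lognormal on every peak intensity (specified as a
CV; unit mean), plus an optional constant baseline and Gaussian m/z
jitter. Determinism: one integer seed per config; series derive per-run
seeds as seed + run index. The simulator does not model chimeric spectra,
dynamic exclusion, survey scans, isotope envelopes, retention-time drift
between runs, or detector saturation — the last being the likely cause of
the nonlinearity real assays show for some peptides. Passing tests
therefore demonstrate correctness of the computational pipeline under the
stated signal model, not robustness to every pathology of real LC-MS data.

## Files and interfaces

Runs are read/written as mzML (implemented directly over lxml: 32/64-bit
float arrays, none/zlib compression, minute/second time units) or as a
plain TSV (one row per centroid peak) that round-trips bit-exactly and
carries run metadata in a `#meta` JSON comment line. Identification
records come from CSV/TSV with probabilities accepted as fractions or
percent (auto-detected by value > 1). The CLI exposes `targets`,
`simulate` and `quantify`; the validation regressions (linearity table,
replicate CV) are produced by `quantify` when the runs carry amount
metadata, so no separate `validate` subcommand exists. Exit codes: 0 ok,
2 for unreadable or malformed data.

## Known limitations

- Fragment charge states above 1 are not generated (the assay monitors
  +1 fragments only).
- No retention-time alignment across runs; replicate runs are integrated
  independently.
- Intensity ranks for the top-10 rule are taken per run from the
  identification export; cross-run ranking is out of scope.
- The simulated problem sizes (one peptide, ~100 scans per species per
  run, 50-100 Monte-Carlo repetitions) are chosen to exercise every
  pipeline stage quickly; all scale linearly if enlarged.
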