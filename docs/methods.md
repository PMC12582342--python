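# Methods

`proteoturn` implements dynamic proteome profiling for heavy-water (D₂O)
labelling studies of human skeletal muscle: a cohort drinks small daily
doses of D₂O, body-water deuterium enrichment is held near steady state,
and newly synthesized protein incorporates deuterium at amino-acid C–H
positions. The shift in each peptide's mass-isotopomer distribution over a
labelling window yields a first-order turnover rate per protein, which is
combined with absolute abundance estimates to give absolute synthesis
rates, compared across study conditions.

## Labelling model

For each proteotypic peptide the relative isotopomer abundance is

    RIA = m1 / (m0 + m1)

where m0 and m1 are the monoisotopic and first heavy isotopomer
intensities. During labelling RIA rises mono-exponentially from its
baseline toward a plateau fixed by the peptide's count *N* of
deuterium-accessible C–H positions and the precursor-pool excess
deuterium-to-protium ratio:

    RIA_plateau = 1 − [ 1/(1 − RIA_t0) + N·(DH_exp − DH_nat) ]⁻¹

This expression reduces *exactly* to RIA_t0 when DH_exp = DH_nat (the
unlabelled limit), which the implementation special-cases so the identity
holds in floating point; the property is asserted in the tests. With
boundary samples at the start (t₀) and end (t₁) of a labelling period the
rate constant is

    k = −1/(t₁−t₀) · ln(1 − (RIA_t1 − RIA_t0)/(RIA_plateau − RIA_t0))

The degradation rate constant adjusts for abundance change over the
window, k_deg = k·P(t₁)/P(t₀); the fractional synthesis rate is FSR =
100·k (%/day); the absolute synthesis rate is ASR = P(t₁)·k_deg in ng per
µg total protein per day, with P = LFQ abundance (fmol/µg) × molecular
weight (kDa) × 10⁻³.

### Peptide → protein aggregation

Per-peptide estimates are pooled at the level of the **rise fraction**
f = (RIA_t1 − RIA_t0)/(RIA_plateau − RIA_t0): the protein-level fraction
is the median over the protein's peptides, and the exponential is
inverted once. Negative fractions (apparent RIA declines) and fractions
≥ 1 (apparently at plateau) *are included* in the median: they are
symmetric measurement noise around the true fraction for slow and fast
proteins respectively, and excluding them before pooling truncates the
noise distribution and inflates slow-protein rates substantially (in
simulation at 2% intensity CV, an exclude-then-median estimator
overestimates 1 %/day proteins by ≈ 2-fold). A negative aggregate rate is
reported with a `negative_rise` flag — never clipped — and retained in
compartment-summed ASR so that summed contrasts stay unbiased; an
aggregate fraction ≥ 1 is flagged `at_plateau` with no finite rate.
Peptides whose kinetic headroom is too small (plateau − RIA_t0 below the
`min_rise` threshold, default 0.01) or that fail the baseline QC
cross-check (|measured − theoretical natural RIA_t0| > 0.03) are excluded
from aggregation; all thresholds are configurable.

### Chemistry layer

Elemental compositions come from residue formulas (one water per peptide,
carbamidomethyl-C fixed and oxidation-M variable modifications as formula
deltas, so compositions stay integral). Natural isotope patterns are
computed by per-element polynomial convolution at unit-mass resolution
(isotopologues aggregated by nominal mass shift, matching a low-resolution
m0/m1 readout), truncated at order 4 by default; the convolution agrees
with an exhaustive isotopologue enumeration oracle to 10⁻¹². The
per-residue deuterium-accessible C–H counts are the Commerford-derived
empirical values shipped as an editable TSV (`data/exchangeable_h.tsv`);
element isotope abundances are IUPAC representative values
(`data/isotope_abundances.tsv`). Both tables can be substituted by the
user and every downstream number follows the substituted table.
Modifications are taken to contribute no exchangeable hydrogens (their
hydrogens are not placed by cytosolic amino-acid metabolism); this is a
documented choice, not a claim about any particular laboratory's
convention.

## Body-water enrichment

The acetone-exchange GC-MS assay is calibrated by ordinary least squares
of the mean replicate ion ratio I59/I58 against external D₂O standards
(0–5% in 0.5% steps, triplicate). The linear (not quadratic) form is
appropriate for selected-ion-monitoring ratios over this range. Plasma
samples invert the line; negative inversions clamp to zero with a QC
flag. Molar percent enrichment converts to a D:H mole ratio via
MPE/(100 − MPE), added to the natural background DH_nat = 1.5576 × 10⁻⁴
(VSMOW). The precursor enrichment of a subject in a period is the mean
over that period's sampled days (no between-day interpolation).

## Abundance quantification

*Normalization.* Label-free peptide intensities are normalized by median
log-ratio to the feature-wise median reference profile. The
implementation first centers each sample at its log-median and then
applies the median-ratio polish; the output is then an exact function of
each sample's intensity *shape*, which makes the operation exactly
idempotent and exactly invariant to per-sample scalar factors (both
asserted at 10⁻¹² in tests).

*Absolute scale.* Top-3 (Hi-3) quantification: protein fmol = (mean of
its three most intense peptides / mean of the spiked yeast ADH1
standard's top three) × ADH1 load, divided by the protein load on
column. Intensity ties break by peptide id for determinism; proteins with
fewer than three peptides use what is available and carry a flag.

*Targeted verification.* PRM light/heavy quantification uses one-point
calibration: abundance = (Σ light fragments / Σ heavy fragments) × spiked
amount. The ratio dot product (rdotp) is implemented as the cosine
similarity of the light and heavy fragment-intensity vectors (the
originating tool's exact definition is unpublished); a peptide is
quantified only if rdotp ≥ 0.91 in **every** sample — one failing sample
excludes the peptide everywhere.

*Reproducibility.* Within-subject CV between two repeat samples uses the
two-point sample SD (|a−b|/√2) over the pair mean, summarized by median
and interquartile range across proteins.

## Statistics

Protein abundance across the four serial timepoints, and ASR across the
three periods, are tested by one-way repeated-measures ANOVA with subject
as the blocking factor, F = MS_time/MS_(subject×time), df (T−1),
(T−1)(S−1); no sphericity correction is applied. Multiplicity is
summarized by Storey q-values: π̂₀ from a cubic-polynomial smoother over
the λ grid 0.05–0.95 evaluated at λ = 0.95 (clamped to (0, 1]; for fewer
than 100 tests the smoother is unstable and π̂₀ = 1 is used, which
reduces q-values to Benjamini–Hochberg), with the q-value at the p = 0.05
boundary reported as a scalar summary. Two-period contrasts are paired
t-tests on within-subject differences with log₂(mean ratio) effect sizes;
an exact sign-permutation p (statistic: mean paired difference) is
available and matches exhaustive enumeration in the tests.
Compartment-summed ASR is compared across periods by the RM-ANOVA omnibus
plus the three paired contrasts with Bonferroni ×3 scaling capped at 1.

Temporal clustering uses fuzzy c-means (alternating optimization,
fuzzifier m = 1.25, convergence when the largest center shift < 10⁻⁸, cap
500 iterations) on per-protein z-scored mean temporal profiles; a profile
joins a cluster only if its maximum membership reaches 0.25. The
objective Σ uᵐd² is recorded every iteration and is non-increasing.
Overrepresentation analysis is an upper-tail hypergeometric test of each
user-supplied term set against the experiment-specific background, with
Benjamini–Hochberg adjustment across terms and significance at adjusted
p ≤ 0.01.

## Energetics

Energy availability EA = (energy intake − exercise energy expenditure)
per kg fat-free mass per day. Percent reduction is 100·(a−b)/a with
round-half-even integer reporting. Substrate oxidation from indirect
calorimetry uses linear gas-exchange combinations fat = a₁·V̇O₂ −
a₂·V̇CO₂, cho = b₁·V̇CO₂ − b₂·V̇O₂ with per-context coefficient sets in an
editable table (`data/oxidation_coefficients.tsv`; rest: Frayn
whole-body; exercise: moderate-to-high-intensity coefficients). Negative
rates clamp to zero with a flag; RER outside [0.6, 1.3] flags the record.

## Synthetic cohort

The generator emulates the full study layout with known ground truth:
10 subjects; three consecutive 5-day periods — free living (FL, days −5
to 0), energy balance (EB, 0 to 5), energy deficit (ED, 5 to 10) —
sampled at days −5/0/5/10; body-water enrichment steady at 0.84% with
0.11% between-subject SD; 300 proteins (53% sarcoplasmic, 20%
myofibrillar, 27% mitochondrial, mirroring the 388/147/203 annotation
split of a typical muscle proteome) with 5 proteotypic tryptic peptides
each, drawn from random sequences with realistic residue composition (no
external database). Degradation rates are lognormal per compartment
(medians 1, 5 and 2 %/day for myofibrillar, sarcoplasmic and
mitochondrial pools; σ = 0.4 in log units — generator parameters, not
biological claims); the energy-deficit condition multiplies mitochondrial
rates by 1.47, so the mitochondrial summed-ASR ED/EB ratio is the primary
recoverable effect. RIA trajectories follow the forward model above, with
boundary values chained across consecutive periods, so the generator is
the exact inverse of the analysis: with all noise at zero the pipeline
recovers every true rate to machine precision (asserted at 10⁻¹⁰).

Noise defaults: 2% CV multiplicative noise on each isotopomer channel,
15% CV protein-level lognormal abundance noise per sample (shared by a
protein's peptides), fixed per-peptide response factors (log-SD 0.1),
per-sample instrument scale factors (log-SD 0.2, removed by
normalization), and additive GC-MS ratio noise (SD 10⁻⁴). The 15%
abundance noise implies a two-point within-subject CV median near 10%
(0.6745σ for a lognormal pair), somewhat below what repeat human biopsies
typically show; the generator models measurement and biological
variability as a single term and has no batch structure, missingness
beyond complete data, chromatographic drift, or peptide-level
interference — passing tests certify the estimators, not the full
messiness of real acquisitions.

Problem sizes used in the shipped checks (chosen to exercise the full
cohort layout while keeping any single run under a minute for the
kinetics benchmark and a few tens of seconds for the end-to-end run): the
`paper` preset is the full 10 × 300 × 5 layout; the `small` preset
(4 subjects, 40 proteins, 2 peptides) serves the I/O and CLI tests; the
kinetics-recovery benchmark uses 200 fast-turnover proteins.

## Known limitations

- A two-point, 5-day design at 0.84% enrichment carries a per-peptide
  rise-fraction noise of roughly 0.1–0.17 at 2% channel CV against a
  kinetic headroom (plateau − baseline) of only ≈ 0.05–0.08. Rates around
  5 %/day are recovered with ≈ 6–9% median error after pooling peptides
  and subjects, but 1–2 %/day proteins are information-limited: their
  relative errors are several-fold larger regardless of estimator, and
  single-peptide estimates are frequently negative. This is a property of
  the design, not the code.
- Equation parsing: the plateau and rate formulas are isolated in single
  functions (`ria_plateau`, `rate_constant`) so an alternative algebraic
  reading can be swapped in without touching the rest of the pipeline.
- Whether abundance adjustment of k_deg happens at the peptide or protein
  level is underdetermined by the upstream description; protein-level
  P(t₁)/P(t₀) ratios are used here.
- The Storey smoother is a cubic polynomial rather than a smoothing
  spline; on uniform-null simulations π̂₀ lands in [0.85, 1.05].
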