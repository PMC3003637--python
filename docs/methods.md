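# Methods

## Retention model

The package models the gradient RP-LC retention time of a tryptic peptide
as an ordinary least-squares multiple linear regression on two structural
descriptors,

    t_R = k1 + k2 · log Σ(k+1)_AA + k3 · clogP ,

with t_R in minutes. The composite descriptor log Σ(k+1)_AA sums, over the
peptide's residues, each residue's chromatographic retention factor k plus
one, then takes the base-10 logarithm; the "+1" keeps the logarithm finite
for peptides containing no retained residue, in which case the descriptor
reduces to log10(length). Only the seven most-retained (hydrophobic)
amino acids — I, L, M, F, W, Y, V — carry non-zero factors; all other
residues are ascribed k = 0. clogP, the calculated octanol/water partition
coefficient of the whole peptide, is always a supplied input column
(originally computed with an external logP predictor); the package never
computes it.

The model assumes a fixed chromatographic system: one column, one gradient
(the bundled data come from a 90-min 0→60% acetonitrile gradient on a C18
column), one mobile-phase chemistry. Coefficients fitted under one system
do not transfer to another without recalibration, and no gradient- or
column-transfer model is attempted.

Fit statistics follow the standard MLR conventions: R is the positive
multiple correlation coefficient (equal to the Pearson correlation between
fitted and observed times on the calibration set), s = sqrt(SSE/(n−3)) the
standard error of estimate, F = (R²/2)/((1−R²)/(n−3)) with (2, n−3)
degrees of freedom, plus per-coefficient two-sided t-tests. The estimator
is plain OLS with intercept (backed by statsmodels); a calibration set
with n ≤ 3 or a constant/collinear descriptor column raises an explicit
error rather than falling back to a pseudo-inverse. F is reported as
infinity for an exact fit.

### Two coefficient sets

The bundled calibration table (50 tryptic peptides of eight standard
proteins) is distributed together with a reported coefficient set
(−25.07, 33.16, 0.60), shipped here as `REFERENCE_MODEL`. Those
coefficients are internally inconsistent with the very table they
accompany: they undershoot its `t_r_pred` column by ~6 min for typical
peptides (e.g. 18.79 vs 25.13 min for ALKALPMHIR), while the reported fit
statistics (n = 50, R = 0.974, s = 1.45, F = 431) *are* consistent with an
OLS refit of the table, which gives (−17.58, 32.21, 0.76) with R = 0.974,
s = 1.44, F = 440. Which model produced the distributed `t_r_pred` column
is undecidable from the available information. The package therefore
treats the refit (`peprt.tables.calibration_model()`) as canonical and
keeps the reference coefficients only as a labelled constant. The
reference set's coefficient standard errors were not distributed and are
not asserted. The 21-peptide external test set mentioned alongside the
calibration data was never printed and cannot be bundled.

## Retention factors: the inverse problem

The per-residue k values behind the composite descriptor are not
tabulated in the bundled data, but 10^descriptor − length is exactly
linear in the residue counts of the retained set, so the factors are
recoverable from the printed descriptor column by non-negative least
squares (scipy NNLS) over the unique (sequence, descriptor) rows. With an
outlier tolerance of 0.003 (matching the 4-decimal printing of the
descriptor column), rows that cannot be reconstructed are iteratively
excluded and reported — never silently absorbed. On the bundled tables
exactly one row is excluded (YICENQDTISSKL, printed 1.4238, reconstructed
1.435; its Δt_R also breaks the table's sort order — evidently a
transcription defect in the source data). The solved defaults are shipped
in `peprt/data/retention_factors.tsv`:

    V 1.086, M 1.303, I 3.323, Y 3.576, L 3.990, F 6.435, W 9.666

They reproduce 83 of the 84 printed descriptor values within ±0.003.
These are reconstructions of, not measurements of, the underlying
experimental retention data (which were never distributed), and they are
user-overridable via a two-column text file.

## Masses and digestion

Peptide masses use the *average* mass scale with a proton mass of
1.00728 Da: the distributed m/z columns match average, not monoisotopic,
masses (LVNEVTEFAK²⁺ computes to 575.655 vs the printed 575.650, where
monoisotopic would give 574.9). This is an inference from the printed
values — the mass convention of the original measurements was not stated.
Cysteine is treated as unmodified by default: the digestion protocol the
bundled data derive from used DTT reduction with no alkylation step, and
the majority of cysteine-containing rows match unmodified C. However, 11
of the 84 distributed m/z values (all cysteine-containing peptides of two
of the eight model proteins) are offset by exactly +58.04 Da per cysteine,
i.e. they were computed with carboxymethyl-cysteine. The bundled tables
therefore mix two cysteine states; with the unmodified default, 73/84
distributed m/z values agree within 0.05 Th, and no single global cysteine
state does better. The mixed rows are listed in the anomaly sidecar.

In-silico digestion cleaves C-terminal of every K and R with **no proline
exception**. The bundled data force this choice: the printed
missed-cleavage count of 5 for LKPDPNTLCDEFKADEKKFWGKYLYEIAR counts the
K–P site (the Keil rule would give 4). Missed cleavages are counted as
internal K/R (positions 1..L−1); the distributed count of 0 for
FYLPNCNKNGFYHSR contradicts its internal K under any tryptic rule and is
flagged as a data defect. Digestion emits every fragment spanning
0..max_missed internal sites; the zero-missed fragments partition the
parent.

## Classification

Records are partitioned by two independent binary verdicts. The score
verdict applies the charge-dependent Xcorr thresholds 1.9 / 2.2 / 3.75
for 1+/2+/3+, strict (>) for charges 1–2 and inclusive (≥) for charge 3,
following the wording of the criteria ("higher than", "over", "at
least"); ΔCn > 0.08 is enforced only when a ΔCn value is present, since
the bundled identification tables do not carry one (the accompanying text
asserts all spectra exceeded it). Charges outside {1, 2, 3} raise rather
than extrapolate. The retention verdict accepts |Δt_R| strictly below
5.0 min, comparing magnitudes (the tables print signed differences; the
narrated group ranges are magnitudes). No bundled row sits exactly on any
boundary, so the strictness choices are documentation rather than fate.
The four groups (pass/pass → CORRECT, fail/fail → INCORRECT, pass/fail →
POTENTIAL_FALSE_POSITIVE, fail/pass → POTENTIAL_FALSE_NEGATIVE) form a
partition: every classifiable record lands in exactly one.

Applied to the pooled bundled strain tables with printed retention times,
the classifier reproduces the original block assignments for 33 of 34
rows; the single disagreement (ANNNSGNSNNLLVPGAAQAIDQMK, charge 3, Xcorr
3.41, originally listed as correct although 3.41 < 3.75) is flagged, and
the package follows the stated thresholds. The narrated group spreads
(correct 0.01–3.90 min, incorrect 5.66–83.74, potential false positives
6.41–10.05, potential false negatives up to 4.57) are observed ranges,
not additional thresholds; only the 5-min cutoff classifies.

## Synthetic data

The generator emulates the *structure* of an LC-MS/MS identification
table at the bundled calibration's conditions: by default 50 peptides of
length 5–30 with hydrophobic residues at 35% frequency (roughly their
proteome-wide share), descriptors computed from the shipped retention
factors, clogP drawn Normal(−4, 2.5) (the bundled range is −11.8..0.8),
retention times equal to the canonical model prediction plus Gaussian
noise with σ = 1.45 min (the calibration residual scale), and Xcorr drawn
Normal(3.5, 0.8) for genuine and Normal(1.0, 0.4) for spurious matches
(clipped at 0), with spurious matches eluting uniformly across a 90-min
run. A single integer seed fixes everything.

What it does not emulate: real amino-acid composition and its correlation
with clogP, charge-dependent score distributions, retention-time drift or
peak-shape effects, shared peptides between proteins, or any spectral
content. Passing parameter-recovery tests on this generator shows the
estimators are correct under the model's own assumptions, not that the
model describes any particular chromatographic system.

## Numerical choices and degenerate inputs

- Descriptor logarithms are base 10 throughout (forced by the bundled
  values: an unretained 14-mer prints 1.1461 = log10 14).
- NNLS ties/bounds: factors are constrained non-negative; a design matrix
  whose residue-count columns are rank deficient raises an error naming
  residues never observed.
- Table I/O writes retention columns at 2 decimals, m/z and descriptors at
  4; written tables round-trip exactly at that precision. Missing values
  round-trip as empty cells.
- Empty inputs (header-only tables, empty test sets) return empty results
  without error; missing mandatory columns and unparseable cells raise
  with row/column context.
- The statistical suite sizes simulations for a laptop-class run: 1000
  replicates for the confidence-interval coverage check and 200–400 for
  the other Monte-Carlo properties, chosen so binomial sampling error is
  well inside the asserted bounds.

## Known limitations

- The model carries no sequence-position information; permuted sequences
  share a prediction.
- Predictions can be negative for very short hydrophilic peptides (the
  intercept is ~−18 min); they are reported as-is.
- clogP must be supplied; without it the model degrades to a single
  descriptor and the package refuses to fit rather than guess.
- The shipped retention factors inherit the 4-decimal rounding of the
  descriptor column they were reconstructed from.
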