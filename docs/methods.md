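# Methods

This note documents the models and procedures implemented in
`codonclusters`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Codon usage tables

A table maps each of the 61 sense codons to a frequency in occurrences per
thousand codons (the convention of public codon-usage databases). Tables
are built by pooling codon counts over a set of ORFs, or read from a
two/three-column TSV or from free-text `CODON freq (count)` blocks; U is
normalised to T everywhere. All %MinMax quantities are invariant to
rescaling a table, and CAI uses within-family ratios, so the per-thousand
unit is cosmetic. The genetic code defaults to the standard (NCBI table 1)
code and is configurable; stop codons are counted during tabulation but
excluded from every metric, and a CDS's trailing stop codon is silently
stripped before analysis.

## %MinMax

For each sliding window of `W` codons (default 18, step 1) let `A` be the
window mean of the actual codons' frequencies, and `Max`, `Min`, `Avg` the
window means of each position's family maximum, minimum and unweighted
mean. The window scores `100·(A−Avg)/(Max−Avg)` when `A ≥ Avg`, else
`−100·(Avg−A)/(Avg−Min)`; both branches agree (0) at `A = Avg`. A window
composed entirely of single-codon families (Met/Trp) has
`A = Max = Min = Avg`; it is scored 0, the unique continuous completion.
A CDS of `L` sense codons yields `L − W + 1` values.

One published description of the window count reads as `L − 18` windows,
which would imply `W = 19`; the Rare Codon Calculator's own default is
`W = 18` with `L − 17` windows, which is what this package uses. `W` is a
parameter everywhere, so either convention is reproducible.

Degenerate inputs fail loudly with typed errors: length not divisible by
three (frame), non-ACGT characters (alphabet), internal stop codons
(premature stop), and `L < W` (too short). Profiles are computed on the
sequence as given; purification-tag codons at the 5′ end can be dropped
with `trim_5prime` (CLI `--trim-5prime-codons`).

## Host/target comparison

Both metrics compare the profiles of the *same* CDS under two tables; the
profiles must share `W`, window starts and trim flags (enforced).

- `Δ%MinMax = (1/n) Σᵢ |xᵢ − yᵢ|`, in percentage points; a metric
  (symmetric, non-negative, triangle inequality).
- `%MinMax correlation`: Pearson r of the window values, two-tailed p from
  `t = r·√((n−2)/(1−r²))` with `n − 2` degrees of freedom, `n` = number of
  windows. A constant profile (e.g. a gene recoded to only most-frequent
  codons) has no defined correlation; the result carries an explicit
  `defined=False` flag and is excluded from dataset-level analyses, never
  coerced to 0. Constancy is judged scale-relatively (spread below ~1e-12
  of the value magnitude), since a flat profile at +100 carries rounding
  jitter.

## Secondary-structure stratification

Annotations are one character per residue over {H, E, C}; dashes, dots and
blanks normalise to coil, which by construction also holds disordered
residues. Window-to-class assignment is not uniquely defined by a
residue-level annotation; two rules are implemented:

- `center` (default): a window belongs to the class of its centre residue
  (`start + ⌊W/2⌋`). Cheap, and insensitive to relabelling non-centre
  residues.
- `majority`: the modal class over the window's residues, ties broken
  H > E > C.

Neither rule is claimed to reproduce any particular published bookkeeping;
the rule used is recorded in report headers. Per-class correlations need at
least 3 windows (the p-value has n − 2 degrees of freedom) and nonzero
variance, otherwise they are reported undefined. Dataset-level per-class
analyses include only proteins whose *residue-level* content of the class
exceeds 5% (strict); the fraction is computed from the annotation, not from
window classes.

## CAI

`CAI = exp((1/L)·Σ ln w)` over all L sense codons, including singleton
families (w = 1). Relative adaptiveness `w` is the codon's frequency over
its family maximum. Zero-frequency codons would make `ln w` diverge; they
receive `w = 0.5/(family's maximum raw count)` when the table carries
counts, else `w = 1e-3` — a pseudocount that preserves ranking. A family
whose frequencies are all zero is an error. The reference table should
describe highly expressed genes of the host; with any other table the
absolute CAI values shift but the gene ranking logic is unchanged, so no
attempt is made to match any specific web tool's absolute output.

## Study statistics

- **Solubility**: `Isf/(Isf + Iif)` from band intensities; both-zero is an
  explicit undefined signal. Binary calls use a strict `> 0.30` threshold
  (the conventional 30% cut); external predictor scores are binarised at
  `≥ 0.50`.
- **Classifier evaluation**: prediction accuracy `(TN+TP)/total` and the
  Matthews correlation coefficient, with MCC defined as 0 whenever a
  marginal is zero.
- **Discrete screen scores**: 0–5 expression/solubility values are averaged
  arithmetically when a target has several reports.
- **Outlier screen**: single-pass. OLS of outcome on feature, 95% band
  half-width at each point's abscissa, exclude points whose absolute
  residual exceeds 3× that half-width. Two bands are available and behave
  very differently at screen scale (n ≈ 30):
  - *confidence* (mean-response) band: half-width ∝ s/√n, so the 3×
    threshold is ≈ 1.1 residual standard deviations. It reliably catches a
    single gross artifact — whose displacement then dominates s — but on
    clean data it also trims ~15% of points toward the fitted line, which
    measurably inflates the type-I error of the downstream correlation
    test (22% at nominal 5% in null simulations).
  - *prediction* (observation) band: the 3× threshold is ≈ 6 residual
    standard deviations, which a lone outlier can never exceed once it has
    inflated the fit's own residual scale; in practice it excludes nothing
    on clean data and preserves the nominal test level (8% measured).

  The low-level `regression_outlier_filter` defaults to the confidence
  band (the literal reading of the screening rule it implements); the
  dataset-level study analysis defaults to the prediction band, because
  there the priority is not fabricating associations. Both layers accept
  either band, and the choice is recorded in report headers. Whether
  outliers are removed before or after stratified analyses is likewise an
  open convention; this package applies the screen independently per
  feature × outcome pair, after the per-class content filter.

## The study model

`CodonUsageStudy` bundles CDSs, host/target tables, optional annotations
and outcome measurements; `fit()` computes per-gene features (Δ%MinMax,
%MinMax correlation overall and per class, CAI, GC) and correlates each
feature with each outcome (Pearson, two-tailed) after the outlier screen.
`StudyResults.summary()` renders both tables; `run_batch` drives the same
analysis from a manifest JSON and writes TSV reports whose headers record
version, flags, seed and input checksums.

## Synthetic screens

`simulate_study` emulates a 30-target expression screen:

- Two independent random usage tables (host, target). Within each family,
  codon weights are `softmax(skew·z)` with standard-normal z; `skew = 0`
  gives exact within-family uniformity (every profile ≡ 0), the default
  `skew = 1.5` gives a mean family dominance of ~0.68, comparable to real
  organisms. Amino-acid totals are Dirichlet; sense frequencies sum to
  1000.
- Genes: uniform-random proteins of 80–500 residues (the conventional
  screen size filter), back-translated under a configurable regime —
  `frequency_sampled` (default; emulates a native gene of the target
  organism), `uniform_random`, `max_codon` (one amino acid – one codon),
  or `harmonized` (rank-matching: each position takes the host codon whose
  within-family frequency rank equals the reference codon's rank in the
  source table; ties broken by frequency then lexicographic codon order).
- Secondary structure: segment classes drawn at the 38/17/45 H/E/C
  composition typical of such screens, geometric segment lengths (mean 6).
  Long-range consistency (paired strands, domain architecture) is not
  modelled, so stratified results on synthetic data validate bookkeeping,
  not structural biology.
- Outcomes: `solubility = a + b·r + ε`, clipped to [0, 1] and converted to
  band intensities; `expression = c − d·Δ%MinMax + ε`, floored at 0.01 and
  converted to a ladder-relative intensity ratio. Defaults
  `a = 0.5, b = 0.6, σ = 0.08` and `c = 2.0, d = 0.015, σ = 0.20` were
  chosen once, at design time, so that outcomes stay in physical range and
  the planted associations have the strengths real screens of this size
  report (|r| ≈ 0.8 for solubility, ≈ 0.7 for expression); they are
  configuration, not empirical claims. The planted per-gene values are
  written to a sidecar JSON for recovery tests.

A green end-to-end test on this generator establishes that the pipeline
recovers planted linear effects at the correct sign and nominal error
rates; it says nothing about whether real solubility is linear in the
%MinMax correlation.

### A structural limit of rank-matched harmonization

On independently drawn random tables, rank-matched recoding yields a
median %MinMax correlation of ~0.8 between the recoded gene's host profile
and the native profile — high, and well above frequency re-sampling, but
not arbitrarily close to 1. The cap is structural: %MinMax is sensitive to
frequency magnitudes, and two tables generally space their within-family
frequencies differently at matched ranks. Even magnitude-aware
(nearest-relative-frequency) matching only reaches ~0.86 in the same
setting. Harmonization preserves the landscape's shape to the extent the
two organisms' within-family frequency *profiles* resemble each other.

## Numerical conventions

- Profile values are clipped to [−100, 100] to absorb rounding at the
  rails; window means use cumulative sums (agreement with a naive
  per-window loop is ~1e-12 relative).
- Pearson r is clamped to [−1, 1]; |r| = 1 reports p = 0.
- The outlier screen adds an absolute guard of `1e-10·(max|y| + range(x))`
  so exactly-linear data never self-excludes through rounding noise.
- Table round-trips through TSV preserve frequencies to better than 1e-9
  (written at 17 significant digits).
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence`; a seed fixes the generated bundle
  byte-for-byte.

## Known limitations

- mRNA folding energy, tRNA adaptation, codon-pair bias and ribosome
  kinetics are out of scope; the package quantifies codon-usage landscapes
  only.
- Secondary-structure annotations are consumed, not predicted.
- Gel densitometry is reduced to supplied intensity numbers.
- The synthetic generator's proteins are uniform-random; real amino-acid
  composition, domain structure and the covariation of codon usage with
  expression level are not emulated.
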