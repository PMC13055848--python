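# Methods

## The measurement being modeled

The pipeline analyzes a cell-type-specific proximity-labeling experiment that
profiles two membrane compartments of the same neurons in parallel: an
endosome-lumen-targeted peroxidase labels proteins transiting the
endolysosomal system (the *endocytome*), and a surface-retained peroxidase
labels the plasma-membrane-exposed proteome (the *surfaceome*). Labeled
proteins from each condition are quantified together in one isobaric-label
(TMT) experiment: three biological replicates per compartment plus two
negative-control channels (no enzyme/peroxide) that measure non-specific
background binding, eight channels in total.

Three facts about this design drive every analysis choice:

1. **Background binding is substantial.** Roughly half of detected proteins
   are cytosolic contaminants that stick to the enrichment matrix. They are
   removed ratiometrically, not by abundance.
2. **Replicates are few (n = 3 per compartment).** Per-protein variance
   estimates on 4 residual degrees of freedom are unstable, which motivates
   empirical-Bayes variance shrinkage.
3. **Both compartments label abundant proteins.** A protein's primary
   residence can only be resolved by the *relative* labeling between the two
   compartments, hence the log2(surf/endo) statistic and the top-N overlap
   analysis.

## Stage 1 — reporter-ion impurity correction

Isobaric reporter ions bleed into neighbouring channels with known isotope
impurity fractions. With the column convention used here (entry (i, j) of the
impurity matrix = fraction of channel j's true signal read in channel i), the
measured channel vector per protein is `measured = M @ true`. Correction is
the exact linear solve `true = M^{-1} measured` (implemented with a LAPACK
solve; determinant-based elimination gives the same exact answer), followed
by clamping negative components to zero, since negative ion intensities are
unphysical. Matrices with a condition-number estimate above 1e8 are rejected
rather than silently amplifying noise. The row-vs-column convention of
impurity tables varies between vendors; the column convention is asserted by
the validator (columns sum to ≤ 1, diagonal dominant per column) so a
transposed matrix is caught at load time.

## Stage 2 — experimental-to-NC ratios

For each protein, `nc_mean` is the arithmetic mean of the two negative
control channels, and each experimental channel's ratio is
`(I + c) / (nc_mean + c)` with pseudocount `c` (default 1.0 intensity unit).
The arithmetic mean was chosen over the geometric mean for symmetry and
because NC channels are expected to be on the same scale; the pseudocount
exists solely to keep ratios finite and positive at zero intensities and is
negligible at typical reporter intensities (~1e4–1e7). No between-channel
normalization is applied before ratioing. Note that isobaric quantification
is subject to ratio compression from co-isolated precursors, so fold changes
are conservative estimates of true abundance differences.

## Stage 3 — the four-step filter cascade

1. **Unique-peptide gate.** Proteins with fewer than 2 unique peptides are
   dropped; single-peptide identifications are too unreliable to carry
   quantitative conclusions.
2. **Ratiometric ROC cutoff per replicate.** Every protein is annotated TP
   (has a signal peptide and/or a transmembrane domain — i.e. it can
   plausibly reach the labeling compartments) or FP (neither — a putative
   contaminant). Within each experimental replicate, proteins are ranked by
   NC-ratio descending; after each distinct ratio value (ties processed as a
   block so the curve is well defined) the cumulative TPR and FPR are
   recorded. The chosen cutoff is the ratio maximizing TPR − FPR (the Youden
   index); on ties the earliest, i.e. most stringent, threshold wins.
   Retention is inclusive (`ratio ≥ cutoff`): the protein at the maximizing
   rank is part of the ROC point that justified the cutoff, so excluding it
   would contradict the curve's own construction. A config flag switches to
   strict retention.
3. **Replicate intersection.** Per condition, only proteins retained in all
   three replicates survive — an AND across replicates that suppresses
   single-replicate artifacts.
4. **Union across conditions.** The final filtered proteome is the union of
   the endosome and surface sets; most proteins appear in both.

The cutoff is computed per replicate channel (each replicate gets its own
ROC curve), which is the stricter reading of a per-group analysis; ratioing
against replicate-averaged intensities instead would only change borderline
retention.

## Stage 4 — moderated-t compartment enrichment

Testing operates on the log2 NC-ratios per replicate channel, so the NC
channels act as a per-protein reference and plex-wide intensity effects
cancel in the fold change. For each filtered protein with ENDO values
`a_1..a_3` and SURF values `b_1..b_3`:

- `log2fc = mean(b) − mean(a)` — positive means surface-enriched;
- `s²` = pooled residual variance on `df = n₁ + n₂ − 2 = 4` degrees of
  freedom;
- a scaled inverse-chi-square prior `(d₀, s₀²)` is fitted to all `s²` by
  moment matching on `log s²`: the mean and variance of `log s²` have
  digamma/trigamma closed forms under the model, the excess variance of
  `log s²` beyond the known `trigamma(df/2)` sampling contribution determines
  `d₀` (trigamma inverted by Newton iteration), and the mean then determines
  `s₀²`. When the excess is ≤ 0 the variances are essentially constant and
  the prior is the degenerate `d₀ = ∞`, `s₀² = ` the common variance;
- the posterior variance `s²_post = (d₀ s₀² + df s²) / (d₀ + df)` shrinks
  each protein's variance toward the prior — small variances are pulled up
  (guarding against spuriously huge t values), large ones pulled down;
- `t = log2fc / sqrt(s²_post (1/n₁ + 1/n₂))` is referred to a Student-t
  distribution on `d₀ + df` degrees of freedom (normal when `d₀ = ∞`),
  two-sided.

This construction agrees with the reference R implementation (limma's
`lmFit`/`eBayes` with a two-group design) to machine precision; the test
suite includes that cross-check. One deliberate difference: for exactly
constant input variances this package returns the constant itself as `s₀²`,
rather than the `exp(mean(log s²) − digamma(df/2) + log(df/2))` limit, which
is biased for degenerate inputs.

P-values are adjusted with Benjamini–Hochberg (step-up) by default;
raw-p thresholding is a config option since published compartment counts can
depend on which rule was applied. Calls at level α (default 0.05):
SURF_ENRICHED if `p_adj < α` and `log2fc > 0`, ENDO_ENRICHED if `log2fc < 0`,
otherwise NOT_SIGNIFICANT.

## Stage 5 — top-N TM ranking and category subsets

Per condition, transmembrane proteins are ranked by the condition-mean
NC-ratio (default) or condition-mean raw intensity — published "top N
labeled" lists rarely state the metric, so both are offered and the choice is
recorded in the run manifest. Ties break lexicographically by protein id,
making the ranking invariant to input order. The overlap between the two
top-N lists uses the first list's size as the denominator (the directional
"fraction of these also found there" reading). Category subsets (secreted,
TM, or any custom boolean annotation column) are returned ordered by
ascending log2(surf/endo), i.e. most endosome-enriched first.

## Stage 6 — multi-omic ligand–receptor integration

For each endosome-enriched secreted protein (a candidate internalized
ligand), the pipeline asks which cell class expresses its transcript and
whether its receptor is itself detected in the profiled proteome.

- **Robust expression rule.** After averaging the two developmental time
  points per cell class, a transcript is called robustly expressed when
  `frac_expressing > 0.30` (strict) and `mean_log2(CPM+1) ≥ 4.0` (inclusive).
  The asymmetry (strict fraction, inclusive level) mirrors the wording of the
  rule as usually stated; at realistic expression values nothing sits exactly
  on either boundary. The four outcomes over ORN/PN partition the genes:
  ORN_ONLY, PN_ONLY, BOTH, NEITHER.
- **"More abundant in PN"** is operationalized as: robustly expressed in PN
  *and* averaged PN mean exceeding the ORN mean. This is a display aid, not a
  statistical test, and is switchable.
- **Receptor status.** ENDO_ENRICHED (`*`) if the receptor's compartment call
  is endosome-enriched; SURF_ENRICHED if surface-enriched; DUAL (`**`) if the
  receptor is in the filtered proteome without a significant preference
  (detected by both labels); NOT_DETECTED if absent from the union set.
  Receptor ids missing from the annotation table are recorded as unmatched,
  not errors.
- A helper summarizes a raw cell × gene count matrix into the expected
  long-format table (CPM → log2(CPM+1) → per-class mean; "expressing" means
  count > 0 — a higher per-cell cutoff would only matter for ambient-RNA-
  heavy data, which the pre-summarized inputs are assumed to have handled).

## The synthetic-data generator

The generator emulates the statistical structure of the experiment, not its
chemistry. Five protein classes with fixed proportions (surface residents
20%, endosome residents 10%, dual-compartment 15%, contaminants 45%,
secreted ligands 10% — chosen so that, as in real enrichment data, about half
of detections lack both targeting signatures) receive class-determined
channel means on the log2 scale: negative controls at a base intensity
(2^16), labeled classes 8-fold above base in their home compartment's
channels and 8/4 = 2-fold above base in the other compartment, dual proteins
8-fold in all six labeled channels, contaminants flat across all eight
channels. Independent Gaussian noise (sd 0.25 log2 units, the reporter-ion
noise convention) is added per channel, adjacent-channel isotope spill (5%
per column) is applied so the correction stage has real work, and 11% of
proteins are assigned a single unique peptide, mirroring the proportion
removed by the peptide gate in typical processed data. Expression summaries
plant each ligand gene's cell-type pattern at clearly separated values
(mean 6.0 / fraction 0.60 when expressed vs 1.5 / 0.10 when not) with
jitter small enough not to cross the decision thresholds.

What the generator does *not* emulate — and therefore what passing tests do
not certify on real data: peptide-level missingness and shared peptides,
intensity-dependent variance trends, ratio compression from co-isolation,
correlated replicate batch effects, and single-cell count overdispersion
beyond what the threshold rule needs. Recovery metrics are computed over
proteins passing the unique-peptide gate: single-peptide proteins are
planted as unquantifiable by construction, so including them would only
measure the planted fraction, not the classifier.

## Numerical and degenerate-input choices

- Zero-noise data has zero residual variance, which no t-statistic survives;
  exactness checks at zero noise therefore assert the filter cascade (union =
  planted labeled set, Youden = 1 everywhere) and the fold-change signs,
  not p-values.
- The trigamma inverse uses Newton iteration from `y₀ = 0.5 + 1/x` with
  closed-form asymptotic shortcuts for extreme arguments; convergence
  tolerance 1e-8 relative.
- ROC cutoff requires at least one TP and one FP; single-class inputs raise a
  typed degenerate-input error rather than returning a meaningless curve.
- Missing intensity cells are rejected, never imputed.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds reproduce every table
  byte-for-byte.

## Problem sizes used in the checks

The bundled checks run at desk scale: 500 random ROC instances (≤ 100
proteins), 1,000 impurity-inversion vectors, G = 5,000 null proteins for
calibration, G = 50,000 variances for prior recovery (d₀ = 4 recovered within
10%, s₀² = 1 within 5%), and G = 2,000 proteins for the end-to-end run, where
compartment-call sensitivity and specificity against planted truth both
exceed 0.9 and contaminant leakage into the union stays below 5%.

## Known limitations

- The cutoff analysis assumes the TP/FP annotation is a fair proxy for
  labeling plausibility; proteins with non-canonical membrane association
  (lipid anchors) are counted as FPs and can push cutoffs up.
- With BH adjustment and many true positives, the effective raw-p threshold
  approaches α, so the false-call rate among truly unenriched proteins
  approaches α as well — specificity near (1 − α), not 1.
- Reproducing a published dataset's absolute protein counts requires that
  dataset's annotation source and significance rule; counts are sensitive to
  both, and the run manifest records the configuration for exactly this
  reason.
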