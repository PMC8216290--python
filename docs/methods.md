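# Methods

This note records the models, numerical choices and open design
decisions behind the package, and what the synthetic-data tests do and
do not establish about real data.

## Sequence contexts

The unit of analysis is the 15 nt window around a stop codon:
positions −6..−1 (last six coding nucleotides), +1..+3 (the stop
triplet) and +4..+9 (first six nucleotides of the 3′ trailer). The
internal alphabet is RNA; DNA input is converted on entry, and
ambiguity codes are rejected because the feature encoding has no
defined representation for them. GC content is the G+C fraction over
all 15 nt, computed exactly.

ORF scanning builds, for every codon position, the context that would
exist were that codon replaced by UAG. A terminal stop codon is
stripped and never used as downstream sequence (the scan enumerates
*candidate* amber sites within the coding region). Edge positions
lacking six nucleotides on a side are skipped unless UTR flanks are
supplied; flank-derived sites are marked as not frame-aligned and are
scored but excluded from synonymous optimization, since their flanks
do not lie on codon boundaries. Contexts falling into a poly-A
trailer are not filtered — no such exclusion is defined for the
model, and the training pipeline treats them like any other context.

## Enrichment preprocessing (amberome)

The training responses come from a 2×2 design: pulldown vs full
proteome, ncAA-fed synthetase line ("treated") vs control line, with
replicate-paired columns. The pipeline is:

1. **Filtering** — a protein is kept iff it has ≥ 2 (configurable)
   quantified values in at least one replicate set.
2. **Imputation** (full proteomes only) — missing values are drawn per
   sample column from N(μ − 1.8σ, (0.2σ)²), where μ, σ are the
   column's observed mean and SD: the conventional
   missing-at-low-abundance model. The pulldown branch uses observed
   values only; imputing enrichment data would manufacture signal
   where the pulldown simply failed to capture a protein.
3. **Normalization** — each pulldown replicate minus its matched
   full-proteome replicate, within each line. This cancels protein
   abundance exactly: adding any per-replicate constant to both
   members of a pair leaves the result unchanged (tested as an
   invariant).
4. **Enrichment test** — pooled-variance (classical Student's)
   two-sided t-test of normalized treated vs control replicates;
   p < 0.01 defines the enriched ("amberome") fraction, p ≥ 0.01 the
   background. Zero pooled variance is resolved by convention: equal
   means → t = 0, p = 1; unequal means → p = 0 with a flag.
   Proteins with fewer than two paired values per line after dropout
   are reported untested (NaN), not silently dropped — power
   statements in the tests are therefore made over testable proteins.

Full-proteome differential expression uses the SAM-style statistic
d = Δmean / (pooled SE + s0) with s0 = 1 and a permutation-estimated
FDR (default 0.05). The permutation null excludes the observed label
assignment and its mirror: with 3v3 replicates only 20 balanced splits
exist, and redrawing the identity split would inject the signal into
the null, inflating the FDR estimate. Fewer than 10 distinct
permutations is an error (exact enumeration would be required). The
significance threshold is the most inclusive observed |d| whose
estimated FDR (mean null exceedances per permutation / observed
exceedances) stays at or below the level.

## Regression core

The 52-entry feature layout is fixed: positions −6..−1, +4..+9 × A,C,
G,U (48 indicators), stop-codon indicators UAA/UAG/UGA, then GC.
Features are standardized with training-set mean and sample SD;
constant columns (always the three stop indicators when training is
amber-only) keep scale 1 and are flagged.

The fit solves the ridge normal equations with an *unpenalized
intercept*, jointly: on a column-centered design this is identical to
centering y, taking w = (XᵀX + k·I)⁻¹Xᵀy, and restoring the response
mean as the intercept — but the joint form also makes the closed-form
leave-one-out identity (residual / (1 − leverage), with the intercept
inside the hat matrix) agree with explicit per-fold refits to machine
precision, which is asserted in the tests. The solve uses a
symmetric positive-definite factorization, never an explicit inverse.
k = 0 on a rank-deficient design is refused, naming the dependent
columns.

Defaults: k = 10^0.3 ≈ 1.995; the LOO-CV grid is 10^p for p ∈ [−2, 2]
in 0.1 steps, ties broken toward stronger regularization. The LOO
error is reported both as the mean and the sum of squared LOO
residuals, since either normalization is in use in the field.

**Identifiability.** The indicator encoding is deliberately redundant:
each position block sums to one, and GC is itself a linear combination
of the indicators. About 16 of the 52 scaled-weight dimensions
therefore lie in the design's null space and are determined only by
the ridge penalty (which selects the minimum-norm representative).
Scores are unaffected, but *weight* comparisons must be made within
the identifiable subspace — the synthetic generator plants the
minimum-norm representative for exactly this reason (below).

The decoy control refits the identical pipeline after permuting the
responses; feature elimination iteratively removes the whole block
(position = 4 indicators, GC = 1 column) with the smallest sum of
squared coefficients, refits, and records the reduced model's LOO
error until only the stop block remains (13 removals). A score above
1.0 (strict) classifies a context as permissive.

## Logo construction

All 61⁴ = 13,845,841 flanking 12-mers whose four in-frame codons are
sense codons are scored with the stop fixed at UAG. The logo
statistic per (position, nucleotide) is the pooled-variance two-sample
two-tailed Student's t of scores with that nucleotide at that position
versus all others; positive t means enrichment among high-scoring
contexts. Group sizes are unequal by construction (sense-codon
composition), which pooled variance handles.

Two routes produce identical results: a streaming accumulator keeping
only per-cell count/sum/sum-of-squares (O(1) memory, any score
stream), and an exact closed form exploiting the additivity of the
linear model — scores decompose as const + a(upstream hexamer) +
b(downstream hexamer), so every moment reduces to sums over the 3721
sense-codon hexamers and the full 13.8M pass takes milliseconds.
Cells whose pooled variance vanishes get t = 0 by convention and are
flagged; this arises only in degenerate models (e.g. a single nonzero
weight), where the cell carrying all the signal has zero within-group
variance. Rendering (stacked letters scaled by t) is an optional
matplotlib layer; the canonical output is the TSV of t, p and n per
cell.

## Optimizer

Synonymous classes come from the standard genetic code (the method
targets mammalian nuclear genes; alternate codes are out of scope).
For a frame-aligned amber site the Cartesian product of the synonym
classes of the two codons on each side of UAG is scored exhaustively
(worst case 6⁴ = 1296 variants); every variant provably encodes the
same amino acids, which the tests verify by translation. The
recommendation threshold is a score gain ≥ 2.5, the lower end of the
empirically useful range, exposed as a flag.

## Reporter arithmetic

RRE = (mNG/mSc)amber / (mNG/mSc)wild-type, a ratio of ratios that is
exactly invariant to instrument gain. Incorporation efficiency
IE = RRE(+ncAA) − RRE(−ncAA) subtracts background readthrough by
near-cognate tRNAs and may legitimately be negative (reported, not
clipped). Fold changes between two efficiencies use the odds ratio
IEmax(1−IEmin)/(IEmin(1−IEmax)), defined only for IE ∈ (0,1). IE is
computed per replicate and then averaged (the default; the
average-RREs-first order is exposed as a flag, as the two orders
differ in general). The reported score-vs-IE R² is the squared
Pearson correlation of mean IE against model score.

## Synthetic data: what it emulates, and what it does not

* `gen_contexts` — uniform over the 61⁴ valid flanking 12-mers (each
  in-frame codon uniform over sense codons). Real transcriptomes
  have biased codon usage; uniformity is chosen to exercise the full
  feature space, not to mimic usage.
* `gen_training_table` — responses are intercept + w·(scaled
  features) + N(0, noise_sd), with the planted w projected onto the
  scaled design's row space (see *Identifiability*). Defaults used
  throughout the tests: n = 500, noise SD 0.1 on a response scale of
  roughly −3..5.
* `gen_lfq_experiment` — shared per-protein baselines (N(26, 3) on the
  log2 scale), a pulldown capture offset, i.i.d. Gaussian replicate
  noise (SD 0.3), a planted +effect_lfc shift in the treated pulldown
  only, and missingness whose cell probability decays linearly with
  abundance percentile (mean = missing_rate). Planted proteins carry
  UAG; background stops follow mammalian usage (UAA 0.30, UAG 0.23,
  UGA 0.47). Real LFQ data additionally shows peptide-level effects,
  batch structure and heavier-tailed noise — none emulated.
* `gen_reporter_table` — MFIs around nominal instrument values with
  unit-mean lognormal noise of coefficient of variation `cv`
  (multiplicative noise is the conventional model for fluorescence
  intensities).

Passing tests on these generators establishes the *estimators* —
calibration of the t-test and FDR procedure, recovery of planted
weights, correctness of the closed forms — not performance on real
proteomes, whose violations of the noise models are listed above.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: 50 random
ridge problems against a BFGS minimizer (agreement < 1e-6), LOO
identity on 15×4 problems (< 1e-8), recovery at n = 500, null
calibration at 10⁴ proteins, logo streaming checks on 10⁵ sampled
k-mers, and one exhaustive 13,845,841-context enumeration (seconds,
via the hexamer decomposition for moments and a generator for the
count). The decoy's out-of-sample R² in the acceptance script is
averaged over 10 shuffles, because a single decoy's R² is
approximately χ²₁-distributed over shuffles (heavy right tail) and a
one-draw estimate misrepresents decoy specificity.

## Known limitations

* The model is linear in single-position indicators: no interaction
  terms, no RNA secondary structure, no sequence beyond ±6 nt — about
  half the variance in measured incorporation efficiency is expected
  to remain unexplained.
* Scores transfer across PylRS/PylT-based systems and cell lines, but
  not necessarily to other orthogonal pairs, whose context preferences
  can differ.
* The logo's weighted t construction follows the stated two-sample
  form; other weighted-logo tools may differ in detail, so bit-parity
  with external logo software is not a goal.
* Selenocysteine recoding and ambiguity-code handling are out of
  scope.
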