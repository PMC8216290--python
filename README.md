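# ipass

Sequence-context scoring of amber (UAG) stop codons for non-canonical
amino-acid (ncAA) incorporation in mammalian cells.

## The problem

Genetic code expansion with an orthogonal pyrrolysyl-tRNA
synthetase/tRNA pair (PylRS/PylT) decodes an in-frame amber stop codon
as an ncAA — but how efficiently depends strongly on the nucleotides
flanking the UAG. Picking an incorporation site blind means cloning
and screening many amber mutants per protein. This package implements
**iPASS** (Identification of Permissive Amber Sites for Suppression):
a linear model that predicts the *relative* ncAA incorporation
efficiency of any UAG context from the six nucleotides on each side of
the stop codon, plus the surrounding workflow that produces its
training data and consumes its scores.

## The model

A stop-codon context covers positions −6..−1 (upstream), +1..+3 (the
stop) and +4..+9 (downstream). It is encoded as a 52-entry feature
vector **x**: 12 × 4 nucleotide indicators, 3 stop-codon indicators,
and the G+C fraction of the 15 nt window. Features are standardized
and a ridge regression is fit in closed form,

    w = (XᵀX + k·I)⁻¹ Xᵀy,      k = 10^0.3 ≈ 1.995 by default,

where **y** are normalized log2 enrichment fold changes of
endogenously amber-suppressed proteins, measured by chemoselective
pulldown of ncAA-tagged proteomes (SORT-E): pulldown abundances are
normalized per replicate against matched full proteomes, and a
pooled-variance Student's t-test (p < 0.01) defines the enriched
training set. The regularization constant can be selected by
leave-one-out cross-validation using the closed-form LOO identity. A
score is `intercept + w·x_scaled`, on the training fold-change scale;
**score > 1.0 flags a permissive site**, and a gain of **≥ 2.5 after
synonymous exchange** of the two codons on each side of UAG is the
recommendation threshold for silent-mutation optimization.

Modules: `ipass.contexts` (FASTA/context extraction, ORF scanning),
`ipass.amberome` (LFQ filtering, imputation, normalization, enrichment
and SAM-style permutation-FDR tests), `ipass.model` (encoding, ridge,
LOO-CV, decoy, feature elimination), `ipass.logo` (exhaustive
enumeration of all 61⁴ = 13,845,841 stop-free contexts and
score-weighted per-position t-value logos), `ipass.optimize`
(synonymous-codon search), `ipass.reporter` (dual-fluorescence
RRE/incorporation-efficiency arithmetic), `ipass.synth` (synthetic
data generators).

## Worked example

```python
from ipass.synth import random_planted_model, gen_training_table
from ipass.model import train_model, ipass_score, classify_permissive
from ipass.contexts import context_from_15mer
from ipass.optimize import rank_sites

# training data: contexts with enrichment responses (here synthetic)
planted = random_planted_model(seed=7, noise_sd=0.1)
contexts, y, _ = gen_training_table(planted, n=500, seed=7)
model = train_model(contexts, y)
print("k =", round(model.k, 3))                    # k = 1.995

ctx = context_from_15mer("CUAAGGUAGUCGCUG")        # -6..+9, UAG at +1..+3
s = ipass_score(model, ctx)
print(round(s, 3), classify_permissive(s))         # 5.595 permissive

table = rank_sites("AUGAAACUGAGGUCGCUGAAACCCUAA", model)
print(table.round(3).to_string(index=False))
```

prints (abridged):

```
codon_index original_codon         context  score permissive  best_score  delta
          5            UCG CUGAGGUAGCUGAAA  6.378 permissive       7.179  0.801
          3            CUG AUGAAAUAGAGGUCG  4.782 permissive       6.028  1.247
          4            AGG AAACUGUAGUCGCUG  3.146 permissive       7.072  3.926
          6            CUG AGGUCGUAGAAACCC  2.781 permissive      10.832  8.051
```

One row per codon of the ORF that can be replaced by UAG (edge codons
lacking six flanking nucleotides are skipped unless UTR flanks are
supplied). `score` is the model's prediction for the site as-is;
`best_score`/`delta` describe the best synonymous recoding of the two
codons on each side — for site 6 a silent exchange is predicted to
raise the score by 8.1, well past the ≥ 2.5 recommendation threshold.

The same workflows are exposed as a CLI:
`ipass extract | amberome | fit | score | scan | optimize | logo |
reporter | simulate` (see `ipass --help`).

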