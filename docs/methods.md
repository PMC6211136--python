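# Methods

## Data model and encodings

The analysis dataset `W = {X, y}` is assembled from a genotype matrix
(minor-allele dosages 0/1/2, missing allowed; TSV, PLINK `.raw` or
biallelic VCF) and a phenotype table (binary case status plus binary
exposures). For VCF input the minor allele is determined from the sample
allele frequencies in the file, ties oriented toward ALT. Subjects with
any missing genotype or selected exposure are removed listwise at
assembly — no imputation — matching how small candidate-gene studies are
typically analysed.

Each SNP contributes binary predictors under one of three genetic models:
recessive (1 iff two minor-allele copies), dominant (1 iff at least one),
or genotypic (two indicators, zero copies as reference). The complement of
a recessive predictor is rendered as "≥ 1 copy of the major allele" — the
dominant effect of the major allele — because that is how a complemented
recessive literal inside an interaction reads epidemiologically. The
complement of the genotypic two-copy indicator is rendered literally as
"0 or 1 copies"; no collapsing is attempted.

## Quality control

Markers are screened by (i) Hardy–Weinberg equilibrium **in controls
only** (cases may deviate through genuine association; controls should
not), default threshold p ≥ 0.001 using a 1-df chi-square goodness-of-fit
without continuity correction, with an exact conditional test (enumeration
over heterozygote counts given allele counts) available by flag;
(ii) minor-allele frequency ≥ 0.05 over all subjects; (iii) missingness,
default "any missing fails" (`max_missing = 0`) since downstream assembly
is complete-case anyway. Gene-region windowing keeps markers within ±5 kb
of supplied gene intervals (1-based closed coordinates; BED input is
converted from its 0-based half-open convention).

## Logic trees and the annealing search

Trees are capped at 8 leaves. Fitting minimises in-bag misclassification
(mean of (y − ŷ)²; no model-size penalty beyond the leaf cap) by
simulated annealing over the classical move set: alternate a leaf's
literal, toggle a leaf's complement, alternate an operator, split a leaf,
delete a leaf, grow a branch, prune a branch — chosen uniformly among the
moves legal for the current tree (growth moves are excluded at the leaf
cap; a single-leaf tree admits only leaf alternation, complement toggling
and splitting, so the tree can never become empty).

The chain starts at a random single leaf. The start temperature is
calibrated on a pilot random walk of 100 moves so that a median worsening
move would be accepted with probability ~0.5; the end temperature accepts
a median worsening move with probability 0.01; cooling is geometric. The
pilot walk is exploratory only — the chain restarts at a fresh random leaf
before annealing, since otherwise the pilot leaves it at an arbitrary
bloated state. The best-scoring tree visited is returned, preferring fewer
leaves on exact score ties, then first visited. With a fixed seed the
search is bit-reproducible.

The default budget is 25,000 iterations per tree, appropriate for
~150-predictor problems; the bundled analyses and tests pass explicit
shorter schedules (300–4,000 iterations) scaled to their much smaller
predictor counts, and permutation refits default to a short schedule
(`AnnealingSchedule.fast()`) because hundreds of forest refits multiply
any per-tree budget. During the search, predictor columns are bit-packed
into machine words (bit i = subject i), so evaluating a tree is a handful
of bitwise operations plus a popcount; the public `evaluate` is
vectorised numpy.

A tree's prime implicants are the terms of its disjunctive normal form,
obtained by recursive distribution; contradictory terms are dropped,
duplicate literals merged, and absorbed terms (supersets of another term)
removed. Implicant identity across trees is by canonical (sorted) literal
set.

## Forest, out-of-bag machinery, importance

`B` bootstrap samples of size `n` (uniform, with replacement; a draw with
an empty OOB set is redrawn) each receive one annealed tree. OOB
prediction uses the ≥ 0.5 vote-share rule over the trees for which a
subject is out of bag; subjects OOB in no tree (probability
`(1 − 1/e)^B`, negligible at practical B) are excluded from OOB metrics
with a warning. Forest OOB misclassification is the mismatch fraction over
voted subjects; per-tree OOB misclassification restricts to that tree's
OOB rows. ROC curves and AUC on OOB vote shares use the standard threshold
sweep (trapezoid AUC, tie-handling equivalent to the Mann–Whitney
statistic).

**VI2** (frequency importance) of implicant `X_j` is the fraction of trees
whose DNF contains it.

**VI1** (permutation importance) treats the implicant as a variable in its
own right: within each tree containing `X_j`, the implicant's 0/1
indicator is replaced by a randomly permuted copy over that tree's OOB
rows (the rest of the tree's DNF is untouched), the tree's OOB error is
recomputed, and the increases are summed over trees and divided by `B`.
Trees not containing the implicant are unaffected and contribute exactly
zero. An alternative reading — permuting the implicant's constituent
*columns* in the data matrix by one shared row permutation and re-scoring
every tree that uses any of them — is available
(`vi_permutation(mode="columns")`) and is the semantics used for the
per-predictor importance table, where the unit genuinely is a data column.
It is not used for implicant ranking because it makes importance
monotone-increasing under literal-set inflation: any superset of an
informative implicant inherits at least the implicant's own score plus a
positive bias from each extra column (permuting any used column in a
better-than-chance tree pushes OOB error toward 0.5), so noise supersets
would systematically outrank the clean implicant.

Reports normalise VI1 by its maximum absolute value within each table
(implicants and predictors normalised independently) — a plotting
convention for frequency-versus-importance displays, not part of
inference.

## Permutation inference

The permutation p-value of `X_j` is the proportion of forests fitted to
outcome-permuted data whose importance for `X_j` is at least the observed
value. Two null constructions are provided:

- **identity-matched** (default; the classical proportion definition):
  each permuted forest is searched for the same canonical literal set,
  contributing 0 when absent. Correct for a *pre-specified* implicant.
- **selection-adjusted** (`selection_adjusted=True`): the observed value
  is compared against the *maximum* importance over all implicants of each
  permuted forest. This is the calibrated test for an implicant chosen
  because it topped the observed ranking: the observed top is a maximum
  over hundreds of candidates, and specific multi-literal conjunctions
  essentially never recur in permuted refits, so the identity-matched p
  for a selected top implicant is severely anti-conservative under a
  global null, while the max-null version is conservative-to-uniform (the
  test suite checks this calibration on outcome-independent data).

A zero exceedance count is reported as "< 1/n_perm"; an optional
`(count+1)/(n_perm+1)` correction is off by default. No multiplicity
adjustment across implicants is applied; reports carry a note to that
effect.

## Logistic confirmation and table statistics

Each reported implicant is re-examined alone: its indicator enters a
univariate logistic regression; the odds ratio is the exponentiated
coefficient (identical to the 2×2 cross-product ratio for a binary
indicator) with Wald 95% CI and p-value. Separation or an empty cell
raises an error pointing at exact/penalised methods rather than returning
a meaningless Wald interval. Cohort-description helpers: Pearson
chi-square with Yates continuity correction (default, because it
reproduces the published cohort-table p-values; uncorrected by flag) and
two-sample t from group summaries (pooled by default, Welch by flag).

## Synthetic data generator

`make_study` emulates the target study's shape: default 204 subjects, 148
SNPs (positions spaced on one chromosome for region-selection tests), four
smoke-exposure variables and sex at the cohort's observed prevalences
(childhood passive smoke 0.34, adult passive smoke 0.19, ever smoker 0.24,
current smoker 0.15, female 0.86), genotypes in Hardy–Weinberg proportions
at MAFs drawn uniform on [0.1, 0.5], and an outcome from a logistic model
whose linear predictor holds indicator terms for planted Boolean
conjunctions over the encoded predictors. The default truth is one G × E
term — childhood passive smoke AND ≥ 1 major-allele copy of the first
SNP — at odds ratio 2.3 (the magnitude of the interaction odds ratios the
method targets), with the planted SNP's MAF at 0.45 so the recessive
genotype is common enough for the conjunction to differ from the bare
exposure, and baseline log-odds −0.26 giving ~0.49 case prevalence.
Optional LD blocks are generated by thresholding equicorrelated latent
Gaussian haplotype vectors at the MAF quantile: each SNP stays in HWE
marginally while within-block genotypes correlate. Exposures are
independent of genotypes by default.

What the generator does *not* emulate: realistic LD decay, admixture,
genotyping-array site ascertainment, exposure measurement error and
recall bias, or gene–environment dependence (available only through the
planted-term structure). Passing recovery tests on this generator
therefore demonstrates correctness of the machinery under the assumed
sampling model, not field performance on real cohorts.

## Known limitations and calibration findings

- **Weak-interaction identifiability.** A planted conjunction of an
  exposure with a *complemented* recessive literal overlaps the bare
  exposure on ~(1 − MAF²) ≥ 75% of exposed subjects. At odds ratio 2.3 and
  n = 600 the structural misclassification advantage of the conjunction
  over the bare exposure (~0.01) is comparable to its between-dataset
  sampling deviation (~0.008), so in a sizeable fraction of generated
  datasets the bare exposure is the genuinely better predictor and tops
  the importance ranking; the exact planted conjunction ranks first in
  only a minority of replicates. This mirrors the motivating use case,
  where the exposure main effect was the most important implicant and
  interactions appeared with lower frequency. Conjunctions with positive
  (rare) literals at larger effect sizes are recovered reliably
  (see `examples/03_fit_forest.py`).
- In-bag annealing overfits: junk literals that improve the bootstrap fit
  by one or two subjects attach to genuine terms, so a true conjunction is
  often found as part of a larger term rather than exactly; frequency
  importance uses exact identity and splits such credit.
- Degenerate inputs: a constant outcome yields a warning and a best-effort
  single-leaf tree; constant predictor columns are retained with a
  warning; monomorphic markers get HWE p = 1 and are removed by the MAF
  filter.
- Ties: vote share exactly 0.5 predicts "case" (the ≥ rule); equal-scoring
  trees prefer fewer leaves, then first visited.
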