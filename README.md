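# logicforest

Detection of gene–environment (G × E) interactions in case–control studies
with **Logic Forest**: a bagged ensemble of Boolean logic trees over
binary-encoded SNP and exposure predictors, with importance measures and
permutation inference for *prime implicants* — the conjunctions of
predictor literals the trees discover — followed by classical
logistic-regression confirmation.

## Who this is for

Epidemiologists and statistical geneticists analysing candidate-gene
case–control data (a few hundred subjects, on the order of 100–200 SNPs
plus binary exposures such as smoking history) who want to screen the
space of higher-order Boolean interactions rather than testing only main
effects and pre-specified two-way products. With `p` binary predictors
there are `2^p − 1` candidate main effects and interactions — over 10⁷ at
`p = 25`, ~10⁴⁵ at `p = 150` — so exhaustive regression modelling is
impossible and a stochastic search over tree-structured Boolean rules is
used instead.

## The model

Given `W = {X, y}` with `X` an `n × p` binary predictor matrix and `y` a
binary outcome, a **logic tree** `T` is a binary tree with AND/OR internal
nodes and leaves that are predictors or their complements (at most 8
leaves); a subject is predicted diseased when the expression is true. A
**Logic Forest** `LF(W, B) = {T₁, …, T_B}` fits one tree per bootstrap
sample by simulated annealing over the classical move set, minimising
misclassification. Each tree's out-of-bag (OOB) subjects give unbiased
error estimates:

- OOB prediction (per subject): vote share ≥ 0.5 over the trees for which
  the subject is OOB;
- `MC_OOB({T_b}, y, X) = (1/n) Σᵢ (yᵢ − ŷᵢ_OOB)²`, the forest OOB
  misclassification;
- `MC_OOB(T_b, y, X)`: the same restricted to tree b's OOB rows.

Writing each tree in disjunctive normal form yields its prime implicants
`X_j`. Two importance measures are computed for every `X_j` found in the
forest:

- `VI1(X_j) = (1/B) Σ_b [MC_OOB(T_b, y, X^j) − MC_OOB(T_b, y, X)]`, where
  `X^j` permutes the implicant (see `docs/methods.md` for the exact
  permutation semantics); ranges −1 to 1, positive values indicating
  association with the outcome;
- `VI2(X_j) = (1/B) Σ_b I(X_j ∈ T_b)`, the fraction of trees containing it.

Permutation p-values come from refitting forests to outcome-permuted data:
the p-value of `X_j` is the proportion of permuted-outcome forests whose
importance for `X_j` is at least the observed one. Identified effects are
then confirmed one at a time by univariate logistic regression on the
implicant's 0/1 indicator (odds ratio, Wald 95% CI).

SNP dosages (minor-allele copies 0/1/2) enter as binary predictors under
the **recessive** (1 iff 2 copies), **dominant** (1 iff ≥ 1 copy) or
**genotypic** (two indicators, 0 copies as reference) model; markers are
first screened by Hardy–Weinberg equilibrium in controls (p ≥ 0.001), MAF
≥ 0.05 and missingness.

## Worked example

```python
import math
import logicforest as lf

cfg = lf.SimulationConfig(
    n_subjects=400, n_snps=20, seed=11,
    truth=[lf.TruthTerm((("psc", False), ("snp001_R", False)), math.log(6.0))],
    baseline_log_odds=-0.8,
)
gm, ph, manifest = lf.make_study(cfg)          # synthetic cohort
W = lf.assemble_dataset(gm, ph, scheme="recessive")

model = lf.fit_forest(W, B=60, schedule=lf.AnnealingSchedule(n_iter=2000), rng=1)
records, _ = lf.aggregate(model, W, rng=2, n_reps=5)
for r in records[:2]:
    print(f"VI1={r.vi1:+.4f} VI2={r.vi2:.2f} {r.prime_implicant.render(W.descriptors)}")
```

prints (from `examples/03_fit_forest.py`):

```
B=60 trees, OOB misclassification 0.360, OOB AUC 0.449
  VI1=+0.0021  VI2=0.08  trees=  5  2 copies of the minor allele of snp001 & psc  <- planted
  VI1=+0.0017  VI2=0.07  trees=  4  2 copies of the minor allele of snp006 & ever_smoker
```

The top prime implicant is exactly the planted G × E conjunction: subjects
with childhood passive-smoke exposure *and* two minor-allele copies at the
first SNP. VI1 is the average OOB error increase when that conjunction's
indicator is permuted in the trees containing it; VI2 says it appeared in
8% of trees. The low AUC is expected — most subjects carry no risk term,
so discrimination is weak even when the interaction is real, which is why
implicant-level importance rather than overall accuracy is the discovery
signal.

The `examples/` directory walks through each capability (simulation, QC,
forest fitting, permutation p-values, logistic confirmation); a thin CLI
(`logicforest simulate|qc|fit|permtest|confirm|run-all`) wraps the same
functions for shell use.

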