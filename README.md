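# idstrat — age-stratified inbreeding depression from pedigreed genotype data

Inbreeding depression (ID) is the decline in trait value per unit increase in
the inbreeding coefficient *F*.  Not all inbreeding is equal: a
homozygous-by-descent (HBD) segment inherited from an ancestor one or two
generations back is long and potentially loaded with young deleterious
variants, while a short segment tracing to an ancestor fifty generations back
has survived many rounds of purifying selection.  `idstrat` implements a
pipeline for asking whether recent and ancient inbreeding depress a
quantitative trait differently in a pedigreed livestock-style population —
and, just as importantly, for quantifying when the data simply cannot tell.

## What it computes

**Six inbreeding coefficients.**  F_PED (Meuwissen–Luo pedigree recursion),
F_HET (excess homozygosity), F_UNI (correlation of uniting gametes), F_GRM-1
and F_GRM-2 (VanRaden genomic-relationship diagonal, ratio-of-sums and
mean-of-ratios rules), and F_HBD from a hidden Markov model.

**The multi-class HBD HMM.**  The genome is a mosaic of HBD and non-HBD
segments.  In HBD class *c* segment lengths are exponential with rate R_c per
Morgan, so each class collects ancestors roughly 0.5·R_c generations back.
The default ladder is nine classes, R_c = {2, 4, …, 512}, plus one non-HBD
class (an 11-class ladder up to 2048 is provided for high-density data).
Per-individual mixing proportions are fitted by Baum–Welch EM with rates held
fixed; F_HBD sums the posterior genome fractions of classes with R_c ≤ 256.

**Base-population allele frequencies.**  Genomic estimators need the allele
frequencies of the pedigree's founder generation, not the drifted
current-sample values.  These are estimated marker by marker with the
gene-content mixed model z = 1μ + Wu + e, var(u) = Aσ²ᵤ, solved by
pedigree-BLUP at h² = 0.99 (founder frequency = μ/2).

**REML mixed models for ID.**  The single-F model
y_i = μ + u_i + b·F_i + e_i with u ~ N(0, G σ²_g), where G matches the fitted
estimator (pedigree **A** for F_PED, VanRaden 1 for F_UNI/F_GRM-1, VanRaden 2
for F_GRM-2, and the AF = 0.5 similarity matrix for F_HET/F_HBD); and the
stratified model y_i = μ + u_i + Σ_c b_c·F_HBD-c,i + e_i fitting all eight
R_c ≤ 256 classes at once.  Wald tests are screened at the Bonferroni
threshold 0.05/66 ≈ 7.6e-4.

**Truth-labelled simulation.**  A gene-drop simulator produces a pedigreed
population (default: 100 founders, 20 generations, breeding population
shrinking to 30, ~1,000 genotyped individuals over four birth-year cohorts)
with every HBD tract labelled by the generation of its common-ancestor
haplotype, drifted allele frequencies, and phenotypes with configurable
per-class depression — so every stage can be checked against known truth.

## Worked example

```
python analysis/01_simulate.py 1
python analysis/02_founder_af.py
python analysis/03_hbd_decode.py
python analysis/04_inbreeding_estimators.py
python analysis/05_fit_inbreeding_depression.py 1
python analysis/06_power_study.py 1
```

The drivers write their tables under `results/` and narrate what they found.
On the default scenario (seed 1) the run prints, among other things:

```
MAE vs true founder AF: gene-content BLUP 0.1020 vs sample AF 0.1065
corr(F_HBD founder AF, F_HBD sample AF) = 0.9999
cross-source correlation per estimator (founder vs sample AF):
  f_het   1.000
  f_uni   0.968
  f_grm1  0.898
  f_grm2  0.701
  f_hbd   1.000
```

— the pedigree-BLUP founder frequencies beat the drifted sample frequencies,
and the estimators split into an AF-robust group (F_HET, F_HBD) and an
AF-sensitive group ordered F_UNI > F_GRM-1 > F_GRM-2, the pattern that
decides which estimator to trust when base-population frequencies are
unavailable.  The single-F fits recover the simulated depression of −21
trait units per unit F with every estimator (e.g. `f_hbd  effect −24.4
se 1.9`, `f_grm1  effect −20.7  se 1.7`, all p far below 7.6e-4), and the
power study exposes the variation–power link across HBD age classes:

```
     class  mean_effect  detection_rate  f_class_sd
  f_hbd_R2        -20.4            1.00      0.0343
  f_hbd_R8        -20.7            1.00      0.0443
 f_hbd_R32        -20.9            0.82      0.0192
 f_hbd_R64        -24.0            0.12      0.0045
f_hbd_R128        -27.5            0.04      0.0008
rank corr(detection rate, class sd) = 0.94
null study pooled detection at alpha=0.05: 0.040
```

A constant −21 effect is detected essentially always in the variable recent
classes and almost never in the ancient ones — so a non-significant ancient
class in real data is weak evidence of absence, which is the study's central
methodological point.

## Layout

```
src/idstrat/        library: data_io, simulate, founder_af, estimators,
                    hbd, mixed_model, experiments
analysis/           numbered drivers reproducing the study, step by step
tests/              pytest suite, including end-to-end scientific checks
docs/methods.md     model and design notes
```
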