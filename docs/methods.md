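# Methods

## The question and the overall design

When inbreeding depression (ID) is regressed on a single inbreeding
coefficient, all homozygosity is treated as equivalent.  This package
implements the stratified alternative: partition an individual's genome into
homozygous-by-descent (HBD) classes indexed by the age of the common
ancestor, and fit one depression coefficient per class.  Because the answer
is hostage to two statistical artefacts — ancient classes vary little across
individuals, and their short segments are estimated less accurately — the
pipeline is built around a truth-labelled simulation that measures exactly
those artefacts.

## Multi-class HBD hidden Markov model

States: K HBD classes plus one non-HBD class.  Segment lengths in class c
are exponential with rate R_c per Morgan (expected length 1/R_c), so class c
collects ancestors roughly 0.5·R_c generations back.  Default ladder
R_c = {2, 4, …, 512} (K = 9); a high-density ladder {2, …, 2048} (K = 11) is
provided for dense marker panels that can resolve shorter segments.  The
non-HBD state shares the rate of the fastest HBD class, which saves one free
parameter; this convention is exposed in `HBDModelSpec`.

Transitions over a gap of d Morgan:
T[c → c'] = e^(−R_c·d)·1[c = c'] + (1 − e^(−R_c·d))·M_c', where M is the
individual's mixing distribution over the K+1 states; M is also the initial
distribution at chromosome starts (stationarity of the exit process).
Chromosomes are independent; log-likelihoods add.

Emissions at a marker with allele frequency p and genotyping-error rate ε:
inside HBD, P(hom A1) = (1−ε)p + εp², P(het) = ε·2p(1−p),
P(hom A2) = (1−ε)(1−p) + ε(1−p)²; outside HBD, Hardy–Weinberg.  Missing
genotypes emit likelihood 1 in every state.  ε defaults to 0.0025, a typical
genotyping-array error rate; it bounds how strongly a single heterozygote
can break an HBD segment.

Fitting: rates are fixed; only M is estimated, per individual, by
Baum–Welch.  The M-update counts expected class entries (chromosome-start
occupancies plus post-exit re-entries), which is exact EM on the augmented
chain with an explicit exit indicator, so the log-likelihood is
non-decreasing — asserted numerically in the tests.  Each individual's EM is
independent, so individuals are frozen once their log-likelihood gain falls
below tolerance.  The summaries are the unweighted mean posterior per class
over markers (F_HBD-c) and their sum over classes with R_c ≤ 256 (F_HBD);
the last class is excluded from the aggregate because with few markers per
segment it behaves like a single-site estimator.  A Morgan-length-weighted
variant of the genome fraction is not provided; with the near-uniform maps
used here the two coincide.

This is the single-level mixture formulation (one chain over K+1 states with
exit-to-mixing transitions).  A nested formulation exists in which classes
are peeled off as successive layers of ancestor generations; the two
parameterisations differ in how transition probabilities between HBD classes
are structured but produce the same per-class genome-fraction summaries,
which are the only quantities consumed downstream.  This is the package's
main fidelity caveat relative to layered implementations: per-class
posteriors can differ in the third decimal.

Numerics: per-marker scaling controls underflow and recovers the exact
log-likelihood from the scale accumulators; the forward–backward runs in a
compiled (numba) kernel over all individuals of a chromosome, with a
pure-numpy reference compared to it in the tests, and the whole recursion is
checked against brute-force path enumeration on small fixtures (1e-10).
Convergence in the analysis drivers uses tol 1e-4 on the per-individual
log-likelihood gain with a 200-iteration cap: the aggregate F_HBD is stable
to < 0.007 long before that, while the split of mass between adjacent rate
classes (a weakly identified direction of the likelihood) is what moves
last.

## Inbreeding estimators

- F_PED: Meuwissen–Luo recursion (founders F = 0; an individual with an
  unknown parent cannot be inbred).  Verified against the tabular
  relationship matrix and against Monte-Carlo single-locus gene drop.
- F_HET = (O_hom − E_hom)/(L − E_hom) with E_hom = Σ(1 − 2p(1−p)).
- F_UNI = mean of [x² − (1+2p)x + 2p²]/(2p(1−p)).
- F_GRM-1 = Σ(x−2p)² / Σ2p(1−p) − 1 (ratio of sums);
  F_GRM-2 = mean (x−2p)²/(2p(1−p)) − 1 (mean of ratios).
- F_HBD: from the HMM above.

Missing-data rule: per-individual denominators over non-missing markers for
every per-individual estimator; mean-imputation at 2p is used only when
building relationship matrices, never for per-individual F.  All
AF-dependent estimators take an explicit allele-frequency source so the
founder-vs-sample comparison is a first-class analysis.

Relationship matrices for the mixed model follow the estimator:
pedigree A (tabular method) for F_PED, VanRaden 1 for F_UNI and F_GRM-1,
VanRaden 2 for F_GRM-2, and the similarity matrix obtained by setting all
allele frequencies to 0.5 for F_HET and F_HBD.  The AF = 0.5 similarity
matrix is implemented as VanRaden 1 evaluated at p = 0.5 (rule 2 coincides
at constant p, so one code path suffices).

## Founder allele frequencies by gene-content BLUP

Gene content z (dosage 0/1/2) at one marker is modelled as
z = 1μ + Wu + e with var(u) = Aσ²ᵤ over the whole pedigree and
λ = (1−h²)/h² fixed by h² = 0.99, a value that lets e absorb genotyping
errors rather than being estimated.  A⁻¹ is assembled directly by the
Henderson/Quaas rules with the inbreeding correction (Mendelian sampling
variance d_i = 0.5 − 0.25(F_s + F_d), 0.75 − 0.25F for one known parent,
1 for founders).  With complete genotyping the mixed-model-equation
coefficient matrix is the same for every marker, so it is LU-factorised once
and reused for all right-hand sides; markers with missing calls are grouped
by missingness pattern.  The founder frequency is μ/2, clamped to [0,1], and
markers whose estimated minor-allele frequency falls below 0.01 are flagged
for removal — the founder estimate is used for this refilter, since it is
the quantity being estimated.

A note on the λ → 0 limit: with everyone genotyped, μ tends to the
A⁻¹-weighted GLS mean of gene content, (1'A⁻¹z)/(1'A⁻¹1), which is the
base-generation mean — not the simple sample mean unless the pedigree is
founders-only.  The tests assert the exact limit.

## REML mixed models

y = Xβ + u + e, u ~ N(0, Gσ²_g), e ~ N(0, Iσ²_e).  After an
eigendecomposition G = UΛU', the rotated model has diagonal covariance
σ²_p(h²Λ + (1−h²)I), and the REML log-likelihood profiles down to a 1-D
function of h² maximised by bounded scalar search on [0, 1−1e-6].  This is
exact for a single relationship matrix, derivative-free, and fast enough
that replicated studies reuse one eigendecomposition (`REMLWorkspace`)
across hundreds of refits.  Fixed effects are GLS at the optimum; standard
errors come from the inverse weighted normal equations; p-values use the
two-sided normal (Wald) approximation.  Indefinite G gets a 1e-6 ridge.
Rank-deficient designs raise an error naming the aliased columns; in the
stratified model, class columns with variance below 1e-12 (or collinear with
earlier columns) are dropped and reported, never imputed — a class without
variation is inestimable and must be visible as such.

The fixed-effect structure is intercept + inbreeding term(s) only: the
phenotypes the models are meant for are pre-corrected trait deviations.

Bonferroni screening: 0.05/66 = 7.576e-4, reported at two significant
figures (7.6e-4) alongside full precision.  The per-class detection rate in
the power study uses plain α = 0.05; the Bonferroni threshold belongs to the
trait-by-estimator screen.

## Gene-drop simulation and what it does (not) emulate

Founder haplotypes are drawn site-wise from a uniform(0.05, 0.95) allele
frequency spectrum — no linkage disequilibrium among founders.  Meioses
place crossovers by a Poisson process at 1 per Morgan (Haldane, no
interference), matching the exponential segment-length assumption of the
HMM.  Every haplotype records the mosaic of immediate-parent haplotype
copies it was spliced from; the age g of each HBD tract is recovered by
lifting both of an individual's haplotype lineages one generation at a time
and recording where they first pass through the same ancestral haplotype
copy.  Tracts of meeting generation g have mean length ≈ 1/(2g) Morgan
(verified by Kolmogorov–Smirnov on designed pedigrees), the age–length
relation the HMM exploits with R_c ≈ 2g.  For comparisons with the HMM, a
tract is assigned to the class whose 0.5·R_c is nearest its g.

Default scenario: 100 founders; 20 discrete generations of random mating;
the breeding population shrinks linearly to 30 over the last 10 generations;
the last 4 generations additionally produce surplus offspring so the
genotyped cohort reaches ~1,000 individuals across four birth years.  This
produces coexisting recent and ancient HBD, accumulating inbreeding by birth
year, and substantial drift between founder and sample allele frequencies —
the three phenomena the analysis is about.  5 chromosomes of 1 Morgan carry
6,000 evenly spaced markers (1,200 per chromosome, one per 0.083 cM-scale
unit); genotyping errors replace a call with a Hardy–Weinberg draw at rate
0.001.

Phenotypes: per-marker allelic effects are standard normal; the polygenic
score (dosage-weighted sum) is centred and rescaled to h²·Var_P exactly, the
residual to (1−h²)·Var_P, and the inbreeding term adds b·F (or Σ b_c·F_c).
Defaults h² = 0.35, Var_P = 16 describe a moderately heritable
conformation-type trait; they are configurable assumptions, recorded in the
run manifest, not estimates.  The depression default of −21 trait units per
unit F is a strongly depressive effect on that scale.

What the simulation does not emulate: founder linkage disequilibrium (an
optional coalescent founder model is out of scope), interference, selection,
overlapping generations, dominance-based ID (depression enters through F
directly, not through directional dominance at loci).  Consequently, passing
tests show that the estimators and models behave correctly under the
population-genetic structure they assume; they do not certify performance
under strong LD or selection.

## Scale of the shipped experiments

The default analysis and the acceptance script run the ~1,000-individual,
6,000-marker scenario: large enough that each HBD class with rate ≤ 64 holds
measurable variation, small enough that the full pipeline (two HMM decodes,
six REML fits, two 100-replicate power studies) completes in minutes on one
CPU.  Replicate seeds derive from the master seed by a counter-based hash,
so any single replicate can be recomputed standalone and replicate sets can
be split across processes without changing results.

## Known limitations

- The mixture (non-layered) HBD parameterisation, as discussed above.
- Wald p-values are asymptotic; at a few hundred individuals they are mildly
  anticonservative (the null-calibration test bounds this at the 5% level).
- The gene-content model fixes h² = 0.99 rather than estimating the
  genotyping-error variance.
- Sequence-data emissions (allele counts), Viterbi segment coordinates and
  the estimated-rate one-class model are out of scope; posterior genome
  fractions are sufficient for every downstream use here.
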