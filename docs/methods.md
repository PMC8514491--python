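# Methods

`aquagp` implements the genetic-evaluation workflow used in
family-structured aquaculture breeding: marker-based pedigree
reconstruction, heritability and breeding-value estimation under
genomic (GBLUP) and pedigree (PBLUP) kernels, and an assessment of how
SNP-panel density degrades each statistic.  Every stage is exercised on
a synthetic breeding population whose generator is itself first-class,
tested code.

## The simulated breeding design

The generator emulates a two-generation design typical of marine
finfish breeding programs: a small broodstock with hidden internal
relatedness, mated factorially into many full-sib families.

**Founders.** 28 broodstock fish (9 dams, 19 sires) organised as six
full-sib families (five of four fish, one of three), two half-sib
pairs, and one lone female.  Founder relatedness is genuine, not
labelled: per SNP an ancestral allele frequency is drawn uniformly on
(`maf_low`, `maf_high`) = (0.01, 0.4); unobserved grandparents are
sampled in linkage equilibrium at those frequencies and founder groups
are produced from them by Mendelian transmission with recombination.
The grandparents are discarded, so founders carry unknown parents but
real identical-by-descent sharing.  The lone female is simulated
unrelated; a weak (third-degree) link between the lone female and a half-sib
pair can occur in real broodstock but is not modelled.

**Genome.** 22 chromosomes of 100 cM (the fugu karyotype motivates the
count), ~4075 SNPs spread evenly along a nominal genetic map.  Meiosis
draws a Poisson crossover count per chromosome (Haldane model, no
interference) with uniform crossover positions.  Linkage is essential:
with independent loci the Mendelian-sampling variance among full sibs
— exactly what separates GBLUP from PBLUP — would vanish.

**Matings.** 129 distinct (dam, sire) pairs drawn without replacement
from the 9 x 19 grid; 712 offspring; every family receives at least one
offspring and the remainder is multinomial with uniform weights;
real hatcheries have skewed family sizes, so the distribution is a
configurable knob.  Offspring sex is 1:1.

**Traits.** Additive polygenic traits `y = mu + Zu + e` with i.i.d.
normal SNP effects on a configurable causal subset (default: all SNPs).
Residual variance is set from the realized variance of the true
breeding values so that `var(TBV)/var(y)` equals the configured h2 in
expectation.  Defaults mirror the three harvest traits of the emulated design:
standard length (h2 = 0.538), body weight (0.557) and testes weight
(0.686, recorded in males only); `record_fraction` thins the recorded
set (0.976 for body size, 0.69 of males for testes weight) so the
phenotyped counts come out at ~695 and ~246 of 712.  An optional
per-trait `common_env` fraction adds a full-sib common-environment
effect; it defaults to 0 and exists to express the confounding that
inflates pedigree-based heritability estimates.

**Genotyping noise.** Each call independently drops out with
`missing_rate` = 0.05 and each surviving call is replaced by one of the
other two dosages with `genotype_error_rate` = 0.005 — plausible
amplicon-panel data quality, chosen once; a 60% call-rate filter only
makes sense when missingness is nontrivial.

All randomness flows from one root seed through named substreams
(founders / meiosis / traits / noise / subsets / CV folds), so any
stage is reproducible in isolation and a change in one stage's draw
count cannot perturb another.

**What the generator does not emulate:** genotype-by-environment
effects, non-additive gene action, selection or mutation across
generations, assay-level missingness structure (missingness is uniform,
so the call-rate filter is quiet on synthetic defaults), linkage
disequilibrium between founder lineages beyond what the shallow
grandparent pedigree induces, and real minor-allele-frequency spectra.
Passing tests therefore demonstrate correctness of the estimators under
an additive, randomly-mating, linkage-equilibrium-founder world — not
robustness to the full messiness of field data.

## Quality control

Biallelic SNPs are kept when the minor allele frequency lies strictly
inside (0.01, 0.4) *within each generation* (computed once on
non-missing calls, before any call-rate filtering), then a >= 60%
call-rate filter is applied to the parental generation, survivors are
extracted from the offspring generation, and the call-rate filter is
applied there.  Removal categories are mutually exclusive with
precedence (absent-in-a-generation, MAF-low, MAF-high, F0 call rate, F1
call rate) and always sum to the input count.  The 0.4 upper MAF bound
is unusual but implemented verbatim; it likely reflects panel design.

## LD-kNNi imputation

For a missing call (individual *i*, site *s*): sites are ranked by
squared dosage correlation with *s* over pairwise-complete
observations; over the top `l` = 30 sites the Manhattan distance
(ignoring coordinates missing in either individual, +1 pseudo-count)
from *i* to every individual observed at *s* is computed; among the
`k` = 5 nearest, the dosage maximising the summed inverse distance of
its carriers is imputed.  `l` and `k` are the standard LD-kNNi
defaults; r2 is computed on dosages (no phasing exists).  Dosage ties
resolve toward the smaller dosage (deterministic).  Observed calls are
never modified.

## Relationship matrices and kinship

* **G** (VanRaden method 1): `G = ZZ'/c`, dosages centered at twice the
  sample allele frequency, `c = 2 sum p(1-p)`; monomorphic columns drop
  out of numerator and denominator.  No shrinkage, no internal MAF
  masking (QC already bounds MAF).  Because allele frequencies are
  estimated from the sample itself, all entries are shifted down by the
  mean sample relatedness; contrasts between pair classes are
  unaffected (and are what the tests assert).
* **A**: tabular recursion `a_ii = 1 + 0.5 a(sire,dam)`,
  `a_ij = 0.5(a_j,sire + a_j,dam)` in topological order; founders
  unrelated and non-inbred unless prior pairwise values are injected
  (off by default — the inferred-pedigree BLUP treats broodstock as
  unrelated founders).
* **KING-robust kinship** from heterozygote and opposite-homozygote
  counts over co-observed sites, with degree bands closed below:
  duplicate >= 0.354, 1st >= 0.177, 2nd >= 0.0884, 3rd >= 0.0442.  A
  pair without heterozygous sites yields an explicit "undefined" flag.
* **Mantel test**: Pearson correlation of strictly-lower-triangle
  entries (similarities, not distances), significance by simultaneous
  row/column permutation with the add-one convention (999 permutations
  by default; the density experiment uses 99 since only r is consumed).

## Admixture model and pedigree reconstruction

Genotypes are modelled as Binomial(2, QF) with ancestry proportions Q
(simplex rows) and cluster allele frequencies F in [10^-6, 1-10^-6].
The likelihood is maximised by EM (simultaneous Q/F updates from one
E-step); ancestry-inference software usually optimises this objective by block
relaxation; plain EM is used here deliberately — same objective,
simpler, adequate at desk scale.
Initialisation options:

* `random` — Dirichlet rows and uniform frequencies (with restarts);
* `kmeans` — cluster individuals in a low-rank genotype space and seed
  F from within-cluster frequencies;
* `anchored` — seed one cluster per designated individual.  The
  intended anchors are the broodstock: their *sample identity* is known
  in this design even though their pedigree is not.  Unsupervised fits
  at K ~ 34 are prone to local optima in which clusters capture whole
  families rather than single parental genomes; anchoring removes that
  failure mode without using any pedigree truth.

K is selected by entry-wise masked cross-validation (entries held out,
EM run with observation weights, held-out error = mean squared
deviation of the dosage from 2QF), mirroring the entry-wise CV
semantics of standard ancestry software.

Each offspring is assigned to the (dam, sire) pair whose ancestry
midpoint `(q_d + q_s)/2` is nearest its own Q row (Euclidean); matching offspring to parents by shared ancestry components ("K
axes") is usually done by eye; the midpoint distance is this
package's numeric formalisation.  An assignment is ambiguous when the runner-up is within
`gap_threshold` = 0.05.  Unambiguous assignments plus single-linkage
sib-grouping of the parents (1st-degree calls) assemble the pedigree;
ambiguous offspring are excluded and reported.

## REML and BLUP

The mixed model is `y = mu + Za + e`, `a ~ N(0, K sigma_a^2)`, with the
intercept as the only fixed effect.  After one eigendecomposition of
the kernel restricted to recorded individuals, the restricted
likelihood is profiled over `delta = sigma_e^2/sigma_a^2` on a 61-point
grid over log delta in [-10, 10], refined by bounded scalar
minimisation to 1e-8; each evaluation is O(n).  Kernels with minimum
eigenvalue in (-1e-4, 1e-8) are repaired by adding epsilon to the
spectrum (logged); worse deficits raise.  `h2 =
sigma_a^2/(sigma_a^2+sigma_e^2)`; boundary solutions are flagged, not
clamped.  Breeding values for every kernel individual come from the
cross-block: `a_hat = K[:,obs](K_oo + delta I)^{-1}(y - mu)`.

Cross-validation re-estimates variance components inside every training
fold (the conservative reading of a masked-validation protocol).
Predictive ability is the Pearson correlation between observed
phenotypes and validation predictions pooled across the rotating folds
of one replicate; accuracy divides by the square root of the full-data
h2 for the *same kernel and SNP set*.  Using each subset's own h2
reproduces the accuracy-inflation artifact at low density (h2 collapses
faster than ability, so their ratio rises).  A known small-sample
artifact: under a null phenotype, pooled CV predictions correlate
slightly negatively with observations (fold-mean coupling through the
sample-centered G); it is negligible from a few hundred records.

## Density experiment

Random SNP subsets (default sizes 200-4000, ten replicates each,
uniform without replacement, independent per size x replicate) are
re-analysed end to end: GRM, h2, replicated 10-fold CV, GEBV
correlation against the full panel (over all kernel individuals;
offspring-only is a flag), family-mean GEBV correlation (families =
identical dam-sire pair), and Mantel r of the subset GRM against the
full-panel GRM.  Mean, SD and SE per size are emitted.

## Problem sizes in the shipped checks

The test-suite and acceptance-script runs use the study-scale design
(28 founders, 129 families, 712 offspring, ~4-5k SNPs) with scaled-down
replication: four subset sizes x three replicates, two to three CV
replicates, and ten simulation seeds for parameter-recovery and
model-contrast checks.  Two property choices deserve note: the
full-sib-GRM check asserts the full-sib vs parent-disjoint *contrast*
(robust to sample-frequency centering), and the PBLUP-inflation check
uses 50 families of ~14 offspring with h2 = 0.3 and common-environment
fraction 0.3 — with the default ~5.5-offspring sibships the inflation
exists but is swamped by REML sampling noise, so the test uses a design
where the mechanism has statistical power.

## Known limitations

* The EM optimiser is first-order; at large K it needs the anchored or
  k-means initialisation to reach the parent-per-cluster optimum that
  block-relaxation software finds more reliably.
* PLINK binary formats are not read; VCF and 012 TSV are the contract.
* Half-missing diploid calls are collapsed to fully missing; phasing,
  reference-panel imputation and genotype likelihoods are out of scope.
* The pedigree BLUP uses the inferred pedigree with founder-unrelated
  A; injecting inferred founder kinship into A is available but off by
  default.
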