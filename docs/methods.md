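# Methods

## The admixture model and its estimation

The package implements the classic admixture likelihood for unphased
biallelic genotypes: individual *i* has ancestry proportions
q<sub>i</sub> on the K-simplex, population *k* has allele frequencies
p<sub>kl</sub>, and each genotype is Binomial(2, Σ<sub>k</sub>
q<sub>ik</sub>p<sub>kl</sub>), independent across loci. The no-linkage
assumption is deliberate: structure inference runs on an LD-pruned SNP
panel, where it is a good approximation.

Estimation is EM over the latent ancestry of each allele copy. With
frequencies fixed (supervised mode) the problem separates by individual;
with both blocks free (unsupervised mode) Q and P are updated jointly
from the same responsibilities, which is a valid generalized EM step and
keeps the log-likelihood monotone. Both estimators wrap the plain
iteration in a SQUAREM-style extrapolation: two base EM steps, a
step-length extrapolation along the observed trajectory, one stabilizing
EM step, and a safeguard that keeps the extrapolated point only if the
log-likelihood did not fall below the plain two-step value. The safeguard
preserves the monotonicity guarantee (asserted by tests against the plain
iteration, available as `accelerate=False`) while cutting iteration
counts by an order of magnitude. The supervised fit warm-starts from a
least-squares projection of mean dosage onto the panel frequencies,
clipped onto the simplex.

Numerical choices: frequencies clipped to [1e-6, 1-1e-6]; supervised
stopping rule max|ΔQ| < 1e-6 (up to 2,000 iterations); unsupervised
stopping on log-likelihood improvement (1e-4 default; the ΔK scan uses
0.5, since ΔK consumes likelihood differences thousands of units wide);
unsupervised restarts initialize Q ~ Dirichlet(1) and P as observed
frequencies plus noise. Identical reference rows make Q unidentifiable;
the supervised estimator then returns the uniform vector and a flag
rather than an arbitrary vertex. Missing calls carry zero weight
everywhere.

Replicate runs are aligned before averaging by maximizing column-wise
agreement with the first run — exhaustive over permutations for K ≤ 6,
Hungarian assignment beyond. The Evanno table uses the per-run second
difference L″(K) = L<sub>r</sub>(K+1) − 2L<sub>r</sub>(K) +
L<sub>r</sub>(K−1), pairing run r across K by its restart seed, and
ΔK = mean|L″| / sd[L(K)]. ΔK at boundary K, at non-consecutive K, or
with zero run-to-run SD is flagged undefined rather than guessed.

## PCA and stratification

Genotype PCA centers each SNP at its mean call and scales by
√(p(1−p)) with p the observed allele frequency (the EIGENSTRAT-lineage
normalization; plain standardization is available behind a flag). Missing
calls are mean-imputed before scaling, monomorphic SNPs are dropped, and
projections carry a deterministic sign convention (largest-magnitude
coordinate positive). Variance explained is reported over the full
retained spectrum; its value is data-dependent and not a fixed target.
Outlier-removal iterations are not applied.

The stratification experiment reproduces the confounded-phenotype design:
sample a fixed number of subjects per ancestry subgroup, define cases by
the homozygous genotype at an ancestry-informative marker (AIM), scan all
other SNPs with an additive 1-df test, and compare the genomic-control
inflation factor λ = median(statistic)/0.4549 before and after adding the
top-two eigenvectors (computed on the sampled set's pruned structure
SNPs) as covariates. Without covariates the statistic is the
Cochran–Armitage trend chi-square (equal to N·r²); with covariates it is
the Wald chi-square on the genotype term of a per-SNP logistic
regression, solved by a batch Newton iteration since all SNPs share the
covariate block, with a covariate-adjusted score-test fallback wherever a
fit separates or diverges. The AIM is excluded from the scan: it defines
the phenotype, and keeping it would plant a guaranteed self-association
in λ.

Subgroup assignment fits a two-component Gaussian mixture to the chosen
ancestry coefficient; if the components are not separated (or the
coefficient is constant) the data are flagged unimodal and the median is
used as the threshold.

## LD statistics

D′ comes from the standard two-locus haplotype EM on unphased genotypes
(only the double heterozygote is phase-ambiguous), and its confidence
interval from the normalized likelihood profiled over a 101-point |D′|
grid with allele frequencies held at their estimates — deterministic, in
the style of the Haploview implementation. Blocks follow the Gabriel
rule with the Haploview defaults: strong LD when CI ∈ [0.70, 1] with
upper bound ≥ 0.98, strong recombination when the upper bound < 0.90, a
block when ≥ 95% of informative pairs are strong LD; candidates are
accepted longest-first with a 500 kb span cap, and the bounding pair must
itself be strong LD. Tag-SNP selection is greedy maximum-coverage binning
(genotype r² ≥ threshold within 500 kb), ties broken by lower position
then id; bins partition the panel and are audited post-hoc. Genotype r²
is the composite (unphased) correlation throughout — the pruning filter
and the tagger only need background-LD suppression, and the composite
measure is deterministic and phase-free.

## The synthetic generator

The generator is the package's substitute for the non-redistributable
study genotypes; its defaults are the study conditions.

**Ancestral frequencies.** Balding–Nichols draws: per SNP a shared
ancestral frequency ~ Uniform(0.1, 0.9), then per-population frequencies
Beta-distributed with the population's Fst (default 0.15), clipped at a
1% MAF floor. An estimator oracle (Hudson-style Fst on the generated
matrix) verifies the dial.

**Ancestry proportions.** A two-component mixture of Dirichlet
distributions, moment-matched by Nelder–Mead to the cohort targets: mean
ancestry (42.5% European, 38.3% Native American, 15.2% African) with
coefficient SDs 0.13 (European) and 0.07 (African), components anchored
near the 60/30/10 and 40/40/20 subpopulation centers. The three stated
means sum to 0.96 — the residual ~4% (Asian) component is out of scope —
and the missing mass is absorbed by the ancestry without an SD target
(NA), so the constrained means keep their stated values exactly. The two
components share one concentration, giving two comparably tight modes as
a bimodal coefficient histogram implies. Calibration fails loudly if the
fitted mixture misses any target by more than 5% relative.

A consequence worth stating: with these moments and the simplex
constraint, the European and Native-American coefficients are necessarily
strongly anticorrelated (≈ −0.85). The leading eigenvector of the pooled
PCA therefore tracks the European axis almost perfectly, and the NA
coefficient loads mostly on EV1 too — its correlation with EV2 alone
plateaus around 0.8 regardless of seed. A higher NA–EV2 correlation is a
property of real-data geometry that these moment targets cannot induce.

**Admixture dynamics.** Hybrid-Isolation draws Q once per individual.
Constant Gene Flow builds the focal coefficient by per-generation migrant
replacement (one migrant parent with probability 2m per generation,
halving the resident genome), so the focal mean approaches 1−(1−m)^g and
its variance grows with admixture age until saturation; the
non-decreasing-variance property is tested in the pre-saturation regime
(g ≤ 20 at m = 0.02).

**Genotypes.** In `iid_loci` mode each genotype is Binomial(2, q·p) —
the admixture model exactly, used for structure inference, PCA and the
stratification experiment. In `tracts` mode each haplotype is a Markov
mosaic: ancestry breakpoints at `generations` per Morgan (mean
ancestry-tract length 1/g Morgans, verified against the closed form) and,
within tracts, copying from a local haplotype pool. The pool is
hierarchical: the chromosome is partitioned into ancestral LD blocks
(default 2 per Morgan) holding three pattern haplotypes shared across
ancestries, with per-ancestry pattern frequencies differentiated at the
panel Fst; within-ancestry founder switches arrive at 8 per Morgan. An
unbroken segment carries only pool patterns, so short-range D′ is 1, and
every switch event (rate g + 8 per Morgan) creates recombinant
combinations — strong-LD block extent therefore shrinks as admixture age
grows, which is the direction of the high-CEU vs low-CEU block-size
contrast. Pure admixture LD without the pool (`haplotype_pool_size=None`)
is far too weak to form Gabriel blocks at realistic panel Fst; that mode
is retained for tract-length and LD-decay checks. The genetic map
defaults to 1 cM/Mb over 22 autosomes + X at approximately realistic
lengths; block-analysis tests use a denser 10 cM/Mb single-chromosome map
so that block scale resolves below the 500 kb span cap at a few hundred
SNPs.

**What the generator does not emulate.** Realistic site-frequency
spectra, recombination hotspots and genotyping error are absent; pool
allele frequencies are coarse (multiples over three patterns per block);
the two-stage demographic history (low-CEU group founding first and later
admixing with Europeans) is represented only as the two-component mixture
plus a generation-age difference. Tests passing on this generator
establish correctness of the estimators and procedures under the stated
model, not performance on real genotype data.

## Problem sizes

Structure-scale analyses run at the study scale: a 1,245-sample cohort at
2,663 SNPs with 60/59/56-sample reference panels. The ΔK selection runs
on four 40-sample source panels plus 200 admixed samples at 1,000 SNPs
with 10 restarts per K ∈ {3..6}. The stratification experiment draws 200
subjects per subgroup (400 total), mirroring the study's simulated
association design; block-size comparisons use 250 samples × 1,200 SNPs on
a 24 Mb chromosome (10 cM/Mb) over a 10-seed grid, sized so the per-seed
mean rests on >100 blocks. These sizes keep the full test
suite and the acceptance script within a desk-scale single-CPU run.

## Known limitations

* The pipeline's ingest mode parses VCF/PLINK-text cohorts but the
  end-to-end orchestration currently requires the simulation path, since
  reference panels and the truth table have no external loader.
* The per-SNP logistic Wald statistic is slightly anticonservative in
  small samples, as Wald statistics are; the score fallback is exact
  under the null but only engaged on separation.
* The D′ CI grid has 0.01 resolution; Gabriel classifications at the
  exact thresholds can flip for pairs whose CI endpoints sit on a grid
  knot.
* `assign_subpopulations` is one-dimensional by design; subpopulations
  separated only in a multivariate direction of Q would need the full
  mixture on the simplex.
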