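# admixscope

Population-structure analysis for admixed cohorts: admixture-model
inference, model selection for the number of ancestral populations,
genotype PCA, linkage-disequilibrium (LD) structure, and the effect of
population stratification on association studies.

The package targets the setting of three-way admixed Latin-American
populations — the motivating case is the Guanacaste region of Costa Rica,
whose population mixes European (CEU-like), Native American (NA) and West
African (YRI-like) ancestry and splits into a high-European and a
low-European subpopulation. Because cohort genotypes of this kind are
rarely redistributable, the package ships a first-class synthetic-cohort
generator calibrated to that setting, so every stage of the pipeline can
be exercised and verified end to end.

## The model

Genotypes are biallelic calls `g ∈ {0,1,2}` counting copies of a reference
allele. Individual *i* carries ancestry proportions **q**<sub>i</sub> on
the K-simplex, ancestral population *k* carries allele frequencies
*p*<sub>kl</sub>, and each genotype is

&nbsp;&nbsp;&nbsp;&nbsp;g<sub>il</sub> ~ Binomial(2, Σ<sub>k</sub> q<sub>ik</sub> p<sub>kl</sub>)

independently across SNPs (the classic admixture / STRUCTURE model without
linkage). Estimation is by expectation–maximization over the latent
ancestry of each allele copy:

* **supervised** — ancestral frequencies fixed at reference-panel values,
  per-individual **q** estimated (`SupervisedAdmixture`);
* **unsupervised** — **Q** and **P** estimated jointly from random
  restarts (`UnsupervisedAdmixture`); the per-run maximized log-likelihood
  L(K) feeds the Evanno ΔK criterion
  ΔK = mean|L″(K)| / sd[L(K)], whose argmax selects the number of
  ancestral populations.

Around the estimator sit the standard pipeline stages: QC and panel
intersection (`genotype_io`), sequential greedy LD pruning for structure
SNPs (`structure_snps`), Patterson-normalized genotype PCA (`pca`),
two-locus haplotype EM with D′ confidence intervals, Gabriel-rule block
detection and greedy tag-SNP selection (`ld_analysis`), and a simulated
stratified association study with genomic-control λ and eigenvector
adjustment (`stratification`).

## Worked example

Simulate the calibrated cohort, estimate ancestry against the true panel
frequencies, and split the subpopulations:

```python
import numpy as np
import admixscope as ax

freqs = ax.simulate_ancestral_freqs(2663, 3, fst=0.15, seed=12,
                                    populations=("CEU", "NA", "YRI"))
design = ax.guanacaste_design(n=1245)        # two-component bimodal design
cohort, truth = ax.simulate_cohort(design, freqs, seed=23)

result = ax.supervised_admixture(cohort, freqs)
print(np.round(result.Q.mean(axis=0), 3))    # [0.426 0.422 0.152]
print(round(result.Q[:, 2].std(ddof=1), 3))  # 0.073

labels, threshold, _ = ax.assign_subpopulations(result.Q, ancestry_index=0)
print(np.unique(labels, return_counts=True))
# (array(['high', 'low'], ...), array([359, 886]))
```

The cohort means recover the generating mixture (42.5% European, 15.2%
African after the residual mass is absorbed by the NA component), the
African-coefficient spread matches its 0.07 dispersion target plus a small
estimation-noise inflation, and the European coefficient splits the cohort
into high/low subgroups near the generating component weights.

The same analysis, end to end with TSV outputs and a checksummed
manifest:

```bash
admixscope run --seed 3 --out-dir out/
```

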