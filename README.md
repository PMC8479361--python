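# arcticfit

Mixed-model GWAS and reproductive-value-weighted selection analysis for a
Mendelian fur-colour locus in a wild, age-structured Arctic fox
(*Vulpes lagopus*) population — packaged as a reusable, tested pipeline that
runs end to end on a synthetic pedigreed population with known ground truth.

## The scientific problem

Scandinavian Arctic foxes occur in two colour morphs: white (recessive,
genotype CC at the colour locus) and blue (dominant, TC or TT; the causal
gene is *MC1R*). Two questions arise in such a system:

1. **Gene mapping.** Which marker(s) on a dense SNP array associate with the
   colour morph, once relatedness in a small, pedigreed population is
   accounted for? `arcticfit` fits a polygenic linear mixed model with a
   genomic relatedness matrix (GRM) built from LD-pruned markers, score-tests
   each SNP against the model residuals, corrects for genomic inflation
   (λ_GC = median χ² / 0.4549) and applies a Bonferroni threshold α/m.

2. **Selection on genotype.** Do colour genotypes differ in fitness? Annual
   individual fitness is the reproductive-value-weighted contribution

   Λᵢ = Wᵢ/vₓ = (Bᵢ·v₁/2 + Jᵢ·v₍ₓ₊₁₎)/vₓ,

   where Bᵢ counts recruits, Jᵢ indicates survival, x is the age class
   (1–5, pooled at 5) and the vₓ are reproductive values from per-sex
   Leslie projection matrices under a pre-breeding census
   (1 April – 31 March). The weighting makes Λᵢ age-independent with
   E(Λᵢ) = λ, the population growth rate. Selection is then estimated with
   GLMMs — Poisson for Λᵢ, zero-inflated Poisson for fecundity, binomial for
   survival/breeding/recruitment — with random intercepts for year and
   subpopulation, genotype × environment interactions (rodent-cycle phase,
   snow season, wild/captive origin) tested by likelihood-ratio tests, and a
   genome-wide heterozygosity model to check for heterosis artefacts.

Because the real monitoring data are not deposited, the package ships a
first-class simulator (`arcticfit.synthpop`) that emulates the study design —
pedigree, five age classes, two sexes, monogamous pairing within
subpopulations, an LD block around the causal locus, 1.5 % field phenotyping
error, a four-phase rodent cycle — with every generating parameter exposed
for recovery tests.

## Worked example

```python
from arcticfit.pipeline import RunConfig, run_pipeline
from arcticfit.synthpop import SimConfig

cfg = RunConfig(outdir="demo_run", seed=3,
                simulate=SimConfig(n_founders=120, n_years=8, n_snps=400, seed=3))
report = run_pipeline(cfg)
print(report["gwas"]["top_snp"], report["gwas"]["top_snp_p"])
print(report["concordance"]["fraction"])
print(report["selection"]["F"]["b_TC"], report["selection"]["F"]["se"])
```

prints (seed 3):

```
AX_COLOUR 1.095928838400991e-161
0.9780509218612818
0.15140329765661967 0.09118272137466034
```

The colour locus (`AX_COLOUR`) is the top SNP, far below the Bonferroni
threshold (0.05/400 = 1.25e-4); genotype–phenotype concordance is 97.8 %
(the simulator injects 1.5 % phenotyping error, and post-founder allele
frequencies drift); and heterozygous (TC) females show a log-scale fitness
advantage b_TC = 0.151 ± 0.091 over white (CC) females — positive but not
significant at this sample size, the expected regime for a wild-population
selection estimate of this kind.

The same pipeline is scriptable from the shell:

```bash
arcticfit run --config run.yaml        # full pipeline
arcticfit simulate --out sim --seed 1  # PED/MAP + pedigree/life-history CSVs
arcticfit gwas --ped sim/genotypes --out gwas_out
arcticfit fitness --pedigree sim/pedigree.csv --life-history sim/life_history.csv --out fit_out
arcticfit select --fitness fit_out/fitness.csv --model Lambda --out sel_out
```

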