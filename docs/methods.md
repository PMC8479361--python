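# Methods

## Demographic model and individual fitness

The census is pre-breeding: census year *t* spans 1 April of *t* to 31 March
of *t*+1, so most winter mortality falls inside the year in which it acts,
and pups enter the census at age class 1 the year after birth. Age classes
run 1–5 with everything older pooled into class 5. Survival Jᵢ ∈ {0,1} is
presence after 1 April of *t*+1; fecundity Bᵢ counts the pups born in *t*
that recruit into the *t*+1 census, so pups dying before their first census
never distort fecundity.

Per-sex Leslie matrices are built from the pooled census means: top row
Fₓ = mean(Bᵢ)/2 and subdiagonal Pₓ = mean(Jᵢ). The halving allocates each
recruit equally to its two parents; it mirrors the ½ in the fitness formula
below so that the identity E(Λᵢ) = λ holds per sex. The pooled terminal
class gets a survival self-loop A₅₅ = mean(J | x = 5), the standard
treatment of an open-ended age class, and consistently v₆ := v₅ in the
fitness formula. The matrix is the arithmetic mean over years ("mean
projection matrix"); annual matrices can be built by subsetting the census.

Annual individual fitness is Λᵢ = (Bᵢ·v₁/2 + Jᵢ·v₍ₓ₊₁₎)/vₓ with v the
dominant left eigenvector of A (reproductive values) and λ the dominant
eigenvalue. Since E(Bᵢ | x) = 2Fₓ and E(Jᵢ | x) = Pₓ,
E(Λᵢ | x) = (vA)ₓ/vₓ = λ at every age, which is the point of the weighting:
Λᵢ is age-independent and averages to λ under any age distribution. When A
is estimated from the same census records the sample mean of Λᵢ equals λ
*exactly* (the stage-wise means cancel), which the tests exploit as a sharp
oracle. Λᵢ is invariant to rescaling of v, so the normalization (v₁ = 1,
then u scaled so v·u = 1) is cosmetic; eigenpairs are validated against
‖vA − λv‖∞ and ‖Au − λu‖∞ < 1e−8 and a complex dominant pair is a hard
error. Unknown-parent recruits would be allocated wholly to the known parent
to conserve recruits; the simulator always knows both parents, so this path
is only logged.

## Mixed-model GWAS

The colour morph (blue = 1) is analysed on the observed 0/1 scale with a
linear mixed model: a polygenic model y = Xβ + g + e, g ~ N(0, σ²g·GRM), is
fitted by REML on the GRM eigenbasis (single random effect; the profiled
likelihood is optimized on the log variance-ratio scale to 1e−8, with a
parsimony tie-break to σ²g = 0 when the likelihood is flat, as happens when
the GRM is proportional to the identity). Each SNP is then score-tested
against the environmental residuals σ²e·V⁻¹(y − Xβ̂) with the null variance
taken under the fitted covariance: χ² = (gᵀPy)²/(gᵀPg),
P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹. This equals the marginal-regression t² when
V ∝ I and is asymptotically calibrated under the fitted model. Monomorphic
SNPs get missing p-values and are excluded from λ_GC and the Bonferroni
count, which is recomputed per run as α divided by the number of tested
SNPs.

Genomic control: λ_GC = median χ² / 0.4549364 (the χ²₁ median). By default
statistics are divided by λ_GC only when λ_GC > 1 — deflation is left
uncorrected, the common convention — with `always`/`never` available. The
correction matters most when the scan is run without (or with an
insufficient) relatedness adjustment; the test suite verifies that a
family-clustered polygenic null inflates an unadjusted scan to λ_GC ≈ 2–2.5
and that dividing by λ_GC restores the 5 % type-I error, and separately that
the GRM-adjusted scan sits near λ_GC = 1 without correction.

The GRM is VanRaden-I by default — centred cross-product scaled by pooled
2Σp(1−p), observed allele frequencies of the analysis sample, missing calls
mean-imputed per SNP — with a per-SNP-scaled (`gcta`) alternative. LD
pruning follows the PLINK `indep` semantics with parameters (50, 5, 2):
50-SNP windows advancing by 5 within a scaffold, iteratively removing the
marker with the largest variance inflation factor (diagonal of the inverse
marker-correlation matrix) until all VIF < 2, ties broken by removing the
later marker in map order. Principal components are eigenvectors of the GRM
scaled by √eigenvalue (classical MDS on relatedness), sign-fixed so the
largest-magnitude loading is positive.

The candidate-region scan reuses the same machinery on a continuous trait
(per-individual mean Λᵢ) restricted to one scaffold, with the Bonferroni
count equal to the regional marker count.

## Selection GLMMs

All mixed models use Gaussian random intercepts fitted by the Laplace
approximation, lme4-style: for a candidate variance vector, fixed effects
and random-effect modes are found jointly by damped Newton (penalized IRLS;
convergence at gradient norm < 1e−6, with step halving and a Fisher-type
positive-definiteness safeguard on the weights), and the marginal likelihood
is f(β̂, û) − ½ log det(I + D^{1/2}ZᵀWZD^{1/2}). The outer optimization over
log random-effect SDs (clipped to [−8, 4]) plus any family extras uses
Nelder–Mead. Against an adaptive Gauss–Hermite quadrature oracle the Laplace
log-likelihood agrees to < 0.05 on small data. Coefficient covariances come
from the β block of the inverse joint penalized Hessian (conditional on the
variance estimates, as in lme4); 95 % CIs are Wald.

Families: Poisson log, binomial logit, Gaussian identity (residual SD
profiled in the outer step) and zero-inflated Poisson (log-link counts,
intercept-only structural-zero probability on the logit scale — the
zero-inflation covariates are not specified by the study design, so the
mixture component stays minimal). Λᵢ is continuous but modelled with the
Poisson log-density evaluated through the gamma-function generalization of
the factorial, which keeps the quasi-likelihood estimating equations of the
Poisson fit without rounding; rounding is available as a sensitivity check
by transforming the response before fitting. An all-zero response makes the
ZIP mixture unidentifiable and is rejected.

Conventions mirrored from the study design: Λ models are fitted per sex with
year and subpopulation random intercepts and genotype as a two-level factor
(CC reference, TC), TT rows being excluded whenever a sex stratum has fewer
than 10 of them (configurable); fitness-component models (ZIP fecundity,
binomial survival and breeding) are fitted jointly across sexes with
genotype, sex, and centred age and age² (centring at the sample mean age);
recruitment probability uses only den-marked juveniles with known birth
year, excluding the final, censored cohort, with birth-year and den random
intercepts. Genotype × environment interactions (rodent phase, first/last
snowfall, origin) are tested one environment at a time by LRT; environment
levels with empty genotype cells are dropped with a warning and constant
environments are reported as skipped rather than tested. Non-significant
interaction terms can be pruned (least-significant first) before main
effects are reported. LRTs require converged fits, clip χ² at zero and take
the degrees of freedom from the parameter-count difference — 3 for a 4-level
phase × 2-level genotype interaction.

## The synthetic population

The generator produces the data structure the analyses expect, with known
truth. Defaults (all overridable in `SimConfig`):

- **Founders and structure:** 200 founders, 4 subpopulations, 12 census
  years, ages 1–3 at start, 30 % captive-born. Pairing is annual, monogamous
  and random within subpopulation — the species is socially monogamous and
  the study design says nothing finer.
- **Colour locus:** T (blue) allele frequency 0.11, matching the genotype
  counts of the real panel (882 CC / 234 TC / 9 TT → 0.112); phenotyping
  error 1.5 %, symmetric white↔blue, matching the observed ~98.5 %
  Mendelian concordance.
- **Genotype fitness effects:** multiplier 1.15 on survival and fecundity
  rates for TC and TT (dominant blue advantage). On the log scale this is
  ≈ 0.14 per component, the magnitude of the reported heterozygote
  advantage (Λ effect ≈ 0.17, survival ≈ 0.3, both with wide CIs).
- **Vital rates:** survival (0.50, 0.60, 0.60, 0.55, 0.45) and mean recruit
  rates (0.8, 1.6, 1.8, 1.6, 1.2) per age class, both sexes; breeding
  probability 0.75 per paired female; pup recruitment probability 0.55.
  These put λ a little above 1 — a slowly recovering population.
- **Environment:** deterministic 4-year rodent cycle
  low → increase → peak → decline keyed to (year − origin) mod 4, with
  fecundity multipliers (0.5, 1.4, 1.6, 0.7) and mild survival multipliers;
  lognormal year and subpopulation random effects (SD 0.2 / 0.15 on
  fecundity, half that on survival); first/last snowfall day-of-year
  Normal(280, 10) / Normal(120, 10).
- **Marker panel:** 1,000 SNPs (5,000 in the GWAS-scale checks) evenly
  spaced at 10 kb over 20 scaffolds, causal locus mid-scaffold-11. Founder
  haplotypes inside the ±1 Mb LD block copy the causal allele with
  probability exp(−δ·d/2), giving expected founder r² = exp(−δ·d) with
  δ = 1.05e−5 per bp (r² ≈ 0.9 at the nearest marker, ≈ 0 at the block
  edge); markers elsewhere are independent with uniform(0.1, 0.9)
  frequencies. Transmission is Mendelian: free recombination between
  scaffolds and outside the block, switch probability
  ½(1 − exp(−δ·d)) between adjacent block markers.

Litter sizes are Poisson with the recruit rate divided by the pup
recruitment probability, and each pup recruits independently, so fecundity
stays Poisson at the configured recruit rate while recruitment probability
remains a non-degenerate trait. Non-recruiting pups enter the pedigree
(den-marked) but never the census. Survivors of the final simulated year
have their last-alive record advanced past 1 April, mirroring how a real
monitoring programme infers final-year survival from later observations.

What the simulator does *not* emulate: non-invasive capture–recapture
detection (only a uniform per-record miss probability, default 0, is
exposed — whether real misses cluster by den or subpopulation is unknown,
so no clustering is invented), density dependence, dispersal between
subpopulations, genotyping error (only phenotyping error), and genuine
polygenic background for the colour trait (the trait is strictly
single-locus plus error). Passing tests therefore demonstrate that the
estimators recover what this data-generating process encodes — Mendelian
single-locus architecture, known vital rates, specified genotype effects —
not that they are robust to every failure mode of field data.

## Numerical and design choices

- Positions are 0-based half-open internally, 1-based in MAP/VCF output;
  PED/MAP is the white-space dialect with A/C/G/T alleles and `0 0` missing.
  On reading, the minor allele is counted as alternate except at the named
  colour SNP, where T is always the counted allele.
- One global seed fans out through `numpy.random.SeedSequence.spawn`, so
  pipeline stages can be re-run in isolation; identical seeds give
  byte-identical run reports (artifact hashes included).
- GRM non-PSD after a 1e−6 jitter is a hard error; eigenvalues are floored
  at zero after decomposition.
- LD r² uses pairwise-complete observations and raises a dedicated error on
  monomorphic input or fewer than 3 complete pairs, rather than returning 0.
- Extinction of the simulated population is a flagged result, not an
  exception.
- Problem sizes in the checks: the scan-scale suites use 400 individuals ×
  5,000 SNPs (20 replicate seeds), the calibration suite 5,000 null SNPs ×
  20 seeds (pooled 100,000 p-values), the GLMM suites n = 1,500
  individual-years with 100 recovery and 500 null replicates, and the
  E(Λᵢ) = λ check ≈ 2,000 individual-years over 100 replicate years — sizes
  at which the Monte-Carlo error of each check is several times smaller than
  its tolerance.

## Known limitations

- The binary colour trait is analysed with a linear, not logistic, mixed
  model; this matches the residual-based score-test strategy the field uses
  at this scale but means fitted values are not probabilities.
- The ZIP structural-zero component is intercept-only; zero inflation that
  varies with covariates would be attributed partly to the count component.
- The Laplace approximation is least accurate for binomial models with few
  observations per group; the quadrature oracle bounds the error on small
  data but very sparse groupings (many single-observation dens) will show
  some likelihood bias, a known property shared with lme4's default.
- Sex-specific projection matrices treat the sexes independently; no
  two-sex coupling beyond recruit halving is attempted.
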