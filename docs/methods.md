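# Methods

## Design and data model

The package targets North Carolina Design II populations: `n` recombinant
inbred lines (RILs) from a biparental cross, each mated to two testers,
giving two hybrid populations that can be pooled. Genotypes are coded
relative to the two RIL parents (+1/−1 per bin marker); a hybrid's code at a
locus follows from its parents: equal alleles give a homozygote (additive
score `Z` = the allele, dominance indicator `W` = 0), unequal alleles the
heterozygote (`Z` = 0, `W` = 1), and a missing parental call propagates.
Tester alleles that match neither RIL parent (possible with real
resequencing data) are set missing for that population, since the coding is
defined only relative to the two RIL parents. Genetic (cM) positions are the
authoritative coordinate for all interval arithmetic; physical positions are
carried for reporting only.

## Trial-level models

All phenotype-side variance components are estimated by a single REML
engine that profiles the residual variance out of the restricted likelihood
of `V = σ²(I + Σ γ_i K_i)` and optimizes the log-ratios `γ_i` with L-BFGS-B
(box `log γ ∈ [−12, 12]`, the lower edge treated as an exact zero), followed
by a Nelder–Mead polish. The engine is dense — one Cholesky of an `n × n`
matrix per objective evaluation — which is exact and fast at the population
sizes this design produces (hundreds to a few thousand plots). It matches
`lme4` and a brute-force likelihood optimizer to ~1e-4 on test instances.

- **Outlier razor.** Externally studentized residuals from the per-trait
  fixed-effect model (genotype + environment + replicate-within-environment);
  a single sweep removes observations with |t| strictly greater than 2.8.
  Removal is applied per trait across the whole table handed in; callers
  that want per-population screening pass per-population tables.
- **Across-environment model.** `y = μ + G + E + G×E + R(E) + ε` with
  environments fixed; genotype, G×E and replicate-within-environment random
  for variance estimation. Component significance uses the REML LRT against
  the component-dropped model with the 50:50 χ²₀/χ²₁ boundary mixture.
  BLUEs refit genotype as fixed (GLS at the estimated covariance) with
  centered environment contrasts, so each BLUE is the genotype value at the
  average environment. Broad-sense heritability is on an entry-mean basis:
  `H² = σ²_G / (σ²_G + σ²_G×E/N_E + σ²_ε/(N_E N_R))`.
- **Midparent heterosis.** Step 1 computes within-environment BLUEs
  (genotype fixed, replicate random); step 2 fits
  `MPH = μ + G + E + ε` with G and E random. MPH heritability is
  `σ²_G / (σ²_G + σ²_ε/N_E)` — replicates are already absorbed in step 1,
  so no replicate divisor appears.
- **GCA/SCA.** All combining-ability effects random. With one observation
  per hybrid × environment cell (the usual two-step input) the SCA×E
  variance is confounded with the residual and reported as NaN rather than
  invented. The reported ratio is `σ²_SCA / (σ²_GCA_RIL + σ²_GCA_Tester)`;
  users can recompute alternatives from the stored components.
- **Path analysis.** Path coefficients are standardized partial regression
  coefficients, `p_i = b_i · s_{X_i} / s_Y`, from a complete-case OLS of the
  response on all other traits. The 0.14 display threshold only filters
  formatted output. Collinearity (condition number > 1e8) flags the
  coefficients as unstable.

## Kinship kernels

From the hybrid design matrices the five polygenic kernels are
`K_a ∝ ZZᵀ`, `K_d ∝ WWᵀ` and, for the pairwise-epistatic terms, closed-form
Hadamard identities that avoid enumerating the ~m²/2 pairs:
`K_aa ∝ (G_a∘G_a − D_a)/2` with `G_a = ZZᵀ`, `D_a = (Z∘Z)(Z∘Z)ᵀ`;
`K_ad ∝ G_a∘G_d − (Z∘W)(Z∘W)ᵀ` (ordered pairs `k ≠ k′`); and the analogous
`K_dd`. The identities are exact (tested against brute-force enumeration to
1e-10). The additive-by-dominance and dominance-by-additive scan types
share the single `K_ad` background kernel: the polygenic model has one
ξ_ad term.

Two normalization choices matter and are deliberate:

- **Column centering** (default in `build_kinships`): marker columns are
  mean-centered before kernels are formed. Without centering, `WWᵀ` carries
  a large rank-one component along the all-ones direction (dominance
  indicators have column means near 1/2), which puts the attached variance
  component on a different scale from the realized, centered variance of
  the dominance deviation — in simulation it inflates σ²_d estimates about
  two-fold. With centering, variance components are directly comparable to
  realized component variances. The kernel algebra itself is
  centering-agnostic.
- **Mean-diagonal-1 scaling**: each kernel is divided by its mean diagonal,
  so the λ ratios attached to different kernels are comparable.

Missing hybrid codes are column-mean-imputed only when building kernels;
per-marker tests instead drop the affected rows (see below), keeping
single-marker tests exact.

## Variance components and whitening

The pooled-hybrid model is
`y = Xβ + ξ_a + ξ_d + ξ_aa + ξ_ad + ξ_dd + ε`, with `X = [1, X₁]` and `X₁`
the population indicator (0/1 for the two tester populations), each ξ_x
normal with covariance `K_x σ²_x`. Two backends estimate the six variance
components:

- **Gibbs sampler** (default, mirroring the study's Bayesian settings:
  15,000 iterations, 5,000 burn-in, seeded). Each ξ_x is represented in the
  eigenbasis of its kernel, where the conditional posterior of the
  coefficients is diagonal; variances take scaled-inverse-χ² updates with
  weakly informative priors (df 5, prior scale splitting half the
  phenotypic variance across the genetic terms). Posterior means and SDs
  are reported.
- **REML** (deterministic; the backend used by tests and recovery
  experiments).

On well-identified designs the two agree closely; when a component sits at
the REML boundary the posterior mean stays slightly positive, which is
expected behavior, not disagreement.

Single-population (RIL, TC, TM) scans control the background with the
additive and additive-by-additive kernels only; the pooled analysis uses
all five.

With `λ_x = σ²_x/σ²` fixed from the null fit (one fit per trait/dataset —
per-marker re-estimation is not done), the background is `K = Σ λ_x K_x`,
`K = UDUᵀ`, and all data are transformed by `Q = (D+I)^{−1/2}Uᵀ`, after
which the residual covariance is `Iσ²` and every test is ordinary least
squares. Only the symmetric square root achieves this; a plain `(D+I)^{−1}`
would leave residuals with covariance `(D+I)^{−1}`, so the square-root
transform is used. LRTs are ML-based (`LRT = n·ln(RSS₀/RSS₁)`), since fixed
effects differ between null and full models and REML likelihoods would not
be comparable; `LOD = LRT/4.61`.

## Genome scans

Per marker, the additive test adds the whitened `Z_k` to the null design
and the dominance test the whitened `W_k`; for midparent-heterosis datasets
only the dominance test runs (additive effects cancel from MPH). Epistatic
tests add the whitened element-wise product of the two marker columns to
the two-main-effect null, for the four classes aa (`Z_k, Z_k′`),
ad (`Z_k·W_k′`), da (`W_k·Z_k′`, same main effects as ad) and dd. The
product is formed **before** whitening: the transform is a dense rotation,
so the product of transformed columns does not span the interaction
contrast (in simulation it has essentially zero power for a true
interaction), whereas the whitened product recovers it at full strength.
For a marker pair the ad/da orientation follows marker index order and both
types are reported.

Markers (or pairs) with missing codes are tested on the complete rows only,
re-whitening that row subset against the same background via a Cholesky of
`(K+I)` restricted to those rows — codes are never imputed for tests.
Monomorphic or collinear tested columns are flagged inestimable with
LOD = 0. The background K stays fixed during the scan, including the tested
marker's own contribution; this proximal contamination conservatively
shrinks LOD peaks at very high marker density, which is why power
experiments use a moderately dense simulated map (below).

QTL calling per chromosome: markers above the LOD threshold (2.5 main,
5.0 epistasis) are candidates; peaks are taken greedily in descending LOD
(ties to the lower cM), suppressing candidates within 10 cM; each peak's
support interval is the contiguous marker run with LOD ≥ peak − 1.5,
snapped to marker positions (bin-level resolution is the data's
resolution). QTL whose intervals overlap or whose peaks lie within 0.65 cM
are merged into pleiotropy groups by transitive closure. Effect sizes are
the regression coefficients of the tested columns; `PVE = 1 −
RSS_full/RSS_null` on the whitened data, clipped to [0, 1].

Favorable-QTL analysis (threshold LOD 2.0) classifies each QTL by comparing
mean hybrid performance of the heterozygous class against the homozygous
class(es) at the peak marker; per-hybrid counts of favorable homozygous,
favorable heterozygous and total favorable QTL are correlated with
performance (r₁, r₂, r₃, Pearson with p-values).

## Genomic prediction

GBLUP with `y = Xβ + ξ_a [+ ξ_d] + ε`: variance components by REML on the
training rows, predictions as conditional expectations
`K_{te,tr} V_tr^{−1}(y_tr − X_tr β̂)` summed over kernels (verified against
Henderson's mixed-model equations to 1e-8). CV1 (train on one tester
population, predict the other) is additive-only; within-population, CV2 and
CV3 use additive + dominance. Weighted GS re-maps QTL inside every training
fold (null fit → whitening → additive scan → interval calling at LOD 2.5)
and adds the peak-marker `Z` columns as fixed effects; selection never
touches test phenotypes, which a construction test audits. Accuracy is the
plain Pearson correlation between predicted and observed values over
two-fold partitions (200 repeats by default); undefined correlations
(constant predictions) are recorded as missing, not zero.

CV scheme semantics (stated operationally since they are easy to
mis-read): CV2's training fold is the hybrids of a random half of the RILs
under **both** testers; CV3's training fold pairs one half of the RILs with
the first tester and the complementary half with the second, so training
RIL sets are disjoint across testers and every test hybrid's RIL is
phenotyped under the other tester.

## Synthetic data

`simdata` generates the study conditions: by default 339 F11 RILs, 10
chromosomes × 414 bin markers (≈0.64 cM/bin), two testers sharing a
parental allele at 95% of loci, 4 environments × 2 replicates, and 0.5%
residual heterozygous calls that are flagged and masked to missing before
coding (F11 lines are treated as inbred). RIL chromosomes are two-state
Markov mosaics whose switch probability between adjacent markers is the
Haldane (no-interference) recombination fraction of their cM distance, so
the empirical recombinant fraction between any two markers matches the map
function — the simplest construction with a closed-form oracle. Marker
positions are equally spaced per chromosome (the study reports only the
average density); explicit positions can be supplied.

Phenotypes are drawn from exactly the model the pipeline fits: genetic
values from per-marker additive, dominance and pairwise-epistatic effects,
plus genotype-by-environment, replicate-within-environment and residual
Gaussian noise. Effect vectors are rescaled once — on the pooled hybrids —
so each component's realized variance equals its target, and both the
effects and the realized variances are stored, giving recovery tests an
exact reference. Inbred (RIL and tester) phenotypes use the individual's
own codes as `Z` with `W = 0`, which makes the midparent-heterosis pipeline
runnable end to end. The generator does not model selection, drift,
segregation distortion, genotyping error beyond residual heterozygosity, or
spatial field trends — so passing tests demonstrate correctness of the
estimators under the stated model, not robustness to those artifacts.

## Validation experiment sizes

Tests and acceptance experiments use reduced dimensions chosen so each
estimand is identifiable and the Monte-Carlo error is small relative to the
assertion margin:

- Five-kernel recovery: 500 pooled hybrids (250 RILs × 2 testers), 500
  markers, additive/dominance targets (1.0, 0.5), unit residual, 10 seeds.
  The testers are drawn independently (similarity 0.5): under the study's
  95% tester identity the additive and dominance kernels coincide at shared
  loci (centered `Z = −t·W`), so the two components are not separately
  identifiable there — that confounding is itself asserted by the
  shared-locus scan test, while recovery is assessed where the design
  identifies both components.
- Scan power/Type-I: 339 hybrids, 500 markers on five 250 cM chromosomes
  (2.5 cM spacing), one additive QTL at 10% of phenotypic variance; 50
  power replicates, 20 null genomes.
- Prediction: 300 pooled hybrids, 200 markers, one additive QTL at 15% of
  phenotypic variance, 50 two-fold CV2 repeats for the wGS vs GS
  comparison.

## Known limitations

- The REML engine is dense; beyond ~5,000 observations it becomes slow,
  and no sparse/low-rank path is provided.
- Exhaustive epistasis scans loop in Python over pairs; genome-wide
  all-pairs scans at full marker density are possible but slow — anchor
  scans and explicit pair lists are the intended desk-scale modes.
- At tester similarity near 1 the additive/dominance decomposition of the
  pooled population is intrinsically confounded (two genotype classes per
  locus); the package reports what the data identify rather than resolving
  the aliasing.
- Variance-component significance uses the χ²₀/χ²₁ mixture, which is
  approximate for finite samples and multiple random terms.
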