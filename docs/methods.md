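# Methods

`sbptraj` implements a trajectory-subphenotyping analysis of longitudinal
systolic blood pressure (SBP) in extended families: latent trajectory
classes are derived from repeated SBP measures, ranked by cumulative
hypertensive exposure, and treated as heritable traits in pedigree-based
variance-component and mixed-model association analyses.  Because the family
studies this design targets are access-restricted, every stage runs on
synthetic family data whose generator is part of the package and itself
under test.

## Synthetic cohort generator

**Pedigrees.** Families grow forward from a founder couple; each couple has
`1 + Poisson(mean_offspring - 1)` children and each child in a non-terminal
generation mates with a new unrelated married-in founder with probability
0.8.  The reference cohort uses 20 families, 4 generations and
`mean_offspring = 3.3`, giving roughly 950-1000 members, about a quarter of
them founders.

**Genotypes.** Unlinked biallelic autosomal SNPs are gene-dropped: a per-SNP
allele frequency is drawn uniformly over the requested MAF range (the
counted effect allele is the minor or major allele with equal probability),
founders draw `Binomial(2, p)` dosages, and every non-founder inherits one
allele from each parent.  Mendelian consistency therefore holds by
construction and is checked exhaustively in tests.  QC utilities flag
monomorphic SNPs and founder Hardy-Weinberg violations.

**Phenotypes.** Each individual carries an additive polygenic value `g`
spread through the pedigree (founders `N(0, sigma_g^2)`; children receive
the parental midpoint plus segregation noise `N(0, sigma_g^2 / 2)`, so
`cov(g) = 2 Phi sigma_g^2` in non-inbred pedigrees).  A liability
`g + N(0, sigma_l^2)` is thresholded at the class-proportion quantiles to
assign one of K latent trajectory classes — class membership is therefore
genuinely heritable, with liability heritability
`sigma_g^2 / (sigma_g^2 + sigma_l^2)`.  Observed SBP at a visit is the
class-specific quadratic polynomial of age, plus a sex effect, plus `g`,
plus independent visit noise.  Visits follow a baseline age drawn uniformly
on 25-60 years with 3 subsequent gaps uniform on 4-6.5 years, rescaled when
necessary so the span never exceeds 17 years; visits are then deleted
completely at random (MCAR), which can leave individuals with fewer than 2
measures — those are removed later by the preprocessing filter, as in the
study design this emulates.

The `reference` scenario fixes the study-like conditions: 5 classes with
proportions (0.40, 0.22, 0.18, 0.13, 0.07); class curves (on standardised
age `c = (age - 45) / 10`) with intercepts 113 / 124 / 136 / 149 / 165
mm Hg and increasing slopes and curvatures, i.e. a stable normotensive
majority through steeply rising hypertensive minorities; residual SD 10
mm Hg; sex effect +6 mm Hg (male); polygenic SD 3 mm Hg with liability
heritability 0.5; medication use logistic in the latent SBP
(centre 161, scale 9 mm Hg, calibrated once so about 20% of visit records
are medicated); 12% MCAR visit deletion.  Two generator choices deserve
comment:

* The direct polygenic contribution to SBP is kept at SD 3 mm Hg.  The
  growth mixture assumes repeated measures are independent given class; a
  shared per-individual deviation violates that assumption, and with a large
  polygenic SD the violation is strong enough that BIC prefers a spurious
  sixth class.  The scenario is defined as a *well-separated, recoverable*
  5-class structure, so the unmodelled within-individual correlation is kept
  moderate (ICC about 0.08 at the visit level).
* Real cohorts' visit-age distributions are unknown to us; the uniform
  baseline-age and gap choices are stand-ins, so passing tests demonstrate
  recovery under this design, not under any particular real visit schedule.

## Preprocessing

Medicated SBP readings are corrected by a constant +15 mm Hg.  The analytic
sample keeps individuals with at least 2 measures whose consecutive-visit
SBP changes all lie within 3 SDs of the pooled sample distribution of
changes (computed once on the unfiltered sample; an annualised-change
variant is available).  Cumulative hypertensive years use carry-forward
accrual: an inter-visit interval is credited in full when its starting visit
is hypertensive, defined as raw (pre-offset) SBP >= 140 mm Hg — the
conventional clinical threshold — or medication use (treated hypertension is
hypertension); the final visit starts no interval.

## Covariate screen (lagged path model)

A recursive system of per-visit regressions: SBP at visit 1 on covariates
and one SNP; each later visit additionally on the immediately preceding
SBP.  Equations are estimated by least squares with family-clustered
sandwich SEs (no small-sample factor, so singleton clusters reduce exactly
to HC0).  SNPs enter only when every genotype class has at least 30
carriers.  Fit is summarised by likelihood-ratio discrepancies against the
saturated recursive factorisation (each visit on *all* earlier visits):
RMSEA `sqrt(max(chi2 - df, 0) / (df n))`, CFI and TLI in their standard
forms, with adequacy gates RMSEA < 0.06 and CFI, TLI >= 0.95.  Indirect
covariate effects are cumulative lag-mediated chains
`I_t = sum_{s<t} gamma_s prod_{u=s+1..t} lambda_u` with delta-method SEs
(per-equation estimates treated as independent); the single-step product
was rejected because it duplicates the previous visit's direct test and
lets one chance blip count as two time points.  A covariate is retained
when its direct or indirect path is significant (alpha = 0.05) at >= 2 time
points in >= 2 SNP models.

This module is a transparent stand-in for a full SEM fit: it reproduces the
screening role (which covariates act where) without latent variables.  Two
caveats: with only ~20 family clusters the clustered SEs are noisy and
retention of a moderate sex effect is borderline cohort to cohort, and on
mixture-generated data the lag-1 model is genuinely misspecified (the latent
class acts as a common factor), so RMSEA/CFI flag poor absolute fit — the
adequacy indices describe, they do not gate the pipeline.

## Latent-class growth model

The class-conditional likelihood is censored normal: interior observations
get the normal density around the class curve, observations at or beyond the
bounds get the corresponding tail mass.  Default bounds are infinite (SBP
never reaches instrument limits in these data); finite bounds are supported
and tested.  The mean for individual i in class k at visit j is the class
polynomial in standardised age plus per-visit covariate effects (sex at
each time point, shared across classes).  The residual SD is shared across
classes (a per-class option exists in the fitting core but is not the
default).

Fitting is EM over individual-level responsibilities.  With infinite bounds
the M-step is an exact stacked weighted least-squares solve plus closed-form
sigma; with finite bounds a generalised M-step polishes the WLS solution by
L-BFGS on the weighted censored likelihood, never accepting a worse point,
so the EM ascent property holds in both cases and is asserted on every
trace.  Multistart uses 10 initialisations: k-means on per-individual OLS
(intercept, slope) features, jittered for all but the first start;
convergence at relative log-likelihood change < 1e-8 or 500 iterations; all
randomness flows from one seed.  BIC is reported as
`loglik - p/2 * log(n_individuals)` ("higher is better"), with n the number
of individuals, not observations.

Model selection fits K = 1..6, discards solutions in which any
hard-assigned group has 25 or fewer members, and keeps the max-BIC survivor
(ties toward smaller K).  Order pruning then iteratively drops the least
significant highest-order polynomial term among classes (Wald test from the
converged weighted regression with responsibilities held fixed — an
approximation that ignores assignment uncertainty, adequate for pruning)
and refits until every class's highest retained term is significant;
intercepts are never dropped.  Posterior class probabilities follow Bayes'
rule; hard labels take the argmax with ties to the lowest index.  Classes
are finally relabelled 1..K by ascending class-mean cumulative hypertensive
years (ties by class-mean last-visit SBP), giving the ordinal risk coding.

## Family genetics

Kinship is computed by the recursive tabular method
(`Phi_ii = (1 + Phi_fm) / 2`, `Phi_ij = (Phi_fj + Phi_mj) / 2`) in a
parents-first order; a gene-dropping Monte-Carlo estimator serves as an
independent oracle.  Heritability is REML in the model
`y = Xb + g + e`, `cov(g) = 2 Phi sigma_g^2`: one eigendecomposition of
`A = 2 Phi` diagonalises the covariance, the scale variance is profiled
out, and the restricted likelihood is maximised over `h2 in [0, 1]`
(bounded scalar optimisation plus explicit endpoint checks; the optimum
matches a dense grid search in tests).  SEs come from the observed
information of the 1-D profile; the test of `sigma_g^2 = 0` uses the 50:50
`chi2_0 / chi2_1` boundary mixture.  Binary pairwise class traits are
analysed on the observed 0/1 scale with the same linear model — mirroring
standard practice in this design — not via a liability-scale
transformation.  "Unrelated founders" means both parents missing; no
further one-per-family subsetting is applied.

LD pruning is greedy within a 50-SNP sliding window advancing by 5 SNPs
(standard dialect; only the r^2 < 0.2 rule is externally fixed), dropping
the later SNP of any pair exceeding the threshold, with correlations
estimated in the founder subsample.  PCA standardises founder dosages by
`2p` and `sqrt(2 p (1 - p))` with p the founder allele frequency,
eigendecomposes the founder covariance, and projects all individuals onto
the top loadings (4 components by default).

## Mixed-model association

Testing is two-stage (EMMAX-style): variance components are estimated once
by REML under the null fixed effects (intercept + top 4 PCs), the model is
rotated to the eigenbasis in which the null covariance is diagonal, and
each SNP is tested by OLS on the rotated data — i.e. GLS under the fixed
null covariance — with a t test and per-SNP residual variance.  This makes
the identity-kinship case collapse *exactly* to OLS and keeps finite-sample
type-I error calibrated.  SNPs with MAF <= 1% in the analysed subsample are
excluded; missing dosages are mean-imputed per SNP; pairwise traits code
the comparison class 1 against the rank-1 referent 0 with everyone else
missing; the ordinal trait is the rank 1..K as a number.  Significance
tiers: genome-wide p < 1.3E-7, suggestive p < 1.6E-6.  The genomic
inflation factor is the median association chi-square over the chi-square(1)
median, with QQ coordinates emitted alongside.

An `exact` option re-estimates the variance components jointly per SNP.
The two routes agree closely when h2 is well identified, but on
50-individual instances the restricted likelihood in h2 can be nearly flat
and the two estimates land on different variance components, so
single-instance beta agreement is only guaranteed in the median across
instances (tested as such).

## Reference experiments and problem sizes

`sbptraj.experiments` packages the replicated designs the analysis scripts
and acceptance checks run: 20 replicate `reference` cohorts for class-count
recovery (modal selected K); 100 replicate 20-family (~650-member) pedigrees
per preset for heritability recovery at the range extremes
(`H2_PRESETS`: 0.12 and 0.94); a 200-simulation x 2,000-SNP family-structured
null for GWA type-I error; and a 500-simulation i.i.d. null for the
heritability LRT.  These sizes keep each experiment in the minutes range on
one CPU while leaving Monte-Carlo error well inside the tolerances tested.

## Known limitations

* No linkage disequilibrium beyond sampling noise is simulated, no
  imputation, no X chromosome, and no attempt to re-identify any specific
  reported locus — the real family data are access-restricted.
* The covariate screen is a path-model stand-in for a full SEM estimator;
  its absolute fit indices on mixture data flag the (intentional)
  misspecification of a lag-1 structure.
* Class-membership heritability arises from a thresholded liability; real
  trajectory heritability mechanisms are unknown.
* Wald pruning and posterior-based group sizes ignore class-assignment
  uncertainty.
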