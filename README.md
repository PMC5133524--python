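# sbptraj

Trajectory subphenotyping of longitudinal systolic blood pressure (SBP) in
extended families, with pedigree-based heritability and family-aware
genome-wide association on the derived trajectory classes.

Blood pressure is heterogeneous: cross-sectional SBP mixes people whose
pressure is low and stable with people on steeply rising hypertensive
trajectories.  This package implements the full analysis chain for
partitioning that heterogeneity into discrete longitudinal subphenotypes and
asking whether they are genetic:

1. **Preprocessing** — medicated SBP readings corrected by +15 mm Hg;
   analytic sample restricted to individuals with ≥ 2 measures and no
   consecutive-visit change beyond 3 pooled SDs; per-individual cumulative
   hypertensive years (carry-forward accrual, SBP ≥ 140 mm Hg or medicated).
2. **Covariate screen** — a recursive lagged path model of SBP across
   visits per candidate SNP, with family-clustered sandwich inference,
   RMSEA/CFI/TLI fit summaries, and a retention rule (significant at ≥ 2
   time points in ≥ 2 SNP models).
3. **Latent-class growth model (LCGM)** — a censored-normal mixture over
   quadratic age trajectories, `y_ij | class k ~ N(beta_k0 + beta_k1 c_ij +
   beta_k2 c_ij^2 + theta_v sex_i, sigma^2)` fitted by multistart EM;
   class count chosen by maximum BIC (`loglik − p/2·log n`) subject to all
   groups exceeding 25 members; per-class polynomial orders pruned by Wald
   tests; individuals assigned by maximum posterior probability; classes
   ranked 1..K by mean cumulative hypertensive years.
4. **Family genetics** — recursive pedigree kinship Φ; REML heritability
   `h² = σg²/(σg²+σe²)` of class traits under `cov(g) = 2Φσg²` via spectral
   decomposition; LD pruning (r² < 0.2) and founder PCA with projection of
   all individuals onto the top 4 PCs.
5. **Association** — EMMAX-style two-stage linear mixed model per SNP on
   each pairwise class trait (lowest-risk class as referent) and on the
   ordinal 1..K trait; MAF > 1% filter; genome-wide (p < 1.3E-7) and
   suggestive (p < 1.6E-6) tiers; genomic inflation λ and QQ data.

Because the family cohorts this design targets are access-restricted, the
package ships a first-class synthetic-data module: simulated extended
pedigrees, gene-dropped Mendelian genotypes, and longitudinal SBP generated
from 5 latent trajectory classes with a heritable (liability-threshold)
class membership, sex effects, medication use and MCAR visit missingness —
up to 4 visits spanning at most 17 years.  See `docs/methods.md` for the
model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the chain end to end on the
reference synthetic cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_covariate_screen.py
python analysis/04_fit_trajectories.py
python analysis/05_heritability.py
python analysis/06_gwas.py
```

Output of `01` and `02` (20 families, ~990 members):

```
families: 20, members: 987, founders: 241
SNPs: 2000, Mendelian errors: 0
visit records: 3456 (20.3% medicated)
true class sizes: [392, 203, 184, 126, 82]
analytic sample: 974 of 987 individuals
exclusions: {'extreme_change': 7, 'too_few_visits': 6}
```

`04` selects 5 trajectory classes by BIC — matching the 5 generating
classes — and ranks them by hypertensive-year burden:

```
selected K = 5 (BIC -14213.8, loglik -14131.2, sigma 10.7 mm Hg)
class sizes by risk rank: {1: 397, 2: 202, 3: 182, 4: 112, 5: 81}
  class 4 (rank 1): orders (0, 1, 2), coefs [111.0, 5.2, 0.7] on (age-45)/10, pi = 0.40
  ...
  class 5 (rank 5): orders (0, 1, 2), coefs [178.7, 15.4, 2.4] on (age-45)/10, pi = 0.08
```

i.e. rank 1 is a stable normotensive majority (~111 mm Hg at age 45,
shallow rise) and rank 5 a small steeply rising hypertensive class.  `05`
estimates the heritability of class membership (pairwise vs the rank-1
referent, and ordinal):

```
  trait    h2    se     p
  pair2 0.075 0.069 0.118
  pair3 0.234 0.085 0.001
  pair4 0.623 0.100 0.000
  pair5 0.984 0.069 0.000
ordinal 0.525 0.058 0.000
```

— higher-risk classes are increasingly heritable here because class
membership is driven by a thresholded polygenic liability.  `06` scans all
2,000 SNPs per trait; with no single causal variant simulated, no SNP
reaches the significance tiers and the pooled genomic inflation factor is
λ ≈ 1.04.

The same stages are available as a CLI (`sbptraj simulate|preprocess|traj|
kinship|h2|pca|gwa|run-all`); `sbptraj run-all --seed 1 --out run/` executes
the whole pipeline with provenance (config, per-stage seeds, artifact
checksums) into one run directory.

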