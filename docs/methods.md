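# Methods

This note records the models, the generative assumptions, the numerical
choices and the limitations of `dailysens`, at the level of detail a user
needs to judge what a passing test suite does and does not establish.

## The analysis model

ESM data are two-level: beeps (level 1) nested in subjects (level 2). All
models are linear mixed models with a subject random intercept only, so the
marginal covariance of each subject's outcome vector is compound symmetric,
σ_u²·J + σ_e²·I. Random slopes, autoregressive residuals and multi-lag
structures are out of scope.

**Estimation.** Everything is plain maximum likelihood, never REML. The
reason is structural: the confirmatory stage compares models that differ in
their *fixed* effects by AIC, and REML likelihoods are not comparable across
fixed-effect specifications. The likelihood is maximized by profiling: for
a fixed variance ratio λ = σ_u²/σ_e², GLS gives the coefficients and σ̂_e²
in closed form (via the Sherman–Morrison identity
(I + λJ)⁻¹ = I − λ/(1 + n_g λ)·J, reducing each evaluation to per-group
sums), and a 1-D bounded search over log λ ∈ [log 1e−8, log 1e8]
(`xatol` 1e−9) finishes the job, with an explicit λ = 0 boundary check.
Degenerate clustering therefore reduces *exactly* to OLS. The engine caches
everything that does not depend on the response, which is what makes
10⁴-refit bootstrap loops affordable.

**Inference.** Wald z = coef/SE against the standard normal. With thousands
of level-1 pairs the normal approximation is adequate; no Satterthwaite or
Kenward–Roger degrees-of-freedom correction is attempted. AIC is
2k − 2·loglik with k = fixed effects + 2 variance components + 1 if the
crossover point is free.

**Parameter counting in the crossover family.** The weak fixed-c model
{1, (E−c), G·(E−c), covariates} has one *fewer* parameter than the weak
free-c model, which is the ordinary {1, G, E, G×E, covariates} interaction
model in disguise: the reparameterization (b0, s0, s1, c) ↔
(β₀, β_E, β_{G×E}, β_G) with c = −β_G/β_{G×E} is exact whenever
β_{G×E} ≠ 0. The same algebra holds for the strong free-c model
({1, G, G×E}), so both free-crossover fits are solved linearly; the strong
fit falls back to a 61-point grid over the representable window (observed E
range extended by 50% on each side) plus bounded local refinement only when
the algebraic optimum leaves that window or the interaction coefficient is
numerically zero (|β| < 1e−10, flagged non-identifiable). The extended
window exists so that out-of-bounds optima remain representable — the
bounds check that gates the DS label needs them.

**Crossover interval.** Parametric bootstrap: resimulate the response from
the fitted model (fresh random intercepts and residuals), refit the linear
representation, collect ĉ* = −β̂*_G/β̂*_{G×E}, take the 2.5/97.5
percentiles (B = 500 by default; deterministic under a seed). Refits with a
numerically zero interaction are dropped; if they exceed 10% of B the CI is
flagged unreliable. Coverage of this percentile interval is checked by
simulation (≈ 0.95 under a well-identified weak DS regime).

**Model competition.** Six fits, lowest AIC wins; ties break toward fewer
parameters, then fixed-crossover before free-crossover (parsimony). A
differential-susceptibility winner is labelled "DS W"/"DS S" only when its
crossover CI lies inside the observed per-dataset min/max of E (the
*observed* bounds, not the theoretical 1–7 scale — the rating extremes are
often unused, and an interaction crossing outside the observed range has no
evidential support there). Otherwise it is reported as unclassified DS.
Note an intrinsic operating characteristic of AIC here: under a *strong*
truth the weak variant wins whenever the likelihood-ratio statistic for
s0 exceeds 2, which happens with probability P(χ²₁ > 2) ≈ 0.16 — so even
ideal data yield "DS S" only ~84% of the time, the rest splitting into
"DS W".

**Screening and correction.** The screening model for every
outcome × context × threshold cell includes the two ancestry PCs. FDR
(Benjamini–Hochberg, via statsmodels) is applied within each
outcome × context family across the four score thresholds; the
FDR-*adjusted* p gates the confirmatory stage. Before the competition the
PCs are re-tested in the screening fit and dropped when p ≥ .05
(covariate trimming); covariates always enter additively and are never
multiplied into (E − c).

**Polygenic scores.** Greedy clumping visits SNPs in ascending p (ties:
chromosome, position, id), keeps the visited SNP, and removes not-yet-kept
SNPs within ±1000 kb with r² ≥ 0.1, where r² is the squared Pearson
correlation of dosage vectors in the analysis sample itself (a desk-scale
substitution for an external reference panel; zero-variance SNPs tag
nothing and contribute r² = 0). Scoring uses strict p < τ, flips dosages to
2−dosage when the coded alleles are swapped, drops SNPs whose allele labels
match neither orientation, and mean-imputes missing dosages per SNP.
Scores are z-scored across subjects only at the modelling stage — the
stored profile keeps raw sums. Ancestry axes come from an SVD of the
column-standardized dosage matrix (PCA; signs fixed by making each
component's largest-magnitude loading positive).

## The generator

The generator is the package's stand-in for a one-week ESM protocol in a
non-clinical young-adult sample, with genotype and GWAS inputs to match.

* **Genotypes.** Equicorrelated latent-Gaussian blocks: within a block each
  haplotype thresholds a correlation-ρ Gaussian vector at the allele-
  frequency quantile; dosage = sum of two haplotypes. Dosage correlation is
  attenuated relative to ρ (thresholding), which tests account for by
  comparing against a Monte-Carlo oracle of the same scheme, not against ρ.
  Blocks sit ≥ 2000 kb apart so a clumping window never spans blocks.
  Realistic chromosome-scale LD maps are a non-goal.
* **Summary statistics.** A SNP is causal with probability `prop_causal`
  and reports β ~ N(0, beta_sd²); a null SNP reports pure sampling noise at
  its per-SNP standard error 1/√(n_gwas·2·maf(1−maf)). P-values are
  two-sided normal tails of β/SE — exactly uniform under the null, strictly
  decreasing in the standardized effect.
* **Schedules.** Eight signals/day in [600, 1320] minutes, consecutive gaps
  in [10, 170] min, drawn by rejection sampling of sorted uniforms
  (acceptance ≈ 16%, capped with a clear "impossible schedule" error).
* **Context.** Single-item appraisals from discretized Beta draws rescaled
  to 1–7: stressful ≈ Beta(0.25, 1.0) (mean ≈ 2.15, >50% at the floor),
  positive ≈ Beta(3.4, 1.3) (mean ≈ 5.35). Only the observed means/floor
  shares were targets; the true distributional form of momentary appraisals
  is unknown, so these are presets, not estimates. Context items carry no
  extra item noise: they *are* the environment that drives the regime.
* **Outcomes.** The target index follows
  y_{t+1} = b0 + u_i + (s0 + s1·G_i)·(E_t − c) + ε within days; the first
  beep of a day has no carry-over from the previous evening (matching the
  analysis restriction to within-day lags). Non-target indices are
  baseline + random intercept + noise, with baselines near observed
  person-mean levels (paranoia 1.2, PLE 1.1, negative-like 1.35, NA 1.5,
  PA 4.7) so symptom items show realistic floor effects. Items equal the
  latent index plus N(0, item_noise_sd²), rounded and clipped to 1–7; a
  continuous test mode (`round_items=False`) disables discretization so
  oracle checks can be exact. Defaults for the regime (s0 = −0.03,
  s1 = −0.02, c = 5.0, σ_u = 0.25, σ_e = 0.35 on paranoia vs the positive
  context) are of the order of the small standardized interactions such
  designs report.
* **Missingness.** Completion is Bernoulli per beep with a per-subject rate
  drawn from a Beta distribution with mean `compliance` (default 40.7/56)
  and SD `compliance_sd` (default 0.15): this reproduces both the ~40.7
  mean and the ~9 SD of completed questionnaires per person. Missingness is
  independent of everything else (MCAR); informative missingness is out of
  scope. `compliance_sd=0` restores a constant rate.

**What passing tests do not show.** The generator's data are Gaussian given
the regime, its LD is block-wise and exchangeable, its missingness is
ignorable, and the G driving the phenotype is the computed score itself.
Real data violate all four (ordinal skewed items, long-range LD, reactive
compliance, causal SNPs imperfectly tagged by the score), so recovery and
coverage results here certify the *estimator and selection machinery*, not
field performance on any particular cohort.

## Simulation sizes and numerical conventions

Recovery and coverage runs use 100 replicates of 300 subjects × ~42 pairs
(bootstrap B = 200); selection-rate runs 100 replicates of 150 subjects;
type-I runs 40 pipeline seeds of 100 subjects (1600 screened cells); the
acceptance script scales these to 40/50/20 replicates to finish in a few
minutes on one core. Those sizes put Monte-Carlo error well inside the
asserted bands. Recovery-type simulations run in continuous test mode with
a mid-scale baseline (b0 = 3) so floor-clipping does not bias the check —
the clipped regime is exercised separately by the pipeline-level tests.
Matrix rank is verified before every fit and rank deficiencies are reported
with the offending column names; tie-breaks (clumping order, AIC ties) are
total orders so all outputs are permutation-invariant and reproducible
byte-for-byte under a fixed seed.

## Known limitations

* Wald-normal inference can be mildly anti-conservative in small samples
  (few subjects); no small-sample df correction is offered.
* The percentile bootstrap interval for c is first-order; no BCa or
  profile-likelihood interval is implemented.
* The LD reference equals the analysis sample; with very small n this
  makes clumping noisy in ways an external panel would not be.
* Between/within index reliabilities use the classic two-level Cronbach
  decomposition (alpha over person-mean item scores; alpha over
  person-mean-centered item scores); multilevel SEM reliabilities (omega)
  are a non-goal, and reported reliabilities of real instruments need not
  match this decomposition.
* The pipeline's classification stage inherits the selection step:
  crossover estimates are reported only for FDR-significant cells and are
  subject to the usual winner's-curse inflation.
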