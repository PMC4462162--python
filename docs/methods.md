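# Methods

This note records the models, the numerical choices, and the design
decisions behind `famvar`, together with what the synthetic-data validation
does and does not demonstrate.

## Nested linear mixed model (lmm)

Model: `y = Xβ + Z_c u_c + Z_f u_f + e` with independent random intercepts
for centers (`σ²_c`) and families nested within centers (`σ²_f`), and
residual `σ²_e`.  Families are validated to be nested (a family spanning
two centers is an error).  The two-level variant (family only) is obtained
by omitting `center_ids`.

*Estimation.*  The covariance `V` of disjoint nested intercepts has a
closed-form inverse: a per-family Woodbury step
(`(σ²_e I + σ²_f J)⁻¹ = σ_e⁻²(I − σ²_f/(σ²_e + nσ²_f) J)`) followed by a
per-center rank-one update.  All REML quantities are therefore O(n) per
evaluation.  The restricted likelihood is profiled over the residual
variance and maximised over the log variance *ratios* with a coarse grid
start plus Nelder–Mead at tight tolerances (`xatol 1e-10`); with one or two
free ratios this reaches the REML optimum to well below the 1e-6 agreement
the balanced-ANOVA oracle test demands, without gradient code.  Ratios
driven below 1e-7 are treated as boundary estimates and refit with the
component removed.  The reported log-likelihood includes `+½log|X'X|`,
making it invariant to reparameterisations of the fixed-effect basis.

*Uncertainty.*  `varpar_cov` is the inverse negative numeric Hessian
(central differences, relative step 1e-4) of the REML log-likelihood in the
natural variance parameters; boundary components get zero rows.  The
residual ICC `σ²_f/(σ²_f+σ²_e)` takes a delta-method SE through this
matrix and a 95% CI on the logit scale (back-transformed; pinned to 0 at
the boundary).  An `include_center` flag switches to
`(σ²_c+σ²_f)/(σ²_c+σ²_f+σ²_e)`; the default conditions on center because
recruitment site is a nuisance grouping, not a source of sibling
resemblance.  The family-variance test refers `2Δloglik` to the 50:50
`χ²₀/χ²₁` mixture (null on the boundary), with the reduced model keeping
the center intercept.

## Negative-binomial GLMM with AGHQ (nbglmm)

Model: counts `y_ij | b_j ~ NB2(m_ij, α)`, `m_ij = exp(x'β + offset + b_j)`,
`b_j ~ N(0, σ²)`, NB2 variance `m + αm²` ("mean dispersion"); `α` and `σ²`
are optimised on the log scale and reported on the natural scale.  The
per-family integral over `b` uses adaptive Gauss–Hermite quadrature: a
vectorised Newton search finds each family's posterior mode and curvature
(the integrand is log-concave), and the integrand is evaluated at
`b̂ + √2·ĥ·t_k` for `n_quad = 7` Hermite nodes, accumulated with
log-sum-exp.  The recentring is recomputed at every objective evaluation.
Seven nodes reproduce a 51-node reference to better than 1e-4 in total
log-likelihood on the test fixtures; the node count is exposed for users
who want to verify convergence on their own data.

The outer optimisation is BFGS with finite-difference gradients, started
from a Poisson IRLS fit, a moment estimate of `α`, and `σ² = 0.2`.
`varpar_cov` is again a numeric-Hessian inverse, in `(β, ln α, ln σ²)`.

The Poisson GLMM is the `α → 0` limit (same machinery); the overdispersion
test and the family-variance test (against a plain NB2 GLM, also provided)
use the same boundary chi-bar mixture as above.  If the NB optimiser ends
below the Poisson likelihood (an `α → 0` boundary case), the Poisson
solution is taken as the NB fit, preserving the nesting inequality.

*Deviance residuals.*
`d = sign(y−m̂)·√(2[y ln(y/m̂) − (y+1/α̂) ln((1+α̂y)/(1+α̂m̂))])` with
`y ln(y/m̂) := 0` at `y = 0` and the Poisson deviance as the `α̂ → 0`
limit.  By default `m̂` uses fixed effects + offset only (population
averaged): the GREML consumers of these residuals are unrelated singletons
where no cluster effect is estimable.  `conditional=True` adds the cluster
posterior modes for family data.

## Count-data ICC (icc)

With marginal expectation `μ` (including the `e^{σ²/2}` log-normal
inflation), between-family variance is `μ²(e^{σ²}−1)` and total variance
`μ + αμ²e^{σ²} + μ²(e^{σ²}−1)`; their ratio is the sibling correlation of
episode rates.  Two conventions for `μ`: the model marginal
`exp(β₀ + offset + σ²/2)` (default, evaluated at `offset = 0`, i.e. per
unit exposure, making the ICC exposure-free) or the empirical mean observed
rate.  The ICC is exposure-scale dependent — longer exposures average away
Poisson noise and raise the observed-rate correlation — which is why the
default standardises to unit exposure and why the Monte-Carlo oracle
(sibling pairs sharing one intercept at equal exposure) is the arbiter of
correctness rather than any particular published point estimate, whose
exact exposure convention is not recoverable.  When a center variance is
supplied, siblings additionally share the center effect: the latent shared
variance becomes `σ²_f + σ²_c` with numerator `μ²e^{σ²_c}(e^{σ²_f}−1)`.

The delta-method SE propagates `(β₀, ln α, ln σ²)` uncertainty through the
closed form via a numeric gradient; CIs are logit-scale.  The model-free
`empirical_icc_counts` is a one-way ANOVA moment estimator (unequal family
sizes, Fisher's `n₀`) with an SE from the spread of 20 family-batch
estimates; it serves as the simulation oracle, not as an inference tool.

## Maximal heritability (heritability)

`COV_FS = ½V_A + ¼V_D + V_C`, `ICC = COV_FS/V_P`, `h²_max = min(2·ICC, 1)`.
CI bounds are transformed by the same doubling-and-clipping.  No attempt is
made to separate `V_D`/`V_C` from a single relative class — with only full
siblings the decomposition is unidentifiable, which is precisely why the
quantity is reported as an upper bound.

## GREML (greml, plinkio)

GRM: `A_jk = (1/M_jk) Σ_i (x_ij−2p_i)(x_ik−2p_i)/(2p_i(1−p_i))` over SNPs
non-missing in both individuals, frequencies estimated once on the full
input sample (before any pruning), MAF filter 0.01.  Pruning is greedy:
repeatedly drop the individual in the most pairs above the cutoff (ties by
input order) until no pair exceeds it; verified against exhaustive maximum
retained sets on small instances.  PCs are GRM eigenvectors scaled by
√eigenvalue with a largest-loading-positive sign convention.

AI-REML runs in the GRM eigenbasis (one `eigh` per fit; `V` diagonal
there), starting from `σ²_g = σ²_e = var(y)/2`, with average-information
steps, EM fallback whenever the AI step is infeasible or decreases the
restricted likelihood by more than 1e-4, components clipped at
`1e-8·var(y)`, and convergence when the log-likelihood changes by <1e-6
with a small gradient.  `se(ĥ²)` is a delta-method transform of the
inverse AI matrix; the `σ²_g = 0` test uses the boundary mixture, so
p ∈ (0, 0.5].

*Cutoff at desk scale.*  GRM off-diagonals among unrelated individuals
have sd ≈ `1/√M`.  The conventional cutoff 0.025 assumes dense panels
(M ~ 4×10⁵, sd ≈ 0.0015).  Desk-scale panels (M ~ 2×10³, sd ≈ 0.022) would
prune almost everyone at 0.025, so tests and examples that combine pruning
with estimation either use a dense simulated panel or raise the cutoff to
keep it at several noise sds — the role the default plays on real data.
The default config keeps 0.025.

PLINK bed (variant-major, magic `6c 1b 01`, two-bit codes LSB-first) and
the GCTA binary GRM triplet (float32 lower triangle, per-pair SNP counts,
FID/IID text) are coded directly from the published byte layouts.

## Power (power)

`var(ĥ²) = 2/(n²·var(A_jk))` with `var(A_jk) = 2×10⁻⁵` by default (the
standard value for dense common-SNP panels in European-ancestry samples;
use `1/M` for idealised independent-SNP panels).  Power uses the
noncentral-χ²₁ distribution with `NCP = h⁴/var(ĥ²)` against the two-sided
α critical value; `detectable_h2` inverts this.  Two-sided α = 0.05 is the
default because it reproduces the motivating study's detectable-h²
statement (0.255 at n = 3468, 0.374 at n = 2368); a one-sided
normal-approximation mode is exposed.

## Synthetic data (simulate)

The family generator emulates an affected-sibling recurrent-MDD study:
691 families of 2–5 siblings by default (size weights {2: .55, 3: .25,
4: .13, 5: .07} — the real sibship composition is unpublished, so these are
configurable), families assigned uniformly to 8 centers, ages truncated
normal (45 ± 12, range 18–75) with a within-family age correlation of 0.3
(siblings are interviewed at similar ages), sex ~ Bernoulli(0.68 female).

sqrt(AAO) follows the nested Gaussian model with defaults
`σ²_c, σ²_f, σ²_e = 0.05, 0.25, 0.65` (sibling ICC 0.278, matching the
moderate familial clustering such studies report) and intercept 5
(AAO ≈ 25 y).  AAO is floored at 5 y and capped at age − 0.5 y (onset
precedes interview; duration stays positive for the log offset).  The cap
binds for ~9% of subjects and attenuates the realised ICC by roughly one
sampling SE at 5000 families — the recovery tests bound this jointly with
Monte-Carlo error.  An optional `aao_beta_age` (default 0) couples AAO to
age for studying age-adjustment behaviour.

Episode counts are NB2 draws with log rate `−1.2` per year (≈ 0.3
episodes/year), `α = 0.6`, family variance 0.29 on the log scale (rate-scale
sibling ICC ≈ 0.084, the small clustering typical of episodicity), and
exposure = illness duration.  Recurrent ascertainment is emulated by
zero-truncation (resample until ≥ 1), toggleable; model-recovery tests
disable it so the fitted (untruncated) NB GLMM is the exact generative
model, while pipeline demos keep it on.

The genotype generator draws independent HWE SNPs (no linkage
disequilibrium, no population structure beyond optional planted subgroups
in tests) with a Gaussian-effects polygenic score scaled to the requested
`h²` and realised `h²` recorded.  Sibling pairs are built through simulated
parents (expected relatedness 0.5).  Consequently, passing tests show the
estimators are correct under their own assumptions at realistic parameter
values; they cannot show robustness to LD structure, ascertainment on
severity, genotyping artefacts, or informative missingness, none of which
are simulated.

All generators derive independent child streams from one root seed;
identical seeds give bit-identical tables.

## Problem sizes in the validation suite

Chosen as the smallest sizes at which each check is statistically sharp:
balanced ANOVA oracle at 20×5; AGHQ agreement on 30 families; AI-REML vs
dense grid at N = 50; Monte-Carlo ICC oracle at 2×10⁵ pairs per (σ², α)
cell; parameter recovery at 5000 families (both tracks) and N = 1000,
M = 2000 with 40 GREML replicates; boundary-LRT calibration at 500 null
replicates per test.

## Known limitations

* The LMM covers only the study's model shapes (nested intercepts, no
  slopes, no formula language).
* No zero-inflated/hurdle counts and no recurrent-event survival models;
  the NB model treats episodes as exchangeable given the family intercept.
* The GREML engine is single-GRM univariate; no partitioned or bivariate
  analyses, and no liability-scale transforms in the power module.
* Delta-method CIs for ICCs are first-order; near the `icc = 0` boundary
  they degenerate to the point estimate (the bootstrap cross-check in the
  test suite quantifies their accuracy away from the boundary).
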