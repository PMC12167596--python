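# Methods

`emsdfe` estimates the first two moments of the distribution of fitness
effects (DFE) of chemically induced mutations from zero-inflated,
plant-level fitness data, together with the evolutionary quantities derived
from them. This note records the model, the generative process the
synthetic-data module emulates, the numerical choices in the variational
fitter, and the limitations a user should keep in mind.

## The experiment the model describes

Two *Arabidopsis thaliana* accessions adapted differently to a common
field site (a high-fitness "COL-like" and a low-fitness "CV-like" founder)
are mutagenized with EMS; 20 and 16 mutant lines are founded from single
treated seeds. Each line selfs for two generations (M1, M2), is split into
two sublines (M3) to separate maternal from genetic effects, and selfs once
more; the M4 seedlings (60 per subline) are planted in the field in 12
blocks alongside 120-plant unmutagenized controls for these two founders
and for four reference accessions. Fitness is overwinter survival plus dry
biomass at senescence; a dead plant scores 0 mg. The default simulated
design therefore has 5,040 plants.

## Observation model

For plant *l* of subline *k*, line *j*, founder *i*, let

  s = y_i + m_ijk + h_ijkl + b_block

with founder genetic value y_i (log10 mg), subline maternal effect
m ~ N(0, sd_m²), block effect b ~ N(0, sd_b²), and mutational deviation h
(zero for control lines). The plant survives with probability

  p = 1 / (1 + exp(c·s + d)),      (c < 0: fitter genotypes survive more)

and, conditional on survival, log10 dry weight is N(s, eta_i²) with
founder-specific residual SD eta_i. Zeros enter the likelihood through the
1 − p mass, so survival and biomass are fitted jointly; the residual eps
affects only the weight of survivors, never survival.

## Mutational deviation: compound Poisson and its moments

Each EMS line receives P ~ Poisson(lambda) mutations (lambda = 25, an
external estimate, held fixed), each with effect e_m drawn from a
founder-specific DFE with mean mu_i and SD sigma_i. Under selfing a
mutation's dosage n follows the Markov chain on {0, 1, 2} with transitions
from the heterozygous state to {1/4, 1/2, 1/4} and absorbing ends, so
E[n] = 1 and E[n²] = 2 − 2⁻ᵍ after g generations (15/8 at g = 3; 87.5%
homozygosity). The plant-level deviation h = Σ n_m e_m is compound Poisson;
by the CLT it is approximately normal with mean lambda·mu and variance
E[n²]·lambda·(mu² + sigma²) regardless of the DFE's shape — this is what
makes the approach nonparametric in everything but the first two moments.

Because plants share pedigree, h is decomposed into three independent
normal terms whose variances follow from the dosage cross-moments
E[n n′] = 2 − 2^(−g_shared) (the shared ancestor's second moment, since
dosage is a martingale): at g = 3 the line, subline, and individual
components have variances 1.5, 0.25, and 0.125 times lambda(mu² + sigma²).
The line-level term carries the whole mean lambda·mu; any split of the mean
is observationally equivalent and this one keeps the lower terms centered.
All coefficients are computed by exact rational enumeration of the chain,
with the closed forms used as cross-checks, so arbitrary g works.

## Priors

Genetic values y_i: N(0, 10²) — effectively flat. DFE mean mu: N(0, 0.05²),
wide relative to the ~0.001–0.004 log10-mg scale of interest. Half-normal
priors on positive scales: sigma ~ HN(0.05), maternal and block SDs
~ HN(0.5), eta ~ HN(1.0). Survival curve: c ~ N(0, 5²), d ~ N(0, 10²).
lambda and g are fixed design constants, never estimated. The
per-generation spontaneous rate (0.16) enters only downstream.

## Variational inference

The posterior is approximated by a fully factorized Gaussian on an
unconstrained scale (positive parameters log-transformed), optimized by
stochastic gradient ascent on the evidence lower bound with
reparameterization gradients (2 Monte Carlo samples per step), Adam
(learning rate 0.02), and analytic gradients of the joint log density
(verified against finite differences in the test suite).

Three parameterization choices matter and were made deliberately:

1. **Non-centered random effects.** Latents are stored standardized; scales
   enter the likelihood as deterministic products. The centered form has a
   funnel geometry on which a factorized approximation is unstable — in
   development it inflated sigma several-fold by reallocating residual
   variance into the individual-level mutational term.
2. **EMS-level mean as a primary parameter.** The model carries
   w = y + lambda·mu (the mean of EMS lines) instead of mu. Controls pin y,
   EMS lines pin w, so the two are nearly independent a posteriori and the
   factorized approximation reports an honest SD for the derived
   mu = (w − y)/lambda; parameterized directly in (y, mu) the two are
   strongly correlated and mean-field understates Var(mu) severely.
3. **Group-centered latent fields.** Maternal, block, line and subline
   latents are centered within the groups whose mean freedom is confounded
   with y or w; the removed group-mean directions keep their N(0,1) priors
   and are reinstated when posterior draws are summarized. This returns the
   between-group variance (e.g. line-sampling variance V1/20) to the
   marginals of y, w and mu instead of silently conditioning on it.

Convergence is declared when the windowed (250-step) mean ELBO changes by
less than max(5·10⁻⁵ relative, 1 nat — the Monte Carlo noise floor) between
windows, after at least 4,000 steps; the cap is 16,000 steps (about half a
minute for the full 5,040-plant design on one CPU). Restarts are supported
(best final ELBO wins, ties to the lowest index); the default is one
restart because the moment-based initialization — control survivor means
for y, EMS survivor means for w, a founder-level logistic regression for
(c, d) — starts close to the mode. Posterior summaries come from 4,000
draws of the fitted approximation.

Known inferential limitations: mean-field VI still understates the
uncertainty of sigma (identified mainly from ~20 line-level variances, so
its posterior SD should be of order sigma·√(2/L); the reported SD is
several times smaller), and of eta to a lesser degree. The mu and y
marginals are approximately calibrated after the reparameterizations
above. Recovery tests therefore gate on mu, the headline estimand, and
tolerate occasional 2-sigma misses exactly as honest intervals must.

## Synthetic data

The simulator draws everything the model assumes — per-line Poisson
mutation counts, per-mutation effects from any of five DFE families (point
mass, normal, deleterious gamma, beneficial (reflected) gamma, two-normal
mixture, each with closed-form moments), explicit dosage paths through the
M2/M3/M4 pedigree, maternal/block/residual noise, and logistic survival —
so the inference can be tested end to end against known truth. Defaults
are the study conditions: the published point estimates as generative truth,
lambda = 25, g = 3, and the survival curve (c = −0.913, d = 2.594) solved
exactly from the two focal founders' control survival rates (0.51, 0.35).
Maternal and block SDs are not published; both default to 0.02 log10 mg,
consistent with the reported block-effect point estimates (−0.02 ± 0.02).
Blocks are assigned round-robin (balanced) by default; per-line random
substreams make generation reproducible and order-independent.

What the simulator does not emulate: linkage, dominance and epistasis
(assumed absent in the model too), somatic selection, genotype-by-
environment interaction beyond block effects, overdispersed mutation
counts, and any spatial structure within blocks. Passing recovery tests
therefore shows the estimator is correct under its own assumptions — not
that field data satisfy them.

## How normal is h, really?

`clt_diagnostic` samples h by brute force, standardizes it, and reports the
Kolmogorov–Smirnov distance to N(0, 1) next to a threshold calibrated on
exact-normal samples of the same size (99.9% null quantile by default).
At lambda = 25 the measured distances are 0.018 (normal effects), 0.023
(two-normal mixture), 0.032 (gamma families) and 0.052 (point mass, a
lattice distribution) with 10⁴ draws — all *above* the pure-sampling null
band (~0.012). This is a real property, not noise: conditional on the
dosage vector, h ~ N(mu·Σn, sigma²·Σn²), and Σn² varies with ~28%
coefficient of variation under Poisson(25) mutation counts, so h is a
slightly heavy-tailed scale mixture of normals. The deviation is therefore
*statistically detectable* at Monte Carlo resolution while being
*practically negligible* at the experiment's own resolution (a founder
contributes ~20 line-level values; the same distance is an order of
magnitude below the null quantile at that sample size). At lambda = 0.5
the approximation collapses outright (distance ≈ 0.25, dominated by the
atom at h = 0), which the diagnostic flags loudly. The test suite asserts
the strict Monte-Carlo-resolution form of this check and records the
outcome as-is.

## Derived quantities

V_m = 0.16·sigma² per generation (the spontaneous diploid genomic rate of
fitness-affecting mutations times the single-mutation variance; by printed
convention sigma² only, no dosage factor — the package reproduces the
convention rather than "fixing" it), h²_m = V_m/eta², V_g = sample variance
(n−1) of the six founder genetic values, generations to a target
heritability = target/h²_m, generations for the low founder's mutational
fitness distribution to overlap the high founder's mean
= (Δy)²/(4·V_m,low), and V_g/V_m ratios. Rounding conventions (3
significant figures, nearest hundred) are explicit arguments. Recomputing
the generation-count extrapolations from rounded point estimates cannot
reproduce unrounded-posterior results exactly; agreement within 10% is the
documented expectation.

## Classical statistics

Group summaries report survival rates and survivor-only log10-weight
moments. Line-versus-control comparisons use the exact multivariate-t
Dunnett many-to-one procedure (scipy), run twice: on zero-inflated fitness
scores (dead plants as 0) and on survivors only. Fisher's exact test for
albino silique counts is computed by direct hypergeometric enumeration and
cross-checked against an independent implementation in the tests.

## Problem sizes used in the checks

The automated checks use 5 simulated replicates of the full 5,040-plant
design for parameter recovery, 10⁵ lines for the covariance-split oracle,
10⁶ paths for the dosage-moment Monte Carlo, and 10⁴ draws (with 200
calibration replicates) for the CLT diagnostic — sizes chosen so each
stochastic check resolves its target to several standard errors while the
whole suite stays desk-scale.
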