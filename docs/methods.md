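# Methods

## Model

For two groups of WGBS samples, per CpG *i* (coordinate p_i), group *g*,
replicate *r*:

    y_igr | pi_igr      ~ Binomial(n_igr, pi_igr)
    logit(pi_igr) | mu  ~ N(mu_ig, sigma_g^2)          (replicate effect)
    mu_ig | mu_{i-1,g}  ~ N(mu_{i-1,g}, rho_ig^2)      (latent profile)
    rho_ig^2            = rho_g^2 * |p_i - p_{i-1}|
    sigma_g^-2, rho_g^-2 ~ Gamma(shape 0.1, rate 0.1)  (mean 1, var 10)

Each group is fitted independently with its own (sigma_g^2, rho_g^2); with
a single replicate the random-effect layer is collapsed (sigma_g^2 = 0)
and mu enters the binomial likelihood directly. Marginally the model is
logistic-normal with approximate count variance
n pi (1-pi) {1 + (sigma^2 + rho_i^2)(n-1) pi (1-pi)} — binomial variance
times an overdispersion factor combining replicate variability and the
field variance (`overdispersion_variance`).

The RW1 profile is intrinsic (its level is improper). We anchor it with a
weak precision eps = 1e-5 added to every mu diagonal rather than a
sum-to-zero constraint: this keeps the banded factorization trivial and
mimics a diffuse level prior. Results are insensitive for eps in
[1e-8, 1e-3]; the unit tests exercise the assembled precision against the
brute-force inverse of the generative covariance at eps = 1e-5.

Missing observations (a replicate without reads at a site) simply
contribute no likelihood term; sites with zero coverage in a group are
interpolated by the field. Distances enter in raw base pairs; an optional
`distance_cap` config truncates extreme gaps but is off by default.

## Inference

Deterministic, INLA-style, independently per genome chunk and group:

1. **Gaussian approximation.** The joint latents (replicate effects
   interleaved with their site's mu) have a banded prior precision
   (bandwidth 1 + max replicates per site). The posterior mode is found by
   damped Newton iterations with overflow-safe logistic terms; convergence
   at max |gradient| < 1e-6 (cap 50 iterations, failure is reported per
   chunk). Marginal variances of mu come from banded selected inversion
   (Takahashi recursion) of the curvature precision — exact marginals of
   the Gaussian approximation, not samples.
2. **Hyperparameter marginal.** log p(theta | y) is approximated by the
   Laplace identity log p(y|x^) + log p(x^|theta) + log p(theta) −
   log p~_G(x^|y,theta), which reduces to half log-determinants of the
   prior and curvature precisions. Unit tests verify it against dense
   latent-grid cubature within 0.1 nats.
3. **Grid integration.** The mode of log p(theta | y) in log-precision
   coordinates is located by Nelder–Mead from (0, 0); a finite-difference
   Hessian standardizes the axes and an axis-aligned grid of step 0.75 SD
   is extended per direction until the log-density drops by 3 (cap 6
   steps). Weights are normalized densities (equal-volume cells). On
   optimizer failure a fixed 7x7 grid over log-precision [-4, 4]^2 is used
   with a warning. We use the plain Gaussian latent marginals (not the
   simplified/full Laplace per-marginal corrections) — standard for
   binomial models with replicates, and it keeps every step checkable
   against dense oracles.
4. **Posterior profiles.** Per grid point, E(pi_ig | y) and
   E(pi_ig^2 | y) are computed by 20-node Gauss–Hermite quadrature of the
   inverse logit under the Gaussian marginal of mu_ig, then mixed over
   grid weights. d_i = E(pi_i1|y) − E(pi_i2|y).

Chunks are independent blocks of the precision matrix, so a genome-wide
run is bitwise identical to concatenating per-chunk runs (tested); failed
chunks yield missing profiles rather than aborting.

### Preprocessing

CpGs covered (total reads > 0) in fewer than 50% of all samples are
removed; sites at exactly 50% are kept. The genome is split into chunks
wherever the gap to the previous CpG exceeds 3000 bp (strict inequality)
or the chromosome changes.

## FDR procedure

Once the field is integrated out the d_i are treated as marginally
independent and modeled by a three-component truncated-normal mixture on
[-1, 1]: null center fixed at 0, component order theta_- < 0 < theta_+,
and pi_0 >= pi_- + pi_+ enforced by projection (scale the alternative
weights down, renormalize) after each M-step. EM details:

- E-step with exact truncated-normal densities; the M-step updates
  weights in closed form and each center/SD by golden-section maximization
  of the weighted truncated-normal likelihood expressed through sufficient
  statistics (the truncation normalizer has no closed-form M-step).
- Initialization pi = (0.1, 0.8, 0.1), theta_± = ± the 90th percentile of
  |d|, all SDs = sd(d); 10 restarts with seeded multiplicative jitter, the
  best final likelihood wins.
- Convergence when the mean per-sample log-likelihood increment falls
  below `tol` (default 1e-8, the sklearn.mixture convention); an update
  that would lower the log-likelihood beyond 1e-10 is rejected and the fit
  stops there, so the accepted trace is monotone by construction.
- Fewer than 30 points or all-identical d raise informative errors.

The local FDR of CpG i is P(z_i = "0"); the global FDR of calling
|d_i| >= t is the mean local FDR over the two tails (0 on empty tails, by
logged convention). The chosen t is the smallest observed |d| > 0 whose
estimated FDR is <= the target — maximizing calls subject to the bound;
lowering the target can only shrink the call set. An optional
per-chromosome mode fits mixture and threshold per chromosome and pools
the calls; chromosomes with < 30 usable CpGs fall back to the genome-wide
fit.

DMRs are maximal runs, within one chunk, of consecutive significant CpGs
with |d_i| >= 0.33 and a common sign, kept when >= 5 CpGs long. The
effect-size filter applies per member CpG (stricter and deterministic,
rather than to the region mean), runs never span chunk breaks, and sign
coherence is required because direction-mixed regions are biologically
incoherent. Defaults (5 CpGs, 33%, 5% FDR) are the conventional calling
rule and are all configurable.

## Simulator

The benchmark generator deliberately does not draw from the inference
model. Per dataset:

- **Positions**: 1-based, geometric gaps with mean 100 bp.
- **Baseline**: a two-state methylated/unmethylated Markov chain
  (stay-probability 0.97) shared by both groups, emitting methylation
  probabilities p_high = 0.8 / p_low = 0.2. These emission values are our
  own defaults, chosen so that shifts up to delta_meth = 0.7 stay inside
  [0, 1] after clipping.
- **True DMRs**: intervals of length 9 + Geometric(0.12) CpGs (median 15)
  placed without overlap, total CpG span capped at 5% of the sequence
  (never above 20%); within each interval one randomly chosen group's
  probability is shifted by delta_meth toward the opposite state. Exactly
  the in-DMR CpGs are labeled true.
- **Noise**: eps ~ N(0, s0^2) added on the logit scale, one draw per site
  per group, shared across that group's replicates (a per-replicate
  option exists, off by default). `calibrate-noise` reports the induced
  probability perturbation by Monte Carlo.
- **Switching**: with probability delta per CpG the two groups' (noisy)
  probabilities are swapped for all replicates. Switched sites are NOT
  added to the truth labels: delta models methylation-call error the
  methods must survive, not signal.
- **Reads**: n_igr ~ Poisson(lambda) (optionally resampled from an
  empirical depth pool), y_igr ~ Binomial(n_igr, pi_irg); zero depths are
  recorded as missing. Truth never enters the count files.

The benchmark grid crosses replicates {1,2,3}, depth {10,30}, s0
{0.1,0.2,0.3}, delta_meth {0.2,0.3,0.5,0.7} and delta {0,0.05,0.1} — 216
combinations, five seed-distinct datasets of 5000 CpGs each (5.4M CpGs).

What the simulator does **not** emulate: strand asymmetry, non-CpG
contexts, bisulfite non-conversion (subsumed by delta), coverage
correlation along the genome, and batch effects. Passing benchmarks
therefore demonstrate correct behavior under controlled misspecification
(HMM truth vs. random-walk model), not performance on any real tissue.

## Benchmark metric

Evaluation is CpG-wise: every detected in-DMR CpG is a true positive,
every detected out-of-DMR CpG a false positive. The default ranking score
for our caller is 1 − P(z_i = "0") with |d_i| as a vanishing additive
tie-break (the choice of score is ours; any per-CpG score table is
accepted). ROC curves group tied scores; the partial AUC integrates the
curve by trapezoids over FPR in [0, 0.25] (specificity >= 0.75) and is
reported unnormalized (max 0.25; chance level 0.03125), with a normalized
variant behind a flag. Method comparison reports the argmax-pAUC method
per dataset and flags ties within 1% relative pAUC (we read the ±1% tie
rule as relative).

## Problem sizes and determinism

The test suite runs the full pipeline at 500–5000 CpGs, the null-FDR
check over 20 seeded datasets of 5000 CpGs (single replicate), recovery
at m = 500 with 3 replicates, and pAUC monotonicity over 10 seeds at 2000
CpGs — sizes at which every check completes on one CPU in minutes while
leaving the estimators in their asymptotic regime. All randomness flows
from explicit seeds; inference itself is deterministic, and seeds only
affect simulation and the EM restarts.

## Known limitations

- The Laplace/Gaussian marginal strategy slightly biases extreme-count
  sites relative to exact (MCMC) posteriors; the dense-oracle tests bound
  the approximation error of the implementation, not of the strategy.
- The hyperparameter posterior mean of sigma^2 is noisy at small m; the
  factor-of-two recovery contract reflects that spread.
- Beta-binomial observation models, covariates in the linear predictor,
  separate-class combination of per-chromosome FDRs, BIC-selected extra
  mixture components and kernel-density alternatives for the non-null
  density are out of scope.
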