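# Methods

## The model

`vitalcorr` estimates population-level temporal correlations among
demographic parameters (vital rates) from multi-state capture-recapture
data. Each marked individual *i* is taken through four sequential annual
layers, conditional on its latent state:

- **Survival** — juvenile (first-year) survival
  `Alive_{i,t} ~ Bernoulli(logit^-1(mu_Phi + alpha_{t,Phi_j}))`, and adult
  survival
  `Alive_{i,t} ~ Bernoulli(logit^-1(mu_Phi + f_Phi(age) + gamma_Phi·BS_{i,t-1} + alpha_{t,Phi_ad}))`.
  All individuals of age one and older share a single temporal effect
  (`alpha_{t,Phi_ad}`), which keeps the temporal variance-covariance
  structure comparable across species with different age structures.
- **Breeding** — `Breed ~ Bernoulli(logit^-1(mu_psi + f_psi(age) + gamma_psi·BS + alpha_{t,psi}))`,
  conditional on survival.
- **Success** — at least one offspring raised:
  `Success ~ Bernoulli(logit^-1(mu_pi + ...))`, conditional on breeding.
- **Productivity** — offspring per successful attempt, one of three
  zero-truncated families: Bernoulli on "more than one offspring" (logit
  link), normal truncated at 0 (identity link, residual SD `sigma_Omega'`),
  or Poisson truncated at 0 (log link).

Detection is a fifth Bernoulli layer
(`logit^-1(mu_p + f_p(age) + gamma_p·BS_t + alpha_{t,p})`) whose year effect
is independent of the vital-rate effects.

The year effects of the K active vital rates are jointly multivariate
normal on the link scale, `alpha_t ~ MVN(0, Sigma)`, shared by all
individuals; the quantity of interest is the correlation
`r_XX' = cov_XX' / (sigma_X sigma_X')`. Two pairing conventions are
supported: type 1 pairs reproduction in year t with survival over (t-1, t];
type 2 shifts the survival equations one year so reproduction in year t is
paired with survival over (t, t+1]. Under type 2 the last survival interval
has no paired reproduction year; its year-effect row is constrained only by
the prior, so no transitions are dropped and the correlation is identified
by the T-1 paired years.

Rates not modelled for a given species (e.g. breeding probability in
species where essentially every adult breeds, or productivity where litter
size is fixed at one) are held at their degenerate constants (probability
1, single offspring) and carry no temporal effect.

## Likelihood

The four layers plus detection define a hidden Markov chain over five
latent states (pre-breeder where configured, non-breeder, failed breeder,
successful breeder, dead). The likelihood conditions on first capture
(known entry year and state) and marginalises all latent paths by the
forward recursion; the observation model assumes states and counts are
recorded without error when an individual is detected, contributes `1-p`
for live non-detections and 1 for dead ones, and multiplies in the
productivity mass of any recorded count. Offspring counts enter as recorded
positive integers; the truncated-normal density is evaluated at the
recorded integer with the 0-truncation renormalisation constant.

Two implementations coexist: a readable pure-Python forward recursion
(`model_core.forward_loglik`) and a numba kernel used by the sampler. The
kernel computes a shared table `chi[t, state, age]` — the probability of
never being detected after year t — by backward recursion, so each
individual's forward pass only spans its detected years; identical observed
histories are collapsed into weighted records. Tests pin the kernel to the
pure-Python recursion to 1e-9 and the recursion itself to brute-force
path enumeration to 1e-10.

## Priors and sampler

- Intercepts: Normal(0, 1.5^2) on the link scale; age and breeding-state
  effects: Normal(0, 1); detection-effect scale sigma_p: half-Normal(0, 1).
- Covariance: expanded Cholesky factorisation `Sigma = Lambda Lambda^T`
  with independent Normal(0, 1) priors on the free lower-triangular
  loadings. Every Sigma draw is positive semi-definite by construction.
  The working-deviate/expansion-scale machinery that makes this prior
  convenient for conditionally-conjugate Gibbs samplers is marginalised
  analytically here: our sampler updates the centred year effects and the
  loadings directly, which targets the identical posterior on Sigma.

Sampling is an adaptive Metropolis-within-Gibbs scheme compiled with
numba: scalar random-walk updates for each fixed effect, joint (K+1)-dim
updates of each year's vital-rate and detection effects, cheap data-free
updates of the loadings (several sweeps per iteration), and three
non-trivial moves that break the funnel geometry of the centred
parameterisation:

1. **Translations** — shift an intercept and counter-shift its year-effect
   column; linear predictors are invariant so only priors decide.
2. **Rescalings** — scale a year-effect column jointly with its loading
   row (and analogously alpha_p with sigma_p); the MVN prior term cancels
   against the Jacobian.
3. **pCN column refreshes** — propose a whole year-effect column from a
   Crank-Nicolson blend with its conditional prior given the other
   columns; the acceptance probability reduces to the data-likelihood
   ratio, so weakly identified columns regenerate wholesale.

Proposal scales adapt by Robbins-Monro only during burn-in (target
acceptance 0.44 scalar / 0.28-0.30 block), leaving a valid fixed-kernel
chain afterwards. Chains are reproducible for a fixed seed. Correlation
and SD draws are derived per iteration from the sampled factor
(`r = cov/(sigma sigma')`), never from point estimates. Convergence is
monitored with the Gelman-Rubin statistic on all intercepts, effects,
scales and correlations (year effects excluded: numerous and individually
weakly identified); any R-hat > 1.1 raises a warning and is recorded in
the fit metadata rather than silently dropped. The default long-run
settings are 3 chains x 10,000 iterations (burn-in 2,000, thinning 5);
recovery experiments use the reduced settings below.

## Synthetic data

The generator (`synthetic_data`) draws year effects from the configured
MVN, then simulates every individual through the same five layers the
likelihood assumes — it is the generative mirror of the model, with known
truth for recovery tests. Design choices:

- Recruitment is a constant number of newly marked juveniles (age class 0)
  per year; real studies mark individuals at staggered ages, but constant
  juvenile cohorts are the simplest design that identifies all parameters.
- First-year transitions use reference levels of the age and
  breeding-state terms (the previous breeding state is undefined before
  the first possible reproduction).
- A single integer seed keys one counter-based (Philox) generator with a
  deterministic sub-stream per individual, so datasets are identical no
  matter how generation is parallelised or reordered.
- Truncated-normal productivity draws stay continuous internally; output
  files record the nearest positive integer, because observed productivity
  is an offspring count.

What the generator does **not** emulate: individual heterogeneity beyond
age and state, density dependence, spatial structure, state
misclassification, or trap response. Passing recovery tests therefore
demonstrates correctness of the estimator under the model's own
assumptions, not robustness to their violation in field data.

## Study designs and problem sizes

The reference recovery design (`study.three_rate_design`) is a mid-pace
bird life cycle: juvenile survival 0.5, adult survival 0.8, reproductive
success 0.5, detection 0.9, temporal SDs 0.4 on the logit scale,
r(Phi_j, Phi_ad) = 0.6 and r(Phi_ad, pi) = 0.4 over T = 30 years. The
correlation between juvenile survival and success is not part of the
design brief; we complete the matrix with the single-factor product
0.6 x 0.4 = 0.24, the most parsimonious positive-definite completion. The
detection-effect SD is set to 0.3, a mid-range value for long-term bird
studies.

Cohort sizes and chain lengths are chosen so a complete recovery
experiment (simulate, fit three chains, summarise) runs in well under a
minute on one core: 72 recruits/year (about 185 detectable individuals per
year at equilibrium) with 3 x 1,400 iterations for recovery replicates,
25 recruits/year with 3 x 1,000 iterations for the null-calibration
replicates, and 35 recruits/year with two 3 x 1,100-iteration fits for the
pairing-type contrast. At these sizes the posterior for a single
correlation is wide (posterior SD roughly 0.2-0.3) — consistent with the
general observation that short series underestimate absolute correlation
magnitudes — but sign recovery and +-0.3 mean accuracy hold with margin.

## Cross-species synthesis

Grand means are formed draw-wise: each contributing species' correlation
posterior is deterministically brought to a common draw count (even
thinning when longer, seeded bootstrap when shorter; 3,000 draws by
default), and draw d of the grand mean is the across-species average of
draws d. Because species posteriors are independent, any index pairing is
valid; fixing it makes the procedure reproducible. Species lacking a
parameter pair are excluded from that pair's grand mean and the
contributing count is reported. Type-1 vs type-2 contrasts are differences
of independently fitted posteriors paired by draw index.

## Generation time and the pace-of-life regression

Generation time is computed from a pre-breeding-census, female-based
age-structured projection matrix built from posterior-mean vital rates:
fecundity entries `f_a = psi_a pi_a Omega_a rho Phi_juv` (with `rho` the
daughters-per-offspring factor, default 0.5 and configurable — the census
convention and rho are design choices, exposed rather than hidden) and the
adult survival rates on the subdiagonal with a terminal self-loop. With
dominant eigenvalue lambda, stable age structure w and reproductive values
v (normalised to v·w = 1), generation time is the inverse of the summed
elasticities of lambda to the fecundity components,
`T = 1 / sum_F (f_ij/lambda) v_i w_j`, equivalently
`lambda (v·w)/(v F w)`. Tests verify this against an independent
finite-difference elasticity oracle on random Leslie matrices and the
scalar closed form T = (f+s)/f.

The correlation-vs-pace regression propagates posterior uncertainty by
fitting an ordinary least-squares line of species correlation draws on
fixed generation-time point estimates, one line per aligned draw; the
slope posterior is summarised by its mean and sign probability P, and R^2
is reported at posterior means. No phylogenetic correction is applied.

## Numerical choices and degenerate inputs

- Forward messages are renormalised every year; a zero normaliser (an
  impossible observation under the current parameters) returns -inf and
  the sampler rejects.
- The MVN row density uses forward substitution on the (possibly
  negative-diagonal) factor; |diagonal| < 1e-12 is treated as -inf.
- Zero-variance covariance structures are legal in the generator (exact
  zero effects); correlation draws with a zero SD are excluded from
  r = cov/(sigma sigma') with a warning.
- Reducible or imprimitive projection matrices raise warnings (non-unique
  dominant eigenvalue) or errors (complex leading eigenvalue, zero
  fecundity).
- The P statistic of an exactly-zero posterior mean is reported as 0.5.

## Known limitations

- The reference sampler is a random-walk scheme: effective sample sizes
  per iteration are far below a gradient-based sampler's, and individual
  fits at the reduced test sizes can flag R-hat values above 1.1 for the
  weakly identified juvenile-survival variance components. The flags are
  reported honestly in the fit metadata; recovery accuracy at the tested
  sizes is unaffected.
- Likelihood conditioning on first capture means entry/recruitment rates
  are not modelled.
- Unknown-age adults are not supported by the simulator (all recruits
  enter as juveniles); the likelihood would assign them the terminal age
  class.
- Grand means weight species equally, matching draw-wise averaging; no
  meta-analytic random-effects model is attempted.
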