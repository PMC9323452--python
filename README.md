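# vitalcorr

Temporal correlations among demographic parameters from multi-state
capture-recapture data.

Long-term individual monitoring lets ecologists ask whether the good and
bad years of different vital rates — juvenile survival (Φj), adult survival
(Φad), breeding probability (ψ), breeding success (π) and productivity (Ω)
— coincide at the population level. `vitalcorr` implements the full
pipeline for that question: simulation of capture histories with known
truth, a hidden Markov likelihood that handles imperfect detection,
Bayesian estimation of the temporal variance-covariance matrix of the year
effects, cross-species synthesis of the fitted correlations, and the
relationship between correlations and a species' pace of life.

## Model

Each individual-year decomposes into sequential Bernoulli/count layers on
link scales, e.g. adult survival

    Alive_it | Alive_i,t-1 ~ Bernoulli( logit^-1( μ_Φ + f_Φ(age) + γ_Φ·BS_i,t-1 + α_t,Φad ) )

with analogous equations for breeding, success, productivity
(zero-truncated Bernoulli/normal/Poisson families) and detection. The year
effects of the active vital rates are shared by all individuals and jointly
multivariate normal,

    (α_t,Φj, α_t,Φad, α_t,ψ, α_t,π, α_t,Ω) ~ MVN(0, Σ),     r_XX' = cov_XX' / (σ_X σ_X'),

so the correlations r_XX' are population-level quantities. Reindexing the
survival effects by one year switches between correlating reproduction
with *preceding* (type 1) or *subsequent* (type 2) survival. The
likelihood marginalises the latent alive/breeding states with a forward
recursion conditioned on first capture; the posterior is sampled with an
adaptive Metropolis-within-Gibbs sampler (numba-compiled) under a
parameter-expanded Cholesky prior on Σ. Generation time — the pace-of-life
axis — comes from age-structured projection matrices as the inverse of the
summed fecundity elasticities of λ.

See `docs/methods.md` for the full model, priors, sampler moves and design
choices.

## Worked example

Simulate 30 years of a mid-pace bird life cycle (Φj = 0.5, Φad = 0.8,
π = 0.5, detection 0.9; temporal SDs 0.4 with r(Φj,Φad) = 0.6 and
r(Φad,π) = 0.4) and re-estimate the correlation structure:

```python
from vitalcorr import study, summarize

vr, cov, config = study.three_rate_design()
histories, effects = study.simulate_design(vr, cov, config, n_years=30,
                                           recruits_per_year=40, seed=11)
draws = study.fit_design(histories, config, seed=11)   # 3 chains x 1300 iters
table = summarize(draws)
print(table[table.parameter.str.startswith(("r_", "sigma"))].round(3))
```

Output (about 20 s on one core; 1,160 individuals):

```
     parameter   mean    sd   q2.5  q97.5     P  rhat
   sigma_phi_j  0.390 0.101  0.204  0.603 1.000 1.011
  sigma_phi_ad  0.445 0.106  0.266  0.695 1.000 1.001
      sigma_pi  0.381 0.086  0.236  0.570 1.000 1.009
r_phi_j_phi_ad  0.545 0.238  0.029  0.941 0.978 1.021
    r_phi_j_pi -0.070 0.286 -0.588  0.509 0.611 1.018
   r_phi_ad_pi  0.406 0.265 -0.155  0.844 0.918 1.048
       sigma_p  0.244 0.141  0.010  0.520 1.000 1.008
```

The temporal SDs (truth 0.4) and the two designed correlations (0.6 and
0.4) are recovered; the Φj–π entry tracks the realised 30-year sample
correlation of this particular draw of year effects (−0.03) rather than
the long-run 0.24 — with 30 years the realised correlation itself scatters
widely around the generating value, which is why posterior intervals for
single-population correlations stay wide. `P` is the proportion of
posterior draws sharing the sign of the posterior mean; `rhat` the
Gelman–Rubin statistic (≤ 1.1 taken as converged).

A command-line interface mirrors the library:
`vitalcorr simulate | fit | correlate | grandmean | tally | gentime | metareg`.

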