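"""Independent oracles used by the test suite.

The enumeration oracle computes a capture-history likelihood by summing the
probability of every latent state path explicitly — no forward recursion —
so it checks the marginalisation logic of the model.  The closed-form oracle
covers the certain-detection case, where the likelihood factorises into the
sequential Bernoulli/count layers along the (fully observed) path.
"""

import itertools
import math

import numpy as np

from vitalcorr.model_core import (DEAD, LIVE_STATES, NON_BREEDER,
                                  SUCCESSFUL_BREEDER, ModelConfig, StateSpace,
                                  annual_rates, detection_prob,
                                  productivity_logpmf, transition_matrix)
from vitalcorr.synthetic_data import (CovarianceStructure, VitalRateModel,
                                      draw_temporal_effects, simulate_population)


def enumeration_loglik(history, vr, effects, config) -> float:
    """Sum over all latent state paths consistent with the observations."""
    T = effects.n_years
    space = StateSpace(config.has_pre_breeder)
    e = history.entry_year
    recs = {r.year: r for r in history.records}
    years = list(range(e + 1, T))
    s0 = history.entry_state_index(config)
    total = 0.0
    for path in itertools.product(range(5), repeat=len(years)):
        prob = 1.0
        prev = s0
        for t, s in zip(years, path):
            age = min(t - e, config.max_age)
            rates = {o: annual_rates(vr, effects, t, age, o, config)
                     for o in LIVE_STATES}
            M = transition_matrix(rates, space)
            prob *= M[prev, s]
            if prob == 0.0:
                break
            rec = recs.get(t)
            detected = rec is not None and rec.detected
            if detected:
                if s == DEAD or rec.state_index() != s:
                    prob = 0.0
                    break
                prob *= detection_prob(vr, effects, t, age, s, config)
                if s == SUCCESSFUL_BREEDER and rec.offspring_count is not None:
                    fam = config.productivity_family if config.is_active("omega") else None
                    prob *= math.exp(productivity_logpmf(
                        max(1.0, round(rec.offspring_count)), rates[s].omega,
                        fam, vr.sigma_omega_resid))
            else:
                if s != DEAD:
                    prob *= 1.0 - detection_prob(vr, effects, t, age, s, config)
            prev = s
        total += prob
    return math.log(total) if total > 0 else -math.inf


def full_observation_loglik(history, vr, effects, config) -> float:
    """Closed-form likelihood under certain detection and full observation:
    the product of the survival/breeding/success/productivity layers along
    the observed path, with an extra death term if the individual vanished
    before the final year."""
    T = effects.n_years
    space = StateSpace(config.has_pre_breeder)
    e = history.entry_year
    recs = {r.year: r for r in history.records if r.detected}
    last = max(recs)
    ll = 0.0
    prev = history.entry_state_index(config)
    for t in range(e + 1, last + 1):
        age = min(t - e, config.max_age)
        rec = recs[t]
        s = rec.state_index()
        r = annual_rates(vr, effects, t, age, prev, config)
        ll += math.log(r.phi)
        if config.is_active("psi"):
            bred = s in (2, 3)
            ll += math.log(r.psi if bred else 1.0 - r.psi)
        if config.is_active("pi") and s in (2, 3):
            ll += math.log(r.pi if s == 3 else 1.0 - r.pi)
        if s == 3 and rec.offspring_count is not None and config.is_active("omega"):
            ll += productivity_logpmf(max(1.0, round(rec.offspring_count)), r.omega,
                                      config.productivity_family,
                                      vr.sigma_omega_resid)
        prev = s
    if last < T - 1:
        age = min(last + 1 - e, config.max_age)
        r = annual_rates(vr, effects, last + 1, age, prev, config)
        ll += math.log(1.0 - r.phi)
    return ll


def random_psd_corr(rng, k):
    A = rng.standard_normal((k, k + 2))
    S = A @ A.T + 0.1 * np.eye(k)
    d = 1.0 / np.sqrt(np.diag(S))
    return S * np.outer(d, d)


def random_instance(seed, max_years=4, fixed_p=None):
    """A small random model + simulated histories for oracle comparisons."""
    rng = np.random.default_rng(seed)
    T = int(rng.integers(3, max_years + 1))
    family = [None, "bernoulli_extra_offspring", "truncated_normal",
              "truncated_poisson"][rng.integers(0, 4)]
    active = ["phi_j", "phi_ad"]
    if rng.random() < 0.5:
        active.append("psi")
    if rng.random() < 0.7:
        active.append("pi")
    if family is not None:
        active.append("omega")
    has_pb = bool(rng.random() < 0.3)
    gamma = set()
    if rng.random() < 0.5:
        gamma.add("phi")
    if rng.random() < 0.3 and fixed_p is None:
        gamma.add("p")
    mu = {"phi": rng.uniform(-0.5, 1.5), "p": rng.uniform(0.0, 2.0)}
    bs = {}
    if "psi" in active:
        mu["psi"] = rng.uniform(0.0, 2.0)
    if "pi" in active:
        mu["pi"] = rng.uniform(-1.0, 1.0)
    sig_om = None
    if family == "bernoulli_extra_offspring":
        mu["omega"] = rng.uniform(-1.0, 1.0)
    elif family == "truncated_normal":
        mu["omega"] = rng.uniform(1.0, 3.0)
        sig_om = rng.uniform(0.5, 1.0)
    elif family == "truncated_poisson":
        mu["omega"] = rng.uniform(0.0, 1.2)
    if "phi" in gamma:
        bs["phi"] = {2: rng.uniform(-0.5, 0.5), 3: rng.uniform(-0.5, 0.5)}
    if "p" in gamma:
        bs["p"] = {2: rng.uniform(-0.5, 0.5), 3: rng.uniform(-0.5, 0.5)}
    vr = VitalRateModel(mu=mu, age_effects={"phi": {1: rng.uniform(-0.5, 1.0)}},
                        bs_effects=bs, productivity_family=family,
                        sigma_omega_resid=sig_om, active_params=tuple(active))
    config = ModelConfig(active_params=tuple(active), productivity_family=family,
                         gamma_params=frozenset(gamma),
                         correlation_type=int(rng.integers(1, 3)),
                         has_pre_breeder=has_pb, fixed_p=fixed_p)
    active = config.active_params
    cov = CovarianceStructure(param_order=active,
                              sigma=rng.uniform(0.0, 0.6, len(active)),
                              corr=random_psd_corr(rng, len(active)),
                              sigma_p=rng.uniform(0.0, 0.4))
    effects = draw_temporal_effects(cov, T, seed=int(rng.integers(0, 2 ** 31)))
    histories = simulate_population(vr, cov, effects, recruits_per_year=2,
                                    n_years=T, seed=int(rng.integers(0, 2 ** 31)),
                                    config=config)
    return vr, cov, config, effects, histories
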