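"""Deterministic probability machinery: links, rates, transitions, forward HMM."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import enumeration_loglik, full_observation_loglik, random_instance
from vitalcorr.model_core import (DEAD, FAILED_BREEDER, NON_BREEDER, PRE_BREEDER,
                                  SUCCESSFUL_BREEDER, ModelConfig, ModelError,
                                  Rates, StateSpace, annual_rates,
                                  apply_correlation_type, dataset_loglik,
                                  forward_loglik, inverse_link, logit,
                                  observation_probs, productivity_logpmf,
                                  survival_effect_row, transition_matrix)
from vitalcorr.synthetic_data import (Record, TemporalEffects, VitalRateModel,
                                      IndividualHistory)


# ---------------------------------------------------------------------------
# links and densities
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, link, expected", [
    (0.0, "logit", 0.5),
    (0.0, "log", 1.0),
    (1.3862943611198906, "logit", 0.8),
    (2.5, "identity", 2.5),
])
def test_inverse_link(x, link, expected):
    assert inverse_link(x, link) == pytest.approx(expected, abs=1e-12)


def test_inverse_link_rejects_unknown():
    with pytest.raises(ModelError):
        inverse_link(0.0, "probit")


def test_truncated_poisson_pmf_matches_renormalised_poisson():
    lam = 2.0
    for c in (1, 2, 5):
        expected = stats.poisson.pmf(c, lam) / (1 - stats.poisson.pmf(0, lam))
        got = math.exp(productivity_logpmf(c, lam, "truncated_poisson"))
        assert got == pytest.approx(expected, rel=1e-12)
    assert productivity_logpmf(0, lam, "truncated_poisson") == -math.inf


def test_truncated_normal_density_matches_scipy():
    loc, sd = 1.5, 0.8
    dist = stats.truncnorm(a=(0 - loc) / sd, b=np.inf, loc=loc, scale=sd)
    for c in (1.0, 2.0, 3.0):
        got = math.exp(productivity_logpmf(c, loc, "truncated_normal", sd))
        assert got == pytest.approx(dist.pdf(c), rel=1e-10)


def test_bernoulli_extra_offspring_family():
    q = 0.3
    assert math.exp(productivity_logpmf(1, q, "bernoulli_extra_offspring")) == \
        pytest.approx(0.7, rel=1e-12)
    assert math.exp(productivity_logpmf(2, q, "bernoulli_extra_offspring")) == \
        pytest.approx(0.3, rel=1e-12)


# ---------------------------------------------------------------------------
# annual rates
# ---------------------------------------------------------------------------

def _zero_effects(config, T=5):
    return TemporalEffects(alpha=np.zeros((T, config.n_effects)),
                           alpha_p=np.zeros(T), param_order=config.active_params)


def test_annual_rates_all_zero_intercepts_give_half():
    config = ModelConfig(age_cuts={"phi": ()}, productivity_family=None,
                         active_params=("phi_j", "phi_ad", "psi", "pi"))
    vr = VitalRateModel(mu={"phi": 0.0, "psi": 0.0, "pi": 0.0, "p": 0.0},
                        productivity_family=None,
                        active_params=config.active_params)
    r = annual_rates(vr, _zero_effects(config), year=2, age=3,
                     prev_bs=NON_BREEDER, config=config)
    assert (r.phi, r.psi, r.pi, r.p) == (0.5, 0.5, 0.5, 0.5)


def test_annual_rates_sums_linear_predictor_terms():
    # intercept 1.0, age-class offset -0.5, failed-breeder effect +0.2,
    # year effect +0.3 -> logit^-1(1.0)
    config = ModelConfig(age_cuts={"phi": (2,)}, gamma_params=frozenset({"phi"}),
                         productivity_family=None,
                         active_params=("phi_j", "phi_ad"))
    vr = VitalRateModel(mu={"phi": 1.0, "p": 0.0},
                        age_effects={"phi": {1: -0.5}},
                        bs_effects={"phi": {FAILED_BREEDER: 0.2}},
                        productivity_family=None,
                        active_params=config.active_params)
    eff = _zero_effects(config)
    eff.alpha[3, config.effect_column("phi_ad")] = 0.3
    r = annual_rates(vr, eff, year=3, age=4, prev_bs=FAILED_BREEDER, config=config)
    assert r.phi == pytest.approx(inverse_link(1.0, "logit"), abs=1e-12)
    assert r.phi == pytest.approx(0.7310585786300049, abs=1e-10)


def test_inactive_reproductive_probability_is_exactly_one():
    config = ModelConfig(productivity_family=None,
                         active_params=("phi_j", "phi_ad", "pi"))
    vr = VitalRateModel(mu={"phi": 0.3, "pi": 0.1, "p": 1.0},
                        productivity_family=None,
                        active_params=config.active_params)
    r = annual_rates(vr, _zero_effects(config), year=1, age=2,
                     prev_bs=NON_BREEDER, config=config)
    assert r.psi == 1.0
    assert r.omega == 1.0


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------

def _rates(phi, psi, pi):
    return Rates(phi=phi, psi=psi, pi=pi, omega=1.0, p=0.9)


@pytest.mark.parametrize("phi, psi, pi", [
    (0.0, 0.5, 0.5), (1.0, 1.0, 1.0), (0.8, 0.5, 0.5), (0.37, 0.91, 0.13),
])
def test_transition_matrix_rows_sum_to_one(phi, psi, pi):
    M = transition_matrix(_rates(phi, psi, pi), StateSpace())
    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
    assert M[DEAD, DEAD] == 1.0


def test_transition_matrix_zero_survival_sends_all_to_dead():
    M = transition_matrix(_rates(0.0, 0.5, 0.5), StateSpace())
    for s in (PRE_BREEDER, NON_BREEDER, FAILED_BREEDER, SUCCESSFUL_BREEDER):
        assert M[s, DEAD] == 1.0


def test_transition_matrix_certain_success():
    M = transition_matrix(_rates(1.0, 1.0, 1.0), StateSpace())
    assert np.all(M[:DEAD, SUCCESSFUL_BREEDER] == 1.0)


def test_transition_matrix_bernoulli_chain_products():
    M = transition_matrix(_rates(0.8, 0.5, 0.5), StateSpace())
    row = M[NON_BREEDER]
    assert row[DEAD] == pytest.approx(0.2)
    assert row[NON_BREEDER] == pytest.approx(0.4)
    assert row[FAILED_BREEDER] == pytest.approx(0.2)
    assert row[SUCCESSFUL_BREEDER] == pytest.approx(0.2)


def test_pre_breeder_survivor_stays_pre_breeder_only_with_flag():
    M = transition_matrix(_rates(1.0, 0.0, 0.5), StateSpace(has_pre_breeder=True))
    assert M[PRE_BREEDER, PRE_BREEDER] == 1.0
    M = transition_matrix(_rates(1.0, 0.0, 0.5), StateSpace(has_pre_breeder=False))
    assert M[PRE_BREEDER, NON_BREEDER] == 1.0


# ---------------------------------------------------------------------------
# observation probabilities
# ---------------------------------------------------------------------------

def test_observation_probs_cases():
    r = Rates(phi=0.8, psi=1.0, pi=0.5, omega=2.0, p=0.9,
              family="truncated_poisson")
    dead_missed = Record(year=1, alive=False, state="dead", detected=False)
    assert observation_probs(r, DEAD, dead_missed) == 1.0
    alive_missed = Record(year=1, alive=True, state="non_breeder", detected=False)
    assert observation_probs(r, NON_BREEDER, alive_missed) == pytest.approx(0.1)
    seen_nb = Record(year=1, alive=True, state="non_breeder", detected=True)
    assert observation_probs(r, FAILED_BREEDER, seen_nb) == 0.0
    seen_sb = Record(year=1, alive=True, state="successful_breeder",
                     offspring_count=2, detected=True)
    lam = 2.0
    expected = 0.9 * (lam ** 2 * math.exp(-lam) / 2) / (1 - math.exp(-lam))
    assert observation_probs(r, SUCCESSFUL_BREEDER, seen_sb) == \
        pytest.approx(expected, rel=1e-10)


def test_observation_probs_rejects_count_on_non_successful_state():
    r = Rates(phi=0.8, psi=1.0, pi=0.5, omega=2.0, p=0.9)
    with pytest.raises(ModelError):
        bad = Record.__new__(Record)
        bad.year, bad.alive, bad.state = 1, True, "failed_breeder"
        bad.offspring_count, bad.detected = 2, True
        observation_probs(r, FAILED_BREEDER, bad)


# ---------------------------------------------------------------------------
# correlation-type indexing
# ---------------------------------------------------------------------------

def test_type1_survival_reads_contemporaneous_rows():
    config = ModelConfig(productivity_family=None,
                         active_params=("phi_j", "phi_ad"), correlation_type=1)
    assert list(apply_correlation_type(5, config)) == [0, 1, 2, 3, 4]


def test_type2_survival_reads_previous_rows():
    config = ModelConfig(productivity_family=None,
                         active_params=("phi_j", "phi_ad"), correlation_type=2)
    assert list(apply_correlation_type(5, config)) == [-1, 0, 1, 2, 3]
    assert survival_effect_row(3, 2) == 2
    assert survival_effect_row(3, 1) == 3


# ---------------------------------------------------------------------------
# forward log-likelihood
# ---------------------------------------------------------------------------

def _single_rate_setup(phi=0.7, T=2):
    """Survival-only model, certain detection, single effective live state."""
    config = ModelConfig(age_cuts={"phi": ()}, productivity_family=None,
                         active_params=("phi_j", "phi_ad"), fixed_p=1.0)
    vr = VitalRateModel(mu={"phi": logit(phi), "p": 10.0},
                        productivity_family=None,
                        active_params=config.active_params)
    eff = TemporalEffects(alpha=np.zeros((T, 2)), alpha_p=np.zeros(T),
                          param_order=config.active_params)
    return vr, eff, config


def test_forward_survivor_detected_next_year_gives_log_phi():
    vr, eff, config = _single_rate_setup(phi=0.7)
    h = IndividualHistory(individual_id="a", entry_year=0, records=[
        Record(year=0, alive=True, state="non_breeder", detected=True),
        Record(year=1, alive=True, state="successful_breeder", detected=True),
    ])
    assert forward_loglik(h, vr, eff, config) == pytest.approx(math.log(0.7), abs=1e-12)


def test_forward_never_seen_again_certain_detection_forces_death():
    vr, eff, config = _single_rate_setup(phi=0.7)
    h = IndividualHistory(individual_id="a", entry_year=0, records=[
        Record(year=0, alive=True, state="non_breeder", detected=True),
    ])
    assert forward_loglik(h, vr, eff, config) == pytest.approx(math.log(0.3), abs=1e-12)


def test_forward_rejects_observation_before_entry():
    vr, eff, config = _single_rate_setup()
    h = IndividualHistory(individual_id="a", entry_year=1, records=[
        Record(year=0, alive=True, state="non_breeder", detected=True),
    ])
    with pytest.raises(ModelError):
        forward_loglik(h, vr, eff, config)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_forward_matches_path_enumeration(seed):
    """The forward recursion marginalises exactly: it must equal brute-force
    enumeration over all latent state paths on small instances."""
    vr, cov, config, effects, histories = random_instance(seed)
    for h in histories[:4]:
        expected = enumeration_loglik(h, vr, effects, config)
        got = forward_loglik(h, vr, effects, config)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("seed", [3, 17, 41])
def test_forward_collapses_to_layer_products_under_certain_detection(seed):
    vr, cov, config, effects, histories = random_instance(seed, fixed_p=1.0)
    for h in histories:
        expected = full_observation_loglik(h, vr, effects, config)
        got = forward_loglik(h, vr, effects, config)
        assert got == pytest.approx(expected, abs=1e-12)


def test_dataset_loglik_empty_is_zero():
    vr, eff, config = _single_rate_setup()
    res = dataset_loglik([], vr, eff, config)
    assert res.total == 0.0
    assert len(res.contributions) == 0


def test_dataset_loglik_duplication_and_order_invariance(simple_vr, simple_cov,
                                                         simple_config):
    from vitalcorr.synthetic_data import draw_temporal_effects, simulate_population
    eff = draw_temporal_effects(simple_cov, 6, seed=4)
    hs = simulate_population(simple_vr, simple_cov, eff, 3, 6, seed=9,
                             config=simple_config)
    single = dataset_loglik(hs, simple_vr, eff, simple_config)
    doubled = dataset_loglik(hs + hs, simple_vr, eff, simple_config)
    assert doubled.total == pytest.approx(2 * single.total, rel=1e-12)
    permuted = dataset_loglik(hs[::-1], simple_vr, eff, simple_config)
    assert permuted.total == pytest.approx(single.total, rel=1e-14)
    assert single.total == pytest.approx(single.contributions.sum(), rel=1e-14)
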