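"""Generator: year-effect draws, population simulation, dataset round trips."""

import math

import numpy as np
import pytest

from vitalcorr.model_core import ModelConfig, ModelError, logit
from vitalcorr.synthetic_data import (CovarianceStructure, IndividualHistory,
                                      Record, VitalRateModel,
                                      draw_temporal_effects, read_dataset,
                                      simulate_population, write_dataset)


# ---------------------------------------------------------------------------
# temporal effects
# ---------------------------------------------------------------------------

def test_zero_variance_effects_are_exactly_zero():
    cov = CovarianceStructure(param_order=("phi_j", "phi_ad"),
                              sigma=np.zeros(2), corr=np.eye(2), sigma_p=0.0)
    eff = draw_temporal_effects(cov, 10, seed=1)
    assert eff.alpha.shape == (10, 2)
    assert np.all(eff.alpha == 0.0)
    assert np.all(eff.alpha_p == 0.0)


def test_effect_draws_reproduce_closed_form_covariance():
    # sigma = (0.3, 0.3), r = 0.5 -> cov = 0.045; Monte-Carlo at T = 50,000
    cov = CovarianceStructure(param_order=("phi_j", "phi_ad"),
                              sigma=np.array([0.3, 0.3]),
                              corr=np.array([[1.0, 0.5], [0.5, 1.0]]))
    eff = draw_temporal_effects(cov, 50_000, seed=7)
    sample_cov = np.cov(eff.alpha.T)[0, 1]
    assert abs(sample_cov - 0.045) < 0.005
    assert abs(eff.alpha.mean(axis=0)).max() < 0.01


def test_effect_draws_deterministic_for_fixed_seed():
    cov = CovarianceStructure(param_order=("phi_j", "phi_ad"),
                              sigma=np.array([0.4, 0.2]),
                              corr=np.array([[1.0, -0.3], [-0.3, 1.0]]),
                              sigma_p=0.2)
    a = draw_temporal_effects(cov, 25, seed=42)
    b = draw_temporal_effects(cov, 25, seed=42)
    assert np.array_equal(a.alpha, b.alpha)
    assert np.array_equal(a.alpha_p, b.alpha_p)


def test_non_psd_correlation_is_rejected_with_matrix_in_message():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    with pytest.raises(ModelError, match="positive semi-definite"):
        CovarianceStructure(param_order=("phi_j", "phi_ad", "pi"),
                            sigma=np.ones(3), corr=bad)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _degenerate_setup(T=6):
    config = ModelConfig(age_cuts={"phi": ()}, productivity_family=None,
                         active_params=("phi_j", "phi_ad"))
    vr = VitalRateModel(mu={"phi": 50.0, "p": 50.0}, productivity_family=None,
                        active_params=config.active_params)
    cov = CovarianceStructure(param_order=config.active_params,
                              sigma=np.zeros(2), corr=np.eye(2))
    eff = draw_temporal_effects(cov, T, seed=0)
    return vr, cov, eff, config


def test_degenerate_rates_everyone_survives_succeeds_and_is_detected():
    vr, cov, eff, config = _degenerate_setup()
    hs = simulate_population(vr, cov, eff, 4, 6, seed=3, config=config)
    for h in hs:
        for rec in h.records:
            assert rec.alive
            assert rec.detected
            if rec.year > h.entry_year:
                assert rec.state == "successful_breeder"


def test_realized_survival_matches_binomial_rate():
    """~100k survival transitions at phi = 0.8 (no age or state effects, zero
    temporal variance): the realized frequency is binomial around 0.8."""
    config = ModelConfig(productivity_family=None,
                         active_params=("phi_j", "phi_ad"))
    vr = VitalRateModel(mu={"phi": logit(0.8), "p": 0.0},
                        productivity_family=None,
                        active_params=config.active_params)
    cov = CovarianceStructure(param_order=config.active_params,
                              sigma=np.zeros(2), corr=np.eye(2))
    T = 30
    eff = draw_temporal_effects(cov, T, seed=0)
    hs = simulate_population(vr, cov, eff, 800, T, seed=5, config=config)
    at_risk = survived = 0
    for h in hs:
        alive_prev = True
        for rec in sorted(h.records, key=lambda r: r.year):
            if rec.year == h.entry_year:
                continue
            if alive_prev:
                at_risk += 1
                survived += rec.alive
            alive_prev = rec.alive
    assert at_risk > 100_000
    freq = survived / at_risk
    assert 0.796 < freq < 0.804


def test_truncated_poisson_counts_match_zero_truncated_mean():
    config = ModelConfig(productivity_family="truncated_poisson",
                         active_params=("phi_j", "phi_ad", "omega"))
    vr = VitalRateModel(mu={"phi": logit(0.9), "omega": math.log(2.0), "p": 5.0},
                        productivity_family="truncated_poisson",
                        active_params=config.active_params)
    cov = CovarianceStructure(param_order=config.active_params,
                              sigma=np.zeros(3), corr=np.eye(3))
    eff = draw_temporal_effects(cov, 12, seed=0)
    hs = simulate_population(vr, cov, eff, 300, 12, seed=8, config=config)
    counts = [r.offspring_count for h in hs for r in h.records
              if r.offspring_count is not None]
    counts = np.array(counts)
    assert counts.min() >= 1
    expected = 2.0 / (1.0 - math.exp(-2.0))  # ~2.313
    assert counts.mean() == pytest.approx(expected, abs=3 * counts.std() / len(counts) ** 0.5 + 0.01)


def test_realized_annual_frequencies_track_year_effects(simple_vr, simple_cov,
                                                        simple_config):
    """Per-year realized adult survival follows inv-logit(mu + f + alpha_t)."""
    from vitalcorr.model_core import inverse_link
    T = 8
    eff = draw_temporal_effects(simple_cov, T, seed=3)
    hs = simulate_population(simple_vr, simple_cov, eff, 600, T, seed=11,
                             config=simple_config)
    col = simple_config.effect_column("phi_ad")
    eta_ad = logit(0.8)
    for t in range(2, T):
        at_risk = survived = 0
        for h in hs:
            if h.entry_year > t - 2:
                continue
            prev = next(r for r in h.records if r.year == t - 1)
            cur = next(r for r in h.records if r.year == t)
            if prev.alive:
                at_risk += 1
                survived += cur.alive
        p_true = inverse_link(eta_ad + eff.alpha[t, col], "logit")
        se = (p_true * (1 - p_true) / at_risk) ** 0.5
        assert abs(survived / at_risk - p_true) < 4 * se + 1e-9


def test_strong_positive_correlation_shows_in_annual_frequencies():
    """With sigma large and r = 0.9, realized annual adult-survival and
    success frequencies are positively correlated across years."""
    corr = np.array([[1.0, 0.9, 0.81], [0.9, 1.0, 0.9], [0.81, 0.9, 1.0]])
    cov = CovarianceStructure(param_order=("phi_j", "phi_ad", "pi"),
                              sigma=np.array([1.2, 1.2, 1.2]), corr=corr)
    config = ModelConfig(active_params=cov.param_order, productivity_family=None)
    vr = VitalRateModel(mu={"phi": logit(0.6), "pi": 0.0, "p": 5.0},
                        age_effects={"phi": {1: 0.5}},
                        productivity_family=None, active_params=cov.param_order)
    T = 34
    eff = draw_temporal_effects(cov, T, seed=21)
    hs = simulate_population(vr, cov, eff, 150, T, seed=2, config=config)
    surv = np.zeros(T)
    risk = np.zeros(T)
    succ = np.zeros(T)
    brood = np.zeros(T)
    for h in hs:
        recs = {r.year: r for r in h.records}
        for t in range(h.entry_year + 2, T):
            if recs[t - 1].alive:
                risk[t] += 1
                surv[t] += recs[t].alive
            if recs[t].alive and recs[t].state in ("failed_breeder",
                                                   "successful_breeder"):
                brood[t] += 1
                succ[t] += recs[t].state == "successful_breeder"
    years = [t for t in range(2, T) if risk[t] > 20 and brood[t] > 20]
    assert len(years) >= 30
    f_surv = np.array([surv[t] / risk[t] for t in years])
    f_succ = np.array([succ[t] / brood[t] for t in years])
    assert np.corrcoef(f_surv, f_succ)[0, 1] > 0.3


def test_zero_variance_gives_uncorrelated_annual_frequencies():
    cov = CovarianceStructure(param_order=("phi_j", "phi_ad", "pi"),
                              sigma=np.zeros(3), corr=np.eye(3))
    config = ModelConfig(active_params=cov.param_order, productivity_family=None)
    vr = VitalRateModel(mu={"phi": logit(0.75), "pi": 0.0, "p": 5.0},
                        productivity_family=None, active_params=cov.param_order)
    T = 40
    eff = draw_temporal_effects(cov, T, seed=1)
    hs = simulate_population(vr, cov, eff, 120, T, seed=6, config=config)
    surv = np.zeros(T); risk = np.zeros(T); succ = np.zeros(T); brood = np.zeros(T)
    for h in hs:
        recs = {r.year: r for r in h.records}
        for t in range(h.entry_year + 2, T):
            if recs[t - 1].alive:
                risk[t] += 1
                surv[t] += recs[t].alive
            if recs[t].alive and recs[t].state != "non_breeder":
                brood[t] += 1
                succ[t] += recs[t].state == "successful_breeder"
    years = [t for t in range(2, T) if risk[t] > 20 and brood[t] > 20]
    f1 = np.array([surv[t] / risk[t] for t in years])
    f2 = np.array([succ[t] / brood[t] for t in years])
    # binomial noise only: correlation centred on zero
    assert abs(np.corrcoef(f1, f2)[0, 1]) < 2.5 / np.sqrt(len(years))


def test_simulation_deterministic_and_order_free(simple_vr, simple_cov,
                                                 simple_config):
    eff = draw_temporal_effects(simple_cov, 6, seed=2)
    a = simulate_population(simple_vr, simple_cov, eff, 5, 6, seed=77,
                            config=simple_config)
    b = simulate_population(simple_vr, simple_cov, eff, 5, 6, seed=77,
                            config=simple_config)
    assert [h.observed_tuple() for h in a] == [h.observed_tuple() for h in b]


# ---------------------------------------------------------------------------
# dataset round trips
# ---------------------------------------------------------------------------

def test_write_read_round_trip(tmp_path, simple_vr, simple_cov, simple_config):
    eff = draw_temporal_effects(simple_cov, 7, seed=5)
    hs = simulate_population(simple_vr, simple_cov, eff, 6, 7, seed=13,
                             config=simple_config)
    path = tmp_path / "histories.csv"
    write_dataset(hs, path)
    back = read_dataset(path)
    assert [h.observed_tuple() for h in back] == [h.observed_tuple() for h in hs]


def test_empty_dataset_round_trip(tmp_path):
    path = tmp_path / "empty.csv"
    write_dataset([], path)
    assert read_dataset(path) == []


def test_detected_dead_row_is_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("individual_id,year,detected,state,count\n"
                    "a,0,1,non_breeder,\n"
                    "a,1,1,dead,\n")
    with pytest.raises(ModelError, match="line 3"):
        read_dataset(path)


def test_count_outside_successful_year_is_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("individual_id,year,detected,state,count\n"
                    "a,0,1,failed_breeder,2\n")
    with pytest.raises(ModelError, match="line 2"):
        read_dataset(path)


def test_history_invariants_enforced():
    with pytest.raises(ModelError, match="detected while dead"):
        IndividualHistory(individual_id="x", entry_year=0, records=[
            Record(year=0, alive=False, state="dead", detected=True)])
    with pytest.raises(ModelError, match="resurrection"):
        IndividualHistory(individual_id="x", entry_year=0, records=[
            Record(year=0, alive=False, state="dead"),
            Record(year=1, alive=True, state="non_breeder")])
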