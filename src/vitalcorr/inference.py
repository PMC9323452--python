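"""Bayesian estimation of the temporal variance-covariance structure.

The posterior targets the hidden-Markov capture-recapture likelihood of
:mod:`model_core` under weakly informative priors: normal priors on link-scale
intercepts and effects, a parameter-expanded Cholesky prior on the temporal
variance-covariance matrix (year effects are multivariate normal with
covariance Lambda Lambda^T, the free lower-triangular loadings carrying
normal priors — sign redundancy of the factor is the expansion, marginalised
analytically by our random-walk sampler), and a half-normal prior on the
independent detection-effect scale.

Sampling uses an adaptive Metropolis-within-Gibbs reference sampler compiled
with numba; correlations are derived draw-wise from the sampled covariance
factor, never from point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .model_core import (DEAD, FAILED_BREEDER, NON_BREEDER, PRE_BREEDER,
                         STATE_NAMES, SUCCESSFUL_BREEDER, ModelConfig, ModelError)

__all__ = [
    "PriorSpec", "MCMCSettings", "PosteriorDraws", "sample_posterior",
    "rhat", "summarize", "sign_probability", "pack_histories",
    "draw_prior_covariances",
]


# ---------------------------------------------------------------------------
# Priors and sampler settings
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Hyperparameters of the weakly informative default priors.

    Intercepts are Normal(0, intercept_sd^2) on the link scale, age and
    breeding-state effects Normal(0, effect_sd^2), free Cholesky loadings
    Normal(0, loading_sd^2) (inducing the expanded-factor prior on the
    covariance matrix), the detection-effect scale half-Normal(0,
    scale_sd_p), and the truncated-normal productivity residual SD is
    log-normal with the given parameters.
    """

    intercept_mean: float = 0.0
    intercept_sd: float = 1.5
    effect_sd: float = 1.0
    loading_sd: float = 1.0
    scale_sd_p: float = 1.0
    log_sigma_omega_mean: float = 0.0
    log_sigma_omega_sd: float = 1.0

    def __post_init__(self):
        for name in ("intercept_sd", "effect_sd", "loading_sd", "scale_sd_p",
                     "log_sigma_omega_sd"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")


@dataclass
class MCMCSettings:
    """Chain design.  Defaults mirror a mid-range long-run setting; recovery
    experiments and tests scale iterations down."""

    chains: int = 3
    iterations: int = 10000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.iterations <= self.burn_in or self.thin < 1:
            raise ModelError("invalid MCMC settings")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# Parameter layout and data packing
# ---------------------------------------------------------------------------

_GAMMA_STATES = (PRE_BREEDER, FAILED_BREEDER, SUCCESSFUL_BREEDER)  # NB is reference


class _Layout:
    """Maps the flat sampler vector theta to named model terms."""

    def __init__(self, config: ModelConfig, priors: PriorSpec):
        self.names: list[str] = []
        self.prior_mean: list[float] = []
        self.prior_sd: list[float] = []
        self.config = config

        def add(name, mean, sd):
            self.names.append(name)
            self.prior_mean.append(mean)
            self.prior_sd.append(sd)
            return len(self.names) - 1

        def gamma_idx(param):
            idx = -np.ones(4, dtype=np.int64)
            if param in config.gamma_params:
                for s in _GAMMA_STATES:
                    if s == PRE_BREEDER and not config.has_pre_breeder:
                        continue
                    idx[s] = add(f"gamma_{param}[{STATE_NAMES[s]}]", 0.0, priors.effect_sd)
            return idx

        def age_idx(param):
            n = config.n_age_classes(param)
            idx = -np.ones(n, dtype=np.int64)
            for c in range(1, n):
                idx[c] = add(f"f_{param}[{c}]", 0.0, priors.effect_sd)
            return idx

        self.i_mu_phi = add("mu_phi", priors.intercept_mean, priors.intercept_sd)
        self.f_phi = age_idx("phi")
        self.g_phi = gamma_idx("phi")

        if config.is_active("psi"):
            self.i_mu_psi = add("mu_psi", priors.intercept_mean, priors.intercept_sd)
            self.f_psi = age_idx("psi")
            self.g_psi = gamma_idx("psi")
        else:
            self.i_mu_psi = -1
            self.f_psi = -np.ones(1, dtype=np.int64)
            self.g_psi = -np.ones(4, dtype=np.int64)

        if config.is_active("pi"):
            self.i_mu_pi = add("mu_pi", priors.intercept_mean, priors.intercept_sd)
            self.f_pi = age_idx("pi")
            self.g_pi = gamma_idx("pi")
        else:
            self.i_mu_pi = -1
            self.f_pi = -np.ones(1, dtype=np.int64)
            self.g_pi = -np.ones(4, dtype=np.int64)

        if config.is_active("omega"):
            self.i_mu_om = add("mu_omega", priors.intercept_mean, priors.intercept_sd)
            self.f_om = age_idx("omega")
            if config.productivity_family == "truncated_normal":
                self.i_lsig_om = add("log_sigma_omega_resid",
                                     priors.log_sigma_omega_mean,
                                     priors.log_sigma_omega_sd)
            else:
                self.i_lsig_om = -1
        else:
            self.i_mu_om = -1
            self.f_om = -np.ones(1, dtype=np.int64)
            self.i_lsig_om = -1

        if config.fixed_p is None:
            self.i_mu_p = add("mu_p", priors.intercept_mean, priors.intercept_sd)
            self.f_p = age_idx("p")
            self.g_p = gamma_idx("p")
        else:
            self.i_mu_p = -1
            self.f_p = -np.ones(1, dtype=np.int64)
            self.g_p = -np.ones(4, dtype=np.int64)

    @property
    def n_theta(self) -> int:
        return len(self.names)


def _age_class_map(config: ModelConfig, param: str, A: int) -> np.ndarray:
    return np.array([config.age_class(param, a) for a in range(A + 1)], dtype=np.int64)


def build_packed_model(config: ModelConfig, n_years: int, priors: PriorSpec):
    """Kernel model tuple plus the theta layout for a given configuration."""
    layout = _Layout(config, priors)
    A = config.max_age
    fam_code = {None: 0, "bernoulli_extra_offspring": 1,
                "truncated_normal": 2, "truncated_poisson": 3}[config.productivity_family
                                                               if config.is_active("omega") else None]

    def col(p):
        return config.effect_column(p) if config.is_active(p) else -1

    # translation moves: theta entries whose increase can be absorbed by a
    # uniform decrease of year-effect columns (or of the detection effects)
    # without changing any linear predictor
    moves = []
    if config.is_active("phi_j"):
        mask = np.zeros(config.n_effects)
        mask[config.effect_column("phi_j")] = 1.0
        mask[config.effect_column("phi_ad")] = 1.0
        moves.append((layout.i_mu_phi, mask, 0))
        if config.n_age_classes("phi") == 2 and layout.f_phi[1] >= 0:
            m2 = np.zeros(config.n_effects)
            m2[config.effect_column("phi_ad")] = 1.0
            moves.append((layout.f_phi[1], m2, 0))
    for p, i_mu in (("psi", layout.i_mu_psi), ("pi", layout.i_mu_pi),
                    ("omega", layout.i_mu_om)):
        if i_mu >= 0:
            mask = np.zeros(config.n_effects)
            mask[config.effect_column(p)] = 1.0
            moves.append((i_mu, mask, 0))
    if layout.i_mu_p >= 0:
        moves.append((layout.i_mu_p, np.zeros(config.n_effects), 1))
    if moves:
        trans_idx = np.array([m[0] for m in moves], dtype=np.int64)
        trans_mask = np.stack([m[1] for m in moves]).astype(np.float64)
        trans_p = np.array([m[2] for m in moves], dtype=np.uint8)
    else:
        trans_idx = np.zeros(0, dtype=np.int64)
        trans_mask = np.zeros((0, config.n_effects), dtype=np.float64)
        trans_p = np.zeros(0, dtype=np.uint8)
    layout.translations = (trans_idx, trans_mask, trans_p)

    model = (
        int(n_years), int(A), int(config.correlation_type),
        int(config.has_pre_breeder), int(config.n_effects),
        col("phi_j"), col("phi_ad"), col("psi"), col("pi"), col("omega"),
        fam_code,
        _age_class_map(config, "phi", A), _age_class_map(config, "psi", A),
        _age_class_map(config, "pi", A), _age_class_map(config, "omega", A),
        _age_class_map(config, "p", A),
        layout.i_mu_phi, layout.i_mu_psi, layout.i_mu_pi, layout.i_mu_om,
        layout.i_mu_p, layout.i_lsig_om,
        layout.f_phi, layout.f_psi, layout.f_pi, layout.f_om, layout.f_p,
        layout.g_phi, layout.g_psi, layout.g_pi, layout.g_p,
        float(config.fixed_p if config.fixed_p is not None else np.nan),
    )
    return model, layout


def pack_histories(histories: Sequence, config: ModelConfig, n_years: int,
                   collapse: bool = True):
    """Pack the observed portion of histories into kernel arrays.

    Truncated-normal offspring counts are rounded to the nearest positive
    integer, matching the recorded-count convention of the dataset files.
    With ``collapse`` (default), individuals with identical observed
    histories are merged into one weighted record — the likelihood is
    unchanged, evaluation cost drops.
    """
    n = len(histories)
    entry = np.empty(n, dtype=np.int64)
    entry_state = np.empty(n, dtype=np.int64)
    last_det = np.empty(n, dtype=np.int64)
    det = np.zeros((n, n_years), dtype=np.uint8)
    obs_state = -np.ones((n, n_years), dtype=np.int8)
    cnt = -np.ones((n, n_years), dtype=np.float64)
    for i, h in enumerate(histories):
        entry[i] = h.entry_year
        entry_state[i] = h.entry_state_index(config)
        ld = h.entry_year
        for rec in h.records:
            if rec.year < h.entry_year:
                raise ModelError(f"{h.individual_id}: observation before entry year")
            if not rec.detected or rec.year == h.entry_year:
                continue
            if rec.year >= n_years:
                raise ModelError(f"{h.individual_id}: year {rec.year} outside study span")
            s = rec.state_index()
            if s == DEAD:
                raise ModelError(f"{h.individual_id}: detected in state 'dead'")
            det[i, rec.year] = 1
            obs_state[i, rec.year] = s
            if rec.offspring_count is not None:
                if s != SUCCESSFUL_BREEDER:
                    raise ModelError(f"{h.individual_id}: count in a non-successful year")
                cnt[i, rec.year] = max(1.0, round(float(rec.offspring_count)))
            ld = max(ld, rec.year)
        last_det[i] = ld
    weight = np.ones(n, dtype=np.float64)
    if not collapse or n == 0:
        return entry, entry_state, last_det, det, obs_state, cnt, weight

    groups: dict = {}
    for i in range(n):
        key = (entry[i], entry_state[i], det[i].tobytes(), obs_state[i].tobytes(),
               cnt[i].tobytes())
        groups.setdefault(key, []).append(i)
    reps = np.array([idx[0] for idx in groups.values()], dtype=np.int64)
    w = np.array([len(idx) for idx in groups.values()], dtype=np.float64)
    return (entry[reps], entry_state[reps], last_det[reps],
            np.ascontiguousarray(det[reps]), np.ascontiguousarray(obs_state[reps]),
            np.ascontiguousarray(cnt[reps]), w)


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC samples across chains with sampler metadata.

    ``params`` maps parameter names (intercepts, effects, temporal SDs
    ``sigma_<param>``, correlations ``r_<param>_<param>``, ``sigma_p``) to
    arrays of shape (chains, draws).  Year effects are kept separately in
    ``year_effects`` (chains, draws, T, K) and ``detection_effects``.
    """

    params: dict
    year_effects: np.ndarray
    detection_effects: np.ndarray
    param_order: tuple
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def correlation_names(self) -> list:
        return [k for k in self.params if k.startswith("r_")]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) table."""
        rows = []
        for name, arr in self.params.items():
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(arr.shape[1]),
                    "parameter": name, "value": arr[c]}))
        return pd.concat(rows, ignore_index=True)


def correlation_pair_name(p1: str, p2: str) -> str:
    return f"r_{p1}_{p2}"


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n) with m >= 2 chains of equal length n.
    Computed from the within-chain variance W and the between-chain variance
    B as sqrt(((n-1)/n W + B/n) / W); approximately 1 for well-mixed chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ModelError("R-hat requires at least 2 chains of equal length "
                         "(shape (m, n) with m >= 2)")
    m, n = chains.shape
    if n < 10:
        raise ModelError("R-hat requires chains of length >= 10")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def sign_probability(draws: np.ndarray) -> float:
    """Proportion of draws sharing the sign of the posterior mean ('P')."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ModelError("cannot summarise an empty draw vector")
    s = np.sign(draws.mean())
    if s == 0:
        return 0.5
    return float(np.mean(np.sign(draws) == s))


def summarize(draws: PosteriorDraws | dict, min_draws: int = 1000) -> pd.DataFrame:
    """Posterior mean, SD, equal-tailed 95% CRI, sign probability P and
    R-hat for every monitored parameter (year effects excluded)."""
    if isinstance(draws, PosteriorDraws):
        params = draws.params
    else:
        params = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in draws.items()}
    if not params:
        raise ModelError("no parameters to summarise")
    rows = []
    for name, arr in params.items():
        pooled = arr.reshape(-1)
        if pooled.size == 0:
            raise ModelError(f"parameter {name} has no draws")
        if pooled.size < min_draws:
            warnings.warn(f"only {pooled.size} draws for {name}; summaries may be "
                          f"unstable (floor {min_draws})", stacklevel=2)
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        rows.append({
            "parameter": name,
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
            "q2.5": float(lo),
            "q97.5": float(hi),
            "P": sign_probability(pooled),
            "rhat": rhat(arr) if arr.shape[0] >= 2 and arr.shape[1] >= 10 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Posterior sampling
# ---------------------------------------------------------------------------

def _chain_seed(seed: int, chain: int) -> int:
    return int((seed * 100003 + 7919 * (chain + 1)) % (2 ** 31 - 1))


def sample_posterior(histories: Sequence, config: ModelConfig,
                     priors: PriorSpec | None = None,
                     mcmc: MCMCSettings | None = None) -> PosteriorDraws:
    """Sample the posterior of the capture-recapture model.

    Runs ``mcmc.chains`` independent adaptive Metropolis-within-Gibbs chains
    (reproducible for a fixed seed), derives temporal SDs and correlations
    draw-wise from the sampled covariance factor, and flags non-convergence
    (any monitored R-hat > 1.1) in ``meta['converged']`` without discarding
    the draws.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCSettings()
    n_years = 1 + max(max(r.year for r in h.records) for h in histories)
    model, layout = build_packed_model(config, n_years, priors)
    data = pack_histories(histories, config, n_years)

    K = config.n_effects
    T = n_years
    n_theta = layout.n_theta
    prior_mean = np.asarray(layout.prior_mean, dtype=float)
    prior_sd = np.asarray(layout.prior_sd, dtype=float)

    keep = mcmc.retained_per_chain
    theta_ch = np.empty((mcmc.chains, keep, n_theta))
    Lam_ch = np.empty((mcmc.chains, keep, K, K))
    sp_ch = np.empty((mcmc.chains, keep))
    alpha_ch = np.empty((mcmc.chains, keep, T, K))
    alphap_ch = np.empty((mcmc.chains, keep, T))
    ll_ch = np.empty((mcmc.chains, keep))
    accept = []

    for c in range(mcmc.chains):
        cseed = _chain_seed(mcmc.seed, c)
        rng = np.random.Generator(np.random.Philox(cseed))
        theta0 = prior_mean + 0.3 * prior_sd * rng.standard_normal(n_theta)
        Lam0 = 0.3 * np.eye(K) + 0.05 * np.tril(rng.standard_normal((K, K)))
        alpha0 = np.zeros((T, K))
        alphap0 = np.zeros(T)
        trans_idx, trans_mask, trans_p = layout.translations
        out = _kernel.run_chain(
            cseed, mcmc.iterations, mcmc.burn_in, mcmc.thin,
            theta0, alpha0, alphap0, Lam0, float(np.log(0.3)),
            prior_mean, prior_sd, priors.loading_sd, priors.scale_sd_p,
            trans_idx, trans_mask, trans_p,
            model, data)
        theta_ch[c], Lam_ch[c], sp_ch[c], alpha_ch[c], alphap_ch[c], ll_ch[c] = out[:6]
        accept.append({"theta": np.asarray(out[6]), "year": np.asarray(out[7])})

    params: dict[str, np.ndarray] = {}
    for j, name in enumerate(layout.names):
        params[name] = theta_ch[:, :, j]

    # covariance draws -> temporal SDs and correlations, per draw
    Sigma = Lam_ch @ np.swapaxes(Lam_ch, -1, -2)
    sd = np.sqrt(np.einsum("ctkk->ctk", Sigma))
    for k, p in enumerate(config.active_params):
        params[f"sigma_{p}"] = sd[:, :, k]
    for a in range(K):
        for b in range(a + 1, K):
            name = correlation_pair_name(config.active_params[a], config.active_params[b])
            with np.errstate(invalid="ignore", divide="ignore"):
                params[name] = Sigma[:, :, a, b] / (sd[:, :, a] * sd[:, :, b])
    if config.fixed_p is None:
        params["sigma_p"] = sp_ch

    monitored_rhat = {}
    if mcmc.chains >= 2 and keep >= 10:
        monitored_rhat = {name: rhat(arr) for name, arr in params.items()}
    converged = all(v <= 1.1 for v in monitored_rhat.values()) if monitored_rhat else None
    if converged is False:
        worst = max(monitored_rhat, key=monitored_rhat.get)
        warnings.warn(f"possible non-convergence: R-hat({worst}) = "
                      f"{monitored_rhat[worst]:.3f} > 1.1", stacklevel=2)

    meta = {
        "iterations": mcmc.iterations, "burn_in": mcmc.burn_in, "thin": mcmc.thin,
        "chains": mcmc.chains, "seed": mcmc.seed, "n_years": n_years,
        "n_individuals": len(histories), "theta_names": list(layout.names),
        "acceptance": accept, "rhat": monitored_rhat, "converged": converged,
        "loglik": ll_ch,
    }
    return PosteriorDraws(params=params, year_effects=alpha_ch,
                          detection_effects=alphap_ch,
                          param_order=config.active_params, meta=meta)


# ---------------------------------------------------------------------------
# Prior predictive check helper
# ---------------------------------------------------------------------------

def draw_prior_covariances(K: int, n_draws: int, priors: PriorSpec | None = None,
                           seed: int = 0) -> np.ndarray:
    """Draw covariance matrices from the expanded-Cholesky prior
    (Lambda Lambda^T with normal loadings); all are PSD by construction."""
    priors = priors or PriorSpec()
    rng = np.random.Generator(np.random.Philox(seed))
    out = np.empty((n_draws, K, K))
    for i in range(n_draws):
        L = np.tril(priors.loading_sd * rng.standard_normal((K, K)))
        out[i] = L @ L.T
    return out
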