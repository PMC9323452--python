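"""Deterministic probability machinery for multi-state capture-recapture models.

The demographic model decomposes each individual-year into four sequential
Bernoulli/count layers — survival, breeding, success, productivity — each with
a linear predictor on a link scale (logit for probabilities; logit, identity
or log for productivity depending on the family) combining an intercept, an
age-class effect, a previous-breeding-state effect and a shared temporal
random effect.  Detection is a fifth Bernoulli layer with its own independent
year effect.  This module assembles annual rates, builds the latent-state
transition and observation probabilities, and evaluates the per-individual
forward (hidden Markov) log-likelihood that marginalises the unobserved
alive/breeding states under imperfect detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import IndividualHistory, TemporalEffects, VitalRateModel

# ---------------------------------------------------------------------------
# State coding
# ---------------------------------------------------------------------------

PRE_BREEDER = 0
NON_BREEDER = 1
FAILED_BREEDER = 2
SUCCESSFUL_BREEDER = 3
DEAD = 4

STATE_NAMES = ("pre_breeder", "non_breeder", "failed_breeder",
               "successful_breeder", "dead")
STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}
LIVE_STATES = (PRE_BREEDER, NON_BREEDER, FAILED_BREEDER, SUCCESSFUL_BREEDER)

#: Parameters that may carry temporal random effects, in canonical order.
PARAM_ORDER = ("phi_j", "phi_ad", "psi", "pi", "omega")

PRODUCTIVITY_FAMILIES = (None, "bernoulli_extra_offspring", "truncated_normal",
                         "truncated_poisson")


class ModelError(ValueError):
    """Raised for invalid model configuration or inconsistent inputs."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Structural configuration of the capture-recapture model.

    Parameters
    ----------
    age_cuts
        Per-parameter ascending ages at which a new age class starts
        (keys among ``phi, psi, pi, omega, p``).  The class of age ``a`` is
        the number of cuts ``<= a``; class 0 is the reference level of the
        age function.  For survival the default ``[2]`` gives the classic
        juvenile (first-year) vs adult split.
    gamma_params
        Parameters carrying previous-breeding-state effects (subset of
        ``phi, psi, pi, p``; the productivity layer has none).
    active_params
        Which of the five vital rates are modelled as time varying.
        Juvenile and adult survival are always active.
    productivity_family
        ``None`` (single offspring, fixed), ``bernoulli_extra_offspring``,
        ``truncated_normal`` or ``truncated_poisson``.
    correlation_type
        1: reproduction in year t is paired with survival over (t-1, t].
        2: reproduction in year t is paired with survival over (t, t+1],
        i.e. survival equations consume year-effect rows shifted back one
        year relative to type 1.
    has_pre_breeder
        Whether individuals keep a distinct pre-breeder state until their
        first breeding attempt.
    fixed_p
        If given, detection probability is fixed at this value instead of
        being modelled (useful for fully observed designs).
    """

    age_cuts: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"phi": (2,), "psi": (), "pi": (), "omega": (), "p": ()})
    gamma_params: frozenset = frozenset()
    active_params: tuple = ("phi_j", "phi_ad", "psi", "pi", "omega")
    productivity_family: str | None = "truncated_poisson"
    correlation_type: int = 1
    has_pre_breeder: bool = False
    condition_on_first_capture: bool = True
    fixed_p: float | None = None

    def __post_init__(self):
        if self.correlation_type not in (1, 2):
            raise ModelError(f"correlation_type must be 1 or 2, got {self.correlation_type}")
        if self.productivity_family not in PRODUCTIVITY_FAMILIES:
            raise ModelError(f"unknown productivity family {self.productivity_family!r}")
        self.active_params = tuple(self.active_params)
        unknown = set(self.active_params) - set(PARAM_ORDER)
        if unknown:
            raise ModelError(f"unknown active parameters {sorted(unknown)}")
        if "phi_j" not in self.active_params or "phi_ad" not in self.active_params:
            raise ModelError("phi_j and phi_ad must always be active")
        # canonical ordering
        self.active_params = tuple(p for p in PARAM_ORDER if p in self.active_params)
        if not self.condition_on_first_capture:
            raise ModelError("only likelihoods conditioned on first capture are supported")
        if "omega" in self.active_params and self.productivity_family is None:
            raise ModelError("active productivity requires a productivity family")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        kwargs = dict(d)
        if "age_cuts" in kwargs:
            kwargs["age_cuts"] = {k: tuple(v) for k, v in kwargs["age_cuts"].items()}
        if "gamma_params" in kwargs:
            kwargs["gamma_params"] = frozenset(kwargs["gamma_params"])
        if "active_params" in kwargs:
            kwargs["active_params"] = tuple(kwargs["active_params"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- derived helpers ----------------------------------------------------

    @property
    def n_effects(self) -> int:
        """Number of columns of the multivariate-normal year-effect matrix."""
        return len(self.active_params)

    def effect_column(self, param: str) -> int:
        try:
            return self.active_params.index(param)
        except ValueError:
            raise ModelError(f"parameter {param!r} is not time varying in this model")

    def is_active(self, param: str) -> bool:
        return param in self.active_params

    def age_class(self, param: str, age: int) -> int:
        """Age class (index into the age function) of ``age`` for ``param``."""
        cuts = self.age_cuts.get(param, ())
        return int(sum(age >= c for c in cuts))

    def n_age_classes(self, param: str) -> int:
        return len(self.age_cuts.get(param, ())) + 1

    @property
    def max_age(self) -> int:
        """Smallest age at which every age function has reached its last class."""
        cuts = [c for v in self.age_cuts.values() for c in v]
        return max(cuts) if cuts else 1

    def entry_state(self) -> int:
        return PRE_BREEDER if self.has_pre_breeder else NON_BREEDER


@dataclass(frozen=True)
class StateSpace:
    """Ordered latent states: four live breeding states plus absorbing death."""

    has_pre_breeder: bool = False

    @property
    def states(self) -> tuple:
        return STATE_NAMES

    @property
    def n_states(self) -> int:
        return 5

    @property
    def dead(self) -> int:
        return DEAD

    @property
    def live_states(self) -> tuple:
        return LIVE_STATES

    def non_breeding_destination(self, origin: int) -> int:
        """State of a survivor that does not breed this year.

        A pre-breeder that skips breeding remains a pre-breeder (when the
        species keeps that state); every other live non-breeding survivor
        becomes a non-breeder.
        """
        if self.has_pre_breeder and origin == PRE_BREEDER:
            return PRE_BREEDER
        return NON_BREEDER


# ---------------------------------------------------------------------------
# Links and elementary densities
# ---------------------------------------------------------------------------

def inverse_link(x: float, link: str) -> float:
    """Inverse link: logit⁻¹ maps to (0,1); log to (0,∞); identity to ℝ."""
    if link == "logit":
        return 1.0 / (1.0 + math.exp(-x))
    if link == "log":
        return math.exp(x)
    if link == "identity":
        return float(x)
    raise ModelError(f"unknown link {link!r}")


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def recorded_count(count: float) -> float:
    """Offspring counts enter the likelihood as recorded integers: the
    truncated-normal generative draw is continuous, but observers record the
    nearest positive whole number."""
    return max(1.0, round(float(count)))


def productivity_logpmf(count: float, location: float, family: str | None,
                        sigma_resid: float | None = None) -> float:
    """Log-probability of an offspring count under the productivity family.

    ``location`` is on the family's natural scale: the probability of
    producing more than one offspring (logit link inverted upstream), the
    mean of the normal truncated at 0 (identity link), or the Poisson mean
    parameter (log link inverted upstream).  For the truncated-normal family
    counts are treated as continuous values recorded at integers, so the
    returned value is a log-density.
    """
    if count < 1:
        return -math.inf
    if family is None:
        return 0.0 if count == 1 else -math.inf
    if family == "bernoulli_extra_offspring":
        q = location
        return math.log(q) if count >= 2 else math.log1p(-q)
    if family == "truncated_normal":
        if sigma_resid is None or sigma_resid <= 0:
            raise ModelError("truncated_normal productivity needs sigma_resid > 0")
        z = (count - location) / sigma_resid
        logdens = -0.5 * z * z - math.log(sigma_resid) - 0.5 * math.log(2 * math.pi)
        # renormalisation for truncation at 0: P(X > 0) = Phi(location/sigma)
        lognorm = math.log(0.5 * math.erfc(-location / (sigma_resid * math.sqrt(2.0))))
        return logdens - lognorm
    if family == "truncated_poisson":
        lam = location
        return (count * math.log(lam) - lam - math.lgamma(count + 1.0)
                - math.log1p(-math.exp(-lam)))
    raise ModelError(f"unknown productivity family {family!r}")


# ---------------------------------------------------------------------------
# Year-effect indexing (type-1 vs type-2 correlations)
# ---------------------------------------------------------------------------

def survival_effect_row(year: int, correlation_type: int) -> int:
    """Year-effect row feeding the survival transition *into* ``year``.

    Under type-1 pairing, survival over (t-1, t] shares row t with the
    reproduction outcomes of year t.  Under type-2 pairing the survival
    equations are shifted one year back, so survival over (t, t+1] reads
    row t — pairing reproduction with *subsequent* survival.
    """
    return year if correlation_type == 1 else year - 1


def apply_correlation_type(n_years: int, config: ModelConfig) -> np.ndarray:
    """Map from transition year t (survival into year t, t = 1..T-1) to the
    year-effect row consumed by that transition.  Reproduction outcomes of
    year t always read row t."""
    return np.array([survival_effect_row(t, config.correlation_type)
                     for t in range(n_years)], dtype=np.int64)


# ---------------------------------------------------------------------------
# Annual rates
# ---------------------------------------------------------------------------

@dataclass
class Rates:
    """Annual rate bundle for one (year, age, previous-state) combination.

    ``omega`` is the productivity location on its link's inverse scale
    (probability of >1 offspring, truncated-normal location, or Poisson mean).
    Inactive rates are fixed constants: psi = pi = 1 and a single offspring.
    """

    phi: float
    psi: float
    pi: float
    omega: float
    p: float
    family: str | None = None
    sigma_resid: float | None = None


def annual_rates(vr: "VitalRateModel", effects: "TemporalEffects", year: int,
                 age: int, prev_bs: int, config: ModelConfig) -> Rates:
    """Assemble all annual rates for an individual of ``age`` in ``year``
    whose breeding state in the previous year was ``prev_bs``.

    The survival rate is the probability of surviving *into* ``year`` (so it
    consumes the year-effect row given by the correlation type); breeding,
    success, productivity and detection are outcomes of ``year`` itself.
    First-year (age 1) transitions use the juvenile survival year effect and
    the reference levels of the age and breeding-state terms.
    """
    if not 0 <= year < effects.n_years:
        raise ModelError(f"year {year} outside the effects range 0..{effects.n_years - 1}")

    def eta(param: str, col_param: str, state_for_gamma: int | None) -> float:
        x = vr.mu[param]
        ac = config.age_class(param, age)
        if ac > 0:
            x += vr.age_effects.get(param, {}).get(ac, 0.0)
        if state_for_gamma is not None and param in config.gamma_params:
            x += vr.bs_effects.get(param, {}).get(state_for_gamma, 0.0)
        if col_param is not None and config.is_active(col_param):
            row = year
            if col_param in ("phi_j", "phi_ad"):
                row = survival_effect_row(year, config.correlation_type)
                if row < 0:
                    raise ModelError("no survival transition into year 0 under "
                                     "type-2 pairing")
            x += effects.alpha[row, config.effect_column(col_param)]
        return x

    # first-year transitions (age 1) use the juvenile survival year effect
    # and reference-level breeding-state terms throughout: the previous
    # breeding state is undefined before the first possible reproduction
    juvenile = age == 1
    bs = None if juvenile else prev_bs
    phi_col = "phi_j" if juvenile else "phi_ad"
    phi = inverse_link(eta("phi", phi_col, bs), "logit")

    psi = (inverse_link(eta("psi", "psi", bs), "logit")
           if config.is_active("psi") else 1.0)
    pi = (inverse_link(eta("pi", "pi", bs), "logit")
          if config.is_active("pi") else 1.0)

    if config.is_active("omega"):
        loc = eta("omega", "omega", None)
        if config.productivity_family == "truncated_poisson":
            loc = math.exp(loc)  # log link: report the Poisson mean parameter
        elif config.productivity_family == "bernoulli_extra_offspring":
            loc = inverse_link(loc, "logit")
        omega = loc
    else:
        omega = 1.0

    if config.fixed_p is not None:
        p = config.fixed_p
    else:
        x = vr.mu["p"]
        ac = config.age_class("p", age)
        if ac > 0:
            x += vr.age_effects.get("p", {}).get(ac, 0.0)
        # detection depends on the *current* breeding state; the caller passes
        # it through observation_probs, so here we use the reference level.
        p = inverse_link(x + effects.alpha_p[year], "logit")

    return Rates(phi=phi, psi=psi, pi=pi, omega=omega, p=p,
                 family=config.productivity_family if config.is_active("omega") else None,
                 sigma_resid=vr.sigma_omega_resid)


def detection_prob(vr: "VitalRateModel", effects: "TemporalEffects", year: int,
                   age: int, state: int, config: ModelConfig) -> float:
    """Detection probability of a live individual in ``state`` in ``year``."""
    if config.fixed_p is not None:
        return config.fixed_p
    x = vr.mu["p"]
    ac = config.age_class("p", age)
    if ac > 0:
        x += vr.age_effects.get("p", {}).get(ac, 0.0)
    if "p" in config.gamma_params:
        x += vr.bs_effects.get("p", {}).get(state, 0.0)
    return inverse_link(x + effects.alpha_p[year], "logit")


# ---------------------------------------------------------------------------
# Transition and observation probabilities
# ---------------------------------------------------------------------------

def transition_matrix(rates, state_space: StateSpace) -> np.ndarray:
    """Stochastic matrix over latent states for one transition.

    ``rates`` is either a single :class:`Rates` bundle applied to every live
    origin state, or a mapping ``origin state -> Rates`` (breeding-state
    effects make rates origin-dependent).  From any live origin the sequential
    Bernoulli layers give P(dead) = 1-phi, P(non-breeding survivor) =
    phi(1-psi), P(failed) = phi psi (1-pi), P(successful) = phi psi pi.
    Death is absorbing.
    """
    M = np.zeros((5, 5))
    for s in LIVE_STATES:
        r = rates[s] if isinstance(rates, Mapping) else rates
        dest_nb = state_space.non_breeding_destination(s)
        M[s, DEAD] = 1.0 - r.phi
        M[s, dest_nb] += r.phi * (1.0 - r.psi)
        M[s, FAILED_BREEDER] += r.phi * r.psi * (1.0 - r.pi)
        M[s, SUCCESSFUL_BREEDER] += r.phi * r.psi * r.pi
    M[DEAD, DEAD] = 1.0
    return M


def observation_probs(rates: Rates, latent_state: int, record) -> float:
    """Probability of one year's observation given the latent state.

    A detected individual has its breeding state (and any offspring count)
    recorded without error: detection in a state other than the latent one
    has probability zero, detection in the matching live state has
    probability p times the productivity mass of the recorded count (for
    successful breeders), and non-detection has probability 1-p for live
    states and 1 for the dead state.
    """
    detected = record.detected
    if record.offspring_count is not None and detected and \
            record.state_index() != SUCCESSFUL_BREEDER:
        raise ModelError("offspring count recorded for a non-successful observed state")
    if latent_state == DEAD:
        return 0.0 if detected else 1.0
    if not detected:
        return 1.0 - rates.p
    if record.state_index() != latent_state:
        return 0.0
    prob = rates.p
    if latent_state == SUCCESSFUL_BREEDER and record.offspring_count is not None:
        prob *= math.exp(productivity_logpmf(recorded_count(record.offspring_count),
                                             rates.omega, rates.family,
                                             rates.sigma_resid))
    return prob


# ---------------------------------------------------------------------------
# Forward (hidden Markov) log-likelihood
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodResult:
    """Total log-likelihood with per-individual contributions."""

    total: float
    contributions: np.ndarray

    def __post_init__(self):
        self.contributions = np.asarray(self.contributions, dtype=float)


def _rate_tables(vr, effects, year, age, config):
    """Per-origin-state rates and per-state detection for one (year, age)."""
    by_state = {s: annual_rates(vr, effects, year, age, s, config) for s in LIVE_STATES}
    det = {s: detection_prob(vr, effects, year, age, s, config) for s in LIVE_STATES}
    return by_state, det


def forward_loglik(history: "IndividualHistory", vr: "VitalRateModel",
                   effects: "TemporalEffects", config: ModelConfig) -> float:
    """Log-likelihood of one observed capture history.

    Conditions on the first capture (known entry year and state) and sums
    over every latent alive/breeding-state path consistent with the
    detections, via the forward recursion of the hidden Markov chain.  The
    recursion runs through the final study year so that non-detections after
    the last sighting contribute the probability of being dead or alive but
    missed.
    """
    T = effects.n_years
    space = StateSpace(config.has_pre_breeder)
    e = history.entry_year
    obs = {rec.year: rec for rec in history.observed_records()}
    for y in obs:
        if y < e:
            raise ModelError(f"observation in year {y} before entry year {e}")

    f = np.zeros(5)
    f[history.entry_state_index(config)] = 1.0
    loglik = 0.0
    for t in range(e + 1, T):
        age = min(t - e, config.max_age)
        by_state, det = _rate_tables(vr, effects, t, age, config)
        M = transition_matrix(by_state, space)
        g = f @ M
        rec = obs.get(t)
        if rec is not None and rec.detected:
            o = rec.state_index()
            prob = g[o] * det[o]
            if o == SUCCESSFUL_BREEDER and rec.offspring_count is not None:
                prob *= math.exp(productivity_logpmf(
                    recorded_count(rec.offspring_count), by_state[o].omega,
                    config.productivity_family if config.is_active("omega") else None,
                    vr.sigma_omega_resid))
            g = np.zeros(5)
            g[o] = prob
        else:
            for s in LIVE_STATES:
                g[s] *= 1.0 - det[s]
        norm = g.sum()
        if norm <= 0.0:
            return -math.inf
        loglik += math.log(norm)
        f = g / norm
    return loglik


def dataset_loglik(histories: Sequence["IndividualHistory"], vr: "VitalRateModel",
                   effects: "TemporalEffects", config: ModelConfig) -> LikelihoodResult:
    """Sum of per-individual forward log-likelihoods (order invariant)."""
    contribs = np.array([forward_loglik(h, vr, effects, config) for h in histories])
    return LikelihoodResult(total=float(contribs.sum()) if len(contribs) else 0.0,
                            contributions=contribs)
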