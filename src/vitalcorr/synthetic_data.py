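"""Simulation of individual capture histories with known vital-rate truth.

The generator reproduces exactly the statistical structure the inference
model assumes: annual survival, breeding, success and productivity layers
with logit/log/identity links, age-class and previous-breeding-state effects,
year effects drawn from a multivariate normal with a specified temporal
variance-correlation structure, and Bernoulli detection with its own
independent year effect.  Newly marked juveniles are recruited in constant
numbers each year and followed until death or the end of the study.

A single integer seed drives one counter-based (Philox) generator; each
individual gets a deterministic sub-stream so datasets are reproducible
independently of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import model_core as mc
from .model_core import (DEAD, LIVE_STATES, NON_BREEDER, PARAM_ORDER, PRE_BREEDER,
                         STATE_INDEX, STATE_NAMES, SUCCESSFUL_BREEDER, ModelConfig,
                         ModelError, StateSpace)

__all__ = [
    "VitalRateModel", "CovarianceStructure", "TemporalEffects", "Record",
    "IndividualHistory", "draw_temporal_effects", "simulate_population",
    "write_dataset", "read_dataset", "load_simulation_config",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VitalRateModel:
    """Mean structure of the five vital rates plus detection.

    ``mu`` holds link-scale intercepts keyed by ``phi, psi, pi, omega, p``
    (logit for probabilities; logit/identity/log for productivity depending
    on the family).  ``age_effects[param][age_class]`` are offsets relative
    to age class 0 and ``bs_effects[param][state]`` offsets relative to the
    non-breeder reference state; reference levels are fixed at zero.
    """

    mu: dict
    age_effects: dict = field(default_factory=dict)
    bs_effects: dict = field(default_factory=dict)
    productivity_family: str | None = None
    sigma_omega_resid: float | None = None
    active_params: tuple = ("phi_j", "phi_ad", "psi", "pi", "omega")

    def __post_init__(self):
        self.active_params = tuple(p for p in PARAM_ORDER if p in self.active_params)
        if "phi_j" not in self.active_params or "phi_ad" not in self.active_params:
            raise ModelError("phi_j and phi_ad must always be active")
        for table in (self.age_effects, self.bs_effects):
            for param, levels in table.items():
                ref = 0 if table is self.age_effects else NON_BREEDER
                if levels.get(ref, 0.0) != 0.0:
                    raise ModelError(f"reference level of {param} effects must be 0")
        if self.productivity_family == "truncated_normal":
            if not (self.sigma_omega_resid and self.sigma_omega_resid > 0):
                raise ModelError("truncated_normal productivity requires sigma_omega_resid > 0")
        elif self.sigma_omega_resid is not None:
            raise ModelError("sigma_omega_resid only applies to truncated_normal productivity")

    def default_config(self, **overrides) -> ModelConfig:
        """A :class:`ModelConfig` consistent with this mean structure."""
        kwargs = dict(
            active_params=self.active_params,
            productivity_family=self.productivity_family,
            gamma_params=frozenset(p for p, v in self.bs_effects.items() if v),
        )
        kwargs.update(overrides)
        return ModelConfig(**kwargs)


@dataclass
class CovarianceStructure:
    """Temporal variance-correlation structure of the year effects.

    ``sigma`` are link-scale temporal standard deviations of the active
    parameters in ``param_order``; ``corr`` their correlation matrix (the
    implied covariance is r * sigma_X * sigma_X'); ``sigma_p`` the SD of the
    independent detection year effect.
    """

    param_order: tuple
    sigma: np.ndarray
    corr: np.ndarray
    sigma_p: float = 0.0

    def __post_init__(self):
        self.param_order = tuple(self.param_order)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        K = len(self.param_order)
        if self.sigma.shape != (K,) or self.corr.shape != (K, K):
            raise ModelError("sigma/corr dimensions inconsistent with param_order")
        if np.any(self.sigma < 0) or self.sigma_p < 0:
            raise ModelError("temporal standard deviations must be nonnegative")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ModelError(f"correlation matrix is not symmetric:\n{self.corr}")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise ModelError(f"correlation matrix must have unit diagonal:\n{self.corr}")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ModelError(f"correlations must lie in [-1, 1]:\n{self.corr}")
        if np.linalg.eigvalsh(self.corr).min() < -1e-8:
            raise ModelError(f"correlation matrix is not positive semi-definite:\n{self.corr}")

    @property
    def n_params(self) -> int:
        return len(self.param_order)

    def covariance(self) -> np.ndarray:
        return self.corr * np.outer(self.sigma, self.sigma)

    def factor(self) -> np.ndarray:
        """A (possibly rank-deficient) square root A with A A^T = covariance."""
        w, V = np.linalg.eigh(self.covariance())
        return V * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class TemporalEffects:
    """Realised year effects: T x K matrix for the active vital rates plus an
    independent length-T vector for detection."""

    alpha: np.ndarray
    alpha_p: np.ndarray
    param_order: tuple

    def __post_init__(self):
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.alpha_p = np.asarray(self.alpha_p, dtype=float)
        if self.alpha.shape[0] != self.alpha_p.shape[0]:
            raise ModelError("alpha and alpha_p span different numbers of years")
        if self.alpha.shape[1] != len(self.param_order):
            raise ModelError("alpha has wrong number of parameter columns")

    @property
    def n_years(self) -> int:
        return self.alpha.shape[0]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.n_years)


@dataclass
class Record:
    """One individual-year: latent truth plus the observation layer."""

    year: int
    alive: bool
    state: str
    offspring_count: float | None = None
    detected: bool = False

    def state_index(self) -> int:
        return STATE_INDEX[self.state]


@dataclass
class IndividualHistory:
    """One animal's per-year latent states and detections from entry onward."""

    individual_id: str
    entry_year: int
    entry_age_class: int = 0
    records: list = field(default_factory=list)

    def __post_init__(self):
        dead_seen = False
        for rec in self.records:
            if rec.detected and not rec.alive:
                raise ModelError(f"{self.individual_id}: detected while dead in year {rec.year}")
            if dead_seen and rec.alive:
                raise ModelError(f"{self.individual_id}: resurrection in year {rec.year}")
            if rec.offspring_count is not None and rec.state != "successful_breeder":
                raise ModelError(f"{self.individual_id}: offspring count outside a "
                                 f"successful-breeder year ({rec.year})")
            dead_seen = dead_seen or not rec.alive

    def observed_records(self) -> list:
        return self.records

    def entry_state_index(self, config: ModelConfig) -> int:
        first = min(self.records, key=lambda r: r.year, default=None)
        if first is not None and first.year == self.entry_year:
            return first.state_index()
        return config.entry_state()

    def last_detection_year(self) -> int:
        det = [r.year for r in self.records if r.detected]
        return max(det) if det else self.entry_year

    def observed_tuple(self):
        """Observed portion only (for round-trip comparisons)."""
        out = []
        for rec in sorted(self.records, key=lambda r: r.year):
            if rec.detected:
                cnt = rec.offspring_count
                if cnt is not None:
                    cnt = int(max(1, round(cnt)))
                out.append((rec.year, 1, rec.state, cnt))
            else:
                out.append((rec.year, 0, None, None))
        return (self.individual_id, self.entry_year, tuple(out))


# ---------------------------------------------------------------------------
# Year effects
# ---------------------------------------------------------------------------

def draw_temporal_effects(cov: CovarianceStructure, n_years: int,
                          seed: int | np.random.Generator) -> TemporalEffects:
    """Draw i.i.d. multivariate-normal year effects (and the independent
    detection year effect) for ``n_years`` years."""
    if n_years < 2:
        raise ModelError("n_years must be at least 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.Generator(np.random.Philox(seed)))
    A = cov.factor()
    alpha = rng.standard_normal((n_years, cov.n_params)) @ A.T
    alpha_p = cov.sigma_p * rng.standard_normal(n_years)
    return TemporalEffects(alpha=alpha, alpha_p=alpha_p, param_order=cov.param_order)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

def _individual_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based generator keyed deterministically per individual
    return np.random.Generator(np.random.Philox(key=(int(seed) << 32) + index))


def _draw_count(rng: np.random.Generator, omega: float, family: str | None,
                sigma_resid: float | None) -> float:
    if family is None:
        return 1.0
    if family == "bernoulli_extra_offspring":
        return 1.0 + (rng.random() < omega)
    if family == "truncated_normal":
        while True:
            x = rng.normal(omega, sigma_resid)
            if x > 0:
                return float(x)
    if family == "truncated_poisson":
        while True:
            x = rng.poisson(omega)
            if x >= 1:
                return float(x)
    raise ModelError(f"unknown productivity family {family!r}")


def simulate_population(vr: VitalRateModel, cov: CovarianceStructure,
                        effects: TemporalEffects, recruits_per_year: int,
                        n_years: int, seed: int,
                        config: ModelConfig | None = None) -> list:
    """Simulate capture histories for cohorts of newly marked juveniles.

    ``recruits_per_year`` individuals enter at age 0 in each of years
    0..T-2 and are taken through the survival -> breeding -> success ->
    productivity -> detection layers every subsequent year, sharing the
    supplied year effects.  First-year transitions use the juvenile survival
    year effect and reference-level age/state terms.
    """
    if config is None:
        config = vr.default_config()
    if effects.n_years < n_years:
        raise ModelError("temporal effects span fewer years than requested")
    if tuple(effects.param_order) != tuple(config.active_params):
        raise ModelError("effects columns do not match the active parameters")
    if set(vr.bs_effects) - set(config.gamma_params) - {"p"}:
        raise ModelError("breeding-state effects configured for inactive gamma terms")

    space = StateSpace(config.has_pre_breeder)
    A = config.max_age
    # rate lookup tables shared by all individuals: [year][age][origin state];
    # year 0 holds no transitions (recruits enter at year 0 at the earliest)
    rates_tab = [None] + \
        [[[mc.annual_rates(vr, effects, t, a, s, config) for s in range(4)]
          for a in range(A + 1)] for t in range(1, n_years)]
    det_tab = [None] + \
        [[[mc.detection_prob(vr, effects, t, a, s, config) for s in range(4)]
          for a in range(A + 1)] for t in range(1, n_years)]

    histories = []
    idx = 0
    entry_state = STATE_NAMES[config.entry_state()]
    for e in range(n_years - 1):
        for _ in range(recruits_per_year):
            rng = _individual_rng(seed, idx)
            recs = [Record(year=e, alive=True, state=entry_state, detected=True)]
            state = config.entry_state()
            alive = True
            for t in range(e + 1, n_years):
                if not alive:
                    recs.append(Record(year=t, alive=False, state="dead"))
                    continue
                a = min(t - e, A)
                r = rates_tab[t][a][state]
                if rng.random() >= r.phi:
                    alive = False
                    recs.append(Record(year=t, alive=False, state="dead"))
                    continue
                if rng.random() < r.psi:
                    if rng.random() < r.pi:
                        new_state = SUCCESSFUL_BREEDER
                        count = _draw_count(rng, r.omega, r.family, r.sigma_resid)
                    else:
                        new_state = mc.FAILED_BREEDER
                        count = None
                else:
                    new_state = space.non_breeding_destination(state)
                    count = None
                detected = rng.random() < det_tab[t][a][new_state]
                recs.append(Record(year=t, alive=True, state=STATE_NAMES[new_state],
                                   offspring_count=count, detected=detected))
                state = new_state
            histories.append(IndividualHistory(
                individual_id=f"y{e:03d}_i{idx:06d}", entry_year=e, records=recs))
            idx += 1
    return histories


# ---------------------------------------------------------------------------
# Dataset I/O (long-format CSV)
# ---------------------------------------------------------------------------

def write_dataset(histories: Iterable[IndividualHistory], path,
                  include_truth: bool = True) -> None:
    """Write histories as a long-format CSV (one row per individual-year).

    Observed columns: ``individual_id, year, detected, state, count`` — state
    and count filled only for detected years, truncated-normal counts rounded
    to the nearest positive integer.  With ``include_truth`` the latent
    truth is kept in ``true_alive, true_state, true_count`` columns for
    recovery testing.
    """
    rows = []
    for h in histories:
        for rec in sorted(h.records, key=lambda r: r.year):
            cnt = rec.offspring_count
            obs_cnt = int(max(1, round(cnt))) if (rec.detected and cnt is not None) else None
            row = {
                "individual_id": h.individual_id,
                "year": rec.year,
                "detected": int(rec.detected),
                "state": rec.state if rec.detected else "",
                "count": obs_cnt,
            }
            if include_truth:
                row["true_alive"] = int(rec.alive)
                row["true_state"] = rec.state
                row["true_count"] = cnt
            rows.append(row)
    cols = ["individual_id", "year", "detected", "state", "count"]
    if include_truth:
        cols += ["true_alive", "true_state", "true_count"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_dataset(path) -> list:
    """Read a long-format capture-history CSV back into histories.

    The observed portion round-trips losslessly; latent truth columns are
    restored when present.  Malformed rows raise :class:`ModelError` with
    the offending line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "state": str})
    required = {"individual_id", "year", "detected", "state", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"dataset missing columns {sorted(missing)}")
    has_truth = "true_state" in df.columns

    histories = []
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("year")
        recs = []
        for pos, row in grp.iterrows():
            line = pos + 2  # header is line 1
            detected = int(row["detected"])
            state = row["state"] if isinstance(row["state"], str) and row["state"] else None
            cnt = row["count"]
            cnt = None if pd.isna(cnt) else float(cnt)
            if detected and state is None:
                raise ModelError(f"line {line}: detected individual has no recorded state")
            if detected and state == "dead":
                raise ModelError(f"line {line}: individual detected in state 'dead'")
            if state is not None and state not in STATE_INDEX:
                raise ModelError(f"line {line}: unknown state {state!r}")
            if cnt is not None and (not detected or state != "successful_breeder"):
                raise ModelError(f"line {line}: offspring count outside a detected "
                                 "successful-breeder year")
            if has_truth and not pd.isna(row["true_state"]):
                alive = bool(int(row["true_alive"]))
                true_state = row["true_state"]
                true_cnt = row["true_count"]
                true_cnt = None if pd.isna(true_cnt) else float(true_cnt)
            else:
                # observed-only file: latent truth unknown, keep the observed
                # state (undetected years default to the reference live state)
                alive = True
                true_state = state if state is not None else "non_breeder"
                true_cnt = cnt
            recs.append(Record(year=int(row["year"]), alive=alive, state=true_state,
                               offspring_count=true_cnt, detected=bool(detected)))
        entry = min((r.year for r in recs if r.detected),
                    default=min(r.year for r in recs))
        histories.append(IndividualHistory(individual_id=ind, entry_year=entry,
                                           records=recs))
    return histories


# ---------------------------------------------------------------------------
# YAML simulation configuration
# ---------------------------------------------------------------------------

def load_simulation_config(path):
    """Load a YAML simulation configuration.

    Expected blocks: ``vital_rates`` (mu, age_effects, bs_effects, family,
    sigma_omega_resid, active), ``covariance`` (params, sigma, corr,
    sigma_p) and ``design`` (years, recruits, seed, correlation_type,
    pre_breeder).  Returns ``(vr, cov, design)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    vrd = raw["vital_rates"]
    bs = {p: {STATE_INDEX[k]: float(v) for k, v in tbl.items()}
          for p, tbl in vrd.get("bs_effects", {}).items()}
    age = {p: {int(k): float(v) for k, v in tbl.items()}
           for p, tbl in vrd.get("age_effects", {}).items()}
    vr = VitalRateModel(
        mu={k: float(v) for k, v in vrd["mu"].items()},
        age_effects=age, bs_effects=bs,
        productivity_family=vrd.get("family"),
        sigma_omega_resid=vrd.get("sigma_omega_resid"),
        active_params=tuple(vrd.get("active", ("phi_j", "phi_ad", "psi", "pi", "omega"))),
    )
    cvd = raw["covariance"]
    cov = CovarianceStructure(
        param_order=tuple(cvd["params"]),
        sigma=np.asarray(cvd["sigma"], dtype=float),
        corr=np.asarray(cvd["corr"], dtype=float),
        sigma_p=float(cvd.get("sigma_p", 0.0)),
    )
    design = dict(raw.get("design", {}))
    return vr, cov, design
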