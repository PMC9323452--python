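"""Generation time from projection matrices and the correlation-pace regression.

Generation time — the mean age of mothers at the stable age distribution —
is computed as the inverse of the summed elasticities of the asymptotic
growth rate to the fecundity entries of an age-structured, female-based
projection matrix (equivalently T = lambda (v.w) / (v F w), with v and w the
reproductive-value and stable-age eigenvectors and F the fecundity part of
the matrix).  Species-specific correlation posteriors are then regressed on
generation time, propagating posterior uncertainty by fitting the regression
draw by draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .correlation_analysis import SpeciesCorrelationSet, resample_draws
from .inference import sign_probability
from .model_core import ModelError

__all__ = [
    "ProjectionModel", "MetaRegressionResult", "build_projection_matrix",
    "generation_time", "meta_regression",
]


@dataclass
class ProjectionModel:
    """Age-structured projection matrix with its eigen-analysis.

    ``A`` is the full matrix, ``F`` the fecundity components of its entries
    (same shape; survival components are ``A - F``).  ``w`` is the stable
    age distribution (sums to 1), ``v`` reproductive values scaled so that
    v.w = 1, ``elasticities`` e_ij = (a_ij/lambda) v_i w_j, and ``T`` the
    generation time 1 / sum of fecundity elasticities.
    """

    A: np.ndarray
    F: np.ndarray
    lam: float
    w: np.ndarray
    v: np.ndarray
    elasticities: np.ndarray
    T: float


def _eigen_analysis(A: np.ndarray):
    vals, right = np.linalg.eig(A)
    lead = np.argmax(vals.real)
    if abs(vals[lead].imag) > 1e-10:
        raise ModelError("dominant eigenvalue is not real; matrix may be reducible")
    lam = float(vals[lead].real)
    if lam <= 0:
        raise ModelError("dominant eigenvalue must be positive")
    order = np.argsort(-vals.real)
    if len(vals) > 1 and abs(vals[order[0]]) - abs(vals[order[1]]) < 1e-12 * abs(lam):
        warnings.warn("dominant eigenvalue is not unique; matrix may be "
                      "imprimitive or reducible", stacklevel=3)
    w = right[:, lead].real
    w = w / w.sum()
    lvals, left = np.linalg.eig(A.T)
    llead = np.argmax(lvals.real)
    v = left[:, llead].real
    if v @ w < 0:
        v = -v
    v = v / (v @ w)
    return lam, w, v


def build_projection_matrix(mean_rates: dict, config: dict | None = None) -> ProjectionModel:
    """Assemble a pre-breeding-census female projection matrix.

    ``mean_rates`` has keys ``phi_juv`` (first-year survival), ``phi``
    (adult survival per age class, sequence), and optionally per-class
    ``psi``, ``pi``, ``omega`` (scalars or sequences; defaults 1).  The
    fecundity entry of class a is psi_a * pi_a * omega_a * rho * phi_juv
    with ``rho`` the daughters-per-offspring factor (config key, default
    0.5); the survival subdiagonal carries the adult survival rates and the
    terminal class keeps a self-loop.
    """
    config = config or {}
    rho = float(config.get("rho", 0.5))
    phi = np.atleast_1d(np.asarray(mean_rates["phi"], dtype=float))
    n = phi.size
    if np.any((phi <= 0) | (phi >= 1)):
        raise ModelError("adult survival rates must lie in (0, 1)")
    phi_j = float(mean_rates["phi_juv"])
    if not 0 < phi_j < 1:
        raise ModelError("juvenile survival must lie in (0, 1)")

    def per_class(key):
        val = mean_rates.get(key, 1.0)
        arr = np.broadcast_to(np.asarray(val, dtype=float), (n,)).copy()
        return arr

    fec = per_class("psi") * per_class("pi") * per_class("omega") * rho * phi_j
    if np.all(fec == 0):
        raise ModelError("all fecundities are zero; no generation time exists")

    A = np.zeros((n, n))
    F = np.zeros((n, n))
    A[0, :] += fec
    F[0, :] = fec
    for j in range(n - 1):
        A[j + 1, j] += phi[j]
    A[n - 1, n - 1] += phi[n - 1]

    lam, w, v = _eigen_analysis(A)
    E = (A / lam) * np.outer(v, w)
    fec_elas = float((F / lam * np.outer(v, w)).sum())
    return ProjectionModel(A=A, F=F, lam=lam, w=w, v=v, elasticities=E,
                           T=1.0 / fec_elas)


def generation_time(model: ProjectionModel) -> float:
    """Generation time = 1 / (sum of elasticities of lambda to fecundities)."""
    fec_elas = float((model.F / model.lam * np.outer(model.v, model.w)).sum())
    if fec_elas <= 0:
        raise ModelError("fecundity elasticities sum to zero")
    return 1.0 / fec_elas


@dataclass
class MetaRegressionResult:
    """Draw-wise OLS of species correlations on generation time."""

    pair: tuple
    slopes: np.ndarray
    intercepts: np.ndarray
    slope_mean: float
    slope_P: float
    r_squared: float
    n_species: int

    def summary(self) -> dict:
        lo, hi = np.quantile(self.slopes, [0.025, 0.975])
        return {"slope": self.slope_mean, "q2.5": float(lo), "q97.5": float(hi),
                "P": self.slope_P, "r_squared": self.r_squared,
                "n_species": self.n_species}


def meta_regression(sets: Sequence[SpeciesCorrelationSet], pair: tuple,
                    n_draws: int = 3000, seed: int = 0) -> MetaRegressionResult:
    """Regress species correlation draws on fixed generation times.

    For each aligned posterior draw d, an ordinary least-squares line is fit
    to the species' correlation draws against their (point-estimate)
    generation times; the slope posterior is summarised with its sign
    probability P, and R-squared is computed at the posterior means.
    """
    contrib = [s for s in sets if pair in s.draws and s.generation_time is not None]
    if len(contrib) < 3:
        raise ModelError("meta-regression needs at least 3 species with the pair "
                         "and a generation time")
    g = np.array([s.generation_time for s in contrib], dtype=float)
    R = np.stack([resample_draws(s.draws[pair], n_draws, seed=seed + i)
                  for i, s in enumerate(contrib)])  # (S, n_draws)
    gc = g - g.mean()
    var_g = float(gc @ gc)
    slopes = (gc @ R) / var_g
    intercepts = R.mean(axis=0) - slopes * g.mean()

    means = R.mean(axis=1)
    slope_hat = float(gc @ means) / var_g
    resid = means - (means.mean() + slope_hat * gc)
    ss_tot = float(((means - means.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0

    return MetaRegressionResult(pair=pair, slopes=slopes, intercepts=intercepts,
                                slope_mean=float(slopes.mean()),
                                slope_P=sign_probability(slopes),
                                r_squared=r2, n_species=len(contrib))
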