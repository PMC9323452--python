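"""Cross-species synthesis of fitted temporal correlations.

Species-specific posteriors of pairwise correlations are combined by
draw-wise averaging into grand-mean posteriors, tallied by sign and
credible-interval overlap with zero, and contrasted between the two pairing
conventions (reproduction with preceding vs subsequent survival).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import sign_probability
from .model_core import ModelError

__all__ = [
    "SpeciesCorrelationSet", "GrandMeanResult", "correlations_from_sigma",
    "grand_mean", "direction_tally", "compare_types", "resample_draws",
]


@dataclass
class SpeciesCorrelationSet:
    """Posterior correlation draws of one species under one pairing type.

    ``draws`` maps a parameter pair (tuple of two names) to a 1-D vector of
    posterior draws of their temporal correlation; ``generation_time`` is
    filled by the pace-of-life analysis.
    """

    species: str
    correlation_type: int
    draws: dict = field(default_factory=dict)
    generation_time: float | None = None

    def __post_init__(self):
        for pair, v in self.draws.items():
            v = np.asarray(v, dtype=float)
            if np.any(np.abs(v) > 1 + 1e-9):
                raise ModelError(f"{self.species}: correlation draws for {pair} "
                                 "outside [-1, 1]")
            self.draws[pair] = np.clip(v, -1.0, 1.0)

    def pairs(self):
        return list(self.draws)


@dataclass
class GrandMeanResult:
    """Posterior of the across-species mean correlation for one pair."""

    pair: tuple
    draws: np.ndarray
    n_species: int

    def summary(self) -> dict:
        d = self.draws
        lo, hi = np.quantile(d, [0.025, 0.975])
        return {"mean": float(d.mean()), "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                "q2.5": float(lo), "q97.5": float(hi), "P": sign_probability(d),
                "n_species": self.n_species}


# ---------------------------------------------------------------------------

def correlations_from_sigma(sigma_draws: tuple, cov_draws: np.ndarray) -> np.ndarray:
    """Per-draw correlation r = cov / (sigma_X sigma_X').

    ``sigma_draws`` is a pair of SD draw vectors; draws with a zero SD are
    excluded with a warning (degenerate variance carries no correlation).
    """
    s1 = np.asarray(sigma_draws[0], dtype=float)
    s2 = np.asarray(sigma_draws[1], dtype=float)
    cov = np.asarray(cov_draws, dtype=float)
    if not (s1.shape == s2.shape == cov.shape):
        raise ModelError("sigma and covariance draws have mismatched lengths")
    ok = (s1 > 0) & (s2 > 0)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} draws with degenerate "
                      "(zero) temporal SD", stacklevel=2)
    r = cov[ok] / (s1[ok] * s2[ok])
    return np.clip(r, -1.0 - 1e-12, 1.0 + 1e-12)


def resample_draws(draws: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Deterministically bring a draw vector to length ``n``: identity when
    already there, even thinning when longer, seeded bootstrap when shorter."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == n:
        return draws
    if draws.size > n:
        idx = np.linspace(0, draws.size - 1, n).round().astype(int)
        return draws[idx]
    rng = np.random.Generator(np.random.Philox(seed))
    return draws[rng.integers(0, draws.size, n)]


def grand_mean(sets: Sequence[SpeciesCorrelationSet], pair: tuple,
               n_draws: int = 3000, seed: int = 0) -> GrandMeanResult:
    """Posterior of the grand-mean correlation for ``pair``.

    Species posteriors are independent, so each contributing species is
    resampled to a common draw count and draw d of the grand mean is the
    across-species average of the species' draws d.
    """
    contrib = [s for s in sets if pair in s.draws]
    if not contrib:
        raise ModelError(f"no species provides the pair {pair}")
    stacked = np.stack([resample_draws(s.draws[pair], n_draws, seed=seed + i)
                        for i, s in enumerate(contrib)])
    return GrandMeanResult(pair=pair, draws=stacked.mean(axis=0),
                           n_species=len(contrib))


def direction_tally(sets: Sequence[SpeciesCorrelationSet],
                    pairs: Sequence[tuple] | None = None) -> dict:
    """Sign and CRI tallies across species-pair correlation estimates.

    Returns counts of positive/negative posterior means, the fraction of
    95% CRIs overlapping zero, and — when both pairing types are present for
    a species-pair — the fraction of type-1 vs type-2 posterior-mean sign
    flips.  ``per_estimate`` holds the underlying tidy table.
    """
    if pairs is None:
        pairs = sorted({p for s in sets for p in s.draws})
    rows = []
    for s in sets:
        for pair in pairs:
            if pair not in s.draws:
                continue
            d = s.draws[pair]
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({"species": s.species, "type": s.correlation_type,
                         "pair": "~".join(pair), "mean": float(d.mean()),
                         "q2.5": float(lo), "q97.5": float(hi),
                         "P": sign_probability(d),
                         "cri_overlaps_zero": bool(lo <= 0.0 <= hi)})
    table = pd.DataFrame(rows)
    if table.empty:
        return {"per_estimate": table, "n_estimates": 0}
    n_pos = int((table["mean"] > 0).sum())
    n_neg = int((table["mean"] < 0).sum())
    flips = []
    for (species, pair), grp in table.groupby(["species", "pair"]):
        if set(grp["type"]) >= {1, 2}:
            m1 = grp.loc[grp["type"] == 1, "mean"].iloc[0]
            m2 = grp.loc[grp["type"] == 2, "mean"].iloc[0]
            flips.append(np.sign(m1) != np.sign(m2))
    return {
        "per_estimate": table,
        "n_estimates": len(table),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "frac_cri_overlap_zero": float(table["cri_overlaps_zero"].mean()),
        "n_type_comparisons": len(flips),
        "frac_sign_flips": float(np.mean(flips)) if flips else np.nan,
    }


def compare_types(type1: SpeciesCorrelationSet, type2: SpeciesCorrelationSet,
                  pair: tuple, n_draws: int = 3000, seed: int = 0) -> dict:
    """Posterior of r(type 2) - r(type 1) for one pair on the same dataset.

    The two fits are independent, so differences are formed by pairing equal
    draw indices after resampling to a common count; summarised with P.
    """
    if pair not in type1.draws or pair not in type2.draws:
        raise ModelError(f"pair {pair} missing from one of the fits")
    d1 = resample_draws(type1.draws[pair], n_draws, seed=seed)
    d2 = resample_draws(type2.draws[pair], n_draws, seed=seed + 1)
    diff = d2 - d1
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return {"pair": pair, "draws": diff, "mean": float(diff.mean()),
            "q2.5": float(lo), "q97.5": float(hi), "P": sign_probability(diff)}
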