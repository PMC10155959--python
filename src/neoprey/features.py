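"""Neoantigen feature sampling and immunogenicity assignment.

Feature vectors couple log MHC binding affinity, log binding stability and log
agretopicity through a Gaussian copula; transcript abundance is exponential and
foreignness follows a zero- and one-inflated beta mixture. A neoantigen is
putatively immunogenic only if it clears every filter threshold, in which case
its intrinsic immunogenicity R is drawn from a truncated exponential on [0, 1];
otherwise R = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import TeslaCriteria, TeslaFeatureParams

__all__ = [
    "Neoantigen",
    "sample_features",
    "sample_feature_arrays",
    "sample_foreignness",
    "passes_tesla",
    "assign_immunogenicity",
    "sample_founder_clonal_burden",
    "elispot_to_immunogenicity",
    "make_neoantigens",
]

FEATURE_COLUMNS = ("affinity_nM", "stability_h", "agretopicity", "tpm",
                   "foreignness")
#: columns assessed by the filter (transcript abundance is excluded: it is
#: conflated with clonality, which the simulator models explicitly)
ASSESSED_COLUMNS = ("affinity_nM", "stability_h", "agretopicity", "foreignness")


@dataclass
class Neoantigen:
    """One neoantigen: identity, immunogenicity and presenting MHC allele."""

    id: int
    R: float
    mhc_allele: int
    features: Optional[dict] = None
    origin: str = "founder"       # 'founder' | 'gained'

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")
        if self.mhc_allele < 0:
            raise ValueError("mhc_allele must be a nonnegative index")


def sample_feature_arrays(n: int, params: TeslaFeatureParams,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sample ``n`` feature vectors as a dict of plain arrays (fast path)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return {c: np.zeros(0) for c in FEATURE_COLUMNS}
    z = rng.standard_normal((n, 3)) @ params.cholesky.T
    return {
        "affinity_nM": params.marginal_affinity.ppf_from_z(z[:, 0]),
        "stability_h": params.marginal_stability.ppf_from_z(z[:, 1]),
        "agretopicity": params.marginal_agretopicity.ppf_from_z(z[:, 2]),
        "tpm": rng.exponential(scale=1.0 / params.lam, size=n),
        "foreignness": sample_foreignness(n, params, rng),
    }


def sample_features(n: int, params: TeslaFeatureParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Sample ``n`` feature vectors.

    The three copula-coupled features are generated by drawing correlated
    standard-normal scores (Cholesky factor of rho) and pushing each through
    its log-normal marginal; this is exact for Gaussian copulas with
    log-normal margins. Transcript abundance and foreignness are independent
    of the copula block.
    """
    return pd.DataFrame(sample_feature_arrays(n, params, rng))


def sample_foreignness(n: int, params: TeslaFeatureParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw foreignness values from the zero- and one-inflated beta mixture.

    A draw is exactly 0 with probability phat1, exactly 1.0 (the one-inflated
    ">0.99" component) with probability phat2, and Beta(alpha, beta) otherwise.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if params.phat1 + params.phat2 > 1.0:
        raise ValueError("phat1 + phat2 must not exceed 1")
    u = rng.random(n)
    out = np.empty(n)
    zero = u < params.phat1
    one = (~zero) & (u < params.phat1 + params.phat2)
    interior = ~(zero | one)
    out[zero] = 0.0
    out[one] = 1.0
    n_int = int(interior.sum())
    if n_int:
        out[interior] = rng.beta(params.alpha, params.beta, size=n_int)
    return out


def passes_tesla(features,
                 criteria: Optional[TeslaCriteria] = None) -> np.ndarray:
    """Boolean vector: does each feature row clear all four thresholds?

    All comparisons are strict, so boundary values fail. Transcript abundance
    is not assessed. Accepts a DataFrame or a dict of arrays.
    """
    criteria = criteria or TeslaCriteria()
    cols = (features.columns if isinstance(features, pd.DataFrame)
            else features.keys())
    missing = [c for c in ASSESSED_COLUMNS if c not in cols]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    ok = (
        (np.asarray(features["affinity_nM"]) < criteria.affinity_max_nM)
        & (np.asarray(features["stability_h"]) > criteria.stability_min_h)
        & (np.asarray(features["agretopicity"]) > criteria.agretopicity_min)
    )
    fr = np.asarray(features["foreignness"])
    if criteria.foreignness_direction == "pass-if-below":
        ok &= fr < criteria.foreignness_cutoff
    else:
        ok &= fr > criteria.foreignness_cutoff
    return ok


def assign_immunogenicity(pass_flags: np.ndarray, epsilon: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Assign R: 0 for failing entries, truncated-Exp(epsilon) on [0,1] otherwise.

    Sampling is by exact inverse CDF of the truncated exponential,
    F(x) = (1 - e^{-eps x}) / (1 - e^{-eps}).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pass_flags = np.asarray(pass_flags, dtype=bool)
    R = np.zeros(pass_flags.shape, dtype=float)
    n_pass = int(pass_flags.sum())
    if n_pass:
        u = rng.random(n_pass)
        R[pass_flags] = -np.log1p(-u * (1.0 - np.exp(-epsilon))) / epsilon
    return R


def sample_founder_clonal_burden(g1: float, g2: float,
                                 rng: np.random.Generator,
                                 size: Optional[int] = None,
                                 round_to_int: bool = True):
    """Founder clonal neoantigen count: round(Gamma(shape=g1, scale=g2)).

    Rounding is half-up; the result is never negative. ``round_to_int=False``
    returns the raw gamma draws (useful for refitting the distribution).
    """
    if g1 <= 0 or g2 < 0:
        raise ValueError("g1 must be positive and g2 nonnegative")
    if g2 == 0:
        zero = 0 if round_to_int else 0.0
        return zero if size is None else np.zeros(
            size, dtype=int if round_to_int else float)
    draw = rng.gamma(shape=g1, scale=g2, size=size)
    if not round_to_int:
        return float(draw) if size is None else draw
    rounded = np.floor(draw + 0.5).astype(int)
    return int(rounded) if size is None else rounded


def elispot_to_immunogenicity(scores) -> np.ndarray:
    """Min-max scale baseline-corrected ELISpot scores to [0, 1].

    A constant vector carries no evidence of immunogenicity differences and
    maps to all zeros.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("at least one score required")
    if np.any(scores < 0):
        raise ValueError("ELISpot scores must be nonnegative")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def make_neoantigens(n: int, n_alleles: int,
                     params: Optional[TeslaFeatureParams] = None,
                     criteria: Optional[TeslaCriteria] = None,
                     rng: Optional[np.random.Generator] = None,
                     start_id: int = 0,
                     origin: str = "founder") -> list[Neoantigen]:
    """Sample ``n`` complete neoantigens with uniform random allele assignment.

    Two alleles correspond to the mouse hosts (H2-Db/H2-Kb), three to human
    HLA-A/B/C; other counts are permitted for experimentation.
    """
    import warnings

    params = params or TeslaFeatureParams()
    criteria = criteria or TeslaCriteria()
    if rng is None:
        rng = np.random.default_rng()
    if n_alleles not in (2, 3):
        warnings.warn(
            f"n_alleles={n_alleles} is outside the modeled hosts (2 mouse, 3 human)",
            stacklevel=2,
        )
    if n == 0:
        return []
    feats = sample_feature_arrays(n, params, rng)
    flags = passes_tesla(feats, criteria)
    R = assign_immunogenicity(flags, params.epsilon, rng)
    alleles = rng.integers(0, n_alleles, size=n)
    out = []
    for i in range(n):
        out.append(
            Neoantigen(
                id=start_id + i,
                R=float(R[i]),
                mhc_allele=int(alleles[i]),
                features={c: float(feats[c][i]) for c in FEATURE_COLUMNS},
                origin=origin,
            )
        )
    return out
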