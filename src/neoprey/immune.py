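"""Immune compartment: antigen-specific CTL clones, the pooled tumor-ignorant
population, the shared nonspecific stimulus, and lineage-specific killing.

Each CTL clone recognizes exactly one neoantigen. Clones expand on
immunogenicity-weighted antigen stimulus and contract when the shared
nonspecific stimulus C falls below its homeostatic value of 1; C is consumed
in proportion to total CTL numbers relative to the systemic carrying capacity.
Checkpoint blockade multiplies both the antigen-sensitivity term and the
carrying capacity by the same scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ImmuneParams

__all__ = [
    "CTLClone",
    "ImmuneState",
    "init_clone_size",
    "clone_derivative",
    "nsctl_derivative",
    "stimulus_derivative",
    "reactive_fraction",
    "lineage_death_rate",
    "tcr_entropy",
]


@dataclass
class CTLClone:
    id: int
    cognate_neoantigen: int
    size: float

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("clone size must be nonnegative")


class ImmuneState:
    """Clone sizes (indexed by cognate neoantigen id), NSCTL pool and C.

    Clone storage uses an amortized doubling buffer so that spawning clones
    for gained neoantigens stays O(1) even with very mutable tumors.
    """

    def __init__(self, params: ImmuneParams):
        self.params = params
        self._buf = np.zeros(16)
        self._day_buf = np.zeros(16, dtype=int)
        self._n = 0
        self.NSCTL = params.TCR_other
        self.C = params.C0

    @property
    def sizes(self) -> np.ndarray:
        """View of live clone sizes; sizes[k] is cognate to neoantigen k."""
        return self._buf[:self._n]

    @sizes.setter
    def sizes(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.size != self._n:
            raise ValueError("cannot resize clone vector by assignment")
        self._buf[:self._n] = values

    @property
    def created_day(self) -> np.ndarray:
        return self._day_buf[:self._n]

    def add_clone(self, size: float, day: int = 0) -> int:
        """Append the clone for the next registered neoantigen; returns its id."""
        if self._n == self._buf.size:
            self._buf = np.concatenate([self._buf, np.zeros(self._buf.size)])
            self._day_buf = np.concatenate(
                [self._day_buf, np.zeros(self._day_buf.size, dtype=int)])
        self._buf[self._n] = float(size)
        self._day_buf[self._n] = day
        self._n += 1
        return self._n - 1

    @property
    def total_reactive(self) -> float:
        return float(self.sizes.sum())

    @property
    def total_ctl(self) -> float:
        return self.NSCTL + self.total_reactive


def init_clone_size(mu: float, rng: np.random.Generator) -> float:
    """Founding clone size 2^n with n ~ Poisson(mu) pre-efflux divisions."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return float(2.0 ** rng.poisson(mu))


def clone_derivative(size: float, S_k: float, C: float,
                     params: ImmuneParams) -> float:
    """dCTL_k/dt = CTL_k*T_d*(C-1) + ICB*S_k*T_a*C.

    The antigen term is per-capita stimulus S_k*T_a*C/CTL_k times CTL_k:
    antigen available to each cell shrinks as the clone grows.
    """
    return size * params.T_d * (C - 1.0) + params.icb * S_k * params.T_a * C


def nsctl_derivative(NSCTL: float, C: float, params: ImmuneParams) -> float:
    """dNSCTL/dt = NSCTL*T_d*(C-1): the tumor-ignorant pool sees no antigen."""
    return NSCTL * params.T_d * (C - 1.0)


def stimulus_derivative(total_ctl: float, params: ImmuneParams) -> float:
    """dC/dt = kin - kin*fout - kin*(1-fout)*total_ctl/(ICB*CTL_ss).

    Replenished at kin, consumed by non-CTLs (kin*fout) and by CTLs in
    proportion to their number relative to the (treatment-scaled) systemic
    carrying capacity. C is clamped at 0 by the integrator.
    """
    return (params.kin - params.kin * params.fout
            - params.kin * (1.0 - params.fout) * total_ctl
            / (params.icb * params.CTL_ss))


def reactive_fraction(sizes_on_lineage: np.ndarray, NSCTL: float) -> float:
    """phi: reactive CTLs on a lineage's immunopeptidome over all CTLs.

    ``sizes_on_lineage`` are the clone sizes whose cognate neoantigens the
    lineage actually presents (E_k * MHC_k = 1). Degenerate all-zero input
    returns 0.
    """
    reactive = float(np.sum(sizes_on_lineage))
    denom = NSCTL + reactive
    if denom <= 0:
        return 0.0
    return reactive / denom


def _killing_h(x, form: str):
    if form == "rational":
        return x / (1.0 + x * x)
    if form == "hill1":
        return x / (1.0 + x)
    if form == "hill2":
        return x * x / (1.0 + x * x)
    raise ValueError(f"unknown killing_form {form!r}")


def lineage_death_rate(phi, params: ImmuneParams, fdie: float = 0.3):
    """kd_i = f_die + (k_mag + 1 - f_die) * h(phi * k_kill).

    ``fdie`` is the tumor-side natural turnover fraction. The default
    rational form h(x) = x/(1+x^2) lets kd exceed 1 with k_mag = 1 (tumor
    shrinkage becomes possible once reactive CTLs outnumber ignorant ones
    roughly 3:1) and is increasing on the feasible domain since
    phi*k_kill <= k_kill < 1. Accepts scalars or arrays.
    """
    x = np.asarray(phi, dtype=float) * params.k_kill
    kd = fdie + (params.k_mag + 1.0 - fdie) * _killing_h(x, params.killing_form)
    return kd if kd.ndim else float(kd)


def tcr_entropy(sizes, mode: str = "shannon") -> float:
    """Diversity of the tumor-reactive repertoire.

    'shannon': H = -sum p_k ln p_k on clone frequencies (nats).
    'wentropy': the unnormalized -sum x^2 ln x^2 convention of MATLAB's
    wavelet-entropy routine, provided for auditability only (scale-dependent).
    """
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[sizes > 0]
    if sizes.size == 0:
        raise ValueError("entropy undefined for an empty repertoire")
    if mode == "wentropy":
        return float(-np.sum(sizes ** 2 * np.log(sizes ** 2)))
    if mode != "shannon":
        raise ValueError("mode must be 'shannon' or 'wentropy'")
    p = sizes / sizes.sum()
    return float(-np.sum(p * np.log(p)))
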