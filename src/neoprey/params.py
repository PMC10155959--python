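"""Model parameter containers and species/histology presets.

Every quantity carries the symbol it is published under (kg, f_die, nG, ...)
so a configuration file can be audited line-by-line against the source table.
Rates are per day; cell volumes in cm^3; populations in cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TeslaFeatureParams",
    "TeslaCriteria",
    "TumorParams",
    "ImmuneParams",
    "Preset",
    "get_preset",
    "PRESET_NAMES",
]


def _default_rho() -> np.ndarray:
    # Gaussian-copula correlation over (log affinity, log stability, log
    # agretopicity). Must be symmetric positive definite.
    return np.array(
        [
            [1.0, -0.3495, -0.930],
            [-0.3495, 1.0, 0.2041],
            [-0.930, 0.2041, 1.0],
        ]
    )


@dataclass
class LogNormalMarginal:
    """Log-normal marginal given as (median, sd of the log)."""

    median: float
    log_sd: float

    def ppf_from_z(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal scores to the marginal (exact for log-normals)."""
        return np.exp(np.log(self.median) + self.log_sd * z)


@dataclass
class TeslaFeatureParams:
    """Distributional parameters for neoantigen feature sampling.

    The copula couples the three log-scale features; transcript abundance is
    exponential (rate parameterization) and foreignness is a zero- and
    one-inflated beta mixture. ``epsilon`` is the rate of the truncated
    exponential used for intrinsic immunogenicity R on [0, 1].
    """

    rho: np.ndarray = field(default_factory=_default_rho)
    lam: float = 6.6625           # transcript-abundance exponential rate
    phat1: float = 0.7603         # P(foreignness == 0)
    phat2: float = 0.0685         # P(foreignness > 0.99), emitted as 1.0
    alpha: float = 0.0597         # interior beta shape 1
    beta: float = 1.4404          # interior beta shape 2
    epsilon: float = 6.0          # immunogenicity truncated-exp rate
    # Marginals for the copula-coupled features. Not published; centered on
    # prefiltered predicted-binder scales (candidate neoantigen pipelines
    # select strong predicted binders, so affinities sit at tens of nM and
    # stabilities near an hour), giving a joint filter pass rate of ~7.7%
    # and ~5 putatively immunogenic neoantigens per median founder burden.
    marginal_affinity: LogNormalMarginal = field(
        default_factory=lambda: LogNormalMarginal(100.0, 1.5)
    )
    marginal_stability: LogNormalMarginal = field(
        default_factory=lambda: LogNormalMarginal(0.75, 1.0)
    )
    marginal_agretopicity: LogNormalMarginal = field(
        default_factory=lambda: LogNormalMarginal(1.0, 1.5)
    )

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self._chol = None
        self.validate()

    @property
    def cholesky(self) -> np.ndarray:
        """Cached lower Cholesky factor of rho (validated once)."""
        if self._chol is None:
            self.validate()
        return self._chol

    def validate(self) -> None:
        rho = self.rho
        if rho.shape != (3, 3):
            raise ValueError("rho must be a 3x3 correlation matrix")
        if not np.allclose(rho, rho.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValueError("rho must have unit diagonal")
        try:
            self._chol = np.linalg.cholesky(rho)
        except np.linalg.LinAlgError as exc:
            raise ValueError("rho must be positive definite") from exc
        if not (0.0 <= self.phat1 <= 1.0 and 0.0 <= self.phat2 <= 1.0):
            raise ValueError("phat1 and phat2 must lie in [0, 1]")
        if self.phat1 + self.phat2 > 1.0:
            raise ValueError("phat1 + phat2 must not exceed 1")
        for name in ("lam", "alpha", "beta", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TeslaCriteria:
    """Immunogenicity filter thresholds (all strict inequalities)."""

    affinity_max_nM: float = 34.0
    stability_min_h: float = 1.4
    agretopicity_min: float = 0.1
    foreignness_cutoff: float = 1e-16
    # The cutoff direction is configurable because the upstream consortium
    # treats *high* foreignness as immunogenic; the default follows the
    # calibration source as printed.
    foreignness_direction: str = "pass-if-below"

    def __post_init__(self) -> None:
        for name in ("affinity_max_nM", "stability_min_h", "agretopicity_min",
                     "foreignness_cutoff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")
        if self.foreignness_direction not in ("pass-if-below", "pass-if-above"):
            raise ValueError(
                "foreignness_direction must be 'pass-if-below' or 'pass-if-above'"
            )


@dataclass
class TumorParams:
    """Tumor-compartment parameters (logistic growth + immunopeptidome events)."""

    kg: float = 0.02              # crude birth rate, 1/day
    fdie: float = 0.3             # fraction of deaths not immune-attributed
    cellVol: float = 4.19e-9      # cell volume, cm^3 (~4 pL)
    K: float = 5e11               # carrying capacity, cells
    nG: float = 2.5e-9            # base neoantigen gain rate, /cell/day
    nGS: float = 2.303            # log-sd of per-tumor base gain rate
    nGSt: float = 2.303           # log-sd of day-to-day gain-rate jitter
    nL: float = 1.68e-9           # neoantigen loss rate, /cell/day
    hlaL: float = 1.68e-9         # MHC allele loss rate, /cell/day
    hlaL0: float = 0.14           # founder clonal MHC-loss probability
    g1: float = 1.14              # founder burden gamma shape
    g2: float = 56.24             # founder burden gamma scale
    n_mhc_alleles: int = 3
    extinction_threshold: float = 0.5   # cells; below this a lineage is pruned
    # 'mean': the log-normal per-tumor base rate and daily jitter both have
    # mean nG (resp. base), so nG is the realized average gain rate.
    # 'median' makes nG the median instead, which inflates the realized
    # average by e^{sigma^2/2} (~14x at sigma = 2.303).
    gain_rate_convention: str = "mean"

    def __post_init__(self) -> None:
        if self.kg <= 0 or self.K <= 0 or self.cellVol <= 0:
            raise ValueError("kg, K and cellVol must be positive")
        if not 0.0 <= self.fdie <= 1.0:
            raise ValueError("fdie must lie in [0, 1]")
        for name in ("nG", "nGS", "nGSt", "nL", "hlaL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.hlaL0 <= 1.0:
            raise ValueError("hlaL0 must lie in [0, 1]")
        if self.gain_rate_convention not in ("median", "mean"):
            raise ValueError("gain_rate_convention must be 'median' or 'mean'")


@dataclass
class ImmuneParams:
    """CTL-compartment parameters (clone dynamics, shared stimulus, killing)."""

    C0: float = 1.0               # initial nonspecific stimulus
    kin: float = 0.01             # stimulus fractional turnover, 1/day
    fout: float = 0.3             # non-CTL consumption fraction
    CTL_ss: float = 1e11          # steady-state T-cell population (T_ss)
    TCR_other: float = 1e11       # baseline nonspecific T cells
    T_d: float = 0.05             # naive T-cell fractional turnover, 1/day
    mu: float = 4.0               # Poisson divisions before thymic efflux
    T_a: float = 3e-2             # antigen-stimulus scaling factor
    k_kill: float = 0.7           # saturable-killing shape
    k_mag: float = 1.0            # saturable-killing magnitude (k_max)
    killing_form: str = "rational"  # 'rational' | 'hill1' | 'hill2'
    icb: float = 1.0              # treatment multiplier (>= 1)

    def __post_init__(self) -> None:
        for name in ("kin", "CTL_ss", "TCR_other", "T_d", "T_a", "k_kill",
                     "k_mag"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if not 0.0 <= self.fout <= 1.0:
            raise ValueError("fout must lie in [0, 1]")
        if self.icb < 1.0:
            raise ValueError("icb must be >= 1")
        if self.killing_form not in ("rational", "hill1", "hill2"):
            raise ValueError("killing_form must be rational, hill1 or hill2")


@dataclass
class Preset:
    """A named bundle of tumor + immune parameters and simulation mode flags."""

    name: str
    tumor: TumorParams
    immune: ImmuneParams
    species: str                  # 'mouse' | 'human'
    immunodeficient: bool = False
    events_enabled: bool = True
    features: TeslaFeatureParams = field(default_factory=TeslaFeatureParams)
    criteria: TeslaCriteria = field(default_factory=TeslaCriteria)
    founder_cells: float = 1.0

    def with_icb(self, strength: float) -> "Preset":
        return replace(self, immune=replace(self.immune, icb=float(strength)))


def _mouse_tumor(kg: float = 0.2) -> TumorParams:
    # Mouse runs hold the immunopeptidome constant: all event rates zero.
    return TumorParams(
        kg=kg, fdie=0.3, cellVol=4.19e-9, K=7e8,
        nG=0.0, nGS=0.0, nGSt=0.0, nL=0.0, hlaL=0.0, hlaL0=0.0,
        n_mhc_alleles=2,
    )


def _mouse_immune() -> ImmuneParams:
    return ImmuneParams(
        kin=0.4, fout=0.3, CTL_ss=1e8, TCR_other=1e8,
        T_d=0.0333, mu=4.0, T_a=3e-3,
    )


def _human_tumor() -> TumorParams:
    return TumorParams()


def _human_immune() -> ImmuneParams:
    return ImmuneParams()


PRESET_NAMES = (
    "mouse_nsg",
    "mouse_c57bl6",
    "mc38_immunodeficient",
    "mc38_immunocompetent",
    "human_nsclc",
    "rcc_like",
    "msi_like",
)


def get_preset(name: str) -> Preset:
    """Return a fresh Preset by name.

    Mouse presets start from a single ~4.77e7-cell lineage with a fixed
    neoantigen panel and no stochastic immunopeptidome events. Human presets
    start from a single founder cell with a gamma-distributed clonal burden.
    The MC38 variants raise the mouse growth rate by 50%; the RCC-like preset
    halves human growth and cuts gain/loss/MHC-loss rates by 90%; the MSI-like
    preset doubles growth and triples the founder clonal burden scale.
    """
    if name == "mouse_nsg":
        return Preset(name, _mouse_tumor(), _mouse_immune(), "mouse",
                      immunodeficient=True, events_enabled=False,
                      founder_cells=4.77e7)
    if name == "mouse_c57bl6":
        return Preset(name, _mouse_tumor(), _mouse_immune(), "mouse",
                      immunodeficient=False, events_enabled=False,
                      founder_cells=4.77e7)
    if name == "mc38_immunodeficient":
        return Preset(name, _mouse_tumor(kg=0.3), _mouse_immune(), "mouse",
                      immunodeficient=True, events_enabled=False,
                      founder_cells=4.77e7)
    if name == "mc38_immunocompetent":
        return Preset(name, _mouse_tumor(kg=0.3), _mouse_immune(), "mouse",
                      immunodeficient=False, events_enabled=False,
                      founder_cells=4.77e7)
    if name == "human_nsclc":
        return Preset(name, _human_tumor(), _human_immune(), "human",
                      founder_cells=1.0)
    if name == "rcc_like":
        t = _human_tumor()
        t = replace(t, kg=t.kg * 0.5, nG=t.nG * 0.1, nL=t.nL * 0.1,
                    hlaL=t.hlaL * 0.1)
        return Preset(name, t, _human_immune(), "human", founder_cells=1.0)
    if name == "msi_like":
        t = _human_tumor()
        t = replace(t, kg=t.kg * 2.0, g2=t.g2 * 3.0)
        return Preset(name, t, _human_immune(), "human", founder_cells=1.0)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
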