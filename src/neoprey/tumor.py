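"""Tumor compartment: lineages, immunopeptidomes, growth and stochastic events.

A tumor is a set of lineages under shared logistic growth with lineage-specific
death. Each lineage carries per-neoantigen expression flags and per-allele MHC
intactness flags; the immunopeptidome is their product. Lineages branch through
three irreversible stochastic events — neoantigen gain, neoantigen loss, MHC
allele loss — each moving exactly one cell from the parent into a child lineage
differing by exactly that one modification.

Because flags are immutable after creation, two children produced from the same
parent by the same modification carry identical immunopeptidomes and identical
dynamics; they are aggregated into a single lineage (the repeat event moves one
cell into the existing child). This is an exact reduction: growth, killing and
clonality counting all depend on a lineage only through its immunopeptidome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .features import Neoantigen, make_neoantigens, sample_founder_clonal_burden
from .params import Preset, TumorParams

__all__ = [
    "TumorLineage",
    "TumorState",
    "Event",
    "lineage_derivative",
    "presented_cells",
    "sample_tumor_gain_rate",
    "daily_gain_rate",
    "draw_daily_events",
    "apply_event",
    "init_founder",
    "sample_founder_mhc",
    "diameter_to_cells",
    "cells_to_diameter",
    "clonal_subclonal_burden",
]


@dataclass
class TumorLineage:
    id: int
    parent_id: Optional[int]
    N: float
    expressed: np.ndarray = None   # sorted neoantigen ids with E=1
    mhc: np.ndarray = None         # per-allele intactness flags
    presented: np.ndarray = None   # cached ids with E=1 and intact allele

    def presented_ids(self, allele_of: dict[int, int]) -> set:
        """Neoantigen ids in this lineage's immunopeptidome (E * MHC = 1)."""
        return {int(k) for k in self.expressed if self.mhc[allele_of[int(k)]]}


@dataclass
class Event:
    day: int
    type: str          # 'gain' | 'loss' | 'mhc_loss'
    parent_id: int
    child_id: Optional[int]
    target: int        # neoantigen id for gain/loss, allele index for mhc_loss


class TumorState:
    """Living lineages plus the registry of every neoantigen ever created."""

    def __init__(self, params: TumorParams):
        self.params = params
        self.lineages: list[TumorLineage] = []
        self.registry: list[Neoantigen] = []
        self.base_gain_rate: float = params.nG
        self.event_log: list[Event] = []
        self._next_lineage_id = 0
        self._by_id: dict[int, TumorLineage] = {}
        self._child_of: dict[tuple, int] = {}   # (parent, type, target) -> id
        # registry scalars live in amortized doubling buffers so that very
        # mutable tumors (tens of thousands of gains) stay O(1) per event
        self._R_buf = np.zeros(16)
        self._allele_buf = np.zeros(16, dtype=np.int64)
        self._m = 0
        self._concat_cache = None

    # -- registry ---------------------------------------------------------
    def register(self, neo: Neoantigen) -> None:
        if neo.id != self._m:
            raise ValueError("registry ids must be consecutive from 0")
        self.registry.append(neo)
        if self._m == self._R_buf.size:
            self._R_buf = np.concatenate([self._R_buf,
                                          np.zeros(self._R_buf.size)])
            self._allele_buf = np.concatenate(
                [self._allele_buf, np.zeros(self._allele_buf.size,
                                            dtype=np.int64)])
        self._R_buf[self._m] = neo.R
        self._allele_buf[self._m] = neo.mhc_allele
        self._m += 1

    @property
    def n_neoantigens(self) -> int:
        return self._m

    @property
    def R(self) -> np.ndarray:
        return self._R_buf[:self._m]

    @property
    def allele(self) -> np.ndarray:
        return self._allele_buf[:self._m]

    @property
    def allele_of(self) -> dict[int, int]:
        return {n.id: n.mhc_allele for n in self.registry}

    # -- lineages ---------------------------------------------------------
    def new_lineage(self, parent_id: Optional[int], N: float,
                    expressed, mhc: np.ndarray) -> TumorLineage:
        mhc = np.asarray(mhc, dtype=bool).copy()
        expressed = np.asarray(sorted(expressed) if isinstance(expressed, set)
                               else expressed, dtype=np.int64)
        if expressed.size:
            alle = self._allele_buf[expressed]
            presented = expressed[mhc[alle]]
        else:
            presented = np.zeros(0, dtype=np.int64)
        lin = TumorLineage(self._next_lineage_id, parent_id, N,
                           expressed, mhc, presented)
        self._next_lineage_id += 1
        self.lineages.append(lin)
        self._by_id[lin.id] = lin
        self._concat_cache = None
        return lin

    def get_lineage(self, lineage_id: int) -> Optional[TumorLineage]:
        return self._by_id.get(lineage_id)

    @property
    def N_vector(self) -> np.ndarray:
        return np.array([lin.N for lin in self.lineages])

    @property
    def total_N(self) -> float:
        return float(sum(lin.N for lin in self.lineages))

    def set_N(self, values: np.ndarray) -> None:
        for lin, v in zip(self.lineages, values):
            lin.N = float(max(v, 0.0))

    def prune_extinct(self) -> int:
        """Drop lineages below the extinction threshold; returns count removed."""
        thr = self.params.extinction_threshold
        dead = [lin for lin in self.lineages if lin.N < thr]
        if dead:
            self.lineages = [lin for lin in self.lineages if lin.N >= thr]
            for lin in dead:
                del self._by_id[lin.id]
            self._concat_cache = None
        return len(dead)

    def concat_presented(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, cols): per-lineage presented sizes and their ids,
        concatenated in lineage order. Cached until the state changes."""
        if self._concat_cache is None:
            lengths = np.array([lin.presented.size for lin in self.lineages],
                               dtype=np.int64)
            cols = (np.concatenate([lin.presented for lin in self.lineages])
                    if lengths.sum() else np.zeros(0, dtype=np.int64))
            self._concat_cache = (lengths, cols)
        return self._concat_cache

    def invalidate_cache(self) -> None:
        self._concat_cache = None


def lineage_derivative(N_i: float, total_N: float, kd_i: float,
                       params: TumorParams) -> float:
    """dN_i/dt = kg * N_i * (1 - total/K) * (1 - kd_i), cells/day."""
    return params.kg * N_i * (1.0 - total_N / params.K) * (1.0 - kd_i)


def presented_cells(state: TumorState) -> tuple[np.ndarray, np.ndarray]:
    """Per-neoantigen presented-cell counts.

    Returns (raw, S): raw_k = sum_i N_i * E_{k,i} * MHC_{a(k),i} and
    S_k = R_k * raw_k, the immunogenicity-weighted count that drives the
    cognate CTL clone.
    """
    m = state.n_neoantigens
    lengths, cols = state.concat_presented()
    if cols.size == 0:
        raw = np.zeros(m)
    else:
        weights = np.repeat(state.N_vector, lengths)
        raw = np.bincount(cols, weights=weights, minlength=m)
    return raw, state.R * raw


def sample_tumor_gain_rate(params: TumorParams,
                           rng: np.random.Generator) -> float:
    """Per-tumor base neoantigen gain rate, log-normal around nG.

    'mean' convention (default): the distribution's mean equals nG, so nG is
    the realized average gain rate across tumors. 'median' makes nG the
    median instead.
    """
    if params.nG == 0:
        return 0.0
    mu = math.log(params.nG)
    if params.gain_rate_convention == "mean":
        mu -= 0.5 * params.nGS ** 2
    return float(math.exp(mu + params.nGS * rng.standard_normal()))


def daily_gain_rate(base: float, params: TumorParams,
                    rng: np.random.Generator) -> float:
    """One day's gain rate: the base rate with log-normal day-to-day jitter.

    Under the 'mean' convention the jitter has mean 1, so the tumor's base
    rate is its long-run average; under 'median' the jitter has median 1.
    """
    if base == 0.0:
        return 0.0
    mu = 0.0
    if params.gain_rate_convention == "mean":
        mu = -0.5 * params.nGSt ** 2
    return float(base * math.exp(mu + params.nGSt * rng.standard_normal()))


def draw_daily_events(state: TumorState, day_rate: float,
                      params: TumorParams, dt: float,
                      rng: np.random.Generator) -> list[Event]:
    """Draw one day's stochastic immunopeptidome events (tau-leaping).

    Per living lineage the number of events of each type is Poisson with mean
    rate*N_i*dt; losses require at least one expressed neoantigen and MHC
    losses at least one intact allele. Targets are uniform among eligible
    candidates. Events are emitted losses first, then MHC losses, then gains,
    so replays are seed-reproducible.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    events: list[Event] = []
    lineages = state.lineages
    if not lineages:
        return events
    N = np.array([lin.N for lin in lineages])
    N = np.where(N >= 1.0, N, 0.0)
    if not N.any():
        return events

    def draw(rate):
        if rate == 0.0:
            return None
        counts = rng.poisson(rate * N * dt)
        idx = np.flatnonzero(counts)
        return idx, counts

    for kind, rate in (("loss", params.nL), ("mhc_loss", params.hlaL),
                       ("gain", day_rate)):
        drawn = draw(rate)
        if drawn is None:
            continue
        idx, counts = drawn
        for i in idx:
            lin = lineages[i]
            c = int(counts[i])
            if kind == "loss":
                if lin.expressed.size == 0:
                    continue
                targets = rng.choice(lin.expressed, size=c)
                events.extend(Event(-1, "loss", lin.id, None, int(t))
                              for t in targets)
            elif kind == "mhc_loss":
                intact = np.flatnonzero(lin.mhc)
                if intact.size == 0:
                    continue
                targets = rng.choice(intact, size=c)
                events.extend(Event(-1, "mhc_loss", lin.id, None, int(t))
                              for t in targets)
            else:
                events.extend(Event(-1, "gain", lin.id, None, -1)
                              for _ in range(c))
    return events


def apply_event(state: TumorState, event: Event,
                neoantigen_factory: Optional[Callable[[], Neoantigen]] = None,
                day: int = 0) -> Optional[TumorLineage]:
    """Apply one event: deduct 1 cell from the parent, branch a 1-cell child.

    A repeat of an earlier (parent, modification) pair moves the cell into
    the existing child lineage instead of duplicating it (identical
    immunopeptidome, identical dynamics). Gains always create a fresh
    neoantigen via ``neoantigen_factory`` (the caller spawns its cognate CTL
    clone). Events whose parent has fewer than 1 cell, or whose target is no
    longer eligible, are discarded but still logged with child_id None.
    Total cell count is conserved exactly.
    """
    parent = state.get_lineage(event.parent_id)
    event.day = day
    if parent is None or parent.N < 1.0:
        state.event_log.append(event)
        return None
    if event.type in ("loss", "mhc_loss"):
        key = (event.parent_id, event.type, event.target)
        child_id = state._child_of.get(key)
        if child_id is not None:
            child = state.get_lineage(child_id)
            if child is not None:
                parent.N -= 1.0
                child.N += 1.0
                event.child_id = child.id
                state.event_log.append(event)
                return child
    if event.type == "loss":
        pos = np.searchsorted(parent.expressed, event.target)
        if pos >= parent.expressed.size or parent.expressed[pos] != event.target:
            state.event_log.append(event)
            return None
        expressed = np.delete(parent.expressed, pos)
        mhc = parent.mhc
    elif event.type == "mhc_loss":
        if not parent.mhc[event.target]:
            state.event_log.append(event)
            return None
        expressed = parent.expressed
        mhc = parent.mhc.copy()
        mhc[event.target] = False
    elif event.type == "gain":
        if neoantigen_factory is None:
            raise ValueError("gain event requires a neoantigen_factory")
        neo = neoantigen_factory()
        state.register(neo)
        expressed = np.append(parent.expressed, neo.id)  # ids are monotone
        event.target = neo.id
        mhc = parent.mhc
    else:
        raise ValueError(f"unknown event type {event.type!r}")
    parent.N -= 1.0
    child = state.new_lineage(parent.id, 1.0, expressed, mhc)
    if event.type in ("loss", "mhc_loss"):
        state._child_of[(event.parent_id, event.type, event.target)] = child.id
    event.child_id = child.id
    state.event_log.append(event)
    return child


def sample_founder_mhc(n: int, hlaL0: float, n_alleles: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Founder MHC intactness flags for ``n`` founders (n x n_alleles bool).

    With probability hlaL0 a founder suffers clonal loss of exactly one
    uniformly chosen allele; otherwise all alleles are intact.
    """
    mhc = np.ones((n, n_alleles), dtype=bool)
    lost = rng.random(n) < hlaL0
    which = rng.integers(0, n_alleles, size=n)
    mhc[np.arange(n)[lost], which[lost]] = False
    return mhc


def init_founder(preset: Preset, rng: np.random.Generator,
                 panel: Optional[list[Neoantigen]] = None) -> TumorState:
    """Initialize the founding tumor state for a preset.

    Mouse: one lineage of ~4.77e7 cells carrying the supplied fixed panel,
    all expressed, both alleles intact. Human: one founder cell with a
    gamma-distributed clonal neoantigen burden, copula-sampled features, and
    a hlaL0 chance of clonal loss of one of the three alleles.
    """
    state = TumorState(preset.tumor)
    n_alleles = preset.tumor.n_mhc_alleles
    if preset.species == "mouse":
        if panel is None:
            raise ValueError("mouse initialization requires a neoantigen panel")
        for neo in panel:
            state.register(neo)
        mhc = np.ones(n_alleles, dtype=bool)
        state.new_lineage(None, preset.founder_cells,
                          np.arange(len(panel)), mhc)
        state.base_gain_rate = 0.0
        return state
    burden = sample_founder_clonal_burden(preset.tumor.g1, preset.tumor.g2, rng)
    neos = make_neoantigens(burden, n_alleles, preset.features,
                            preset.criteria, rng, start_id=0, origin="founder")
    for neo in neos:
        state.register(neo)
    mhc = sample_founder_mhc(1, preset.tumor.hlaL0, n_alleles, rng)[0]
    state.new_lineage(None, preset.founder_cells, np.arange(burden), mhc)
    state.base_gain_rate = sample_tumor_gain_rate(preset.tumor, rng)
    return state


def diameter_to_cells(d: float, cellVol: float = 4.19e-9) -> float:
    """Cell count of a spherical tumor of diameter ``d`` cm."""
    if d <= 0 or cellVol <= 0:
        raise ValueError("diameter and cell volume must be positive")
    return (math.pi / 6.0) * d ** 3 / cellVol


def cells_to_diameter(N: float, cellVol: float = 4.19e-9) -> float:
    """Diameter (cm) of a spherical tumor of ``N`` cells."""
    if N <= 0 or cellVol <= 0:
        raise ValueError("cell count and cell volume must be positive")
    return (6.0 * N * cellVol / math.pi) ** (1.0 / 3.0)


def clonal_subclonal_burden(state: TumorState, method: str = "lineage",
                            cell_fraction: float = 0.95) -> tuple[int, int, int]:
    """(clonal, subclonal, total) neoantigen counts over living lineages.

    method='lineage' (literal reading): clonal iff present in the
    immunopeptidome of every living (N >= 1) lineage; subclonal iff present
    in at least one but not all. This is degenerate for large branching
    tumors — a single 1-cell lineage that lost an MHC allele demotes a third
    of the founder neoantigens — so cohort biomarkers use method='cell':
    clonal iff presented by at least ``cell_fraction`` of living cells,
    mirroring how clonal calls are made from cancer-cell fractions in the
    sequencing cohorts the model is calibrated to. Neoantigens absent from
    every living lineage are excluded entirely.
    """
    living_mask = np.array([lin.N >= 1.0 for lin in state.lineages])
    n_living = int(living_mask.sum())
    if n_living == 0:
        raise ValueError("no living lineage")
    lengths, cols = state.concat_presented()
    keep = np.repeat(living_mask, lengths)
    m = state.n_neoantigens
    if method == "lineage":
        counts = np.bincount(cols[keep], minlength=m)
        clonal = int(np.sum(counts == n_living))
        total = int(np.sum(counts > 0))
    elif method == "cell":
        N = state.N_vector
        N = np.where(N >= 1.0, N, 0.0)
        raw = np.bincount(cols[keep],
                          weights=np.repeat(N, lengths)[keep], minlength=m)
        total = int(np.sum(raw > 0))
        clonal = int(np.sum(raw >= cell_fraction * N.sum()))
    else:
        raise ValueError("method must be 'lineage' or 'cell'")
    return clonal, total - clonal, total
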