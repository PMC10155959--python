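"""Hybrid deterministic-stochastic simulation engine.

Within each day the coupled ODE system (tumor lineages, CTL clones, the
tumor-ignorant pool and the shared stimulus) flows deterministically under an
adaptive integrator; at day boundaries stochastic immunopeptidome events are
drawn per lineage (tau-leaping at dt = 1 day) and applied, branching lineages
and spawning cognate CTL clones for gained neoantigens. Everything is driven
by a single seeded generator, so (preset, seed) fully determines the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import analysis
from .features import Neoantigen, make_neoantigens
from .immune import ImmuneState, init_clone_size, lineage_death_rate
from .params import Preset, get_preset
from .tumor import (apply_event, cells_to_diameter,
                    clonal_subclonal_burden, daily_gain_rate,
                    draw_daily_events, init_founder, presented_cells)

__all__ = [
    "IcbSchedule",
    "Simulation",
    "CohortResult",
    "run_mouse",
    "run_to_diameter",
    "run_icb",
    "simulate_cohort",
    "stage_mix_targets",
]

#: TRACERx-like stage mix: (target diameter cm, patient count out of 100)
STAGE_MIX = ((1.5, 26), (3.5, 36), (4.5, 13), (5.0, 25))


@dataclass
class IcbSchedule:
    """Checkpoint-blockade schedule: fold strength and duration."""

    strength: float = 10.0
    start_diameter_cm: float = 5.0
    duration_days: int = 365

    def __post_init__(self) -> None:
        if self.strength < 1:
            raise ValueError("strength must be >= 1")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Simulation:
    """One tumor-immune system advancing in daily steps."""

    def __init__(self, preset: Preset, seed=None,
                 panel: Optional[list[Neoantigen]] = None,
                 record_burden: bool = True):
        self.preset = preset
        self.rng = _as_rng(seed)
        self.day = 0
        self.record_burden = record_burden
        self.tumor = init_founder(preset, self.rng, panel=panel)
        self.immune = ImmuneState(preset.immune)
        for _ in self.tumor.registry:
            self.immune.add_clone(init_clone_size(preset.immune.mu, self.rng))
        # the ignorant pool is what remains of the steady-state repertoire
        self.immune.NSCTL = max(
            preset.immune.TCR_other - self.immune.total_reactive, 0.0)
        self._records: list[dict] = []
        self._record()

    # -- bookkeeping -------------------------------------------------------
    def _record(self) -> None:
        t = self.tumor
        im = self.immune
        row = {
            "day": self.day,
            "total_N": t.total_N,
            "diameter_cm": cells_to_diameter(max(t.total_N, 1e-12),
                                             t.params.cellVol),
            "n_lineages": len(t.lineages),
            "n_neoantigens": t.n_neoantigens,
            "C": im.C,
            "NSCTL": im.NSCTL,
            "total_reactive": im.total_reactive,
            "n_reactive_clones": int(np.sum(im.sizes > 0)),
        }
        if self.record_burden and t.lineages:
            clonal, subclonal, total = clonal_subclonal_burden(t,
                                                               method="cell")
            row.update(n_clonal=clonal, n_subclonal=subclonal,
                       n_presented=total)
        self._records.append(row)

    def trajectory(self) -> pd.DataFrame:
        df = pd.DataFrame(self._records)
        if len(df):
            df["volume_norm"] = df["total_N"] / df["total_N"].iloc[0]
        return df

    @property
    def diameter_cm(self) -> float:
        return cells_to_diameter(max(self.tumor.total_N, 1e-12),
                                 self.tumor.params.cellVol)

    # -- dynamics ----------------------------------------------------------
    def _rhs_full(self, P, R_active, j, a):
        """RHS over y = [N (j), active clones (a), NSCTL, passive pool, C].

        Clones whose cognate neoantigen has R = 0 receive no antigen stimulus
        ever (S_k = R_k*raw_k = 0), so they all share the per-capita dynamics
        T_d*(C-1) and are integrated exactly as one aggregate state; their
        contribution to the per-lineage reactive fraction is below one part
        in 1e5 of the ignorant pool and is neglected there.
        """
        tp, ip = self.preset.tumor, self.preset.immune
        kg, K, fdie = tp.kg, tp.K, tp.fdie
        T_d, T_a, icb = ip.T_d, ip.T_a, ip.icb
        PT = P.T.tocsr()

        def rhs(t, y):
            N = np.maximum(y[:j], 0.0)
            ctl = np.maximum(y[j:j + a], 0.0)
            NSCTL = max(y[-3], 0.0)
            passive = max(y[-2], 0.0)
            C = max(y[-1], 0.0)
            total = N.sum()
            raw = PT @ N
            S = R_active * raw
            react = P @ ctl
            denom = NSCTL + react
            phi = np.divide(react, denom, out=np.zeros_like(react),
                            where=denom > 0)
            kd = lineage_death_rate(phi, ip, fdie)
            dN = kg * N * (1.0 - total / K) * (1.0 - kd)
            dctl = ctl * T_d * (C - 1.0) + icb * S * T_a * C
            growth_ns = T_d * (C - 1.0)
            dC = (ip.kin - ip.kin * ip.fout
                  - ip.kin * (1.0 - ip.fout)
                  * (NSCTL + passive + ctl.sum()) / (icb * ip.CTL_ss))
            return np.concatenate(
                [dN, dctl, [NSCTL * growth_ns, passive * growth_ns, dC]])

        return rhs

    def _rhs_immunodeficient(self, j):
        tp = self.preset.tumor
        kg, K, fdie = tp.kg, tp.K, tp.fdie

        def rhs(t, y):
            N = np.maximum(y, 0.0)
            return kg * N * (1.0 - N.sum() / K) * (1.0 - fdie)

        return rhs

    def _solve(self, rhs, y0, t0, t1, atol, depth=0):
        for method in ("RK45", "LSODA"):
            sol = solve_ivp(rhs, (t0, t1), y0, method=method,
                            rtol=1e-6, atol=atol)
            if sol.success:
                return sol.y[:, -1]
        if depth >= 6:
            raise RuntimeError(
                f"integrator failed on day {self.day}; state dim {y0.size}, "
                f"total_N={self.tumor.total_N:.3e}, C={self.immune.C:.3e}")
        tm = 0.5 * (t0 + t1)
        y_mid = self._solve(rhs, y0, t0, tm, atol, depth + 1)
        return self._solve(rhs, y_mid, tm, t1, atol, depth + 1)

    def _active_presentation(self, active: np.ndarray):
        """Sparse (j x a) presentation matrix restricted to R>0 neoantigens."""
        from scipy import sparse

        t = self.tumor
        j = len(t.lineages)
        m = t.n_neoantigens
        lengths, cols = t.concat_presented()
        member = np.zeros(m, dtype=bool)
        member[active] = True
        sel = member[cols] if cols.size else np.zeros(0, dtype=bool)
        rows = np.repeat(np.arange(j), lengths)[sel]
        colmap = np.zeros(m, dtype=np.int64)
        colmap[active] = np.arange(active.size)
        c2 = colmap[cols[sel]]
        return sparse.csr_matrix((np.ones(rows.size), (rows, c2)),
                                 shape=(j, active.size))

    def _integrate_day(self) -> None:
        t = self.tumor
        j = len(t.lineages)
        N0 = t.N_vector
        if self.preset.immunodeficient:
            if j == 0:
                return
            atol = np.full(j, 1e-3)
            y1 = self._solve(self._rhs_immunodeficient(j), N0, 0.0, 1.0, atol)
            t.set_N(np.maximum(y1, 0.0))
        else:
            im = self.immune
            R = t.R
            active = np.flatnonzero(R > 0)
            passive_mask = np.ones(im.sizes.size, dtype=bool)
            passive_mask[active] = False
            passive0 = float(im.sizes[passive_mask].sum())
            P = self._active_presentation(active)
            a = active.size
            y0 = np.concatenate([N0, im.sizes[active],
                                 [im.NSCTL, passive0, im.C]])
            atol = np.concatenate([np.full(j + a + 2, 1e-3), [1e-9]])
            y1 = self._solve(self._rhs_full(P, R[active], j, a),
                             y0, 0.0, 1.0, atol)
            y1 = np.maximum(y1, 0.0)
            t.set_N(y1[:j])
            im.sizes[active] = y1[j:j + a]
            if passive0 > 0:
                im.sizes[passive_mask] *= float(y1[-2]) / passive0
            im.NSCTL = float(y1[-3])
            im.C = float(y1[-1])
        t.prune_extinct()

    def _gain_factory(self):
        preset = self.preset

        def factory() -> Neoantigen:
            return make_neoantigens(
                1, preset.tumor.n_mhc_alleles, preset.features,
                preset.criteria, self.rng,
                start_id=self.tumor.n_neoantigens, origin="gained")[0]

        return factory

    def _apply_daily_events(self) -> None:
        tp = self.preset.tumor
        rate = daily_gain_rate(self.tumor.base_gain_rate, tp, self.rng)
        events = draw_daily_events(self.tumor, rate, tp, 1.0, self.rng)
        if not events:
            return
        factory = self._gain_factory()
        for ev in events:
            apply_event(self.tumor, ev, neoantigen_factory=factory,
                        day=self.day)
            if ev.type == "gain" and ev.child_id is not None:
                self.immune.add_clone(
                    init_clone_size(self.preset.immune.mu, self.rng),
                    day=self.day)

    def step_day(self) -> None:
        """Advance one day: ODE flow, then stochastic events, then record."""
        self._integrate_day()
        self.day += 1
        if self.preset.events_enabled:
            self._apply_daily_events()
        self._record()

    def run_days(self, n: int) -> None:
        for _ in range(n):
            self.step_day()


# -- run drivers -----------------------------------------------------------

def run_mouse(preset: Union[str, Preset], panel: list[Neoantigen],
              weeks: int = 5, seed=None) -> pd.DataFrame:
    """Simulate murine tumor growth from a fixed neoantigen panel.

    Returns a daily trajectory (day 0 baseline plus 7*weeks simulated days)
    with tumor volume normalized to baseline. Immunodeficient presets freeze
    the immune compartment entirely (death rate = f_die).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if preset.species != "mouse":
        raise ValueError("run_mouse requires a mouse preset")
    if not panel:
        raise ValueError("panel must contain at least one neoantigen")
    for neo in panel:
        if not 0.0 <= neo.R <= 1.0 or not 0 <= neo.mhc_allele < 2:
            raise ValueError("malformed panel entry")
    sim = Simulation(preset, seed=seed, panel=panel)
    sim.run_days(7 * weeks)
    return sim.trajectory()


def run_to_diameter(preset: Union[str, Preset], target_d: float, seed=None,
                    max_days: int = 6000,
                    record_burden: bool = False) -> Simulation:
    """Grow a human tumor until its diameter first reaches ``target_d`` cm.

    Returns the Simulation at first crossing; ``sim.reached`` is False if the
    tumor was immune-controlled and never reached the target within
    ``max_days`` (a valid biological outcome, not an error).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    sim = Simulation(preset, seed=seed, record_burden=record_burden)
    sim.reached = sim.diameter_cm >= target_d
    while not sim.reached and sim.day < max_days:
        sim.step_day()
        if sim.diameter_cm >= target_d:
            sim.reached = True
    return sim


def run_icb(sim: Simulation, schedule: IcbSchedule) -> pd.DataFrame:
    """Treat an existing tumor: scale antigen sensitivity and CTL carrying
    capacity by the schedule's strength for its duration.

    Returns a daily treatment trajectory carrying the presented-cell count of
    the pre-treatment rank-1 neoantigen, the summed abundance of the 5 most
    abundant pre-treatment clones, and the cumulative count of reactive
    lineages that emerged during treatment.
    """
    preset = sim.preset.with_icb(schedule.strength)
    sim.preset = preset
    sim.immune.params = preset.immune
    rank1_id, _, _, _ = analysis.rank1_neoantigen(sim.tumor)
    n_clones_start = sim.immune.sizes.size
    order = np.argsort(sim.immune.sizes)[::-1]
    top5_ids = order[:5]
    rows = []

    def record():
        raw, _ = presented_cells(sim.tumor)
        rows.append({
            "day": sim.day,
            "diameter_cm": sim.diameter_cm,
            "total_N": sim.tumor.total_N,
            "rank1_presented": float(raw[rank1_id]) if rank1_id >= 0 else np.nan,
            "top5_sum": float(sim.immune.sizes[top5_ids].sum()),
            "new_reactive_lineages": int(sim.immune.sizes.size - n_clones_start),
            "C": sim.immune.C,
            "NSCTL": sim.immune.NSCTL,
            "total_reactive": sim.immune.total_reactive,
        })

    record()
    for _ in range(schedule.duration_days):
        sim.step_day()
        record()
    return pd.DataFrame(rows)


@dataclass
class CohortResult:
    """Per-tumor baseline features and (optionally) treatment outcomes."""

    preset_name: str
    master_seed: int
    table: pd.DataFrame
    trajectories: list = field(default_factory=list)


def stage_mix_targets(n: int) -> list[float]:
    """Target diameters for ``n`` tumors in the published NSCLC stage mix."""
    total = sum(c for _, c in STAGE_MIX)
    targets: list[float] = []
    for d, c in STAGE_MIX:
        targets.extend([d] * int(round(n * c / total)))
    while len(targets) > n:
        targets.pop()
    while len(targets) < n:
        targets.append(STAGE_MIX[-1][0])
    return targets


def simulate_cohort(preset: Union[str, Preset], n_tumors: int,
                    targets: Optional[Union[float, Sequence[float]]] = None,
                    master_seed: int = 0,
                    schedule: Optional[IcbSchedule] = None,
                    max_days: int = 6000,
                    max_redraws: int = 10) -> CohortResult:
    """Simulate a virtual cohort with per-tumor independent substreams.

    ``targets`` may be a single diameter, a per-tumor list, or None for the
    published stage mix. Tumors that never reach their target (immune
    control) are redrawn from a fresh substream when a treatment schedule is
    given (the treated cohort is conditioned on reaching treatment size);
    without a schedule they are kept and flagged ``reached = False``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    if targets is None:
        target_list = stage_mix_targets(n_tumors)
    elif np.isscalar(targets):
        target_list = [float(targets)] * n_tumors
    else:
        target_list = [float(t) for t in targets]
        if len(target_list) != n_tumors:
            raise ValueError("targets length must equal n_tumors")
    root = np.random.SeedSequence(master_seed)
    streams = root.spawn(n_tumors)
    rows = []
    trajectories = []
    for i, (ss, target) in enumerate(zip(streams, target_list)):
        attempts = ss.spawn(max_redraws + 1)
        sim = None
        redraws = 0
        for attempt_ss in attempts:
            sim = run_to_diameter(preset, target,
                                  seed=np.random.default_rng(attempt_ss),
                                  max_days=max_days)
            if sim.reached or schedule is None:
                break
            redraws += 1
        row = {"tumor_id": i, "target_d": target, "reached": sim.reached,
               "redraws": redraws, "growth_days": sim.day,
               "baseline_diameter": sim.diameter_cm}
        clonal, subclonal, total = clonal_subclonal_burden(sim.tumor,
                                                           method="cell")
        row.update(n_clonal=clonal, n_subclonal=subclonal, n_presented=total,
                   n_neoantigens=sim.tumor.n_neoantigens,
                   n_lineages=len(sim.tumor.lineages))
        row["immunopeptidome_entropy"] = analysis.immunopeptidome_entropy(
            sim.tumor)
        sizes = sim.immune.sizes
        row["tcr_entropy_pre"] = (analysis.tcr_entropy_safe(sizes))
        r1_id, r1_R, r1_clon, r1_prod = analysis.rank1_neoantigen(sim.tumor)
        row.update(rank1_R=r1_R, rank1_clonality=r1_clon,
                   rank1_weighted=r1_prod)
        if schedule is not None and sim.reached:
            traj = run_icb(sim, schedule)
            trajectories.append(traj)
            shrink = analysis.max_shrinkage(traj)
            row.update(
                max_shrinkage=shrink,
                responder=analysis.classify_response(shrink),
                immunoediting_fc=analysis.immunoediting_fold_change(traj),
                new_reactive_lineages=int(
                    traj["new_reactive_lineages"].iloc[-1]),
                tcr_entropy_post=analysis.tcr_entropy_safe(sim.immune.sizes),
                top5_baseline=float(traj["top5_sum"].iloc[0]),
            )
        rows.append(row)
    name = preset.name
    return CohortResult(name, master_seed, pd.DataFrame(rows), trajectories)
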