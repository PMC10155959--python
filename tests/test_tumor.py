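"""Tumor compartment: growth law, presentation, events, conversions."""

import numpy as np
import pytest

from neoprey.features import Neoantigen
from neoprey.params import TumorParams, get_preset
from neoprey.tumor import (Event, TumorState, apply_event, cells_to_diameter,
                           clonal_subclonal_burden, daily_gain_rate,
                           diameter_to_cells, draw_daily_events, init_founder,
                           lineage_derivative, presented_cells,
                           sample_founder_mhc, sample_tumor_gain_rate)


def make_state(n_neo=3, R=(0.5, 0.2, 0.0), alleles=(0, 1, 0), n_alleles=2):
    state = TumorState(TumorParams(n_mhc_alleles=n_alleles))
    for k in range(n_neo):
        state.register(Neoantigen(k, R[k], alleles[k]))
    return state


class TestGrowthLaw:
    def test_zero_at_capacity(self):
        p = get_preset("mouse_nsg").tumor
        assert lineage_derivative(1e6, p.K, 0.9, p) == pytest.approx(0.0)

    def test_zero_at_kd_one(self):
        p = get_preset("mouse_nsg").tumor
        assert lineage_derivative(1e6, 1e6, 1.0, p) == pytest.approx(0.0)

    def test_direct_substitution(self):
        """kg=0.2, K=7e8, N=total=4.77e7, kd=0.3 -> ~6.22e6 cells/day."""
        p = get_preset("mouse_nsg").tumor
        expected = 0.2 * 4.77e7 * (1 - 4.77e7 / 7e8) * 0.7
        assert lineage_derivative(4.77e7, 4.77e7, 0.3, p) == pytest.approx(
            expected)
        assert expected == pytest.approx(6.22e6, rel=1e-2)


class TestPresentedCells:
    def test_single_lineage(self):
        state = make_state()
        state.new_lineage(None, 100.0, np.array([0]), np.ones(2, bool))
        raw, S = presented_cells(state)
        assert raw[0] == 100.0 and S[0] == pytest.approx(50.0)
        assert raw[1] == 0.0

    def test_mhc_loss_silences(self):
        state = make_state()
        mhc = np.array([False, True])  # allele 0 lost
        state.new_lineage(None, 100.0, np.array([0, 1]), mhc)
        raw, S = presented_cells(state)
        assert S[0] == 0.0            # neo 0 on lost allele
        assert S[1] == pytest.approx(20.0)

    def test_unexpressed_silences(self):
        state = make_state()
        state.new_lineage(None, 100.0, np.array([1]), np.ones(2, bool))
        raw, _ = presented_cells(state)
        assert raw[0] == 0.0


class TestGainRates:
    def test_degenerate(self, rng):
        p = TumorParams(nGS=0.0, nGSt=0.0)
        base = sample_tumor_gain_rate(p, rng)
        assert base == pytest.approx(p.nG)
        assert daily_gain_rate(base, p, rng) == pytest.approx(p.nG)

    def test_mean_convention(self, rng):
        p = TumorParams()  # default mean-preserving
        draws = np.array([sample_tumor_gain_rate(p, rng)
                          for _ in range(100_000)])
        assert abs(np.mean(draws) / p.nG - 1) < 0.25  # heavy-tailed mean

    def test_median_convention(self, rng):
        p = TumorParams(gain_rate_convention="median")
        draws = np.array([sample_tumor_gain_rate(p, rng)
                          for _ in range(20_000)])
        assert abs(np.median(draws) / p.nG - 1) < 0.05

    def test_decade_spread(self, rng):
        """log-sd 2.303 = one decade: ~68% of draws within 10x of the median."""
        p = TumorParams(gain_rate_convention="median")
        draws = np.array([sample_tumor_gain_rate(p, rng)
                          for _ in range(20_000)])
        frac = np.mean((draws > p.nG / 10) & (draws < p.nG * 10))
        assert abs(frac - 0.683) < 0.02


class TestEvents:
    def test_zero_rates_empty(self, rng):
        state = make_state()
        state.new_lineage(None, 1e6, np.array([0, 1, 2]), np.ones(2, bool))
        p = TumorParams(nG=0, nL=0, hlaL=0, nGS=0, nGSt=0)
        assert draw_daily_events(state, 0.0, p, 1.0, rng) == []

    def test_poisson_mean(self):
        """One lineage of 1e9 cells at nL=1.68e-9: ~1.68 losses/day."""
        rng = np.random.default_rng(0)
        state = make_state()
        state.new_lineage(None, 1e9, np.array([0, 1, 2]), np.ones(2, bool))
        p = TumorParams(nG=0, hlaL=0)
        counts = [len(draw_daily_events(state, 0.0, p, 1.0, rng))
                  for _ in range(3000)]
        assert abs(np.mean(counts) - 1.68) < 3 * np.sqrt(1.68 / 3000)

    def test_no_eligible_mhc(self, rng):
        state = make_state()
        state.new_lineage(None, 1e9, np.array([0]), np.zeros(2, bool))
        p = TumorParams(nG=0, nL=0, hlaL=1e-5)
        evs = draw_daily_events(state, 0.0, p, 1.0, rng)
        assert all(e.type != "mhc_loss" for e in evs)

    def test_conservation_and_structure(self):
        state = make_state()
        state.new_lineage(None, 100.0, np.array([0, 1]), np.ones(2, bool))
        before = state.total_N
        child = apply_event(state, Event(0, "loss", 0, None, 0))
        assert state.total_N == pytest.approx(before)
        assert child.N == 1.0
        assert list(child.expressed) == [1]
        assert state.get_lineage(0).N == 99.0

    def test_mhc_loss_child_excludes_allele(self):
        state = make_state()
        state.new_lineage(None, 10.0, np.array([0, 1, 2]), np.ones(2, bool))
        child = apply_event(state, Event(0, "mhc_loss", 0, None, 0))
        # neoantigens 0 and 2 sit on allele 0 and disappear from presentation
        assert set(child.presented) == {1}
        assert set(child.expressed) == {0, 1, 2}

    def test_gain_extends_registry(self, feature_params, rng):
        state = make_state()
        state.new_lineage(None, 10.0, np.array([0, 1]), np.ones(2, bool))
        factory = lambda: Neoantigen(state.n_neoantigens, 0.4, 1,
                                     origin="gained")
        child = apply_event(state, Event(0, "gain", 0, None, -1), factory)
        assert state.n_neoantigens == 4
        assert child.expressed.size == 3

    def test_parent_below_one_cell_discarded(self):
        state = make_state()
        state.new_lineage(None, 0.7, np.array([0]), np.ones(2, bool))
        child = apply_event(state, Event(0, "loss", 0, None, 0))
        assert child is None
        assert state.event_log[-1].child_id is None

    def test_repeat_event_merges_into_child(self):
        """Identical (parent, type, target) children aggregate exactly."""
        state = make_state()
        state.new_lineage(None, 100.0, np.array([0, 1]), np.ones(2, bool))
        c1 = apply_event(state, Event(0, "loss", 0, None, 1))
        c2 = apply_event(state, Event(0, "loss", 0, None, 1))
        assert c1 is c2
        assert c1.N == 2.0
        assert len(state.lineages) == 2
        assert state.total_N == pytest.approx(100.0)


class TestFounders:
    def test_mouse_exact_size(self, bbn_panel):
        preset = get_preset("mouse_nsg")
        state = init_founder(preset, np.random.default_rng(0), panel=bbn_panel)
        assert state.total_N == 4.77e7
        assert state.n_neoantigens == 34
        clonal, sub, total = clonal_subclonal_burden(state)
        assert (clonal, sub, total) == (34, 0, 34)

    def test_founder_mhc_loss_fraction(self):
        rng = np.random.default_rng(1)
        mhc = sample_founder_mhc(100_000, 0.14, 3, rng)
        frac = np.mean(mhc.sum(axis=1) == 2)
        assert abs(frac - 0.14) < 3 * np.sqrt(0.14 * 0.86 / 100_000)
        assert np.all(mhc.sum(axis=1) >= 2)

    def test_no_loss_when_rate_zero(self, rng):
        mhc = sample_founder_mhc(1000, 0.0, 3, rng)
        assert mhc.all()

    def test_human_founder_single_cell(self, human_preset):
        state = init_founder(human_preset, np.random.default_rng(2))
        assert state.total_N == 1.0
        assert len(state.lineages) == 1


class TestDiameterConversion:
    def test_mouse_baseline_volume(self):
        """200 mm^3 at 4.19e-9 cm^3/cell is ~4.77e7 cells."""
        d = (6 * 0.2 / np.pi) ** (1 / 3)
        assert diameter_to_cells(d) == pytest.approx(4.773e7, rel=1e-3)

    def test_five_cm(self):
        assert diameter_to_cells(5.0) == pytest.approx(1.562e10, rel=1e-3)

    def test_round_trip(self):
        for d in (0.1, 1.5, 5.0):
            assert cells_to_diameter(diameter_to_cells(d)) == pytest.approx(d)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            diameter_to_cells(0.0)
        with pytest.raises(ValueError):
            cells_to_diameter(-1.0)


class TestClonalSubclonal:
    def test_single_lineage_all_clonal(self):
        state = make_state(10, R=tuple([0.1] * 10), alleles=tuple([0] * 10))
        state.new_lineage(None, 50.0, np.arange(10), np.ones(2, bool))
        assert clonal_subclonal_burden(state) == (10, 0, 10)

    def test_two_lineages_shared_subset(self):
        state = make_state(5, R=tuple([0.1] * 5), alleles=tuple([0] * 5))
        state.new_lineage(None, 50.0, np.arange(5), np.ones(2, bool))
        state.new_lineage(0, 50.0, np.array([0, 1, 2]), np.ones(2, bool))
        assert clonal_subclonal_burden(state) == (3, 2, 5)

    def test_lost_everywhere_excluded(self):
        state = make_state(3)
        state.new_lineage(None, 50.0, np.array([0, 1]), np.ones(2, bool))
        assert clonal_subclonal_burden(state) == (2, 0, 2)

    def test_cell_fraction_mode_ignores_negligible_lineages(self):
        state = make_state(3, R=(0.1, 0.1, 0.1), alleles=(0, 1, 0))
        state.new_lineage(None, 1e6, np.array([0, 1, 2]), np.ones(2, bool))
        state.new_lineage(0, 1.0, np.array([1, 2]), np.ones(2, bool))
        # lineage mode: the 1-cell branch demotes neo 0
        assert clonal_subclonal_burden(state)[0] == 2
        # cell mode: 1 cell of 1e6 leaves neo 0 effectively clonal
        assert clonal_subclonal_burden(state, method="cell")[0] == 3

    def test_no_living_lineage_raises(self):
        state = make_state(1, R=(0.1,), alleles=(0,))
        state.new_lineage(None, 0.4, np.array([0]), np.ones(2, bool))
        with pytest.raises(ValueError):
            clonal_subclonal_burden(state)
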