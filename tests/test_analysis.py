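"""Response metrics, biomarkers, correlations, sensitivity harness."""

import numpy as np
import pandas as pd
import pytest

from neoprey import analysis as an
from neoprey.features import Neoantigen
from neoprey.params import TumorParams


def traj_from_diameters(diams):
    d = np.asarray(diams, dtype=float)
    return pd.DataFrame({"day": np.arange(d.size), "diameter_cm": d,
                         "total_N": d ** 3})


def small_state(R, alleles, lineage_specs):
    """lineage_specs: list of (N, expressed ids)."""
    from neoprey.tumor import TumorState

    state = TumorState(TumorParams(n_mhc_alleles=2))
    for k, (r, a) in enumerate(zip(R, alleles)):
        state.register(Neoantigen(k, r, a))
    for N, expr in lineage_specs:
        state.new_lineage(None, N, np.asarray(expr, dtype=int),
                          np.ones(2, bool))
    return state


class TestShrinkageAndResponse:
    def test_monotone_growth_not_responder(self):
        traj = traj_from_diameters([5.0, 5.2, 5.5, 6.0])
        s = an.max_shrinkage(traj)
        assert s <= 0 and not an.classify_response(s)

    def test_boundary_inclusive_on_diameter(self):
        traj = traj_from_diameters([5.0, 4.0, 3.5, 4.2])
        s = an.max_shrinkage(traj, on="diameter_cm")
        assert s == pytest.approx(0.30)
        assert an.classify_response(s)

    def test_small_shrinkage(self):
        traj = traj_from_diameters([5.0, 4.9, 5.3])
        s = an.max_shrinkage(traj, on="diameter_cm")
        assert s == pytest.approx(0.02) and not an.classify_response(s)

    def test_default_is_cell_basis(self):
        traj = pd.DataFrame({"day": [0, 1], "diameter_cm": [5.0, 4.5],
                             "total_N": [1000.0, 600.0]})
        assert an.max_shrinkage(traj) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            an.max_shrinkage(traj_from_diameters([]))


class TestRank1:
    def test_single_clonal(self):
        state = small_state([0.8], [0], [(100.0, [0])])
        assert an.rank1_metrics(state) == pytest.approx((0.8, 1.0, 0.8))

    def test_half_clonal(self):
        state = small_state([0.8], [0], [(50.0, [0]), (50.0, [])])
        assert an.rank1_metrics(state) == pytest.approx((0.8, 0.5, 0.4))

    def test_all_zero_flagged(self):
        state = small_state([0.0, 0.0], [0, 1], [(10.0, [0, 1])])
        rid, r, c, p = an.rank1_neoantigen(state)
        assert rid == -1 and (r, c, p) == (0.0, 0.0, 0.0)

    def test_tie_breaks_to_higher_clonality(self):
        state = small_state([0.5, 0.5], [0, 1],
                            [(80.0, [0, 1]), (20.0, [1])])
        rid, _, c, _ = an.rank1_neoantigen(state)
        assert rid == 1 and c == pytest.approx(1.0)


class TestImmunoediting:
    def test_fold_change(self):
        traj = pd.DataFrame({"rank1_presented": [100.0, 80.0, 20.0]})
        assert an.immunoediting_fold_change(traj) == pytest.approx(0.2)

    def test_absent_at_start_is_missing(self):
        traj = pd.DataFrame({"rank1_presented": [0.0, 0.0]})
        assert np.isnan(an.immunoediting_fold_change(traj))


class TestSensSpec:
    def test_perfect_separation(self):
        metric = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        sens, spec, thr, direction = an.biomarker_sens_spec(metric, labels)
        assert sens == 1.0 and spec == 1.0 and direction == 1

    def test_inverted_labels_symmetric(self):
        metric = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        sens, spec, thr, direction = an.biomarker_sens_spec(metric, labels)
        assert sens == 1.0 and spec == 1.0 and direction == -1

    def test_uninformative_metric(self):
        rng = np.random.default_rng(0)
        metric = rng.random(2000)
        labels = rng.random(2000) < 0.4
        sens, spec, _, _ = an.biomarker_sens_spec(metric, labels)
        assert sens + spec - 1.0 < 0.1  # Youden's J near zero

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            an.biomarker_sens_spec([1.0, 2.0], [True, True])


class TestEntropies:
    def test_single_neoantigen_zero(self):
        state = small_state([0.5], [0], [(100.0, [0])])
        assert an.immunopeptidome_entropy(state) == 0.0

    def test_two_equal_ln2(self):
        state = small_state([0.5, 0.5], [0, 1], [(50.0, [0, 1])])
        assert an.immunopeptidome_entropy(state) == pytest.approx(np.log(2))

    def test_weighted(self):
        state = small_state([0.5, 0.5, 0.5], [0, 1, 0],
                            [(50.0, [0, 1, 2]), (50.0, [0])])
        # presented cells 100/50/50 -> weights (0.5, 0.25, 0.25)
        assert an.immunopeptidome_entropy(state) == pytest.approx(1.0397208)

    def test_no_presented_raises(self):
        state = small_state([0.5], [0], [(100.0, [])])
        with pytest.raises(ValueError):
            an.immunopeptidome_entropy(state)


class TestEntropyPercentiles:
    def test_all_responders(self):
        df = pd.DataFrame({"immunopeptidome_entropy": [1, 2, 3, 4.0],
                           "responder": [True] * 4})
        assert an.entropy_percentile_response(df, 25) == (1.0, 1.0)

    def test_partition_identity_at_50(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"immunopeptidome_entropy": rng.random(40),
                           "responder": rng.random(40) < 0.35})
        top, bottom = an.entropy_percentile_response(df, 50)
        assert (top + bottom) / 2 == pytest.approx(df["responder"].mean())

    def test_independent_metric_near_base_rate(self):
        rng = np.random.default_rng(8)
        n = 4000
        df = pd.DataFrame({"immunopeptidome_entropy": rng.random(n),
                           "responder": rng.random(n) < 0.3})
        top, bottom = an.entropy_percentile_response(df, 25)
        for frac in (top, bottom):
            assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / (n // 4))

    def test_bad_percentile(self):
        df = pd.DataFrame({"immunopeptidome_entropy": [1.0],
                           "responder": [True]})
        with pytest.raises(ValueError):
            an.entropy_percentile_response(df, 60)


class TestTop5:
    def test_normalization_identity(self):
        trajs = [pd.DataFrame({"day": [0, 1], "top5_sum": [s, 2 * s]})
                 for s in (10.0, 30.0)]
        df = an.top5_trajectory(trajs)
        assert np.mean([df[i].iloc[0] for i in range(2)]) == pytest.approx(1.0)

    def test_flat_when_frozen(self):
        trajs = [pd.DataFrame({"day": [0, 1, 2], "top5_sum": [5.0] * 3})]
        df = an.top5_trajectory(trajs)
        assert np.ptp(df[0]) == 0.0


class TestCorrelate:
    def test_linear(self):
        x = np.arange(10.0)
        r, p = an.correlate(x, 2 * x, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(-2, 2, 30)
        rs, _ = an.correlate(x, x ** 3, "spearman")
        rp, _ = an.correlate(x, x ** 3, "pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_closed_form_five_points(self):
        """Product-moment correlation against the textbook formula."""
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 9.0])
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
        r, _ = an.correlate(x, y, "pearson")
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            an.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLocalSensitivity:
    def test_delta_zero_trivial(self):
        """With delta=0 every fold change is exactly 1 (matched seeds)."""
        res = an.local_sensitivity("human_nsclc", ["kg"], delta=0.0, n=2,
                                   master_seed=1, target_d=0.02, max_days=900)
        assert np.allclose(res.table["fold_neoantigens"], 1.0)
        assert np.allclose(res.table["fold_tcr_entropy"], 1.0, equal_nan=True)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            an.local_sensitivity("human_nsclc", ["not_a_param"], n=2,
                                 target_d=0.02, max_days=50)

    def test_perturbation_produces_table(self):
        res = an.local_sensitivity("human_nsclc", ["nG"], delta=0.2, n=2,
                                   master_seed=1, target_d=0.02, max_days=900)
        assert set(res.table["parameter"]) == {"nG"}
        assert len(res.table) == 2  # up and down
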