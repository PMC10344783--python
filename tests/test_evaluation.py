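"""Error taxonomy, karyotype accuracy, distance matrices, binomial test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fiberalign import (ReferenceMap, SimulatedCell, binomial_preference_test,
                        classify_selections, contact_comparison,
                        karyotype_accuracy, match_bins, median_distance_matrix,
                        simulate_polymer, simulation_params)
from fiberalign.aligner import PolymerTrace

from conftest import spot_frame


def make_trace(orders, xyz, spot_ids, T, chrom="chrT", cell=0):
    orders = np.asarray(orders, dtype=int)
    return PolymerTrace(chrom, cell, orders, np.asarray(spot_ids),
                        np.asarray(xyz, dtype=float),
                        np.zeros(len(orders) + 1), 0.0, T)


class TestClassifySelections:
    def test_hand_built_five_locus_case(self):
        """One fiber over 5 loci: selected TP, selected TP, stray chosen over
        present signal, present signal skipped, stray chosen with no signal.
        Coverage 0.4, Type II 0.2, Type III 0.2, Type I (global) 0.2."""
        labels = ["TP", "TP", "TP", "FP", "TP", "FP"]
        fibers = [0, 0, 0, -1, 0, -1]
        orders = [1, 2, 3, 3, 4, 5]          # fiber spot at 5 was dropped
        xyz = np.zeros((6, 3))
        spots = spot_frame(orders, xyz, labels=labels, fibers=fibers)
        cell = SimulatedCell(0, 5000.0, {"chrT": 1},
                             {"chrT": np.zeros((1, 5, 3))}, spots)
        # the trace selects rows 0, 1, the stray at locus 3, skips 4,
        # and the stray at locus 5
        trace = make_trace([1, 2, 3, 5], np.zeros((4, 3)),
                           spots.index[[0, 1, 3, 5]], T=5)
        rep = classify_selections([trace], cell, "chrT")
        assert (rep.n_covered, rep.n_type2, rep.n_type3) == (2, 1, 1)
        assert rep.n_type1 == 1
        assert rep.coverage_rate == pytest.approx(0.4)
        assert rep.type2_rate == pytest.approx(0.2)
        assert rep.type3_rate == pytest.approx(0.2)
        assert rep.type1_rate_global == pytest.approx(0.2)
        assert rep.type1_rate == pytest.approx(1.0)  # 1 dropped locus offered a stray

    def test_perfect_selection(self):
        spots = spot_frame([1, 2, 3], np.zeros((3, 3)))
        cell = SimulatedCell(0, 5000.0, {"chrT": 1},
                             {"chrT": np.zeros((1, 3, 3))}, spots)
        trace = make_trace([1, 2, 3], np.zeros((3, 3)), spots.index, T=3)
        rep = classify_selections([trace], cell, "chrT")
        assert rep.coverage_rate == 1.0
        assert rep.n_type2 == rep.n_type3 == rep.n_type1 == 0

    def test_empty_trace_set_is_all_type3(self):
        spots = spot_frame([1, 2, 3], np.zeros((3, 3)))
        cell = SimulatedCell(0, 5000.0, {"chrT": 1},
                             {"chrT": np.zeros((1, 3, 3))}, spots)
        rep = classify_selections([], cell, "chrT")
        assert rep.n_type3 == 3 and rep.n_covered == 0

    def test_budget_closure_is_exact(self):
        # coverage + TypeII + TypeIII must account for every detected spot
        rng = np.random.default_rng(4)
        labels = ["TP"] * 6 + ["FP"] * 2
        fibers = [0, 0, 0, 1, 1, 1, -1, -1]
        orders = [1, 2, 4, 1, 3, 4, 2, 3]
        spots = spot_frame(orders, rng.normal(size=(8, 3)), labels=labels,
                           fibers=fibers)
        cell = SimulatedCell(0, 5000.0, {"chrT": 2},
                             {"chrT": np.zeros((2, 4, 3))}, spots)
        trace = make_trace([1, 2, 4], np.zeros((3, 3)), spots.index[[0, 6, 2]],
                           T=4)
        rep = classify_selections([trace], cell, "chrT")
        assert rep.n_covered + rep.n_type2 + rep.n_type3 == rep.n_detected


class TestKaryotypeAccuracy:
    def test_identity_confusion(self):
        out = karyotype_accuracy([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert np.array_equal(np.diag(out["confusion"].to_numpy()), np.ones(5))
        assert out["n_undercount"] == out["n_overcount"] == 0
        assert (out["detection_fraction"].dropna() == 1.0).all()

    def test_under_and_overcounts(self):
        out = karyotype_accuracy([1, 3, 2], [2, 2, 2])
        assert out["n_undercount"] == 1 and out["n_overcount"] == 1
        assert out["detection_fraction"][2] == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            karyotype_accuracy([1], [1, 2])


class TestMedianDistanceMatrix:
    def test_single_trace_gives_exact_pairwise(self):
        xyz = np.array([[0, 0, 0], [100, 0, 0], [100, 200, 0.0]])
        tr = make_trace([1, 2, 3], xyz, [0, 1, 2], T=3)
        m = median_distance_matrix([tr])
        assert m[0, 1] == pytest.approx(100)
        assert m[0, 2] == pytest.approx(np.hypot(100, 200))
        assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)

    def test_invariant_to_trace_ordering(self):
        rng = np.random.default_rng(1)
        traces = [make_trace([1, 2, 3], rng.normal(size=(3, 3)), [0, 1, 2], 3)
                  for _ in range(5)]
        a = median_distance_matrix(traces)
        b = median_distance_matrix(traces[::-1])
        assert np.allclose(a, b, equal_nan=True)

    def test_never_coassigned_pair_is_missing(self):
        t1 = make_trace([1, 2], np.zeros((2, 3)), [0, 1], T=3)
        t2 = make_trace([2, 3], np.zeros((2, 3)), [2, 3], T=3)
        m = median_distance_matrix([t1, t2])
        assert np.isnan(m[0, 2])

    def test_unconfined_ensemble_grows_as_sqrt_separation(self, sim_params):
        pos = 3e6 + 1.0e6 * np.arange(12)
        ref = ReferenceMap("chrT", pos)
        rng = np.random.default_rng(3)
        traces = []
        for k in range(300):
            xyz = simulate_polymer(ref, sim_params, np.inf, rng)
            traces.append(make_trace(np.arange(1, 13), xyz, np.arange(12), 12))
        m = median_distance_matrix(traces)
        seps = np.arange(1, 12)
        med = np.array([np.nanmedian(np.diag(m, k)) for k in seps])
        slope = np.polyfit(np.log(seps), np.log(med), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)


class TestContactComparison:
    def _dist(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 3)).cumsum(axis=0) * 300
        return np.linalg.norm(x[:, None] - x[None, :], axis=-1)

    def test_monotone_decay_gives_perfect_anticorrelation(self):
        d = self._dist()
        assert contact_comparison(d, np.exp(-d / 1000)) == pytest.approx(-1.0)

    def test_identity_gives_perfect_correlation(self):
        d = self._dist()
        assert contact_comparison(d, d) == pytest.approx(1.0)

    def test_independent_matrices_uncorrelated(self):
        rhos = [abs(contact_comparison(self._dist(50, s),
                                       np.abs(np.random.default_rng(100 + s)
                                              .normal(size=(50, 50)))))
                for s in range(6)]
        assert np.median(rhos) < 0.3

    def test_threshold_mode_uses_contact_frequencies(self):
        rng = np.random.default_rng(7)
        stack = np.stack([self._dist(20, s) for s in range(40)])
        freq_truth = (stack < 500).mean(axis=0)
        rho = contact_comparison(stack, freq_truth + 1e-9, threshold_nm=500.0)
        assert rho > 0.95

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contact_comparison(self._dist(10), np.ones((5, 5)))

    def test_bin_matching_keeps_closest_locus(self):
        ref = ReferenceMap("chrT", np.array([0.2e6, 1.1e6, 1.9e6, 3.05e6]))
        li, bi = match_bins(ref, 1e6)
        # bins at 0, 1, 2, 3 Mb -> loci 0.2, 1.1, 1.9, 3.05
        assert li.tolist() == [0, 1, 2, 3]
        assert bi.tolist() == [0, 1, 2, 3]


class TestBinomialPreferenceTest:
    def test_xist_preference_value(self):
        assert binomial_preference_test(20, 30) == pytest.approx(0.049369,
                                                                 abs=5e-7)

    def test_zero_successes_is_certain(self):
        assert binomial_preference_test(0, 17) == 1.0

    def test_all_successes_small_n(self):
        assert binomial_preference_test(5, 5) == pytest.approx(0.03125)

    @pytest.mark.parametrize("k,n", [(3, 10), (55, 100), (480, 1000)])
    def test_matches_survival_function_oracle(self, k, n):
        assert binomial_preference_test(k, n) == pytest.approx(
            float(stats.binom.sf(k - 1, n, 0.5)), abs=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_preference_test(11, 10)
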