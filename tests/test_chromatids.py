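"""Territory clustering, sister pairing and the misselection scan."""

import numpy as np
import pytest

from fiberalign import (ReferenceMap, assign_sisters, cis_trans_profiles,
                        cluster_territories, interpolate_trace,
                        misselection_scan, simulate_sister_pair,
                        simulation_params)
from fiberalign.aligner import PolymerTrace


def make_trace(xyz, T=None, orders=None, cell=0):
    xyz = np.asarray(xyz, dtype=float)
    T = T or len(xyz)
    orders = np.asarray(orders if orders is not None
                        else np.arange(1, len(xyz) + 1), dtype=int)
    return PolymerTrace("chrT", cell, orders, np.arange(len(orders)), xyz,
                        np.zeros(len(orders)), 0.0, T)


@pytest.fixture(scope="module")
def ref12():
    pos = 3e6 + np.cumsum(np.random.default_rng(2).uniform(0.3e6, 1.9e6, 12))
    return ReferenceMap("chrT", pos)


class TestClusterTerritories:
    def test_distant_fibers_form_two_territories(self):
        rng = np.random.default_rng(0)
        a = make_trace(rng.normal(scale=300, size=(10, 3)))
        b = make_trace(rng.normal(scale=300, size=(10, 3)) + 10_000.0)
        labels = cluster_territories([a, b], eps_nm=2_000.0)
        assert len(set(labels)) == 2

    def test_compact_state_is_one_cluster(self):
        rng = np.random.default_rng(1)
        traces = [make_trace(rng.normal(scale=200, size=(10, 3)))
                  for _ in range(4)]
        labels = cluster_territories(traces, eps_nm=2_000.0)
        assert len(set(labels)) == 1

    def test_vanishing_radius_separates_everything(self):
        rng = np.random.default_rng(2)
        traces = [make_trace(rng.normal(scale=500, size=(8, 3)))
                  for _ in range(3)]
        labels = cluster_territories(traces, eps_nm=1e-6)
        assert len(set(labels)) == 3


class TestAssignSisters:
    def _four_traces(self, pair_sep=200.0, terr_sep=8_000.0, seed=3):
        """Two sister pairs in two distant territories: (0,1) and (2,3)."""
        rng = np.random.default_rng(seed)
        base1 = rng.normal(scale=400, size=(10, 3)).cumsum(axis=0)
        base2 = rng.normal(scale=400, size=(10, 3)).cumsum(axis=0)
        base2 += terr_sep
        return [make_trace(base1),
                make_trace(base1 + rng.normal(scale=pair_sep, size=(10, 3))),
                make_trace(base2),
                make_trace(base2 + rng.normal(scale=pair_sep, size=(10, 3)))]

    def test_exactly_three_matchings(self):
        sa = assign_sisters(self._four_traces())
        assert len(sa.matchings) == 3
        flat = [frozenset(m) for m in sa.matchings]
        assert len(set(flat)) == 3

    def test_sa_recovers_true_pairs(self):
        sa = assign_sisters(self._four_traces())
        assert frozenset(map(frozenset, sa.sa)) == \
            frozenset({frozenset({0, 1}), frozenset({2, 3})})

    def test_ea_recovers_true_pairs_at_the_ends(self):
        sa = assign_sisters(self._four_traces())
        assert frozenset(map(frozenset, sa.ea)) == \
            frozenset({frozenset({0, 1}), frozenset({2, 3})})

    def test_alternates_are_the_remaining_matchings(self):
        sa = assign_sisters(self._four_traces())
        all_m = {frozenset(map(frozenset, m)) for m in sa.matchings}
        got = {frozenset(map(frozenset, m)) for m in (sa.sa, sa.alt1, sa.alt2)}
        assert got == all_m

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            assign_sisters(self._four_traces()[:3])

    def test_unpaired_control_is_start_to_end(self):
        traces = self._four_traces()
        sa = assign_sisters(traces)
        expect = [np.linalg.norm(t.coords_nm[0] - t.coords_nm[-1])
                  for t in traces]
        assert np.allclose(sa.control_nm, expect)


class TestCisTransProfiles:
    def test_identical_fibers_have_zero_shadow(self, ref12):
        xyz = np.random.default_rng(4).normal(scale=400, size=(12, 3))
        profile, shadow = cis_trans_profiles([(make_trace(xyz),
                                               make_trace(xyz))], ref12)
        assert np.allclose(shadow, 0.0)
        assert {"cis", "trans"} == set(profile["kind"])

    def test_paired_sisters_trans_exceeds_cis_at_short_range(self, ref12,
                                                             sim_params):
        pairs = []
        for s in range(6):
            a, b = simulate_sister_pair(ref12, sim_params, pairing_strength=1.0,
                                        seed=s)
            pairs.append((make_trace(a), make_trace(b)))
        profile, shadow = cis_trans_profiles(pairs, ref12)
        first_bin = profile[profile["bin_mid_bp"] ==
                            profile["bin_mid_bp"].min()]
        cis0 = first_bin[first_bin["kind"] == "cis"]["mean_nm"]
        trans0 = first_bin[first_bin["kind"] == "trans"]["mean_nm"]
        if len(cis0) and len(trans0):
            assert trans0.iloc[0] > cis0.iloc[0]
        assert np.median(shadow) > 0

    def test_independent_fibers_trans_flat_in_separation(self, ref12,
                                                         sim_params):
        pairs = []
        for s in range(8):
            a, b = simulate_sister_pair(ref12, sim_params, pairing_strength=0.0,
                                        radius_nm=1_500.0, seed=100 + s)
            pairs.append((make_trace(a), make_trace(b)))
        profile, _ = cis_trans_profiles(pairs, ref12)
        trans = profile[profile["kind"] == "trans"].sort_values("bin_mid_bp")
        lo, hi = trans["mean_nm"].iloc[0], trans["mean_nm"].iloc[-1]
        assert abs(hi - lo) / lo < 0.5


class TestInterpolation:
    def test_gaps_filled_linearly(self):
        xyz = np.array([[0, 0, 0], [300.0, 0, 0]])
        tr = make_trace(xyz, T=3, orders=[1, 3])
        filled = interpolate_trace(tr)
        assert np.allclose(filled[1], [150.0, 0, 0])

    def test_needs_two_assigned_loci(self):
        tr = make_trace(np.zeros((1, 3)), T=5, orders=[3])
        with pytest.raises(ValueError):
            interpolate_trace(tr)


class TestMisselectionScan:
    def test_identical_fibers_have_no_events(self, ref12, sim_params):
        xyz = np.random.default_rng(5).normal(scale=400, size=(12, 3)).cumsum(axis=0)
        scan = misselection_scan(make_trace(xyz), make_trace(xyz), ref12,
                                 sim_params)
        assert scan.n_misselections == 0 and scan.n_crossovers == 0

    def test_deliberately_exchanged_block_is_one_crossover(self, ref12,
                                                           sim_params):
        """Swap one 3-locus block between two well-separated fibers: the scan
        must flag exactly that block as a single cross-over event."""
        a, b = simulate_sister_pair(ref12, sim_params, pairing_strength=2.0,
                                    seed=9)
        b = b + np.array([4_000.0, 0.0, 0.0])     # separate so swaps are costly
        a2, b2 = a.copy(), b.copy()
        blk = slice(5, 8)                          # loci 6..8 (1-based)
        a2[blk], b2[blk] = b[blk].copy(), a[blk].copy()
        scan = misselection_scan(make_trace(a2), make_trace(b2), ref12,
                                 sim_params)
        # the swap-back window at the block start must be flagged, nothing
        # upstream of the block may be (downstream windows can legitimately
        # flag the re-unification of the tail, since only upstream bonds are
        # recalculated)
        assert bool(scan.flagged[scan.window_starts == 6][0])
        assert not scan.flagged[scan.window_starts < 6].any()
        assert scan.n_crossovers >= 1
        assert scan.crossover_events[0][0] == 6

    def test_symmetric_in_fiber_order(self, ref12, sim_params):
        a, b = simulate_sister_pair(ref12, sim_params, pairing_strength=1.0,
                                    seed=10)
        s1 = misselection_scan(make_trace(a), make_trace(b), ref12, sim_params)
        s2 = misselection_scan(make_trace(b), make_trace(a), ref12, sim_params)
        assert np.array_equal(s1.flagged, s2.flagged)

    def test_invariant_to_rigid_translation(self, ref12, sim_params):
        a, b = simulate_sister_pair(ref12, sim_params, pairing_strength=1.0,
                                    seed=11)
        shift = np.array([5_000.0, -2_000.0, 800.0])
        s1 = misselection_scan(make_trace(a), make_trace(b), ref12, sim_params)
        s2 = misselection_scan(make_trace(a + shift), make_trace(b + shift),
                               ref12, sim_params)
        assert np.array_equal(s1.flagged, s2.flagged)

    def test_short_reference_rejected(self, sim_params):
        tiny = ReferenceMap("c", np.array([1e6, 2e6, 3e6, 4e6, 5e6]))
        xyz = np.zeros((5, 3))
        with pytest.raises(ValueError):
            misselection_scan(make_trace(xyz), make_trace(xyz), tiny,
                              sim_params)
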