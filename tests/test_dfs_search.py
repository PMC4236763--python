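import numpy as np
import pytest

from efmdfs.dfs_search import (DepthFirstEnumerator, SearchState,
                               enumerate_efms, load_state)
from efmdfs.lp_engine import ConstraintSet, get_backend
from efmdfs.nullspace_core import compute_nsrref, is_elementary, leading_independent_rows
from efmdfs.oracle_fixtures import (brute_force_efms, layered_branch_network,
                                    _net)
from conftest import BACKENDS, random_networks


@pytest.mark.parametrize("backend_name", BACKENDS)
def test_fixture_counts(chain, diamond, toy, backend_name):
    backend = get_backend(backend_name)
    for net, count in ((chain, 1), (diamond, 2), (toy, 9)):
        res = enumerate_efms(net, backend=backend, check_duplicates=True)
        assert res.n_efms == count
        assert res.counters["efms"] == count


class TestInitialize:
    def test_chain_initial_mode(self, chain):
        enum = DepthFirstEnumerator(chain)
        state, record = enum.initialize()
        assert state.iff == []  # DoF-1 = 0 presets for a one-dimensional nullspace
        assert record is not None
        assert np.allclose(record.flux, [1.0, 1.0, 1.0])

    def test_initial_mode_identified_by_preset_pivots(self):
        # branch reactions listed first, so presetting the leading pivot to
        # zero still leaves the other branch as a feasible initial mode
        net = _net(["A", "B", "C", "D"], ["b1", "b2", "c1", "c2", "up", "out"],
                   [{"A": -1, "B": 1}, {"B": -1, "D": 1}, {"A": -1, "C": 1},
                    {"C": -1, "D": 1}, {"A": 1}, {"D": -1}])
        enum = DepthFirstEnumerator(net)
        state, record = enum.initialize()
        assert record is not None
        assert len(record.iff_set) == enum.dof - 1 == 1
        assert record.iff_set == frozenset(enum.basis.pivot_rows[:1])
        assert sorted(np.flatnonzero(record.support)) == [2, 3, 4, 5]

    def test_preset_iff_is_leading_pivots(self, toy):
        enum = DepthFirstEnumerator(toy)
        state, record = enum.initialize()
        assert state.iff == enum.basis.pivot_rows[:5] == sorted(state.iff)
        # the first pivot here is the sole substrate uptake, which every mode
        # needs: presetting it inactive leaves no feasible initial FAF
        assert record is None

    def test_no_initial_mode_when_nothing_feasible(self, diamond):
        # the source r1 is a pivot here; forcing it inactive kills every flux,
        # so no downstream lone FAF is feasible
        enum = DepthFirstEnumerator(diamond)
        state, record = enum.initialize()
        assert record is None
        assert state.phase == "backward"


class TestBackTrack:
    def test_empty_iff_terminates(self, diamond):
        enum = DepthFirstEnumerator(diamond)
        state = SearchState([], [], np.zeros((6, 1), dtype=np.int8), 5, "backward")
        enum.back_track(state)
        assert state.phase == "done"

    def test_feasible_conversion_switches_to_forward(self, diamond):
        enum = DepthFirstEnumerator(diamond)
        state = SearchState([0], [], np.zeros((6, 1), dtype=np.int8), 0, "backward")
        enum.back_track(state)
        assert state.phase == "forward"
        assert state.faf == [0] and state.iff == []
        assert state.cursor == 0

    def test_downstream_faf_cleared_on_pop(self, toy):
        enum = DepthFirstEnumerator(toy)
        state = SearchState([0, 1, 2], [10, 12],
                            np.zeros((14, 5), dtype=np.int8), 12, "backward")
        enum.back_track(state)
        assert all(f <= state.cursor for f in state.faf)
        assert state.faf[-1] == state.cursor


class TestCheckPoints:
    def test_enough_iff_trivially_proceeds(self, toy):
        enum = DepthFirstEnumerator(toy)
        state, _ = enum.initialize()
        assert enum.check_points(state, state.cursor + 1) != "prune"

    def test_insufficient_candidates_prunes(self, diamond):
        enum = DepthFirstEnumerator(diamond)
        state = SearchState([], [], np.zeros((6, 1), dtype=np.int8), 5, "forward")
        assert enum.check_points(state, 6) == "prune"

    def test_forced_active_mode_detected(self, diamond):
        # all four reactions of one branch forced active: nullity 1
        enum = DepthFirstEnumerator(diamond)
        state = SearchState([], [0, 1, 3, 5], np.zeros((6, 1), dtype=np.int8),
                            -1, "forward")
        assert enum.check_points(state, 0) == "efm_found"

    def test_rank_deficient_candidates_prune(self, diamond):
        enum = DepthFirstEnumerator(diamond)
        # only candidate left is r4 whose row duplicates r2's; with iff empty
        # the remaining rank cannot reach DoF-1... rank({r4}) = 1 = DoF-1,
        # so instead block everything: no candidates at all
        state = SearchState([], [0, 1, 2, 3, 4, 5][:0],
                            np.zeros((6, 1), dtype=np.int8), 5, "forward")
        assert enum.check_points(state, 6) == "prune"


class TestEnumerate:
    def test_diamond_constrained_to_one_branch(self, diamond):
        cs = ConstraintSet(flux_bounds=((3, 1.0),))
        res = enumerate_efms(diamond, cs, check_duplicates=True)
        assert res.n_efms == 1
        assert list(np.flatnonzero(res.efms.records[0].support)) == [0, 1, 3, 5]

    def test_infeasible_constraints_empty_stream(self, diamond):
        cs = ConstraintSet(iff=frozenset({1, 2}), faf=frozenset({5}))
        res = enumerate_efms(diamond, cs)
        assert res.n_efms == 0

    def test_dof_zero_network(self):
        net = _net(["A", "B"], ["r1", "r2"], [{"A": 1}, {"B": 1}])
        assert enumerate_efms(net).n_efms == 0

    def test_matches_oracle_on_random_networks(self):
        for net in random_networks(15, seed=77, max_rxns=14, max_dof=5):
            res = enumerate_efms(net, check_duplicates=True)
            assert res.efms.same_supports(brute_force_efms(net))

    @pytest.mark.parametrize("backend_name", BACKENDS)
    def test_backends_agree(self, backend_name):
        backend = get_backend(backend_name)
        for net in random_networks(5, seed=13, max_rxns=12, max_dof=4):
            res = enumerate_efms(net, backend=backend, check_duplicates=True)
            assert res.efms.same_supports(brute_force_efms(net))

    def test_every_record_is_elementary(self, toy):
        for rec in enumerate_efms(toy).efms:
            assert is_elementary(rec.support, toy.stoich)

    def test_iff_sets_unique_and_leading(self, toy):
        """Each mode's identifier is the lexicographically smallest
        rank-(DoF-1) subset of its inactive reactions."""
        basis = compute_nsrref(toy.stoich)
        seen = set()
        for net in [toy] + list(random_networks(8, seed=55, max_rxns=13, max_dof=4)):
            bas = compute_nsrref(net.stoich)
            seen.clear()
            for rec in enumerate_efms(net).efms:
                assert rec.iff_set not in seen
                seen.add(rec.iff_set)
                inactive = sorted(np.flatnonzero(~rec.support))
                expected = leading_independent_rows(bas.ns, bas.dof - 1,
                                                    candidates=inactive)
                assert rec.iff_set == frozenset(expected)

    def test_counters_track_lp_and_rank_calls(self, toy):
        res = enumerate_efms(toy)
        assert res.counters["lp_calls"] > 0
        assert res.counters["rank_tests"] > 0
        assert res.counters["efms"] == 9


class TestResume:
    @pytest.mark.parametrize("stop", [1, 4, 8])
    def test_interrupt_resume_equals_full_run(self, toy, stop):
        full = enumerate_efms(toy).efms
        first = enumerate_efms(toy, stop_after=stop)
        assert first.n_efms == stop and first.snapshot is not None
        rest = enumerate_efms(toy, resume_snapshot=first.snapshot,
                              check_duplicates=True)
        keys = first.efms.support_keys() | rest.efms.support_keys()
        assert len(first.efms) + len(rest.efms) == len(full)
        assert keys == full.support_keys()

    def test_state_json_roundtrip(self, toy):
        first = enumerate_efms(toy, stop_after=3)
        enum = DepthFirstEnumerator(toy)
        state = load_state(first.snapshot, enum)
        assert state.iff == sorted(state.iff)
        assert state.m_record.shape == (14, 5)


class TestConstantMemory:
    def test_buffer_never_exceeds_batch_size(self):
        """A run producing far more modes than the batch size retains at most
        one batch of records at a time."""
        net = layered_branch_network(7)  # 128 EFMs
        flushed = []

        class Sink:
            def append(self, batch):
                flushed.append(len(batch))

            def finalize(self):
                pass

        res = enumerate_efms(net, sink=Sink(), batch_size=8, collect=False)
        assert res.n_efms == 128
        assert res.efms is None  # nothing retained beyond the buffer
        assert res.counters["max_buffered"] <= 8
        assert sum(flushed) == 128
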