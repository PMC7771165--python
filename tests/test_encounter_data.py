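"""Encounter-history data model: occasion collapse, latent/observed maps, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flankscr.encounter_data import (
    TrapArray, ObservedEncounterData, MatchState,
    collapse_to_occasions, merge_pair, split_history, latent_to_observed,
    is_feasible, single_side_observed,
    read_traps, write_traps, read_detections, write_detections,
    detections_to_observed, observed_to_detections,
    write_history_matrix, read_history_matrix,
)
from flankscr.simulate import simulate_study, SimConfig


def _raw(rows):
    return pd.DataFrame(rows, columns=["record_id", "kind", "trap_id", "day", "code"])


class TestCollapseToOccasions:
    def test_sixty_days_three_per_occasion_gives_twenty(self):
        rows = [("w1", "left", "A", d, 1) for d in (1, 30, 60)]
        out = collapse_to_occasions(_raw(rows), occasion_length=3, n_days=60)
        assert sorted(out["occasion"]) == [1, 10, 20]

    def test_same_occasion_detections_collapse_to_one_event(self):
        rows = [("w1", "left", "A", 1, 1), ("w1", "left", "A", 2, 1)]
        out = collapse_to_occasions(_raw(rows), occasion_length=3)
        assert len(out) == 1 and out["occasion"].iloc[0] == 1

    def test_occasion_boundary_days_three_and_four(self):
        rows = [("w1", "left", "A", 3, 1), ("w1", "left", "A", 4, 1)]
        out = collapse_to_occasions(_raw(rows), occasion_length=3)
        assert sorted(out["occasion"]) == [1, 2]

    def test_day_beyond_survey_rejected(self):
        with pytest.raises(ValueError, match="exceeds the survey length"):
            collapse_to_occasions(_raw([("w1", "left", "A", 61, 1)]),
                                  occasion_length=3, n_days=60)

    def test_both_flanks_within_occasion_combine_to_code_three(self):
        rows = [("w1", "known", "A", 1, 1), ("w1", "known", "A", 2, 2)]
        out = collapse_to_occasions(_raw(rows), occasion_length=3)
        assert out["code"].tolist() == [3]

    def test_simultaneity_dominates_on_collapse(self):
        rows = [("w1", "known", "A", 1, 4), ("w1", "known", "A", 2, 1)]
        out = collapse_to_occasions(_raw(rows), occasion_length=3)
        assert out["code"].tolist() == [4]


class TestMergeSplit:
    @pytest.mark.parametrize("left,right,expected", [
        ([1, 0, 1], [0, 2, 0], [1, 2, 1]),    # disjoint cells
        ([1, 0], [2, 0], [3, 0]),             # co-occurrence -> code 3
        ([0, 0], [0, 2], [0, 2]),             # identity on one side
    ])
    def test_merge_examples(self, left, right, expected):
        got = merge_pair(np.array([left], dtype=np.int8),
                         np.array([right], dtype=np.int8))
        assert got.tolist() == [expected]

    def test_merge_never_produces_simultaneity(self):
        merged = merge_pair(np.array([[1, 1, 0]]), np.array([[2, 0, 2]]))
        assert 4 not in merged

    def test_merge_rejects_wrong_codes(self):
        with pytest.raises(ValueError):
            merge_pair(np.array([[2]]), np.array([[2]]))

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_merge_then_split_recovers_inputs(self, cells):
        left = np.array([[1 if l else 0 for l, _ in cells]], dtype=np.int8)
        right = np.array([[2 if r else 0 for _, r in cells]], dtype=np.int8)
        l2, r2 = split_history(merge_pair(left, right))
        assert np.array_equal(l2, left) and np.array_equal(r2, right)


class TestLatentToObserved:
    def test_simultaneity_yields_known_record(self):
        out = latent_to_observed([np.array([[4, 1]], dtype=np.int8)])
        assert out.n_known == 1 and out.n1 == 0 and out.n2 == 0
        assert out.known[0].tolist() == [[4, 1]]

    def test_code_three_splits_into_both_singles(self):
        out = latent_to_observed([np.array([[3, 0]], dtype=np.int8)])
        assert (out.n_known, out.n1, out.n2) == (0, 1, 1)
        assert out.left[0].tolist() == [[1, 0]]
        assert out.right[0].tolist() == [[2, 0]]

    def test_left_only_individual_yields_left_record(self):
        out = latent_to_observed([np.array([[1, 0]], dtype=np.int8)])
        assert (out.n_known, out.n1, out.n2) == (0, 1, 0)

    def test_undetected_individuals_emit_nothing(self):
        out = latent_to_observed([np.zeros((1, 2), dtype=np.int8),
                                  np.array([[1, 0]], dtype=np.int8)])
        assert out.n_records == 1


class TestFeasibility:
    def test_empty_matching_is_feasible(self):
        data = ObservedEncounterData(left=[np.array([[1, 0]], dtype=np.int8)],
                                     right=[np.array([[0, 2]], dtype=np.int8)])
        assert is_feasible(MatchState(pairs=[]), data)

    def test_record_reuse_is_infeasible(self):
        data = ObservedEncounterData(
            left=[np.array([[1, 0]], dtype=np.int8),
                  np.array([[0, 1]], dtype=np.int8)],
            right=[np.array([[0, 2]], dtype=np.int8)])
        assert not is_feasible(MatchState(pairs=[(0, 0), (1, 0)]), data)

    def test_true_matching_of_simulated_survey_is_feasible(self):
        cfg = SimConfig(N=25, trap_grid=(4, 4), trap_spacing=1000.0,
                        n_occasions=6, beta=(-1.2,), sigma=700.0,
                        delta1=0.3, delta2=0.3, alpha=0.3)
        for seed in range(3):
            data, truth, traps, grid = simulate_study(cfg, seed=seed)
            assert is_feasible(truth.true_match(data), data)

    def test_counts_identity(self):
        data, truth, traps, grid = simulate_study("wildcat_like", seed=2)
        assert data.n_records == data.n_known + data.n1 + data.n2
        match = truth.true_match(data)
        n = match.n_individuals(data)
        assert data.n_records >= n >= data.n_known


class TestSingleSide:
    def test_right_side_projection(self):
        known = np.array([[4, 1], [0, 0]], dtype=np.int8)
        data = ObservedEncounterData(
            known=[known],
            left=[np.array([[1, 0], [0, 0]], dtype=np.int8)],
            right=[np.array([[0, 0], [2, 0]], dtype=np.int8)])
        right = single_side_observed(data, "right")
        # known projects to its right flank; left single drops out
        assert right.n_known == 2 and right.n1 == 0 and right.n2 == 0
        assert right.known[0].tolist() == [[2, 0], [0, 0]]


class TestIO:
    def test_traps_round_trip(self, small_traps, tmp_path):
        path = tmp_path / "traps.csv"
        write_traps(small_traps, path)
        back = read_traps(path)
        assert back.ids == small_traps.ids
        assert np.allclose(back.xy, small_traps.xy)
        assert np.array_equal(back.operation, small_traps.operation)

    def test_detections_round_trip(self, small_traps, tmp_path):
        data = ObservedEncounterData(
            known=[np.array([[4, 0], [0, 0], [3, 1]], dtype=np.int8)],
            left=[np.array([[1, 0], [0, 0], [0, 1]], dtype=np.int8)],
            right=[np.array([[0, 2], [2, 0], [0, 0]], dtype=np.int8)])
        df = observed_to_detections(data, small_traps)
        path = tmp_path / "det.csv"
        write_detections(df, path)
        back = read_detections(path, small_traps)
        for a, b in zip(data.known + data.left + data.right,
                        back.known + back.left + back.right):
            assert np.array_equal(a, b)

    def test_unknown_trap_id_rejected(self, small_traps):
        df = _raw([]).drop(columns="day").assign(occasion=[], code=[])
        df = pd.DataFrame([{"record_id": "w", "kind": "left", "trap_id": "ZZ",
                            "occasion": 1, "code": 1}])
        with pytest.raises(KeyError, match="ZZ"):
            detections_to_observed(df, small_traps)

    def test_history_matrix_round_trip_and_counts(self, small_traps, tmp_path):
        # wildcat-survey shaped record table: 13 known + 3 left + 5 right
        rng = np.random.default_rng(0)
        known = []
        for _ in range(13):
            h = np.zeros((3, 2), dtype=np.int8)
            h[rng.integers(3), rng.integers(2)] = 4
            known.append(h)
        left = [np.array([[1, 0], [0, 0], [0, 0]], dtype=np.int8)] * 3
        right = [np.array([[0, 2], [0, 0], [0, 0]], dtype=np.int8)] * 5
        data = ObservedEncounterData(known=known, left=list(left), right=list(right))
        path = tmp_path / "hist.csv"
        write_history_matrix(data, small_traps, path)
        back = read_history_matrix(path, small_traps)
        assert back.n_records == 21
        assert (back.n_known, back.n1, back.n2) == (13, 3, 5)
        for a, b in zip(data.known, back.known):
            assert np.array_equal(a, b)

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            ObservedEncounterData(left=[np.array([[5]], dtype=np.int8)])
        with pytest.raises(ValueError, match="left"):
            ObservedEncounterData(left=[np.array([[2]], dtype=np.int8)])
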