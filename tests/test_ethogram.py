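import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosnet.counts import ValidationError
from fosnet.ethogram import (
    STATES6,
    Ethogram,
    bootstrap_logratio_ci,
    default_segments,
    group_average_transitions,
    group_transition_shift,
    habituation_ratio,
    ilr_basis,
    ilr_inverse,
    ilr_transform,
    majority_filter,
    multivariate_group_test,
    occupancy,
    open_field_metrics,
    sliding_state_probability,
    split_locomotion,
    transition_matrix,
)


class TestMajorityFilter:
    def test_constant_sequence_unchanged(self):
        seq = np.array(["grooming"] * 30, dtype=object)
        assert (majority_filter(seq) == seq).all()

    def test_single_blip_removed(self):
        seq = np.array(["locomotion"] * 20, dtype=object)
        seq[10] = "reared"
        out = majority_filter(seq, 11)
        assert (out == "locomotion").all()

    def test_window_one_is_identity(self):
        seq = np.array(["a", "b", "a", "c"], dtype=object)
        assert (majority_filter(seq, 1) == seq).all()

    def test_tie_keeps_current_label(self):
        # window 3 at index 1 sees {a, b, b}; at index 2 sees {b, b, a}
        seq = np.array(["a", "a", "b", "b"], dtype=object)
        out = majority_filter(seq, 3)
        assert out.tolist() == ["a", "a", "b", "b"]

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            majority_filter(np.array(["a", "b"], dtype=object), 4)

    def test_length_preserved(self, rng):
        seq = rng.choice(list("abc"), 101).astype(object)
        assert len(majority_filter(seq, 11)) == 101


class TestSplitLocomotion:
    def test_non_locomotion_untouched_and_bins_partition(self):
        states = np.array(
            ["grooming", "locomotion", "locomotion", "locomotion", "reared"],
            dtype=object,
        )
        vel = np.array([0.1, 1.0, 3.0, 9.0, 0.2])
        out = split_locomotion(states, vel, (2.0, 5.0))
        assert out.tolist() == [
            "grooming", "locomotion_slow", "locomotion_medium",
            "locomotion_fast", "reared",
        ]
        n_loco = (states == "locomotion").sum()
        assert sum(s.startswith("locomotion_") for s in out) == n_loco

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValidationError):
            split_locomotion(np.array(["locomotion"], dtype=object),
                             np.array([-1.0]), (2.0, 5.0))

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            split_locomotion(np.array(["locomotion"], dtype=object),
                             np.array([1.0]), (5.0, 2.0))


class TestOccupancy:
    def test_single_state_sequence(self):
        seq = np.array(["reared"] * 10, dtype=object)
        occ = occupancy(seq, {"all": (0, 10)}, alphabet=STATES6)
        assert occ.loc["all", "reared"] == 1.0
        assert occ.loc["all"].sum() == 1.0

    def test_hand_counted_fractions(self):
        seq = np.array(["a"] * 3 + ["b"] * 2 + ["a"] * 5, dtype=object)
        occ = occupancy(seq, {"first": (0, 5), "rest": (5, 10)},
                        alphabet=("a", "b"))
        assert occ.loc["first"].tolist() == [0.6, 0.4]
        assert occ.loc["rest"].tolist() == [1.0, 0.0]

    def test_rows_sum_to_one(self, rng):
        seq = rng.choice(list(STATES6), 500).astype(object)
        occ = occupancy(seq, default_segments(500, frame_rate=1.0),
                        alphabet=STATES6)
        assert np.allclose(occ.sum(axis=1), 1.0)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValidationError):
            occupancy(np.array(["a"], dtype=object), {"bad": (1, 1)})


class TestHabituationRatio:
    def _occ(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2"])

    def test_identical_days_ratio_one(self):
        occ = self._occ([[0.3, 0.7], [0.4, 0.6]])
        assert np.allclose(habituation_ratio(occ, occ.copy()), 1.0)

    def test_hand_geometric_means(self):
        day1 = self._occ([[0.1, 0.9], [0.4, 0.6]])
        day2 = self._occ([[0.2, 0.8], [0.8, 0.2]])
        ratio = habituation_ratio(day1, day2)
        assert ratio["s1"] == pytest.approx(
            np.sqrt(0.2 * 0.8) / np.sqrt(0.1 * 0.4)
        )
        assert ratio["s1"] == pytest.approx(2.0)

    def test_invariant_to_animal_order(self):
        day1 = self._occ([[0.1, 0.9], [0.4, 0.6], [0.2, 0.8]])
        day2 = self._occ([[0.3, 0.7], [0.5, 0.5], [0.1, 0.9]])
        r1 = habituation_ratio(day1, day2)
        r2 = habituation_ratio(day1.iloc[::-1], day2.iloc[[1, 0, 2]])
        assert np.allclose(r1, r2)

    def test_strict_zero_policy_names_offender(self):
        day1 = self._occ([[0.0, 1.0], [0.4, 0.6]])
        with pytest.raises(ValidationError, match="state='s1'"):
            habituation_ratio(day1, day1.copy(), zero_policy="strict")


class TestTransitionMatrix:
    def test_hand_counted_two_state(self):
        tm = transition_matrix(np.array(list("AABBA"), dtype=object))
        assert tm.probs.loc["A", "B"] == 1.0
        assert tm.probs.loc["B", "A"] == 1.0
        assert np.allclose(np.diag(tm.probs), 0.0)

    def test_rows_with_transitions_sum_to_one(self, rng):
        seq = rng.choice(list("abcd"), 400).astype(object)
        tm = transition_matrix(seq)
        sums = tm.probs.sum(axis=1)
        for state in tm.probs.index:
            if state not in tm.silent_states:
                assert sums[state] == pytest.approx(1.0)

    def test_constant_sequence_flagged_empty(self):
        tm = transition_matrix(np.array(["a"] * 5, dtype=object),
                               alphabet=("a", "b"))
        assert tm.empty and "a" in tm.silent_states


class TestGroupTransitionShift:
    def _tm(self, seq):
        return transition_matrix(np.array(list(seq), dtype=object),
                                 alphabet=("A", "B", "C"))

    def _occ(self, seq):
        return occupancy(np.array(list(seq), dtype=object),
                         {"all": (0, len(seq))}, alphabet=("A", "B", "C")).loc["all"]

    def test_identical_days_give_zero_shift(self):
        seqs = ["ABCAB", "BCABC"]
        tms = [self._tm(s) for s in seqs]
        occs = [self._occ(s) for s in seqs]
        shift = group_transition_shift(tms, occs, tms, occs)
        assert np.allclose(shift.fillna(0.0), 0.0)

    def test_single_occupant_dominates_row(self):
        # only mouse 1 ever visits state C
        s1, s2 = "CACB", "ABAB"
        avg = group_average_transitions(
            [self._tm(s1), self._tm(s2)], [self._occ(s1), self._occ(s2)]
        )
        expected = self._tm(s1).probs.loc["C"]
        assert np.allclose(avg.loc["C"], expected)

    def test_antisymmetry(self):
        d1, d2 = ["ABCAB", "BCABC"], ["ACBAC", "CBACB"]
        tm1, oc1 = [self._tm(s) for s in d1], [self._occ(s) for s in d1]
        tm2, oc2 = [self._tm(s) for s in d2], [self._occ(s) for s in d2]
        fwd = group_transition_shift(tm1, oc1, tm2, oc2)
        rev = group_transition_shift(tm2, oc2, tm1, oc1)
        assert np.allclose(fwd.fillna(0.0), -rev.fillna(0.0))


class TestSlidingStateProbability:
    def test_constant_target_gives_one(self):
        seq = np.array(["a"] * 50, dtype=object)
        assert np.allclose(sliding_state_probability(seq, "a", 11), 1.0)

    def test_step_sequence_ramp(self):
        seq = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        out = sliding_state_probability(seq, "a", 5)
        assert np.allclose(out, [1.0, 0.8, 0.6, 0.4, 0.2, 0.0])

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValidationError):
            sliding_state_probability(np.array(["a"] * 5, dtype=object), "a", 6)


class TestOpenFieldMetrics:
    def test_stationary_trace_zero_distance(self):
        m = open_field_metrics(np.full(10, 5.0), np.full(10, 7.0))
        assert m.distance == 0.0

    def test_unit_square_perimeter(self):
        x = np.array([0, 1, 1, 0, 0], float)
        y = np.array([0, 0, 1, 1, 0], float)
        assert open_field_metrics(x, y, margin=0.1).distance == pytest.approx(4.0)

    def test_trace_far_from_borders_is_fully_inner(self):
        x = np.array([200.0, 210.0, 205.0])
        y = np.array([200.0, 195.0, 205.0])
        m = open_field_metrics(x, y, margin=150.0, bounds=(0, 400, 0, 400))
        assert m.inner_fraction == 1.0

    def test_missing_positions_skipped_and_counted(self):
        x = np.array([0.0, np.nan, 2.0])
        y = np.array([0.0, np.nan, 0.0])
        m = open_field_metrics(x, y)
        assert m.n_missing == 1 and m.distance == pytest.approx(2.0)


class TestIlr:
    def test_uniform_composition_maps_to_zero(self):
        comp = np.full(5, 0.2)
        assert np.allclose(ilr_transform(comp), 0.0)

    def test_output_dimension(self):
        comp = np.array([0.1, 0.2, 0.3, 0.4])
        assert ilr_transform(comp).shape == (3,)

    def test_matches_gram_schmidt_oracle_three_parts(self):
        # independent construction: orthonormalize the SBP contrast vectors
        comp = np.array([0.5, 0.3, 0.2])
        contrasts = np.array([[1.0, -0.5, -0.5], [0.0, 1.0, -1.0]]).T
        q, _ = np.linalg.qr(contrasts)
        # fix signs to match the partition convention (first part positive)
        for j in range(q.shape[1]):
            if q[j, j] < 0:
                q[:, j] *= -1
        clr = np.log(comp) - np.log(comp).mean()
        assert np.allclose(ilr_transform(comp), clr @ q)

    def test_isometry_and_inverse_roundtrip(self, rng):
        comp = rng.dirichlet(np.ones(6), size=20)
        coords = ilr_transform(comp)
        clr = np.log(comp) - np.log(comp).mean(axis=1, keepdims=True)
        assert np.allclose(
            np.linalg.norm(coords, axis=1), np.linalg.norm(clr, axis=1)
        )
        assert np.allclose(ilr_inverse(coords), comp, atol=1e-12)

    def test_basis_orthonormal(self):
        for d in (2, 4, 8):
            v = ilr_basis(d)
            assert np.allclose(v.T @ v, np.eye(d - 1), atol=1e-12)
            assert np.allclose(v.sum(axis=0), 0.0, atol=1e-12)

    def test_zero_part_rejected(self):
        with pytest.raises(ValidationError):
            ilr_transform(np.array([0.0, 0.5, 0.5]))


class TestBootstrapLogratioCi:
    def test_zero_variance_groups_give_zero_width(self):
        occ = pd.DataFrame([[0.3, 0.7]] * 4, columns=["s1", "s2"])
        ref = pd.DataFrame([[0.6, 0.4]] * 4, columns=["s1", "s2"])
        ci = bootstrap_logratio_ci(occ, ref, n_boot=200, seed=0)
        assert np.allclose(ci.table["upper"] - ci.table["lower"], 0.0)
        assert ci.table.loc["s1", "point"] == pytest.approx(np.log(0.3 / 0.6))

    def test_fixed_seed_reproducible(self, rng):
        occ = pd.DataFrame(rng.dirichlet(np.ones(3) * 5, 6),
                           columns=["a", "b", "c"])
        ref = pd.DataFrame(rng.dirichlet(np.ones(3) * 5, 6),
                           columns=["a", "b", "c"])
        c1 = bootstrap_logratio_ci(occ, ref, n_boot=500, seed=7)
        c2 = bootstrap_logratio_ci(occ, ref, n_boot=500, seed=7)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_degenerate_group_rejected(self):
        occ = pd.DataFrame([[0.5, 0.5]], columns=["a", "b"])
        with pytest.raises(ValidationError):
            bootstrap_logratio_ci(occ, occ, n_boot=10)


class TestMultivariateGroupTest:
    def test_identical_animals_give_p_one(self):
        coords = np.zeros((8, 2))
        labels = ["g1"] * 4 + ["g2"] * 4
        assert multivariate_group_test(coords, labels, 99, seed=0) == 1.0

    def test_separated_groups_reach_floor(self, rng):
        coords = np.vstack([rng.normal(0, 0.1, (6, 2)),
                            rng.normal(8, 0.1, (6, 2))])
        labels = ["a"] * 6 + ["b"] * 6
        p = multivariate_group_test(coords, labels, 199, seed=1)
        assert p == pytest.approx(1 / 200, abs=1e-9)

    def test_null_type_one_error_calibrated(self, rng):
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            coords = rng.normal(size=(12, 2))
            labels = ["a"] * 6 + ["b"] * 6
            p = multivariate_group_test(coords, labels, 99, seed=rep)
            hits += p <= 0.05
        # binomial 3-sigma band around 0.05
        assert abs(hits / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_ethogram_validation_rejects_unknown_states(seed):
    rng = np.random.default_rng(seed)
    states = rng.choice(list(STATES6) + ["martian"], 20).astype(object)
    if "martian" not in states:
        states[0] = "martian"
    with pytest.raises(ValidationError):
        Ethogram(states, np.zeros(20), np.zeros(20), np.zeros(20))
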