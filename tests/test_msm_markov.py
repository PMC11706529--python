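"""Discretization, transition estimation, propagation, and simulation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortasurv.cohort_model import OutcomeTimes
from aortasurv.msm_markov import (
    ALLOWED_MASK,
    N_STATES,
    STATE_INDEX,
    IntervalCounts,
    NonHomogeneousMCM,
    counts_from_trajectories,
    discretize,
    estimate_transition_matrices,
    propagate_occupancy,
    simulate_cohort,
    validate_transition_matrix,
)

from conftest import random_model

H, C, R, D = (STATE_INDEX[s] for s in "HCRD")


def outcome(censor=36.0, aortic=None, reint=None, death=None):
    return OutcomeTimes(censor_time=censor, aortic_event_time=aortic,
                        reintervention_time=reint, death_time=death)


def identity_model(n_steps=6):
    return NonHomogeneousMCM(6.0, tuple(np.eye(4) for _ in range(n_steps)))


class TestDiscretize:
    def test_event_at_month_seven_lands_in_second_interval(self):
        counts = discretize([outcome(aortic=7.0)])
        # interval 1: H->H; interval 2: H->C; thereafter C->C
        assert counts[0].transitions[H, H] == 1
        assert counts[1].transitions[H, C] == 1
        assert counts[2].transitions[C, C] == 1

    def test_boundary_event_belongs_to_first_interval(self):
        counts = discretize([outcome(aortic=6.0)])
        assert counts[0].transitions[H, C] == 1

    def test_censor_mid_interval_bookkeeping(self):
        counts = discretize([outcome(censor=9.0)])
        assert counts[0].n_at_risk[H] == 1 and counts[0].transitions[H, H] == 1
        assert counts[1].n_at_risk[H] == 1 and counts[1].n_censored[H] == 1
        assert counts[1].transitions.sum() == 0
        assert all(c.n_at_risk.sum() == 0 for c in counts[2:])

    def test_death_within_interval_is_observed_despite_short_followup(self):
        counts = discretize([outcome(censor=8.0, death=8.0)])
        assert counts[1].transitions[H, D] == 1
        # dead patients remain trivially observed in D
        assert counts[2].transitions[D, D] == 1

    def test_worst_state_wins_within_interval(self):
        counts = discretize([outcome(aortic=7.0, reint=11.0)])
        assert counts[1].transitions[H, R] == 1  # straight to R, skipping C

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            discretize([outcome()], 6.0, 20.0)


class TestEstimate:
    def test_stated_arithmetic_example(self):
        c = IntervalCounts(interval=1)
        c.n_at_risk[H] = 100
        c.n_censored[H] = 2
        c.transitions[H, C] = 5
        c.transitions[H, R] = 2
        c.transitions[H, D] = 1
        c.transitions[H, H] = 90
        m = estimate_transition_matrices([c]).matrices[0]
        assert m[H].tolist() == pytest.approx([90 / 98, 5 / 98, 2 / 98, 1 / 98])

    def test_no_events_gives_identity(self):
        c = IntervalCounts(interval=1)
        c.n_at_risk[H] = 10
        c.transitions[H, H] = 10
        assert np.array_equal(estimate_transition_matrices([c]).matrices[0], np.eye(4))

    def test_empty_risk_set_gives_identity_row(self, caplog):
        c = IntervalCounts(interval=1)
        with caplog.at_level("WARNING"):
            m = estimate_transition_matrices([c]).matrices[0]
        assert np.array_equal(m, np.eye(4))
        assert "empty risk set" in caplog.text

    def test_negative_counts_rejected(self):
        c = IntervalCounts(interval=1)
        c.transitions[H, C] = -1
        with pytest.raises(ValueError, match="negative"):
            estimate_transition_matrices([c])

    def test_estimation_of_complete_trajectories_is_exact(self):
        # censoring-free trajectories: estimated cells equal the empirical
        # transition fractions as exact rationals
        trajs = [
            "HHCCRDD", "HHHHHHH", "HCRDDDD", "HHHHCCC",
            "HHHHHHD", "HRRRRDD", "HHHHHHH", "HHHCRRR",
        ]
        counts = counts_from_trajectories([list(t) for t in trajs], 6)
        model = estimate_transition_matrices(counts)
        for k, c in enumerate(counts):
            for i in range(N_STATES):
                n = int(c.n_at_risk[i])
                if n == 0:
                    continue
                for j in range(N_STATES):
                    if ALLOWED_MASK[i, j]:
                        expected = Fraction(int(c.transitions[i, j]), n)
                        assert abs(model.matrices[k][i, j] - float(expected)) < 1e-15

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_estimated_matrices_are_valid(self, seed):
        rng = np.random.default_rng(seed)
        counts = []
        for k in range(1, 4):
            c = IntervalCounts(interval=k)
            for i in range(N_STATES):
                n = int(rng.integers(0, 50))
                c.n_at_risk[i] = n
                cens = int(rng.integers(0, n + 1))
                c.n_censored[i] = cens
                remaining = n - cens
                dests = [j for j in range(N_STATES) if ALLOWED_MASK[i, j]]
                alloc = rng.multinomial(remaining, np.ones(len(dests)) / len(dests))
                for j, a in zip(dests, alloc):
                    c.transitions[i, j] = a
            counts.append(c)
        model = estimate_transition_matrices(counts)
        for m in model.matrices:
            validate_transition_matrix(m)  # row sums, [0,1], structural zeros


class TestPropagate:
    def test_identity_keeps_initial(self):
        occ = propagate_occupancy(identity_model(), [0.7, 0.2, 0.05, 0.05])
        assert np.allclose(occ.probs, np.tile([0.7, 0.2, 0.05, 0.05], (7, 1)))

    def test_single_step_row_readoff(self):
        m = np.array([[0.9, 0.06, 0.03, 0.01], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        occ = propagate_occupancy(NonHomogeneousMCM(6.0, (m,)))
        assert np.allclose(occ.probs[1], [0.9, 0.06, 0.03, 0.01])

    def test_two_steps_equal_hand_product(self):
        rng = np.random.default_rng(8)
        model = random_model(rng, n_steps=2)
        occ = propagate_occupancy(model)
        init = np.array([1.0, 0, 0, 0])
        assert np.allclose(occ.probs[2], init @ model.matrices[0] @ model.matrices[1],
                           atol=1e-15)

    def test_bad_initial_rejected(self):
        with pytest.raises(ValueError, match="length"):
            propagate_occupancy(identity_model(), [1.0, 0.0])
        with pytest.raises(ValueError, match="sum to 1"):
            propagate_occupancy(identity_model(), [0.5, 0.1, 0.1, 0.1])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_and_monotone_absorption(self, seed):
        model = random_model(np.random.default_rng(seed))
        occ = propagate_occupancy(model)
        assert np.allclose(occ.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(occ.probs[:, D]) >= -1e-12)
        assert np.all(np.diff(occ.probs[:, H]) <= 1e-12)


class TestSimulate:
    def test_identity_model_constant_trajectories(self):
        traj, occ = simulate_cohort(identity_model(), 50, seed=0)
        assert np.all(traj == H)
        assert np.allclose(occ.probs[:, H], 1.0)

    def test_forced_death_model(self):
        m = np.zeros((4, 4))
        m[:, D] = 1.0
        m[D, D] = 1.0
        traj, occ = simulate_cohort(NonHomogeneousMCM(6.0, (m, m)), 30, seed=1)
        assert np.all(traj[:, 1:] == D)
        assert occ.probs[1, D] == 1.0

    def test_seeded_reproducibility(self):
        model = random_model(np.random.default_rng(4))
        t1, o1 = simulate_cohort(model, 500, seed=9)
        t2, o2 = simulate_cohort(model, 500, seed=9)
        assert np.array_equal(t1, t2) and np.array_equal(o1.probs, o2.probs)

    def test_occupancy_is_exact_relative_frequency(self):
        model = random_model(np.random.default_rng(5))
        traj, occ = simulate_cohort(model, 200, seed=2)
        for k in range(model.n_steps + 1):
            counts = np.bincount(traj[:, k], minlength=4)
            assert np.array_equal(occ.probs[k], counts / 200)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            simulate_cohort(identity_model(), 0, seed=0)


class TestMatrixValidation:
    def test_disallowed_cell_rejected(self):
        m = np.eye(4)
        m[2, 0] = 0.1
        m[2, 2] = 0.9
        with pytest.raises(ValueError, match="disallowed"):
            validate_transition_matrix(m)

    def test_row_sum_violation_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.9
        with pytest.raises(ValueError, match="sums to"):
            validate_transition_matrix(m)

    def test_csv_roundtrip(self, tmp_path):
        model = random_model(np.random.default_rng(6), n_steps=3)
        path = tmp_path / "matrices.csv"
        model.to_csv(path)
        back = NonHomogeneousMCM.from_csv(path)
        for a, b in zip(model.matrices, back.matrices):
            assert np.allclose(a, b, atol=1e-12)
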