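import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ifcea.markov import (
    CalibrationError,
    TrajectorySpec,
    TransitionMatrix,
    TransitionShape,
    apply_relative_risk,
    calibrate_relative_risk,
    calibrate_transitions,
    prevalence,
    probability_to_rate,
    rate_to_probability,
    simulate_cohort_fractions,
    simulate_individuals,
)

IDENTITY = TransitionMatrix(np.eye(4), arm="id")


@pytest.fixture(scope="module")
def matrix():
    return TransitionMatrix.from_rates([0.15, 0.20, 0.01], [0.30, 0.30, 0.50])


class TestRateConversion:
    def test_zero_rate(self):
        assert rate_to_probability(0.0, 3.0) == 0.0

    def test_closed_form(self):
        assert rate_to_probability(0.5, 0.5) == pytest.approx(1 - np.exp(-0.25), abs=1e-9)
        assert rate_to_probability(0.5, 0.5) == pytest.approx(0.221199, abs=1e-6)

    @given(st.floats(min_value=0.01, max_value=2.0), st.floats(min_value=0.1, max_value=3.0))
    def test_round_trip(self, r, t):
        assert probability_to_rate(rate_to_probability(r, t), t) == pytest.approx(r, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1)
        with pytest.raises(ValueError):
            probability_to_rate(1.0)


class TestTransitionMatrix:
    def test_from_rates_structure(self, matrix):
        p = matrix.p
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        # adjacency restriction: corners are zero
        assert p[0, 2] == p[0, 3] == p[1, 3] == p[3, 0] == p[3, 1] == p[2, 0] == 0.0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=0.6), min_size=3, max_size=3),
        st.lists(st.floats(min_value=0.0, max_value=0.6), min_size=3, max_size=3),
    )
    def test_row_stochastic_for_any_feasible_rates(self, w, r):
        m = TransitionMatrix.from_rates(w, r)
        assert np.allclose(m.p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m.p >= 0)

    def test_invalid_matrices_rejected(self):
        bad = np.full((4, 4), 0.25)
        bad[0, 0] = 0.5  # row sums to 1.25
        with pytest.raises(ValueError):
            TransitionMatrix(bad, adjacency_restricted=False)
        with pytest.raises(ValueError):
            TransitionMatrix(np.full((4, 4), 0.25))  # violates adjacency

    def test_csv_roundtrip(self, matrix, tmp_path):
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        back = TransitionMatrix.from_csv(path)
        assert np.allclose(back.p, matrix.p, atol=1e-12)


class TestRelativeRisk:
    def test_identity_at_rr_one(self, matrix):
        out = apply_relative_risk(matrix, 1.0)
        assert np.allclose(out.p, matrix.p, atol=1e-12)

    def test_zero_rr_removes_worsening(self, matrix):
        out = apply_relative_risk(matrix, 0.0)
        assert out.p[0, 1] == out.p[1, 2] == out.p[2, 3] == 0.0
        assert np.allclose(out.p.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_rate_space_oracle(self, matrix):
        rr = 0.5
        out = apply_relative_risk(matrix, rr)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = 1 - np.exp(-rr * (-np.log(1 - matrix.p[i, j])))
                assert out.p[i, j] == pytest.approx(expected, abs=1e-12)
        # improving transitions untouched
        for i in range(4):
            for j in range(i):
                assert out.p[i, j] == matrix.p[i, j]


class TestProjection:
    def test_identity_matrix_constant(self):
        init = np.array([0.4, 0.3, 0.2, 0.1])
        traj = simulate_cohort_fractions(init, IDENTITY, TrajectorySpec(n_cycles=20))
        assert np.allclose(traj.occupancy, init, atol=1e-15)

    def test_absorbing_healthy_state(self):
        m = TransitionMatrix(
            np.tile([1.0, 0, 0, 0], (4, 1)), adjacency_restricted=False
        )
        traj = simulate_cohort_fractions([0.25, 0.25, 0.25, 0.25], m)
        assert np.allclose(traj.prevalence_series(), 0.0, atol=1e-15)

    def test_matches_loop_oracle(self, matrix):
        init = np.array([0.413, 0.240, 0.336, 0.011])
        traj = simulate_cohort_fractions(init, matrix, TrajectorySpec(n_cycles=20))
        occ = init.copy()
        for t in range(20):
            occ = np.array([sum(occ[i] * matrix.p[i, j] for i in range(4)) for j in range(4)])
            assert np.allclose(traj.occupancy[t], occ, atol=1e-12)

    def test_init_validation(self, matrix):
        with pytest.raises(ValueError):
            simulate_cohort_fractions([0.5, 0.5], matrix)
        with pytest.raises(ValueError):
            simulate_cohort_fractions([0.5, 0.5, 0.5, 0.5], matrix)


class TestMicrosimulation:
    def test_identity_keeps_states(self):
        states = np.array([0, 1, 2, 3] * 25)
        traj = simulate_individuals(states, IDENTITY, TrajectorySpec(n_cycles=5), seed=0)
        assert np.allclose(traj.occupancy, 0.25, atol=1e-12)

    def test_seed_determinism(self, matrix):
        states = np.zeros(500, dtype=int)
        a = simulate_individuals(states, matrix, seed=11)
        b = simulate_individuals(states, matrix, seed=11)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_agrees_with_deterministic_at_20k(self, matrix):
        n = 20_000
        counts = (np.array([0.413, 0.240, 0.336, 0.011]) * n).round().astype(int)
        counts[0] += n - counts.sum()
        states = np.repeat(np.arange(4), counts)
        init = counts / n
        spec = TrajectorySpec(n_cycles=20)
        micro = simulate_individuals(states, matrix, spec, seed=4)
        det = simulate_cohort_fractions(init, matrix, spec)
        se = np.sqrt(det.occupancy * (1 - det.occupancy) / n)
        assert np.all(np.abs(micro.occupancy - det.occupancy) <= 3 * se + 1e-12)

    def test_bad_states_rejected(self, matrix):
        with pytest.raises(ValueError):
            simulate_individuals(np.array([0, 5]), matrix)


class TestPrevalence:
    def test_survey_occupancy(self):
        assert prevalence([0.413, 0.240, 0.336, 0.011]) == pytest.approx(0.587)

    @pytest.mark.parametrize("occ,expected", [([1, 0, 0, 0], 0.0), ([0, 0, 0, 1], 1.0)])
    def test_extremes(self, occ, expected):
        assert prevalence(occ) == expected


class TestCalibration:
    def test_recovers_target_end_prevalence(self):
        cal = calibrate_transitions(0.57, 0.36, 20)
        # oracle: re-project the returned matrix
        init = TransitionShape().init_occupancy(0.57)
        traj = simulate_cohort_fractions(init, cal.matrix, TrajectorySpec(n_cycles=20))
        assert traj.prevalence_series()[-1] == pytest.approx(0.36, abs=1e-4)
        assert cal.converged

    def test_monotone_in_recovery_multiplier(self):
        shape = TransitionShape()
        init = shape.init_occupancy(0.57)
        r = np.asarray(shape.recovery_rates)
        ends = []
        for k in (0.5, 1.0, 2.0, 4.0):
            m = TransitionMatrix.from_rates(shape.worsening_rates, k * r)
            ends.append(simulate_cohort_fractions(init, m).prevalence_series()[-1])
        assert all(a > b for a, b in zip(ends, ends[1:]))

    def test_zero_worsening_stationary_target(self):
        shape = TransitionShape(worsening_rates=(0.0, 0.0, 0.0))
        cal = calibrate_transitions(0.4, 0.4, 20, shape)
        assert cal.multiplier == 0.0
        assert cal.achieved_end_prevalence == pytest.approx(0.4, abs=1e-4)

    def test_unreachable_target_reports_bracket(self):
        with pytest.raises(CalibrationError, match="bracket"):
            # higher than even zero recovery can reach
            calibrate_transitions(0.1, 0.95, 2)

    def test_relative_risk_calibration(self):
        cal = calibrate_transitions(0.57, 0.36, 20)
        init = TransitionShape().init_occupancy(0.59)
        m_ifc, rr = calibrate_relative_risk(cal.matrix, init, 0.27, 20)
        end = simulate_cohort_fractions(init, m_ifc).prevalence_series()[-1]
        assert end == pytest.approx(0.27, abs=1e-4)
        assert 0 < rr < 1


class TestDominance:
    @given(st.floats(min_value=0.05, max_value=0.95))
    def test_lower_worsening_rr_never_worse(self, rr):
        """From a common start, the reduced-worsening arm has lower or
        equal prevalence at every cycle."""
        base = TransitionMatrix.from_rates([0.15, 0.20, 0.01], [0.3, 0.3, 0.5])
        low = apply_relative_risk(base, rr)
        init = np.array([0.413, 0.240, 0.336, 0.011])
        a = simulate_cohort_fractions(init, base).prevalence_series()
        b = simulate_cohort_fractions(init, low).prevalence_series()
        assert np.all(b <= a + 1e-12)
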