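"""Exact model layer: transition rule, sampler, oracle, stationarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinising import (
    ExactDistribution,
    ModelParameters,
    conditional_activation,
    empirical_moments,
    evolve_exact,
    exact_moment_series,
    exact_moments,
    sample_trajectories,
    stationary_joint,
)
from kinising.core_model import enumerate_states, state_index, transition_matrix


class TestConditionalActivation:
    def test_zero_parameters_give_fair_coin(self):
        params = ModelParameters(H=np.zeros(3), J=np.zeros((3, 3)))
        p = conditional_activation(np.array([1, -1, 1]), params)
        assert np.allclose(p, 0.5)

    def test_closed_form_single_coupling(self):
        # h_0 = 1 for the first unit: p = e / (e + 1/e)
        params = ModelParameters(H=np.zeros(2), J=np.array([[0.0, 1.0], [0.0, 0.0]]))
        p = conditional_activation(np.array([1, 1]), params)
        assert p[0] == pytest.approx(np.e / (np.e + np.exp(-1)), abs=1e-12)
        assert p[1] == pytest.approx(0.5, abs=1e-12)

    def test_sign_flip_symmetry(self, small_params):
        prev = np.array([1, -1, -1, 1])
        p = conditional_activation(prev, small_params)
        flipped = ModelParameters(H=-small_params.H, J=small_params.J)
        q = conditional_activation(-prev, flipped)
        assert np.allclose(q, 1 - p, atol=1e-14)

    def test_rejects_bad_input(self, small_params):
        with pytest.raises(ValueError):
            conditional_activation(np.array([1, -1, 0, 1]), small_params)
        with pytest.raises(ValueError):
            conditional_activation(np.ones(3, dtype=np.int8), small_params)


class TestSampler:
    def test_strong_field_pins_spins(self):
        params = ModelParameters(H=np.full(3, 10.0), J=np.zeros((3, 3)))
        ens = sample_trajectories(params, -np.ones(3, dtype=np.int8), T=3, R=10_000, seed=0)
        assert (ens.data[:, 1:, :] == 1).mean() > 0.9999

    def test_deterministic_per_seed(self, small_params):
        s0 = np.ones(4, dtype=np.int8)
        a = sample_trajectories(small_params, s0, T=5, R=20, seed=42)
        b = sample_trajectories(small_params, s0, T=5, R=20, seed=42)
        c = sample_trajectories(small_params, s0, T=5, R=20, seed=43)
        assert (a.data == b.data).all()
        assert (a.data != c.data).any()

    def test_initial_row_is_s0(self, tiny_ensemble):
        assert (tiny_ensemble.data[:, 0, :] == 1).all()

    def test_matches_oracle_moments(self, critical_params_n5):
        """Empirical rates track enumeration within binomial error."""
        params = critical_params_n5
        T, R = 8, 40_000
        s0 = np.ones(5, dtype=np.int8)
        emp = empirical_moments(sample_trajectories(params, s0, T, R, seed=1))
        exact = exact_moment_series(params, ExactDistribution.point_mass(s0), T)
        se = 4.0 / np.sqrt(R)
        assert np.abs(emp.m[1:] - exact.m[1:]).max() < se
        assert np.abs(emp.C[1:] - exact.C[1:]).max() < 2 * se
        assert np.abs(emp.D[1:] - exact.D[1:]).max() < 2 * se


class TestEmpiricalMoments:
    def test_constant_data_has_zero_covariance(self):
        from kinising import TrajectoryEnsemble

        data = np.ones((5, 4, 3), dtype=np.int8)
        series = empirical_moments(TrajectoryEnsemble(data=data))
        assert np.allclose(series.m, 1.0)
        assert np.allclose(series.C, 0.0)
        assert np.allclose(series.D, 0.0)

    def test_fair_coin_data_is_uncorrelated(self, rng):
        from kinising import TrajectoryEnsemble

        R = 20_000
        data = rng.choice([-1, 1], size=(R, 3, 4)).astype(np.int8)
        series = empirical_moments(TrajectoryEnsemble(data=data))
        bound = 5.0 / np.sqrt(R)
        off = ~np.eye(4, dtype=bool)
        assert np.abs(series.m).max() < bound
        assert np.abs(series.C[:, off]).max() < bound
        assert np.abs(series.D[1:]).max() < bound

    def test_single_trial_rejected(self):
        from kinising import TrajectoryEnsemble

        with pytest.raises(ValueError):
            empirical_moments(TrajectoryEnsemble(data=np.ones((1, 3, 2), dtype=np.int8)))


class TestExactEvolution:
    def test_transition_rows_are_normalised(self, small_params):
        M = transition_matrix(small_params)
        assert np.allclose(M.sum(axis=0), 1.0, atol=1e-12)
        assert (M > 0).all()

    def test_factorisation_without_couplings(self):
        H = np.array([0.3, -0.7])
        params = ModelParameters(H=H, J=np.zeros((2, 2)))
        p0 = ExactDistribution.point_mass(np.array([1, -1]))
        p2 = evolve_exact(params, p0, 2)[2]
        expected = ExactDistribution.product(np.tanh(H)).p
        assert np.allclose(p2.p, expected, atol=1e-14)

    def test_two_unit_swap_coupling_by_hand(self):
        # J couples each unit to the other; from (+1, +1) each next spin is
        # independently +1 with probability e / (e + 1/e).
        params = ModelParameters(H=np.zeros(2), J=np.array([[0.0, 1.0], [1.0, 0.0]]))
        p0 = ExactDistribution.point_mass(np.array([1, 1]))
        p1 = evolve_exact(params, p0, 1)[1]
        a = np.e / (np.e + np.exp(-1))
        expected = np.array([(1 - a) ** 2, a * (1 - a), (1 - a) * a, a**2])
        assert np.allclose(p1.p, expected, atol=1e-14)

    def test_normalisation_preserved(self, critical_params_n5):
        p0 = ExactDistribution.point_mass(np.ones(5, dtype=np.int8))
        for p in evolve_exact(critical_params_n5, p0, 10):
            assert abs(p.p.sum() - 1.0) < 1e-12

    def test_size_guard(self):
        params = ModelParameters(H=np.zeros(17), J=np.zeros((17, 17)))
        with pytest.raises(ValueError, match="N <= 16"):
            evolve_exact(params, ExactDistribution(np.full(2**17, 2.0**-17)), 1)


class TestExactMoments:
    def test_no_couplings_no_correlations(self):
        params = ModelParameters(H=np.array([0.2, -0.4, 0.9]), J=np.zeros((3, 3)))
        p_prev = ExactDistribution.product(np.array([0.1, -0.3, 0.5]))
        ms = exact_moments(params, p_prev)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(ms.m, np.tanh(params.H), atol=1e-14)
        assert np.allclose(ms.C[off], 0.0, atol=1e-14)
        assert np.allclose(ms.D, 0.0, atol=1e-14)

    def test_weak_coupling_delayed_covariance(self, small_params):
        """D approaches J_il (1-m_i^2)(1-m_l^2) as couplings shrink."""
        scale = 1e-4
        params = ModelParameters(H=small_params.H, J=scale * small_params.J)
        m_prev = np.array([0.2, -0.1, 0.4, 0.0])
        p_prev = ExactDistribution.product(m_prev)
        ms = exact_moments(params, p_prev)
        lin = params.J * np.outer(1 - ms.m**2, 1 - m_prev**2)
        assert np.abs(ms.D - lin).max() / np.abs(lin).max() < 1e-3

    def test_moment_invariants(self, critical_params_n5):
        p0 = ExactDistribution.point_mass(np.ones(5, dtype=np.int8))
        p_prev = evolve_exact(critical_params_n5, p0, 4)[4]
        ms = exact_moments(critical_params_n5, p_prev)
        assert (np.abs(ms.m) <= 1).all()
        assert np.allclose(ms.C, ms.C.T, atol=1e-12)
        assert np.allclose(np.diag(ms.C), 1 - ms.m**2, atol=1e-12)
        bound = np.sqrt(np.outer(1 - ms.m**2, 1 - ms.m**2))
        assert (np.abs(ms.C) <= bound + 1e-12).all()
        assert (np.abs(ms.D) <= 1).all()


class TestStationaryJoint:
    def test_field_only_stationary_state(self):
        H = np.array([0.5, -0.2, 0.1])
        params = ModelParameters(H=H, J=np.zeros((3, 3)))
        pi, _ = stationary_joint(params)
        assert np.allclose(pi.p, ExactDistribution.product(np.tanh(H)).p, atol=1e-10)

    def test_fixed_point_and_eigenvector(self):
        from kinising import SKEnsembleSpec, sample_sk

        params = sample_sk(SKEnsembleSpec(N=5), seed=21)
        pi, joint = stationary_joint(params, tol=1e-14)
        # left fixed by one further exact step
        step = evolve_exact(params, pi, 1)[1]
        assert np.abs(step.p - pi.p).sum() < 1e-12
        # agrees with the leading eigenvector of the transition matrix
        M = transition_matrix(params)
        w, v = np.linalg.eig(M)
        lead = np.real(v[:, np.argmax(np.real(w))])
        lead = np.abs(lead) / np.abs(lead).sum()
        assert np.abs(pi.p - lead).max() < 1e-10
        # joint marginalises correctly
        assert np.allclose(joint.sum(axis=0), pi.p, atol=1e-12)
        assert np.allclose(joint.sum(axis=1), pi.p, atol=1e-10)

    def test_detailed_balance_symmetric_couplings(self):
        rng = np.random.default_rng(8)
        A = rng.normal(0, 0.3, (4, 4))
        params = ModelParameters(H=rng.normal(0, 0.2, 4), J=(A + A.T) / 2)
        pi, _ = stationary_joint(params, tol=1e-14)
        ms = exact_moments(params, pi)
        assert np.abs(ms.D - ms.D.T).max() < 1e-9


class TestStateEncoding:
    @given(st.integers(min_value=1, max_value=8))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_enumeration_roundtrip(self, N):
        S = enumerate_states(N)
        assert S.shape == (2**N, N)
        for idx in (0, 2**N - 1, 2 ** (N - 1)):
            assert state_index(S[idx]) == idx

    def test_little_endian_convention(self):
        S = enumerate_states(3)
        assert (S[1] == [1, -1, -1]).all()  # bit 0 set -> unit 0 up
        assert (S[4] == [-1, -1, 1]).all()


def test_transition_probabilities_sum_to_one_exhaustive():
    """Chapman-Kolmogorov sanity: each previous state emits a distribution."""
    from kinising import SKEnsembleSpec, sample_sk

    for N in (2, 4, 6, 8):
        params = sample_sk(SKEnsembleSpec(N=N, beta=1.2), seed=N)
        M = transition_matrix(params)
        assert np.allclose(M.sum(axis=0), 1.0, atol=1e-12)
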