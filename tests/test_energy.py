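"""Minimum-control-energy solver: closed forms, oracle agreement, invariances."""

import numpy as np
import pytest
from scipy.linalg import expm, solve_lyapunov

from brainctl import synth
from brainctl.energy import (
    build_control_matrix,
    controllability_gramian,
    min_transition_energy,
    normalize_connectome,
    oracle_discretized_energy,
    transition_energy_matrix,
)

SCALAR_E = 2.0 / (1.0 - np.exp(-2.0))  # A=-1, B=1, 0 -> 1 over T=1


def random_stable_system(n, rng):
    A = synth.gen_connectome(n, seed=int(rng.integers(2**31)))
    return normalize_connectome(A).A_norm


class TestNormalizeConnectome:
    def test_zero_matrix_maps_to_minus_identity(self):
        sm = normalize_connectome(np.zeros((4, 4)))
        assert np.allclose(sm.A_norm, -np.eye(4))

    def test_hand_computed_3x3(self):
        # symmetric ring: eigenvalues of A are {2, -1, -1}; lambda_max = 2
        A = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        sm = normalize_connectome(A)
        assert np.allclose(sm.A_norm, A / 3.0 - np.eye(3))
        assert sm.spectral_radius == pytest.approx(2.0)

    def test_always_stable(self, rng):
        for _ in range(5):
            A_norm = random_stable_system(8, rng)
            assert np.linalg.eigvalsh(0.5 * (A_norm + A_norm.T)).max() < 0

    @pytest.mark.parametrize(
        "bad",
        [np.array([[0.0, 1], [2, 0]]), np.array([[0.0, -1], [-1, 0]]), np.ones((2, 2))],
        ids=["asymmetric", "negative", "nonzero-diagonal"],
    )
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValueError):
            normalize_connectome(bad)


class TestControlMatrix:
    def test_uniform_is_identity(self):
        cm = build_control_matrix(n_regions=5)
        assert np.array_equal(cm.B, np.eye(5))

    def test_minmax_forces_1_to_2(self):
        cm = build_control_matrix(np.array([0.0, 5.0, 10.0]))
        assert np.allclose(cm.diag, [1.0, 1.5, 2.0])

    def test_bounds_for_arbitrary_nonnegative_maps(self, rng):
        for _ in range(20):
            v = rng.gamma(2.0, 2.0, size=30)
            d = build_control_matrix(v).diag
            assert d.min() >= 1.0 and d.max() <= 2.0
            assert d.min() == pytest.approx(1.0) and d.max() == pytest.approx(2.0)

    def test_rejects_negative_and_constant_maps(self):
        with pytest.raises(ValueError):
            build_control_matrix(np.array([-1.0, 2.0]))
        with pytest.raises(ValueError, match="constant"):
            build_control_matrix(np.full(5, 3.0))


class TestGramian:
    def test_scalar_closed_form(self):
        W = controllability_gramian(np.array([[-1.0]]), np.array([[1.0]]), 1.0)
        assert W[0, 0] == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-12)

    def test_zero_input_matrix(self):
        W = controllability_gramian(-np.eye(3), np.zeros((3, 3)), 1.0)
        assert np.allclose(W, 0.0)

    def test_long_horizon_approaches_lyapunov_solution(self, rng):
        A_norm = random_stable_system(5, rng)
        W_inf = solve_lyapunov(A_norm, -np.eye(5))
        W = controllability_gramian(A_norm, np.eye(5), 200.0)
        assert np.allclose(W, W_inf, atol=1e-6)


class TestMinTransitionEnergy:
    def test_scalar_closed_form(self):
        E = min_transition_energy(np.array([[-1.0]]), np.array([[1.0]]), [0.0], [1.0], T=1.0)
        assert E == pytest.approx(SCALAR_E, abs=1e-9)

    def test_zero_to_zero_costs_nothing(self, rng):
        A_norm = random_stable_system(4, rng)
        E = min_transition_energy(A_norm, np.eye(4), np.zeros(4), np.zeros(4))
        assert E == pytest.approx(0.0, abs=1e-12)

    def test_scaling_B_divides_energy_by_s_squared(self, rng):
        A_norm = random_stable_system(5, rng)
        x0, xT = rng.standard_normal(5), rng.standard_normal(5)
        E1 = min_transition_energy(A_norm, np.eye(5), x0, xT)
        E3 = min_transition_energy(A_norm, 3.0 * np.eye(5), x0, xT)
        assert E3 == pytest.approx(E1 / 9.0, rel=1e-9)

    def test_energy_quadratic_in_target_gap(self, rng):
        # doubling v = xT - e^{AT} x0 quadruples the energy
        A_norm = random_stable_system(5, rng)
        eAT = expm(A_norm)
        x0 = rng.standard_normal(5)
        v = rng.standard_normal(5)
        E1 = min_transition_energy(A_norm, np.eye(5), x0, eAT @ x0 + v)
        E2 = min_transition_energy(A_norm, np.eye(5), x0, eAT @ x0 + 2 * v)
        assert E2 == pytest.approx(4 * E1, rel=1e-9)

    def test_matches_discretized_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(2, 9))
            A_norm = random_stable_system(n, rng)
            B = np.diag(1.0 + rng.random(n))
            x0, xT = rng.standard_normal(n), rng.standard_normal(n)
            E = min_transition_energy(A_norm, B, x0, xT)
            Eo = oracle_discretized_energy(A_norm, B, x0, xT, n_steps=2000)
            assert Eo == pytest.approx(E, rel=0.01)


class TestTransitionEnergyMatrix:
    def test_zero_centroids_give_zero_matrix(self, rng):
        A_norm = random_stable_system(4, rng)
        te = transition_energy_matrix(A_norm, np.eye(4), np.zeros((3, 4)))
        assert np.allclose(te.E, 0.0)

    def test_shape_and_asymmetry(self, rng):
        A_norm = random_stable_system(6, rng)
        C = rng.standard_normal((4, 6))
        te = transition_energy_matrix(A_norm, np.eye(6), C)
        assert te.E.shape == (4, 4)
        assert np.all(te.E >= 0)
        assert not np.allclose(te.E, te.E.T)  # direction matters

    def test_matches_pairwise_solver(self, rng):
        A_norm = random_stable_system(5, rng)
        C = rng.standard_normal((3, 5))
        te = transition_energy_matrix(A_norm, np.eye(5), C)
        for i in range(3):
            for j in range(3):
                E = min_transition_energy(A_norm, np.eye(5), C[i], C[j])
                assert te.E[i, j] == pytest.approx(E, rel=1e-9)

    def test_amplitude_scaling_is_quadratic(self, rng):
        A_norm = random_stable_system(5, rng)
        C = rng.standard_normal((4, 5))
        E1 = transition_energy_matrix(A_norm, np.eye(5), C).E
        E07 = transition_energy_matrix(A_norm, np.eye(5), 0.7 * C).E
        assert np.allclose(E07, 0.49 * E1, rtol=1e-9)

    def test_missing_states_propagate_as_nan(self, rng):
        A_norm = random_stable_system(4, rng)
        C = rng.standard_normal((3, 4))
        te = transition_energy_matrix(
            A_norm, np.eye(4), C, missing=np.array([False, True, False])
        )
        assert np.isnan(te.E[1]).all() and np.isnan(te.E[:, 1]).all()
        assert np.isfinite(te.E[0, 2])

    def test_permutation_equivariance(self, rng):
        A = synth.gen_connectome(6, seed=0)
        perm = rng.permutation(6)
        C = rng.standard_normal((3, 6))
        E1 = transition_energy_matrix(normalize_connectome(A).A_norm, np.eye(6), C).E
        E2 = transition_energy_matrix(
            normalize_connectome(A[np.ix_(perm, perm)]).A_norm, np.eye(6), C[:, perm]
        ).E
        assert np.allclose(E1, E2, rtol=1e-8)


class TestControlWeightMonotonicity:
    def test_larger_B_never_costs_more(self, rng):
        """If B2 B2' - B1 B1' is PSD, every transition energy drops (or ties)."""
        for _ in range(10):
            n = int(rng.integers(3, 8))
            A_norm = random_stable_system(n, rng)
            d1 = 1.0 + rng.random(n)
            d2 = d1 + rng.random(n)  # elementwise larger diagonal
            C = rng.standard_normal((3, n))
            E1 = transition_energy_matrix(A_norm, np.diag(d1), C).E
            E2 = transition_energy_matrix(A_norm, np.diag(d2), C).E
            assert np.all(E2 <= E1 + 1e-10)

    def test_receptor_weighted_below_uniform(self, rng):
        A_norm = random_stable_system(10, rng)
        C = rng.standard_normal((4, 10))
        B_rec = build_control_matrix(rng.gamma(2.0, 1.0, 10)).B
        E_uni = transition_energy_matrix(A_norm, np.eye(10), C).E
        E_rec = transition_energy_matrix(A_norm, B_rec, C).E
        assert np.all(E_rec <= E_uni + 1e-10)


class TestHorizonSensitivity:
    def test_entry_ordering_stable_across_T(self, rng):
        """Qualitative ordering of transition energies holds for T in {0.5,1,3,5}."""
        A_norm = random_stable_system(8, rng)
        C = synth.gen_state_centroids(8, 4, seed=2)
        energies = [
            transition_energy_matrix(A_norm, np.eye(8), C, T=T).E.ravel()
            for T in (0.5, 1.0, 3.0, 5.0)
        ]
        from scipy.stats import spearmanr

        # adjacent horizons agree strongly; even the extremes stay concordant
        for e1, e2 in zip(energies[:-1], energies[1:]):
            assert spearmanr(e1, e2).statistic > 0.75
        for e in energies[1:]:
            assert spearmanr(energies[0], e).statistic > 0.5
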