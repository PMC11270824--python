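"""Wavefunction propagation: unitarity, oracles, two-exciton algebra."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import cg2des as cg
from cg2des.propagation import (
    build_two_exciton_basis,
    cumulative_propagators,
    propagate_one,
    propagate_two,
    step_unitaries,
    transition_dipole_ef,
    two_exciton_hamiltonian,
)
from cg2des.units import TWO_PI_C


@pytest.fixture(scope="module")
def noisy_dimer_traj(dimer_single):
    return cg.generate_ou_trajectory(
        dimer_single.bath, dimer_single.means, 260, 2.0, seed=21
    )


class TestOneExciton:
    def test_decoupled_sites_accumulate_pure_phases(self, dimer_single):
        traj = cg.generate_ou_trajectory(
            dimer_single.bath, dimer_single.means, 65, 2.0, seed=2
        )
        J0 = cg.CouplingMatrix(np.zeros((2, 2)))
        U = propagate_one(traj, J0, dimer_single.segmentation, 0, 0, 64).U
        phases = np.exp(-1j * TWO_PI_C * 2.0 * traj.energies[:64].sum(axis=0))
        assert np.allclose(U, np.diag(phases), atol=1e-10)

    def test_static_dimer_matches_dense_exponential(
        self, dimer_single, static_dimer_traj
    ):
        U = propagate_one(
            static_dimer_traj, dimer_single.J, dimer_single.segmentation, 0, 0, 128
        ).U
        H = np.array([[11500.0, 100.0], [100.0, 12000.0]])
        assert np.abs(U - expm(-1j * TWO_PI_C * H * 256.0)).max() < 1e-10

    def test_unitarity_over_coherence_window(self, dimer_single, noisy_dimer_traj):
        U = propagate_one(
            noisy_dimer_traj, dimer_single.J, dimer_single.segmentation, 0, 0, 128
        ).U
        assert np.abs(U @ U.conj().T - np.eye(2)).max() < 1e-8

    def test_composition_property(self, dimer_single, noisy_dimer_traj):
        args = (noisy_dimer_traj, dimer_single.J, dimer_single.segmentation, 0)
        U_ac = propagate_one(*args, 0, 100).U
        U_ab = propagate_one(*args, 0, 40).U
        U_bc = propagate_one(*args, 40, 100).U
        assert np.abs(U_ac - U_bc @ U_ab).max() < 1e-12

    def test_zero_steps_is_identity(self, dimer_single, noisy_dimer_traj):
        U = propagate_one(
            noisy_dimer_traj, dimer_single.J, dimer_single.segmentation, 0, 10, 10
        ).U
        assert np.array_equal(U, np.eye(2))

    def test_frames_out_of_range_rejected(self, dimer_single, noisy_dimer_traj):
        with pytest.raises(ValueError):
            propagate_one(
                noisy_dimer_traj, dimer_single.J, dimer_single.segmentation,
                0, 0, 10_000,
            )

    def test_trotter_is_second_order(self, dimer_single):
        """Halving the step reduces the splitting error by about 4x."""
        H = np.array([[11500.0, 100.0], [100.0, 12000.0]])
        ref = expm(-1j * TWO_PI_C * H * 256.0)
        errs = []
        for dt, n in [(2.0, 128), (1.0, 256)]:
            eps = np.tile(H.diagonal(), (n, 1))
            U = cumulative_propagators(
                step_unitaries(eps, dimer_single.J.J, dt, method="trotter")
            )[-1]
            errs.append(np.abs(U - ref).max())
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)


class TestTwoExcitonBasis:
    @pytest.mark.parametrize(
        "n, mode, dim",
        [(2, "strict", 1), (2, "bosonic", 3), (27, "strict", 351), (3, "bosonic", 6)],
    )
    def test_dimension_formula(self, n, mode, dim):
        assert build_two_exciton_basis(n, mode).dimension == dim

    def test_single_site_edge_cases(self):
        with pytest.raises(ValueError):
            build_two_exciton_basis(0, "strict")
        assert build_two_exciton_basis(1, "strict").dimension == 0
        assert build_two_exciton_basis(1, "bosonic").dimension == 1

    def test_ordering_is_deterministic_lexicographic(self):
        basis = build_two_exciton_basis(3, "strict")
        assert [tuple(p) for p in basis.pairs] == [(0, 1), (0, 2), (1, 2)]


class TestTwoExcitonHamiltonian:
    def test_static_dimer_pair_energy(self):
        basis = build_two_exciton_basis(2, "strict")
        H = two_exciton_hamiltonian(
            np.array([11500.0, 12000.0]), np.zeros((2, 2)), basis
        )
        assert np.allclose(H, [[23500.0]])

    def test_zero_coupling_gives_diagonal_pair_sums(self):
        basis = build_two_exciton_basis(4, "strict")
        eps = np.array([1.0, 2.0, 4.0, 8.0])
        H = two_exciton_hamiltonian(eps, np.zeros((4, 4)), basis)
        expected = [eps[m] + eps[n] for m, n in basis.pairs]
        assert np.allclose(H, np.diag(expected))

    def test_matches_hard_core_fock_space_construction(self):
        """Oracle: restrict the full 2^N-state Hamiltonian of hard-core
        two-level sites to the doubly excited subspace."""
        rng = np.random.default_rng(0)
        N = 3
        eps = rng.uniform(11_000, 13_000, N)
        J = rng.uniform(-200, 200, (N, N))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0.0)
        states = list(itertools.product([0, 1], repeat=N))
        idx = {s: i for i, s in enumerate(states)}
        Hfull = np.zeros((2**N, 2**N))
        for s in states:
            i = idx[s]
            Hfull[i, i] = sum(e * o for e, o in zip(eps, s))
            for a in range(N):
                for b in range(N):
                    if a != b and s[a] == 1 and s[b] == 0:
                        t = list(s)
                        t[a], t[b] = 0, 1
                        Hfull[idx[tuple(t)], i] += J[b, a]
        basis = build_two_exciton_basis(N, "strict")
        vecs = []
        for m, n in basis.pairs:
            s = [0] * N
            s[m] = s[n] = 1
            vecs.append(idx[tuple(s)])
        assert np.allclose(
            two_exciton_hamiltonian(eps, J, basis), Hfull[np.ix_(vecs, vecs)]
        )

    def test_bosonic_mode_couples_double_occupancy_with_sqrt2(self):
        basis = build_two_exciton_basis(2, "bosonic", anharmonicity=-100.0)
        eps = np.array([10.0, 20.0])
        J = np.array([[0.0, 5.0], [5.0, 0.0]])
        H = two_exciton_hamiltonian(eps, J, basis)
        # basis order (0,0), (0,1), (1,1)
        assert H[0, 0] == pytest.approx(2 * 10.0 - 100.0)
        assert H[2, 2] == pytest.approx(2 * 20.0 - 100.0)
        assert H[0, 1] == pytest.approx(np.sqrt(2) * 5.0)
        assert H[1, 2] == pytest.approx(np.sqrt(2) * 5.0)
        assert H[0, 2] == 0.0


class TestTwoExcitonPropagation:
    def test_dimer_pair_state_accumulates_sum_phase(self, dimer_single):
        traj = cg.generate_ou_trajectory(
            dimer_single.bath, dimer_single.means, 129, 2.0, seed=3
        )
        basis = build_two_exciton_basis(2, "strict")
        U = propagate_two(
            traj, dimer_single.J, dimer_single.segmentation, 0, basis, 0, 128
        ).U
        phase = np.exp(-1j * TWO_PI_C * 2.0 * traj.energies[:128].sum())
        assert abs(U[0, 0] - phase) < 1e-10

    def test_unitarity(self, dimer_single, noisy_dimer_traj):
        basis = build_two_exciton_basis(2, "bosonic")
        U = propagate_two(
            noisy_dimer_traj, dimer_single.J, dimer_single.segmentation,
            0, basis, 0, 128,
        ).U
        assert np.abs(U @ U.conj().T - np.eye(3)).max() < 1e-8

    def test_trotter_agrees_with_dense_path(self):
        rng = np.random.default_rng(9)
        N = 3
        means = rng.uniform(11_500, 12_500, N)
        J = rng.uniform(-80, 80, (N, N))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0.0)
        system = cg.SystemModel(
            means=means,
            bath=cg.BathParams([150.0] * N, [200.0] * N),
            J=cg.CouplingMatrix(J),
            dipoles=cg.DipoleSet(np.ones((N, 3))),
            segmentation=cg.Segmentation([0] * N),
            temperature=None,
        )
        traj = cg.generate_ou_trajectory(system.bath, means, 257, 0.03125, seed=5)
        basis = build_two_exciton_basis(N, "strict")
        args = (traj, system.J, system.segmentation, 0, basis, 0, 256)
        dense = propagate_two(*args, method="dense").U
        trotter = propagate_two(*args, method="trotter").U
        # second-order splitting error, negligible at a fine step
        assert np.abs(dense - trotter).max() < 1e-6


class TestTransitionDipoles:
    def test_dimer_strict_swaps_site_dipoles(self):
        mu = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        basis = build_two_exciton_basis(2, "strict")
        A = transition_dipole_ef(mu, basis)
        assert np.allclose(A[0, 0], mu[1])  # from e on site 0 -> add site 1
        assert np.allclose(A[0, 1], mu[0])

    def test_zero_dipoles_give_zero_matrix(self):
        basis = build_two_exciton_basis(3, "strict")
        assert not transition_dipole_ef(np.zeros((3, 3)), basis).any()

    def test_matches_operator_algebra_oracle(self):
        """Oracle: apply sum_n mu_n (B_n^+ + B_n) between explicit
        hard-core Fock manifolds."""
        rng = np.random.default_rng(1)
        N = 3
        mu = rng.uniform(-1, 1, (N, 3))
        basis = build_two_exciton_basis(N, "strict")
        states = list(itertools.product([0, 1], repeat=N))
        idx = {s: i for i, s in enumerate(states)}
        singles = [
            idx[tuple(1 if k == a else 0 for k in range(N))] for a in range(N)
        ]
        doubles = []
        for m, n in basis.pairs:
            s = [0] * N
            s[m] = s[n] = 1
            doubles.append(idx[tuple(s)])
        A = transition_dipole_ef(mu, basis)
        for x in range(3):
            M = np.zeros((2**N, 2**N))
            for a in range(N):
                for s in states:
                    t = list(s)
                    t[a] = 1 - s[a]
                    M[idx[tuple(t)], idx[s]] += mu[a, x]
            assert np.allclose(A[:, :, x], M[np.ix_(doubles, singles)])

    def test_bosonic_mode_double_occupancy_factor(self):
        mu = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        basis = build_two_exciton_basis(2, "bosonic")
        A = transition_dipole_ef(mu, basis)
        assert np.allclose(A[0, 0], np.sqrt(2) * mu[0])  # (0,0) from e=0
        assert not A[0, 1].any()
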