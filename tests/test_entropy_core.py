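import numpy as np
import pytest
import scipy.linalg

import h2rs
from h2rs.alphabet import pair_code, swap_pair_permutation
from h2rs.errors import MatrixValidationError


def dist_from_pairs(pairs_probs):
    """ColumnPairDistribution from {(aa, aa): prob}."""
    p = np.zeros(400)
    for (a, b), prob in pairs_probs.items():
        p[pair_code(a, b)] = prob
    return h2rs.ColumnPairDistribution(k=1, l=2, p=p, n_valid=100)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.5], np.log(2)),
            (np.full(20, 0.05), np.log(20)),
        ],
    )
    def test_analytic_values(self, p, expected):
        assert h2rs.shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            h2rs.shannon_entropy([0.5, 0.6])


class TestUShannon:
    def test_perfect_two_state_correlation(self):
        dist = dist_from_pairs({("A", "A"): 0.5, ("C", "C"): 0.5})
        assert h2rs.u_shannon(dist) == pytest.approx(1.0)

    def test_independent_columns(self):
        dist = dist_from_pairs({
            ("A", "A"): 0.25, ("A", "C"): 0.25,
            ("C", "A"): 0.25, ("C", "C"): 0.25,
        })
        assert h2rs.u_shannon(dist) == pytest.approx(0.0, abs=1e-12)

    def test_conserved_pair_is_zero_by_convention(self):
        assert h2rs.u_shannon(dist_from_pairs({("A", "A"): 1.0})) == 0.0


class TestDensityMatrix:
    def test_identity_similarity_gives_diagonal(self, rng, identity_matrix):
        dist = h2rs.random_pair_distribution(rng)
        rho = h2rs.density_matrix(dist, identity_matrix)
        assert np.allclose(rho.matrix, np.diag(dist.p))

    def test_trace_is_one(self, rng, example_matrix):
        for _ in range(5):
            dist = h2rs.random_pair_distribution(rng)
            rho = h2rs.density_matrix(dist, example_matrix)
            assert np.trace(rho.matrix) == pytest.approx(1.0, abs=1e-10)

    def test_concentrated_distribution_is_pure_state(self, example_matrix):
        dist = dist_from_pairs({("W", "Y"): 1.0})
        rho = h2rs.density_matrix(dist, example_matrix)
        i = pair_code("W", "Y")
        assert rho.matrix[i, i] == 1.0
        assert np.count_nonzero(rho.matrix) == 1


class TestPartialTrace:
    def test_diagonal_case_reduces_to_marginals(self, rng, identity_matrix):
        dist = h2rs.random_pair_distribution(rng)
        rho = h2rs.density_matrix(dist, identity_matrix)
        pk, pl = dist.marginals()
        assert np.allclose(h2rs.partial_trace(rho, "first").matrix, np.diag(pk))
        assert np.allclose(h2rs.partial_trace(rho, "second").matrix, np.diag(pl))

    def test_traces_are_one(self, rng, example_matrix):
        dist = h2rs.random_pair_distribution(rng)
        rho = h2rs.density_matrix(dist, example_matrix)
        for position in ("first", "second"):
            marg = h2rs.partial_trace(rho, position)
            assert np.trace(marg.matrix) == pytest.approx(1.0, abs=1e-10)

    def test_two_state_block_by_hand(self, example_matrix):
        # support {(A,A), (C,A)}: both states share the second residue A,
        # so the first-position marginal carries the off-diagonal coupling
        p1, p2 = 0.7, 0.3
        dist = dist_from_pairs({("A", "A"): p1, ("C", "A"): p2})
        a = example_matrix.values[pair_code("A", "A"), pair_code("C", "A")]
        rho = h2rs.density_matrix(dist, example_matrix)
        s = h2rs.partial_trace(rho, "first").matrix
        iA, iC = 0, 1
        assert s[iA, iA] == pytest.approx(p1)
        assert s[iC, iC] == pytest.approx(p2)
        assert s[iA, iC] == pytest.approx(np.sqrt(p1 * p2) * a)
        # second-position marginal: both states have residue A -> pure
        t = h2rs.partial_trace(rho, "second").matrix
        assert t[iA, iA] == pytest.approx(1.0)


class TestVonNeumannEntropy:
    def test_diagonal_equals_shannon(self, rng, identity_matrix):
        dist = h2rs.random_pair_distribution(rng)
        rho = h2rs.density_matrix(dist, identity_matrix)
        assert h2rs.von_neumann_entropy(rho) == pytest.approx(
            h2rs.shannon_entropy(dist.p), abs=1e-10
        )

    def test_pure_state_is_zero(self, example_matrix):
        dist = dist_from_pairs({("H", "K"): 1.0})
        rho = h2rs.density_matrix(dist, example_matrix)
        assert h2rs.von_neumann_entropy(rho) == pytest.approx(0.0, abs=1e-12)

    def test_against_independent_eigensolver(self, rng, example_matrix):
        dist = h2rs.random_pair_distribution(rng)
        rho = h2rs.density_matrix(dist, example_matrix)
        lam = scipy.linalg.eigh(rho.matrix, eigvals_only=True)
        lam = np.clip(lam, 0, 1)
        expected = -np.sum(lam[lam > 0] * np.log(lam[lam > 0]))
        assert h2rs.von_neumann_entropy(rho) == pytest.approx(expected, abs=1e-10)

    def test_invalid_density_rejected(self):
        bad = np.zeros((400, 400))
        bad[0, 0], bad[1, 1] = 1.5, -0.5
        with pytest.raises(MatrixValidationError):
            h2rs.von_neumann_entropy(h2rs.DensityMatrix(bad))


class TestUvne:
    def test_identity_matches_shannon_ratio(self, rng, identity_matrix):
        for _ in range(20):
            dist = h2rs.random_pair_distribution(rng)
            rep = h2rs.u_vne(dist, identity_matrix)
            denom = rep.h_k + rep.h_l
            ratio = 0.0 if denom == 0 else (denom - rep.h_kl) / denom
            assert rep.u_vne == pytest.approx(ratio, abs=1e-9)
            assert rep.vne_kl == pytest.approx(rep.h_kl, abs=1e-9)

    def test_independent_columns_score_zero(self, identity_matrix):
        dist = dist_from_pairs({
            ("A", "A"): 0.25, ("A", "C"): 0.25,
            ("C", "A"): 0.25, ("C", "C"): 0.25,
        })
        assert h2rs.u_vne(dist, identity_matrix).u_vne == pytest.approx(0.0, abs=1e-12)

    def test_against_step_by_step_oracle(self, rng, example_matrix):
        """Replay the full pipeline independently: build the 400x400
        density matrix, take partial traces with explicit loops, and
        eigendecompose with a separately-called solver."""
        dist = h2rs.random_pair_distribution(rng)
        A = example_matrix.values
        sp = np.sqrt(dist.p)
        rho = np.outer(sp, sp) * A

        def vne(m):
            lam = np.clip(scipy.linalg.eigh(m, eigvals_only=True), 0, 1)
            lam = lam[lam > 0]
            return -np.sum(lam * np.log(lam))

        s = np.zeros((20, 20))
        t = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                for u in range(20):
                    s[i, j] += rho[20 * i + u, 20 * j + u]
                    t[i, j] += rho[20 * u + i, 20 * u + j]
        expected = (vne(s) + vne(t) - vne(rho)) / (vne(s) + vne(t))
        got = h2rs.u_vne(dist, example_matrix).u_vne
        assert got == pytest.approx(expected, abs=1e-9)

    def test_bounds_over_random_fixtures(self, rng, example_matrix):
        for _ in range(50):
            dist = h2rs.random_pair_distribution(rng)
            u = h2rs.u_vne(dist, example_matrix).u_vne
            assert 0.0 <= u <= 1.0 + 1e-9

    def test_swap_symmetry(self, rng, example_matrix):
        perm = swap_pair_permutation()
        for _ in range(5):
            dist = h2rs.random_pair_distribution(rng)
            swapped = h2rs.ColumnPairDistribution(
                k=2, l=1, p=dist.p[perm], n_valid=dist.n_valid
            )
            a_perm = example_matrix.permuted(perm)
            assert h2rs.u_vne(swapped, a_perm).u_vne == pytest.approx(
                h2rs.u_vne(dist, example_matrix).u_vne, abs=1e-10
            )


class TestRenyiEntropy:
    def test_two_state_alpha_two(self, identity_matrix):
        dist = dist_from_pairs({("A", "A"): 0.5, ("C", "C"): 0.5})
        rho = h2rs.density_matrix(dist, identity_matrix)
        assert h2rs.renyi_entropy(rho, 2) == pytest.approx(np.log(2), abs=1e-12)

    def test_alpha_near_one_approaches_vne(self, rng, example_matrix):
        for _ in range(10):
            dist = h2rs.random_pair_distribution(rng)
            rho = h2rs.density_matrix(dist, example_matrix)
            diff = abs(h2rs.renyi_entropy(rho, 1.001) - h2rs.von_neumann_entropy(rho))
            assert diff <= 1e-2

    def test_pure_state_is_zero(self, example_matrix):
        dist = dist_from_pairs({("D", "E"): 1.0})
        rho = h2rs.density_matrix(dist, example_matrix)
        for alpha in (0.5, 2, 3):
            assert h2rs.renyi_entropy(rho, alpha) == pytest.approx(0.0, abs=1e-10)

    def test_trace_path_equals_eigen_path(self, rng, example_matrix):
        dist = h2rs.random_pair_distribution(rng)
        rho = h2rs.density_matrix(dist, example_matrix)
        lam = np.clip(rho.eigenvalues, 0, 1)
        via_eigs = -np.log(np.sum(lam**2))
        assert h2rs.renyi_entropy(rho, 2) == pytest.approx(via_eigs, abs=1e-10)

    def test_alpha_one_rejected(self, identity_matrix):
        dist = dist_from_pairs({("A", "A"): 0.5, ("C", "C"): 0.5})
        rho = h2rs.density_matrix(dist, identity_matrix)
        with pytest.raises(ValueError):
            h2rs.renyi_entropy(rho, 1)
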