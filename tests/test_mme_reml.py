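"""Mixed-model equations and AI-REML against closed-form/GLS oracles."""

import numpy as np
import pytest

from nucleusgs import (
    a_inverse,
    a_matrix,
    genomic_relationship,
    h_inverse,
    reml_varcomp,
    solve_mme,
)

from conftest import random_pedigree


def gls_oracle(y, X, Z, K, lam):
    """Dense generalized-least-squares solution of the animal model.

    V = Z K Z' + lam^-1-free parametrisation: use sigma_a2 = 1, sigma_e2 = lam.
    """
    n_animals = K.shape[0]
    V = Z @ K @ Z.T + lam * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    g = K @ Z.T @ Vinv @ (y - X @ b)
    return b, g


class TestSolveMme:
    def test_matches_gls_oracle_on_10_animals(self):
        sire, dam, _ = random_pedigree(n=10, n_founders=4, seed=3, max_parent_gap=10)
        A = a_matrix(sire, dam)
        rng = np.random.default_rng(0)
        rec = np.array([0, 1, 2, 3, 5, 7, 8])
        y = rng.standard_normal(rec.size) + 2.0
        X = np.ones((rec.size, 1))
        Z = np.zeros((rec.size, 10))
        Z[np.arange(rec.size), rec] = 1.0
        lam = 1.7
        sol = solve_mme(y, X, rec, a_inverse(sire, dam), lam)
        b0, g0 = gls_oracle(y, X, Z, A, lam)
        assert np.allclose(sol.b, b0, atol=1e-8)
        assert np.allclose(sol.g, g0, atol=1e-8)

    def test_unrelated_animals_closed_form_regression(self):
        # y_i on unrelated animals: g_i = h2 * (y_i - mean) with lam=(1-h2)/h2
        n, h2 = 8, 0.4
        y = np.random.default_rng(1).standard_normal(n)
        kinv = np.eye(n)
        sol = solve_mme(y, np.ones((n, 1)), np.arange(n), kinv, (1 - h2) / h2)
        assert np.allclose(sol.g, h2 * (y - y.mean()), atol=1e-10)

    def test_infinite_shrinkage_sends_g_to_zero(self):
        sire, dam, _ = random_pedigree(n=12, n_founders=5, seed=4, max_parent_gap=12)
        y = np.random.default_rng(2).standard_normal(12)
        sol = solve_mme(y, np.ones((12, 1)), np.arange(12), a_inverse(sire, dam), 1e9)
        assert np.max(np.abs(sol.g)) < 1e-6

    def test_ssgblup_without_genotypes_equals_pedigree_blup(self):
        sire, dam, _ = random_pedigree(n=40, n_founders=8, seed=5, max_parent_gap=40)
        ainv = a_inverse(sire, dam)
        rec = np.arange(10, 40)
        y = np.random.default_rng(3).standard_normal(rec.size)
        X = np.ones((rec.size, 1))
        h = h_inverse(ainv, np.zeros((0, 0)), np.zeros((0, 0)), np.array([], dtype=int))
        s1 = solve_mme(y, X, rec, ainv, 2.0)
        s2 = solve_mme(y, X, rec, h, 2.0)
        assert np.array_equal(s1.g, s2.g)

    def test_gblup_invariant_to_marker_permutation_and_monomorphics(self):
        rng = np.random.default_rng(6)
        M = rng.integers(0, 3, size=(25, 400))
        y = rng.standard_normal(25)
        X = np.ones((25, 1))
        rec = np.arange(25)

        def fit(markers):
            G = genomic_relationship(markers) + 0.01 * np.eye(25)
            return solve_mme(y, X, rec, np.linalg.inv(G), 2.0).g

        base = fit(M)
        assert np.allclose(fit(M[:, rng.permutation(400)]), base, atol=1e-8)
        assert np.allclose(fit(np.hstack([M, np.zeros((25, 3), int)])), base, atol=1e-8)

    def test_dimension_mismatch_and_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            solve_mme(np.ones(3), np.ones((3, 1)), np.arange(3), np.eye(3), -1.0)
        with pytest.raises(ValueError):
            solve_mme(np.ones(4), np.ones((3, 1)), np.arange(3), np.eye(3), 1.0)


class TestReml:
    def test_recovers_components_on_balanced_half_sib_design(self):
        # 60 sires x 25 offspring, sigma_a2=0.4, sigma_e2=0.6; oracle is the
        # simulated truth: estimates must land within ~2 SE
        rng = np.random.default_rng(10)
        n_s, n_o = 60, 25
        n = n_s * n_o
        sire_eff = rng.normal(0, np.sqrt(0.4), n_s)
        # half-sib phenotype: 0.5*sire BV + mendelian + residual
        y = np.repeat(sire_eff * 0.5, n_o) + rng.normal(0, np.sqrt(0.3), n) + rng.normal(0, np.sqrt(0.6), n)
        # relationship: block 0.25 within sire families
        K = np.kron(np.eye(n_s), np.full((n_o, n_o), 0.25))
        np.fill_diagonal(K, 1.0)
        vc = reml_varcomp(y, np.ones((n, 1)), K, n_repeats=1)
        assert vc.converged
        assert vc.sigma_a2 == pytest.approx(0.4, abs=2.5 * max(vc.se_a2, 0.05))
        # total: 0.1 (between-family) + 0.3 (within) + 0.6 (residual)
        assert vc.sigma_p2 == pytest.approx(1.0, abs=0.1)

    def test_zero_signal_hits_boundary(self):
        # strong family structure, pure-noise phenotypes: additive variance
        # must collapse towards the zero boundary (replicate means)
        n_s, n_o = 50, 20
        n = n_s * n_o
        K = np.kron(np.eye(n_s), np.full((n_o, n_o), 0.25))
        np.fill_diagonal(K, 1.0)
        ests = []
        for seed in range(3):
            y = np.random.default_rng(100 + seed).standard_normal(n)
            vc = reml_varcomp(y, np.ones((n, 1)), K, n_repeats=1)
            ests.append(vc.sigma_a2)
            assert vc.sigma_e2 == pytest.approx(1.0, abs=0.15)
        assert np.mean(ests) < 0.06

    def test_repeat_averaging_is_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        K = np.eye(100)
        y = rng.standard_normal(100)
        a = reml_varcomp(y, np.ones((100, 1)), K, n_repeats=3, seed=5)
        b = reml_varcomp(y, np.ones((100, 1)), K, n_repeats=3, seed=5)
        assert a.sigma_a2 == b.sigma_a2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            reml_varcomp(np.ones(1), np.ones((1, 1)), np.eye(1))
        with pytest.raises(ValueError):
            reml_varcomp(np.ones(5), np.ones((5, 1)), np.eye(4))
        with pytest.raises(ValueError, match="zero variance"):
            reml_varcomp(np.ones(5), np.ones((5, 1)), np.eye(5))
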