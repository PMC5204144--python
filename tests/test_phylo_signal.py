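"""Blomberg's K, error-aware K, tip randomization and Pagel's lambda."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylodemog.phylo_signal import (
    PhyloCovariance,
    _lambda_transform,
    blomberg_K,
    blomberg_K_batch,
    blomberg_K_with_se,
    pagel_lambda,
    permutation_test,
    phylo_vcv,
)
from phylodemog.synthetic_data import simulate_bm_matrix, simulate_traits, simulate_tree

from conftest import tree_from_newick


def k_explicit(x, C):
    """Independent K oracle: explicit matrix inversion, no shared code path."""
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Ci @ x) / (one @ Ci @ one)
    r = x - a
    mse0 = r @ r / (n - 1)
    mse = r @ Ci @ r / (n - 1)
    expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return (mse0 / mse) / expected


class TestPhyloVcv:
    def test_balanced_four_tip_matrix(self, balanced4):
        assert balanced4.labels == ("A", "B", "C", "D")
        expected = np.array(
            [[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]], dtype=float
        )
        np.testing.assert_allclose(balanced4.matrix, expected)

    def test_star_tree_is_scaled_identity(self):
        C = phylo_vcv(tree_from_newick("(A:1,B:1,C:1,D:1);"))
        np.testing.assert_allclose(C.matrix, np.eye(4))

    def test_diagonal_equals_root_to_tip_distance(self):
        C = phylo_vcv(tree_from_newick("((A:1,B:2):3,(C:4,D:5):1);"))
        by_label = dict(zip(C.labels, np.diag(C.matrix)))
        assert by_label == {"A": 4.0, "B": 5.0, "C": 5.0, "D": 6.0}

    def test_rejects_missing_branch_length(self):
        with pytest.raises(ValueError, match="branch length"):
            phylo_vcv(tree_from_newick("((A:1,B),C:2);"))

    def test_symmetric_and_dominated_by_diagonal(self):
        C = phylo_vcv(simulate_tree(40, seed=3)).matrix
        np.testing.assert_allclose(C, C.T)
        assert np.all(np.diag(C)[:, None] >= C - 1e-12)


class TestBlombergK:
    def test_clade_pattern_matches_oracle(self, balanced4):
        x = np.array([0.0, 0.0, 10.0, 10.0])
        assert blomberg_K(x, balanced4).estimate == pytest.approx(1.8, abs=1e-10)
        assert blomberg_K(x, balanced4).estimate == pytest.approx(
            k_explicit(x, balanced4.matrix), abs=1e-10
        )

    def test_anticlade_pattern_matches_oracle(self, balanced4):
        x = np.array([0.0, 10.0, 0.0, 10.0])
        assert blomberg_K(x, balanced4).estimate == pytest.approx(0.6, abs=1e-10)
        assert blomberg_K(x, balanced4).estimate == pytest.approx(
            k_explicit(x, balanced4.matrix), abs=1e-10
        )

    def test_star_tree_identity(self, star5):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=5)
            assert blomberg_K(x, star5).estimate == pytest.approx(1.0, abs=1e-10)

    def test_constant_trait_rejected(self, balanced4):
        with pytest.raises(ValueError, match="degenerate"):
            blomberg_K(np.full(4, 3.0), balanced4)

    @pytest.mark.parametrize("n_tips", [5, 6, 8])
    def test_small_tree_oracle_equivalence(self, n_tips):
        """Production cho_solve path agrees with explicit inversion to 1e-10."""
        tree = simulate_tree(n_tips, seed=n_tips)
        C = phylo_vcv(tree)
        rng = np.random.default_rng(n_tips + 100)
        for _ in range(10):
            x = rng.normal(size=n_tips)
            assert blomberg_K(x, C).estimate == pytest.approx(
                k_explicit(x, C.matrix), abs=1e-10
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=st.floats(-50, 50),
        b=st.floats(-20, 20).filter(lambda v: abs(v) > 1e-3),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, a, b, seed):
        tree = simulate_tree(16, seed=5)
        C = phylo_vcv(tree)
        x = np.random.default_rng(seed).normal(size=16)
        k0 = blomberg_K(x, C).estimate
        k1 = blomberg_K(a + b * x, C).estimate
        assert k1 == pytest.approx(k0, rel=1e-9)

    def test_batch_matches_single(self, balanced4):
        X = np.array([[0, 0, 10, 10], [0, 10, 0, 10]], dtype=float).T
        np.testing.assert_allclose(blomberg_K_batch(X, balanced4.matrix), [1.8, 0.6])


class TestKWithSe:
    def test_zero_se_reduces_to_plain_k(self, balanced4):
        x = np.array([0.0, 1.0, 9.0, 10.0])
        plain = blomberg_K(x, balanced4).estimate
        r = blomberg_K_with_se(x, np.zeros(4), balanced4)
        assert r.estimate == pytest.approx(plain, abs=1e-12)
        assert r.se_used

    def test_error_aware_k_debiases_noisy_bm(self):
        """Observation noise pulls naive K down; modelling the SE restores it."""
        tree = simulate_tree(64, seed=21)
        C = phylo_vcv(tree)
        depth = float(np.diag(C.matrix).mean())
        rng = np.random.default_rng(22)
        se = np.full(64, 0.6 * np.sqrt(depth))  # substantial intrageneric spread
        naive, aware = [], []
        _, X = simulate_bm_matrix(tree, 100, 1.0, seed=23)
        for j in range(100):
            x = X[:, j] + rng.normal(0, se)
            naive.append(blomberg_K(x, C).estimate)
            aware.append(blomberg_K_with_se(x, se, C).estimate)
        assert abs(np.mean(aware) - 1.0) < abs(np.mean(naive) - 1.0)
        assert np.mean(aware) > np.mean(naive)  # error-aware K is larger on average

    def test_pure_noise_raises(self, star5):
        # trait variance fully explained by the stated errors: sigma^2 -> 0
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.05, 5)
        with pytest.raises(RuntimeError, match="indistinguishable"):
            blomberg_K_with_se(x, np.full(5, 50.0), star5)


class TestPermutationTest:
    def test_clustered_trait_is_significant(self):
        tree = simulate_tree(64, seed=31)
        C = phylo_vcv(tree)
        _, X = simulate_bm_matrix(tree, 1, 1.0, seed=32)  # genuine BM signal
        r = permutation_test(X[:, 0], None, C, n_perm=500, seed=33)
        assert r.significant
        assert r.perm_quantiles[0] < r.perm_quantiles[1]
        assert r.perm_count == 500 and r.seed == 33

    def test_with_se_permutes_pairs(self):
        tree = simulate_tree(32, seed=41)
        C = phylo_vcv(tree)
        _, X = simulate_bm_matrix(tree, 1, 1.0, seed=42)
        se = np.abs(np.random.default_rng(43).normal(0, 0.3, 32))
        r = permutation_test(X[:, 0], se, C, n_perm=200, seed=44)
        assert r.se_used and r.perm_count == 200

    def test_too_few_permutations_rejected(self, balanced4):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(np.array([0.0, 0, 10, 10]), None, balanced4, n_perm=0)


class TestPagelLambda:
    def test_transform_identity_and_star(self, balanced4):
        C = balanced4.matrix
        np.testing.assert_allclose(_lambda_transform(C, 1.0), C)
        np.testing.assert_allclose(_lambda_transform(C, 0.0), np.diag(np.diag(C)))

    def test_bm_data_gives_lambda_near_one(self):
        tree = simulate_tree(150, seed=51)
        C = phylo_vcv(tree)
        ests = []
        _, X = simulate_bm_matrix(tree, 20, 1.0, seed=52)
        for j in range(20):
            ests.append(pagel_lambda(X[:, j], C).estimate)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.05)

    def test_shuffled_data_gives_lambda_near_zero(self):
        tree = simulate_tree(150, seed=61)
        C = phylo_vcv(tree)
        ests = []
        for j in range(10):
            ts = simulate_traits(tree, "shuffled", seed=600 + j)
            ests.append(pagel_lambda(ts.genus_values, C).estimate)
        assert np.mean(ests) < 0.15

    def test_intermediate_lambda_recovered(self):
        tree = simulate_tree(150, seed=71)
        C = phylo_vcv(tree)
        ests = [
            pagel_lambda(simulate_traits(tree, "lambda", lam=0.5, seed=700 + j).genus_values, C).estimate
            for j in range(20)
        ]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.12)

    def test_reports_likelihood_ratio_against_star(self):
        tree = simulate_tree(80, seed=81)
        C = phylo_vcv(tree)
        _, X = simulate_bm_matrix(tree, 1, 1.0, seed=82)
        r = pagel_lambda(X[:, 0], C)
        assert r.log_likelihood is not None
        assert 0 <= r.lrt_pvalue < 0.05  # real signal: star model strongly rejected
        assert r.notes["lambda_max"] >= 1.0
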