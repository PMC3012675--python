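"""Gauge fixing, affinity extraction, structure normalization, deconvolution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isospace import adapt
from isospace.model import ValidationError


class TestSolveScaling:
    def test_proportional_columns_recovered_exactly(self):
        W = np.array([[2.0, 4.0], [3.0, 6.0], [5.0, 10.0]])
        d = adapt.solve_scaling(W)
        np.testing.assert_allclose(d, [1.0, 0.5])
        assert adapt.eq_objective(W, d) == pytest.approx(0.0, abs=1e-12)

    def test_single_column_identity(self):
        np.testing.assert_array_equal(adapt.solve_scaling(np.ones((4, 1))), [1.0])

    def test_beats_random_perturbations(self, rng):
        a = np.exp(rng.normal(np.log(100), 1, 20))
        G = (rng.uniform(size=(20, 3)) < 0.8).astype(float)
        G[G.sum(1) == 0, 0] = 1
        W = a[:, None] * G * np.array([0.3, 1.0, 4.0]) * np.exp(rng.normal(0, 0.1, (20, 3)))
        d = adapt.solve_scaling(W)
        obj = adapt.eq_objective(W, d)
        for _ in range(1000):
            d_pert = d * np.exp(rng.normal(0, 0.3, 3))
            assert obj <= adapt.eq_objective(W, d_pert) + 1e-9

    def test_matches_grid_search_oracle(self, rng):
        """Brute-force oracle: 2-parameter log-grid search of the objective."""
        a = np.exp(rng.normal(np.log(100), 1, 20))
        G = (rng.uniform(size=(20, 3)) < 0.8).astype(float)
        G[G.sum(1) == 0, 0] = 1
        W = a[:, None] * G * np.array([0.5, 1.0, 2.0]) * np.exp(rng.normal(0, 0.1, (20, 3)))
        d = adapt.solve_scaling(W)
        x = np.log(d)

        mask = W > 1e-3 * W.max(0)
        logW = np.log(np.where(mask, W, 1.0))
        pair_data = []
        for j, l in ((0, 1), (0, 2), (1, 2)):
            rows = mask[:, j] & mask[:, l]
            pair_data.append((j, l, logW[rows, j] - logW[rows, l]))
        grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
        X2, X3 = np.meshgrid(grid, grid, indexing="ij")
        obj = np.zeros_like(X2)
        xs = {0: 0.0, 1: X2, 2: X3}
        for j, l, diffs in pair_data:
            delta = xs[j] - xs[l]
            for dval in diffs:
                obj += np.abs(dval + delta)
        i2, i3 = np.unravel_index(np.argmin(obj), obj.shape)
        assert abs(x[1] - grid[i2]) <= 0.02 + 1e-9
        assert abs(x[2] - grid[i3]) <= 0.02 + 1e-9

    def test_gauge_invariance_of_objective(self, rng):
        W = rng.uniform(0.1, 5.0, size=(10, 3))
        d = adapt.solve_scaling(W)
        assert adapt.eq_objective(W, d) == pytest.approx(
            adapt.eq_objective(W, 7.3 * d), abs=1e-8
        )

    def test_zero_column_raises(self):
        W = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            adapt.solve_scaling(W)


class TestApplyScaling:
    def test_identity_and_product_preservation(self, rng):
        W = rng.uniform(size=(6, 3))
        H = rng.uniform(size=(3, 5))
        W1, H1 = adapt.apply_scaling(W, H, np.ones(3))
        np.testing.assert_array_equal(W1, W)
        d = rng.uniform(0.2, 5.0, size=3)
        Wt, Ht = adapt.apply_scaling(W, H, d)
        assert np.max(np.abs(Wt @ Ht - W @ H)) < 1e-12
        assert (Wt >= 0).all() and (Ht >= 0).all()

    def test_scalar_case(self):
        Wt, Ht = adapt.apply_scaling(np.array([[2.0]]), np.array([[3.0]]), [2.0])
        assert Wt[0, 0] == 4.0 and Ht[0, 0] == 1.5

    def test_non_positive_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            adapt.apply_scaling(np.ones((2, 1)), np.ones((1, 2)), [0.0])


class TestAffinityAndStructure:
    def test_row_max_affinities(self):
        np.testing.assert_array_equal(
            adapt.extract_affinities(np.array([[2.0, 2.0], [3.0, 3.0], [5.0, 5.0]])),
            [2.0, 3.0, 5.0],
        )
        np.testing.assert_array_equal(
            adapt.extract_affinities(np.array([[1.0, 4.0], [6.0, 2.0]])), [4.0, 6.0]
        )

    def test_all_zero_row_names_probe(self):
        with pytest.raises(ValidationError, match="1"):
            adapt.extract_affinities(np.array([[1.0, 2.0], [0.0, 0.0]]))

    def test_continuous_structure_range(self):
        Wt = np.array([[1.0, 4.0]])
        np.testing.assert_allclose(
            adapt.continuous_structure(Wt, adapt.extract_affinities(Wt)), [[0.25, 1.0]]
        )

    @given(st.integers(0, 10_000))
    def test_row_max_is_one(self, seed):
        r = np.random.default_rng(seed)
        Wt = r.uniform(0.01, 10.0, size=(6, 3))
        G = adapt.continuous_structure(Wt, adapt.extract_affinities(Wt))
        assert G.min() >= 0 and G.max() <= 1 + 1e-12
        np.testing.assert_allclose(G.max(axis=1), 1.0)

    def test_proportional_columns_give_all_ones(self):
        W = np.array([[2.0, 4.0], [3.0, 6.0], [5.0, 10.0]])
        Wt, _ = adapt.apply_scaling(W, np.ones((2, 2)), adapt.solve_scaling(W))
        G = adapt.continuous_structure(Wt, adapt.extract_affinities(Wt))
        np.testing.assert_allclose(G, np.ones((3, 2)), atol=1e-12)

    def test_fill_structure_clamps(self, rng):
        G = rng.uniform(size=(5, 2))
        G[0, 0] = 0.0
        filled = adapt.fill_structure(G, 1e-3)
        assert filled[0, 0] == 1e-3
        assert filled.min() >= 1e-3
        already = rng.uniform(0.5, 1.0, size=(3, 2))
        np.testing.assert_array_equal(adapt.fill_structure(already, 1e-3), already)


class TestDeconvolveKnownStructure:
    def test_forward_simulation_inverted(self, rng):
        A = rng.uniform(1.0, 5.0, size=6)
        G = np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1], [1, 1]], dtype=float)
        T = rng.uniform(0.1, 1.0, size=(2, 7))
        Y = A[:, None] * (G @ T)
        T_hat, resid, ambiguous = adapt.deconvolve_known_structure(Y, G, A)
        np.testing.assert_allclose(T_hat, T, atol=1e-6)
        assert resid < 1e-8
        assert not ambiguous

    def test_single_isoform_reduces_to_scalar_regression(self, rng):
        A = rng.uniform(1.0, 3.0, size=4)
        G = np.ones((4, 1))
        T = rng.uniform(size=(1, 5))
        Y = A[:, None] * (G @ T)
        T_hat, _, _ = adapt.deconvolve_known_structure(Y, G, A)
        np.testing.assert_allclose(T_hat, T, atol=1e-8)

    def test_complementary_cassette_ambiguity_flagged(self):
        """Isoform pair {constitutive+cassette, constitutive}: multiple exact
        (A, T) solutions reproduce Y, so the structure is flagged ambiguous."""
        G = np.array([[1.0, 1.0], [1.0, 0.0]])
        A = np.array([2.0, 3.0])
        T = np.array([[0.4, 0.8, 0.2], [0.5, 0.1, 0.9]])
        Y = A[:, None] * (G @ T)
        T_hat, resid, ambiguous = adapt.deconvolve_known_structure(Y, G, A)
        assert resid < 1e-8
        assert ambiguous
        # second, different exact solution: halve the unique-probe signal's
        # concentration while doubling that probe's affinity
        A2 = np.array([2.0, 2.0 * 3.0])
        T2 = np.vstack([T[0] / 2.0, T[1] + T[0] / 2.0])
        Y2 = A2[:, None] * (G @ T2)
        np.testing.assert_allclose(Y2, Y, atol=1e-12)
        assert not np.allclose(T2, T)

    def test_zero_column_rejected(self):
        with pytest.raises(ValidationError):
            adapt.deconvolve_known_structure(np.ones((2, 2)), np.array([[1.0, 0.0], [1.0, 0.0]]))
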