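"""Bi-cross-validation: block reconstruction, rank selection, outlier repair."""

import numpy as np
import pytest

from isospace.bicrossval import (
    bcv_error_table,
    detect_and_correct_outliers,
    estimate_num_transcripts,
    partition_matrix,
    reconstruct_block,
)
from isospace.model import ValidationError


class TestPartition:
    def test_even_and_ceil_splits(self, rng):
        p4 = partition_matrix(np.ones((4, 4)), rng)
        assert (len(p4.rows1), len(p4.rows2), len(p4.cols1), len(p4.cols2)) == (2, 2, 2, 2)
        p3 = partition_matrix(np.ones((3, 3)), rng)
        assert (len(p3.rows1), len(p3.rows2)) == (2, 1)
        assert (len(p3.cols1), len(p3.cols2)) == (2, 1)

    def test_partition_covers_all_indices_once(self, rng):
        p = partition_matrix(np.ones((7, 5)), rng)
        assert sorted([*p.rows1, *p.rows2]) == list(range(7))
        assert sorted([*p.cols1, *p.cols2]) == list(range(5))

    def test_too_small_matrix(self, rng):
        with pytest.raises(ValidationError):
            partition_matrix(np.ones((1, 5)), rng)


class TestReconstructBlock:
    def test_rank_one_identity(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.outer(v, v)
        P, Q = Y[:2, :2], Y[:2, 2:]
        R, S = Y[2:, :2], Y[2:, 2:]
        np.testing.assert_allclose(reconstruct_block(Q, S, R, 1), P, atol=1e-12)

    def test_rank_k_identity_over_random_instances(self, rng):
        """Exact reconstruction of noiseless rank-k blocks (100 instances)."""
        for _ in range(100):
            k = int(rng.integers(1, 4))
            W = rng.uniform(0.5, 2.0, size=(8, k))
            H = rng.uniform(0.5, 2.0, size=(k, 8))
            Y = W @ H
            P, Q, R, S = Y[:4, :4], Y[:4, 4:], Y[4:, :4], Y[4:, 4:]
            assert np.linalg.norm(reconstruct_block(Q, S, R, k) - P) < 1e-9

    def test_singular_s_uses_pseudoinverse(self):
        S = np.outer([1.0, 2.0], [1.0, 1.0])  # rank 1
        out = reconstruct_block(np.ones((2, 2)), S, np.ones((2, 2)), 1)
        assert np.all(np.isfinite(out))

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            reconstruct_block(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)), 3)


class TestErrorTable:
    def test_noiseless_rank1_zero_error_at_k1(self, rng):
        Y = np.outer(np.arange(1, 9, dtype=float), np.arange(1, 11, dtype=float))
        tbl = bcv_error_table(Y, k_max=2, n_resamples=20, rng=rng)
        assert tbl.shape == (20, 2)
        assert np.all(tbl[:, 0] < 1e-9)

    def test_true_rank_not_worse_than_smaller_k(self, rng):
        """On noiseless rank-2 data the k=2 error is below the k=1 error."""
        W = rng.uniform(0.5, 2.0, size=(10, 2))
        H = rng.uniform(0.5, 2.0, size=(2, 12))
        tbl = bcv_error_table(W @ H, k_max=3, n_resamples=30, rng=rng)
        assert np.all(tbl[:, 1] <= tbl[:, 0] + 1e-9)

    def test_kmax_truncated_with_warning(self, rng):
        with pytest.warns(UserWarning, match="truncated"):
            tbl = bcv_error_table(np.ones((4, 4)) + np.eye(4), 10, 5, rng)
        assert tbl.shape[1] == 2


class TestEstimateNumTranscripts:
    def test_separated_error_distributions(self, rng):
        """k1 >> k2 ~ k3 selects k=2 (smallest statistically tied with best)."""
        tbl = np.column_stack(
            [
                rng.normal(10.0, 0.1, 250),
                rng.normal(1.0, 0.1, 250),
                rng.normal(0.99, 0.1, 250),
            ]
        )
        assert estimate_num_transcripts(tbl) == 2

    def test_noiseless_rank2_full_procedure(self, rng):
        W = rng.uniform(0.5, 2.0, size=(12, 2))
        H = rng.uniform(0.5, 2.0, size=(2, 14))
        tbl = bcv_error_table(W @ H, k_max=4, n_resamples=60, rng=rng)
        assert estimate_num_transcripts(tbl) == 2

    def test_degenerate_table_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_num_transcripts(np.ones((20, 3))) == 1

    def test_never_exceeds_argmin_median(self, rng):
        for _ in range(20):
            tbl = rng.uniform(1.0, 2.0, size=(40, 5))
            k_star = int(np.argmin(np.median(tbl, axis=0))) + 1
            assert estimate_num_transcripts(tbl) <= k_star


class TestOutlierCorrection:
    def test_clean_rank1_flags_nothing(self, rng):
        Y = np.outer(np.arange(1, 9, dtype=float), np.arange(1, 9, dtype=float))
        corrected, mask, _ = detect_and_correct_outliers(Y, 40, rng=rng)
        assert mask.sum() == 0
        np.testing.assert_array_equal(corrected, Y)

    def test_planted_outlier_recovered(self, rng):
        u = np.arange(1, 9, dtype=float)
        Y = np.outer(u, u)
        truth = Y[3, 4]
        Y[3, 4] *= 20.0
        corrected, mask, _ = detect_and_correct_outliers(Y, 80, rng=rng)
        assert mask[3, 4]
        assert mask.sum() == 1
        assert corrected[3, 4] == pytest.approx(truth, rel=0.1)

    def test_idempotent_on_own_output(self, rng):
        gene_rng = np.random.default_rng(3)
        Y = np.outer(
            gene_rng.uniform(1, 5, 10), gene_rng.uniform(1, 5, 12)
        ) * np.exp(gene_rng.normal(0, 0.1, (10, 12)))
        first, mask1, _ = detect_and_correct_outliers(Y, 60, rng=rng)
        second, mask2, _ = detect_and_correct_outliers(first, 60, rng=rng)
        assert mask2.sum() <= max(1, 0.01 * Y.size)

    def test_needs_enough_resamples(self, rng):
        with pytest.raises(ValidationError):
            detect_and_correct_outliers(np.ones((4, 4)), n_resamples=5, rng=rng)
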