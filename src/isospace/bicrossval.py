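"""Bi-cross-validation on the probe matrix: rank selection and outlier repair.

The matrix is randomly split into four blocks

    Y = [[P, Q],
         [R, S]]

and each block is predicted from the other three through a rank-k truncated
pseudoinverse of its diagonally opposite block, ``P̃_k = Q · S_k⁺ · R``.  For a
noiseless matrix of rank k (with the opposite block of equal rank) the
reconstruction is exact; with noise, the reconstruction error as a function of
k has its expectation minimized near the true rank.  Repeating the split many
times yields, per candidate rank, a distribution of whole-matrix errors:

* the estimated transcript count is the smallest rank whose error
  distribution is not significantly larger (one-sided Wilcoxon rank-sum)
  than that of the rank with minimal median error;
* the same resampling, run at the largest feasible rank, yields per-entry
  distributions of cross-validated estimates used to flag and replace
  outlier intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .model import ValidationError

DEFAULT_RESAMPLES = 250
_SV_RCOND = 1e-12


@dataclass
class Partition:
    """Random row/column split of a matrix into four blocks."""

    rows1: np.ndarray
    rows2: np.ndarray
    cols1: np.ndarray
    cols2: np.ndarray

    @property
    def min_block_dim(self) -> int:
        return min(len(self.rows1), len(self.rows2), len(self.cols1), len(self.cols2))


def partition_matrix(Y, rng: np.random.Generator) -> Partition:
    """Randomly permute rows/columns and split each in half (ceil on the P-side).

    The split uses roughly 75% of the entries to predict the remaining 25%.
    """
    m, n = np.asarray(Y).shape
    if m < 2 or n < 2:
        raise ValidationError("matrix too small to partition (need >= 2x2)")
    rperm = rng.permutation(m)
    cperm = rng.permutation(n)
    m1 = (m + 1) // 2
    n1 = (n + 1) // 2
    return Partition(rperm[:m1], rperm[m1:], cperm[:n1], cperm[n1:])


def _rank_truncated_svd(S: np.ndarray):
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s > _SV_RCOND * (s[0] if s.size else 1.0)
    return U[:, keep], s[keep], Vt[keep]


def reconstruct_block(Q, S, R, k: int) -> np.ndarray:
    """``P̃_k = Q · S_k⁺ · R`` with the rank-k truncated pseudoinverse of S."""
    Q = np.asarray(Q, dtype=float)
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if k < 1 or k > min(S.shape):
        raise ValidationError(f"k={k} out of range for S of shape {S.shape}")
    U, s, Vt = _rank_truncated_svd(S)
    k_eff = min(k, s.size)  # rank-deficient S: pseudoinverse uses what exists
    Sk_pinv = (Vt[:k_eff].T / s[:k_eff]) @ U[:, :k_eff].T
    return Q @ Sk_pinv @ R


def _block_views(Y: np.ndarray, part: Partition):
    """The four (target, same-row, opposite, same-col) quadruples.

    Each block plays the role of P once; its predictors are the block sharing
    its rows, the diagonally opposite block, and the block sharing its columns.
    """
    r1, r2, c1, c2 = part.rows1, part.rows2, part.cols1, part.cols2
    B = lambda r, c: Y[np.ix_(r, c)]
    return [
        ((r1, c1), B(r1, c1), B(r1, c2), B(r2, c2), B(r2, c1)),
        ((r1, c2), B(r1, c2), B(r1, c1), B(r2, c1), B(r2, c2)),
        ((r2, c1), B(r2, c1), B(r2, c2), B(r1, c2), B(r1, c1)),
        ((r2, c2), B(r2, c2), B(r2, c1), B(r1, c1), B(r1, c2)),
    ]


def _reconstructions_all_k(Q, S, R, k_max: int):
    """Cumulative rank-1 expansion of Q·S_k⁺·R for k = 1..k_max."""
    U, s, Vt = _rank_truncated_svd(S)
    QV = Q @ Vt.T  # (mQ, r)
    UR = U.T @ R  # (r, nR)
    out = []
    acc = np.zeros((Q.shape[0], R.shape[1]))
    for k in range(1, k_max + 1):
        if k <= s.size:
            acc = acc + np.outer(QV[:, k - 1], UR[k - 1]) / s[k - 1]
        out.append(acc.copy())
    return out


def bcv_error_table(
    Y,
    k_max: int,
    n_resamples: int = DEFAULT_RESAMPLES,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Whole-matrix Frobenius reconstruction error per resample and rank.

    Returns an array of shape ``(n_resamples, k_eff)`` where ``k_eff`` is
    ``k_max`` truncated to the largest rank feasible for the half/half split
    (a warning is emitted when truncation occurs).
    """
    Y = np.asarray(Y, dtype=float)
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    rng = np.random.default_rng(rng)
    m, n = Y.shape
    feasible = min((m + 1) // 2, m // 2, (n + 1) // 2, n // 2)
    k_eff = min(k_max, feasible)
    if k_eff < k_max:
        warnings.warn(
            f"k_max={k_max} infeasible for a {m}x{n} matrix; truncated to {k_eff}",
            stacklevel=2,
        )
    errors = np.empty((n_resamples, k_eff))
    for L in range(n_resamples):
        part = partition_matrix(Y, rng)
        sq = np.zeros(k_eff)
        for _, target, Q, S, R in _block_views(Y, part):
            recons = _reconstructions_all_k(Q, S, R, k_eff)
            for j, Pk in enumerate(recons):
                d = target - Pk
                sq[j] += np.dot(d.ravel(), d.ravel())
        errors[L] = np.sqrt(sq)
    return errors


def estimate_num_transcripts(error_table: np.ndarray, alpha: float = 0.05) -> int:
    """Smallest rank whose errors are not significantly above the best rank's.

    ``k* = argmin_k median(errors_k)``; the estimate is the smallest k for
    which a one-sided Wilcoxon rank-sum test of ``errors_k > errors_k*`` is
    not significant at ``alpha``.  Always ``k_hat <= k*``.
    """
    tbl = np.asarray(error_table, dtype=float)
    if tbl.ndim != 2 or tbl.shape[0] < 2:
        raise ValidationError("need an error table with at least 2 resamples")
    if np.ptp(tbl) == 0:
        warnings.warn("degenerate error table (all errors equal); returning k=1")
        return 1
    medians = np.median(tbl, axis=0)
    k_star = int(np.argmin(medians))
    for k in range(k_star + 1):
        if k == k_star:
            return k_star + 1
        with np.errstate(all="ignore"):
            p = mannwhitneyu(
                tbl[:, k], tbl[:, k_star], alternative="greater", method="asymptotic"
            ).pvalue
        if not (p < alpha):
            return k + 1
    return k_star + 1  # pragma: no cover - loop always returns


def detect_and_correct_outliers(
    Y,
    n_resamples: int = DEFAULT_RESAMPLES,
    c: float = 3.0,
    rng: np.random.Generator | None = None,
):
    """Flag and replace entries far from their cross-validated estimates.

    Every resample reconstructs each entry from the complementary blocks at
    the largest feasible rank, giving per-entry estimate distributions.  An
    entry is an outlier when its residual ``|y - median(est)|`` exceeds ``c``
    robust standard deviations, where the scale is the normal-consistent MAD
    (1.4826 × MAD) of the entry's estimates, floored by the global MAD of all
    residuals (per-entry estimate spread alone underestimates the noise
    level), plus a small absolute guard (``1e-8 ×`` the median magnitude of
    Y) so numerically exact reconstructions never trigger flags.  Flagged
    entries are replaced by the median estimate (clipped at zero).

    Returns ``(Y_corrected, mask, medians)``.
    """
    Y = np.asarray(Y, dtype=float)
    if n_resamples < 10:
        raise ValidationError("outlier detection needs at least 10 resamples")
    rng = np.random.default_rng(rng)
    m, n = Y.shape
    estimates = np.empty((n_resamples, m, n))
    for L in range(n_resamples):
        part = partition_matrix(Y, rng)
        k_big = max(part.min_block_dim - 1, 1)
        est = np.empty_like(Y)
        for (ridx, cidx), _, Q, S, R in _block_views(Y, part):
            est[np.ix_(ridx, cidx)] = _reconstructions_all_k(Q, S, R, k_big)[-1]
        estimates[L] = est
    med = np.median(estimates, axis=0)
    resid = np.abs(Y - med)
    sigma_entry = 1.4826 * np.median(np.abs(estimates - med), axis=0)
    sigma_global = 1.4826 * np.median(resid)
    atol = 1e-8 * (np.median(np.abs(Y)) + np.finfo(float).tiny)
    mask = resid > c * np.maximum(sigma_entry, sigma_global) + atol
    if np.any(mask.all(axis=1)):
        warnings.warn("at least one probe row was flagged entirely as outliers")
    corrected = np.where(mask, np.maximum(med, 0.0), Y)
    return corrected, mask, med
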