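"""Gauge fixing of the NMF factors ("Adapt") and affinity/structure split.

An NMF solution is only defined up to ``(W·D)·(D⁻¹·H)`` for any positive
diagonal ``D``.  Under the deconvolution model ``Y ≈ diag(A)·G·T`` with a
binary structure ``G`` that contains many more ones than zeros, the columns of
``diag(A)·G`` are equal to the affinity profile wherever the probe hybridizes.
The "correct" gauge is therefore the one making the columns of ``W̃ = W·D`` as
mutually similar as possible, formalized as the L1 problem

    min_D  Σ_i Σ_{j<k} | log(d_jj·w_ij) − log(d_kk·w_ik) |

which is convex piecewise-linear in ``x_j = log d_jj`` and solved exactly as
a small linear program under the gauge ``x_1 = 0`` (the objective is
invariant to a common shift of all ``x_j``); a robust pairwise-median /
least-squares reconciliation provides the starting point and the fallback.
The median of the log-ratios makes the solution insensitive to outlier
probes.

Once ``W̃`` is fixed, the per-probe affinity is its row maximum and the
continuous structure ``G̃ = diag(Ã)⁻¹·W̃`` lies in [0, 1] with a one in every
row.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.optimize import linprog, nnls

from .model import ValidationError

FILL_FLOOR = 1e-3


def eq_objective(W, d, floor_frac: float = FILL_FLOOR) -> float:
    """L1 column-similarity objective for a candidate diagonal ``d``.

    Entries below ``floor_frac ×`` the column maximum are excluded (their
    logarithm carries no structure information).
    """
    W = np.asarray(W, dtype=float)
    d = np.asarray(d, dtype=float)
    mask = W > floor_frac * W.max(axis=0)
    logWd = np.where(mask, np.log(np.where(mask, W, 1.0)) + np.log(d)[None, :], np.nan)
    total = 0.0
    k = W.shape[1]
    for j, l in itertools.combinations(range(k), 2):
        rows = mask[:, j] & mask[:, l]
        total += np.abs(logWd[rows, j] - logWd[rows, l]).sum()
    return float(total)


def _pairwise_terms(W: np.ndarray, floor_frac: float):
    """Per column pair (j, l): the log-ratio samples log(w_ij) - log(w_il)."""
    k = W.shape[1]
    mask = W > floor_frac * W.max(axis=0)
    logW = np.log(np.where(mask, W, 1.0))
    terms = []
    for j, l in itertools.combinations(range(k), 2):
        shared = mask[:, j] & mask[:, l]
        if shared.any():
            terms.append((j, l, logW[shared, j] - logW[shared, l]))
    return terms


def _median_reconcile(k: int, terms) -> np.ndarray:
    """Robust approximation: median pairwise offsets + least-squares graph fit."""
    rows_A, rhs = [], []
    for j, l, diffs in terms:
        row = np.zeros(k)
        row[l], row[j] = 1.0, -1.0
        rows_A.append(row)
        rhs.append(np.median(diffs))  # x_l - x_j
    x = np.zeros(k)
    if rows_A:
        A = np.array(rows_A)[:, 1:]  # gauge x_0 = 0
        x[1:], *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
    return x


def _lp_minimize(k: int, terms) -> np.ndarray | None:
    """Exact minimizer of sum |d_m + x_j - x_l| via LP (epigraph form)."""
    data = [(j, l, d) for j, l, diffs in terms for d in diffs]
    if not data:
        return None
    n_t = len(data)
    nv = (k - 1) + n_t  # x_2..x_k then one slack per absolute term
    c = np.zeros(nv)
    c[k - 1:] = 1.0
    A_ub = np.zeros((2 * n_t, nv))
    b_ub = np.empty(2 * n_t)
    for m, (j, l, d) in enumerate(data):
        # |(x_j - x_l) + d| <= t_m
        if j > 0:
            A_ub[2 * m, j - 1] = 1.0
            A_ub[2 * m + 1, j - 1] = -1.0
        if l > 0:
            A_ub[2 * m, l - 1] = -1.0
            A_ub[2 * m + 1, l - 1] = 1.0
        A_ub[2 * m, k - 1 + m] = -1.0
        A_ub[2 * m + 1, k - 1 + m] = -1.0
        b_ub[2 * m] = -d
        b_ub[2 * m + 1] = d
    bounds = [(None, None)] * (k - 1) + [(0.0, None)] * n_t
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        return None
    return np.concatenate([[0.0], res.x[: k - 1]])


def solve_scaling(W, floor_frac: float = FILL_FLOOR) -> np.ndarray:
    """Diagonal ``d > 0`` minimizing the L1 column-similarity objective.

    Exact LP solve of the convex piecewise-linear objective; falls back to
    the pairwise-median / least-squares approximation if the LP solver does
    not converge.  Gauge convention: ``d_1 = 1`` (first log-scale fixed at
    zero).

    Raises
    ------
    ValidationError
        If some column has no entry above the exclusion floor.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValidationError("W must be 2-dimensional")
    k = W.shape[1]
    colmax = W.max(axis=0)
    if np.any(colmax <= 0):
        raise ValidationError(
            f"columns without scale information: {np.nonzero(colmax <= 0)[0].tolist()}"
        )
    if k == 1:
        return np.ones(1)
    terms = _pairwise_terms(W, floor_frac)
    if not terms:
        warnings.warn("no column pair shares above-floor probes; returning identity scaling")
        return np.ones(k)
    x = _lp_minimize(k, terms)
    if x is None:
        x = _median_reconcile(k, terms)
    return np.exp(x)


def apply_scaling(W, H, d):
    """``(W̃, H̃) = (W·D, D⁻¹·H)``; preserves the product exactly."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    d = np.asarray(d, dtype=float).ravel()
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValidationError("scaling diagonal must be positive and finite")
    if W.shape[1] != d.size or H.shape[0] != d.size:
        raise ValidationError("scaling diagonal length does not match factor shapes")
    return W * d[None, :], H / d[:, None]


def extract_affinities(W_tilde) -> np.ndarray:
    """Per-probe affinity = row maximum of the adapted factor ``W̃``."""
    W = np.asarray(W_tilde, dtype=float)
    a = W.max(axis=1)
    dead = np.nonzero(a <= 0)[0]
    if dead.size:
        raise ValidationError(
            f"probe rows hybridize against no transcript (all-zero): {dead.tolist()}"
        )
    return a


def continuous_structure(W_tilde, affinities) -> np.ndarray:
    """``G̃ = diag(Ã)⁻¹·W̃``; entries in [0, 1], row maximum exactly 1."""
    W = np.asarray(W_tilde, dtype=float)
    a = np.asarray(affinities, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("affinities must be strictly positive")
    return W / a[:, None]


def fill_structure(G_tilde, floor: float = FILL_FLOOR) -> np.ndarray:
    """Raise entries below ``floor`` to ``floor`` ("filled" structure).

    Keeps downstream log-domain operations defined on near-zero entries.
    """
    return np.maximum(np.asarray(G_tilde, dtype=float), floor)


def _identifiability_nullity(A, G, T, rtol: float = 1e-8):
    """Dimension of the solution manifold of (A, T) -> Y around a solution.

    Linearizes ``Y = diag(A)·G·T`` in ``(dA, dT)`` and counts the null-space
    dimension of the constraint matrix.  A structure is identifiable when the
    nullity equals the number of trivial gauge directions, i.e. the number of
    connected components of the probe–transcript incidence graph (one common
    scale per component).
    """
    A = np.asarray(A, float)
    G = np.asarray(G, float)
    T = np.asarray(T, float)
    m, k = G.shape
    n = T.shape[1]
    GT = G @ T  # (m, n)
    # unknown vector: [dA (m), dT flattened row-major (k*n)]
    M = np.zeros((m * n, m + k * n))
    for i in range(m):
        for s in range(n):
            r = i * n + s
            M[r, i] = GT[i, s]
            M[r, m + s::n] = A[i] * G[i]  # dT[:, s] entries
    sv = np.linalg.svd(M, compute_uv=False)
    tol = rtol * (sv[0] if sv.size else 1.0)
    nullity = M.shape[1] - int((sv > tol).sum())
    # connected components of the bipartite probe/transcript graph
    adj = (G > 0).astype(int)
    comp = -np.ones(k, dtype=int)
    n_comp = 0
    for j in range(k):
        if comp[j] >= 0:
            continue
        stack, comp[j] = [j], n_comp
        while stack:
            cur = stack.pop()
            shared = (adj[:, cur:cur + 1] * adj).sum(axis=0) > 0
            for nxt in np.nonzero(shared)[0]:
                if comp[nxt] < 0:
                    comp[nxt] = n_comp
                    stack.append(nxt)
        n_comp += 1
    return nullity, n_comp


def deconvolve_known_structure(Y, G, affinities=None):
    """Estimate concentrations for a known binary structure by per-sample NNLS.

    Solves ``Y[:, s] ≈ diag(A)·G·T[:, s]`` with ``T ≥ 0`` for every sample.
    When affinities are not supplied, the leading left singular vector of Y
    (non-negative up to sign for a non-negative matrix) serves as the affinity
    profile — adequate up to the overall scale absorbed by T.

    Returns ``(T, residual, ambiguous)`` where ``ambiguous`` is True when the
    structure admits continuum-many exact (A, T) solutions beyond trivial
    per-component rescaling (the classic deconvolution ambiguity).
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if not np.isin(G, (0.0, 1.0)).all():
        raise ValidationError("G must be binary")
    if np.any(G.sum(axis=0) == 0):
        raise ValidationError("G has an all-zero transcript column")
    if affinities is None:
        U, s, _ = np.linalg.svd(Y, full_matrices=False)
        a = np.abs(U[:, 0])
        a = np.maximum(a, 1e-6 * max(a.max(), 1.0))
    else:
        a = np.asarray(affinities, dtype=float)
        if np.any(a <= 0):
            raise ValidationError("affinities must be positive")
    M = a[:, None] * G
    k, n = G.shape[1], Y.shape[1]
    T = np.empty((k, n))
    sq = 0.0
    for s_idx in range(n):
        T[:, s_idx], r = nnls(M, Y[:, s_idx])
        sq += r * r
    nullity, n_comp = _identifiability_nullity(a, G, np.maximum(T, 1e-9))
    return T, float(np.sqrt(sq)), bool(nullity > n_comp)
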