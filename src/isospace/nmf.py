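"""Non-negative matrix factorization core, ``Y ≈ W·H``.

Multiplicative (Lee–Seung) updates for the Frobenius objective, run for a
fixed iteration budget (3000 by default) with a seedable uniform random
initialization.  The per-iteration loss trace is recorded so that the
theoretical monotone non-increase of the objective can be verified, and the
best of ``n_restarts`` independent initializations is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ValidationError

DEFAULT_N_ITER = 3000
_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray  # (m, k), non-negative
    H: np.ndarray  # (k, n), non-negative
    loss: float  # final Frobenius loss ||Y - WH||_F
    loss_trace: np.ndarray  # loss after each iteration (best restart)
    seed_state: int | None  # restart index of the best run


def nmf_factorize(
    Y,
    k: int,
    n_iter: int = DEFAULT_N_ITER,
    n_restarts: int = 1,
    rng: np.random.Generator | None = None,
    tol: float | None = None,
) -> NMFResult:
    """Factorize a non-negative matrix at internal dimension ``k``.

    Parameters
    ----------
    tol : float, optional
        Relative loss-decrease tolerance for optional early stopping; by
        default the full iteration budget is spent.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValidationError("Y must be 2-dimensional")
    if np.any(Y < 0):
        raise ValidationError("Y must be non-negative")
    m, n = Y.shape
    if not 1 <= k <= min(m, n):
        raise ValidationError(f"k={k} out of range for a {m}x{n} matrix")
    rng = np.random.default_rng(rng)
    init_scale = np.sqrt(max(Y.mean(), _EPS) / k)

    best: NMFResult | None = None
    for restart in range(max(n_restarts, 1)):
        W = rng.uniform(size=(m, k)) * init_scale
        H = rng.uniform(size=(k, n)) * init_scale
        trace = np.empty(n_iter)
        prev = np.inf
        stop_at = n_iter
        for it in range(n_iter):
            H *= (W.T @ Y) / (W.T @ W @ H + _EPS)
            W *= (Y @ H.T) / (W @ (H @ H.T) + _EPS)
            loss = np.linalg.norm(Y - W @ H)
            if not np.isfinite(loss):
                raise ValidationError(
                    f"NMF loss became non-finite at iteration {it} "
                    f"(k={k}, restart {restart})"
                )
            trace[it] = loss
            if tol is not None and prev - loss <= tol * max(prev, _EPS):
                stop_at = it + 1
                break
            prev = loss
        result = NMFResult(W, H, float(trace[stop_at - 1]), trace[:stop_at], restart)
        if best is None or result.loss < best.loss:
            best = result
    return best
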